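# dabsms

Self-supervised atlas-based segmentation of 3D volumes by deformation-field
regression. A convolutional U-Net maps a single-channel target volume to a
dense 3-channel displacement field on the atlas grid; training needs no
per-case labels and is driven by a composite loss:

- **cc** — global cross-correlation similarity between the pulled-back target
  and the atlas image,
- **grad / wgrad** — mean squared gradient of the displacement field,
  optionally weighted toward the atlas-segmentation boundary via a signed
  Euclidean distance map (weights clamped to [0.5, 1.0] between 1 and 4 mm),
- **ms** — a region-variance (piecewise-constant / Mumford–Shah style) term:
  the sum of foreground and background intensity variances of the warped
  target under the atlas mask.

Segmentations are obtained by transferring the atlas mask (fixed-point field
inversion + nearest-neighbor sampling) and the atlas surface mesh (vertex
transport) into target space, and are scored with Dice and the symmetric
95th-percentile Hausdorff distance, with optional exclusion regions and
paired t-tests.

Everything runs on plain NumPy/SciPy — the network, its backpropagation and
all loss gradients are implemented in-repo (no GPU or autodiff framework
required), so the full pipeline works on a single CPU.

## Package layout

| module | contents |
| --- | --- |
| `dabsms.volumes` | `ImageVolume`/`MaskVolume`/`AtlasBundle`, NIfTI I/O, intensity windowing, centroid cube cropping with mean fill |
| `dabsms.warp` | displacement fields, pull-back warping, point/surface transport, field inversion, random smooth fields, gradient maps |
| `dabsms.losses` | cc / grad / wgrad / ms terms with analytic gradients, distance & weight maps, named weight presets |
| `dabsms.nn`, `dabsms.network` | 3D U-Net (4 levels, 3 encoder + 3 decoder blocks, near-zero final layer) with hand-written backprop |
| `dabsms.training` | seeded training loop, greedy two-stage weight sweep, n-trial median protocol |
| `dabsms.evaluation` | Dice, 95HD, exclusion handling, paired t-test, cohort evaluation |
| `dabsms.synthetic` | phantom atlas + deformed-cohort generator with ground-truth masks and fields |

## CLI

```bash
dabsms synth --spec phantom.json --out data/ --seed 1     # synthetic atlas + cohort
dabsms preprocess --atlas a.nii.gz --atlas-mask m.nii.gz \
    --targets vols/ --out prep/ --side 64 --voxel-size 0.30
dabsms train --config train.json --data data/ --out run/
dabsms segment --model run/model.npz --target data/case000.nii.gz \
    --atlas-mask data/atlas_mask.nii.gz --out-mask pred.nii.gz
dabsms evaluate --pred-dir preds/ --gt-dir gts/ --out metrics.csv
dabsms sweep --config sweep.json --data data/ --out sweep.csv
```

Training config example (`train.json`):

```json
{
  "train": {"seed": 1, "epochs": 25, "learning_rate": 1e-3, "weights": "iac"},
  "network": {"levels": 4, "base_channels": 16},
  "max_steps": 400
}
```

Weight presets: `vxm` (cc + 0.5 grad), `iac` (cc + 0.5 grad + 0.5 ms),
`segthor` (cc + grad + 0.5 ms), `hkits21` (cc + 2.0 wgrad + 0.5 ms); custom
dicts like `{"cc": 1.0, "grad": 0.5, "ms": 0.5}` also work.

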