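"""Segmentation-quality metrics and cohort evaluation.

Dice is computed on voxels; the 95th-percentile Hausdorff distance is
computed on surface-mesh vertices, pooling both directed nearest-vertex
distance sets before taking the percentile (linear interpolation).  An
optional exclusion mask removes voxels/vertices from both prediction and
ground truth before either metric is computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from .volumes import AtlasBundle, MaskVolume
from .warp import SurfaceMesh, extract_surface, transform_points, transfer_mask

__all__ = ["MetricsResult", "dice", "hd95", "paired_ttest", "evaluate_cohort", "summarize"]


@dataclass
class MetricsResult:
    case_id: str
    dice: float
    hd95: float
    flags: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.dice <= 1.0):
            raise ValueError(f"dice must be in [0, 1], got {self.dice}")
        if self.hd95 < 0:
            raise ValueError(f"hd95 must be >= 0, got {self.hd95}")


def dice(pred: MaskVolume, gt: MaskVolume, exclusion: Optional[MaskVolume] = None) -> float:
    """2|P∩G| / (|P| + |G|) over voxels outside the exclusion mask."""
    if pred.shape != gt.shape:
        raise ValueError("prediction and ground truth grids differ")
    p = pred.voxels.astype(bool)
    g = gt.voxels.astype(bool)
    if exclusion is not None:
        if exclusion.shape != gt.shape:
            raise ValueError("exclusion mask grid differs")
        keep = ~exclusion.voxels.astype(bool)
        p = p & keep
        g = g & keep
    n_g = int(g.sum())
    if n_g == 0:
        raise ValueError("ground truth is empty after exclusion")
    n_p = int(p.sum())
    inter = int((p & g).sum())
    return 2.0 * inter / (n_p + n_g)


def _filter_vertices(verts: np.ndarray, exclusion: Optional[MaskVolume]) -> np.ndarray:
    if exclusion is None:
        return verts
    idx = np.clip(np.rint(verts), 0, np.asarray(exclusion.shape) - 1).astype(np.intp)
    inside = exclusion.voxels[idx[:, 0], idx[:, 1], idx[:, 2]].astype(bool)
    return verts[~inside]


def hd95(
    pred_surface: SurfaceMesh,
    gt_surface: SurfaceMesh,
    exclusion: Optional[MaskVolume] = None,
    spacing: float | Sequence[float] = 1.0,
) -> float:
    """Symmetric 95th-percentile vertex-to-nearest-vertex distance, in mm."""
    sp = np.atleast_1d(np.asarray(spacing, dtype=np.float64))
    if sp.size == 1:
        sp = np.repeat(sp, 3)
    pv = _filter_vertices(pred_surface.vertices, exclusion) * sp
    gv = _filter_vertices(gt_surface.vertices, exclusion) * sp
    if len(pv) == 0 or len(gv) == 0:
        raise ValueError("a surface is empty after exclusion filtering")
    d_pg = cKDTree(gv).query(pv)[0]
    d_gp = cKDTree(pv).query(gv)[0]
    pooled = np.concatenate([d_pg, d_gp])
    return float(np.percentile(pooled, 95.0))


def paired_ttest(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided dependent t-test for paired samples on a - b."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length samples of length >= 2")
    diffs = a - b
    if np.allclose(diffs, diffs[0]):
        raise ValueError("t statistic undefined: paired differences have zero variance")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def summarize(results: Sequence) -> dict:
    """Cohort summary in median / standard-deviation form."""
    def get(r, k):
        return getattr(r, k) if hasattr(r, k) else r[k]

    d = np.array([get(r, "dice") for r in results], dtype=np.float64)
    h = np.array([get(r, "hd95") for r in results], dtype=np.float64)
    return {
        "n": len(results),
        "dice_median": float(np.median(d)),
        "dice_sd": float(d.std(ddof=0)),
        "hd95_median": float(np.median(h)),
        "hd95_sd": float(h.std(ddof=0)),
        "per_case": list(results),
    }


def evaluate_cohort(model, cohort, atlas: AtlasBundle) -> dict:
    """Predict a field per case, transfer mask + surface, score vs. ground truth.

    ``model`` is anything with the DeformationModel forward contract (a
    zero-field mock reproduces the affine baseline).  Cohort cases need
    ``target`` and ``gt_mask`` attributes.
    """
    from .network import predict_field

    atlas_surface = extract_surface(atlas.transfer_mask)
    voxel = atlas.grid.voxel_size
    results = []
    for case in cohort:
        f = predict_field(model, case.target)
        tr = transfer_mask(atlas.transfer_mask, f)
        pred_vertices = transform_points(atlas_surface.vertices, f)
        pred_surface = SurfaceMesh(vertices=pred_vertices, faces=atlas_surface.faces)
        gt_surface = extract_surface(case.gt_mask)
        d = dice(tr.mask, case.gt_mask, exclusion=atlas.exclusion_mask)
        h = hd95(pred_surface, gt_surface, exclusion=atlas.exclusion_mask, spacing=voxel)
        results.append(
            MetricsResult(
                case_id=getattr(case, "case_id", ""),
                dice=d,
                hd95=h,
                flags={
                    "exclusion_applied": atlas.exclusion_mask is not None,
                    "inverse_field_warning": not tr.converged,
                },
            )
        )
    return summarize(results)
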