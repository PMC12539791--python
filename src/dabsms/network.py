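"""Deformation-regressing 3D U-Net: one scalar volume in, 3-channel field out.

Topology: an initial feature-extraction convolution, then ``levels - 1``
encoder levels (max-pool + conv) and the same number of decoder levels
(trilinear upsample + skip concatenation + conv), and a final convolution
to 3 channels.  The final layer is initialized near zero so an untrained
model predicts (approximately) the identity transform.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .volumes import CubeGrid, ImageVolume
from .warp import DisplacementField

__all__ = ["UNetSpec", "DeformationModel", "build_model", "predict_field", "param_count", "save_model", "load_model"]

_FINAL_INIT_SCALE = 1e-5


@dataclass(frozen=True)
class UNetSpec:
    levels: int = 4
    base_channels: int = 16
    channel_growth: int = 2
    kernel: int = 3
    activation: str = "leaky_relu"
    leaky_slope: float = 0.2
    final_channels: int = 3

    def __post_init__(self):
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if self.kernel != 3:
            raise ValueError("only 3x3x3 kernels are supported")
        if self.activation != "leaky_relu":
            raise ValueError("only leaky_relu is supported")
        if self.final_channels != 3:
            raise ValueError("the model regresses a 3-channel displacement field")

    @property
    def encoder_blocks(self) -> int:
        return self.levels - 1

    @property
    def decoder_blocks(self) -> int:
        return self.levels - 1

    @property
    def down_factor(self) -> int:
        return 2 ** (self.levels - 1)

    def channels(self) -> list[int]:
        return [self.base_channels * self.channel_growth**l for l in range(self.levels)]


def param_count(spec: UNetSpec) -> int:
    """Number of trainable parameters — a pure function of the spec."""
    ch = spec.channels()
    k = 27
    n = (1 * k + 1) * ch[0]  # stem
    for l in range(1, spec.levels):
        n += (ch[l - 1] * k + 1) * ch[l]  # encoder convs
    for l in range(spec.levels - 2, -1, -1):
        n += ((ch[l + 1] + ch[l]) * k + 1) * ch[l]  # decoder convs (after concat)
    n += (ch[0] * k + 1) * spec.final_channels  # head
    return n


class DeformationModel:
    """U-Net over numpy arrays with explicit forward/backward passes."""

    def __init__(self, spec: UNetSpec, seed: int = 0, dtype=np.float32):
        self.spec = spec
        self.seed = seed
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(seed)
        ch = spec.channels()
        self.stem = nn.Conv3d(1, ch[0], rng)
        self.enc = [nn.Conv3d(ch[l - 1], ch[l], rng) for l in range(1, spec.levels)]
        self.dec = [nn.Conv3d(ch[l + 1] + ch[l], ch[l], rng) for l in range(spec.levels - 2, -1, -1)]
        self.head = nn.Conv3d(ch[0], spec.final_channels, rng, weight_scale=_FINAL_INIT_SCALE)
        self._convs = [self.stem, *self.enc, *self.dec, self.head]
        if self.dtype != np.float32:
            for conv in self._convs:
                conv.weight = conv.weight.astype(self.dtype)
                conv.bias = conv.bias.astype(self.dtype)
                conv.grad_weight = conv.grad_weight.astype(self.dtype)
                conv.grad_bias = conv.grad_bias.astype(self.dtype)
        n_act = 1 + len(self.enc) + len(self.dec)
        self._acts = [nn.LeakyReLU(spec.leaky_slope) for _ in range(n_act)]
        self._cache: dict = {}

    # -- parameter plumbing -------------------------------------------------

    def parameters(self) -> list[np.ndarray]:
        return [p for conv in self._convs for p in conv.params]

    def gradients(self) -> list[np.ndarray]:
        return [g for conv in self._convs for g in conv.grads]

    def zero_grad(self) -> None:
        for g in self.gradients():
            g[...] = 0.0

    def clear_caches(self) -> None:
        """Drop the backward caches (inference-only use; saves memory)."""
        for conv in self._convs:
            conv._cols_cache = None
        self._cache = {}

    def checksum(self) -> float:
        return float(sum(np.abs(p.astype(np.float64)).sum() for p in self.parameters()))

    # -- forward / backward -------------------------------------------------

    def _check_side(self, side: int) -> None:
        if side % self.spec.down_factor:
            raise ValueError(
                f"input side {side} is not divisible by the down-sampling factor {self.spec.down_factor}"
            )

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (1, S, S, S) float32 -> (3, S, S, S) float32."""
        if x.ndim != 4 or x.shape[0] != 1:
            raise ValueError(f"expected input of shape (1, S, S, S), got {x.shape}")
        self._check_side(x.shape[1])
        acts = iter(self._acts)
        cache = self._cache = {"pool": [], "pre_pool_shapes": [], "acts": []}

        act = next(acts)
        a = act.forward(self.stem.forward(x.astype(self.dtype)))
        cache["acts"].append(act)
        skips = [a]
        for l, conv in enumerate(self.enc):
            cache["pre_pool_shapes"].append(a.shape)
            a, idx = nn.maxpool2(a)
            cache["pool"].append(idx)
            act = next(acts)
            a = act.forward(conv.forward(a))
            cache["acts"].append(act)
            if l < len(self.enc) - 1:
                skips.append(a)
        cache["skips"] = skips
        cache["concat_splits"] = []
        for l, conv in enumerate(self.dec):
            a = nn.upsample2(a)
            skip = skips[-(l + 1)]
            cache["concat_splits"].append(a.shape[0])
            a = np.concatenate([a, skip], axis=0)
            act = next(acts)
            a = act.forward(conv.forward(a))
            cache["acts"].append(act)
        return self.head.forward(a)

    def backward(self, grad_out: np.ndarray) -> None:
        """Accumulate parameter gradients given dL/d(output field)."""
        cache = self._cache
        g = self.head.backward(grad_out.astype(self.dtype))
        skip_grads: list[np.ndarray] = []
        acts = cache["acts"]
        ai = len(acts) - 1
        for l in range(len(self.dec) - 1, -1, -1):
            g = self.dec[l].backward(acts[ai].backward(g))
            ai -= 1
            split = cache["concat_splits"][l]
            skip_grads.append(g[split:])
            g = nn.upsample2_adjoint(np.ascontiguousarray(g[:split]))
        # the reversed decoder walk visits the shallowest skip first, so
        # skip_grads[j] already pairs with skips[j] (stem first)
        for l in range(len(self.enc) - 1, -1, -1):
            if l < len(self.enc) - 1:
                g = g + skip_grads[l + 1]
            g = self.enc[l].backward(acts[ai].backward(g))
            ai -= 1
            g = nn.maxpool2_adjoint(g, cache["pool"][l], cache["pre_pool_shapes"][l])
        g = g + skip_grads[0]
        self.stem.backward(acts[ai].backward(g))


def build_model(spec: UNetSpec | None = None, seed: int = 0) -> DeformationModel:
    """Deterministically initialized model; the final layer is near zero."""
    return DeformationModel(spec or UNetSpec(), seed=seed)


def predict_field(model: DeformationModel, target: ImageVolume) -> DisplacementField:
    side = target.shape[0]
    if target.shape != (side,) * 3:
        raise ValueError(f"expected a cubic volume, got {target.shape}")
    x = np.asarray(target.voxels, dtype=np.float32)[None]
    u = model.forward(x)
    if hasattr(model, "clear_caches"):  # mock models in tests may lack it
        model.clear_caches()
    grid = CubeGrid(side=side, voxel_size=target.spacing[0])
    return DisplacementField(u=u.astype(np.float64), grid=grid)


def save_model(model: DeformationModel, path) -> None:
    arrays = {f"p{i}": p for i, p in enumerate(model.parameters())}
    np.savez(path, spec=json.dumps(asdict(model.spec)), seed=model.seed, **arrays)


def load_model(path) -> DeformationModel:
    with np.load(path, allow_pickle=False) as data:
        spec = UNetSpec(**json.loads(str(data["spec"])))
        model = DeformationModel(spec, seed=int(data["seed"]))
        for i, p in enumerate(model.parameters()):
            p[...] = data[f"p{i}"]
    return model
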