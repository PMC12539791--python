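"""Loss terms for self-supervised deformation training.

All terms operate on dense numpy grids and come with analytic gradients
(``*_grad`` helpers) with respect to the warped image or the displacement
field, so the training loop can backpropagate without an autodiff
framework.

Terms:

* ``loss_cc``     — 0.5 - r/2 with r the global Pearson correlation between
  the pulled-back target and the atlas image.
* ``loss_grad``   — mean squared gradient magnitude of the displacement.
* ``loss_wgrad``  — same, weighted by a boundary-distance weight map W
  (W enters inside the squared norm, i.e. contributes W^2).
* ``loss_ms``     — sum of foreground and background intensity variances of
  the pulled-back target under the atlas mask (region-variance /
  piecewise-constant energy).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import distance_transform_edt

from .volumes import AtlasBundle, ImageVolume, MaskVolume
from .warp import DisplacementField, _central_diff, _central_diff_adjoint, grad_map

__all__ = [
    "DistanceMap",
    "WeightMap",
    "MSStats",
    "LossWeights",
    "PRESETS",
    "loss_cc",
    "loss_cc_grad",
    "signed_distance",
    "weight_map",
    "loss_grad",
    "loss_grad_grad",
    "loss_wgrad",
    "loss_wgrad_grad",
    "ms_stats",
    "loss_ms",
    "loss_ms_grad",
    "total_loss",
    "total_loss_grad",
]


@dataclass(frozen=True)
class DistanceMap:
    """Signed Euclidean distance to the mask boundary, mm; negative inside."""

    values: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=np.float64))


@dataclass(frozen=True)
class WeightMap:
    """Dimensionless boundary weights, every value in [0.5, 1.0]."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.min() < 0.5 - 1e-12 or v.max() > 1.0 + 1e-12:
            raise ValueError("weight map values must lie in [0.5, 1.0]")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class MSStats:
    """Masked means and population variances of a warped image."""

    mu_int: float
    mu_ext: float
    var_int: float
    var_ext: float

    def __post_init__(self):
        if self.var_int < 0 or self.var_ext < 0:
            raise ValueError("variances must be >= 0")


@dataclass(frozen=True)
class LossWeights:
    """Coefficients of the combined loss; absent terms are 0."""

    w_cc: float = 1.0
    w_grad: float = 0.0
    w_wgrad: float = 0.0
    w_ms: float = 0.0

    def __post_init__(self):
        for name in ("w_cc", "w_grad", "w_wgrad", "w_ms"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.w_cc == self.w_grad == self.w_wgrad == self.w_ms == 0:
            raise ValueError("at least one weight must be > 0")


#: Named weight presets (best per-dataset combinations).
PRESETS = {
    "vxm": LossWeights(w_cc=1.0, w_grad=0.5),
    "iac": LossWeights(w_cc=1.0, w_grad=0.5, w_ms=0.5),
    "segthor": LossWeights(w_cc=1.0, w_grad=1.0, w_ms=0.5),
    "hkits21": LossWeights(w_cc=1.0, w_wgrad=2.0, w_ms=0.5),
}


def _vox(x) -> np.ndarray:
    if isinstance(x, (ImageVolume, MaskVolume)):
        return np.asarray(x.voxels, dtype=np.float64)
    return np.asarray(x, dtype=np.float64)


# ---------------------------------------------------------------------------
# Image similarity
# ---------------------------------------------------------------------------

def loss_cc(warped, atlas_image) -> float:
    """0.5 - r/2, r = global Pearson correlation of the two volumes.

    0 at a perfect positive linear relation, 1 at a perfect negative one.
    """
    w = _vox(warped).ravel()
    a = _vox(atlas_image).ravel()
    if w.shape != a.shape:
        raise ValueError("warped and atlas grids differ")
    wc = w - w.mean()
    ac = a - a.mean()
    nw = np.linalg.norm(wc)
    na = np.linalg.norm(ac)
    if nw == 0 or na == 0:
        raise ValueError("correlation undefined for a constant volume")
    r = float(wc @ ac / (nw * na))
    return 0.5 - 0.5 * r


def loss_cc_grad(warped, atlas_image) -> np.ndarray:
    """d(loss_cc)/d(warped), same shape as the warped volume."""
    w = _vox(warped)
    a = _vox(atlas_image)
    shape = w.shape
    wc = (w - w.mean()).ravel()
    ac = (a - a.mean()).ravel()
    nw = np.linalg.norm(wc)
    na = np.linalg.norm(ac)
    if nw == 0 or na == 0:
        raise ValueError("correlation undefined for a constant volume")
    r = wc @ ac / (nw * na)
    # dr/dw = ac/(nw*na) - r * wc/nw^2  (both terms are mean-free)
    dr = ac / (nw * na) - r * wc / (nw * nw)
    return (-0.5 * dr).reshape(shape)


# ---------------------------------------------------------------------------
# Distance map and boundary weighting
# ---------------------------------------------------------------------------

def signed_distance(mask: MaskVolume) -> DistanceMap:
    """Signed Euclidean distance map of a binary mask, in mm.

    Distance from each voxel center to the nearest voxel center of the
    opposite class; negative on foreground voxels, positive on background.
    """
    m = mask.voxels.astype(bool)
    if not m.any():
        raise ValueError("mask is empty")
    if m.all():
        raise ValueError("mask covers the whole grid")
    sp = mask.spacing
    d_to_fg = distance_transform_edt(~m, sampling=sp)  # >0 outside, 0 inside
    d_to_bg = distance_transform_edt(m, sampling=sp)  # >0 inside, 0 outside
    return DistanceMap(values=d_to_fg - d_to_bg, spacing=sp)


def weight_map(dist: DistanceMap, t_lower: float = 1.0, t_upper: float = 4.0) -> WeightMap:
    """W = 0.5 + (tU - max(tL, min(tU, |D|))) / (2 (tU - tL)), elementwise."""
    if not (0 <= t_lower < t_upper):
        raise ValueError(f"thresholds must satisfy 0 <= tL < tU, got ({t_lower}, {t_upper})")
    d = np.abs(dist.values)
    clamped = np.maximum(t_lower, np.minimum(t_upper, d))
    return WeightMap(values=0.5 + (t_upper - clamped) / (2.0 * (t_upper - t_lower)))


# ---------------------------------------------------------------------------
# Smoothness
# ---------------------------------------------------------------------------

def loss_grad(field: DisplacementField) -> float:
    """Mean squared gradient magnitude: (1/(3N)) sum_vox grad_map."""
    n = np.prod(field.grid.shape)
    return float(grad_map(field).sum() / (3.0 * n))


def loss_grad_grad(field: DisplacementField) -> np.ndarray:
    """d(loss_grad)/du, shape (3, S, S, S)."""
    n = np.prod(field.grid.shape)
    out = np.zeros_like(field.u)
    for c in range(3):
        for axis in range(3):
            d = _central_diff(field.u[c], axis)
            out[c] += _central_diff_adjoint(2.0 * d, axis)
    return out / (3.0 * n)


def loss_wgrad(field: DisplacementField, w: WeightMap) -> float:
    """(1/(3N)) sum_vox W^2 * grad_map (W inside the squared norm)."""
    if w.values.shape != field.grid.shape:
        raise ValueError("weight map grid differs from the field grid")
    n = np.prod(field.grid.shape)
    return float((w.values**2 * grad_map(field)).sum() / (3.0 * n))


def loss_wgrad_grad(field: DisplacementField, w: WeightMap) -> np.ndarray:
    if w.values.shape != field.grid.shape:
        raise ValueError("weight map grid differs from the field grid")
    n = np.prod(field.grid.shape)
    w2 = w.values**2
    out = np.zeros_like(field.u)
    for c in range(3):
        for axis in range(3):
            d = _central_diff(field.u[c], axis)
            out[c] += _central_diff_adjoint(2.0 * w2 * d, axis)
    return out / (3.0 * n)


# ---------------------------------------------------------------------------
# Region variance (piecewise-constant energy)
# ---------------------------------------------------------------------------

def ms_stats(warped, ms_mask: MaskVolume) -> MSStats:
    """Masked means and population variances over foreground/background."""
    w = _vox(warped)
    m = ms_mask.voxels.astype(bool)
    if w.shape != m.shape:
        raise ValueError("warped and mask grids differ")
    n_int = int(m.sum())
    n_ext = int((~m).sum())
    if n_int == 0 or n_ext == 0:
        raise ValueError("region-variance statistics need nonempty foreground and background")
    fg = w[m]
    bg = w[~m]
    mu_int = float(fg.mean())
    mu_ext = float(bg.mean())
    return MSStats(
        mu_int=mu_int,
        mu_ext=mu_ext,
        var_int=float(((fg - mu_int) ** 2).mean()),
        var_ext=float(((bg - mu_ext) ** 2).mean()),
    )


def loss_ms(stats: MSStats) -> float:
    """Sum of intra-class variances."""
    return stats.var_int + stats.var_ext


def loss_ms_grad(warped, ms_mask: MaskVolume) -> np.ndarray:
    """d(var_int + var_ext)/d(warped).

    The mean terms drop out because sum (w - mu) over each region is 0.
    """
    w = _vox(warped)
    m = ms_mask.voxels.astype(bool)
    n_int = m.sum()
    n_ext = (~m).sum()
    if n_int == 0 or n_ext == 0:
        raise ValueError("region-variance statistics need nonempty foreground and background")
    mu_int = w[m].mean()
    mu_ext = w[~m].mean()
    out = np.zeros_like(w)
    out[m] = 2.0 * (w[m] - mu_int) / n_int
    out[~m] = 2.0 * (w[~m] - mu_ext) / n_ext
    return out


# ---------------------------------------------------------------------------
# Combined loss
# ---------------------------------------------------------------------------

def resolve_weights(weights) -> LossWeights:
    if isinstance(weights, LossWeights):
        return weights
    if isinstance(weights, str):
        try:
            return PRESETS[weights]
        except KeyError:
            raise KeyError(f"unknown preset {weights!r}; available: {sorted(PRESETS)}") from None
    if isinstance(weights, dict):
        return LossWeights(
            w_cc=float(weights.get("cc", weights.get("w_cc", 0.0))),
            w_grad=float(weights.get("grad", weights.get("w_grad", 0.0))),
            w_wgrad=float(weights.get("wgrad", weights.get("w_wgrad", 0.0))),
            w_ms=float(weights.get("ms", weights.get("w_ms", 0.0))),
        )
    raise TypeError(f"cannot interpret weights: {weights!r}")


def total_loss(warped, bundle: AtlasBundle, field: DisplacementField, weights) -> tuple[float, dict]:
    """Weighted sum of the active terms plus an unweighted breakdown.

    Terms with zero weight are not evaluated (the region-variance
    statistics in particular are skipped entirely when w_ms == 0).
    """
    w = resolve_weights(weights)
    components: dict[str, float] = {}
    total = 0.0
    if w.w_cc > 0:
        components["cc"] = loss_cc(warped, bundle.image)
        total += w.w_cc * components["cc"]
    if w.w_grad > 0:
        components["grad"] = loss_grad(field)
        total += w.w_grad * components["grad"]
    if w.w_wgrad > 0:
        wm = bundle.ensure_weight_map()
        components["wgrad"] = loss_wgrad(field, wm)
        total += w.w_wgrad * components["wgrad"]
    if w.w_ms > 0:
        components["ms"] = loss_ms(ms_stats(warped, bundle.ms_mask))
        total += w.w_ms * components["ms"]
    return total, components


def total_loss_grad(warped, bundle: AtlasBundle, field: DisplacementField, weights):
    """Combined loss, breakdown, and gradients (d/d warped, d/d u)."""
    w = resolve_weights(weights)
    total, components = total_loss(warped, bundle, field, w)
    d_warped = np.zeros(bundle.image.shape)
    d_u = np.zeros_like(field.u)
    if w.w_cc > 0:
        d_warped += w.w_cc * loss_cc_grad(warped, bundle.image)
    if w.w_ms > 0:
        d_warped += w.w_ms * loss_ms_grad(warped, bundle.ms_mask)
    if w.w_grad > 0:
        d_u += w.w_grad * loss_grad_grad(field)
    if w.w_wgrad > 0:
        d_u += w.w_wgrad * loss_wgrad_grad(field, bundle.ensure_weight_map())
    return total, components, d_warped, d_u
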