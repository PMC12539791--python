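"""Volume and mask domain types, NIfTI I/O, and preprocessing.

Coordinate convention used throughout the package: 0-based voxel indices,
a voxel's coordinate is its center, and world = origin + index * spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "ImageVolume",
    "MaskVolume",
    "AtlasBundle",
    "IntensityWindow",
    "CubeGrid",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "normalize_intensity",
    "denormalize_intensity",
    "estimate_window",
    "mask_centroid",
    "crop_to_cube",
    "crop_mask_to_cube",
]


def _as_triplet(x) -> tuple[float, float, float]:
    t = tuple(float(v) for v in np.atleast_1d(x).ravel())
    if len(t) == 1:
        t = t * 3
    if len(t) != 3:
        raise ValueError(f"expected 3 components, got {len(t)}")
    return t  # type: ignore[return-value]


@dataclass(frozen=True)
class ImageVolume:
    """A 3D scalar grid with physical spacing (mm) and origin (mm)."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise ValueError(f"voxels must be 3D, got ndim={vox.ndim}")
        if any(s < 2 for s in vox.shape):
            raise ValueError(f"grid dimensions must be >= 2 per axis, got {vox.shape}")
        if not np.all(np.isfinite(vox)):
            raise ValueError("voxel values must be finite")
        sp = _as_triplet(self.spacing)
        if any(s <= 0 for s in sp):
            raise ValueError(f"spacing components must be > 0, got {sp}")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing", sp)
        object.__setattr__(self, "origin", _as_triplet(self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def with_voxels(self, voxels: np.ndarray) -> "ImageVolume":
        return replace(self, voxels=voxels)


@dataclass(frozen=True)
class MaskVolume:
    """A binary (0/1) 3D grid sharing the geometry conventions of ImageVolume."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise ValueError(f"mask must be 3D, got ndim={vox.ndim}")
        uniq = np.unique(vox)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"mask values must be 0/1, got {uniq[:10]}")
        object.__setattr__(self, "voxels", vox.astype(np.uint8))
        object.__setattr__(self, "spacing", _as_triplet(self.spacing))
        object.__setattr__(self, "origin", _as_triplet(self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def foreground_count(self) -> int:
        return int(self.voxels.sum())

    def same_grid_as(self, other) -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)


@dataclass(frozen=True)
class IntensityWindow:
    """Affine intensity normalization window (e.g. in HU)."""

    imin: float
    imax: float

    def __post_init__(self):
        if not self.imax > self.imin:
            raise ValueError(f"imax ({self.imax}) must exceed imin ({self.imin})")


@dataclass(frozen=True)
class CubeGrid:
    """Isotropic cubic sampling grid: ``side`` voxels at ``voxel_size`` mm."""

    side: int = 64
    voxel_size: float = 1.0

    def __post_init__(self):
        if self.side < 8:
            raise ValueError(f"side must be >= 8, got {self.side}")
        if self.voxel_size <= 0:
            raise ValueError(f"voxel_size must be > 0, got {self.voxel_size}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.side,) * 3

    @property
    def spacing(self) -> tuple[float, float, float]:
        return (self.voxel_size,) * 3


@dataclass
class AtlasBundle:
    """Atlas image plus its masks and cached distance/weight maps.

    ``ms_mask`` defaults to ``transfer_mask`` when no tissue-based variant
    is supplied.  The distance and weight maps are derived lazily (they
    depend only on the transfer mask, which is constant during training).
    """

    image: ImageVolume
    transfer_mask: MaskVolume
    ms_mask: Optional[MaskVolume] = None
    exclusion_mask: Optional[MaskVolume] = None
    distance_map: object = None  # losses.DistanceMap, cached
    weight_map: object = None  # losses.WeightMap, cached

    def __post_init__(self):
        if self.ms_mask is None:
            self.ms_mask = self.transfer_mask
        for name in ("transfer_mask", "ms_mask", "exclusion_mask"):
            m = getattr(self, name)
            if m is not None and m.shape != self.image.shape:
                raise ValueError(f"{name} grid {m.shape} != image grid {self.image.shape}")

    @property
    def grid(self) -> CubeGrid:
        side = self.image.shape[0]
        return CubeGrid(side=side, voxel_size=self.image.spacing[0])

    def ensure_weight_map(self, t_lower: float = 1.0, t_upper: float = 4.0):
        """Compute and cache the signed distance map and boundary weight map."""
        from . import losses  # local import to avoid a cycle

        if self.weight_map is None:
            if self.distance_map is None:
                self.distance_map = losses.signed_distance(self.transfer_mask)
            self.weight_map = losses.weight_map(self.distance_map, t_lower, t_upper)
        return self.weight_map


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _affine_from(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def read_volume(path) -> ImageVolume:
    """Read a scalar 3D NIfTI volume."""
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
    except Exception as exc:  # pragma: no cover - nibabel error classes vary
        raise ValueError(f"cannot read NIfTI volume from {path}: {exc}") from exc
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D scalar volume, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return ImageVolume(voxels=data, spacing=spacing, origin=origin)


def write_volume(vol: ImageVolume, path) -> None:
    img = nib.Nifti1Image(np.asarray(vol.voxels, dtype=np.float64), _affine_from(vol.spacing, vol.origin))
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def read_mask(path) -> MaskVolume:
    vol = read_volume(path)
    return MaskVolume(voxels=(vol.voxels > 0.5).astype(np.uint8), spacing=vol.spacing, origin=vol.origin)


def write_mask(mask: MaskVolume, path) -> None:
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), _affine_from(mask.spacing, mask.origin))
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def normalize_intensity(vol: ImageVolume, window: IntensityWindow) -> ImageVolume:
    """Affine map v -> (v - imin) / (imax - imin).

    Values outside the window are retained (mapped below 0 / above 1), not
    clipped.
    """
    scale = window.imax - window.imin
    return vol.with_voxels((vol.voxels - window.imin) / scale)


def denormalize_intensity(vol: ImageVolume, window: IntensityWindow) -> ImageVolume:
    scale = window.imax - window.imin
    return vol.with_voxels(vol.voxels * scale + window.imin)


def estimate_window(volumes: Sequence[ImageVolume], lo_pct: float = 1.0, hi_pct: float = 99.0) -> IntensityWindow:
    """Percentile-based window over the pooled intensity distribution.

    The normalization constants are a dataset-level choice; this helper is a
    robust default and is always overridable by an explicit window.
    """
    if len(volumes) == 0:
        raise ValueError("need at least one volume")
    if not (0 <= lo_pct < hi_pct <= 100):
        raise ValueError(f"percentiles must satisfy 0 <= lo < hi <= 100, got ({lo_pct}, {hi_pct})")
    pooled = np.concatenate([np.ravel(v.voxels) for v in volumes])
    lo, hi = np.percentile(pooled, [lo_pct, hi_pct])
    if hi <= lo:
        raise ValueError("degenerate window: pooled intensities have no spread at these percentiles")
    return IntensityWindow(imin=float(lo), imax=float(hi))


def mask_centroid(mask: MaskVolume) -> np.ndarray:
    """Arithmetic mean of foreground voxel index coordinates."""
    idx = np.argwhere(mask.voxels > 0)
    if idx.shape[0] == 0:
        raise ValueError("cannot compute the centroid of an empty mask")
    return idx.mean(axis=0)


def _crop_coords(shape, spacing, center, grid: CubeGrid, affine: Optional[np.ndarray]):
    side = grid.side
    offs = (np.arange(side) - (side - 1) / 2.0) * grid.voxel_size
    # sample positions in source voxel-index units, per axis
    axes = [center[a] + offs / spacing[a] for a in range(3)]
    cc = np.meshgrid(*axes, indexing="ij")
    coords = np.stack([c.ravel() for c in cc])  # (3, side^3) index coords
    if affine is not None:
        affine = np.asarray(affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        world = coords * np.asarray(spacing)[:, None]
        world = affine[:3, :3] @ world + affine[:3, 3:4]
        coords = world / np.asarray(spacing)[:, None]
    return coords


def crop_to_cube(
    vol: ImageVolume,
    center,
    grid: CubeGrid,
    affine: Optional[np.ndarray] = None,
) -> ImageVolume:
    """Resample ``vol`` on an isotropic cube centered at ``center``.

    ``center`` is in the source grid's voxel-index frame.  Trilinear
    interpolation; samples falling outside the source extent receive the
    mean of the in-bounds samples of this crop.  An optional user-supplied
    4x4 ``affine`` (mm units, applied to sample positions) covers the case
    of inputs that are not yet aligned to the atlas.
    """
    coords = _crop_coords(vol.shape, vol.spacing, np.asarray(center, float), grid, affine)
    out = map_coordinates(np.asarray(vol.voxels, float), coords, order=1, mode="constant", cval=np.nan)
    inside = np.isfinite(out)
    if not inside.any():
        raise ValueError("crop lies entirely outside the source volume")
    if not inside.all():
        out[~inside] = out[inside].mean()
    return ImageVolume(
        voxels=out.reshape(grid.shape),
        spacing=grid.spacing,
        origin=(0.0, 0.0, 0.0),
    )


def crop_mask_to_cube(
    mask: MaskVolume,
    center,
    grid: CubeGrid,
    affine: Optional[np.ndarray] = None,
) -> MaskVolume:
    """Nearest-neighbor counterpart of :func:`crop_to_cube` for label data.

    Out-of-bounds samples become background.
    """
    coords = _crop_coords(mask.shape, mask.spacing, np.asarray(center, float), grid, affine)
    out = map_coordinates(mask.voxels.astype(np.float64), coords, order=0, mode="constant", cval=0.0)
    return MaskVolume(voxels=out.reshape(grid.shape).astype(np.uint8), spacing=grid.spacing)
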