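"""Phantom generator: atlas + deformed target cohorts with known ground truth.

The phantoms satisfy the statistical assumption of the region-variance
loss — a near-constant interior intensity distinguishable from the
background — so every module in the package can be exercised without any
external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .volumes import AtlasBundle, CubeGrid, ImageVolume, MaskVolume
from .warp import DisplacementField, invert_field, random_smooth_field, trilinear_sample, _identity_coords

__all__ = ["PhantomSpec", "CohortSpec", "CohortCase", "make_atlas", "make_cohort", "baseline_metrics"]


@dataclass(frozen=True)
class PhantomSpec:
    grid: CubeGrid = field(default_factory=lambda: CubeGrid(side=32, voxel_size=1.0))
    shape: Literal["ellipsoid", "bent-tube"] = "ellipsoid"
    semi_axes: tuple[float, float, float] | None = None  # voxels; default scaled to the grid
    interior_mean: float = 0.8
    exterior_mean: float = 0.2
    n_distractors: int = 0
    distractor_contrast: float = 0.3
    distractor_margin_mm: float = 4.0
    noise_sd: float = 0.02
    edge_smooth: float = 0.0  # voxels; Gaussian partial-volume blur of the image
    seed: int = 0

    def __post_init__(self):
        if abs(self.interior_mean - self.exterior_mean) <= 3.0 * self.noise_sd:
            raise ValueError("interior/exterior means must differ by more than 3 * noise_sd")

    def resolved_semi_axes(self) -> tuple[float, float, float]:
        if self.semi_axes is not None:
            return self.semi_axes
        s = self.grid.side
        return (0.30 * s, 0.22 * s, 0.26 * s)


@dataclass(frozen=True)
class CohortSpec:
    n_targets: int = 8
    amplitude: float = 3.0  # voxels, peak displacement magnitude
    smoothness: float = 6.0  # voxels, Gaussian scale of the random fields
    noise_sd: float = 0.02
    n_distractors: int = 0  # per-target background structures at random positions
    distractor_contrast: float = 0.3
    distractor_margin_mm: float = 4.0
    gamma_range: tuple[float, float] = (1.0, 1.0)  # per-target monotone intensity remap
    seed: int = 0


@dataclass
class CohortCase:
    target: ImageVolume
    gt_mask: MaskVolume
    gt_field: DisplacementField
    case_id: str = ""


def _ellipsoid_mask(grid: CubeGrid, center, semi_axes) -> np.ndarray:
    ii = _identity_coords(grid.shape)
    q = sum(((ii[a] - center[a]) / semi_axes[a]) ** 2 for a in range(3))
    return (q <= 1.0).astype(np.uint8)


def _bent_tube_mask(grid: CubeGrid, radius: float) -> np.ndarray:
    s = grid.side
    # quadratic arc through the cube, tube of constant radius around it
    t = np.linspace(0.0, 1.0, 200)
    cx = 0.25 * s + 0.5 * s * t
    cy = 0.5 * s + 0.18 * s * np.sin(np.pi * t)
    cz = 0.35 * s + 0.3 * s * t
    curve = np.stack([cx, cy, cz], axis=1)  # (200, 3)
    ii = _identity_coords(grid.shape).reshape(3, -1).T  # (N, 3)
    d2 = np.min(((ii[:, None, :] - curve[None, :, :]) ** 2).sum(-1), axis=1)
    return (d2 <= radius**2).reshape(grid.shape).astype(np.uint8)


def _check_margin(mask: np.ndarray, margin: int = 4) -> None:
    idx = np.argwhere(mask > 0)
    if idx.size == 0:
        raise ValueError("phantom mask is empty")
    lo = idx.min(axis=0)
    hi = idx.max(axis=0)
    shape = np.asarray(mask.shape)
    if (lo < margin).any() or (hi > shape - 1 - margin).any():
        raise ValueError(f"phantom shape must keep a >= {margin}-voxel margin to the cube border")


def make_atlas(spec: PhantomSpec) -> AtlasBundle:
    """Rasterize the analytic shape, paint intensities, add noise.

    Distractor structures (small bright ellipsoids) are kept at least
    ``distractor_margin_mm`` away from the shape boundary so the
    boundary-weight band only covers true boundary.
    """
    rng = np.random.default_rng(spec.seed)
    grid = spec.grid
    s = grid.side
    if spec.shape == "ellipsoid":
        mask = _ellipsoid_mask(grid, ((s - 1) / 2.0,) * 3, spec.resolved_semi_axes())
    elif spec.shape == "bent-tube":
        mask = _bent_tube_mask(grid, radius=0.12 * s)
    else:
        raise ValueError(f"unknown phantom shape {spec.shape!r}")
    _check_margin(mask)

    image = np.where(mask > 0, spec.interior_mean, spec.exterior_mean).astype(np.float64)

    if spec.n_distractors > 0:
        from scipy.ndimage import distance_transform_edt

        dist_mm = distance_transform_edt(mask == 0, sampling=grid.spacing)
        placed = 0
        attempts = 0
        while placed < spec.n_distractors and attempts < 200:
            attempts += 1
            c = rng.uniform(3, s - 4, size=3)
            ci = tuple(int(round(v)) for v in c)
            if dist_mm[ci] < spec.distractor_margin_mm + 2.0 * grid.voxel_size:
                continue
            axes = rng.uniform(1.5, 3.0, size=3)
            blob = _ellipsoid_mask(grid, c, axes).astype(bool)
            blob &= dist_mm > spec.distractor_margin_mm
            image[blob] = spec.exterior_mean + spec.distractor_contrast
            placed += 1

    if spec.edge_smooth > 0:
        from scipy.ndimage import gaussian_filter

        # partial-volume-style blur: the mask stays crisp, the image does not
        image = gaussian_filter(image, sigma=spec.edge_smooth, mode="nearest")

    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)

    vol = ImageVolume(voxels=image, spacing=grid.spacing)
    m = MaskVolume(voxels=mask, spacing=grid.spacing)
    return AtlasBundle(image=vol, transfer_mask=m)


def make_cohort(atlas: AtlasBundle, spec: CohortSpec) -> list[CohortCase]:
    """Forward-simulate targets so that pull_back(target, gt_field) ~ atlas.

    Each target is the atlas image resampled through the (approximate)
    inverse of a random smooth field, plus fresh noise; the ground-truth
    mask is the atlas transfer mask carried through the same mapping.

    Optional per-target distractors (small bright ellipsoids at positions
    that differ from case to case, kept ``distractor_margin_mm`` away from
    the deformed mask) emulate background anatomy that varies across
    patients: it misleads global image similarity but not the
    region-variance term.
    """
    grid = atlas.grid
    ident = _identity_coords(grid.shape)
    atlas_img = np.asarray(atlas.image.voxels, np.float64)
    atlas_mask = atlas.transfer_mask.voxels
    noise_rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 0xA5)))
    cases = []
    for k in range(spec.n_targets):
        fseed = int(np.random.SeedSequence((spec.seed, k)).generate_state(1)[0])
        gt_field = random_smooth_field(grid, amplitude=spec.amplitude, smoothness=spec.smoothness, seed=fseed)
        v, _, _ = invert_field(gt_field)
        coords = ident + v
        target = trilinear_sample(atlas_img, coords)
        idx = [np.clip(np.rint(coords[a]), 0, grid.shape[a] - 1).astype(np.intp) for a in range(3)]
        gt = atlas_mask[idx[0], idx[1], idx[2]]
        try:
            _check_margin(gt, margin=1)
        except ValueError as exc:
            raise ValueError(f"deformed mask of case {k} leaves the cube: {exc}") from exc
        g_lo, g_hi = spec.gamma_range
        if g_lo != 1.0 or g_hi != 1.0:
            # scanner-to-scanner style nonlinearity: monotone gamma remap of the
            # intensity range.  Homogeneous regions stay homogeneous (the
            # region-variance partition is preserved) but blurred-edge profiles
            # shift, so plain intensity similarity mislocalizes the boundary.
            gamma = noise_rng.uniform(g_lo, g_hi)
            lo, hi = target.min(), target.max()
            if hi > lo:
                target = lo + (hi - lo) * ((target - lo) / (hi - lo)) ** gamma
        if spec.n_distractors > 0:
            from scipy.ndimage import distance_transform_edt

            s = grid.side
            dist_mm = distance_transform_edt(gt == 0, sampling=grid.spacing)
            placed = 0
            attempts = 0
            while placed < spec.n_distractors and attempts < 200:
                attempts += 1
                c = noise_rng.uniform(3, s - 4, size=3)
                ci = tuple(int(round(v)) for v in c)
                if dist_mm[ci] < spec.distractor_margin_mm + 2.0 * grid.voxel_size:
                    continue
                axes = noise_rng.uniform(1.5, 3.0, size=3)
                blob = _ellipsoid_mask(grid, c, axes).astype(bool)
                blob &= dist_mm > spec.distractor_margin_mm
                target[blob] = target[blob].mean() + spec.distractor_contrast
                placed += 1
        if spec.noise_sd > 0:
            target = target + noise_rng.normal(0.0, spec.noise_sd, size=target.shape)
        cases.append(
            CohortCase(
                target=ImageVolume(voxels=target, spacing=grid.spacing),
                gt_mask=MaskVolume(voxels=gt, spacing=grid.spacing),
                gt_field=gt_field,
                case_id=f"case{k:03d}",
            )
        )
    return cases


def baseline_metrics(atlas: AtlasBundle, cohort: list[CohortCase]) -> dict:
    """Identity-transform (affine-only) baseline: atlas mask vs. each gt mask."""
    from .evaluation import dice, hd95, summarize
    from .warp import extract_surface

    atlas_surface = extract_surface(atlas.transfer_mask)
    voxel = atlas.grid.voxel_size
    results = []
    for case in cohort:
        d = dice(atlas.transfer_mask, case.gt_mask, exclusion=atlas.exclusion_mask)
        h = hd95(atlas_surface, extract_surface(case.gt_mask), exclusion=atlas.exclusion_mask, spacing=voxel)
        results.append({"case": case.case_id, "dice": d, "hd95": h})
    return summarize(results)
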