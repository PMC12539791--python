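"""Displacement fields, warping, surface transfer and field gradients.

A field stores a per-voxel displacement ``u`` (voxel units) on the atlas
cube; the mapping it realizes is ``phi(x) = x + u(x)`` from atlas index
coordinates to target index coordinates.  Pulling a target back onto the
atlas grid samples the target at ``phi(x)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import nibabel as nib
import numpy as np
from scipy.ndimage import gaussian_filter

from .volumes import CubeGrid, ImageVolume, MaskVolume

__all__ = [
    "DisplacementField",
    "SurfaceMesh",
    "MaskTransferResult",
    "pull_back",
    "pull_back_vjp",
    "transform_points",
    "extract_surface",
    "transfer_mask",
    "invert_field",
    "random_smooth_field",
    "grad_map",
    "read_field",
    "write_field",
    "write_ply",
]


@dataclass(frozen=True)
class DisplacementField:
    """3-channel displacement grid (voxel units) on an isotropic cube."""

    u: np.ndarray  # (3, S, S, S)
    grid: CubeGrid

    def __post_init__(self):
        u = np.asarray(self.u, dtype=np.float64)
        if u.ndim != 4 or u.shape[0] != 3:
            raise ValueError(f"u must have shape (3, S, S, S), got {u.shape}")
        if u.shape[1:] != self.grid.shape:
            raise ValueError(f"field grid {u.shape[1:]} != cube grid {self.grid.shape}")
        if not np.all(np.isfinite(u)):
            raise ValueError("displacement values must be finite")
        object.__setattr__(self, "u", u)

    @classmethod
    def zero(cls, grid: CubeGrid) -> "DisplacementField":
        return cls(u=np.zeros((3,) + grid.shape), grid=grid)


@dataclass
class SurfaceMesh:
    """Triangle mesh in voxel coordinates (convert to mm via spacing)."""

    vertices: np.ndarray  # (V, 3) float
    faces: np.ndarray  # (F, 3) int

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ValueError("face indices out of range")


@dataclass
class MaskTransferResult:
    mask: MaskVolume
    converged: bool
    residual: float


# ---------------------------------------------------------------------------
# Trilinear sampling (with analytic gradient w.r.t. the sample coordinates)
# ---------------------------------------------------------------------------

def _corners_and_weights(vol_shape, pts):
    """Clamp pts to the grid, return corner indices and blend fractions."""
    p = [np.clip(pts[a], 0.0, vol_shape[a] - 1.0) for a in range(3)]
    i0 = [np.minimum(np.floor(p[a]), vol_shape[a] - 2).astype(np.intp) for a in range(3)]
    i0 = [np.maximum(i, 0) for i in i0]
    f = [p[a] - i0[a] for a in range(3)]
    return i0, f


def trilinear_sample(vol: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Sample ``vol`` (3D) at ``pts`` (3, ...) with border replication."""
    i0, f = _corners_and_weights(vol.shape, pts)
    x0, y0, z0 = i0
    fx, fy, fz = f
    v = 0.0
    for dx in (0, 1):
        wx = fx if dx else 1.0 - fx
        for dy in (0, 1):
            wy = fy if dy else 1.0 - fy
            for dz in (0, 1):
                wz = fz if dz else 1.0 - fz
                v = v + vol[x0 + dx, y0 + dy, z0 + dz] * (wx * wy * wz)
    return v


def trilinear_sample_with_grad(vol: np.ndarray, pts: np.ndarray):
    """Return sampled values and d(value)/d(pts) of shape (3, ...).

    The spatial derivative is the analytic derivative of the trilinear
    blend; it is set to zero where a coordinate is clamped outside the
    grid (border replication makes the sample constant there).
    """
    i0, f = _corners_and_weights(vol.shape, pts)
    x0, y0, z0 = i0
    fx, fy, fz = f
    c = {}
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                c[(dx, dy, dz)] = vol[x0 + dx, y0 + dy, z0 + dz]

    def lerp(a, b, t):
        return a * (1.0 - t) + b * t

    # collapse z, then y, then x
    cz = {(dx, dy): lerp(c[(dx, dy, 0)], c[(dx, dy, 1)], fz) for dx in (0, 1) for dy in (0, 1)}
    cy = {dx: lerp(cz[(dx, 0)], cz[(dx, 1)], fy) for dx in (0, 1)}
    val = lerp(cy[0], cy[1], fx)

    dval_dx = cy[1] - cy[0]
    dy0 = cz[(0, 1)] - cz[(0, 0)]
    dy1 = cz[(1, 1)] - cz[(1, 0)]
    dval_dy = lerp(dy0, dy1, fx)
    dz = {(dx, dy): c[(dx, dy, 1)] - c[(dx, dy, 0)] for dx in (0, 1) for dy in (0, 1)}
    dzy = {dx: lerp(dz[(dx, 0)], dz[(dx, 1)], fy) for dx in (0, 1)}
    dval_dz = lerp(dzy[0], dzy[1], fx)

    grad = np.stack([dval_dx, dval_dy, dval_dz])
    for a in range(3):
        outside = (pts[a] < 0.0) | (pts[a] > vol.shape[a] - 1.0)
        grad[a][outside] = 0.0
    return val, grad


def _identity_coords(shape) -> np.ndarray:
    ii = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape], indexing="ij")
    return np.stack(ii)


def pull_back(target: ImageVolume, field: DisplacementField) -> ImageVolume:
    """Resample ``target`` onto the atlas grid: output(x) = T(x + u(x))."""
    if target.shape != field.grid.shape:
        raise ValueError(f"target grid {target.shape} != field grid {field.grid.shape}")
    coords = _identity_coords(field.grid.shape) + field.u
    out = trilinear_sample(np.asarray(target.voxels, np.float64), coords)
    return ImageVolume(voxels=out, spacing=field.grid.spacing)


def pull_back_vjp(target: ImageVolume, field: DisplacementField, grad_out: np.ndarray):
    """Forward pull-back plus the vector-Jacobian product w.r.t. ``u``.

    Returns (warped_voxels, dL/du) given dL/d(warped) = ``grad_out``.
    """
    coords = _identity_coords(field.grid.shape) + field.u
    val, spatial = trilinear_sample_with_grad(np.asarray(target.voxels, np.float64), coords)
    return val, spatial * grad_out[None]


def transform_points(points: np.ndarray, field: DisplacementField) -> np.ndarray:
    """Map points through phi: p -> p + u~(p), u~ = trilinear interp of u."""
    pts = np.asarray(points, dtype=np.float64)
    squeeze = pts.ndim == 1
    pts = np.atleast_2d(pts)
    coords = pts.T  # (3, N)
    disp = np.stack([trilinear_sample(field.u[c], coords) for c in range(3)], axis=1)
    out = pts + disp
    return out[0] if squeeze else out


def extract_surface(mask: MaskVolume) -> SurfaceMesh:
    """Closed triangulated isosurface of a 0/1 mask at level 0.5."""
    from skimage.measure import marching_cubes

    if mask.foreground_count() == 0:
        raise ValueError("cannot extract a surface from an empty mask")
    padded = np.pad(mask.voxels.astype(np.float64), 1)
    verts, faces, _, _ = marching_cubes(padded, level=0.5)
    return SurfaceMesh(vertices=verts - 1.0, faces=faces)


def invert_field(field: DisplacementField, n_iter: int = 20, tol: float = 0.05):
    """Fixed-point inverse displacement: v_{k+1}(y) = -u~(y + v_k(y)).

    Returns (v, converged, residual) where residual is the mean absolute
    update of the final iteration (voxel units).
    """
    shape = field.grid.shape
    ident = _identity_coords(shape)
    v = np.zeros_like(field.u)
    residual = np.inf
    for _ in range(n_iter):
        coords = ident + v
        v_new = -np.stack([trilinear_sample(field.u[c], coords) for c in range(3)])
        residual = float(np.mean(np.abs(v_new - v)))
        v = v_new
        if residual < tol:
            break
    return v, residual < tol, residual


def transfer_mask(
    atlas_mask: MaskVolume,
    field: DisplacementField,
    target_grid: Optional[CubeGrid] = None,
    n_iter: int = 20,
    tol: float = 0.05,
) -> MaskTransferResult:
    """Map an atlas-space mask into target space through phi.

    The target-space mask is M(phi^-1(y)), with phi^-1 approximated by
    fixed-point iteration and nearest-neighbor sampling of the mask.
    """
    if atlas_mask.shape != field.grid.shape:
        raise ValueError("atlas mask must live on the field's grid")
    if target_grid is None:
        target_grid = field.grid
    if target_grid.shape != field.grid.shape:
        raise ValueError("target grid must match the field grid")
    v, converged, residual = invert_field(field, n_iter=n_iter, tol=tol)
    coords = _identity_coords(field.grid.shape) + v
    idx = [np.clip(np.rint(coords[a]), 0, field.grid.shape[a] - 1).astype(np.intp) for a in range(3)]
    out = atlas_mask.voxels[idx[0], idx[1], idx[2]]
    mask = MaskVolume(voxels=out, spacing=target_grid.spacing)
    return MaskTransferResult(mask=mask, converged=converged, residual=residual)


def random_smooth_field(
    grid: CubeGrid,
    amplitude: float = 3.0,
    smoothness: float = 6.0,
    seed: int = 0,
) -> DisplacementField:
    """Gaussian-smoothed white noise rescaled to a peak magnitude.

    Per channel: standard-normal noise smoothed at scale ``smoothness``
    (voxels, zero-padded borders so displacements taper off toward the
    cube faces), then the whole field is rescaled so the maximum
    displacement-vector magnitude equals ``amplitude``.  Deterministic in
    ``seed`` (numpy PCG64).
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if smoothness <= 0:
        raise ValueError("smoothness must be > 0")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((3,) + grid.shape)
    if amplitude == 0:
        return DisplacementField.zero(grid)
    u = np.stack([gaussian_filter(noise[c], sigma=smoothness, mode="constant") for c in range(3)])
    mag = np.sqrt((u**2).sum(axis=0))
    peak = mag.max()
    if peak > 0:
        u *= amplitude / peak
    return DisplacementField(u=u, grid=grid)


def _central_diff(x: np.ndarray, axis: int) -> np.ndarray:
    """Central finite difference with replicate borders: (x[i+1]-x[i-1])/2."""
    xp = np.pad(x, [(1, 1) if a == axis else (0, 0) for a in range(x.ndim)], mode="edge")
    sl_hi = [slice(None)] * x.ndim
    sl_lo = [slice(None)] * x.ndim
    sl_hi[axis] = slice(2, None)
    sl_lo[axis] = slice(None, -2)
    return (xp[tuple(sl_hi)] - xp[tuple(sl_lo)]) / 2.0


def _central_diff_adjoint(g: np.ndarray, axis: int) -> np.ndarray:
    """Adjoint of :func:`_central_diff` (same shape)."""
    a = np.zeros_like(g)

    def sl(s):
        out = [slice(None)] * g.ndim
        out[axis] = s
        return tuple(out)

    # y[i] = (x[min(i+1,n-1)] - x[max(i-1,0)]) / 2
    a[sl(slice(1, None))] += g[sl(slice(None, -1))] / 2.0
    a[sl(slice(-1, None))] += g[sl(slice(-1, None))] / 2.0
    a[sl(slice(None, -1))] -= g[sl(slice(1, None))] / 2.0
    a[sl(slice(0, 1))] -= g[sl(slice(0, 1))] / 2.0
    return a


def grad_map(field: DisplacementField) -> np.ndarray:
    """Per-voxel sum over channels of the squared gradient magnitude of u."""
    out = np.zeros(field.grid.shape)
    for c in range(3):
        for axis in range(3):
            d = _central_diff(field.u[c], axis)
            out += d * d
    return out


# ---------------------------------------------------------------------------
# Field I/O: 3-channel NIfTI, channel order (x, y, z) in the index frame
# ---------------------------------------------------------------------------

def write_field(field: DisplacementField, path) -> None:
    data = np.moveaxis(field.u, 0, -1)  # (S, S, S, 3)
    aff = np.diag(list(field.grid.spacing) + [1.0])
    nib.save(nib.Nifti1Image(data, aff), str(path))


def write_ply(mesh: SurfaceMesh, path) -> None:
    """Write a mesh as ASCII PLY (vertices in voxel coordinates)."""
    lines = [
        "ply",
        "format ascii 1.0",
        f"element vertex {len(mesh.vertices)}",
        "property float x",
        "property float y",
        "property float z",
        f"element face {len(mesh.faces)}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    for v in mesh.vertices:
        lines.append(f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f}")
    for f in mesh.faces:
        lines.append(f"3 {f[0]} {f[1]} {f[2]}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_field(path) -> DisplacementField:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4 or data.shape[-1] != 3:
        raise ValueError(f"{path}: expected a (S,S,S,3) displacement volume, got {data.shape}")
    side = data.shape[0]
    voxel = float(img.header.get_zooms()[0])
    return DisplacementField(u=np.moveaxis(data, -1, 0), grid=CubeGrid(side=side, voxel_size=voxel))
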