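"""Independent brute-force reference implementations used only by tests.

Everything here is written as plain (triple-)loops over voxels or pairs,
deliberately sharing no code with the package internals.
"""

from __future__ import annotations

import math

import numpy as np


def oracle_loss_cc(warped: np.ndarray, atlas: np.ndarray) -> float:
    n = warped.size
    mw = sum(float(v) for v in warped.ravel()) / n
    ma = sum(float(v) for v in atlas.ravel()) / n
    num = 0.0
    sw = 0.0
    sa = 0.0
    for i in range(warped.shape[0]):
        for j in range(warped.shape[1]):
            for k in range(warped.shape[2]):
                dw = float(warped[i, j, k]) - mw
                da = float(atlas[i, j, k]) - ma
                num += dw * da
                sw += dw * dw
                sa += da * da
    return 0.5 - 0.5 * num / (math.sqrt(sw) * math.sqrt(sa))


def _cdiff_at(u: np.ndarray, i: int, j: int, k: int, axis: int) -> float:
    idx_hi = [i, j, k]
    idx_lo = [i, j, k]
    n = u.shape[axis]
    idx_hi[axis] = min(idx_hi[axis] + 1, n - 1)
    idx_lo[axis] = max(idx_lo[axis] - 1, 0)
    return (float(u[tuple(idx_hi)]) - float(u[tuple(idx_lo)])) / 2.0


def oracle_grad_map(u: np.ndarray) -> np.ndarray:
    """u: (3, D, H, W) -> per-voxel sum of squared central differences."""
    _, d, h, w = u.shape
    out = np.zeros((d, h, w))
    for c in range(3):
        for i in range(d):
            for j in range(h):
                for k in range(w):
                    for axis in range(3):
                        g = _cdiff_at(u[c], i, j, k, axis)
                        out[i, j, k] += g * g
    return out


def oracle_loss_grad(u: np.ndarray) -> float:
    d, h, w = u.shape[1:]
    return float(oracle_grad_map(u).sum()) / (3.0 * d * h * w)


def oracle_loss_wgrad(u: np.ndarray, w_map: np.ndarray) -> float:
    d, h, w = u.shape[1:]
    gm = oracle_grad_map(u)
    total = 0.0
    for i in range(d):
        for j in range(h):
            for k in range(w):
                total += w_map[i, j, k] ** 2 * gm[i, j, k]
    return total / (3.0 * d * h * w)


def oracle_ms_stats(warped: np.ndarray, mask: np.ndarray):
    fg = []
    bg = []
    for i in range(warped.shape[0]):
        for j in range(warped.shape[1]):
            for k in range(warped.shape[2]):
                (fg if mask[i, j, k] else bg).append(float(warped[i, j, k]))
    mu_int = sum(fg) / len(fg)
    mu_ext = sum(bg) / len(bg)
    var_int = sum((v - mu_int) ** 2 for v in fg) / len(fg)
    var_ext = sum((v - mu_ext) ** 2 for v in bg) / len(bg)
    return mu_int, mu_ext, var_int, var_ext


def oracle_percentile(values, pct: float) -> float:
    """Linear-interpolation percentile on the sorted list."""
    xs = sorted(float(v) for v in values)
    if len(xs) == 1:
        return xs[0]
    pos = pct / 100.0 * (len(xs) - 1)
    lo = int(math.floor(pos))
    hi = min(lo + 1, len(xs) - 1)
    frac = pos - lo
    return xs[lo] * (1.0 - frac) + xs[hi] * frac


def oracle_hd95(pred_pts: np.ndarray, gt_pts: np.ndarray) -> float:
    """All-pairs symmetric 95th-percentile nearest-point distance."""
    def directed(a, b):
        out = []
        for p in a:
            best = math.inf
            for q in b:
                d = math.dist(p, q)
                if d < best:
                    best = d
            out.append(best)
        return out

    pooled = directed(pred_pts, gt_pts) + directed(gt_pts, pred_pts)
    return oracle_percentile(pooled, 95.0)


def oracle_hausdorff(pred_pts: np.ndarray, gt_pts: np.ndarray) -> float:
    def directed(a, b):
        return max(min(math.dist(p, q) for q in b) for p in a)

    return max(directed(pred_pts, gt_pts), directed(gt_pts, pred_pts))


def oracle_nearest_opposite_distance(mask: np.ndarray, spacing, i, j, k) -> float:
    """Signed distance of one voxel by exhaustive search, mm; negative inside."""
    target = not bool(mask[i, j, k])
    best = math.inf
    for a in range(mask.shape[0]):
        for b in range(mask.shape[1]):
            for c in range(mask.shape[2]):
                if bool(mask[a, b, c]) == target:
                    d = math.sqrt(
                        ((a - i) * spacing[0]) ** 2 + ((b - j) * spacing[1]) ** 2 + ((c - k) * spacing[2]) ** 2
                    )
                    best = min(best, d)
    return -best if mask[i, j, k] else best
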