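"""Minimal 3D convolutional building blocks with hand-written backprop.

No autodiff framework is available in the target environment, so each
layer exposes ``forward`` and ``backward`` (vector-Jacobian product) and
keeps whatever cache it needs between the two.  Everything runs on
single samples laid out channel-first: (C, D, H, W), float32.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv3d", "LeakyReLU", "maxpool2", "maxpool2_adjoint", "upsample2", "upsample2_adjoint", "Adam"]


class Conv3d:
    """3x3x3 convolution, stride 1, zero 'same' padding, via im2col + GEMM."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, weight_scale: float = 1.0):
        fan_in = c_in * 27
        std = np.sqrt(2.0 / fan_in) * weight_scale
        self.weight = (rng.standard_normal((c_out, c_in, 3, 3, 3)) * std).astype(np.float32)
        self.bias = np.zeros(c_out, dtype=np.float32)
        self.grad_weight = np.zeros_like(self.weight)
        self.grad_bias = np.zeros_like(self.bias)
        self._cols_cache: np.ndarray | None = None

    @staticmethod
    def _cols(x: np.ndarray) -> np.ndarray:
        """(C, D, H, W) -> (C*27, D*H*W) patch matrix.

        Built from 27 shifted-slice copies written straight into the
        output buffer, which is much cheaper than a strided im2col gather.
        """
        c, d, h, w = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))
        cols = np.empty((c, 27, d, h, w), dtype=x.dtype)
        k = 0
        for dx in range(3):
            for dy in range(3):
                for dz in range(3):
                    cols[:, k] = xp[:, dx : dx + d, dy : dy + h, dz : dz + w]
                    k += 1
        return cols.reshape(c * 27, d * h * w)

    def _apply(self, x: np.ndarray, weight: np.ndarray, bias: np.ndarray | None, cols=None):
        c_out = weight.shape[0]
        d, h, w = x.shape[1:]
        if cols is None:
            cols = self._cols(x)
        out = weight.reshape(c_out, -1) @ cols
        if bias is not None:
            out += bias[:, None]
        return out.reshape(c_out, d, h, w), cols

    def forward(self, x: np.ndarray) -> np.ndarray:
        out, self._cols_cache = self._apply(x, self.weight, self.bias)
        return out

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        assert self._cols_cache is not None, "forward must run before backward"
        cols = self._cols_cache
        self._cols_cache = None
        c_out = self.weight.shape[0]
        g = grad_out.reshape(c_out, -1)
        self.grad_weight += (g @ cols.T).reshape(self.weight.shape)
        self.grad_bias += g.sum(axis=1)
        # dx = conv(grad_out) with spatially flipped, channel-transposed kernels
        w_t = np.ascontiguousarray(self.weight[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4))
        return self._apply(grad_out, w_t, None)[0]

    @property
    def params(self):
        return [self.weight, self.bias]

    @property
    def grads(self):
        return [self.grad_weight, self.grad_bias]


class LeakyReLU:
    def __init__(self, slope: float = 0.2):
        self.slope = slope
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x >= 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad_out, self.slope * grad_out)


def maxpool2(x: np.ndarray):
    """2x2x2 max pooling; returns (pooled, argmax) for the adjoint."""
    c, d, h, w = x.shape
    xr = (
        x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
        .transpose(0, 1, 3, 5, 2, 4, 6)
        .reshape(c, d // 2, h // 2, w // 2, 8)
    )
    idx = xr.argmax(-1)
    out = np.take_along_axis(xr, idx[..., None], -1)[..., 0]
    return out, idx


def maxpool2_adjoint(grad_out: np.ndarray, idx: np.ndarray, in_shape) -> np.ndarray:
    c, d, h, w = in_shape
    buf = np.zeros((c, d // 2, h // 2, w // 2, 8), dtype=grad_out.dtype)
    np.put_along_axis(buf, idx[..., None], grad_out[..., None], -1)
    return (
        buf.reshape(c, d // 2, h // 2, w // 2, 2, 2, 2)
        .transpose(0, 1, 4, 2, 5, 3, 6)
        .reshape(c, d, h, w)
    )


def _up2_axis(x: np.ndarray, axis: int) -> np.ndarray:
    x = np.moveaxis(x, axis, 0)
    n = x.shape[0]
    lo = x[np.maximum(np.arange(n) - 1, 0)]
    hi = x[np.minimum(np.arange(n) + 1, n - 1)]
    out = np.empty((2 * n,) + x.shape[1:], dtype=x.dtype)
    out[0::2] = 0.25 * lo + 0.75 * x
    out[1::2] = 0.75 * x + 0.25 * hi
    return np.moveaxis(out, 0, axis)


def _up2_axis_adjoint(g: np.ndarray, axis: int) -> np.ndarray:
    g = np.moveaxis(g, axis, 0)
    ge = g[0::2]
    go = g[1::2]
    dx = 0.75 * (ge + go)
    dx[:-1] += 0.25 * ge[1:]
    dx[0] += 0.25 * ge[0]
    dx[1:] += 0.25 * go[:-1]
    dx[-1] += 0.25 * go[-1]
    return np.moveaxis(dx, 0, axis)


def upsample2(x: np.ndarray) -> np.ndarray:
    """Trilinear x2 upsampling of (C, D, H, W), half-voxel-centers convention."""
    for axis in (1, 2, 3):
        x = _up2_axis(x, axis)
    return x


def upsample2_adjoint(grad_out: np.ndarray) -> np.ndarray:
    for axis in (3, 2, 1):
        grad_out = _up2_axis_adjoint(grad_out, axis)
    return grad_out


class Adam:
    """Standard Adam on a flat list of parameter arrays (in-place updates)."""

    def __init__(self, params, lr: float = 1e-4, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * (g * g)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
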