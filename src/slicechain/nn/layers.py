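"""Minimal CNN building blocks on numpy arrays.

Forward passes are expressed as im2col + matrix multiplication so the
heavy lifting happens inside BLAS; backward passes are hand-derived and
verified against numerical differentiation in the test suite.  All layers
work in whatever float dtype the input carries (float32 in production,
float64 in gradient checks).

Conventions: 2D tensors are (N, C, H, W); 3D tensors are (N, C, D, H, W)
with D the slice/depth axis.  All convolutions are stride 1 and zero
padded to preserve spatial extent, except the 2×2-stride-2 transposed
convolution used for upsampling.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "Conv3d",
    "ConvTranspose2d",
    "MaxPool2d",
    "InPlanePool3d",
    "DepthCollapsePool",
    "BatchNorm",
    "ReLU",
    "he_uniform",
]


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = data
        self.grad = np.zeros_like(data)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def he_uniform(shape: tuple[int, ...], fan_in: int, rng: np.random.Generator, dtype) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Layer:
    """Base class: layers expose named params and optional running state."""

    def params(self) -> Iterator[tuple[str, Param]]:
        for name, value in vars(self).items():
            if isinstance(value, Param):
                yield name, value

    def state(self) -> dict[str, np.ndarray]:
        """Non-trainable arrays that must persist across save/load."""
        return {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


# ---------------------------------------------------------------------------
# convolutions
# ---------------------------------------------------------------------------

class Conv3d(Layer):
    """3×3×3 (or 1×1×1) zero-padded stride-1 convolution on (N, C, D, H, W).

    im2col is built offset-by-offset as (k³, C, M) so each copy is a large
    strided block rather than a per-element gather; the matmul then runs as
    (C_out, k³·C) @ (k³·C, M).
    """

    def __init__(self, c_in: int, c_out: int, kernel: int = 3, *,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        if kernel not in (1, 3):
            raise ValueError("Conv3d supports kernel 1 or 3")
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * kernel**3
        self.weight = Param(he_uniform((c_out, c_in, kernel, kernel, kernel), fan_in, rng, dtype))
        self.bias = Param(np.zeros(c_out, dtype=dtype))
        self._cols: np.ndarray | None = None

    @staticmethod
    def _im2col(x: np.ndarray, k: int) -> np.ndarray:
        """Column matrix (k³·C, M) with offset-major ordering."""
        n, c, d, h, w = x.shape
        m = n * d * h * w
        if k == 1:
            return x.transpose(1, 0, 2, 3, 4).reshape(c, m)
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        cols = np.empty((k**3, c, m), dtype=x.dtype)
        o = 0
        for dz in range(k):
            for dy in range(k):
                for dx in range(k):
                    cols[o] = xp[:, :, dz:dz + d, dy:dy + h, dx:dx + w].transpose(
                        1, 0, 2, 3, 4).reshape(c, m)
                    o += 1
        return cols.reshape(k**3 * c, m)

    def _wmat(self, w: np.ndarray) -> np.ndarray:
        # (C_out, C_in, k, k, k) -> (C_out, k³·C_in), offset-major
        c_out = w.shape[0]
        return w.transpose(0, 2, 3, 4, 1).reshape(c_out, -1)

    def _raw(self, x: np.ndarray, w: np.ndarray, cache: bool) -> np.ndarray:
        n, c, d, h, w_ = x.shape
        cols = self._im2col(x, self.kernel)
        if cache:
            self._cols = cols
        c_out = w.shape[0]
        y = self._wmat(w) @ cols
        return y.reshape(c_out, n, d, h, w_).transpose(1, 0, 2, 3, 4)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = self._raw(x, self.weight.data, cache=True)
        return y + self.bias.data[None, :, None, None, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, c_out, d, h, w = gy.shape
        k = self.kernel
        gy_mat = gy.transpose(1, 0, 2, 3, 4).reshape(c_out, -1)
        gw_mat = gy_mat @ self._cols.T  # (C_out, k³·C_in)
        self.weight.grad += gw_mat.reshape(c_out, k, k, k, self.c_in).transpose(0, 4, 1, 2, 3)
        self.bias.grad += gy_mat.sum(axis=1)
        # input gradient = correlation of gy with the flipped, transposed kernel
        w_hat = self.weight.data[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4) if k == 3 \
            else self.weight.data.transpose(1, 0, 2, 3, 4)
        self._cols = None
        return self._raw(gy, np.ascontiguousarray(w_hat), cache=False)


class Conv2d(Layer):
    """3×3 or 1×1 zero-padded stride-1 convolution on (N, C, H, W)."""

    def __init__(self, c_in: int, c_out: int, kernel: int = 3, *,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        if kernel not in (1, 3):
            raise ValueError("Conv2d supports kernel 1 or 3")
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * kernel**2
        self.weight = Param(he_uniform((c_out, c_in, kernel, kernel), fan_in, rng, dtype))
        self.bias = Param(np.zeros(c_out, dtype=dtype))
        self._cols: np.ndarray | None = None

    @staticmethod
    def _im2col(x: np.ndarray, k: int) -> np.ndarray:
        """Column matrix (k²·C, M) with offset-major ordering."""
        n, c, h, w = x.shape
        m = n * h * w
        if k == 1:
            return x.transpose(1, 0, 2, 3).reshape(c, m)
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        cols = np.empty((k**2, c, m), dtype=x.dtype)
        o = 0
        for dy in range(k):
            for dx in range(k):
                cols[o] = xp[:, :, dy:dy + h, dx:dx + w].transpose(1, 0, 2, 3).reshape(c, m)
                o += 1
        return cols.reshape(k**2 * c, m)

    def _wmat(self, w: np.ndarray) -> np.ndarray:
        c_out = w.shape[0]
        return w.transpose(0, 2, 3, 1).reshape(c_out, -1)

    def _raw(self, x: np.ndarray, w: np.ndarray, cache: bool) -> np.ndarray:
        n, c, h, w_ = x.shape
        cols = self._im2col(x, self.kernel)
        if cache:
            self._cols = cols
        c_out = w.shape[0]
        y = self._wmat(w) @ cols
        return y.reshape(c_out, n, h, w_).transpose(1, 0, 2, 3)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = self._raw(x, self.weight.data, cache=True)
        return y + self.bias.data[None, :, None, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, c_out, h, w = gy.shape
        k = self.kernel
        gy_mat = gy.transpose(1, 0, 2, 3).reshape(c_out, -1)
        gw_mat = gy_mat @ self._cols.T
        self.weight.grad += gw_mat.reshape(c_out, k, k, self.c_in).transpose(0, 3, 1, 2)
        self.bias.grad += gy_mat.sum(axis=1)
        w_hat = self.weight.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3) if k == 3 \
            else self.weight.data.transpose(1, 0, 2, 3)
        self._cols = None
        return self._raw(gy, np.ascontiguousarray(w_hat), cache=False)


class ConvTranspose2d(Layer):
    """2×2 stride-2 transposed convolution: doubles H and W."""

    def __init__(self, c_in: int, c_out: int, *,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        self.c_in, self.c_out = c_in, c_out
        rng = rng or np.random.default_rng(0)
        self.weight = Param(he_uniform((c_in, c_out, 2, 2), c_in, rng, dtype))
        self.bias = Param(np.zeros(c_out, dtype=dtype))
        self._xmat: np.ndarray | None = None
        self._xshape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        xmat = x.transpose(0, 2, 3, 1).reshape(-1, c)
        self._xmat, self._xshape = xmat, x.shape
        f = self.c_out
        y = xmat @ self.weight.data.reshape(c, f * 4)
        y = y.reshape(n, h, w, f, 2, 2).transpose(0, 3, 1, 4, 2, 5).reshape(n, f, 2 * h, 2 * w)
        return y + self.bias.data[None, :, None, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, f, h2, w2 = gy.shape
        h, w = h2 // 2, w2 // 2
        c = self.c_in
        gy_mat = gy.reshape(n, f, h, 2, w, 2).transpose(0, 2, 4, 1, 3, 5).reshape(-1, f * 4)
        self.weight.grad += (self._xmat.T @ gy_mat).reshape(self.weight.data.shape)
        self.bias.grad += gy.sum(axis=(0, 2, 3))
        gx = gy_mat @ self.weight.data.reshape(c, f * 4).T
        self._xmat = None
        return gx.reshape(n, h, w, c).transpose(0, 3, 1, 2)


# ---------------------------------------------------------------------------
# pooling
# ---------------------------------------------------------------------------

class MaxPool2d(Layer):
    """2×2 stride-2 max pooling on (N, C, H, W)."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, h // 2, w // 2, 4)
        self._idx = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        g = np.zeros((n, c, h // 2, w // 2, 4), dtype=gy.dtype)
        np.put_along_axis(g, self._idx[..., None], gy[..., None], axis=-1)
        return g.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)


class InPlanePool3d(Layer):
    """1×2×2 stride-(1,2,2) max pooling on (N, C, D, H, W): halves H, W, keeps D."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, d, h, w = x.shape
        xr = x.reshape(n, c, d, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 3, 5, 4, 6).reshape(
            n, c, d, h // 2, w // 2, 4)
        self._idx = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, c, d, h, w = self._shape
        g = np.zeros((n, c, d, h // 2, w // 2, 4), dtype=gy.dtype)
        np.put_along_axis(g, self._idx[..., None], gy[..., None], axis=-1)
        return g.reshape(n, c, d, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 3, 5, 4, 6).reshape(
            n, c, d, h, w)


class DepthCollapsePool(Layer):
    """3×1×1 max pooling over the full depth axis: (N, C, D, H, W) -> (N, C, H, W)."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._idx = x.argmax(axis=2)
        self._shape = x.shape
        return np.take_along_axis(x, self._idx[:, :, None], axis=2)[:, :, 0]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        g = np.zeros(self._shape, dtype=gy.dtype)
        np.put_along_axis(g, self._idx[:, :, None], gy[:, :, None], axis=2)
        return g


# ---------------------------------------------------------------------------
# normalization / activation
# ---------------------------------------------------------------------------

class BatchNorm(Layer):
    """Per-channel batch normalization over axis 1 of an N-D tensor.

    Training mode normalizes with mini-batch statistics and updates the
    running averages with momentum 0.99; inference mode uses the running
    averages.
    """

    def __init__(self, channels: int, momentum: float = 0.99, eps: float = 1e-5, dtype=np.float32):
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.gamma = Param(np.ones(channels, dtype=dtype))
        self.beta = Param(np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)

    def state(self) -> dict[str, np.ndarray]:
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def _bshape(self, ndim: int) -> tuple[int, ...]:
        return (1, self.channels) + (1,) * (ndim - 2)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        axes = (0,) + tuple(range(2, x.ndim))
        bs = self._bshape(x.ndim)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = (m * self.running_mean + (1 - m) * mean).astype(
                self.running_mean.dtype)
            self.running_var = (m * self.running_var + (1 - m) * var).astype(
                self.running_var.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(bs)) * inv_std.reshape(bs)
        self._cache = (xhat, inv_std, axes, bs, train, x.shape)
        return self.gamma.data.reshape(bs) * xhat + self.beta.data.reshape(bs)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, inv_std, axes, bs, train, xshape = self._cache
        self.gamma.grad += (gy * xhat).sum(axis=axes)
        self.beta.grad += gy.sum(axis=axes)
        g_xhat = gy * self.gamma.data.reshape(bs)
        if not train:
            return g_xhat * inv_std.reshape(bs)
        n_per_ch = gy.size // self.channels
        sum_g = g_xhat.sum(axis=axes).reshape(bs)
        sum_gx = (g_xhat * xhat).sum(axis=axes).reshape(bs)
        return (inv_std.reshape(bs) / n_per_ch) * (
            n_per_ch * g_xhat - sum_g - xhat * sum_gx)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, gy, 0.0)
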