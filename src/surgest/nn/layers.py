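"""Layers of the CPU training engine.

Convolutions are im2col + GEMM; the im2col/col2im pair is realised as a short
loop over kernel offsets of fully vectorised strided slices, which keeps both
directions exact and fast enough for the volume sizes this package works at.
"""

from __future__ import annotations

import numpy as np

from .core import Module, Parameter

__all__ = [
    "Linear",
    "ReLU",
    "Sigmoid",
    "Conv3d",
    "Conv2d",
    "ConvTranspose2d",
    "AvgPool3d",
    "GlobalAvgPool3d",
    "BatchNorm2d",
    "LayerNorm",
]


def _triple(v):
    return tuple(v) if isinstance(v, (tuple, list)) else (v, v, v)


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


def he_normal(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    return (rng.standard_normal(size=shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Linear(Module):
    """Affine map applied to the last axis (leading axes are flattened)."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        self.d_in, self.d_out = d_in, d_out
        self.W = Parameter(glorot_uniform(rng, d_in, d_out, (d_in, d_out)))
        self.b = Parameter(np.zeros(d_out, dtype=np.float32)) if bias else None

    def forward(self, x, train=False):
        x = np.asarray(x, dtype=np.float32)
        self._in_shape = x.shape
        self._x2 = x.reshape(-1, self.d_in)
        y = self._x2 @ self.W.value
        if self.b is not None:
            y += self.b.value
        return y.reshape(*self._in_shape[:-1], self.d_out)

    def backward(self, dy):
        dy2 = dy.reshape(-1, self.d_out).astype(np.float32)
        self.W.grad += self._x2.T @ dy2
        if self.b is not None:
            self.b.grad += dy2.sum(axis=0)
        return (dy2 @ self.W.value.T).reshape(self._in_shape)


class ReLU(Module):
    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0)


class Sigmoid(Module):
    def forward(self, x, train=False):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))
        return self._y.astype(np.float32)

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class Conv3d(Module):
    """3D convolution over (B, C, T, H, W) input."""

    def __init__(self, c_in, c_out, kernel, stride=1, padding=0, rng=None, bias=True):
        self.c_in, self.c_out = c_in, c_out
        self.kernel = _triple(kernel)
        self.stride = _triple(stride)
        self.padding = _triple(padding)
        k = int(np.prod(self.kernel))
        # weight stored flat as (c_out, c_in * kt*kh*kw) for the GEMM
        self.W = Parameter(he_normal(rng, c_in * k, (c_out, c_in * k)))
        self.b = Parameter(np.zeros(c_out, dtype=np.float32)) if bias else None

    def _out_size(self, size, axis):
        return (size + 2 * self.padding[axis] - self.kernel[axis]) // self.stride[axis] + 1

    def forward(self, x, train=False):
        x = np.asarray(x, dtype=np.float32)
        B, C, T, H, W = x.shape
        if C != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {C}")
        pt, ph, pw = self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (pt, pt), (ph, ph), (pw, pw))) if any(self.padding) else x
        To, Ho, Wo = self._out_size(T, 0), self._out_size(H, 1), self._out_size(W, 2)
        if min(To, Ho, Wo) < 1:
            raise ValueError(f"input {x.shape[2:]} too small for kernel {self.kernel}")
        kt, kh, kw = self.kernel
        st, sh, sw = self.stride
        K = kt * kh * kw
        cols = np.empty((K, B, C, To, Ho, Wo), dtype=np.float32)
        i = 0
        for a in range(kt):
            for b in range(kh):
                for c in range(kw):
                    cols[i] = xp[:, :, a : a + st * To : st, b : b + sh * Ho : sh, c : c + sw * Wo : sw]
                    i += 1
        P = To * Ho * Wo
        # (K, B, C, P) -> (B*P, C*K)
        cols2 = np.ascontiguousarray(
            cols.reshape(K, B, C, P).transpose(1, 3, 2, 0)
        ).reshape(B * P, C * K)
        y = cols2 @ self.W.value.T
        if self.b is not None:
            y += self.b.value
        self._cache = (cols2, x.shape, (To, Ho, Wo))
        return np.ascontiguousarray(
            y.reshape(B, To, Ho, Wo, self.c_out).transpose(0, 4, 1, 2, 3)
        )

    def backward(self, dy):
        cols2, in_shape, (To, Ho, Wo) = self._cache
        B, C, T, H, W = in_shape
        P = To * Ho * Wo
        kt, kh, kw = self.kernel
        st, sh, sw = self.stride
        pt, ph, pw = self.padding
        K = kt * kh * kw
        dy2 = np.ascontiguousarray(dy.transpose(0, 2, 3, 4, 1)).reshape(B * P, self.c_out)
        self.W.grad += dy2.T @ cols2
        if self.b is not None:
            self.b.grad += dy2.sum(axis=0)
        dcols2 = dy2 @ self.W.value  # (B*P, C*K)
        dcols = np.ascontiguousarray(
            dcols2.reshape(B, P, C, K).transpose(3, 0, 2, 1)
        ).reshape(K, B, C, To, Ho, Wo)
        dxp = np.zeros((B, C, T + 2 * pt, H + 2 * ph, W + 2 * pw), dtype=np.float32)
        i = 0
        for a in range(kt):
            for b in range(kh):
                for c in range(kw):
                    dxp[:, :, a : a + st * To : st, b : b + sh * Ho : sh, c : c + sw * Wo : sw] += dcols[i]
                    i += 1
        if any(self.padding):
            return dxp[:, :, pt : pt + T, ph : ph + H, pw : pw + W]
        return dxp


class Conv2d(Module):
    """2D convolution over (B, C, H, W); thin wrapper over Conv3d with T=1."""

    def __init__(self, c_in, c_out, kernel, stride=1, padding=0, rng=None, bias=True):
        k = kernel if isinstance(kernel, (tuple, list)) else (kernel, kernel)
        s = stride if isinstance(stride, (tuple, list)) else (stride, stride)
        p = padding if isinstance(padding, (tuple, list)) else (padding, padding)
        self.inner = Conv3d(c_in, c_out, (1, *k), (1, *s), (0, *p), rng=rng, bias=bias)

    def forward(self, x, train=False):
        y = self.inner.forward(x[:, :, None], train=train)
        return y[:, :, 0]

    def backward(self, dy):
        return self.inner.backward(dy[:, :, None])[:, :, 0]


class ConvTranspose2d(Module):
    """Transposed 2D convolution with kernel == stride (exact s-fold upsampling).

    With a square kernel equal to the stride the output windows do not
    overlap, so the operation is a per-pixel linear map followed by a spatial
    interleave — cheap and exactly invertible in shape.
    """

    def __init__(self, c_in, c_out, factor: int, rng=None, bias=True):
        self.c_in, self.c_out, self.factor = c_in, c_out, factor
        self.W = Parameter(glorot_uniform(rng, c_in, c_out * factor * factor,
                                          (c_in, c_out, factor, factor)))
        self.b = Parameter(np.zeros(c_out, dtype=np.float32)) if bias else None

    def forward(self, x, train=False):
        x = np.asarray(x, dtype=np.float32)
        B, C, H, W = x.shape
        if C != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {C}")
        self._x = x
        s = self.factor
        t = np.tensordot(x, self.W.value, axes=([1], [0]))  # (B, H, W, c_out, s, s)
        y = np.ascontiguousarray(t.transpose(0, 3, 1, 4, 2, 5)).reshape(
            B, self.c_out, H * s, W * s
        )
        if self.b is not None:
            y += self.b.value[None, :, None, None]
        return y

    def backward(self, dy):
        B, C, H, W = self._x.shape
        s = self.factor
        t = np.ascontiguousarray(
            dy.reshape(B, self.c_out, H, s, W, s).transpose(0, 2, 4, 1, 3, 5)
        )  # (B, H, W, c_out, s, s)
        self.W.grad += np.tensordot(self._x, t, axes=([0, 2, 3], [0, 1, 2]))
        if self.b is not None:
            self.b.grad += dy.sum(axis=(0, 2, 3))
        return np.tensordot(t, self.W.value, axes=([3, 4, 5], [1, 2, 3])).transpose(0, 3, 1, 2)


class AvgPool3d(Module):
    """Average pooling with kernel == stride; pooled sizes must divide evenly."""

    def __init__(self, kernel):
        self.kernel = _triple(kernel)

    def forward(self, x, train=False):
        B, C, T, H, W = x.shape
        kt, kh, kw = self.kernel
        if T % kt or H % kh or W % kw:
            raise ValueError(f"input {x.shape[2:]} not divisible by pool {self.kernel}")
        self._in_shape = x.shape
        return x.reshape(B, C, T // kt, kt, H // kh, kh, W // kw, kw).mean(axis=(3, 5, 7))

    def backward(self, dy):
        B, C, T, H, W = self._in_shape
        kt, kh, kw = self.kernel
        scale = 1.0 / (kt * kh * kw)
        dy = dy[:, :, :, None, :, None, :, None] * scale
        return np.broadcast_to(
            dy, (B, C, T // kt, kt, H // kh, kh, W // kw, kw)
        ).reshape(B, C, T, H, W).astype(np.float32)


class GlobalAvgPool3d(Module):
    """(B, C, T, H, W) -> (B, C)."""

    def forward(self, x, train=False):
        self._in_shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, dy):
        B, C, T, H, W = self._in_shape
        scale = 1.0 / (T * H * W)
        return np.broadcast_to(
            (dy * scale)[:, :, None, None, None], self._in_shape
        ).astype(np.float32)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.gamma = Parameter(np.ones(channels, dtype=np.float32))
        self.beta = Parameter(np.zeros(channels, dtype=np.float32))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._buffers = ("running_mean", "running_var")

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * invstd[None, :, None, None]
        self._cache = (xhat.astype(np.float32), invstd.astype(np.float32), train)
        return (self.gamma.value[None, :, None, None] * xhat
                + self.beta.value[None, :, None, None]).astype(np.float32)

    def backward(self, dy):
        xhat, invstd, trained = self._cache
        B, C, H, W = dy.shape
        n = B * H * W
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma.value[None, :, None, None]
        if not trained:
            return dxhat * invstd[None, :, None, None]
        term = (
            n * dxhat
            - dxhat.sum(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        )
        return (invstd[None, :, None, None] / n) * term


class LayerNorm(Module):
    """Normalisation over the last axis with learned affine."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.dim = dim
        self.eps = eps
        self.gamma = Parameter(np.ones(dim, dtype=np.float32))
        self.beta = Parameter(np.zeros(dim, dtype=np.float32))

    def forward(self, x, train=False):
        mean = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * invstd
        self._cache = (xhat.astype(np.float32), invstd.astype(np.float32))
        return (self.gamma.value * xhat + self.beta.value).astype(np.float32)

    def backward(self, dy):
        xhat, invstd = self._cache
        n = self.dim
        lead = tuple(range(dy.ndim - 1))
        self.gamma.grad += (dy * xhat).sum(axis=lead)
        self.beta.grad += dy.sum(axis=lead)
        dxhat = dy * self.gamma.value
        term = (
            n * dxhat
            - dxhat.sum(axis=-1, keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=-1, keepdims=True)
        )
        return (invstd / n) * term
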