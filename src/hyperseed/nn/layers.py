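"""Standard layers: convolution (im2col), batch norm, pooling, linear.

Convolution and pooling lower the input to patch matrices with
``numpy.lib.stride_tricks.sliding_window_view`` so the heavy lifting is
a single BLAS matmul; the col2im scatter in backward loops over the
(small) kernel support with strided slice adds, which handles
overlapping windows correctly.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core import Module, Parameter, he_normal

__all__ = [
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "Sigmoid",
    "MaxPool2d",
    "GlobalAvgPool",
    "Linear",
    "Identity",
]


def _out_size(n: int, k: int, stride: int, pad: int) -> int:
    return (n + 2 * pad - k) // stride + 1


class Conv2d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int = 0,
        bias: bool = True,
        rng: np.random.Generator | None = None,
        zero_init: bool = False,
    ) -> None:
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.k = kernel_size
        self.stride = stride
        self.padding = padding
        fan_in = in_channels * kernel_size * kernel_size
        if zero_init:
            w = np.zeros((out_channels, in_channels, self.k, self.k), dtype=np.float32)
        else:
            rng = rng or np.random.default_rng(0)
            w = he_normal(rng, (out_channels, in_channels, self.k, self.k), fan_in)
        self.weight = Parameter(w, "conv.weight")
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32), "conv.bias") if bias else None

    def _im2col(self, x: np.ndarray) -> tuple[np.ndarray, tuple[int, int]]:
        p = self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        win = win[:, :, :: self.stride, :: self.stride]  # (N, C, OH, OW, k, k)
        n, c, oh, ow = win.shape[:4]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, oh * ow, c * self.k * self.k)
        return np.ascontiguousarray(cols), (oh, ow)

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        cols, (oh, ow) = self._im2col(x)
        self._cache = (x.shape, cols)
        wmat = self.weight.data.reshape(self.out_channels, -1)
        out = cols @ wmat.T  # (N, OH*OW, O)
        if self.bias is not None:
            out += self.bias.data
        return out.transpose(0, 2, 1).reshape(x.shape[0], self.out_channels, oh, ow)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x_shape, cols = self._cache
        n, _, oh, ow = dout.shape
        dmat = dout.reshape(n, self.out_channels, oh * ow).transpose(0, 2, 1)  # (N, OH*OW, O)
        self.weight.grad += np.einsum("nlo,nlk->ok", dmat, cols).reshape(self.weight.data.shape)
        if self.bias is not None:
            self.bias.grad += dout.sum(axis=(0, 2, 3))
        wmat = self.weight.data.reshape(self.out_channels, -1)
        dcols = dmat @ wmat  # (N, OH*OW, C*k*k)
        # col2im scatter
        p, s, k = self.padding, self.stride, self.k
        _, c, h, w = x_shape
        d6 = dcols.reshape(n, oh, ow, c, k, k).transpose(0, 3, 1, 2, 4, 5)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + oh * s : s, j : j + ow * s : s] += d6[:, :, :, :, i, j]
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class BatchNorm2d(Module):
    buffer_names = ("running_mean", "running_var")

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1) -> None:
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(channels, dtype=np.float32), "bn.gamma")
        self.beta = Parameter(np.zeros(channels, dtype=np.float32), "bn.beta")
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean + self.momentum * mean).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var + self.momentum * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps).astype(np.float32)
        xhat = (x - mean[None, :, None, None]) / std[None, :, None, None]
        self._cache = (xhat, std)
        return (self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]).astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, std = self._cache
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        g = self.gamma.data[None, :, None, None]
        if self.training:
            m = dout.shape[0] * dout.shape[2] * dout.shape[3]
            dxhat = dout * g
            dx = (
                dxhat
                - dxhat.mean(axis=(0, 2, 3), keepdims=True)
                - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
            ) / std[None, :, None, None]
            return dx.astype(np.float32)
        return (dout * g / std[None, :, None, None]).astype(np.float32)


class ReLU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0.0).astype(np.float32)


class Sigmoid(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        out = 1.0 / (1.0 + np.exp(-x))
        self._out = out.astype(np.float32)
        return self._out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return (dout * self._out * (1.0 - self._out)).astype(np.float32)


class MaxPool2d(Module):
    def __init__(self, kernel_size: int = 3, stride: int = 2, padding: int = 1) -> None:
        self.k = kernel_size
        self.stride = stride
        self.padding = padding

    def forward(self, x: np.ndarray) -> np.ndarray:
        p, k, s = self.padding, self.k, self.stride
        fill = np.float32(-np.inf)
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=fill) if p else x
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        n, c, oh, ow = win.shape[:4]
        flat = win.reshape(n, c, oh, ow, k * k)
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        self._cache = (x.shape, idx)
        return np.ascontiguousarray(out, dtype=np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x_shape, idx = self._cache
        p, k, s = self.padding, self.k, self.stride
        n, c, h, w = x_shape
        oh, ow = dout.shape[2], dout.shape[3]
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for t in range(k * k):
            i, j = divmod(t, k)
            sel = (idx == t) * dout
            dxp[:, :, i : i + oh * s : s, j : j + ow * s : s] += sel
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class GlobalAvgPool(Module):
    """(N, C, H, W) -> (N, C) mean over the spatial support."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3)).astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return (np.broadcast_to(dout[:, :, None, None], self._shape) / (h * w)).astype(np.float32)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator | None = None) -> None:
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(he_normal(rng, (out_features, in_features), in_features), "fc.weight")
        self.bias = Parameter(np.zeros(out_features, dtype=np.float32), "fc.bias")

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return (x @ self.weight.data.T + self.bias.data).astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.weight.grad += dout.T @ self._x
        self.bias.grad += dout.sum(axis=0)
        return (dout @ self.weight.data).astype(np.float32)


class Identity(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout
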