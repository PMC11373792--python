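"""Deformable 2-D convolution with learned fractional offsets.

Each kernel tap samples the input at its regular grid position plus a
per-output-position offset predicted by a companion standard
convolution; sampling is bilinear with zero padding beyond the borders.
The offset predictor is zero-initialized, so an untrained layer is
exactly a standard convolution — the degenerate-equivalence property
the tests pin down — and training starts from that point.

Offset channel layout: channels ``2 t`` and ``2 t + 1`` carry the
(row, column) offset of tap ``t`` in row-major kernel order.
"""

from __future__ import annotations

import numpy as np

from .core import Module, Parameter, he_normal
from .layers import Conv2d

__all__ = ["DeformableConv2d"]


class DeformableConv2d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int = 0,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ) -> None:
        rng = rng or np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.k = kernel_size
        self.stride = stride
        self.padding = padding
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Parameter(
            he_normal(rng, (out_channels, in_channels, kernel_size, kernel_size), fan_in),
            "dcn.weight",
        )
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32), "dcn.bias") if bias else None
        # zero-init so initial behavior == standard convolution
        self.offset_conv = Conv2d(
            in_channels, 2 * kernel_size * kernel_size, kernel_size,
            stride=stride, padding=padding, bias=True, zero_init=True,
        )

    # -- sampling helpers ---------------------------------------------
    def _positions(self, offsets: np.ndarray, h: int, w: int) -> tuple[np.ndarray, np.ndarray]:
        """Absolute fractional sample positions (py, px), each (N, kk, OH, OW)."""
        n, _, oh, ow = offsets.shape
        k, s, p = self.k, self.stride, self.padding
        kk = k * k
        off = offsets.reshape(n, kk, 2, oh, ow)
        base_y = (np.arange(oh) * s - p)[None, None, :, None] + (np.arange(k).repeat(k)).reshape(1, kk, 1, 1)
        base_x = (np.arange(ow) * s - p)[None, None, None, :] + (np.tile(np.arange(k), k)).reshape(1, kk, 1, 1)
        py = base_y + off[:, :, 0]
        px = base_x + off[:, :, 1]
        return py.astype(np.float64), px.astype(np.float64)

    @staticmethod
    def _gather(xf: np.ndarray, iy: np.ndarray, ix: np.ndarray, h: int, w: int) -> np.ndarray:
        """Gather x at integer (iy, ix), zero outside; returns (N, C, kk, OH, OW)."""
        valid = (iy >= 0) & (iy < h) & (ix >= 0) & (ix < w)
        flat = np.clip(iy, 0, h - 1) * w + np.clip(ix, 0, w - 1)
        n = xf.shape[0]
        n_idx = np.arange(n)[:, None, None, None]
        v = xf[n_idx, flat]                 # (N, kk, OH, OW, C)
        v = np.moveaxis(v, -1, 1)           # (N, C, kk, OH, OW)
        return v * valid[:, None]

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        n, c, h, w = x.shape
        offsets = self.offset_conv.forward(x)          # (N, 2kk, OH, OW)
        if offsets.shape[1] != 2 * self.k * self.k:
            raise ValueError(
                f"offset tensor has {offsets.shape[1]} channels, "
                f"expected {2 * self.k * self.k}"
            )
        py, px = self._positions(offsets, h, w)
        y0 = np.floor(py).astype(np.int64)
        x0 = np.floor(px).astype(np.int64)
        wy = (py - y0).astype(np.float32)
        wx = (px - x0).astype(np.float32)

        xf = x.transpose(0, 2, 3, 1).reshape(n, h * w, c)
        v00 = self._gather_t(xf, y0, x0, h, w)
        v01 = self._gather_t(xf, y0, x0 + 1, h, w)
        v10 = self._gather_t(xf, y0 + 1, x0, h, w)
        v11 = self._gather_t(xf, y0 + 1, x0 + 1, h, w)
        wy_ = wy[:, None]
        wx_ = wx[:, None]
        sampled = (
            (1 - wy_) * (1 - wx_) * v00
            + (1 - wy_) * wx_ * v01
            + wy_ * (1 - wx_) * v10
            + wy_ * wx_ * v11
        ).astype(np.float32)                           # (N, C, kk, OH, OW)

        wmat = self.weight.data.reshape(self.out_channels, c * self.k * self.k)
        oh, ow = sampled.shape[3], sampled.shape[4]
        smat = sampled.reshape(n, c * self.k * self.k, oh * ow)
        out = np.einsum("ok,nkl->nol", wmat, smat).reshape(n, self.out_channels, oh, ow)
        if self.bias is not None:
            out += self.bias.data[None, :, None, None]
        self._cache = (x, sampled, y0, x0, wy, wx, (v00, v01, v10, v11))
        return out.astype(np.float32)

    def _gather_t(self, xf: np.ndarray, iy: np.ndarray, ix: np.ndarray, h: int, w: int) -> np.ndarray:
        return self._gather(xf, iy, ix, h, w).astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, sampled, y0, x0, wy, wx, (v00, v01, v10, v11) = self._cache
        n, c, h, w = x.shape
        kk = self.k * self.k
        oh, ow = dout.shape[2], dout.shape[3]

        wmat = self.weight.data.reshape(self.out_channels, c * kk)
        dmat = dout.reshape(n, self.out_channels, oh * ow)
        smat = sampled.reshape(n, c * kk, oh * ow)
        self.weight.grad += np.einsum("nol,nkl->ok", dmat, smat).reshape(self.weight.data.shape)
        if self.bias is not None:
            self.bias.grad += dout.sum(axis=(0, 2, 3))
        dsamp = np.einsum("ok,nol->nkl", wmat, dmat).reshape(n, c, kk, oh, ow)

        wy_ = wy[:, None]
        wx_ = wx[:, None]
        # gradient w.r.t. input: scatter bilinear weights to the 4 neighbors
        dx_flat = np.zeros((n, h * w, c), dtype=np.float64)
        for iy, ix, coef in (
            (y0, x0, (1 - wy_) * (1 - wx_)),
            (y0, x0 + 1, (1 - wy_) * wx_),
            (y0 + 1, x0, wy_ * (1 - wx_)),
            (y0 + 1, x0 + 1, wy_ * wx_),
        ):
            valid = (iy >= 0) & (iy < h) & (ix >= 0) & (ix < w)
            flat = np.clip(iy, 0, h - 1) * w + np.clip(ix, 0, w - 1)
            contrib = (dsamp * coef * valid[:, None]).transpose(0, 2, 3, 4, 1)  # (N, kk, OH, OW, C)
            n_idx = np.arange(n)[:, None, None, None]
            np.add.at(dx_flat, (n_idx, flat), contrib)
        dx = dx_flat.reshape(n, h, w, c).transpose(0, 3, 1, 2).astype(np.float32)

        # gradient w.r.t. sampling positions -> offsets
        dpy = (dsamp * (
            -(1 - wx_) * v00 - wx_ * v01 + (1 - wx_) * v10 + wx_ * v11
        )).sum(axis=1)                                  # (N, kk, OH, OW)
        dpx = (dsamp * (
            -(1 - wy_) * v00 + (1 - wy_) * v01 - wy_ * v10 + wy_ * v11
        )).sum(axis=1)
        doff = np.stack([dpy, dpx], axis=2).reshape(n, 2 * kk, oh, ow).astype(np.float32)
        dx += self.offset_conv.backward(doff)
        return dx.astype(np.float32)
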