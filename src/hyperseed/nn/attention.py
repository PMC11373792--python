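"""Channel and spatial attention blocks: squeeze-excitation and CBAM.

Both blocks preserve the feature-map shape and rescale features by
weights in (0, 1) produced through a sigmoid. The CBAM channel MLP is
shared between its average- and max-pooled descriptors, so its
parameter gradients accumulate over both branches; the arithmetic is
written out by hand here rather than reusing :class:`Linear`, because
one layer object would otherwise need two independent caches.
"""

from __future__ import annotations

import numpy as np

from .core import Module, Parameter, he_normal
from .layers import Conv2d

__all__ = ["SEBlock", "CBAMBlock"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return (1.0 / (1.0 + np.exp(-x))).astype(np.float32)


class SEBlock(Module):
    """Squeeze-and-excitation: global average pool -> C/r -> C -> sigmoid.

    ``reduction`` is the channel bottleneck ratio (hidden width is
    ``max(1, C // reduction)``); output channel c is input channel c
    scaled by its learned weight in (0, 1).
    """

    def __init__(self, channels: int, reduction: int = 16, rng: np.random.Generator | None = None) -> None:
        rng = rng or np.random.default_rng(0)
        hidden = max(1, channels // reduction)
        self.channels = channels
        self.reduction = reduction
        self.w1 = Parameter(he_normal(rng, (hidden, channels), channels), "se.w1")
        self.b1 = Parameter(np.zeros(hidden, dtype=np.float32), "se.b1")
        self.w2 = Parameter(he_normal(rng, (channels, hidden), hidden), "se.w2")
        self.b2 = Parameter(np.zeros(channels, dtype=np.float32), "se.b2")

    def squeeze(self, x: np.ndarray) -> np.ndarray:
        return x.mean(axis=(2, 3)).astype(np.float32)

    def excite(self, s: np.ndarray) -> np.ndarray:
        z = s @ self.w1.data.T + self.b1.data
        h = np.maximum(z, 0.0)
        return _sigmoid(h @ self.w2.data.T + self.b2.data)

    def forward(self, x: np.ndarray) -> np.ndarray:
        s = self.squeeze(x)                       # (N, C)
        z = s @ self.w1.data.T + self.b1.data
        h = np.maximum(z, 0.0)
        w = _sigmoid(h @ self.w2.data.T + self.b2.data)  # (N, C)
        self._cache = (x, s, z, h, w)
        return (x * w[:, :, None, None]).astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, s, z, h, w = self._cache
        n, c, hh, ww = x.shape
        dx = dout * w[:, :, None, None]
        dw = (dout * x).sum(axis=(2, 3))          # (N, C)
        da = dw * w * (1.0 - w)                   # through sigmoid
        self.w2.grad += da.T @ h
        self.b2.grad += da.sum(axis=0)
        dh = da @ self.w2.data
        dz = np.where(z > 0, dh, 0.0)
        self.w1.grad += dz.T @ s
        self.b1.grad += dz.sum(axis=0)
        ds = dz @ self.w1.data                    # (N, C)
        dx = dx + ds[:, :, None, None] / (hh * ww)
        return dx.astype(np.float32)


class CBAMBlock(Module):
    """Convolutional block attention: channel attention then spatial.

    Channel stage: parallel global average- and max-pooled descriptors
    through a shared two-layer MLP, summed, sigmoid, per-channel scale.
    Spatial stage: channel-wise mean and max maps, concatenated, k x k
    convolution (k odd), sigmoid, per-position scale.
    """

    def __init__(
        self,
        channels: int,
        reduction: int = 16,
        kernel_size: int = 7,
        rng: np.random.Generator | None = None,
    ) -> None:
        if kernel_size % 2 == 0:
            raise ValueError("spatial-attention kernel must be odd")
        rng = rng or np.random.default_rng(0)
        hidden = max(1, channels // reduction)
        self.channels = channels
        self.kernel_size = kernel_size
        self.w1 = Parameter(he_normal(rng, (hidden, channels), channels), "cbam.w1")
        self.b1 = Parameter(np.zeros(hidden, dtype=np.float32), "cbam.b1")
        self.w2 = Parameter(he_normal(rng, (channels, hidden), hidden), "cbam.w2")
        self.b2 = Parameter(np.zeros(channels, dtype=np.float32), "cbam.b2")
        self.spatial_conv = Conv2d(2, 1, kernel_size, padding=kernel_size // 2, rng=rng)

    def _mlp(self, v: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        z = v @ self.w1.data.T + self.b1.data
        h = np.maximum(z, 0.0)
        return z, h, h @ self.w2.data.T + self.b2.data

    def _mlp_backward(self, dlogit: np.ndarray, v: np.ndarray, z: np.ndarray, h: np.ndarray) -> np.ndarray:
        self.w2.grad += dlogit.T @ h
        self.b2.grad += dlogit.sum(axis=0)
        dh = dlogit @ self.w2.data
        dz = np.where(z > 0, dh, 0.0)
        self.w1.grad += dz.T @ v
        self.b1.grad += dz.sum(axis=0)
        return dz @ self.w1.data

    def channel_weights(self, x: np.ndarray) -> np.ndarray:
        avg = x.mean(axis=(2, 3))
        mx = x.max(axis=(2, 3))
        _, _, la = self._mlp(avg)
        _, _, lm = self._mlp(mx)
        return _sigmoid(la + lm)

    def spatial_weights(self, y: np.ndarray) -> np.ndarray:
        cat = np.stack([y.mean(axis=1), y.max(axis=1)], axis=1).astype(np.float32)
        return _sigmoid(self.spatial_conv.forward(cat))

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, hh, ww = x.shape
        # channel attention
        avg = x.mean(axis=(2, 3)).astype(np.float32)
        mx = x.max(axis=(2, 3)).astype(np.float32)
        mx_idx = x.reshape(n, c, -1).argmax(axis=2)
        za, ha, la = self._mlp(avg)
        zm, hm, lm = self._mlp(mx)
        wc = _sigmoid(la + lm)                    # (N, C)
        y = (x * wc[:, :, None, None]).astype(np.float32)
        # spatial attention
        mean_c = y.mean(axis=1)                   # (N, H, W)
        max_c = y.max(axis=1)
        maxc_idx = y.argmax(axis=1)               # (N, H, W) winning channel
        cat = np.stack([mean_c, max_c], axis=1).astype(np.float32)
        smap = self.spatial_conv.forward(cat)     # (N, 1, H, W)
        ws = _sigmoid(smap)
        out = (y * ws).astype(np.float32)
        self._cache = (x, avg, mx, mx_idx, za, ha, zm, hm, wc, y, maxc_idx, ws)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, avg, mx, mx_idx, za, ha, zm, hm, wc, y, maxc_idx, ws = self._cache
        n, c, hh, ww = x.shape
        # spatial stage
        dy = dout * ws
        dws = (dout * y).sum(axis=1, keepdims=True)          # (N, 1, H, W)
        dsmap = dws * ws * (1.0 - ws)
        dcat = self.spatial_conv.backward(dsmap.astype(np.float32))  # (N, 2, H, W)
        dy = dy + dcat[:, 0:1] / c                           # mean branch
        scatter = np.zeros_like(y)
        np.put_along_axis(scatter, maxc_idx[:, None], dcat[:, 1:2], axis=1)
        dy = dy + scatter                                     # max branch
        # channel stage
        dx = dy * wc[:, :, None, None]
        dwc = (dy * x).sum(axis=(2, 3))
        dlogit = (dwc * wc * (1.0 - wc)).astype(np.float32)
        davg = self._mlp_backward(dlogit, avg, za, ha)
        dmx = self._mlp_backward(dlogit, mx, zm, hm)
        dx = dx + davg[:, :, None, None] / (hh * ww)
        dxf = dx.reshape(n, c, -1)
        np.put_along_axis(
            dxf, mx_idx[:, :, None], np.take_along_axis(dxf, mx_idx[:, :, None], axis=2) + dmx[:, :, None], axis=2
        )
        return dxf.reshape(x.shape).astype(np.float32)
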