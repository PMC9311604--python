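"""Convolutional block attention (CBAM): channel then spatial gating.

The channel submodule squeezes each feature channel with global average *and*
max pooling, pushes both descriptors through one shared bias-free two-layer
MLP (ReLU hidden layer of width ``max(1, channels // ratio)``, linear output),
sums the two outputs elementwise and applies a sigmoid; the resulting per-
channel weight rescales the input map.  The spatial submodule stacks the
channel-wise mean and max maps, convolves them with a single k x k kernel
(same padding, one bias) and applies a sigmoid to obtain a per-position
weight map.  CBAM applies the two gates in sequence, so every output entry is
the input entry shrunk by two factors in (0, 1).

Feature maps here have height 1 after the depthwise electrode convolution,
so the k x k spatial kernel degenerates gracefully to temporal attention;
even kernel sizes pad with the extra cell on the trailing side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .nn import Layer, Param, glorot_uniform, _same_pad

__all__ = [
    "AttentionConfig",
    "ChannelAttention",
    "SpatialAttention",
    "CBAM",
    "channel_attention",
    "spatial_attention",
    "cbam",
]


@dataclass(frozen=True)
class AttentionConfig:
    """Hyperparameters of one CBAM block.

    ratio
        Reduction ratio r of the shared channel MLP; hidden width is
        ``max(1, channels // r)``.
    kernel
        Side k of the k x k spatial convolution.
    hidden_activation
        Name of the hidden activation of the channel MLP (only ``"relu"``
        is implemented; kept as a field to mirror the published table).
    """

    ratio: int = 2
    kernel: int = 2
    hidden_activation: str = "relu"

    def __post_init__(self):
        if self.ratio < 1 or self.kernel < 1:
            raise ValueError("ratio and kernel must be positive")
        if self.hidden_activation != "relu":
            raise ValueError(f"unsupported hidden activation {self.hidden_activation!r}")


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


class ChannelAttention(Layer):
    """Channel gate: sigmoid(MLP(avgpool) + MLP(maxpool)) per feature channel."""

    def __init__(self, n_channels: int, ratio: int, rng: np.random.Generator,
                 dtype=np.float32, name: str = "channel_attention"):
        self.n_channels = int(n_channels)
        self.ratio = int(ratio)
        hidden = max(1, n_channels // ratio)
        self.w1 = Param(glorot_uniform(rng, (hidden, n_channels), n_channels, hidden, dtype),
                        f"{name}.w1")
        self.w2 = Param(glorot_uniform(rng, (n_channels, hidden), hidden, n_channels, dtype),
                        f"{name}.w2")
        self._cache = None

    def params(self):
        return [self.w1, self.w2]

    def weights(self, x: np.ndarray) -> np.ndarray:
        """Per-channel attention weights, shape (N, C), each in (0, 1)."""
        n, c, h, w = x.shape
        if c != self.n_channels:
            raise ValueError(
                f"channel attention built for {self.n_channels} channels, got {c}")
        flat = x.reshape(n, c, h * w)
        avg = flat.mean(axis=-1)
        idx = flat.argmax(axis=-1)
        mx = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        ha = avg @ self.w1.value.T
        hm = mx @ self.w1.value.T
        ra, rm = np.maximum(ha, 0), np.maximum(hm, 0)
        z = ra @ self.w2.value.T + rm @ self.w2.value.T
        s = _sigmoid(z)
        self._cache = (x, avg, mx, idx, ha, hm, ra, rm, s)
        return s

    def forward(self, x, training=False, rng=None):
        s = self.weights(x)
        return x * s[:, :, None, None]

    def backward(self, dy):
        x, avg, mx, idx, ha, hm, ra, rm, s = self._cache
        n, c, h, w = x.shape
        ds = (dy * x).sum(axis=(2, 3))
        dx = dy * s[:, :, None, None]
        dz = ds * s * (1.0 - s)
        self.w2.grad += dz.T @ ra + dz.T @ rm
        dra = dz @ self.w2.value
        dha = dra * (ha > 0)
        dhm = dra * (hm > 0)
        self.w1.grad += dha.T @ avg + dhm.T @ mx
        davg = dha @ self.w1.value
        dmx = dhm @ self.w1.value
        dx = dx + davg[:, :, None, None] / (h * w)
        dflat = np.zeros((n, c, h * w), dtype=dy.dtype)
        np.put_along_axis(dflat, idx[..., None], dmx[..., None], axis=-1)
        return dx + dflat.reshape(x.shape)


class SpatialAttention(Layer):
    """Spatial gate: sigmoid(conv_kxk([mean over channels; max over channels]))."""

    def __init__(self, kernel: int, rng: np.random.Generator,
                 dtype=np.float32, name: str = "spatial_attention"):
        self.kernel = int(kernel)
        self.pad_h = _same_pad(self.kernel)
        self.pad_w = _same_pad(self.kernel)
        fan_in = 2 * kernel * kernel
        self.weight = Param(glorot_uniform(rng, (2, kernel, kernel), fan_in, 1, dtype),
                            f"{name}.weight")
        self.bias = Param(np.zeros(1, dtype=dtype), f"{name}.bias")
        self._cache = None

    def params(self):
        return [self.weight, self.bias]

    def map(self, x: np.ndarray) -> np.ndarray:
        """Spatial attention map, shape (N, 1, H, W), each entry in (0, 1)."""
        n, c, h, w = x.shape
        avg = x.mean(axis=1)
        idx = x.argmax(axis=1)
        mx = np.take_along_axis(x, idx[:, None], axis=1)[:, 0]
        d = np.stack([avg, mx], axis=1)  # (N, 2, H, W)
        dp = np.pad(d, ((0, 0), (0, 0), self.pad_h, self.pad_w))
        view = sliding_window_view(dp, (self.kernel, self.kernel), axis=(2, 3))
        z = np.einsum("nchwij,cij->nhw", view, self.weight.value, optimize=True)
        p = _sigmoid(z + self.bias.value[0])
        self._cache = (x, idx, dp, p)
        return p[:, None]

    def forward(self, x, training=False, rng=None):
        p = self.map(x)
        return x * p

    def backward(self, dy):
        x, idx, dp, p = self._cache
        n, c, h, w = x.shape
        k = self.kernel
        dpmap = (dy * x).sum(axis=1)  # (N, H, W)
        dx = dy * p[:, None]
        dz = dpmap * p * (1.0 - p)
        view = sliding_window_view(dp, (k, k), axis=(2, 3))
        self.weight.grad += np.einsum("nchwij,nhw->cij", view, dz, optimize=True)
        self.bias.grad += dz.sum(keepdims=True).reshape(1)
        ddp = np.zeros_like(dp)
        for i in range(k):
            for j in range(k):
                ddp[:, :, i:i + h, j:j + w] += dz[:, None] * self.weight.value[None, :, i, j, None, None]
        dd = ddp[:, :, self.pad_h[0]:self.pad_h[0] + h, self.pad_w[0]:self.pad_w[0] + w]
        dx = dx + dd[:, 0:1] / c
        dmax = np.zeros_like(x)
        np.put_along_axis(dmax, idx[:, None], dd[:, 1:2], axis=1)
        return dx + dmax


class CBAM(Layer):
    """Sequential channel-then-spatial attention over a feature map."""

    def __init__(self, n_channels: int, cfg: AttentionConfig, rng: np.random.Generator,
                 dtype=np.float32, name: str = "cbam"):
        self.cfg = cfg
        self.channel = ChannelAttention(n_channels, cfg.ratio, rng, dtype,
                                        name=f"{name}.channel")
        self.spatial = SpatialAttention(cfg.kernel, rng, dtype, name=f"{name}.spatial")

    def params(self):
        return self.channel.params() + self.spatial.params()

    def forward(self, x, training=False, rng=None):
        return self.spatial.forward(self.channel.forward(x, training, rng), training, rng)

    def backward(self, dy):
        return self.channel.backward(self.spatial.backward(dy))


def _as_batch(fmap: np.ndarray) -> np.ndarray:
    fmap = np.asarray(fmap)
    if fmap.ndim != 3:
        raise ValueError(f"feature map must have 3 axes (C, H, W), got shape {fmap.shape}")
    if not np.all(np.isfinite(fmap)):
        raise ValueError("feature map contains non-finite values")
    return fmap[None]


def channel_attention(fmap: np.ndarray, module: ChannelAttention) -> np.ndarray:
    """Channel attention weights for a single (C, H, W) feature map."""
    return module.weights(_as_batch(fmap))[0]


def spatial_attention(fmap: np.ndarray, module: SpatialAttention) -> np.ndarray:
    """Spatial attention map (1, H, W) for a single (C, H, W) feature map."""
    return module.map(_as_batch(fmap))[0]


def cbam(fmap: np.ndarray, module: CBAM) -> np.ndarray:
    """Apply channel-then-spatial attention to a single (C, H, W) feature map."""
    return module.forward(_as_batch(fmap))[0]
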