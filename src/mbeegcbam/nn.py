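"""Minimal NumPy neural-network layers with explicit backward passes.

Every layer operates on 4-axis arrays laid out as (batch, channels, height,
width).  For EEG trials the height axis carries electrodes and the width axis
carries time samples; after the depthwise spatial convolution the electrode
axis collapses to 1 and the feature-channel axis carries filter outputs.

Layers cache whatever the backward pass needs during ``forward`` and
accumulate parameter gradients into ``Param.grad`` during ``backward``.
Gradients are exact (verified against finite differences in the test suite);
the temporal convolution reuses its forward FFTs for both backward products.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import fft as _fft

from . import _kernels

__all__ = [
    "Param",
    "Layer",
    "TemporalConv",
    "DepthwiseSpatialConv",
    "DepthwiseTemporalConv",
    "PointwiseConv",
    "BatchNorm",
    "ELU",
    "AvgPool",
    "Dropout",
    "Dense",
    "softmax",
    "glorot_uniform",
    "he_normal",
]


class Param:
    """A named tensor with an accumulated gradient and a trainable flag."""

    __slots__ = ("value", "grad", "name", "trainable")

    def __init__(self, value: np.ndarray, name: str, trainable: bool = True):
        self.value = np.asarray(value)
        self.grad = np.zeros_like(self.value)
        self.name = name
        self.trainable = trainable

    @property
    def size(self) -> int:
        return int(self.value.size)

    def zero_grad(self) -> None:
        self.grad[...] = 0


class Layer:
    """Base class: ``forward`` caches, ``backward`` returns d(loss)/d(input)."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = False, rng=None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def he_normal(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    """Variance-scaling init used for convolution kernels."""
    std = np.sqrt(2.0 / max(1, fan_in))
    return rng.normal(0.0, std, shape).astype(dtype)


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int, dtype) -> np.ndarray:
    """Uniform fan-based init used for dense / MLP weights."""
    limit = np.sqrt(6.0 / max(1, fan_in + fan_out))
    return rng.uniform(-limit, limit, shape).astype(dtype)


def _same_pad(kernel: int) -> tuple[int, int]:
    # Even kernels put the extra padding cell on the trailing side.
    left = (kernel - 1) // 2
    return left, kernel - 1 - left


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class TemporalConv(Layer):
    """``n_filters`` kernels of shape 1 x K correlated along the time axis.

    Input (N, 1, E, T) -> output (N, F, E, T); same padding, no bias.  The
    convolution runs in the frequency domain: the padded input is transformed
    once per forward call and the cached spectrum serves all three products
    (output, input gradient, weight gradient).
    """

    def __init__(self, n_filters: int, kernel: int, rng: np.random.Generator,
                 dtype=np.float32, name: str = "temporal_conv",
                 input_layer: bool = False):
        if n_filters < 1 or kernel < 1:
            raise ValueError("n_filters and kernel must be positive")
        self.kernel = int(kernel)
        self.pad_left, self.pad_right = _same_pad(self.kernel)
        self.weight = Param(he_normal(rng, (n_filters, kernel), kernel, dtype),
                            f"{name}.weight")
        # an input layer never propagates a gradient to its input
        self.input_layer = bool(input_layer)
        self._cache = None

    def params(self):
        return [self.weight]

    def forward(self, x, training=False, rng=None):
        n, cin, e, t = x.shape
        if cin != 1:
            raise ValueError(f"temporal conv expects a single input channel, got {cin}")
        k = self.kernel
        wp = t + k - 1
        nfft = _fft.next_fast_len(wp, real=True)
        # pad straight to the FFT length so the transform needs no extra copy
        xp = np.pad(x, ((0, 0), (0, 0), (0, 0),
                        (self.pad_left, nfft - t - self.pad_left)))
        xf = _fft.rfft(xp, axis=-1)
        wf = _fft.rfft(self.weight.value, n=nfft, axis=-1)
        # cross-correlation: y[t] = sum_k x_pad[t+k] w[k]
        y = _fft.irfft(xf * np.conj(wf)[None, :, None, :], n=nfft, axis=-1)[..., :t]
        self._cache = (xf, n, e, t, wp, nfft, x.dtype)
        # one contiguity copy here saves repeated implicit copies downstream
        return np.ascontiguousarray(y)

    def backward(self, dy):
        xf, n, e, t, wp, nfft, dtype = self._cache
        k = self.kernel
        w = self.weight.value
        if dy.shape[-1] != nfft:
            dy = np.pad(dy, ((0, 0),) * 3 + ((0, nfft - t),))
        dyf = _fft.rfft(dy, axis=-1)
        # dw[f,k] = sum_{n,e,t} dy[n,f,e,t] x_pad[n,0,e,t+k]
        gf = np.einsum("nel,nfel->fl", xf[:, 0], np.conj(dyf))
        dw = _fft.irfft(gf, n=nfft, axis=-1)[:, :k]
        self.weight.grad += dw.astype(self.weight.value.dtype)
        if self.input_layer:
            return None
        wf = _fft.rfft(w, n=nfft, axis=-1)
        # dx_pad[s] = sum_{f,t} dy[f,t] w[f, s-t]  (plain convolution, summed over filters)
        zf = np.einsum("nfel,fl->nel", dyf, wf)
        dxp = _fft.irfft(zf, n=nfft, axis=-1)[..., :wp]
        return np.ascontiguousarray(dxp[..., self.pad_left:self.pad_left + t][:, None])


class DepthwiseSpatialConv(Layer):
    """Depthwise convolution of size E x 1 over the electrode axis.

    Each of the F input feature channels gets D filters spanning all E
    electrodes, collapsing the electrode axis: (N, F, E, T) -> (N, F*D, 1, T).
    No bias.
    """

    def __init__(self, n_in: int, depth_multiplier: int, n_electrodes: int,
                 rng: np.random.Generator, dtype=np.float32, name: str = "depthwise_spatial"):
        self.n_in = int(n_in)
        self.depth = int(depth_multiplier)
        self.n_electrodes = int(n_electrodes)
        self.weight = Param(
            he_normal(rng, (n_in, depth_multiplier, n_electrodes), n_electrodes, dtype),
            f"{name}.weight")
        self._x = None

    def params(self):
        return [self.weight]

    def forward(self, x, training=False, rng=None):
        n, f, e, t = x.shape
        if f != self.n_in or e != self.n_electrodes:
            raise ValueError(
                f"depthwise spatial conv built for ({self.n_in}, {self.n_electrodes}) "
                f"channels x electrodes, got ({f}, {e})")
        self._x = x
        return _kernels.dw_spatial_forward(np.ascontiguousarray(x), self.weight.value)

    def backward(self, dy):
        dx, dw = _kernels.dw_spatial_backward(np.ascontiguousarray(dy),
                                              self._x, self.weight.value)
        self.weight.grad += dw
        return dx


class DepthwiseTemporalConv(Layer):
    """Per-channel 1 x K convolution along time (first half of the separable conv)."""

    def __init__(self, n_channels: int, kernel: int, rng: np.random.Generator,
                 dtype=np.float32, name: str = "separable_depthwise"):
        self.kernel = int(kernel)
        self.pad_left, self.pad_right = _same_pad(self.kernel)
        self.weight = Param(he_normal(rng, (n_channels, kernel), kernel, dtype),
                            f"{name}.weight")
        self._cache = None

    def params(self):
        return [self.weight]

    def forward(self, x, training=False, rng=None):
        n, c, h, t = x.shape
        if c != self.weight.value.shape[0]:
            raise ValueError("channel count mismatch in separable depthwise conv")
        xp = np.pad(x, ((0, 0), (0, 0), (0, 0), (self.pad_left, self.pad_right)))
        view = sliding_window_view(xp, self.kernel, axis=-1)  # (N,C,H,T,K)
        y = np.einsum("nchtk,ck->ncht", view, self.weight.value, optimize=True)
        self._cache = (xp, x.shape)
        return y

    def backward(self, dy):
        xp, xshape = self._cache
        n, c, h, t = xshape
        k = self.kernel
        view = sliding_window_view(xp, k, axis=-1)
        self.weight.grad += np.einsum("nchtk,ncht->ck", view, dy, optimize=True)
        # full convolution of dy with w gives the padded-input gradient
        dyp = np.pad(dy, ((0, 0), (0, 0), (0, 0), (k - 1, k - 1)))
        vback = sliding_window_view(dyp, k, axis=-1)[..., :t + k - 1, :]
        dxp = np.einsum("nchtk,ck->ncht", vback, self.weight.value[:, ::-1], optimize=True)
        return np.ascontiguousarray(dxp[..., self.pad_left:self.pad_left + t])


class PointwiseConv(Layer):
    """1 x 1 convolution mixing feature channels (second half of the separable conv)."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 dtype=np.float32, name: str = "separable_pointwise"):
        self.weight = Param(he_normal(rng, (n_out, n_in), n_in, dtype), f"{name}.weight")
        self._x = None

    def params(self):
        return [self.weight]

    def forward(self, x, training=False, rng=None):
        self._x = x
        return np.einsum("ncht,oc->noht", x, self.weight.value, optimize=True)

    def backward(self, dy):
        self.weight.grad += np.einsum("noht,ncht->oc", dy, self._x, optimize=True)
        return np.einsum("noht,oc->ncht", dy, self.weight.value, optimize=True)


class BatchNorm(Layer):
    """Batch normalization over the feature-channel axis.

    Training mode normalizes with batch statistics over (batch, height, width)
    and updates exponential running statistics; inference mode uses the stored
    running statistics.  Running statistics are non-trainable parameters and
    are excluded from trainable-parameter counts.
    """

    def __init__(self, n_channels: int, eps: float = 1e-3, momentum: float = 0.99,
                 dtype=np.float32, name: str = "batch_norm"):
        self.eps = float(eps)
        self.momentum = float(momentum)
        self.gamma = Param(np.ones(n_channels, dtype=dtype), f"{name}.gamma")
        self.beta = Param(np.zeros(n_channels, dtype=dtype), f"{name}.beta")
        self.running_mean = Param(np.zeros(n_channels, dtype=dtype),
                                  f"{name}.running_mean", trainable=False)
        self.running_var = Param(np.ones(n_channels, dtype=dtype),
                                 f"{name}.running_var", trainable=False)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta, self.running_mean, self.running_var]

    def forward(self, x, training=False, rng=None):
        if x.shape[1] != self.gamma.size:
            raise ValueError("batch norm channel mismatch")
        x = np.ascontiguousarray(x)
        if training:
            m = x.shape[0] * x.shape[2] * x.shape[3]
            s1, s2 = _kernels.bn_stats(x)
            mu = (s1 / m).astype(x.dtype)
            var = np.maximum(s2 / m - (s1 / m) ** 2, 0.0).astype(x.dtype)
            mom = self.momentum
            self.running_mean.value[...] = mom * self.running_mean.value + (1 - mom) * mu
            self.running_var.value[...] = mom * self.running_var.value + (1 - mom) * var
        else:
            mu = self.running_mean.value
            var = self.running_var.value
        inv_std = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)
        self._cache = (x, mu, inv_std, training)
        scale = self.gamma.value * inv_std
        shift = self.beta.value - mu * scale
        return _kernels.bn_apply(x, scale, shift)

    def backward(self, dy):
        x, mu, inv_std, training = self._cache
        dy = np.ascontiguousarray(dy)
        # sums computed against raw x to avoid materializing xhat
        sdy64, sdyx64 = _kernels.bn_grad_sums(dy, x)
        sdy = sdy64.astype(dy.dtype)
        sdyx = sdyx64.astype(dy.dtype)
        dgamma = inv_std * (sdyx - mu * sdy)
        self.gamma.grad += dgamma
        self.beta.grad += sdy
        g = self.gamma.value * inv_std
        if not training:
            return _kernels.bn_apply(dy, g, np.zeros_like(g))
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        # dx = g * (dy - mean(dy) - xhat * mean(dy * xhat))
        a = g
        b = -g * inv_std * dgamma / m
        c = -g * (sdy / m) - b * mu
        return _kernels.bn_grad_x(dy, x, a.astype(dy.dtype), b.astype(dy.dtype),
                                  c.astype(dy.dtype))


class ELU(Layer):
    """Exponential linear unit, alpha = 1."""

    def __init__(self, alpha: float = 1.0):
        self.alpha = float(alpha)
        self._cache = None

    def forward(self, x, training=False, rng=None):
        neg = self.alpha * np.expm1(np.minimum(x, 0))
        y = np.where(x > 0, x, neg)
        self._cache = (x > 0, neg)
        return y.astype(x.dtype)

    def backward(self, dy):
        pos, neg = self._cache
        return dy * np.where(pos, 1.0, neg + self.alpha).astype(dy.dtype)


class AvgPool(Layer):
    """Non-overlapping 1 x pool average pooling along time; trailing remainder dropped."""

    def __init__(self, pool: int, stage: str = "pooling"):
        if pool < 1:
            raise ValueError("pool size must be positive")
        self.pool = int(pool)
        self.stage = stage
        self._cache = None

    def forward(self, x, training=False, rng=None):
        n, c, h, t = x.shape
        t_out = t // self.pool
        if t_out < 1:
            raise ValueError(
                f"time axis of length {t} too short for {self.stage} "
                f"(pool size {self.pool})")
        self._cache = (x.shape, t_out)
        y = x[..., :t_out * self.pool].reshape(n, c, h, t_out, self.pool).mean(axis=-1)
        return y

    def backward(self, dy):
        xshape, t_out = self._cache
        dx = np.zeros(xshape, dtype=dy.dtype)
        dx[..., :t_out * self.pool] = np.repeat(dy / self.pool, self.pool, axis=-1)
        return dx


class Dropout(Layer):
    """Inverted dropout: active only in training mode, identity at inference."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = float(rate)
        self._mask = None

    def forward(self, x, training=False, rng=None):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs a random generator")
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


class Dense(Layer):
    """Fully connected layer with bias on flat (N, features) input."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 dtype=np.float32, name: str = "dense"):
        self.weight = Param(glorot_uniform(rng, (n_out, n_in), n_in, n_out, dtype),
                            f"{name}.weight")
        self.bias = Param(np.zeros(n_out, dtype=dtype), f"{name}.bias")
        self._x = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x, training=False, rng=None):
        if x.ndim != 2 or x.shape[1] != self.weight.value.shape[1]:
            raise ValueError(
                f"dense layer expects (N, {self.weight.value.shape[1]}) input, "
                f"got {x.shape}")
        self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, dy):
        self.weight.grad += dy.T @ self._x
        self.bias.grad += dy.sum(axis=0)
        return dy @ self.weight.value
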