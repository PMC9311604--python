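"""Fused numeric kernels for the memory-bound hot spots.

The stage-1 tensors (batch x filters x electrodes x samples) are large
enough that every extra elementwise pass costs real time; these numba
kernels fuse the batch-norm statistics, affine application and gradient
expressions into single passes.  All kernels are single-threaded and
bit-stable across calls.
"""

from __future__ import annotations

import numba
import numpy as np

_sig_cfg = dict(cache=False, fastmath=False, nogil=True)


@numba.njit(**_sig_cfg)
def bn_stats(x):
    """Per-channel sum and sum of squares in one pass over (N, C, H, W)."""
    n, c, h, w = x.shape
    s1 = np.zeros(c, dtype=np.float64)
    s2 = np.zeros(c, dtype=np.float64)
    for i in range(n):
        for j in range(c):
            acc1 = 0.0
            acc2 = 0.0
            for k in range(h):
                row = x[i, j, k]
                for l in range(w):
                    v = float(row[l])
                    acc1 += v
                    acc2 += v * v
            s1[j] += acc1
            s2[j] += acc2
    return s1, s2


@numba.njit(**_sig_cfg)
def bn_apply(x, scale, shift):
    """y = x * scale[c] + shift[c]."""
    n, c, h, w = x.shape
    y = np.empty_like(x)
    for i in range(n):
        for j in range(c):
            sc = scale[j]
            sh = shift[j]
            for k in range(h):
                for l in range(w):
                    y[i, j, k, l] = x[i, j, k, l] * sc + sh
    return y


@numba.njit(**_sig_cfg)
def bn_grad_sums(dy, x):
    """Per-channel (sum dy, sum dy*x) in one pass."""
    n, c, h, w = dy.shape
    sdy = np.zeros(c, dtype=np.float64)
    sdyx = np.zeros(c, dtype=np.float64)
    for i in range(n):
        for j in range(c):
            a1 = 0.0
            a2 = 0.0
            for k in range(h):
                for l in range(w):
                    g = float(dy[i, j, k, l])
                    a1 += g
                    a2 += g * float(x[i, j, k, l])
            sdy[j] += a1
            sdyx[j] += a2
    return sdy, sdyx


@numba.njit(**_sig_cfg)
def bn_grad_x(dy, x, a, b, c0):
    """dx = dy * a[c] + x * b[c] + c0[c] in one fused pass."""
    n, c, h, w = dy.shape
    dx = np.empty_like(dy)
    for i in range(n):
        for j in range(c):
            aj, bj, cj = a[j], b[j], c0[j]
            for k in range(h):
                for l in range(w):
                    dx[i, j, k, l] = dy[i, j, k, l] * aj + x[i, j, k, l] * bj + cj
    return dx


@numba.njit(**_sig_cfg)
def dw_spatial_forward(x, w):
    """(N, F, E, T), (F, D, E) -> (N, F*D, 1, T)."""
    n, f, e, t = x.shape
    d = w.shape[1]
    y = np.zeros((n, f * d, 1, t), dtype=x.dtype)
    for i in range(n):
        for j in range(f):
            for m in range(d):
                out = y[i, j * d + m, 0]
                for k in range(e):
                    wv = w[j, m, k]
                    row = x[i, j, k]
                    for l in range(t):
                        out[l] += wv * row[l]
    return y


@numba.njit(**_sig_cfg)
def dw_spatial_backward(dy, x, w):
    """Gradients of dw_spatial_forward: returns (dx, dw)."""
    n, f, e, t = x.shape
    d = w.shape[1]
    dx = np.zeros_like(x)
    dw = np.zeros_like(w)
    for i in range(n):
        for j in range(f):
            for m in range(d):
                g = dy[i, j * d + m, 0]
                for k in range(e):
                    row = x[i, j, k]
                    dxr = dx[i, j, k]
                    wv = w[j, m, k]
                    acc = 0.0
                    for l in range(t):
                        gv = g[l]
                        dxr[l] += wv * gv
                        acc += gv * row[l]
                    dw[j, m, k] += acc
    return dx, dw
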