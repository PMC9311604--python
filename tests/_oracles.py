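"""Independent scalar-loop oracles used to cross-check the vectorized code.

Everything here is written with explicit Python loops straight from the
defining formulas, deliberately sharing no code with the package internals.
"""

import itertools
import math

import numpy as np


def sigmoid(z):
    return 1.0 / (1.0 + math.exp(-z))


def channel_attention_oracle(fmap, w1, w2):
    """Per-channel weights sigmoid(MLP(avg) + MLP(max)) by explicit loops."""
    c, h, w = fmap.shape
    hidden = w1.shape[0]
    avg = [sum(fmap[i, j, k] for j in range(h) for k in range(w)) / (h * w)
           for i in range(c)]
    mx = [max(fmap[i, j, k] for j in range(h) for k in range(w)) for i in range(c)]
    out = []
    for i in range(c):
        z = 0.0
        for desc in (avg, mx):
            hid = [max(0.0, sum(w1[a, b] * desc[b] for b in range(c)))
                   for a in range(hidden)]
            z += sum(w2[i, a] * hid[a] for a in range(hidden))
        out.append(sigmoid(z))
    return np.array(out)


def spatial_attention_oracle(fmap, kernel_weights, bias):
    """Spatial map sigmoid(conv_kxk([mean; max])) with explicit sliding windows.

    Same padding; even kernels put the extra padded cell on the trailing side.
    """
    c, h, w = fmap.shape
    k = kernel_weights.shape[1]
    avg = [[sum(fmap[i, y, x] for i in range(c)) / c for x in range(w)]
           for y in range(h)]
    mx = [[max(fmap[i, y, x] for i in range(c)) for x in range(w)]
          for y in range(h)]
    pad_lead = (k - 1) // 2
    out = np.empty((1, h, w))
    for y in range(h):
        for x in range(w):
            z = bias
            for ci, plane in enumerate((avg, mx)):
                for i in range(k):
                    for j in range(k):
                        yy = y - pad_lead + i
                        xx = x - pad_lead + j
                        if 0 <= yy < h and 0 <= xx < w:
                            z += kernel_weights[ci, i, j] * plane[yy][xx]
            out[0, y, x] = sigmoid(z)
    return out


def cbam_oracle(fmap, w1, w2, kernel_weights, bias):
    """Channel gate then spatial gate, composed from the two oracles above."""
    cw = channel_attention_oracle(fmap, w1, w2)
    gated = fmap * cw[:, None, None]
    sm = spatial_attention_oracle(gated, kernel_weights, bias)
    return gated * sm


def wilcoxon_exact_oracle(diffs):
    """Two-sided exact p by enumerating every sign assignment of |d| ranks."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    order = np.argsort(np.abs(d))
    ranks = np.empty(n)
    # average ranks for ties
    sorted_abs = np.abs(d)[order]
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sorted_abs[j + 1] == sorted_abs[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    w_plus = ranks[d > 0].sum()
    w_all = []
    for signs in itertools.product((0, 1), repeat=n):
        w_all.append(sum(r for r, s in zip(ranks, signs) if s))
    w_all = np.array(w_all)
    lo = float(np.mean(w_all <= w_plus))
    hi = float(np.mean(w_all >= w_plus))
    return min(1.0, 2 * min(lo, hi))
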