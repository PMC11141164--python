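"""Naive loop-based oracles for the attention math, used only in tests.

Every function here evaluates the defining sums position-by-position (or
channel-by-channel) with explicit Python loops and no matrix algebra, so
the vectorized implementations in :mod:`datransunet.attention` can be
checked against an independent route.
"""

from __future__ import annotations

import numpy as np


def spatial_affinity_reference(b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Per-pair exponential/normalize evaluation of the spatial map."""
    b = np.asarray(b, dtype=np.float64)
    c = np.asarray(c, dtype=np.float64)
    ch, h, w = b.shape
    n = h * w
    bf = b.reshape(ch, n)
    cf = c.reshape(ch, n)
    s = np.zeros((n, n))
    for j in range(n):
        logits = np.array([float(bf[:, i] @ cf[:, j]) for i in range(n)])
        logits -= logits.max()
        e = np.exp(logits)
        s[j] = e / e.sum()
    return s


def channel_affinity_reference(a: np.ndarray) -> np.ndarray:
    """Per-pair evaluation of the channel (Gram-matrix) map."""
    a = np.asarray(a, dtype=np.float64)
    ch = a.shape[0]
    af = a.reshape(ch, -1)
    x = np.zeros((ch, ch))
    for j in range(ch):
        logits = np.array([float(af[i] @ af[j]) for i in range(ch)])
        logits -= logits.max()
        e = np.exp(logits)
        x[j] = e / e.sum()
    return x


def _conv1x1_loop(a: np.ndarray, w: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """1x1 convolution evaluated pixel by pixel."""
    cout = w.shape[0]
    _, h, wd = a.shape
    out = np.zeros((cout, h, wd))
    for y in range(h):
        for x in range(wd):
            out[:, y, x] = w[:, :, 0, 0] @ a[:, y, x] + bias
    return out


def pam_reference(a: np.ndarray, weights: dict, alpha: float) -> np.ndarray:
    """Loop evaluation of gated position attention.

    ``weights`` holds the 1x1 convolution parameters ``wq, bq`` (query,
    the "C" projection), ``wk, bk`` (key, "B") and ``wv, bv`` (value,
    "D"), each with torch-style OIHW weight layout.
    """
    a = np.asarray(a, dtype=np.float64)
    ch, h, w = a.shape
    n = h * w
    q = _conv1x1_loop(a, weights["wq"], weights["bq"]).reshape(ch, n)
    k = _conv1x1_loop(a, weights["wk"], weights["bk"]).reshape(ch, n)
    v = _conv1x1_loop(a, weights["wv"], weights["bv"]).reshape(ch, n)
    s = np.zeros((n, n))
    for j in range(n):
        logits = np.array([float(k[:, i] @ q[:, j]) for i in range(n)])
        logits -= logits.max()
        e = np.exp(logits)
        s[j] = e / e.sum()
    e_out = np.zeros((ch, n))
    for j in range(n):
        acc = np.zeros(ch)
        for i in range(n):
            acc += s[j, i] * v[:, i]
        e_out[:, j] = alpha * acc + a.reshape(ch, n)[:, j]
    return e_out.reshape(ch, h, w)


def cam_reference(a: np.ndarray, beta: float) -> np.ndarray:
    """Loop evaluation of gated channel attention."""
    a = np.asarray(a, dtype=np.float64)
    ch, h, w = a.shape
    af = a.reshape(ch, -1)
    x = channel_affinity_reference(a)
    out = np.zeros_like(af)
    for j in range(ch):
        acc = np.zeros(af.shape[1])
        for i in range(ch):
            acc += x[j, i] * af[i]
        out[j] = beta * acc + af[j]
    return out.reshape(ch, h, w)


def hausdorff_reference(points_a: np.ndarray, points_b: np.ndarray) -> float:
    """O(n^2) double-loop symmetric Hausdorff distance between point sets."""
    points_a = np.asarray(points_a, dtype=np.float64)
    points_b = np.asarray(points_b, dtype=np.float64)

    def directed(src, dst):
        worst = 0.0
        for p in src:
            best = min(float(np.sqrt(((p - q) ** 2).sum())) for q in dst)
            worst = max(worst, best)
        return worst

    return max(directed(points_a, points_b), directed(points_b, points_a))
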