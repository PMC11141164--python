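"""Position and channel attention (PAM/CAM) and the dual-attention block.

PAM computes an N x N affinity between all spatial positions of a feature
map (N = H*W) from two 1x1-convolved projections, and mixes a third
projection with that affinity; CAM does the analogue across channels using
the Gram matrix of the raw feature map.  Both carry a learnable residual
gate (alpha, beta) initialized at zero, so each module starts as the
identity and learns how much attention-mixed signal to blend in.

The dual-attention block wraps each module in channel-reducing and
restoring convolutions (intermediate width = in_channels / reduction) and
fuses the two branches with a single 1x1 convolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import functional as F
from .nn.tensor import Tensor


@dataclass(frozen=True)
class DABlockConfig:
    """Configuration of a dual-attention block.

    Parameters
    ----------
    in_channels:
        Channel count of the feature map entering (and leaving) the block.
    reduction:
        Divisor mapping ``in_channels`` to the intermediate width; the
        block computes attention at ``max(1, in_channels // reduction)``
        channels.  16 is the deployed default.
    dropout_rate:
        Optional dropout before the channel-restoring convolution.
    """

    in_channels: int
    reduction: int = 16
    dropout_rate: float = 0.0

    def __post_init__(self):
        if self.in_channels < 1:
            raise ValueError("in_channels must be positive")
        if self.reduction < 1:
            raise ValueError("reduction must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")

    @property
    def mid_channels(self) -> int:
        return max(1, self.in_channels // self.reduction)


def _as_batched(x):
    """Return (array, had_batch_axis) with shape (B, C, H, W)."""
    arr = x.data if isinstance(x, Tensor) else np.asarray(x)
    if arr.ndim == 3:
        return arr[None], False
    if arr.ndim == 4:
        return arr, True
    raise ValueError(f"expected a CxHxW or BxCxHxW array, got shape {arr.shape}")


def _check_finite(arr: np.ndarray, name: str) -> None:
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")


def _row_softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def spatial_affinity(b, c) -> np.ndarray:
    """Row-stochastic N x N spatial attention map.

    ``S[j, i] = exp(b_i . c_j) / sum_i exp(b_i . c_j)`` where ``b_i`` and
    ``c_j`` are the per-position channel vectors of the two projections.
    Accepts ``CxHxW`` or batched ``BxCxHxW`` input; returns ``NxN`` or
    ``BxNxN`` accordingly.
    """
    bb, batched_b = _as_batched(b)
    cc, batched_c = _as_batched(c)
    if bb.shape != cc.shape:
        raise ValueError(f"shape mismatch: {bb.shape} vs {cc.shape}")
    _check_finite(bb, "b")
    _check_finite(cc, "c")
    n, ch = bb.shape[0], bb.shape[1]
    bf = bb.reshape(n, ch, -1)
    cf = cc.reshape(n, ch, -1)
    logits = np.einsum("bci,bcj->bji", bf, cf)  # [j, i] = b_i . c_j
    s = _row_softmax(logits)
    return s if (batched_b or batched_c) else s[0]


def channel_affinity(a) -> np.ndarray:
    """Row-stochastic C x C channel attention map from the Gram matrix.

    ``X[j, i] = exp(a_i . a_j) / sum_i exp(a_i . a_j)`` with ``a_i`` the
    flattened spatial vector of channel ``i``.  The softmax subtracts the
    row maximum before exponentiation for numerical stability, which
    leaves the result unchanged.
    """
    aa, batched = _as_batched(a)
    _check_finite(aa, "a")
    n, ch = aa.shape[0], aa.shape[1]
    af = aa.reshape(n, ch, -1)
    gram = np.einsum("bjn,bin->bji", af, af)
    x = _row_softmax(gram)
    return x if batched else x[0]


class PositionAttention(nn.Module):
    """PAM: gated spatial self-attention with 1x1 query/key/value convs.

    The three projections keep the full channel count and the residual
    gate ``alpha`` starts at zero (the module is initially the identity).
    """

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        self.query = nn.Conv2d(channels, channels, 1, rng)
        self.key = nn.Conv2d(channels, channels, 1, rng)
        self.value = nn.Conv2d(channels, channels, 1, rng)
        self.alpha = nn.Parameter(np.zeros(1))

    def forward(self, x):
        arr, batched = _as_batched(x)
        _check_finite(arr, "input")
        t = x if isinstance(x, Tensor) else Tensor(arr)
        if t.ndim == 3:
            t = F.reshape(t, (1,) + t.shape)
        n, c, h, w = t.shape
        q = F.reshape(self.query(t), (n, c, h * w))   # "C" projection of the affinity
        k = F.reshape(self.key(t), (n, c, h * w))     # "B" projection
        v = F.reshape(self.value(t), (n, c, h * w))   # "D" projection
        logits = F.matmul(F.transpose(q, (0, 2, 1)), k)      # [j, i] = k_i . q_j
        s = F.softmax(logits, axis=-1)
        mixed = F.transpose(F.matmul(s, F.transpose(v, (0, 2, 1))), (0, 2, 1))
        out = self.alpha * F.reshape(mixed, (n, c, h, w)) + t
        if not batched:
            out = F.reshape(out, (c, h, w))
        return out if isinstance(x, Tensor) else out.numpy()


class ChannelAttention(nn.Module):
    """CAM: gated channel self-attention on the raw feature map.

    No convolutions are involved: the affinity is the row-softmaxed Gram
    matrix of flattened channels, and ``beta`` gates the residual mix.
    """

    def __init__(self):
        super().__init__()
        self.beta = nn.Parameter(np.zeros(1))

    def forward(self, x):
        arr, batched = _as_batched(x)
        _check_finite(arr, "input")
        t = x if isinstance(x, Tensor) else Tensor(arr)
        if t.ndim == 3:
            t = F.reshape(t, (1,) + t.shape)
        n, c, h, w = t.shape
        af = F.reshape(t, (n, c, h * w))
        gram = F.matmul(af, F.transpose(af, (0, 2, 1)))
        xmap = F.softmax(gram, axis=-1)
        mixed = F.reshape(F.matmul(xmap, af), (n, c, h, w))
        out = self.beta * mixed + t
        if not batched:
            out = F.reshape(out, (c, h, w))
        return out if isinstance(x, Tensor) else out.numpy()


def _conv_bn_relu(cin: int, cout: int, rng: np.random.Generator) -> nn.Sequential:
    return nn.Sequential(
        nn.Conv2d(cin, cout, 3, rng, padding=1, bias=False),
        nn.BatchNorm2d(cout),
        nn.ReLU(),
    )


class DualAttentionBlock(nn.Module):
    """Parallel PAM and CAM branches with channel reduce/restore convs.

    Each branch: 3x3 conv (C -> mid) + BN + ReLU, the attention module,
    then 3x3 conv (mid -> mid) + BN + ReLU.  The branch outputs are
    summed and a single 1x1 convolution restores the input channel count,
    so the block preserves shape.
    """

    def __init__(self, cfg: DABlockConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        mid = cfg.mid_channels
        self.pre_pam = _conv_bn_relu(cfg.in_channels, mid, rng)
        self.pre_cam = _conv_bn_relu(cfg.in_channels, mid, rng)
        self.pam = PositionAttention(mid, rng)
        self.cam = ChannelAttention()
        self.post_pam = _conv_bn_relu(mid, mid, rng)
        self.post_cam = _conv_bn_relu(mid, mid, rng)
        self.dropout = nn.Dropout(cfg.dropout_rate, np.random.default_rng(rng.integers(2**31)))
        self.out_conv = nn.Conv2d(mid, cfg.in_channels, 1, rng)

    def forward(self, x):
        arr, batched = _as_batched(x)
        if arr.shape[-3] != self.cfg.in_channels:
            raise ValueError(
                f"expected {self.cfg.in_channels} channels, got {arr.shape[-3]}")
        t = x if isinstance(x, Tensor) else Tensor(arr)
        if t.ndim == 3:
            t = F.reshape(t, (1,) + t.shape)
        pam_branch = self.post_pam(self.pam(self.pre_pam(t)))
        cam_branch = self.post_cam(self.cam(self.pre_cam(t)))
        out = self.out_conv(self.dropout(pam_branch + cam_branch))
        if not batched:
            out = F.reshape(out, out.shape[1:])
        return out if isinstance(x, Tensor) else out.numpy()
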