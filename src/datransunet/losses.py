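"""Compound segmentation objectives: equal-weight Dice + cross-entropy.

Binary training uses ``0.5 * BCE + 0.5 * (1 - softDice)`` on sigmoid
probabilities; multi-class training uses ``0.5 * CE + 0.5 * (1 - mean
soft Dice over all K classes, background included)`` on logits.  The
soft Dice carries a smoothing constant ``eps = 1e-5`` in numerator and
denominator; the hard evaluation metrics in :mod:`datransunet.metrics`
use exact set counts instead.
"""

from __future__ import annotations

import numpy as np

from .nn import functional as F
from .nn.tensor import Tensor

DICE_EPS = 1e-5
_LOG_CLIP = 1e-7


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def bce_dice_loss(probabilities, target) -> Tensor:
    """Equal-weight binary cross-entropy + soft-Dice loss.

    Parameters
    ----------
    probabilities:
        Post-sigmoid foreground probabilities, any shape.
    target:
        Binary mask of the same shape.
    """
    p = _as_tensor(probabilities)
    t = np.asarray(target.data if isinstance(target, Tensor) else target, dtype=np.float32)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    if np.any(p.data < 0) or np.any(p.data > 1):
        raise ValueError("probabilities must lie in [0, 1]; apply a sigmoid first")
    tt = Tensor(t)
    # clip only inside the logs so exact 0/1 predictions stay lossless
    p_safe = p * (1 - 2 * _LOG_CLIP) + _LOG_CLIP
    bce = -F.mean(tt * F.log(p_safe) + (1.0 - tt) * F.log(1.0 - p_safe))
    inter = F.sum_(p * tt)
    soft_dice = (2.0 * inter + DICE_EPS) / (F.sum_(p) + F.sum_(tt) + DICE_EPS)
    return 0.5 * bce + 0.5 * (1.0 - soft_dice)


def ce_dice_loss(logits, target, n_classes: int) -> Tensor:
    """Equal-weight cross-entropy + mean multi-class soft-Dice loss.

    ``logits`` has shape (B, K, H, W) or (K, H, W); ``target`` holds
    integer labels in ``{0..K-1}``.  The Dice term averages over all K
    classes including background.
    """
    x = _as_tensor(logits)
    if x.ndim == 3:
        x = F.reshape(x, (1,) + x.shape)
    t = np.asarray(target.data if isinstance(target, Tensor) else target)
    if t.ndim == 2:
        t = t[None]
    t = t.astype(np.int64)
    if x.shape[1] != n_classes:
        raise ValueError(f"logits have {x.shape[1]} channels, expected {n_classes}")
    if t.min() < 0 or t.max() >= n_classes:
        raise ValueError(f"labels must lie in 0..{n_classes - 1}")
    if x.shape[0] != t.shape[0] or x.shape[2:] != t.shape[1:]:
        raise ValueError(f"shape mismatch: logits {x.shape} vs target {t.shape}")

    onehot = np.eye(n_classes, dtype=np.float32)[t]           # (B, H, W, K)
    onehot = np.transpose(onehot, (0, 3, 1, 2))               # (B, K, H, W)
    oh = Tensor(onehot)

    logp = F.log_softmax(x, axis=1)
    ce = -F.mean(F.sum_(oh * logp, axis=1))

    probs = F.softmax(x, axis=1)
    inter = F.sum_(probs * oh, axis=(0, 2, 3))
    denom = F.sum_(probs, axis=(0, 2, 3)) + F.sum_(oh, axis=(0, 2, 3))
    dice_per_class = (2.0 * inter + DICE_EPS) / (denom + DICE_EPS)
    mean_dice = F.mean(dice_per_class)
    return 0.5 * ce + 0.5 * (1.0 - mean_dice)
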