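"""Hard evaluation metrics: Dice, IoU, Hausdorff distance and HD95.

Dice and IoU use exact set counts (no smoothing).  Hausdorff distances
are computed between the boundary point sets of prediction and truth,
where the boundary is the mask minus its 8-connected erosion, with
Euclidean pixel distances.  When a class is empty on both sides the
overlap metrics are reported as 1.0 but flagged as undefined; distance
metrics are undefined (NaN) whenever either side is empty and are
excluded from means with a warning.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import binary_erosion
from scipy.spatial import cKDTree

_STRUCTURE8 = np.ones((3, 3), dtype=bool)


def _check_pair(p, t):
    p = np.asarray(p)
    t = np.asarray(t)
    if p.shape != t.shape:
        raise ValueError(f"mask shapes differ: {p.shape} vs {t.shape}")
    return p.astype(bool), t.astype(bool)


def dice_coefficient(prediction, truth) -> float:
    """2|P∩T| / (|P|+|T|); returns 1.0 when both masks are empty."""
    p, t = _check_pair(prediction, truth)
    denom = int(p.sum()) + int(t.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((p & t).sum()) / denom


def iou(prediction, truth) -> float:
    """Jaccard overlap TP / (TP+FP+FN); 1.0 when both masks are empty."""
    p, t = _check_pair(prediction, truth)
    union = int((p | t).sum())
    if union == 0:
        return 1.0
    return int((p & t).sum()) / union


def boundary_points(mask) -> np.ndarray:
    """(n, 2) row/col coordinates of the 8-connectivity boundary."""
    m = np.asarray(mask).astype(bool)
    if not m.any():
        return np.empty((0, 2))
    border = m & ~binary_erosion(m, structure=_STRUCTURE8, border_value=0)
    return np.argwhere(border).astype(float)


def _directed_distances(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    return cKDTree(dst).query(src, k=1)[0]


def hausdorff(prediction, truth) -> float:
    """Symmetric Hausdorff distance between boundary point sets, pixels.

    Returns NaN (undefined) if either mask is empty.
    """
    p, t = _check_pair(prediction, truth)
    bp, bt = boundary_points(p), boundary_points(t)
    if len(bp) == 0 or len(bt) == 0:
        return float("nan")
    return float(max(_directed_distances(bp, bt).max(),
                     _directed_distances(bt, bp).max()))


def hd95(prediction, truth) -> float:
    """Robust Hausdorff: the directed 95th percentiles, symmetrized by max."""
    p, t = _check_pair(prediction, truth)
    bp, bt = boundary_points(p), boundary_points(t)
    if len(bp) == 0 or len(bt) == 0:
        return float("nan")
    return float(max(np.percentile(_directed_distances(bp, bt), 95),
                     np.percentile(_directed_distances(bt, bp), 95)))


@dataclass
class ClassMetrics:
    label: int
    dice: float
    iou: float
    hd: float
    hd95: float
    both_empty: bool
    pred_empty: bool
    truth_empty: bool


@dataclass
class MetricsReport:
    """Per-class metrics with foreground means.

    Means are taken over foreground classes; distance means skip
    undefined (NaN) entries, and classes absent from both masks are
    flagged rather than silently scored.
    """

    per_class: list[ClassMetrics] = field(default_factory=list)

    @property
    def mean_dice(self) -> float:
        return float(np.mean([c.dice for c in self.per_class])) if self.per_class else float("nan")

    @property
    def mean_iou(self) -> float:
        return float(np.mean([c.iou for c in self.per_class])) if self.per_class else float("nan")

    def _mean_defined(self, attr: str) -> float:
        vals = [getattr(c, attr) for c in self.per_class]
        defined = [v for v in vals if np.isfinite(v)]
        if len(defined) < len(vals):
            warnings.warn(f"{attr}: {len(vals) - len(defined)} undefined entries "
                          "excluded from the mean", stacklevel=2)
        return float(np.mean(defined)) if defined else float("nan")

    @property
    def mean_hd(self) -> float:
        return self._mean_defined("hd")

    @property
    def mean_hd95(self) -> float:
        return self._mean_defined("hd95")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(c) for c in self.per_class])

    def summary(self) -> dict:
        return {
            "mean_dice": self.mean_dice,
            "mean_iou": self.mean_iou,
            "mean_hd": self.mean_hd,
            "mean_hd95": self.mean_hd95,
            "n_flagged_empty": sum(c.both_empty for c in self.per_class),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)


def evaluate_masks(prediction, truth, n_classes: int) -> MetricsReport:
    """Score one predicted label mask against truth, per foreground class."""
    p = np.asarray(prediction)
    t = np.asarray(truth)
    if p.shape != t.shape:
        raise ValueError(f"mask shapes differ: {p.shape} vs {t.shape}")
    report = MetricsReport()
    for label in range(1, n_classes):
        pm, tm = p == label, t == label
        report.per_class.append(ClassMetrics(
            label=label,
            dice=dice_coefficient(pm, tm),
            iou=iou(pm, tm),
            hd=hausdorff(pm, tm),
            hd95=hd95(pm, tm),
            both_empty=not pm.any() and not tm.any(),
            pred_empty=not pm.any(),
            truth_empty=not tm.any(),
        ))
    return report
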