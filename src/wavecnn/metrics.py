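"""Pixelwise confusion counts and the four clinical performance metrics.

The positive class is the *wavefront* (map value -1, the "black"/ON pixels);
nonwavefront pixels (+1, white/OFF) are the negative class.  From the
pixel-level confusion counts the standard binary-classification metrics
follow:

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    precision   = TP / (TP + FP)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)

A zero denominator yields ``None`` (undefined), never a silent 0 or 1.

Dataset-level numbers aggregate counts across images before dividing
(micro-average) by default; macro-averaging (mean of per-image metrics,
undefined images dropped) is available via ``aggregate``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = ["ConfusionCounts", "MetricsRecord", "confusion", "compute_metrics", "aggregate"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp,
            self.fn + other.fn, self.tn + other.tn,
        )


@dataclass(frozen=True)
class MetricsRecord:
    """The four metrics; ``None`` marks an undefined (0/0) value."""

    accuracy: Optional[float]
    precision: Optional[float]
    sensitivity: Optional[float]
    specificity: Optional[float]

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


def confusion(
    pred: np.ndarray,
    label: np.ndarray,
    mask: Optional[np.ndarray] = None,
) -> ConfusionCounts:
    """Count TP/FP/FN/TN between a binary prediction and a binary label.

    Both maps take values in {-1, +1}; -1 (wavefront) is positive.
    ``mask``, if given, is True at pixels to *exclude* (e.g. electrode
    artifacts); excluded pixels enter none of the counts.
    """
    pred = np.asarray(pred)
    label = np.asarray(label)
    if pred.shape != label.shape:
        raise ValueError(f"prediction shape {pred.shape} != label shape {label.shape}")
    for name, arr in (("prediction", pred), ("label", label)):
        if not np.all(np.isin(arr, (-1, 1))):
            raise ValueError(f"{name} map is not binary (+/-1)")
    keep = np.ones(pred.shape, dtype=bool) if mask is None else ~np.asarray(mask, bool)
    p = pred == -1
    l = label == -1
    return ConfusionCounts(
        tp=int(np.sum(p & l & keep)),
        fp=int(np.sum(p & ~l & keep)),
        fn=int(np.sum(~p & l & keep)),
        tn=int(np.sum(~p & ~l & keep)),
    )


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def compute_metrics(c: ConfusionCounts) -> MetricsRecord:
    """Accuracy, precision, sensitivity, specificity from confusion counts."""
    if c.total == 0:
        raise ValueError("no evaluated pixels (total count is zero)")
    return MetricsRecord(
        accuracy=_ratio(c.tp + c.tn, c.total),
        precision=_ratio(c.tp, c.tp + c.fp),
        sensitivity=_ratio(c.tp, c.tp + c.fn),
        specificity=_ratio(c.tn, c.tn + c.fp),
    )


def aggregate(counts: Iterable[ConfusionCounts], how: str = "micro") -> MetricsRecord:
    """Combine per-image confusion counts into one metrics record.

    micro: sum the counts, then divide.  macro: average the per-image
    metrics, skipping images where a given metric is undefined.
    """
    counts = list(counts)
    if not counts:
        raise ValueError("no confusion counts to aggregate")
    if how == "micro":
        total = ConfusionCounts()
        for c in counts:
            total = total + c
        return compute_metrics(total)
    if how == "macro":
        records = [compute_metrics(c) for c in counts]

        def mean_of(vals: Sequence[Optional[float]]) -> Optional[float]:
            vv = [v for v in vals if v is not None]
            return float(np.mean(vv)) if vv else None

        return MetricsRecord(
            accuracy=mean_of([r.accuracy for r in records]),
            precision=mean_of([r.precision for r in records]),
            sensitivity=mean_of([r.sensitivity for r in records]),
            specificity=mean_of([r.specificity for r in records]),
        )
    raise ValueError(f"unknown aggregation {how!r} (expected 'micro' or 'macro')")
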