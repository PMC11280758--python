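"""Pixel-classification metrics and cross-validation fold assignment.

The coating is the positive class.  All five metrics derive from the pixel
confusion counts:

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    dice      = 2 TP / (2 TP + FP + FN)
    iou       = TP / (TP + FP + FN)

When a denominator is zero the metric is defined as 1.0 if the numerator is
also zero (empty prediction vs empty truth agrees perfectly) and 0.0
otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp,
            self.tn + other.tn, self.fn + other.fn,
        )


@dataclass
class MetricReport:
    accuracy: float
    precision: float
    dice: float
    recall: float
    iou: float
    aggregation: str = "pooled"

    def as_dict(self) -> Dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "dice": self.dice,
            "recall": self.recall,
            "iou": self.iou,
        }


def confusion(pred_mask: np.ndarray, true_mask: np.ndarray) -> ConfusionCounts:
    """Pixel confusion counts with coating (1) as the positive class."""
    pred = np.asarray(pred_mask)
    true = np.asarray(true_mask)
    if pred.shape != true.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {true.shape}")
    for name, m in (("pred", pred), ("true", true)):
        if not np.isin(m, (0, 1)).all():
            raise ValueError(f"{name} mask must be binary {{0, 1}}")
    p = pred.astype(bool)
    t = true.astype(bool)
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & t)),
        fp=int(np.count_nonzero(p & ~t)),
        tn=int(np.count_nonzero(~p & ~t)),
        fn=int(np.count_nonzero(~p & t)),
    )


def _ratio(num: float, den: float) -> float:
    if den == 0:
        return 1.0 if num == 0 else 0.0
    return num / den


def compute_metrics(c: ConfusionCounts, aggregation: str = "pooled") -> MetricReport:
    if c.total == 0:
        raise ValueError("confusion counts are all zero")
    return MetricReport(
        accuracy=_ratio(c.tp + c.tn, c.total),
        precision=_ratio(c.tp, c.tp + c.fp),
        dice=_ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
        recall=_ratio(c.tp, c.tp + c.fn),
        iou=_ratio(c.tp, c.tp + c.fp + c.fn),
        aggregation=aggregation,
    )


def pooled_report(counts: Sequence[ConfusionCounts]) -> MetricReport:
    """Micro-averaged metrics: pool pixel counts across images, then divide."""
    total = ConfusionCounts(0, 0, 0, 0)
    for c in counts:
        total = total + c
    return compute_metrics(total, aggregation="pooled")


def per_image_mean_report(counts: Sequence[ConfusionCounts]) -> MetricReport:
    """Macro average: compute metrics per image, then average the reports."""
    reports = [compute_metrics(c) for c in counts]
    return MetricReport(
        accuracy=float(np.mean([r.accuracy for r in reports])),
        precision=float(np.mean([r.precision for r in reports])),
        dice=float(np.mean([r.dice for r in reports])),
        recall=float(np.mean([r.recall for r in reports])),
        iou=float(np.mean([r.iou for r in reports])),
        aggregation="per-image-mean",
    )


@dataclass
class FoldSplit:
    """A k-fold partition of sample ids. Sizes differ by at most one."""

    k: int
    assignments: Dict[str, int]
    seed: int

    def fold_ids(self, fold: int) -> List[str]:
        return [i for i, f in self.assignments.items() if f == fold]

    def train_ids(self, fold: int) -> List[str]:
        return [i for i, f in self.assignments.items() if f != fold]


def kfold_split(ids: Sequence[str], k: int = 5, seed: int = 0) -> FoldSplit:
    ids = list(ids)
    if len(ids) < k:
        raise ValueError(f"need at least k={k} samples, got {len(ids)}")
    if len(set(ids)) != len(ids):
        raise ValueError("sample ids must be unique")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    assignments = {ids[int(j)]: int(pos % k) for pos, j in enumerate(order)}
    return FoldSplit(k=k, assignments=assignments, seed=seed)


def fold_summary(reports: Sequence[MetricReport]) -> Dict[str, Dict[str, float]]:
    """Mean and population standard deviation of metrics across folds."""
    names = ["accuracy", "precision", "dice", "recall", "iou"]
    arr = {n: np.array([getattr(r, n) for r in reports]) for n in names}
    return {
        "mean": {n: float(arr[n].mean()) for n in names},
        "std": {n: float(arr[n].std(ddof=0)) for n in names},
    }
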