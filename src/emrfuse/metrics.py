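"""Binary classification metrics with the report's bookkeeping conventions.

Averaged results are reported both as mean-of-folds and as recomputed from
the pooled confusion matrix — the two are labeled distinctly because the
harmonic-mean identity between averaged precision/recall and averaged F1 does
not survive averaging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

__all__ = ["MetricsRow", "MetricsReport", "confusion_counts", "compute_metrics", "f1_from_pr"]

METRIC_COLUMNS = ["accuracy", "precision", "recall", "specificity", "f1"]


def confusion_counts(labels: np.ndarray, predictions: np.ndarray) -> tuple[int, int, int, int]:
    labels = np.asarray(labels, dtype=int)
    predictions = np.asarray(predictions, dtype=int)
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions must have equal length")
    tp = int(np.sum((labels == 1) & (predictions == 1)))
    fp = int(np.sum((labels == 0) & (predictions == 1)))
    fn = int(np.sum((labels == 1) & (predictions == 0)))
    tn = int(np.sum((labels == 0) & (predictions == 0)))
    return tp, fp, fn, tn


def _ratio(num: int, den: int, name: str, flags: list[str]) -> float:
    if den == 0:
        warnings.warn(f"{name}: zero denominator, reporting 0", RuntimeWarning, stacklevel=3)
        flags.append(name)
        return 0.0
    return num / den


@dataclass
class MetricsRow:
    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1: float
    variant: str = "full"
    fold: int | None = None
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in METRIC_COLUMNS}
        d["variant"] = self.variant
        if self.fold is not None:
            d["fold"] = self.fold
        return d


def compute_metrics(labels, predictions, variant: str = "full", fold: int | None = None) -> MetricsRow:
    """Accuracy, precision, recall, specificity and F1 from binary vectors."""
    tp, fp, fn, tn = confusion_counts(labels, predictions)
    flags: list[str] = []
    total = tp + fp + fn + tn
    if total == 0:
        raise ValueError("empty input")
    precision = _ratio(tp, tp + fp, "precision", flags)
    recall = _ratio(tp, tp + fn, "recall", flags)
    specificity = _ratio(tn, tn + fp, "specificity", flags)
    f1 = _ratio_f1(precision, recall, flags)
    return MetricsRow(
        accuracy=(tp + tn) / total,
        precision=precision,
        recall=recall,
        specificity=specificity,
        f1=f1,
        variant=variant,
        fold=fold,
        undefined=tuple(flags),
    )


def _ratio_f1(precision: float, recall: float, flags: list[str]) -> float:
    if precision + recall == 0:
        flags.append("f1")
        return 0.0
    return 2 * precision * recall / (precision + recall)


def f1_from_pr(precision: float, recall: float, decimals: int = 4) -> float:
    """Harmonic mean 2PR/(P+R), rounded half-up to the report precision."""
    if not (0 <= precision <= 1 and 0 <= recall <= 1):
        raise ValueError("precision and recall must lie in [0, 1]")
    if precision + recall == 0:
        warnings.warn("f1_from_pr: both inputs zero, reporting 0", RuntimeWarning, stacklevel=2)
        return 0.0
    value = 2 * precision * recall / (precision + recall)
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class MetricsReport:
    """Per-fold rows plus the two distinct averaging conventions."""

    rows: list[MetricsRow] = field(default_factory=list)
    pooled_confusion: list[tuple[int, int, int, int]] = field(default_factory=list)

    def add_fold(self, labels, predictions, variant: str, fold: int) -> MetricsRow:
        row = compute_metrics(labels, predictions, variant=variant, fold=fold)
        self.rows.append(row)
        self.pooled_confusion.append(confusion_counts(labels, predictions))
        return row

    def mean_of_folds(self, variant: str | None = None) -> dict:
        rows = [r for r in self.rows if variant is None or r.variant == variant]
        if not rows:
            raise ValueError("no fold rows")
        out = {k: float(np.mean([getattr(r, k) for r in rows])) for k in METRIC_COLUMNS}
        out["convention"] = "mean_of_folds"
        return out

    def pooled(self, variant: str | None = None) -> dict:
        idx = [i for i, r in enumerate(self.rows) if variant is None or r.variant == variant]
        if not idx:
            raise ValueError("no fold rows")
        tp = sum(self.pooled_confusion[i][0] for i in idx)
        fp = sum(self.pooled_confusion[i][1] for i in idx)
        fn = sum(self.pooled_confusion[i][2] for i in idx)
        tn = sum(self.pooled_confusion[i][3] for i in idx)
        flags: list[str] = []
        precision = _ratio(tp, tp + fp, "precision", flags)
        recall = _ratio(tp, tp + fn, "recall", flags)
        out = {
            "accuracy": (tp + tn) / (tp + fp + fn + tn),
            "precision": precision,
            "recall": recall,
            "specificity": _ratio(tn, tn + fp, "specificity", flags),
            "f1": _ratio_f1(precision, recall, flags),
            "convention": "pooled_confusion",
        }
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.as_dict() for r in self.rows])
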