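"""Confusion matrices, sensitivity/specificity/precision, and ROC/AUC.

Metrics follow the clinical one-vs-rest convention: each stage in turn is
the positive class and all others collapse to negative, giving TP/FN/FP/TN
counts from which sensitivity = 100*TP/(TP+FN), specificity =
100*TN/(TN+FP), precision = 100*TP/(TP+FP) and accuracy are derived.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_matrix",
    "binary_metrics",
    "overall_accuracy",
    "roc_auc",
    "round_half_up",
]


def round_half_up(x: float, decimals: int) -> float:
    """Decimal rounding with halves away from zero, as printed tables use."""
    scale = 10.0**decimals
    return math.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary one-vs-rest counts."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")
        if self.total == 0:
            raise ValueError("confusion counts are all zero")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class MetricsReport:
    """Percent metrics; a metric with a zero denominator is None (undefined)."""

    sensitivity: float | None
    specificity: float | None
    precision: float | None
    accuracy: float

    def rounded(self) -> "MetricsReport":
        """Values at the precision printed in clinical tables (2 decimals)."""

        def r(v: float | None) -> float | None:
            return None if v is None else round_half_up(v, 2)

        return MetricsReport(
            sensitivity=r(self.sensitivity),
            specificity=r(self.specificity),
            precision=r(self.precision),
            accuracy=r(self.accuracy),
        )


def confusion_matrix(
    y_true,
    y_pred,
    classes: list[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, ConfusionCounts]]:
    """Multiclass confusion matrix plus per-class one-vs-rest counts.

    ``matrix.loc[i, j]`` counts samples with true class i predicted as j.
    """
    y_true = np.asarray(y_true).astype(str)
    y_pred = np.asarray(y_pred).astype(str)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("label sequences must be 1D and equal length")
    if classes is None:
        classes = sorted(set(y_true) | set(y_pred))
    classes = list(classes)
    unknown = (set(y_true) | set(y_pred)) - set(classes)
    if unknown:
        raise ValueError(f"labels outside the scheme: {sorted(unknown)}")
    index = {c: i for i, c in enumerate(classes)}
    mat = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        mat[index[t], index[p]] += 1
    df = pd.DataFrame(mat, index=classes, columns=classes)
    per_class = {}
    n = mat.sum()
    for c in classes:
        i = index[c]
        tp = int(mat[i, i])
        fn = int(mat[i].sum() - tp)
        fp = int(mat[:, i].sum() - tp)
        per_class[c] = ConfusionCounts(tp=tp, fn=fn, fp=fp, tn=int(n - tp - fn - fp))
    return df, per_class


def binary_metrics(c: ConfusionCounts) -> MetricsReport:
    """Sensitivity, specificity, precision and accuracy in percent.

    A metric whose denominator is zero is reported as None rather than 0.
    """
    sens = 100.0 * c.tp / (c.tp + c.fn) if (c.tp + c.fn) else None
    spec = 100.0 * c.tn / (c.tn + c.fp) if (c.tn + c.fp) else None
    prec = 100.0 * c.tp / (c.tp + c.fp) if (c.tp + c.fp) else None
    acc = 100.0 * (c.tp + c.tn) / c.total
    return MetricsReport(sensitivity=sens, specificity=spec, precision=prec, accuracy=acc)


def overall_accuracy(correct, tested) -> float:
    """Pooled accuracy over per-class counts, percent to 1 decimal."""
    correct = np.asarray(correct, dtype=int)
    tested = np.asarray(tested, dtype=int)
    if correct.shape != tested.shape:
        raise ValueError("correct and tested counts must align")
    if (correct < 0).any() or (tested < 0).any() or (correct > tested).any():
        raise ValueError("need 0 <= correct <= tested per class")
    total = int(tested.sum())
    if total == 0:
        raise ValueError("no tested samples")
    return round_half_up(100.0 * correct.sum() / total, 1)


def roc_auc(scores, labels) -> tuple[np.ndarray, np.ndarray, float]:
    """One-vs-rest ROC curve and trapezoid AUC from per-sample scores.

    ``labels`` are booleans (True = target class). The threshold sweep
    visits each distinct score once (descending), so tied scores move the
    operating point in a single step; (0,0) and (1,1) are always included.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1D and equal length")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(~y_sorted)
    # Keep only the last index of each run of tied scores.
    distinct = np.r_[np.flatnonzero(np.diff(s_sorted)), s_sorted.size - 1]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc
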