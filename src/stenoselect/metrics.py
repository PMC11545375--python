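"""Confusion-matrix metrics, the feature decreasing rate, and wrapper fitness.

The selector scalarizes two objectives: classification accuracy on a holdout
split and the feature decreasing rate FDR = 1 - selected/total (note: *not*
the false discovery rate).  The Jaccard variant used throughout is
(TP+TN) / ((A+P) - (TP+TN)) with A and P the actual and predicted instance
counts, which reduces to Acc / (2 - Acc) when A = P.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionCounts",
    "FitnessWeights",
    "MetricReport",
    "DegenerateMetricError",
    "confusion",
    "classification_metrics",
    "feature_decreasing_rate",
    "fitness",
    "table_row",
]


class DegenerateMetricError(ZeroDivisionError):
    """A metric denominator is zero; raised instead of silently returning 0."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer")
        if self.total < 1:
            raise ValueError("confusion counts must cover at least one instance")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class FitnessWeights:
    w_accuracy: float = 0.90
    w_fdr: float = 0.10

    def __post_init__(self) -> None:
        if self.w_accuracy < 0 or self.w_fdr < 0:
            raise ValueError("weights must be non-negative")
        if abs(self.w_accuracy + self.w_fdr - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")


@dataclass(frozen=True)
class MetricReport:
    accuracy: float
    jaccard: float
    f1: float
    sensitivity: float
    specificity: float

    def __post_init__(self) -> None:
        for name in ("accuracy", "jaccard", "f1", "sensitivity", "specificity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")

    def to_json(self) -> str:
        return json.dumps(self.__dict__)


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Count TP/TN/FP/FN for binary label vectors (1 = positive stenosis)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.ndim != 1 or y_true.size < 1:
        raise ValueError("y_true and y_pred must be equal-length 1-D vectors")
    if not (np.isin(y_true, (0, 1)).all() and np.isin(y_pred, (0, 1)).all()):
        raise ValueError("labels must be binary (0/1)")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return ConfusionCounts(tp, tn, fp, fn)


def classification_metrics(
    c: ConfusionCounts, n_actual: int | None = None, n_predicted: int | None = None
) -> MetricReport:
    """Accuracy, Jaccard variant, F1, sensitivity and specificity from counts.

    ``n_actual`` (A) and ``n_predicted`` (P) both default to the evaluation-set
    size ``c.total``; they are exposed separately because the Jaccard variant
    is defined in terms of A and P.
    """
    a = c.total if n_actual is None else n_actual
    p = c.total if n_predicted is None else n_predicted
    correct = c.tp + c.tn

    def _div(num: float, den: float, what: str) -> float:
        if den == 0:
            raise DegenerateMetricError(f"zero denominator computing {what}")
        return num / den

    return MetricReport(
        accuracy=_div(correct, c.total, "accuracy"),
        jaccard=_div(correct, (a + p) - correct, "jaccard"),
        f1=_div(2 * c.tp, 2 * c.tp + c.fp + c.fn, "f1"),
        sensitivity=_div(c.tp, c.tp + c.fn, "sensitivity"),
        specificity=_div(c.tn, c.tn + c.fp, "specificity"),
    )


def feature_decreasing_rate(n_selected: int, n_total: int) -> float:
    """FDR = 1 - n_selected / n_total; higher means fewer features kept."""
    if n_total < 1:
        raise ValueError("n_total must be at least 1")
    if not 0 <= n_selected <= n_total:
        raise ValueError("n_selected must lie in [0, n_total]")
    return 1.0 - n_selected / n_total


def fitness(accuracy: float, fdr: float, w: FitnessWeights = FitnessWeights()) -> float:
    """Scalarized wrapper fitness: w_accuracy * accuracy + w_fdr * fdr."""
    if not (0.0 <= accuracy <= 1.0 and 0.0 <= fdr <= 1.0):
        raise ValueError("accuracy and fdr must lie in [0, 1]")
    return w.w_accuracy * accuracy + w.w_fdr * fdr


def table_row(report: MetricReport, n_selected: int, n_total: int) -> dict[str, float]:
    """One summary row: NSF, FDR, Accuracy, JC, F1, Sens., Spec."""
    return {
        "NSF": n_selected,
        "FDR": feature_decreasing_rate(n_selected, n_total),
        "Accuracy": report.accuracy,
        "JC": report.jaccard,
        "F1": report.f1,
        "Sens.": report.sensitivity,
        "Spec.": report.specificity,
    }
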