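"""Confusion matrices and the accuracy / recall / precision / F1 panel.

Rows of the confusion matrix are true classes and columns predicted classes,
both in the dataset's fixed class-name order (class code c maps to axis
index c - 1). Reported percentages round half-up to two decimals, matching
the precision used in the result tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np


class MetricsError(ValueError):
    pass


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # C x C, rows = truth, cols = predicted
    class_names: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise MetricsError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise MetricsError("negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class ClassRow:
    name: str
    recall: float
    precision: float
    f1: float


@dataclass
class ClassMetrics:
    accuracy: float
    per_class: list[ClassRow]


def confusion(truth, predicted, class_names: list[str] | None = None) -> ConfusionMatrix:
    """Count matrix: counts[i][j] = samples with true class i predicted as j.

    Labels are integer class codes 1..C; ``class_names`` supplies the axis
    names (defaults to ``class1..classC``).
    """
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.size != predicted.size:
        raise MetricsError("truth and predicted differ in length")
    if truth.size == 0:
        raise MetricsError("empty label vectors")
    codes = np.union1d(np.unique(truth), np.unique(predicted))
    n_classes = len(class_names) if class_names else int(codes.max())
    if class_names is None:
        class_names = [f"class{c}" for c in range(1, n_classes + 1)]
    for c in codes:
        if not 1 <= c <= n_classes:
            raise MetricsError(f"unknown label code {c} (expected 1..{n_classes})")
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (truth - 1, predicted - 1), 1)
    return ConfusionMatrix(counts=counts, class_names=list(class_names))


def f1_score(recall: float, precision: float) -> float:
    """Harmonic mean of recall and precision; 0 when both are 0."""
    if recall + precision == 0:
        return 0.0
    return 2.0 * recall * precision / (recall + precision)


def panel(cm: ConfusionMatrix) -> ClassMetrics:
    """Overall accuracy plus per-class recall, precision, F1 (fractions in [0, 1]).

    Zero-denominator conventions: recall and precision are 0 when their
    denominator is 0, and F1 is 0 when recall + precision is 0.
    """
    if cm.total == 0:
        raise MetricsError("empty confusion matrix")
    counts = cm.counts
    accuracy = float(np.trace(counts)) / cm.total
    rows = []
    for i, name in enumerate(cm.class_names):
        tp = counts[i, i]
        fn = counts[i].sum() - tp
        fp = counts[:, i].sum() - tp
        recall = tp / (tp + fn) if tp + fn > 0 else 0.0
        precision = tp / (tp + fp) if tp + fp > 0 else 0.0
        rows.append(ClassRow(name, float(recall), float(precision), f1_score(recall, precision)))
    return ClassMetrics(accuracy=accuracy, per_class=rows)


def percent(x: float) -> float:
    """Fraction -> percentage rounded half-up to 2 decimals (report formatting).

    Goes through the shortest decimal repr so values like 0.99805 round on
    their printed digits, not their binary representation.
    """
    return float((Decimal(str(x)) * 100).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def panel_report(metrics: ClassMetrics) -> dict:
    """JSON-ready panel with percentages at report precision."""
    return {
        "accuracy": percent(metrics.accuracy),
        "classes": [
            {
                "name": row.name,
                "recall": percent(row.recall),
                "precision": percent(row.precision),
                "f1": percent(row.f1),
            }
            for row in metrics.per_class
        ],
    }
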