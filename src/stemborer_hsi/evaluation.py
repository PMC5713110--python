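"""Confusion matrices and per-class / overall accuracy reports."""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

__all__ = ["ConfusionMatrix", "ModelReport", "confusion", "accuracies", "format_report", "percent"]

N_CLASSES = 6


@dataclass
class ConfusionMatrix:
    """6 x 6 counts: rows = actual DI, columns = predicted DI."""

    counts: np.ndarray
    set_name: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (N_CLASSES, N_CLASSES):
            raise ValueError("counts must be 6 x 6")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class ModelReport:
    """Per-class and overall accuracy fractions for one feature set."""

    per_class: dict[int, float]  # classes with zero actual samples are absent
    overall: float
    feature_set: str = ""
    set_name: str = ""


def confusion(actual: np.ndarray, predicted: np.ndarray, set_name: str = "") -> ConfusionMatrix:
    """Count actual-vs-predicted DI pairs into a 6 x 6 matrix."""
    actual = np.asarray(actual, dtype=int).ravel()
    predicted = np.asarray(predicted, dtype=int).ravel()
    if actual.size != predicted.size:
        raise ValueError("actual and predicted must have equal length")
    for name, arr in (("actual", actual), ("predicted", predicted)):
        if arr.size and (arr.min() < 0 or arr.max() >= N_CLASSES):
            raise ValueError(f"{name} labels must lie in 0..5")
    counts = _sk_confusion(actual, predicted, labels=np.arange(N_CLASSES))
    return ConfusionMatrix(counts, set_name=set_name)


def accuracies(cm: ConfusionMatrix, feature_set: str = "") -> ModelReport:
    """Per-class accuracy (diagonal / row sum) and overall accuracy (trace / total)."""
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    row_sums = cm.counts.sum(axis=1)
    per_class = {
        di: cm.counts[di, di] / row_sums[di] for di in range(N_CLASSES) if row_sums[di] > 0
    }
    overall = float(np.trace(cm.counts)) / total
    return ModelReport(per_class=per_class, overall=overall, feature_set=feature_set, set_name=cm.set_name)


def percent(fraction: float, decimals: int = 2) -> float:
    """Render a fraction as a percentage with half-up rounding (table style)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(fraction * 100).quantize(q, rounding=ROUND_HALF_UP))


def format_report(report: ModelReport) -> str:
    """Plain-text accuracy table, percentages with two decimals."""
    lines = [f"Feature set: {report.feature_set or '-'}  ({report.set_name or 'all'})"]
    for di in range(N_CLASSES):
        if di in report.per_class:
            lines.append(f"  DI{di}: {percent(report.per_class[di]):.2f}%")
        else:
            lines.append(f"  DI{di}: -")
    lines.append(f"  Total: {percent(report.overall):.2f}%")
    return "\n".join(lines)
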