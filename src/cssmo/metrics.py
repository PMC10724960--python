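"""Classification metrics: confusion matrix, precision/recall/F1, run stats.

Rows of the confusion matrix are actual classes, columns predicted classes.
Accuracy is on the 0-100 scale (100 * correct / total) and the error rate is
its complement. Precision/recall/F1 are reported per class and
macro-averaged (unweighted mean), with every 0/0 mapped to 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError


@dataclass(frozen=True)
class ConfusionMatrix:
    counts: np.ndarray  # (C, C), rows = actual, cols = predicted

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValidationError("confusion matrix must be square")
        if np.any(counts < 0):
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    error_rate: float
    precision: tuple[float, ...]
    recall: tuple[float, ...]
    f1: tuple[float, ...]
    macro_precision: float
    macro_recall: float
    macro_f1: float


def confusion_from_predictions(
    actual: np.ndarray, predicted: np.ndarray, n_classes: int
) -> ConfusionMatrix:
    actual = np.asarray(actual, dtype=int)
    predicted = np.asarray(predicted, dtype=int)
    if actual.shape != predicted.shape or actual.ndim != 1:
        raise ValidationError("actual/predicted must be equal-length 1-D")
    for v in (actual, predicted):
        if v.size and (v.min() < 0 or v.max() >= n_classes):
            raise ValidationError("class code out of range [0, C)")
    counts = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(counts, (actual, predicted), 1)
    return ConfusionMatrix(counts=counts)


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricsReport:
    if cm.total == 0:
        raise ValidationError("empty confusion matrix")
    counts = cm.counts.astype(float)
    tp = np.diag(counts)
    fp = counts.sum(axis=0) - tp
    fn = counts.sum(axis=1) - tp

    def safe_div(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        return np.where(b > 0, a / np.where(b > 0, b, 1.0), 0.0)

    precision = safe_div(tp, tp + fp)
    recall = safe_div(tp, tp + fn)
    f1 = safe_div(2 * precision * recall, precision + recall)
    accuracy = 100.0 * float(tp.sum()) / cm.total
    return MetricsReport(
        accuracy=accuracy,
        error_rate=100.0 - accuracy,
        precision=tuple(precision),
        recall=tuple(recall),
        f1=tuple(f1),
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
    )


@dataclass(frozen=True)
class RunStatistics:
    """Boxplot-underlying summary of per-run accuracies."""

    mean: float
    sd: float
    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float
    n: int


def summarize_runs(per_run_accuracy) -> RunStatistics:
    """Mean, sample SD (n-1; 0 for a single run) and linear-interp quartiles."""
    arr = np.asarray(list(per_run_accuracy), dtype=float)
    if arr.size == 0:
        raise ValidationError("need at least one run")
    q1, median, q3 = np.percentile(arr, [25, 50, 75])
    return RunStatistics(
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        minimum=float(arr.min()),
        q1=float(q1),
        median=float(median),
        q3=float(q3),
        maximum=float(arr.max()),
        n=int(arr.size),
    )
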