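"""Confusion matrices and classification performance statistics.

Conventions: confusion rows are true classes, columns predicted, in fixed
severity-rank order. Sensitivity of class k is TP_k / (TP_k + FN_k) and
specificity TN_k / (TN_k + FP_k), both as percentages; overall accuracy is
100 * trace / total, which equals the class-count-weighted mean of the
per-class sensitivities; the "mean class error" reported alongside is the
macro average over classes of (100 - sensitivity_k). Percentages are
rounded half-away-from-zero to one decimal for display only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .types import BerryvisError


def confusion(
    true_labels: np.ndarray, predicted_labels: np.ndarray, n_classes: int
) -> np.ndarray:
    """Count matrix: ``cm[i, j]`` = samples with true rank i+1 predicted j+1."""
    t = np.asarray(true_labels, dtype=int).ravel()
    p = np.asarray(predicted_labels, dtype=int).ravel()
    if t.size != p.size:
        raise BerryvisError("true and predicted label lengths differ")
    if t.size and (min(t.min(), p.min()) < 1 or max(t.max(), p.max()) > n_classes):
        raise BerryvisError(f"labels must be ranks in 1..{n_classes}")
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (t - 1, p - 1), 1)
    return cm


def sensitivity(cm: np.ndarray, k: int) -> float:
    """Percent true-positive rate of class ``k`` (0-based row index)."""
    cm = np.asarray(cm)
    row = cm[k].sum()
    if row == 0:
        raise BerryvisError(f"class {k} has no samples (empty row)")
    return 100.0 * cm[k, k] / row


def specificity(cm: np.ndarray, k: int) -> float:
    """Percent true-negative rate of class ``k`` (0-based index)."""
    cm = np.asarray(cm)
    total = cm.sum()
    row = cm[k].sum()
    if total - row == 0:
        raise BerryvisError("specificity undefined: no samples outside class")
    fp = cm[:, k].sum() - cm[k, k]
    tn = total - row - fp
    return 100.0 * tn / (tn + fp)


def overall_accuracy(cm: np.ndarray) -> float:
    """Percent correct: 100 * trace / total."""
    cm = np.asarray(cm)
    total = cm.sum()
    if total == 0:
        raise BerryvisError("empty confusion matrix")
    return 100.0 * np.trace(cm) / total


def accuracy_from_sensitivities(
    sensitivities: np.ndarray, class_counts: np.ndarray
) -> float:
    """Class-count-weighted mean of per-class sensitivities (percent).

    Algebraically identical to trace/total accuracy; used to recompute an
    accuracy from a published per-class table.
    """
    s = np.asarray(sensitivities, dtype=float)
    w = np.asarray(class_counts, dtype=float)
    if s.size != w.size or s.size == 0:
        raise BerryvisError("sensitivities and class_counts must match")
    return float((s * w).sum() / w.sum())


def mean_class_error(per_class_sensitivities: np.ndarray) -> float:
    """Macro average over classes of (100 - sensitivity), percent."""
    s = np.asarray(per_class_sensitivities, dtype=float)
    if s.size == 0:
        raise BerryvisError("need at least one class")
    return float(np.mean(100.0 - s))


def row_percent(cm: np.ndarray) -> np.ndarray:
    """Confusion matrix with each row expressed as percentages of its sum."""
    cm = np.asarray(cm, dtype=float)
    sums = cm.sum(axis=1, keepdims=True)
    if np.any(sums == 0):
        raise BerryvisError("row-percent undefined for an empty class row")
    return 100.0 * cm / sums


def round_display(x: float, decimals: int = 1) -> float:
    """Round half away from zero (the convention of printed tables)."""
    f = 10.0**decimals
    return math.copysign(math.floor(abs(x) * f + 0.5) / f, x)


@dataclass
class ClassMetrics:
    """Per-class sensitivity/specificity plus overall accuracy and mean
    class error, all in percent. ``from_confusion`` derives everything from
    one matrix so internally reported numbers always agree."""

    sensitivities: np.ndarray
    specificities: np.ndarray
    accuracy: float
    error: float
    class_counts: np.ndarray

    @classmethod
    def from_confusion(cls, cm: np.ndarray) -> "ClassMetrics":
        cm = np.asarray(cm)
        n = cm.shape[0]
        sens = np.array([sensitivity(cm, k) for k in range(n)])
        spec = np.array([specificity(cm, k) for k in range(n)])
        return cls(
            sensitivities=sens,
            specificities=spec,
            accuracy=overall_accuracy(cm),
            error=mean_class_error(sens),
            class_counts=cm.sum(axis=1),
        )


@dataclass
class AggregatedMetrics:
    """Mean and sample standard deviation of ClassMetrics over rDCV runs."""

    mean: ClassMetrics
    std: ClassMetrics
    n_runs: int


def aggregate_over_runs(runs: list[ClassMetrics]) -> AggregatedMetrics:
    """Element-wise mean +/- sample std over repeated runs (std 0 if one run)."""
    if not runs:
        raise BerryvisError("need at least one run to aggregate")
    n_classes = runs[0].sensitivities.size
    for r in runs:
        if r.sensitivities.size != n_classes:
            raise BerryvisError("inconsistent class counts across runs")

    def stack(attr):
        return np.array([np.atleast_1d(getattr(r, attr)) for r in runs], dtype=float)

    def agg(attr):
        m = stack(attr)
        mu = m.mean(axis=0)
        sd = m.std(axis=0, ddof=1) if len(runs) > 1 else np.zeros_like(mu)
        return mu, sd

    sens_m, sens_s = agg("sensitivities")
    spec_m, spec_s = agg("specificities")
    acc_m, acc_s = agg("accuracy")
    err_m, err_s = agg("error")
    cnt = runs[0].class_counts
    mean = ClassMetrics(sens_m, spec_m, float(acc_m[0]), float(err_m[0]), cnt)
    std = ClassMetrics(sens_s, spec_s, float(acc_s[0]), float(err_s[0]), cnt)
    return AggregatedMetrics(mean=mean, std=std, n_runs=len(runs))
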