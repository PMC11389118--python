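"""Confusion-matrix metrics, Cohen's kappa and one-way ANOVA.

Per-class precision/recall/F1 and overall accuracy are reported in percent;
kappa stays on its natural [-1, 1] scale (a 0-100% rescaling is a
presentation option only).  The one-way ANOVA returns the full
sum-of-squares decomposition with the F statistic, its p-value and the
upper-alpha critical value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "AnovaTable",
    "confusion_matrix",
    "per_class_metrics",
    "overall_accuracy",
    "cohens_kappa",
    "one_way_anova",
]


@dataclass
class ConfusionMatrix:
    """L x L count matrix; rows are true classes, columns predictions."""

    counts: np.ndarray
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError(f"counts must be square; got shape {self.counts.shape}")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not self.class_names:
            self.class_names = [f"class{i + 1}" for i in range(self.counts.shape[0])]
        if len(self.class_names) != self.counts.shape[0]:
            raise ValueError("class_names length mismatch")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class MetricsReport:
    """Per-class precision/recall/F1 (percent), overall accuracy and kappa."""

    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    overall_accuracy: float
    kappa: float
    class_names: list[str]

    def as_dict(self, kappa_percent: bool = False) -> dict:
        return {
            "per_class": {
                name: {
                    "precision": round(float(p), 3),
                    "recall": round(float(r), 3),
                    "f1": round(float(f), 3),
                }
                for name, p, r, f in zip(
                    self.class_names, self.precision, self.recall, self.f1
                )
            },
            "overall_accuracy": round(float(self.overall_accuracy), 3),
            "kappa": round(float(self.kappa) * (100.0 if kappa_percent else 1.0), 4),
        }


@dataclass
class AnovaTable:
    ss_between: float
    ss_within: float
    ss_total: float
    df_between: int
    df_within: int
    df_total: int
    ms_between: float
    ms_within: float
    f_stat: float
    p_value: float
    f_critical: float
    alpha: float = 0.05

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def confusion_matrix(
    true_labels: Sequence[int],
    predicted_labels: Sequence[int],
    n_classes: int,
    class_names: Sequence[str] | None = None,
    sample_ids: Sequence | None = None,
) -> ConfusionMatrix:
    """Tally an L x L confusion matrix from 1-based label vectors."""
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if t.size == 0:
        raise ValueError("empty label vectors")
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.shape} true vs {p.shape} predicted")
    for name, arr in (("true", t), ("predicted", p)):
        bad = (arr < 1) | (arr > n_classes)
        if np.any(bad):
            i = int(np.argmax(bad))
            sid = sample_ids[i] if sample_ids is not None else i
            raise ValueError(
                f"{name} label {arr[i]} out of range 1..{n_classes} "
                f"for sample {sid!r}"
            )
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (t - 1, p - 1), 1)
    return ConfusionMatrix(counts, list(class_names) if class_names else [])


def per_class_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """One-vs-rest precision, recall and F1 per class, in percent.

    A zero denominator (class never predicted, never present, or both) yields
    0 for the affected metric with a warning.
    """
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    counts = cm.counts.astype(float)
    tp = np.diag(counts)
    fp = counts.sum(axis=0) - tp
    fn = counts.sum(axis=1) - tp

    def _safe(num, den, what):
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
        if np.any(den == 0):
            warnings.warn(
                f"zero denominator for {what} in classes "
                f"{[cm.class_names[i] for i in np.nonzero(den == 0)[0]]}; "
                "reporting 0",
                stacklevel=3,
            )
        return out

    precision = _safe(tp, tp + fp, "precision")
    recall = _safe(tp, tp + fn, "recall")
    f1 = _safe(2 * precision * recall, precision + recall, "F1")
    return MetricsReport(
        precision=100 * precision,
        recall=100 * recall,
        f1=100 * f1,
        overall_accuracy=overall_accuracy(cm),
        kappa=cohens_kappa(cm),
        class_names=cm.class_names,
    )


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Percentage of correctly classified samples, ``100 * trace / total``."""
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    return 100.0 * float(np.trace(cm.counts)) / cm.total


def cohens_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement ``(p_o - p_e) / (1 - p_e)``."""
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    n = cm.total
    p_o = float(np.trace(cm.counts)) / n
    p_e = float(cm.counts.sum(axis=1) @ cm.counts.sum(axis=0)) / (n * n)
    if p_e >= 1.0 - 1e-15:
        if p_o >= 1.0 - 1e-15:
            return 1.0
        raise ZeroDivisionError(
            "kappa undefined: expected agreement is 1 but observed is below 1"
        )
    return (p_o - p_e) / (1.0 - p_e)


def one_way_anova(groups: Sequence[Sequence[float]], alpha: float = 0.05) -> AnovaTable:
    """Single-factor ANOVA over two or more groups of observations.

    Decomposes total variation into between-group and within-group sums of
    squares, with ``F = MS_between / MS_within`` referred to the
    ``F(df_between, df_within)`` distribution.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least 2 observations")
    all_vals = np.concatenate(arrays)
    grand = all_vals.mean()
    ss_between = float(sum(a.size * (a.mean() - grand) ** 2 for a in arrays))
    ss_within = float(sum(((a - a.mean()) ** 2).sum() for a in arrays))
    df_between = len(arrays) - 1
    df_within = all_vals.size - len(arrays)
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0:
        raise ZeroDivisionError("within-group variance is zero; F undefined")
    f_stat = ms_between / ms_within
    return AnovaTable(
        ss_between=ss_between,
        ss_within=ss_within,
        ss_total=ss_between + ss_within,
        df_between=df_between,
        df_within=df_within,
        df_total=df_between + df_within,
        ms_between=ms_between,
        ms_within=ms_within,
        f_stat=f_stat,
        p_value=float(stats.f.sf(f_stat, df_between, df_within)),
        f_critical=float(stats.f.isf(alpha, df_between, df_within)),
        alpha=alpha,
    )
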