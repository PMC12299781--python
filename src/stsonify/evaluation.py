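"""Diagnostic statistics for classification-study confusion matrices.

A confusion matrix here is a square count table with rows = predicted
class and columns = gold-standard class.  The module computes one-vs-rest
sensitivity, specificity, F-score (harmonic mean of precision and recall)
and balanced accuracy per class, overall accuracy with an exact
(Clopper-Pearson) 95% binomial confidence interval, and Cohen's kappa.
Class-collapsing utilities support dichotomization (healthy vs. any
pathology) and severity merging (pooling locations within a severity
grade).

The 5x5 matrix of the package's reference classification study — 44
raters x 15 sonified ECG samples = 660 instances over the classes IE,
I-moderate, I-severe, A-moderate, A-severe — ships as
:data:`STUDY_CONFUSION_MATRIX`.

A note on the F-score: some reports define an "F-score" as
se*sp/(se+sp); that quantity is exposed as
:func:`se_sp_product_ratio` for transparency, but the reported
``f_score`` is the standard 2*P*R/(P+R), which is what published
class-statistics tables for this study actually contain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ConfusionMatrix",
    "ClassStats",
    "STUDY_CONFUSION_MATRIX",
    "STUDY_LABELS",
    "DICHOTOMY_MAPPING",
    "SEVERITY_MAPPING",
    "per_class_stats",
    "all_class_stats",
    "overall_accuracy",
    "cohens_kappa",
    "collapse",
    "se_sp_product_ratio",
    "read_confusion_csv",
    "write_confusion_csv",
    "report",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Square count table: rows = predicted class, columns = gold class."""

    labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=int)
        k = len(self.labels)
        if counts.shape != (k, k):
            raise ValueError(
                f"counts must be {k}x{k} for {k} labels, got {counts.shape}")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if counts.sum() == 0:
            raise ValueError("grand total must be positive")
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels),
                            columns=list(self.labels))


#: Ordered class labels of the reference study (I = inferior, A = anterior).
STUDY_LABELS = ("IE", "I-moderate", "I-severe", "A-moderate", "A-severe")

#: 660 classification instances: 44 raters x 3 blocks x 5 conditions.
STUDY_CONFUSION_MATRIX = ConfusionMatrix(
    labels=STUDY_LABELS,
    counts=np.array([
        [132,   0,   0,   0,   0],
        [  0, 106,  14,  15,   0],
        [  0,   8,  95,   4,  13],
        [  0,  12,   4, 100,  11],
        [  0,   6,  19,  13, 108],
    ]),
)

#: Healthy (0) vs. any pathology (1).
DICHOTOMY_MAPPING = {
    "IE": "0", "I-moderate": "1", "I-severe": "1",
    "A-moderate": "1", "A-severe": "1",
}

#: Pool locations within a severity grade.
SEVERITY_MAPPING = {
    "IE": "IE", "I-moderate": "moderate", "A-moderate": "moderate",
    "I-severe": "severe", "A-severe": "severe",
}


@dataclass(frozen=True)
class ClassStats:
    """One-vs-rest diagnostic statistics for a single class."""

    sensitivity: float
    specificity: float
    f_score: float
    balanced_accuracy: float


def per_class_stats(cm: ConfusionMatrix, class_label: str) -> ClassStats:
    """One-vs-rest se/sp/F/balanced accuracy for *class_label*.

    se = TP / gold positives; sp = TN / gold negatives; F is the harmonic
    mean of precision and recall (0 when precision + recall = 0);
    balanced accuracy = (se + sp) / 2.  Values are never rounded here.
    """
    if class_label not in cm.labels:
        raise ValueError(f"unknown class {class_label!r}; "
                         f"labels are {cm.labels}")
    i = cm.labels.index(class_label)
    tp = cm.counts[i, i]
    col_total = cm.counts[:, i].sum()
    row_total = cm.counts[i, :].sum()
    gold_neg = cm.total - col_total
    fp = row_total - tp
    tn = gold_neg - fp

    if col_total == 0:
        raise ValueError(
            f"sensitivity undefined for {class_label!r}: no gold-standard "
            "instances of this class")
    se = tp / col_total
    sp = tn / gold_neg if gold_neg > 0 else math.nan
    precision = tp / row_total if row_total > 0 else 0.0
    f = (2 * precision * se / (precision + se)
         if precision + se > 0 else 0.0)
    ba = (se + sp) / 2
    return ClassStats(sensitivity=se, specificity=sp, f_score=f,
                      balanced_accuracy=ba)


def all_class_stats(cm: ConfusionMatrix) -> pd.DataFrame:
    """Per-class statistics table (unrounded), one row per class."""
    rows = {}
    for label in cm.labels:
        s = per_class_stats(cm, label)
        rows[label] = {
            "sensitivity": s.sensitivity,
            "specificity": s.specificity,
            "f_score": s.f_score,
            "balanced_accuracy": s.balanced_accuracy,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def overall_accuracy(cm: ConfusionMatrix,
                     alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """Trace / total with an exact (Clopper-Pearson) binomial CI."""
    correct = int(np.trace(cm.counts))
    acc = correct / cm.total
    lo, hi = proportion_confint(correct, cm.total, alpha=alpha,
                                method="beta")
    return acc, (float(lo), float(hi))


def cohens_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement (p_o - p_e) / (1 - p_e)."""
    n = cm.total
    p_o = np.trace(cm.counts) / n
    row = cm.counts.sum(axis=1)
    col = cm.counts.sum(axis=0)
    p_e = float(np.dot(row, col)) / n ** 2
    if p_e == 1.0:
        if p_o == 1.0:
            return 1.0
        return math.nan
    return float((p_o - p_e) / (1.0 - p_e))


def se_sp_product_ratio(cm: ConfusionMatrix, class_label: str) -> float:
    """The alternative 'F-score' definition se*sp/(se+sp).

    Provided for transparency only; it does not reproduce standard
    class-statistics tables (see the module docstring).
    """
    s = per_class_stats(cm, class_label)
    if s.sensitivity + s.specificity == 0:
        return 0.0
    return s.sensitivity * s.specificity / (s.sensitivity + s.specificity)


def collapse(cm: ConfusionMatrix, mapping: dict[str, str]) -> ConfusionMatrix:
    """Merge classes by an old-label -> new-label mapping (total mapping).

    Rows and columns are summed by image label; the grand total is
    conserved.  New labels keep the order of their first appearance.
    """
    missing = [l for l in cm.labels if l not in mapping]
    if missing:
        raise ValueError(f"mapping must cover every label; missing {missing}")
    new_labels: list[str] = []
    for l in cm.labels:
        if mapping[l] not in new_labels:
            new_labels.append(mapping[l])
    k = len(new_labels)
    out = np.zeros((k, k), dtype=int)
    for i, li in enumerate(cm.labels):
        for j, lj in enumerate(cm.labels):
            out[new_labels.index(mapping[li]),
                new_labels.index(mapping[lj])] += cm.counts[i, j]
    return ConfusionMatrix(labels=tuple(new_labels), counts=out)


def read_confusion_csv(path) -> ConfusionMatrix:
    """Read a labeled square count table (first column = predicted labels)."""
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError("confusion matrix must have matching row/column "
                         "labels in the same order")
    return ConfusionMatrix(labels=tuple(str(l) for l in df.index),
                           counts=df.to_numpy(dtype=int))


def write_confusion_csv(cm: ConfusionMatrix, path) -> None:
    cm.to_frame().to_csv(path)


def report(cm: ConfusionMatrix, digits: int = 2) -> str:
    """Human-readable summary: accuracy with CI, kappa, per-class table."""
    acc, (lo, hi) = overall_accuracy(cm)
    kappa = cohens_kappa(cm)
    stats = all_class_stats(cm).round(digits)
    lines = [
        f"n = {cm.total} classification instances, "
        f"{len(cm.labels)} classes",
        f"overall accuracy = {acc:.{digits}f} "
        f"(95% CI {lo:.{digits}f}, {hi:.{digits}f})",
        f"Cohen's kappa = {kappa:.{digits}f}",
        "",
        stats.to_string(),
    ]
    return "\n".join(lines)
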