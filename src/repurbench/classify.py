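"""Confusion-matrix metrics at a rank cutoff, and ROC / PR curves.

A ranking becomes a binary classifier by choosing a rank cutoff: items at
rank ≤ cutoff are predicted positive, the rest negative.  Comparing those
predictions with the gold-standard labels gives the four confusion counts,
from which sensitivity, specificity, FDR, FPR, precision, accuracy, F1 and
MCC follow.

Metrics whose denominator is zero raise :class:`UndefinedMetricError`
rather than silently returning 0 — silent zeros corrupt aggregates.  The
one deliberate exception is F1, computed as ``2·TP/(2·TP+FP+FN)``, which is
defined whenever there is at least one active or one predicted positive.

Curves are emitted at every integer cutoff (LOO rankings are tie-free by
construction, so no score-threshold dialect is needed).  The trapezoid
AUROC over these points equals the pairwise Mann–Whitney statistic; the PR
area uses step interpolation and therefore equals average precision on
binary labels (linear PR interpolation is known to overestimate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .standards import RelevanceVector

__all__ = [
    "ConfusionCounts",
    "UndefinedMetricError",
    "confusion_at_cutoff",
    "sensitivity",
    "specificity",
    "fdr",
    "fpr",
    "precision",
    "accuracy",
    "f1",
    "mcc",
    "roc_curve",
    "auroc_trapezoid",
    "pr_curve",
    "auprc",
]


class UndefinedMetricError(ZeroDivisionError):
    """The metric's denominator is zero for these counts."""


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def N(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    @property
    def n_actives(self) -> int:
        return self.TP + self.FN

    @property
    def n_inactives(self) -> int:
        return self.TN + self.FP


def confusion_at_cutoff(rel: RelevanceVector, cutoff: int) -> ConfusionCounts:
    """Counts when ranks ≤ cutoff are called positive."""
    if not 1 <= cutoff <= rel.N:
        raise ValueError(f"cutoff must be in 1..{rel.N}, got {cutoff}")
    top = rel.rel[:cutoff]
    bottom = rel.rel[cutoff:]
    tp = sum(1 for r in top if r > 0)
    fn = sum(1 for r in bottom if r > 0)
    return ConfusionCounts(TP=tp, FP=cutoff - tp, TN=len(bottom) - fn, FN=fn)


def _ratio(num: int, denom: int, what: str) -> float:
    if denom == 0:
        raise UndefinedMetricError(f"{what} undefined: zero denominator")
    return num / denom


def sensitivity(c: ConfusionCounts) -> float:
    """TP / (TP + FN); a.k.a. recall, true positive rate."""
    return _ratio(c.TP, c.TP + c.FN, "sensitivity")


def specificity(c: ConfusionCounts) -> float:
    """TN / (TN + FP); a.k.a. selectivity, true negative rate."""
    return _ratio(c.TN, c.TN + c.FP, "specificity")


def fdr(c: ConfusionCounts) -> float:
    """False discovery rate FP / (FP + TP)."""
    return _ratio(c.FP, c.FP + c.TP, "FDR")


def fpr(c: ConfusionCounts) -> float:
    """False positive rate FP / (FP + TN)."""
    return _ratio(c.FP, c.FP + c.TN, "FPR")


def precision(c: ConfusionCounts) -> float:
    """TP / (TP + FP); positive predictive value."""
    return _ratio(c.TP, c.TP + c.FP, "precision")


def accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / N.  Misleading on skewed standards — see methods note."""
    return _ratio(c.TP + c.TN, c.N, "accuracy")


def f1(c: ConfusionCounts) -> float:
    """Harmonic mean of precision and recall, as 2·TP/(2·TP+FP+FN)."""
    return _ratio(2 * c.TP, 2 * c.TP + c.FP + c.FN, "F1")


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient, in [−1, 1]."""
    denom_sq = (
        (c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN)
    )
    if denom_sq == 0:
        raise UndefinedMetricError("MCC undefined: a confusion marginal is zero")
    return (c.TP * c.TN - c.FP * c.FN) / float(np.sqrt(denom_sq))


def roc_curve(rel: RelevanceVector) -> np.ndarray:
    """(FPR, TPR) at every cutoff 0..N, as an (N+1, 2) array."""
    n_act = rel.n_actives
    n_inact = rel.N - n_act
    if n_act == 0 or n_inact == 0:
        raise ValueError("ROC requires at least one active and one inactive")
    labels = np.asarray(rel.rel) > 0
    tp = np.concatenate(([0], np.cumsum(labels)))
    fp = np.arange(rel.N + 1) - tp
    return np.column_stack((fp / n_inact, tp / n_act))


def auroc_trapezoid(rel: RelevanceVector) -> float:
    """Area under the ROC curve by the trapezoid rule over FPR."""
    pts = roc_curve(rel)
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


def pr_curve(rel: RelevanceVector) -> np.ndarray:
    """(recall, precision) at every cutoff 1..N, as an (N, 2) array."""
    n_act = rel.n_actives
    if n_act == 0:
        raise ValueError("PR curve requires at least one active")
    labels = np.asarray(rel.rel) > 0
    tp = np.cumsum(labels)
    k = np.arange(1, rel.N + 1)
    return np.column_stack((tp / n_act, tp / k))


def auprc(rel: RelevanceVector) -> float:
    """Area under the PR curve by step summation (≡ AP on binary labels)."""
    pts = pr_curve(rel)
    recall = np.concatenate(([0.0], pts[:, 0]))
    return float(np.sum(np.diff(recall) * pts[:, 1]))
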