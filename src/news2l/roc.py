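"""ROC curves, AUC with DeLong variance, paired AUC comparison, Youden cut-offs.

Direction is fixed as "higher score = more severe": a patient is
test-positive when their score is at or above the threshold.  The empirical
ROC curve has one operating point per distinct score value (ties grouped)
plus the (0,0) and (1,1) corners; its trapezoidal area equals the
Mann–Whitney probability that a random outcome-positive patient outranks a
random outcome-negative one (ties counting one half).

AUC variance and the paired comparison of two scores measured on the same
patients use DeLong's structural components (the jackknife-style placement
values), the standard nonparametric approach for correlated ROC curves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .accuracy import AnalysisError

__all__ = [
    "ROCCurve",
    "CurveComparison",
    "roc_points",
    "auc_mann_whitney",
    "auc_ci_delong",
    "compare_auc_delong",
    "youden_optimal_cutoff",
]


@dataclass(frozen=True)
class ROCCurve:
    """An empirical ROC curve with its AUC and DeLong standard error."""

    thresholds: np.ndarray  # descending; one per operating point between corners
    fpr: np.ndarray  # ascending, starts at 0, ends at 1
    tpr: np.ndarray
    auc: float
    auc_se: float
    auc_ci: tuple[float, float]
    n_pos: int
    n_neg: int
    degenerate_variance: bool = False

    @property
    def points(self) -> np.ndarray:
        """Operating points as an array of (fpr, tpr) rows."""
        return np.column_stack([self.fpr, self.tpr])


@dataclass(frozen=True)
class CurveComparison:
    """Paired DeLong comparison of two AUCs on the same patients."""

    auc_a: float
    auc_b: float
    difference: float
    z_statistic: float
    p_value: float


def _validate(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise AnalysisError("scores and labels must be equal-length 1-D sequences")
    if not set(np.unique(labels)) <= {0, 1}:
        raise AnalysisError("labels must be binary 0/1")
    labels = labels.astype(int)
    if labels.sum() in (0, len(labels)):
        raise AnalysisError("labels contain a single class")
    if np.isnan(scores).any():
        raise AnalysisError("scores contain NaN")
    return scores, labels


def _delong_placements(scores: np.ndarray, labels: np.ndarray):
    """Structural components V10 (per positive) and V01 (per negative).

    Midrank formulation: V10_i = P-hat(X_i > Y) + 0.5 P-hat(X_i = Y), and
    symmetrically for V01.  mean(V10) = mean(V01) = AUC.
    """
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    r_all = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = stats.rankdata(pos)
    r_neg = stats.rankdata(neg)
    v10 = (r_all[:m] - r_pos) / n
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    return v10, v01


def auc_mann_whitney(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUC as the Mann–Whitney pair statistic.

    Mean over all (positive, negative) pairs of 1 if the positive scores
    higher, 0.5 on a tie, 0 otherwise.
    """
    scores, labels = _validate(scores, labels)
    v10, _ = _delong_placements(scores, labels)
    return float(v10.mean())


def roc_points(
    scores: Sequence[float], labels: Sequence[int], ci_level: float = 0.95
) -> ROCCurve:
    """Build the empirical ROC curve for a score against a binary outcome.

    Thresholds between the corner points are the midpoints of adjacent
    distinct score values, so each reported cut-off is achievable and
    unambiguous (no observed score sits on a threshold).
    """
    scores, labels = _validate(scores, labels)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos

    order = np.argsort(-scores, kind="mergesort")
    s_sorted = scores[order]
    l_sorted = labels[order]
    distinct_last = np.r_[np.nonzero(np.diff(s_sorted))[0], len(s_sorted) - 1]
    tps = np.cumsum(l_sorted)[distinct_last]
    fps = np.cumsum(1 - l_sorted)[distinct_last]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    # trailing corner is reached at the lowest distinct value, so it is
    # already present; thresholds are midpoints between adjacent distinct
    # score values, one per interior point
    uniq_desc = s_sorted[distinct_last]
    thresholds = (uniq_desc[:-1] + uniq_desc[1:]) / 2.0

    auc = float(np.trapezoid(tpr, fpr))
    v10, v01 = _delong_placements(scores, labels)
    var = 0.0
    if n_pos >= 2 and n_neg >= 2:
        var = float(np.var(v10, ddof=1) / n_pos + np.var(v01, ddof=1) / n_neg)
    degenerate = var <= 0.0
    se = math.sqrt(max(var, 0.0))
    z = stats.norm.ppf(0.5 + ci_level / 2)
    ci = (max(0.0, auc - z * se), min(1.0, auc + z * se))
    return ROCCurve(
        thresholds=thresholds,
        fpr=fpr,
        tpr=tpr,
        auc=auc,
        auc_se=se,
        auc_ci=ci,
        n_pos=n_pos,
        n_neg=n_neg,
        degenerate_variance=degenerate,
    )


def auc_ci_delong(
    scores: Sequence[float], labels: Sequence[int], ci_level: float = 0.95
) -> tuple[float, float]:
    """Normal-approximation AUC interval from the DeLong variance, clipped to [0,1].

    With perfect separation the estimated variance is zero and the interval
    collapses onto the point estimate (the curve carries a degeneracy flag).
    """
    return roc_points(scores, labels, ci_level).auc_ci


def compare_auc_delong(
    scores_a: Sequence[float], scores_b: Sequence[float], labels: Sequence[int]
) -> CurveComparison:
    """Paired DeLong test of two AUCs computed on the same patients.

    The variance of the AUC difference subtracts twice the covariance of the
    two scores' structural components; the two-sided p-value comes from the
    normal reference.  Identical rankings give difference 0 and p-value 1.
    """
    scores_a, labels = _validate(scores_a, labels)
    scores_b, labels_b = _validate(scores_b, labels)
    if not np.array_equal(labels, labels_b):
        raise AnalysisError("paired comparison requires identical labels")
    v10a, v01a = _delong_placements(scores_a, labels)
    v10b, v01b = _delong_placements(scores_b, labels)
    m, n = len(v10a), len(v01a)
    auc_a, auc_b = float(v10a.mean()), float(v10b.mean())
    diff = auc_a - auc_b
    if m < 2 or n < 2:
        raise AnalysisError("paired DeLong test needs at least 2 per class")
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    cov = s10 / m + s01 / n
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var <= 0:
        z_stat = 0.0 if diff == 0 else math.copysign(float("inf"), diff)
    else:
        z_stat = diff / math.sqrt(var)
    p = 1.0 if math.isfinite(z_stat) and z_stat == 0 else float(2 * stats.norm.sf(abs(z_stat)))
    return CurveComparison(
        auc_a=auc_a, auc_b=auc_b, difference=diff, z_statistic=z_stat, p_value=p
    )


def youden_optimal_cutoff(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[float, float, float]:
    """Cut-off maximising Youden's J = Se + Sp - 1, with its Se and Sp.

    Candidate cut-offs are the midpoints between adjacent distinct observed
    score values; ties on J are broken toward the lower cut-off, i.e. toward
    higher sensitivity — in a triage setting missing a true positive is the
    costlier error.  Returns ``(cutoff, sensitivity, specificity)``.
    """
    scores, labels = _validate(scores, labels)
    uniq = np.unique(scores)
    if len(uniq) < 2:
        raise AnalysisError("need at least two distinct score values")
    candidates = (uniq[:-1] + uniq[1:]) / 2.0  # ascending
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    best = None
    for c in candidates:
        se = float(np.mean(pos >= c))
        sp = float(np.mean(neg < c))
        j = se + sp - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, float(c), se, sp)
    _, cutoff, se, sp = best
    return cutoff, se, sp
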