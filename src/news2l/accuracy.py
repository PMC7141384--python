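"""Diagnostic test accuracy: 2x2 tables, the full metric panel, and CIs.

Given a score, a binary outcome and a cut-off, a 2x2 contingency table is
formed (test-positive iff score >= cutoff) and the standard panel computed:
sensitivity, specificity, predictive values, likelihood ratios, diagnostic
odds ratio, diagnostic accuracy and prevalence.

Confidence intervals: Wilson score intervals for all proportions, log-normal
(Simel) intervals for the likelihood ratios, and Woolf log intervals for the
odds ratio.  When the table has a zero off-diagonal cell the odds ratio is
reported with a Haldane–Anscombe +0.5 continuity correction and flagged.

Published accuracy panels usually print only group sizes and Se/Sp;
:func:`reconstruct_contingency` inverts those back to integer counts
(round-half-up) so every downstream metric can be recomputed and audited.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ContingencyTable",
    "MetricEstimate",
    "DiagnosticReport",
    "SampleSize",
    "AnalysisError",
    "build_contingency",
    "reconstruct_contingency",
    "compute_metrics",
    "sample_size_proportion",
]

METRIC_NAMES = ("Se", "Sp", "PPV", "NPV", "LR_pos", "LR_neg", "OR", "DA", "prevalence")


class AnalysisError(ValueError):
    """Raised when an accuracy analysis is requested on unusable input."""


@dataclass(frozen=True)
class ContingencyTable:
    """TP/FP/FN/TN counts at a single cut-off."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise AnalysisError(f"{name} must be a non-negative integer, got {v}")
        if self.n == 0:
            raise AnalysisError("contingency table is empty")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def positives(self) -> int:
        """Outcome-positive patients (diseased)."""
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        """Outcome-negative patients."""
        return self.fp + self.tn

    @property
    def has_zero_cell(self) -> bool:
        return min(self.tp, self.fp, self.fn, self.tn) == 0


@dataclass(frozen=True)
class MetricEstimate:
    name: str
    point: float
    ci_low: float
    ci_high: float
    ci_level: float = 0.95
    flag: str = ""


@dataclass(frozen=True)
class DiagnosticReport:
    """The full metric panel at one cut-off."""

    cutoff: float
    contingency: ContingencyTable
    metrics: tuple[MetricEstimate, ...]

    def __getitem__(self, name: str) -> MetricEstimate:
        for m in self.metrics:
            if m.name == name:
                return m
        raise KeyError(name)


def build_contingency(
    scores: Sequence[float], labels: Sequence[int], cutoff: float
) -> ContingencyTable:
    """Classify ``score >= cutoff`` as test-positive and tabulate against labels.

    Ties at the cut-off are test-positive.  Requires at least one positive
    and one negative label.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise AnalysisError("scores and labels must have equal length")
    if not set(np.unique(labels)) <= {0, 1}:
        raise AnalysisError("labels must be binary 0/1")
    if labels.min() == labels.max():
        raise AnalysisError("labels contain a single class")
    pos = scores >= cutoff
    lab = labels.astype(bool)
    return ContingencyTable(
        tp=int(np.sum(pos & lab)),
        fp=int(np.sum(pos & ~lab)),
        fn=int(np.sum(~pos & lab)),
        tn=int(np.sum(~pos & ~lab)),
    )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def reconstruct_contingency(
    n_pos: int, n_neg: int, se: float, sp: float
) -> ContingencyTable:
    """Invert printed Se/Sp and group sizes back to integer 2x2 counts.

    tp = round(se * n_pos), tn = round(sp * n_neg) with round-half-up; the
    complements fill fn and fp.
    """
    if n_pos <= 0 or n_neg <= 0:
        raise AnalysisError("group sizes must be positive")
    if not (0 <= se <= 1 and 0 <= sp <= 1):
        raise AnalysisError("se and sp must lie in [0, 1]")
    tp = _round_half_up(se * n_pos)
    tn = _round_half_up(sp * n_neg)
    return ContingencyTable(tp=tp, fp=n_neg - tn, fn=n_pos - tp, tn=tn)


def _wilson(count: int, nobs: int, ci_level: float) -> tuple[float, float]:
    if nobs == 0:
        return (float("nan"), float("nan"))
    lo, hi = proportion_confint(count, nobs, alpha=1 - ci_level, method="wilson")
    return float(lo), float(hi)


def _ratio_ci(log_point: float, se_log: float, z: float) -> tuple[float, float]:
    return math.exp(log_point - z * se_log), math.exp(log_point + z * se_log)


def compute_metrics(
    ct: ContingencyTable, ci_level: float = 0.95, cutoff: float = float("nan")
) -> DiagnosticReport:
    """Compute the nine-metric accuracy panel with confidence intervals.

    Proportions (Se, Sp, PPV, NPV, DA, prevalence) get Wilson score
    intervals; LR+/LR- get Simel log-normal intervals; the odds ratio gets a
    Woolf log interval.  Degenerate cells yield ``inf``/``nan`` points with a
    flag rather than an exception, except the odds ratio which is continuity
    corrected (+0.5 on all cells) and flagged when any cell is zero.
    """
    tp, fp, fn, tn = ct.tp, ct.fp, ct.fn, ct.tn
    n = ct.n
    z = stats.norm.ppf(0.5 + ci_level / 2)

    def prop(name: str, count: int, nobs: int) -> MetricEstimate:
        point = count / nobs if nobs else float("nan")
        lo, hi = _wilson(count, nobs, ci_level)
        flag = "" if nobs else "undefined (empty denominator)"
        return MetricEstimate(name, point, lo, hi, ci_level, flag)

    se_m = prop("Se", tp, ct.positives)
    sp_m = prop("Sp", tn, ct.negatives)
    ppv = prop("PPV", tp, tp + fp)
    npv = prop("NPV", tn, tn + fn)
    da = prop("DA", tp + tn, n)
    prev = prop("prevalence", ct.positives, n)

    # LR+ = Se / (1 - Sp); Simel log variance = 1/tp - 1/pos + 1/fp - 1/neg
    se_, sp_ = se_m.point, sp_m.point
    if fp == 0 or tp == 0:
        point = float("inf") if fp == 0 and tp > 0 else 0.0
        lr_pos = MetricEstimate("LR_pos", point, float("nan"), float("nan"), ci_level,
                                "degenerate cell; CI undefined")
    else:
        point = se_ / (1 - sp_)
        se_log = math.sqrt(1 / tp - 1 / ct.positives + 1 / fp - 1 / ct.negatives)
        lo, hi = _ratio_ci(math.log(point), se_log, z)
        lr_pos = MetricEstimate("LR_pos", point, lo, hi, ci_level)

    if tn == 0 or fn == 0:
        point = 0.0 if fn == 0 and tn > 0 else float("inf")
        lr_neg = MetricEstimate("LR_neg", point, float("nan"), float("nan"), ci_level,
                                "degenerate cell; CI undefined")
    else:
        point = (1 - se_) / sp_
        se_log = math.sqrt(1 / fn - 1 / ct.positives + 1 / tn - 1 / ct.negatives)
        lo, hi = _ratio_ci(math.log(point), se_log, z)
        lr_neg = MetricEstimate("LR_neg", point, lo, hi, ci_level)

    if ct.has_zero_cell:
        a, b, c, d = tp + 0.5, fp + 0.5, fn + 0.5, tn + 0.5
        point = (a * d) / (b * c)
        se_log = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        lo, hi = _ratio_ci(math.log(point), se_log, z)
        or_m = MetricEstimate("OR", point, lo, hi, ci_level,
                              "zero cell; Haldane-Anscombe +0.5 correction")
    else:
        point = (tp * tn) / (fp * fn)
        se_log = math.sqrt(1 / tp + 1 / fp + 1 / fn + 1 / tn)
        lo, hi = _ratio_ci(math.log(point), se_log, z)
        or_m = MetricEstimate("OR", point, lo, hi, ci_level)

    metrics = (se_m, sp_m, ppv, npv, lr_pos, lr_neg, or_m, da, prev)
    return DiagnosticReport(cutoff=cutoff, contingency=ct, metrics=metrics)


@dataclass(frozen=True)
class SampleSize:
    """Required n for estimating a proportion, before and after loss inflation."""

    n: int
    n_inflated: int
    p: float
    margin: float
    conf: float
    loss: float


def sample_size_proportion(
    p: float, margin: float, conf: float = 0.95, loss: float = 0.0
) -> SampleSize:
    """Sample size to estimate a proportion ``p`` within ``margin`` at level ``conf``.

    n = ceil(z^2 * p * (1 - p) / margin^2), inflated by 1/(1 - loss) when an
    anticipated loss-to-follow-up fraction is given.
    """
    if not 0 < p < 1:
        raise AnalysisError("p must lie strictly in (0, 1)")
    if not 0 < margin < 1:
        raise AnalysisError("margin must lie strictly in (0, 1)")
    if not 0 < conf < 1:
        raise AnalysisError("conf must lie strictly in (0, 1)")
    if not 0 <= loss < 1:
        raise AnalysisError("loss must lie in [0, 1)")
    z = stats.norm.ppf(0.5 + conf / 2)
    n = math.ceil(z**2 * p * (1 - p) / margin**2)
    n_inflated = math.ceil(n / (1 - loss)) if loss > 0 else n
    return SampleSize(n=n, n_inflated=n_inflated, p=p, margin=margin, conf=conf, loss=loss)
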