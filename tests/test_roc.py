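"""ROC construction, AUC identities, DeLong tests, Youden cut-off selection."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from news2l.accuracy import AnalysisError
from news2l.roc import (
    auc_ci_delong,
    auc_mann_whitney,
    compare_auc_delong,
    roc_points,
    youden_optimal_cutoff,
)


def _random_instance(rng, n_max=50):
    n = int(rng.integers(4, n_max + 1))
    labels = np.zeros(n, dtype=int)
    labels[: int(rng.integers(1, n))] = 1
    rng.shuffle(labels)
    if labels.sum() in (0, n):
        labels[0], labels[-1] = 1, 0
    # discrete support forces plenty of ties
    scores = rng.integers(0, 8, size=n).astype(float)
    return scores, labels


def test_perfect_ranking_has_unit_auc():
    curve = roc_points([1, 2, 3, 4], [0, 0, 1, 1])
    assert curve.auc == 1.0
    assert auc_mann_whitney([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0


def test_tied_instance_pair_counting():
    # 4 positive/negative pairs scoring 1, 0.5, 1, 1 -> 3.5/4
    assert auc_mann_whitney([1, 2, 2, 3], [0, 0, 1, 1]) == pytest.approx(0.875)
    assert roc_points([1, 2, 2, 3], [0, 0, 1, 1]).auc == pytest.approx(0.875)


def test_all_scores_equal_gives_half():
    assert auc_mann_whitney([3, 3, 3, 3], [0, 1, 0, 1]) == 0.5


def test_null_scores_auc_near_half():
    rng = np.random.default_rng(42)
    labels = np.r_[np.ones(100, int), np.zeros(100, int)]
    scores = rng.permutation(labels).astype(float)
    curve = roc_points(scores, labels)
    # Mann-Whitney null standard error
    m = n = 100
    se = np.sqrt((m + n + 1) / (12 * m * n))
    assert abs(curve.auc - 0.5) < 3 * se


def test_curve_shape_and_trapezoid_identity():
    rng = np.random.default_rng(0)
    for _ in range(50):
        scores, labels = _random_instance(rng)
        curve = roc_points(scores, labels)
        assert curve.fpr[0] == curve.tpr[0] == 0.0
        assert curve.fpr[-1] == curve.tpr[-1] == 1.0
        assert np.all(np.diff(curve.fpr) >= 0)
        assert np.all(np.diff(curve.tpr) >= 0)
        assert len(curve.thresholds) == len(curve.fpr) - 2
        assert curve.auc == pytest.approx(np.trapezoid(curve.tpr, curve.fpr), abs=1e-12)


def test_trapezoid_equals_pair_counting_everywhere():
    rng = np.random.default_rng(1)
    for _ in range(500):
        scores, labels = _random_instance(rng)
        assert roc_points(scores, labels).auc == pytest.approx(
            auc_mann_whitney(scores, labels), abs=1e-12)


def test_auc_agrees_with_sklearn():
    rng = np.random.default_rng(2)
    for _ in range(100):
        scores, labels = _random_instance(rng)
        assert roc_points(scores, labels).auc == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12)


def test_auc_invariant_under_monotone_transform():
    rng = np.random.default_rng(3)
    for _ in range(50):
        scores, labels = _random_instance(rng)
        base = roc_points(scores, labels).auc
        assert roc_points(np.exp(scores), labels).auc == pytest.approx(base, abs=1e-12)
        assert roc_points(scores**3 + 2 * scores, labels).auc == pytest.approx(
            base, abs=1e-12)


def test_boosting_positive_scores_never_lowers_auc():
    rng = np.random.default_rng(4)
    for _ in range(50):
        scores, labels = _random_instance(rng)
        base = roc_points(scores, labels).auc
        boosted = scores + 1.5 * (labels == 1)
        assert roc_points(boosted, labels).auc >= base - 1e-12


def test_single_class_and_nan_rejected():
    with pytest.raises(AnalysisError):
        roc_points([1, 2, 3], [1, 1, 1])
    with pytest.raises(AnalysisError):
        roc_points([1, np.nan, 3], [1, 0, 1])


# ---------------------------------------------------------------------------
# DeLong interval and paired test
# ---------------------------------------------------------------------------

def test_perfect_separation_collapses_interval_with_flag():
    curve = roc_points([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
    assert curve.degenerate_variance
    assert curve.auc_ci == (1.0, 1.0)


def test_interval_contains_point_estimate():
    rng = np.random.default_rng(5)
    for _ in range(50):
        scores, labels = _random_instance(rng)
        curve = roc_points(scores, labels)
        lo, hi = curve.auc_ci
        assert lo <= curve.auc <= hi
        assert auc_ci_delong(scores, labels) == curve.auc_ci


def test_identical_scores_compare_equal():
    scores = np.array([1.0, 2, 3, 4, 5, 6])
    labels = np.array([0, 1, 0, 1, 0, 1])
    cmp = compare_auc_delong(scores, scores, labels)
    assert cmp.difference == 0.0
    assert cmp.p_value == 1.0


def test_rank_preserving_shift_compares_equal():
    scores = np.array([1.0, 2, 3, 4, 5, 6])
    labels = np.array([0, 1, 0, 1, 0, 1])
    cmp = compare_auc_delong(scores, scores + 7.0, labels)
    assert cmp.difference == 0.0
    assert cmp.p_value == 1.0


def test_paired_test_detects_a_dominant_score():
    rng = np.random.default_rng(6)
    labels = np.r_[np.ones(150, int), np.zeros(150, int)]
    strong = np.r_[rng.normal(2.0, 1, 150), rng.normal(0, 1, 150)]
    noise = rng.normal(size=300)
    cmp = compare_auc_delong(strong, noise, labels)
    assert cmp.difference > 0
    assert cmp.p_value < 1e-6


# ---------------------------------------------------------------------------
# Youden cut-off
# ---------------------------------------------------------------------------

def test_youden_perfect_separation_midpoint():
    cutoff, se, sp = youden_optimal_cutoff([1, 2, 3, 4], [0, 0, 1, 1])
    assert cutoff == 2.5
    assert se == 1.0 and sp == 1.0


def test_youden_tie_breaks_toward_sensitivity():
    # J = 0.5 at both 1.5 and 2.5; the lower cut-off keeps Se = 1
    cutoff, se, sp = youden_optimal_cutoff([1, 2, 2, 3], [0, 0, 1, 1])
    assert cutoff == 1.5
    assert se == 1.0 and sp == 0.5


def _exhaustive_youden(scores, labels):
    uniq = np.unique(scores)
    best = None
    for c in (uniq[:-1] + uniq[1:]) / 2:
        se = np.mean(scores[labels == 1] >= c)
        sp = np.mean(scores[labels == 0] < c)
        j = se + sp - 1
        if best is None or j > best[0] + 1e-12:
            best = (j, c)
    return best


def test_youden_matches_exhaustive_scan():
    rng = np.random.default_rng(7)
    for _ in range(200):
        n = int(rng.integers(6, 200))
        labels = (rng.random(n) < 0.4).astype(int)
        if labels.sum() in (0, n):
            labels[0], labels[-1] = 1, 0
        scores = np.round(rng.normal(labels.astype(float), 1.0), 1)
        if len(np.unique(scores)) < 2:
            continue
        cutoff, se, sp = youden_optimal_cutoff(scores, labels)
        j_best, c_best = _exhaustive_youden(scores, labels)
        assert se + sp - 1 == pytest.approx(j_best, abs=1e-12)
        assert cutoff == pytest.approx(c_best)
        # optimality: J at the returned cut-off >= J at every candidate
        uniq = np.unique(scores)
        for c in (uniq[:-1] + uniq[1:]) / 2:
            j_c = np.mean(scores[labels == 1] >= c) + np.mean(
                scores[labels == 0] < c) - 1
            assert se + sp - 1 >= j_c - 1e-12
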