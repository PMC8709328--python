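"""Evaluation statistics against enumeration / closed-form oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.stats import chi2_contingency, hypergeom, norm
from sklearn.metrics import roc_auc_score

from mpus.stats import (
    ConfusionCounts,
    auroc,
    compare_groups,
    confusion_metrics,
    counts_from_predictions,
    detection_rate,
    linear_regression,
    roc_curve,
    two_proportion_test,
    youden_cutoff,
)


class TestConfusionMetrics:
    def test_printed_count_arithmetic(self):
        # 44 of 55 called malignant are right; 27 of 35 called benign are right
        m = confusion_metrics(ConfusionCounts(tp=44, fp=11, tn=27, fn=9))
        assert m.ppv == pytest.approx(44 / 55)
        assert m.accuracy == pytest.approx(71 / 91)
        f = confusion_metrics(ConfusionCounts(tp=44, fp=11, tn=9, fn=27))
        assert f.f1 == pytest.approx(88 / 126)

    def test_perfect_classifier(self):
        m = confusion_metrics(ConfusionCounts(tp=5, fp=0, tn=7, fn=0))
        assert (m.sensitivity, m.specificity, m.ppv, m.npv, m.accuracy, m.f1) == (
            1.0,
            1.0,
            1.0,
            1.0,
            1.0,
            1.0,
        )

    def test_undefined_ratios_are_missing_not_zero(self):
        m = confusion_metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=0))
        assert m.sensitivity is None
        assert m.ppv is None
        assert m.specificity == 1.0

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(ConfusionCounts(0, 0, 0, 0))

    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
    def test_accuracy_is_prevalence_weighted_se_sp(self, tp, fp, tn, fn):
        c = ConfusionCounts(tp, fp, tn, fn)
        if c.total == 0 or tp + fn == 0 or tn + fp == 0:
            return
        m = confusion_metrics(c)
        prev = (tp + fn) / c.total
        assert m.accuracy == pytest.approx(m.sensitivity * prev + m.specificity * (1 - prev))

    def test_counts_from_predictions(self):
        c = counts_from_predictions([True, True, False, False], [True, False, True, False])
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 1, 1)


def brute_force_auroc(scores, labels, larger_is_positive):
    s = np.asarray(scores, float)
    if not larger_is_positive:
        s = -s
    pos = s[np.asarray(labels, bool)]
    neg = s[~np.asarray(labels, bool)]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestAuroc:
    def test_perfectly_separated(self):
        assert auroc([-30, -25, -5, -2], [True, True, False, False]) == 1.0

    def test_four_point_example(self):
        assert auroc([1, 2, 3, 4], [False, True, False, True], larger_is_positive=True) == 0.75

    @given(
        st.lists(st.integers(-5, 5), min_size=2, max_size=50),
        st.data(),
    )
    def test_matches_brute_force_oracle(self, scores, data):
        labels = data.draw(
            st.lists(st.booleans(), min_size=len(scores), max_size=len(scores))
        )
        if not (any(labels) and not all(labels)):
            return
        got = auroc(scores, labels)
        assert got == pytest.approx(brute_force_auroc(scores, labels, False), abs=1e-12)

    def test_matches_sklearn_on_continuous_scores(self, rng):
        scores = rng.normal(size=200)
        labels = rng.random(200) < 0.4
        got = auroc(scores, labels, larger_is_positive=True)
        assert got == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_null_distribution_centres_on_half(self, rng):
        scores = rng.normal(size=10_000)
        labels = rng.random(10_000) < 0.5
        assert auroc(scores, labels) == pytest.approx(0.5, abs=0.02)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([1.0, 2.0], [True, True])


class TestRocYouden:
    def test_sensitivity_monotone_in_threshold(self, rng):
        scores = rng.normal(-15, 10, size=300)
        labels = rng.random(300) < 0.5
        roc = roc_curve(scores, labels)
        assert np.all(np.diff(roc.se) >= 0)  # tightening the cutoff only lowers Se
        assert roc.auroc == pytest.approx(auroc(scores, labels), abs=1e-12)

    def test_separated_classes_cutoff_in_gap(self):
        pos = [-40.0, -35.0, -30.0]
        neg = [-10.0, -5.0, 0.0]
        roc = roc_curve(pos + neg, [True] * 3 + [False] * 3)
        cut = youden_cutoff(roc)
        assert -30.0 <= cut < -10.0

    def test_single_threshold_returned(self):
        roc = roc_curve([-20.0, -20.0], [True, False])
        assert youden_cutoff(roc) == -20.0

    def test_targets_density_equality_boundary(self, rng):
        # two overlapping Gaussians: the population Youden cutoff is where the
        # densities cross; the empirical cutoff is noisy, so check its median
        # over replicates of n = 10^4
        m1, s1, m2, s2 = -25.08, 37.98, -7.08, 42.6
        a = 1 / s1**2 - 1 / s2**2
        b = -2 * (m1 / s1**2 - m2 / s2**2)
        c = m1**2 / s1**2 - m2**2 / s2**2 - 2 * math.log(s2 / s1)
        roots = np.roots([a, b, c])
        J = norm.cdf(roots, m1, s1) - norm.cdf(roots, m2, s2)
        boundary = float(roots[np.argmax(J)])
        cuts = []
        for _ in range(15):
            scores = np.concatenate([rng.normal(m1, s1, 5000), rng.normal(m2, s2, 5000)])
            labels = np.concatenate([np.ones(5000, bool), np.zeros(5000, bool)])
            cuts.append(youden_cutoff(roc_curve(scores, labels)))
        assert abs(np.median(cuts) - boundary) <= 3.0


def exact_mannwhitney_p(a, b):
    """Two-sided exact Mann-Whitney p by full enumeration of rank splits."""
    pooled = list(a) + list(b)
    n1 = len(a)

    def u_stat(idx):
        grp = [pooled[i] for i in idx]
        rest = [pooled[i] for i in range(len(pooled)) if i not in idx]
        return sum(
            1.0 if x > y else (0.5 if x == y else 0.0) for x in grp for y in rest
        )

    u_obs = u_stat(tuple(range(n1)))
    us = [u_stat(idx) for idx in itertools.combinations(range(len(pooled)), n1)]
    mean_u = n1 * (len(pooled) - n1) / 2.0
    dev = abs(u_obs - mean_u)
    return sum(abs(u - mean_u) >= dev - 1e-12 for u in us) / len(us)


class TestCompareGroups:
    def test_identical_groups_not_significant(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert compare_groups(a, a).pvalue >= 0.99

    def test_mannwhitney_exact_matches_enumeration(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        got = compare_groups(a, b, method="mannwhitney")
        assert got.pvalue == pytest.approx(0.1, abs=1e-12)
        assert got.pvalue == pytest.approx(exact_mannwhitney_p(a, b), abs=1e-12)

    def test_normality_gate_picks_t_for_gaussian_data(self, rng):
        a = rng.normal(0, 1, 40)
        b = rng.normal(0.2, 1, 40)
        assert compare_groups(a, b).test == "t"

    def test_gate_picks_mannwhitney_for_skewed_data(self, rng):
        a = rng.exponential(1.0, 60)
        b = rng.exponential(1.3, 60)
        assert compare_groups(a, b).test == "mannwhitney"

    def test_group_separation_detected_in_majority_of_seeds(self):
        # class-conditional AREA moments, class sizes 51/40: the difference is
        # detectable more often than not despite the wide spreads
        rng = np.random.default_rng(0)
        rejections = sum(
            compare_groups(rng.normal(-25.08, 37.98, 51), rng.normal(-7.08, 42.6, 40)).pvalue
            < 0.05
            for _ in range(400)
        )
        assert rejections > 200

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [2.0, 3.0])


class TestTwoProportion:
    def test_printed_comparison(self):
        assert two_proportion_test(66, 91, 71, 91) == pytest.approx(0.39, abs=0.005)

    def test_matches_chisquare_without_correction(self):
        p = two_proportion_test(30, 60, 45, 70)
        chi = chi2_contingency([[30, 30], [45, 25]], correction=False)[1]
        assert p == pytest.approx(chi, abs=1e-10)

    @given(st.integers(1, 40), st.integers(0, 40))
    def test_equal_proportions_give_p_one(self, n, k):
        if k > n:
            return
        assert two_proportion_test(k, n, k, n) == 1.0

    def test_fisher_matches_hypergeometric_enumeration(self):
        p = two_proportion_test(0, 10, 10, 10, method="fisher")
        # only the two extreme 10-choose splits are as unbalanced
        expected = 2 * hypergeom.pmf(0, 20, 10, 10)
        assert p == pytest.approx(expected, rel=1e-9)
        assert p < 1e-4

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            two_proportion_test(5, 4, 1, 10)
        with pytest.raises(ValueError):
            two_proportion_test(1, 0, 1, 10)


class TestRegression:
    def test_identity_line(self):
        x = np.arange(10.0)
        reg = linear_regression(x, x)
        assert reg.intercept == pytest.approx(0.0, abs=1e-12)
        assert reg.slope == pytest.approx(1.0, abs=1e-12)

    def test_two_point_hand_solution(self):
        reg = linear_regression([0.0, 2.0], [1.0, 5.0])
        assert (reg.intercept, reg.slope) == (pytest.approx(1.0), pytest.approx(2.0))

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            linear_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_confidence_interval_coverage(self):
        # nominal 95% intervals cover the truth ~95% of the time
        from scipy.stats import t as t_dist

        rng = np.random.default_rng(0)
        n, n_rep = 30, 500
        tcrit = t_dist.ppf(0.975, n - 2)
        hits_i = hits_s = 0
        for _ in range(n_rep):
            x = rng.uniform(-40, 20, n)
            y = -12.21 + 0.16 * x + rng.normal(0, 10, n)
            reg = linear_regression(x, y)
            hits_i += abs(reg.intercept + 12.21) <= tcrit * reg.intercept_se
            hits_s += abs(reg.slope - 0.16) <= tcrit * reg.slope_se
        assert 0.92 <= hits_i / n_rep <= 0.98
        assert 0.92 <= hits_s / n_rep <= 0.98


class TestDetectionRate:
    @pytest.mark.parametrize(
        "n_type,n_mal,percent", [(20, 71, 28), (0, 71, 0), (71, 71, 100)]
    )
    def test_rounded_percent(self, n_type, n_mal, percent):
        assert detection_rate(n_type, n_mal).percent == percent

    def test_preconditions(self):
        with pytest.raises(ValueError):
            detection_rate(5, 0)
        with pytest.raises(ValueError):
            detection_rate(10, 5)
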