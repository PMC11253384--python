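"""ROC construction, Youden cutoff, exact CIs, bootstrap, DeLong test."""

import itertools

import numpy as np
import pytest
from scipy import stats

from diaphmon.errors import DegenerateInputError, InvalidParameterError
from diaphmon.prediction import (
    bootstrap_roc,
    clopper_pearson,
    delong_test,
    diagnostic_metrics,
    roc_curve,
    youden_cutoff,
)


def pair_count_auc(scores, labels, direction="higher"):
    """Exhaustive concordant-pair counting (ties count one half)."""
    s = np.asarray(scores, float)
    if direction == "lower":
        s = -s
    pos = s[np.asarray(labels, bool)]
    neg = s[~np.asarray(labels, bool)]
    total = 0.0
    for p, q in itertools.product(pos, neg):
        total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestROC:
    def test_perfect_separation(self):
        r = roc_curve([1, 2, 3, 10, 11, 12], [1, 1, 1, 0, 0, 0], "lower")
        assert r.auc == 1.0

    def test_all_identical_scores(self):
        r = roc_curve([5.0] * 6, [1, 0, 1, 0, 1, 0], "lower")
        assert r.auc == pytest.approx(0.5)

    def test_ties_match_pair_counting(self):
        scores = [1.0, 2.0, 2.0, 3.0, 3.0, 4.0, 5.0, 6.0]
        labels = [1, 1, 0, 1, 0, 0, 1, 0]
        for direction in ("lower", "higher"):
            r = roc_curve(scores, labels, direction)
            assert r.auc == pytest.approx(pair_count_auc(scores, labels, direction))

    def test_auc_equals_mann_whitney_on_random_instances(self, rng):
        for _ in range(50):
            n = int(rng.integers(6, 40))
            scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
            labels = rng.integers(0, 2, n)
            if labels.all() or not labels.any():
                continue
            r = roc_curve(scores, labels, "higher")
            u = stats.mannwhitneyu(scores[labels == 1], scores[labels == 0]).statistic
            assert r.auc == pytest.approx(u / ((labels == 1).sum() * (labels == 0).sum()))

    def test_direction_flip_antisymmetry(self, rng):
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, 30)
        a = roc_curve(scores, labels, "lower").auc
        b = roc_curve(scores, labels, "higher").auc
        assert a + b == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateInputError):
            roc_curve([1.0, 2.0], [1, 1], "lower")


class TestYouden:
    def test_perfect_separation_midpoint(self):
        r = roc_curve([1, 2, 3, 10, 11, 12], [1, 1, 1, 0, 0, 0], "lower")
        cut = youden_cutoff(r)
        assert 3 < cut < 10
        d = diagnostic_metrics([1, 2, 3, 10, 11, 12], [1, 1, 1, 0, 0, 0], cut, "lower")
        assert d.youden_j == pytest.approx(1.0)

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(30):
            scores = rng.normal(size=24)
            labels = rng.integers(0, 2, 24)
            if labels.all() or not labels.any():
                continue
            r = roc_curve(scores, labels, "lower")
            cut = youden_cutoff(r)
            best_j = max(
                diagnostic_metrics(scores, labels, c, "lower").youden_j
                for c in np.concatenate([scores - 1e-9, scores + 1e-9])
            )
            got = diagnostic_metrics(scores, labels, cut, "lower").youden_j
            assert got == pytest.approx(best_j, abs=1e-12)

    def test_uninformative_scores_give_zero_j(self):
        r = roc_curve([5.0] * 8, [1, 0] * 4, "lower")
        cut = youden_cutoff(r)
        j = r.sens + r.spec - 1
        assert np.max(j) == pytest.approx(0.0)
        assert cut in (-np.inf, np.inf, 5.0) or np.isfinite(cut)


class TestDiagnostics:
    def test_counts_and_proportions(self):
        # 24 positives (20 called), 22 negatives (15 correctly excluded)
        scores = np.concatenate([np.zeros(20), np.ones(4), np.ones(15), np.zeros(7)])
        labels = np.concatenate([np.ones(24), np.zeros(22)])
        d = diagnostic_metrics(scores, labels, 0.5, "lower")
        assert (d.tp, d.fn, d.tn, d.fp) == (20, 4, 15, 7)
        assert d.sens.value == pytest.approx(0.833, abs=1e-3)
        assert d.spec.value == pytest.approx(0.682, abs=1e-3)
        assert d.ppv.value == pytest.approx(20 / 27, abs=1e-9)
        assert d.npv.value == pytest.approx(15 / 19, abs=1e-9)

    def test_clopper_pearson_zero_of_ten(self):
        ci = clopper_pearson(0, 10)
        assert ci.ci_low == 0.0
        assert ci.ci_high == pytest.approx(0.3085, abs=1e-4)

    def test_all_correct(self):
        d = diagnostic_metrics([0, 0, 1, 1], [1, 1, 0, 0], 0.5, "lower")
        assert d.sens.value == d.spec.value == d.ppv.value == d.npv.value == 1.0

    def test_zero_denominator_marker(self):
        ci = clopper_pearson(0, 0)
        assert np.isnan(ci.value) and (ci.ci_low, ci.ci_high) == (0.0, 1.0)

    def test_infinite_cutoff_rejected(self):
        with pytest.raises(InvalidParameterError):
            diagnostic_metrics([1.0, 2.0], [1, 0], np.inf, "lower")

    def test_clopper_pearson_exhaustive_coverage_small_n(self):
        """Exact intervals cover every true p at >= 95% for n <= 12."""
        p_grid = np.linspace(0.01, 0.99, 99)
        for n in range(1, 13):
            cis = [clopper_pearson(k, n) for k in range(n + 1)]
            for p in p_grid:
                cover = sum(
                    stats.binom.pmf(k, n, p)
                    for k, ci in enumerate(cis)
                    if ci.ci_low <= p <= ci.ci_high
                )
                assert cover >= 0.95 - 1e-9, (n, p)


class TestBootstrap:
    def test_deterministic_given_seed(self, rng):
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, 40)
        if labels.all() or not labels.any():
            labels[0] = 1 - labels[0]
        a = bootstrap_roc(scores, labels, B=50, seed=7)
        b = bootstrap_roc(scores, labels, B=50, seed=7)
        assert (a.auc_ci_low, a.auc_ci_high) == (b.auc_ci_low, b.auc_ci_high)
        np.testing.assert_array_equal(a.cutoff_distribution, b.cutoff_distribution)

    def test_well_separated_single_replicate(self):
        scores = np.concatenate([np.zeros(30), np.ones(30)])
        labels = np.concatenate([np.ones(30), np.zeros(30)])
        b = bootstrap_roc(scores, labels, B=1, seed=0)
        assert b.auc_distribution[0] == 1.0

    def test_percentile_ci_covers_known_auc(self, rng):
        """Gaussian scores with effect size d give AUC = Phi(d/sqrt(2))."""
        d = 0.954  # AUC 0.75
        hits = 0
        n_outer = 40
        for rep in range(n_outer):
            pos = rng.normal(d, 1, 200)
            neg = rng.normal(0, 1, 200)
            scores = np.concatenate([pos, neg])
            labels = np.concatenate([np.ones(200), np.zeros(200)])
            b = bootstrap_roc(scores, labels, B=200, seed=rep, direction="higher")
            hits += b.auc_ci_low <= stats.norm.cdf(d / np.sqrt(2)) <= b.auc_ci_high
        assert hits / n_outer >= 0.9


def naive_delong(scores_a, scores_b, labels):
    """Structural components by explicit loops."""
    labels = np.asarray(labels, bool)

    def comps(s):
        pos = s[labels]
        neg = s[~labels]
        v10 = [np.mean([1.0 if p > q else 0.5 if p == q else 0.0 for q in neg])
               for p in pos]
        v01 = [np.mean([1.0 if p > q else 0.5 if p == q else 0.0 for p in pos])
               for q in neg]
        return np.array(v10), np.array(v01)

    v10a, v01a = comps(np.asarray(scores_a, float))
    v10b, v01b = comps(np.asarray(scores_b, float))
    m, n = len(v10a), len(v01a)
    var = (
        np.var(v10a, ddof=1) + np.var(v10b, ddof=1)
        - 2 * np.cov(v10a, v10b, ddof=1)[0, 1]
    ) / m + (
        np.var(v01a, ddof=1) + np.var(v01b, ddof=1)
        - 2 * np.cov(v01a, v01b, ddof=1)[0, 1]
    ) / n
    return np.mean(v10a), np.mean(v10b), var


class TestDeLong:
    def test_identical_scores(self, rng):
        s = rng.normal(size=20)
        labels = np.array([1, 0] * 10)
        r = delong_test(s, s, labels)
        assert r.z == 0.0 and r.p == 1.0

    def test_monotone_transform_equal_auc(self, rng):
        s = rng.normal(size=20)
        labels = np.array([1, 0] * 10)
        r = delong_test(s, np.exp(s), labels)
        assert r.auc_a == r.auc_b
        assert r.z == 0.0

    def test_variance_matches_explicit_enumeration(self, rng):
        labels = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        a = rng.normal(size=12)
        b = 0.5 * a + rng.normal(size=12)
        r = delong_test(a, b, labels)
        auc_a, auc_b, var = naive_delong(a, b, labels)
        assert r.auc_a == pytest.approx(auc_a)
        assert r.auc_b == pytest.approx(auc_b)
        expected_z = (auc_a - auc_b) / np.sqrt(var)
        assert r.z == pytest.approx(expected_z, rel=1e-9)

    def test_direction_lower_flips_scores(self, rng):
        labels = np.array([1, 0] * 15)
        a = rng.normal(size=30)
        b = rng.normal(size=30)
        r1 = delong_test(a, b, labels, direction="lower")
        r2 = delong_test(-a, -b, labels, direction="higher")
        assert r1.auc_a == pytest.approx(r2.auc_a)
        assert r1.p == pytest.approx(r2.p)
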