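"""Statistical procedures: worked examples, oracles, determinism."""

import numpy as np
import pytest
import scipy.stats

from gutdrift.distances import DistanceMatrix
from gutdrift.errors import GutdriftError
from gutdrift.stats import (
    ContingencyTable2x2,
    adjusted_group_compare,
    chi_square_2x2,
    fisher_exact,
    levene,
    permanova,
    spearman,
    steel_test,
)


def enumeration_fisher_p(a, b, c, d):
    """Exact-integer hypergeometric enumeration of the two-sided p.

    With margins fixed, every admissible table's probability has the
    common denominator C(N, c1); comparing integer numerators makes the
    "no more likely than observed" rule tie-exact.
    """
    from math import comb

    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    nums = [comb(r1, k) * comb(r2, c1 - k) for k in range(lo, hi + 1)]
    obs = nums[a - lo]
    return sum(v for v in nums if v <= obs) / comb(n, c1)


class TestFisherExact:
    def test_published_intake_table(self):
        res = fisher_exact(ContingencyTable2x2(18, 142, 1, 57))
        assert res.p_value == pytest.approx(0.029, abs=0.001)

    def test_balanced_table_p_one(self):
        assert fisher_exact(ContingencyTable2x2(1, 1, 1, 1)).p_value == 1.0

    def test_perfectly_separated_table(self):
        res = fisher_exact(ContingencyTable2x2(5, 0, 0, 5))
        assert res.p_value == pytest.approx(2 / 252, rel=1e-12)

    def test_matches_enumeration_on_random_tables(self, rng):
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 15, 4))
            if a + b == 0 or c + d == 0 or (a + c == 0 and b + d == 0):
                continue
            res = fisher_exact(ContingencyTable2x2(a, b, c, d))
            assert res.p_value == pytest.approx(
                enumeration_fisher_p(a, b, c, d), abs=1e-12
            )

    def test_negative_counts_rejected(self):
        with pytest.raises(GutdriftError, match="nonnegative"):
            ContingencyTable2x2(-1, 2, 3, 4)

    def test_from_labels_cross_tabulates(self):
        tab = ContingencyTable2x2.from_labels(
            ["g1", "g1", "g1", "g2", "g2"], [True, True, False, False, False]
        )
        assert (tab.a, tab.b, tab.c, tab.d) == (2, 1, 0, 2)


class TestChiSquare:
    def test_uniform_table_statistic_zero(self):
        res = chi_square_2x2(ContingencyTable2x2(50, 50, 50, 50))
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_published_alcohol_table_significant(self):
        res = chi_square_2x2(ContingencyTable2x2(73, 87, 13, 45))
        assert res.p_value < 0.05

    def test_matches_cellwise_oracle(self, rng):
        for _ in range(100):
            arr = rng.integers(1, 40, size=(2, 2)).astype(float)
            tab = ContingencyTable2x2(*arr.ravel().astype(int))
            expected_rows = arr.sum(axis=1, keepdims=True)
            expected_cols = arr.sum(axis=0, keepdims=True)
            expected = expected_rows @ expected_cols / arr.sum()
            x2 = float(((arr - expected) ** 2 / expected).sum())
            assert chi_square_2x2(tab).statistic == pytest.approx(x2, rel=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(GutdriftError, match="margin"):
            chi_square_2x2(ContingencyTable2x2(0, 0, 5, 5))


class TestSteel:
    def test_constant_data_p_one(self):
        res = steel_test([1.0] * 5, [[1.0] * 5, [1.0] * 5],
                         n_permutations=200, seed=0)
        assert all(r.p_value == 1.0 for r in res)

    def test_strong_shift_detected(self, rng):
        control = rng.normal(0, 1, 50)
        treatments = [rng.normal(1.0, 1, 50), rng.normal(1.2, 1, 50)]
        res = steel_test(control, treatments, n_permutations=2000, seed=0)
        assert all(r.p_value < 0.005 for r in res)

    def test_deterministic_given_seed(self, rng):
        control = rng.normal(0, 1, 12)
        treat = [rng.normal(0.3, 1, 12)]
        r1 = steel_test(control, treat, n_permutations=500, seed=7)
        r2 = steel_test(control, treat, n_permutations=500, seed=7)
        assert r1[0].p_value == r2[0].p_value

    def test_single_treatment_close_to_rank_sum_permutation(self, rng):
        """With one treatment the max-statistic test is a two-sided
        Wilcoxon rank-sum permutation test (up to Monte-Carlo error)."""
        control = rng.normal(0, 1, 18)
        treat = rng.normal(0.7, 1, 18)
        ours = steel_test(control, [treat], n_permutations=4000, seed=3)[0]

        def stat(x, y):
            return scipy.stats.mannwhitneyu(x, y).statistic

        ref = scipy.stats.permutation_test(
            (control, treat), stat, permutation_type="independent",
            alternative="two-sided", n_resamples=4000,
            rng=np.random.default_rng(5),
        )
        assert ours.p_value == pytest.approx(ref.pvalue, abs=0.03)

    def test_too_small_groups_rejected(self):
        with pytest.raises(GutdriftError, match=">= 2"):
            steel_test([1.0], [[1.0, 2.0]], n_permutations=10, seed=0)


class TestAdjustedGroupCompare:
    def test_reduces_to_t_test_without_covariates(self, rng):
        y = rng.normal(0, 1, 40)
        group = ["x"] * 20 + ["y"] * 20
        res = adjusted_group_compare(y, group)
        ref = scipy.stats.ttest_ind(y[20:], y[:20])
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-10)

    def test_recovers_adjusted_effect(self, rng):
        n = 200
        age = rng.normal(75, 6, n)
        group = np.repeat(["a", "b"], n // 2)
        y = 0.01 * age + 1.0 * (group == "b") + rng.normal(0, 1, n)
        res = adjusted_group_compare(y, group, {"age": age})
        assert res.p_value < 1e-4

    def test_duplicate_covariate_names_offender(self, rng):
        y = rng.normal(0, 1, 30)
        group = ["a", "b"] * 15
        age = rng.normal(70, 5, 30)
        with pytest.raises(GutdriftError, match="age_copy"):
            adjusted_group_compare(y, group, {"age": age, "age_copy": age})

    def test_missing_covariates_dropped_listwise(self, rng):
        y = rng.normal(0, 1, 40)
        group = ["a", "b"] * 20
        age = rng.normal(70, 5, 40)
        age[:4] = np.nan
        res = adjusted_group_compare(y, group, {"age": age})
        y2, g2, a2 = y[4:], group[4:], age[4:]
        ref = adjusted_group_compare(y2, g2, {"age": a2})
        assert res.p_value == pytest.approx(ref.p_value, abs=1e-12)


class TestLevene:
    def test_unequal_spread_detected(self, rng):
        g1 = rng.normal(0, 1, 100)
        g2 = rng.normal(0, 3, 100)
        assert levene([g1, g2]).p_value < 0.01

    def test_matches_anova_on_absolute_deviations(self, rng):
        g1 = rng.normal(0, 1, 30)
        g2 = rng.normal(0, 2, 25)
        res = levene([g1, g2])
        d1 = np.abs(g1 - g1.mean())
        d2 = np.abs(g2 - g2.mean())
        ref = scipy.stats.f_oneway(d1, d2)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_all_constant_groups_rejected(self):
        with pytest.raises(GutdriftError, match="zero dispersion"):
            levene([[1.0, 1.0, 1.0], [2.0, 2.0]])

    def test_median_center_variant(self, rng):
        g1 = rng.normal(0, 1, 50)
        g2 = rng.normal(0, 2, 50)
        res = levene([g1, g2], center="median")
        assert res.method == "levene_median"
        assert res.p_value < 0.05


class TestSpearman:
    def test_monotone_relationships(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert spearman(x, [2.0, 4.0, 9.0, 16.0, 30.0]).statistic == (
            pytest.approx(1.0, abs=1e-12))
        assert spearman(x, [5.0, 4.0, 3.0, 2.0, 1.0]).statistic == (
            pytest.approx(-1.0, abs=1e-12))

    def test_tied_data_matches_rank_then_pearson(self, rng):
        x = rng.integers(0, 5, 40).astype(float)
        y = x + rng.integers(0, 3, 40)
        res = spearman(x, y)
        rx = scipy.stats.rankdata(x)
        ry = scipy.stats.rankdata(y)
        assert res.statistic == pytest.approx(np.corrcoef(rx, ry)[0, 1], abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(GutdriftError, match="constant"):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_exact_mode_agrees_with_t_on_clear_signal(self, rng):
        x = np.arange(7, dtype=float)
        y = x + rng.normal(0, 0.5, 7)
        approx = spearman(x, y)
        exact = spearman(x, y, exact=True)
        assert exact.method == "spearman_exact"
        assert exact.statistic == approx.statistic
        assert exact.p_value == pytest.approx(approx.p_value, abs=0.05)


def euclidean_jsd_like_matrix(rng, n, spread=0.0, groups=None):
    """Small JSD matrix from random compositions; optional group shift."""
    from gutdrift.distances import jsd

    comps = rng.dirichlet(np.ones(5), size=n)
    if spread and groups is not None:
        shifted = rng.dirichlet(np.ones(5) * 0.2, size=n)
        for i, g in enumerate(groups):
            if g == "b":
                comps[i] = (1 - spread) * comps[i] + spread * shifted[i]
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            vals[i, j] = vals[j, i] = jsd(comps[i], comps[j])
    labels = tuple(f"s{i}" for i in range(n))
    return DistanceMatrix(labels, vals, "jsd")


class TestPermanova:
    def test_deterministic_and_p_floor(self, rng):
        # two tight clusters far apart: no permutation beats the observed F
        # (groups of 12 so a permutation recreating the split is ~1e-7)
        n = 24
        within = rng.uniform(0.0, 0.05, (n, n))
        vals = (within + within.T) / 2
        vals[:12, 12:] = 0.8
        vals[12:, :12] = 0.8
        np.fill_diagonal(vals, 0.0)
        m = DistanceMatrix(tuple(f"s{i}" for i in range(n)), vals, "jsd")
        labels = ["a"] * 12 + ["b"] * 12
        res = permanova(m, labels, n_permutations=499, seed=11)
        assert res.p_value == pytest.approx(1 / 500)
        again = permanova(m, labels, n_permutations=499, seed=11)
        assert res.p_value == again.p_value and res.statistic == again.statistic

    def test_relabeling_invariance(self, rng):
        m = euclidean_jsd_like_matrix(rng, 12)
        labels = ["a"] * 6 + ["b"] * 6
        f1 = permanova(m, labels, n_permutations=9, seed=0).statistic
        perm = rng.permutation(12)
        m2 = DistanceMatrix(
            tuple(m.labels[i] for i in perm), m.values[np.ix_(perm, perm)], "jsd"
        )
        f2 = permanova(m2, [labels[i] for i in perm],
                       n_permutations=9, seed=0).statistic
        assert f1 == pytest.approx(f2, rel=1e-12)

    def test_matches_scikit_bio(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import permanova as skbio_permanova

        m = euclidean_jsd_like_matrix(rng, 14)
        labels = ["a"] * 7 + ["b"] * 7
        ours = permanova(m, labels, n_permutations=99, seed=0)
        dm = skbio.DistanceMatrix(m.values, ids=list(m.labels))
        ref = skbio_permanova(dm, grouping=list(labels), permutations=99)
        assert ours.statistic == pytest.approx(ref["test statistic"], rel=1e-10)

    def test_single_group_rejected(self, rng):
        m = euclidean_jsd_like_matrix(rng, 6)
        with pytest.raises(GutdriftError, match=">= 2 groups"):
            permanova(m, ["a"] * 6, n_permutations=9, seed=0)

    def test_label_length_mismatch_rejected(self, rng):
        m = euclidean_jsd_like_matrix(rng, 6)
        with pytest.raises(GutdriftError, match="labels"):
            permanova(m, ["a", "b"], n_permutations=9, seed=0)
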