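"""Count/proportion statistics: χ², Fisher, z, rank-sum, bootstrap, r-to-z."""

import math
from itertools import combinations

import numpy as np
import pytest
from scipy import stats as sp_stats

from caldrift import (
    CategoryProportions,
    ContingencyTable2x2,
    bootstrap_proportion_test,
    chi2_2x2,
    fisher_exact_2x2,
    fisher_r_compare,
    rank_sum_test,
    two_proportion_z,
)


class TestChi2:
    @pytest.mark.parametrize(
        "table,expected",
        [((66, 477, 114, 404), 18.27), ((34, 207, 59, 197), 6.52)],
    )
    def test_published_statistics(self, table, expected):
        stat, p = chi2_2x2(ContingencyTable2x2(*table))
        assert stat == pytest.approx(expected, abs=0.005)
        assert 0 < p < 0.05

    def test_equal_proportions_zero(self):
        stat, p = chi2_2x2(ContingencyTable2x2(10, 90, 10, 90))
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="[Ff]isher"):
            chi2_2x2(ContingencyTable2x2(0, 5, 0, 7))

    def test_equals_squared_z_statistic(self, rng):
        # algebraic identity between Pearson chi^2 and the pooled z test
        for _ in range(30):
            a, b, c, d = rng.integers(1, 200, 4)
            stat, _ = chi2_2x2(ContingencyTable2x2(a, b, c, d))
            z, _, _ = two_proportion_z(a, a + b, c, c + d)
            assert stat == pytest.approx(z**2, rel=1e-9)


class TestFisherExact:
    def test_published_odds_ratios(self):
        odds, p, ci = fisher_exact_2x2(ContingencyTable2x2(66, 477, 114, 404))
        assert odds == pytest.approx(0.4903, abs=0.0005)
        assert p < 0.001
        assert ci[0] < odds < ci[1]
        odds2, _, _ = fisher_exact_2x2(ContingencyTable2x2(34, 207, 59, 197))
        assert odds2 == pytest.approx(0.55, abs=0.005)

    def test_symmetric_table(self):
        odds, p, _ = fisher_exact_2x2(ContingencyTable2x2(5, 5, 5, 5))
        assert odds == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_zero_cell_odds_symbolic(self):
        odds, _, _ = fisher_exact_2x2(ContingencyTable2x2(5, 0, 3, 7))
        assert math.isinf(odds)

    def test_nonint_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(1.5, 2, 3, 4)


class TestTwoProportionZ:
    def test_published_value(self):
        z, p1, _ = two_proportion_z(36, 241, 54, 256)
        assert z == pytest.approx(-1.7811, abs=0.00005)
        assert p1 == pytest.approx(0.037, abs=0.001)

    def test_equal_proportions_zero(self):
        z, _, _ = two_proportion_z(10, 100, 10, 100)
        assert z == pytest.approx(0.0)

    def test_extreme_split_hand_formula(self):
        # p1=0, p2=1, pooled=0.5: z = -1 / sqrt(0.25 * 0.2) = -sqrt(20)
        z, _, _ = two_proportion_z(0, 10, 10, 10)
        assert z == pytest.approx(-math.sqrt(20))

    def test_degenerate_pool_rejected(self):
        with pytest.raises(ValueError):
            two_proportion_z(0, 10, 0, 10)


def enumeration_p(x, y):
    """Independent brute-force two-sided rank-sum p over all assignments."""
    pooled = np.concatenate([x, y])
    ranks = sp_stats.rankdata(pooled)
    n1 = len(x)
    w_obs = ranks[:n1].sum()
    sums = [sum(ranks[list(i)]) for i in combinations(range(len(pooled)), n1)]
    sums = np.array(sums)
    lo = np.mean(sums <= w_obs + 1e-9)
    hi = np.mean(sums >= w_obs - 1e-9)
    return min(1.0, 2 * min(lo, hi))


class TestRankSum:
    def test_complete_separation_rank_sums(self):
        low = np.arange(8.0)
        high = np.arange(8.0) + 100
        w_low, p = rank_sum_test(low, high)
        assert w_low == 36.0
        w_high, _ = rank_sum_test(high, low)
        assert w_high == 100.0
        assert p == pytest.approx(2 / 12870, rel=1e-9)

    @pytest.mark.parametrize("n1,n2", [(3, 3), (4, 6), (5, 5), (8, 8)])
    def test_exact_p_matches_scipy_exact(self, n1, n2, rng):
        for _ in range(5):
            x = rng.normal(0, 1, n1)
            y = rng.normal(0.5, 1, n2)
            _, p = rank_sum_test(x, y)
            u_p = sp_stats.mannwhitneyu(x, y, method="exact").pvalue
            assert p == pytest.approx(u_p, rel=1e-9)

    def test_ties_handled_with_midranks(self, rng):
        x = np.array([1.0, 2.0, 2.0, 3.0])
        y = np.array([2.0, 4.0, 4.0, 5.0])
        w, p = rank_sum_test(x, y)
        assert w == sp_stats.rankdata(np.concatenate([x, y]))[:4].sum()
        assert p == pytest.approx(enumeration_p(x, y), rel=1e-9)

    def test_large_samples_use_normal_approximation(self, rng):
        x = rng.normal(0, 1, 40)
        y = rng.normal(0.8, 1, 40)
        _, p = rank_sum_test(x, y)
        ref = sp_stats.mannwhitneyu(x, y, method="asymptotic", use_continuity=False).pvalue
        assert p == pytest.approx(ref, rel=1e-6)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


class TestBootstrapProportions:
    def single(self, k_ref, n_ref, k_test, n_test):
        return CategoryProportions(("c",), (n_ref,), (k_ref,), (n_test,), (k_test,))

    def test_matched_proportions_near_half(self):
        p = bootstrap_proportion_test(self.single(500, 1000, 250, 500), seed=1)
        assert p == pytest.approx(0.5, abs=0.02)

    def test_reference_probability_zero(self):
        assert bootstrap_proportion_test(self.single(0, 100, 5, 100), seed=1) == 0.0

    def test_reference_probability_one(self):
        assert bootstrap_proportion_test(self.single(100, 100, 30, 100), seed=1) == 1.0

    def test_monotone_in_observed_count(self):
        ps = [
            bootstrap_proportion_test(self.single(50, 100, k, 100), seed=2)
            for k in (30, 45, 60, 75)
        ]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_multi_category_joint_rule_stricter_than_any_single(self):
        cats = CategoryProportions(
            ("a", "b"), (100, 100), (50, 50), (100, 100), (55, 55)
        )
        p_joint = bootstrap_proportion_test(cats, seed=3)
        p_single = bootstrap_proportion_test(self.single(50, 100, 55, 100), seed=3)
        assert p_joint <= p_single

    def test_seeded_reproducibility(self):
        cats = self.single(40, 100, 42, 90)
        assert bootstrap_proportion_test(cats, seed=9) == bootstrap_proportion_test(
            cats, seed=9
        )


class TestFisherRCompare:
    def test_equal_correlations(self):
        z, p = fisher_r_compare(0.3, 50, 0.3, 80)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_antisymmetry(self):
        z1, p1 = fisher_r_compare(0.5, 100, 0.1, 60)
        z2, p2 = fisher_r_compare(0.1, 60, 0.5, 100)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_formula_value(self):
        z, _ = fisher_r_compare(0.5, 100, 0.0, 100)
        expected = math.atanh(0.5) / math.sqrt(2 / 97)
        assert z == pytest.approx(expected)

    def test_matches_permutation_oracle_on_simulated_data(self, rng):
        # two independent samples with different true correlation: the
        # analytic p should broadly agree with a label-permutation null
        n = 150
        cov1 = [[1, 0.5], [0.5, 1]]
        xy1 = rng.multivariate_normal([0, 0], cov1, n)
        xy2 = rng.multivariate_normal([0, 0], np.eye(2), n)
        r1 = np.corrcoef(xy1.T)[0, 1]
        r2 = np.corrcoef(xy2.T)[0, 1]
        z_obs, p_analytic = fisher_r_compare(r1, n, r2, n)
        pooled = np.vstack([xy1, xy2])
        null = []
        for _ in range(400):
            idx = rng.permutation(2 * n)
            a, b = pooled[idx[:n]], pooled[idx[n:]]
            ra = np.corrcoef(a.T)[0, 1]
            rb = np.corrcoef(b.T)[0, 1]
            null.append(math.atanh(ra) - math.atanh(rb))
        p_perm = float(np.mean(np.abs(null) >= abs(math.atanh(r1) - math.atanh(r2))))
        assert p_analytic == pytest.approx(p_perm, abs=0.05)

    def test_degenerate_r_rejected(self):
        with pytest.raises(ValueError):
            fisher_r_compare(1.0, 10, 0.5, 10)
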