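import math
from fractions import Fraction
from itertools import combinations

import numpy as np
import pytest

from mlpagcr.stats import (
    RateEstimate,
    adjust_bonferroni,
    arm_duplication_rates,
    estimate_gcr_rate,
    exact_binomial_overrep,
    expected_arm_rates,
    fisher_exact_2x2,
    fold_change,
    hypergeom_overlap,
    mc_multinomial_test,
    paired_exact_test,
    rank_sum_test,
    round_fold,
)


class TestRateEstimate:
    def test_constant_cultures(self):
        est = estimate_gcr_rate([3e-8] * 7)
        assert est.median == est.ci_low == est.ci_high == 3e-8

    def test_five_cultures_full_range_interval(self):
        # n = 5: the widest pair (x1, x5) has coverage 1 - 2*(1/2)^5
        est = estimate_gcr_rate([1e-8, 2e-8, 3e-8, 4e-8, 5e-8])
        assert est.median == pytest.approx(3e-8)
        assert (est.ci_low, est.ci_high) == (1e-8, 5e-8)
        assert est.coverage == pytest.approx(0.9375)

    def test_even_n_median_is_mid_pair(self):
        assert estimate_gcr_rate([1.0, 2.0, 3.0, 4.0]).median == pytest.approx(2.5)

    def test_interval_narrows_with_n(self):
        x = list(range(1, 50))
        est = estimate_gcr_rate(x)
        assert est.ci_low > min(x) and est.ci_high < max(x)
        assert est.coverage >= 0.95

    def test_coverage_from_order_statistics_oracle(self):
        # exhaustive check of the order-statistic coverage for n = 49:
        # the chosen pair must be the narrowest with >= 95% binomial mass
        n = 49
        est = estimate_gcr_rate(list(range(n)))
        i = list(range(n)).index(est.ci_low) + 1

        def cov(j):
            total = Fraction(0)
            for k in range(j, n - j + 1):
                total += Fraction(math.comb(n, k), 2**n)
            return float(total)

        assert cov(i) >= 0.95
        assert cov(i + 1) < 0.95

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            estimate_gcr_rate([])


class TestFoldChange:
    def make(self, median):
        return RateEstimate(median, median, median, 10, 0.95)

    def test_equal_rates(self):
        r = self.make(8.4e-8)
        assert fold_change(r, r) == 1

    @pytest.mark.parametrize(
        "test,ref,expected",
        [
            (1.7e-6, 8.4e-8, 20),  # 20.24 -> 20
            (1.0e-5, 8.4e-8, 120),  # 119.0 -> 120
        ],
    )
    def test_published_fold_values(self, test, ref, expected):
        assert fold_change(self.make(test), self.make(ref)) == expected

    def test_mismatch_repair_strain_fold_near_three(self):
        fold = fold_change(self.make(2.2e-7), self.make(8.4e-8))
        assert abs(fold - 3) <= 0.5

    def test_round_fold_two_significant_figures(self):
        assert round_fold(0.157) == pytest.approx(0.16)
        assert round_fold(7.02) == 7
        assert round_fold(26.2) == 26

    def test_zero_reference_errors(self):
        with pytest.raises(ValueError):
            fold_change(self.make(1e-8), self.make(0.0))


class TestArmRates:
    def test_partition_of_total_rate(self):
        t = arm_duplication_rates(2.4e-7, {"A": 2, "B": 1}, 3, ["A", "B"])
        assert t.rates["A"] == pytest.approx(1.6e-7)
        assert t.rates["B"] == pytest.approx(0.8e-7)

    def test_wildtype_hotspot_arm_rate(self):
        t = arm_duplication_rates(8.4e-8, {"chrIII-R": 28}, 112, ["chrIII-R"])
        assert t.rates["chrIII-R"] == pytest.approx(2.1e-8)

    def test_zero_counts_annotated_as_upper_limits(self):
        t = arm_duplication_rates(1e-7, {}, 10, ["A", "B"], n_duplications=5)
        assert (t.rates == 0).all()
        assert t.table["upper_limit"].all()
        assert t.upper_limit_rate == pytest.approx(2e-8)


class TestExpectedArmRates:
    def test_identity_when_test_equals_control(self):
        t = arm_duplication_rates(1e-7, {"A": 3, "B": 2, "C": 0}, 5, list("ABC"))
        out = expected_arm_rates(t, t)
        assert np.allclose(out["obs_exp_ratio"], 1.0)
        assert np.allclose(out["log2_ratio"], 0.0)

    def test_uniform_scaling_gives_unit_ratios(self):
        c = arm_duplication_rates(1e-7, {"A": 3, "B": 2}, 5, ["A", "B"])
        t = arm_duplication_rates(3e-7, {"A": 3, "B": 2}, 5, ["A", "B"])
        out = expected_arm_rates(c, t)
        assert np.allclose(out["obs_exp_ratio"], 1.0)
        assert np.allclose(out["expected_rate"], 3 * c.rates)

    def test_hand_computed_example(self):
        c = arm_duplication_rates(8e-8, {"A": 1, "B": 1}, 2, ["A", "B"])
        assert np.allclose(c.rates, 4e-8)
        t = arm_duplication_rates(2.4e-7, {"A": 2, "B": 1}, 3, ["A", "B"])
        out = expected_arm_rates(c, t)
        assert out.loc["A", "expected_rate"] == pytest.approx(1.2e-7)
        assert out.loc["A", "obs_exp_ratio"] == pytest.approx(4.0 / 3.0)
        assert out.loc["B", "obs_exp_ratio"] == pytest.approx(2.0 / 3.0)
        assert out.loc["A", "log2_ratio"] == pytest.approx(0.415, abs=1e-3)
        assert out.loc["B", "log2_ratio"] == pytest.approx(-0.585, abs=1e-3)

    def test_zero_control_uses_scaled_upper_limit(self):
        c = arm_duplication_rates(1e-7, {"A": 4, "B": 0}, 4, ["A", "B"])
        t = arm_duplication_rates(2e-7, {"A": 4, "B": 2}, 4, ["A", "B"])
        out = expected_arm_rates(c, t)
        scale = t.rates.sum() / c.rates.sum()
        assert out.loc["B", "expected_rate"] == pytest.approx(
            c.upper_limit_rate * scale
        )

    def test_significance_flag_against_fold_interval(self):
        c = arm_duplication_rates(1e-7, {"A": 5, "B": 5}, 10, ["A", "B"])
        t = arm_duplication_rates(3e-7, {"A": 9, "B": 1}, 10, ["A", "B"])
        out = expected_arm_rates(c, t, test_rate_ci=(2.5e-7, 3.5e-7))
        # arm A is enriched beyond the bulk-fold CI, arm B depleted below it
        assert out.loc["A", "significant"]
        assert out.loc["B", "significant"]


class TestMultinomialMC:
    def test_exact_expectation_gives_p_one(self):
        res = mc_multinomial_test([5, 5], [0.5, 0.5], replicates=500, seed=1)
        assert res.statistic == 0.0
        assert res.pvalue == 1.0

    def test_extreme_two_category_table_matches_enumeration(self):
        # exhaustive binomial oracle: P(chi2 >= observed) for N=10, p=1/2
        # with observed (10, 0); only tables (10,0) and (0,10) are as
        # extreme, so the exact tail is 2 * (1/2)^10
        exact = float(2 * Fraction(1, 2**10))
        res = mc_multinomial_test([10, 0], [0.5, 0.5], replicates=2000, seed=3)
        se = math.sqrt(exact * (1 - exact) / 2000)
        assert abs(res.pvalue - exact) < 3 * se + 1 / 2001

    def test_empirical_p_floor_is_one_over_r_plus_one(self):
        res = mc_multinomial_test([50, 0, 0], [1 / 3] * 3, replicates=2000, seed=4)
        assert res.pvalue == pytest.approx(1 / 2001)

    def test_dimension_mismatch_errors(self):
        with pytest.raises(ValueError):
            mc_multinomial_test([1, 2, 3], [0.5, 0.5], 10, 0)


class TestExactBinomial:
    def brute_force_tail(self, k, n, p):
        # independent pmf summation from binomial coefficients
        total = 0.0
        for j in range(k, n + 1):
            total += math.comb(n, j) * p**j * (1 - p) ** (n - j)
        return total

    def test_zero_successes_gives_one(self):
        assert exact_binomial_overrep(0, 10, 0.1).pvalue == 1.0

    @pytest.mark.parametrize(
        "k,n,p", [(5, 10, 0.1), (3, 3, 0.5), (7, 20, 0.25), (1, 30, 0.01)]
    )
    def test_matches_brute_force(self, k, n, p):
        res = exact_binomial_overrep(k, n, p)
        assert res.pvalue == pytest.approx(self.brute_force_tail(k, n, p), rel=1e-12)

    def test_known_values(self):
        assert exact_binomial_overrep(5, 10, 0.1).pvalue == pytest.approx(
            1.63e-3, rel=5e-3
        )
        assert exact_binomial_overrep(3, 3, 0.5).pvalue == pytest.approx(0.125)


class TestFisherExact:
    def test_balanced_table(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]).pvalue == pytest.approx(1.0)

    def test_aneuploidy_association_table(self):
        res = fisher_exact_2x2([[11, 38], [0, 112]])
        assert res.pvalue == pytest.approx(8.75e-7, rel=1e-3)

    def test_diagonal_table_enumeration(self):
        # 4 possible tables with margins (3,3)/(3,3); the two diagonal
        # ones each have probability 1/20
        assert fisher_exact_2x2([[3, 0], [0, 3]]).pvalue == pytest.approx(0.1)

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[0, 0], [0, 0]])


class TestPairedExact:
    def test_symmetric_discordance(self):
        assert paired_exact_test(4, 4).pvalue == 1.0

    def test_aneuploidy_discordance(self):
        # oracle: 2 * (C(13,0)+C(13,1)+C(13,2)) / 2^13 = 184/8192
        assert paired_exact_test(11, 2).pvalue == pytest.approx(184 / 8192)
        assert paired_exact_test(11, 2).pvalue == pytest.approx(0.0225, abs=2e-4)

    def test_one_sided_extreme(self):
        assert paired_exact_test(5, 0).pvalue == pytest.approx(0.0625)

    def test_no_discordance_warns(self):
        with pytest.warns(UserWarning):
            assert paired_exact_test(0, 0).pvalue == 1.0


class TestHypergeometric:
    def test_empty_reference(self):
        assert hypergeom_overlap(10, 0, 5, 0).pvalue == 1.0

    def test_shared_profile_overlap(self):
        # exact tail 6476/3365856 for 5+ shared of 7 drawn from 7 of 32
        res = hypergeom_overlap(32, 7, 7, 5)
        assert res.pvalue == pytest.approx(6476 / 3365856, rel=1e-9)

    def test_complete_overlap(self):
        assert hypergeom_overlap(10, 5, 5, 5).pvalue == pytest.approx(1 / 252)

    def test_inconsistent_parameters_error(self):
        with pytest.raises(ValueError):
            hypergeom_overlap(10, 5, 5, 6)


class TestRankSum:
    def test_identical_constant_samples(self):
        assert rank_sum_test([2.0, 2.0], [2.0, 2.0]).pvalue == 1.0

    def test_fully_separated_small_samples(self):
        # 2 / C(6,3) = 0.1: only the two fully separated labelings are as
        # extreme
        assert rank_sum_test([1, 2, 3], [4, 5, 6]).pvalue == pytest.approx(0.1)

    def test_same_multiset_is_nonsignificant(self):
        assert rank_sum_test([1, 2, 3, 4], [4, 3, 2, 1]).pvalue == 1.0


class TestBonferroni:
    def test_three_tests_threshold(self):
        threshold, _ = adjust_bonferroni([0.5, 0.5, 0.5], alpha=0.05)
        assert threshold == pytest.approx(0.0167, abs=1e-4)

    def test_single_test_is_uncorrected(self):
        threshold, _ = adjust_bonferroni([0.2], alpha=0.05)
        assert threshold == 0.05

    def test_decisions(self):
        _, decisions = adjust_bonferroni([0.01, 0.02, 0.5], alpha=0.05)
        assert decisions == [True, False, False]
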