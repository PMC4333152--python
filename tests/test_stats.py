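from fractions import Fraction

import numpy as np
import pytest

from oracles import binom_tail_greater, rank_sum_p_greater, signed_rank_p_greater
from tfosmap.stats import (
    BinomialTestInputs,
    ExaptationInputs,
    binomial_conservation_test,
    exaptation_test,
    paired_wilcoxon_ratio_test,
    signal_comparison,
)


class TestBinomialConservation:
    def test_worked_tail_example(self):
        # P(X >= 7), X ~ Binomial(10, 0.3)
        res = binomial_conservation_test(
            BinomialTestInputs(L=10, C=3, n=10, successes=7),
            alternative="greater")
        expected = float(binom_tail_greater(10, 7, Fraction(3, 10)))
        assert res.p_value == pytest.approx(expected, abs=1e-12)
        assert res.p_value == pytest.approx(0.01059, abs=5e-6)
        assert res.expected == pytest.approx(0.3)

    def test_saturated_null(self):
        res = binomial_conservation_test(
            BinomialTestInputs(L=10, C=10, n=10, successes=10),
            alternative="greater")
        assert res.p_value == 1.0

    def test_zero_successes_greater(self):
        res = binomial_conservation_test(
            BinomialTestInputs(L=10, C=3, n=10, successes=0),
            alternative="greater")
        assert res.p_value == 1.0

    def test_zero_features_rejected(self):
        with pytest.raises(ValueError, match="n = 0"):
            binomial_conservation_test(
                BinomialTestInputs(L=10, C=3, n=0, successes=0))

    def test_impossible_success_warns(self):
        res = binomial_conservation_test(
            BinomialTestInputs(L=10, C=0, n=5, successes=2),
            alternative="greater")
        assert res.p_value == 0.0
        assert res.warning is not None

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exact_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 21))
        k = int(rng.integers(0, n + 1))
        c, l = int(rng.integers(0, 50)), 50
        res = binomial_conservation_test(
            BinomialTestInputs(L=l, C=c, n=n, successes=k),
            alternative="greater")
        assert res.p_value == pytest.approx(
            float(binom_tail_greater(n, k, Fraction(c, l))), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_clopper_pearson_contains_point_estimate(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 100))
        k = int(rng.integers(0, n + 1))
        res = binomial_conservation_test(
            BinomialTestInputs(L=100, C=30, n=n, successes=k), conf=0.99)
        assert res.ci_low <= k / n <= res.ci_high


class TestPairedWilcoxon:
    def test_identical_vectors_degenerate(self):
        res = paired_wilcoxon_ratio_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == 1.0
        assert res.warning is not None

    def test_constant_shift_one_sided(self):
        a = np.arange(1.0, 11.0) + 0.5
        res = paired_wilcoxon_ratio_test(a, a - 0.5, alternative="greater")
        assert res.p_value == pytest.approx(1 / 2**10, abs=1e-12)

    def test_single_pair(self):
        assert paired_wilcoxon_ratio_test([2.0], [1.0],
                                          alternative="greater").p_value \
            == pytest.approx(0.5)
        assert paired_wilcoxon_ratio_test([2.0], [1.0]).p_value \
            == pytest.approx(1.0)

    def test_no_common_tfs_rejected(self):
        with pytest.raises(ValueError, match="common TFs"):
            paired_wilcoxon_ratio_test([], [])

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_sign_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 13))
        diffs = rng.normal(0.3, 1.0, n)
        res = paired_wilcoxon_ratio_test(diffs, np.zeros(n),
                                         alternative="greater")
        assert res.p_value == pytest.approx(
            signed_rank_p_greater(list(diffs)), abs=1e-12)


class TestSignalComparison:
    def test_maximal_separation(self):
        res = signal_comparison([5.0, 6.0, 7.0], [1.0, 2.0, 3.0], m=1)
        assert res.p_value == pytest.approx(0.05, abs=1e-12)  # 1/C(6,3)
        assert res.statistic == 9  # maximal U

    def test_identical_groups_not_significant(self):
        res = signal_comparison([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], m=1)
        assert 0.3 < res.p_value
        assert res.significant is False

    def test_bonferroni_gate(self):
        res1 = signal_comparison([5.0, 6.0, 7.0], [1.0, 2.0, 3.0],
                                 m=1, alpha=0.06)
        res2 = signal_comparison([5.0, 6.0, 7.0], [1.0, 2.0, 3.0],
                                 m=2, alpha=0.06)
        assert res1.significant and not res2.significant

    def test_empty_group_untestable(self):
        res = signal_comparison([], [1.0])
        assert res.untestable

    def test_mean_ratio_reported(self):
        rng = np.random.default_rng(0)
        sc = rng.lognormal(1.0, 0.3, 4000)
        res = signal_comparison(sc * 1.3, rng.lognormal(1.0, 0.3, 4000))
        assert res.expected == pytest.approx(1.3, rel=0.05)
        assert res.significant

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_label_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        n1, n2 = int(rng.integers(2, 8)), int(rng.integers(2, 8))
        x = list(rng.normal(0.5, 1, n1))
        y = list(rng.normal(0.0, 1, n2))
        res = signal_comparison(x, y)
        assert res.p_value == pytest.approx(rank_sum_p_greater(x, y),
                                            abs=1e-12)


class TestExaptation:
    def test_overwhelming_enrichment(self):
        res = exaptation_test(ExaptationInputs(FA=40, nFCo=50, Mo=1, L=100))
        assert res.p_value < 1e-60
        assert res.ci_high == 1.0
        assert 0 < res.ci_low < 40 / 50

    def test_zero_funct_active(self):
        res = exaptation_test(ExaptationInputs(FA=0, nFCo=50, Mo=1, L=100))
        assert res.p_value == 1.0
        assert res.ci_low == 0.0

    def test_empty_denominator_rejected(self):
        with pytest.raises(ValueError, match="nFCo"):
            exaptation_test(ExaptationInputs(FA=0, nFCo=0, Mo=1, L=100))

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            ExaptationInputs(FA=10, nFCo=5, Mo=1, L=100)
        with pytest.raises(ValueError):
            ExaptationInputs(FA=1, nFCo=5, Mo=200, L=100)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exact_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 21))
        fa = int(rng.integers(0, n + 1))
        mo, l = int(rng.integers(1, 100)), 100
        res = exaptation_test(ExaptationInputs(FA=fa, nFCo=n, Mo=mo, L=l))
        assert res.p_value == pytest.approx(
            float(binom_tail_greater(n, fa, Fraction(mo, l))), abs=1e-12)
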