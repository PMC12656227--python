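"""Agreement battery tests: Lilliefors, LoA variants, proportional bias, ICC."""
import numpy as np
import pytest

from tapagree.agreement import (
    DegenerateDataError,
    DegenerateRegressorError,
    InsufficientDataError,
    PairedDifferences,
    UndefinedICCError,
    agreement_report,
    icc_a1,
    icc_bootstrap_ci,
    lilliefors,
    lilliefors_statistic,
    loa_nonparametric,
    loa_parametric,
    proportional_bias,
)

from .helpers import icc_a1_bruteforce


class TestLilliefors:
    def test_three_point_statistic_by_hand(self):
        # ECDF vs fitted Phi at {-1, 0, 1}: D = 1/3 - Phi(-1)
        assert lilliefors_statistic(np.array([-1.0, 0.0, 1.0])) == pytest.approx(
            0.1747, abs=1e-4
        )

    def test_statistic_agrees_with_statsmodels(self, rng):
        d = rng.normal(2.0, 3.0, 40)
        stat, _ = lilliefors(d)
        assert lilliefors_statistic(d) == pytest.approx(stat, abs=1e-12)

    def test_null_retains_normality_most_of_the_time(self, rng):
        hits = sum(lilliefors(rng.normal(0, 1, 1000))[1] > 0.05 for _ in range(60))
        assert hits >= 0.90 * 60

    def test_uniform_alternative_rejected(self, rng):
        rejections = sum(
            lilliefors(rng.uniform(0, 1, 1000))[1] < 0.05 for _ in range(30)
        )
        assert rejections == 30

    def test_degenerate_and_small_inputs(self):
        with pytest.raises(DegenerateDataError):
            lilliefors(np.full(10, 3.0))
        with pytest.raises(InsufficientDataError):
            lilliefors(np.array([1.0, 2.0, 3.0]))


class TestParametricLoa:
    def test_unit_sd_triplet(self):
        res = loa_parametric(np.array([-1.0, 0.0, 1.0]))
        assert res.bias == 0.0
        assert res.loa_low == pytest.approx(-1.96)
        assert res.loa_high == pytest.approx(1.96)
        assert res.rpc == pytest.approx(1.96)

    def test_constant_differences_collapse(self):
        res = loa_parametric(np.full(10, 2.5))
        assert res.bias == 2.5
        assert res.loa_low == res.loa_high == 2.5
        assert res.rpc == 0.0

    def test_loa_symmetric_about_bias(self, rng):
        res = loa_parametric(rng.normal(1.0, 2.0, 50))
        assert res.loa_high - res.bias == pytest.approx(res.bias - res.loa_low, abs=1e-9)

    def test_ci_widths_shrink_with_n(self, rng):
        small = loa_parametric(rng.normal(0, 1, 20))
        large = loa_parametric(rng.normal(0, 1, 2000))
        assert (large.ci_bias[1] - large.ci_bias[0]) < (small.ci_bias[1] - small.ci_bias[0])

    def test_containment_near_95_percent(self, rng):
        d = rng.normal(0, 1, 500)
        res = loa_parametric(d)
        frac = np.mean((d >= res.loa_low) & (d <= res.loa_high))
        assert abs(frac - 0.95) <= 0.03


class TestNonparametricLoa:
    def test_linear_interpolation_percentiles(self):
        res = loa_nonparametric(np.arange(1.0, 101.0), n_boot=100, seed=0)
        assert res.loa_low == pytest.approx(3.475)
        assert res.loa_high == pytest.approx(97.525)

    def test_seeded_bootstrap_is_bitwise_reproducible(self, rng):
        d = rng.normal(0, 1, 40)
        a = loa_nonparametric(d, n_boot=500, seed=3)
        b = loa_nonparametric(d, n_boot=500, seed=3)
        assert a == b

    def test_symmetry_mirrors_limits(self, rng):
        d = rng.normal(0, 1, 200)
        d = np.concatenate([d, -d])  # exactly symmetric
        res = loa_nonparametric(d, n_boot=200, seed=1)
        assert res.bias == pytest.approx(0.0, abs=1e-12)
        assert res.loa_low == pytest.approx(-res.loa_high, abs=1e-9)

    def test_small_n_warns(self):
        with pytest.warns(UserWarning):
            loa_nonparametric(np.arange(5.0), n_boot=50, seed=0)


class TestProportionalBias:
    def test_exact_linear_relation(self, rng):
        m = rng.uniform(10, 50, 30)
        slope, p = proportional_bias(0.5 * m, m)
        assert slope == pytest.approx(0.5)
        assert p < 1e-12

    def test_independent_differences_give_null_slope(self, rng):
        m = rng.normal(50, 5, 500)
        d = rng.normal(0, 1, 500)
        slope, _ = proportional_bias(d, m)
        se = 1.0 / (np.sqrt(500) * m.std())
        assert abs(slope) < 3 * se

    def test_constant_differences_give_zero_slope(self):
        slope, _ = proportional_bias(np.full(10, 2.0), np.arange(10.0))
        assert slope == 0.0

    def test_constant_means_rejected(self):
        with pytest.raises(DegenerateRegressorError):
            proportional_bias(np.arange(5.0), np.full(5, 1.0))


class TestIccA1:
    def test_identical_columns_give_one(self):
        assert icc_a1(np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])) == pytest.approx(1.0)

    def test_shifted_columns_worked_example(self):
        # rows (1,2),(2,3),(3,4): MS_R=2, MS_C=1.5, MS_E=0 -> ICC = 2/3
        x = np.array([[1.0, 2.0], [2.0, 3.0], [3.0, 4.0]])
        assert icc_a1(x) == pytest.approx(2.0 / 3.0, abs=1e-12)

    def test_matches_bruteforce_sums_of_squares(self, rng):
        for _ in range(100):
            n, k = int(rng.integers(3, 11)), int(rng.integers(2, 4))
            x = rng.normal(0, 1, (n, k)) + rng.normal(0, 2, (n, 1))
            assert icc_a1(x) == pytest.approx(icc_a1_bruteforce(x), abs=1e-10)

    def test_matches_pingouin_absolute_agreement(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        x = rng.normal(0, 1, (12, 2)) + rng.normal(0, 2, (12, 1))
        long = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(12), 2),
                "raters": np.tile(["a", "b"], 12),
                "score": x.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(
            long, targets="targets", raters="raters", ratings="score"
        )
        mask = ref["Type"].isin(["ICC2", "ICC(A,1)"])
        icc2 = ref.loc[mask, "ICC"].iloc[0]
        assert icc_a1(x) == pytest.approx(icc2, abs=1e-6)

    def test_noise_degrades_icc_in_expectation(self, rng):
        drops = []
        for _ in range(30):
            base = rng.normal(0, 3, (20, 1)) + rng.normal(0, 0.3, (20, 2))
            noisy = base.copy()
            noisy[:, 1] += rng.normal(0, 1.5, 20)
            drops.append(icc_a1(base) - icc_a1(noisy))
        assert np.mean(drops) > 0

    def test_undefined_on_constant_matrix(self):
        with pytest.raises(UndefinedICCError):
            icc_a1(np.full((5, 2), 7.0))


class TestIccBootstrap:
    def test_identical_columns_degenerate_interval(self):
        x = np.column_stack([np.arange(10.0), np.arange(10.0)])
        assert icc_bootstrap_ci(x, n_boot=200, seed=0) == (1.0, 1.0)

    def test_seeded_reproducibility(self, rng):
        x = rng.normal(0, 1, (20, 2)) + rng.normal(0, 2, (20, 1))
        assert icc_bootstrap_ci(x, 300, seed=5) == icc_bootstrap_ci(x, 300, seed=5)

    def test_interval_brackets_point_estimate(self, rng):
        x = rng.normal(0, 1, (30, 2)) + rng.normal(0, 2, (30, 1))
        lo, hi = icc_bootstrap_ci(x, 500, seed=2)
        assert lo <= icc_a1(x) <= hi


class TestAgreementReport:
    def _paired(self, d, m):
        return PairedDifferences(
            unit_ids=tuple(range(len(d))), d=d, m=m, variable_label="n_taps"
        )

    def test_gate_selects_parametric_under_normality(self, rng):
        d = rng.normal(0, 1, 500)
        m = rng.normal(50, 5, 500)
        res = agreement_report(self._paired(d, m), n_boot=200, seed=0)
        assert res.method_selected == "parametric"

    def test_gate_selects_nonparametric_under_uniform(self, rng):
        d = rng.uniform(-1, 1, 500)
        m = rng.normal(50, 5, 500)
        res = agreement_report(self._paired(d, m), n_boot=200, seed=0)
        assert res.method_selected == "nonparametric"

    def test_both_variants_always_reported(self, rng):
        res = agreement_report(
            self._paired(rng.normal(0, 1, 40), rng.normal(50, 5, 40)),
            n_boot=100,
            seed=0,
        )
        assert res.parametric.variant == "parametric"
        assert res.nonparametric.variant == "nonparametric"
        out = res.to_dict()
        assert "parametric" in out and "nonparametric" in out

    def test_constant_differences_degrade_gracefully(self, rng):
        d = np.zeros(20)
        m = rng.normal(50, 5, 20)
        res = agreement_report(self._paired(d, m), n_boot=100, seed=0)
        assert res.method_selected == "parametric"
        assert np.isnan(res.normality_p)
        assert res.parametric.bias == res.parametric.loa_low == 0.0
        assert res.icc == pytest.approx(1.0)

    def test_method_swap_antisymmetry(self, rng):
        d = rng.normal(0.5, 1, 60)
        m = rng.normal(50, 5, 60)
        a = agreement_report(self._paired(d, m), n_boot=100, seed=4)
        b = agreement_report(self._paired(-d, m), n_boot=100, seed=4)
        assert b.parametric.bias == pytest.approx(-a.parametric.bias)
        assert b.parametric.loa_low == pytest.approx(-a.parametric.loa_high)
        assert b.nonparametric.bias == pytest.approx(-a.nonparametric.bias)
        assert b.nonparametric.loa_low == pytest.approx(-a.nonparametric.loa_high)
        assert b.icc == pytest.approx(a.icc, abs=1e-12)
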