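"""Unit and property tests for the MR estimator suite."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cliffmr import (
    DOUBLING_FACTOR,
    i2_gx,
    ivw,
    mean_f_statistic,
    mode_estimator,
    mr_egger,
    run_mr_suite,
    scale_binary_exposure,
    to_odds_ratio,
    wald_ratio,
    weighted_median,
)
from cliffmr.estimators import MREstimate

from conftest import (
    make_instruments,
    weighted_median_oracle,
    wls_intercept_oracle,
    wls_zero_intercept_oracle,
)


class TestWaldRatio:
    def test_arithmetic(self):
        est = wald_ratio(0.10, 0.02, 0.05, 0.01)
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.1)

    def test_zero_exposure_effect_raises(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(0.0, 0.02, 0.05, 0.01)


class TestIVW:
    def test_single_instrument_reduces_to_wald_ratio(self):
        h = make_instruments([0.1], [0.02], [0.05], [0.01])
        est = ivw(h)
        wald = wald_ratio(0.1, 0.02, 0.05, 0.01)
        assert est.beta == pytest.approx(wald.beta, abs=0)
        assert est.se == pytest.approx(wald.se, abs=0)
        assert "cochran_q" not in est.diagnostics

    def test_identical_ratios_give_zero_heterogeneity(self):
        h = make_instruments([0.1, 0.2], [0.01, 0.01], [0.05, 0.10], [0.01, 0.02])
        est = ivw(h)
        assert est.beta == pytest.approx(0.5)
        assert est.diagnostics["cochran_q"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_zero_intercept_wls_oracle(self):
        bx = [0.1, 0.2, 0.15]
        by = [0.05, 0.09, 0.08]
        so = [0.01, 0.01, 0.02]
        h = make_instruments(bx, [0.01] * 3, by, so)
        expected = wls_zero_intercept_oracle(bx, by, 1 / np.asarray(so) ** 2)
        assert ivw(h).beta == pytest.approx(expected, rel=1e-12)

    def test_random_effects_se_never_below_fixed(self, random_instruments):
        rng = np.random.default_rng(42)
        for _ in range(50):
            h = random_instruments(rng, int(rng.integers(2, 12)))
            est = ivw(h)
            w = 1 / h["se_out"] ** 2
            fixed = 1 / np.sqrt(np.sum(w * h["beta_exp"] ** 2))
            assert est.se >= fixed - 1e-15

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            ivw(make_instruments([], [], [], []))


class TestEgger:
    def test_two_points_exact_interpolation(self):
        h = make_instruments([0.1, 0.3], [0.01, 0.01], [0.02, 0.10], [0.01, 0.02])
        slope, intercept = mr_egger(h)
        # the fitted line passes exactly through both points
        for bx, by in [(0.1, 0.02), (0.3, 0.10)]:
            assert intercept.beta + slope.beta * bx == pytest.approx(by, rel=1e-10)

    def test_matches_wls_oracle(self, random_instruments):
        rng = np.random.default_rng(7)
        for _ in range(50):
            h = random_instruments(rng, int(rng.integers(3, 12)))
            w = 1 / h["se_out"].to_numpy() ** 2
            slope_o, int_o = wls_intercept_oracle(h["beta_exp"], h["beta_out"], w)
            slope, intercept = mr_egger(h)
            assert slope.beta == pytest.approx(slope_o, rel=1e-10)
            assert intercept.beta == pytest.approx(int_o, rel=1e-10)

    def test_intercept_algebraic_identity(self, random_instruments):
        # intercept = weighted mean of beta_out − slope · weighted mean of beta_exp
        rng = np.random.default_rng(8)
        h = random_instruments(rng, 9)
        w = 1 / h["se_out"].to_numpy() ** 2
        slope, intercept = mr_egger(h)
        expected = (np.sum(w * h["beta_out"]) - slope.beta * np.sum(w * h["beta_exp"])) / np.sum(w)
        assert intercept.beta == pytest.approx(expected, rel=1e-10)

    def test_no_spread_raises(self):
        h = make_instruments([0.1, 0.1, 0.1], [0.01] * 3, [0.1, 0.2, 0.3], [0.01] * 3)
        with pytest.raises(ValueError, match="spread"):
            mr_egger(h)

    def test_too_few_instruments_raises(self):
        with pytest.raises(ValueError):
            mr_egger(make_instruments([0.1], [0.01], [0.05], [0.01]))


class TestWeightedMedian:
    def test_degenerate_common_ratio(self):
        h = make_instruments([0.1, 0.2, 0.4], [0.01] * 3, [0.05, 0.10, 0.20],
                             [0.01, 0.03, 0.02])
        assert weighted_median(h, n_boot=0).beta == pytest.approx(0.5)

    def test_equal_weights_interpolation(self):
        # equal ratio weights: cumulative weight crosses 0.5 at the middle ratio
        bx = np.full(5, 0.1)
        ratios = np.array([1.0, 2.0, 3.0, 4.0, 10.0])
        h = make_instruments(bx, [0.01] * 5, ratios * bx, [0.01] * 5)
        assert weighted_median(h, n_boot=0).beta == pytest.approx(3.0)

    def test_matches_loop_oracle(self, random_instruments):
        rng = np.random.default_rng(11)
        for _ in range(100):
            h = random_instruments(rng, int(rng.integers(3, 11)))
            ratios = (h["beta_out"] / h["beta_exp"]).to_numpy()
            weights = (h["beta_exp"] ** 2 / h["se_out"] ** 2).to_numpy()
            expected = weighted_median_oracle(ratios, weights)
            assert weighted_median(h, n_boot=0).beta == pytest.approx(expected, rel=1e-12)

    def test_within_ratio_range(self, random_instruments):
        rng = np.random.default_rng(12)
        for _ in range(30):
            h = random_instruments(rng, 7)
            ratios = h["beta_out"] / h["beta_exp"]
            beta = weighted_median(h, n_boot=0).beta
            assert ratios.min() - 1e-12 <= beta <= ratios.max() + 1e-12

    def test_more_robust_to_outlier_than_ivw(self):
        rng = np.random.default_rng(13)
        moved_wm, moved_ivw = [], []
        for _ in range(20):
            bx = rng.uniform(0.1, 0.3, 10)
            so = np.full(10, 0.01)
            by = 0.5 * bx + rng.normal(0, 0.002, 10)
            h = make_instruments(bx, [0.01] * 10, by, so)
            base_wm = weighted_median(h, n_boot=0).beta
            base_ivw = ivw(h).beta
            by2 = by.copy()
            by2[0] = 5.0 * bx[0]  # one wild outlier with ordinary weight
            h2 = make_instruments(bx, [0.01] * 10, by2, so)
            moved_wm.append(abs(weighted_median(h2, n_boot=0).beta - base_wm))
            moved_ivw.append(abs(ivw(h2).beta - base_ivw))
        assert np.mean(moved_wm) < np.mean(moved_ivw)

    def test_bootstrap_se_reproducible(self):
        rng = np.random.default_rng(14)
        bx = rng.uniform(0.1, 0.3, 8)
        h = make_instruments(bx, [0.01] * 8, 0.3 * bx, [0.01] * 8)
        a = weighted_median(h, n_boot=200, seed=5)
        b = weighted_median(h, n_boot=200, seed=5)
        assert a.se == b.se
        assert a.se > 0


class TestModeEstimator:
    def test_degenerate_common_ratio(self):
        h = make_instruments([0.25, 0.5, 1.0], [0.01] * 3,
                             [0.05, 0.1, 0.2], [0.01] * 3)  # ratios exactly 0.2
        est = mode_estimator(h, n_boot=0)
        assert est.beta == pytest.approx(0.2)
        assert est.se == 0.0
        assert est.diagnostics.get("degenerate")

    def test_majority_cluster_wins(self):
        # 7 ratios near 0.1, 3 near 0.9: the simple mode sits at the big cluster
        rng = np.random.default_rng(21)
        ratios = np.concatenate([rng.normal(0.1, 0.01, 7), rng.normal(0.9, 0.01, 3)])
        bx = np.full(10, 0.2)
        h = make_instruments(bx, [0.01] * 10, ratios * bx, [0.01] * 10)
        est = mode_estimator(h, weighted=False, n_boot=0)
        assert abs(est.beta - 0.1) < 0.05

    def test_weighted_equals_simple_under_equal_weights(self):
        rng = np.random.default_rng(22)
        bx = np.full(8, 0.2)  # equal beta_exp and se_out → equal kernel weights
        ratios = rng.normal(0.5, 0.1, 8)
        h = make_instruments(bx, [0.01] * 8, ratios * bx, [0.02] * 8)
        simple = mode_estimator(h, weighted=False, n_boot=0).beta
        weighted = mode_estimator(h, weighted=True, n_boot=0).beta
        assert simple == pytest.approx(weighted, abs=0)

    def test_bootstrap_se_reproducible(self):
        rng = np.random.default_rng(23)
        bx = rng.uniform(0.1, 0.3, 6)
        h = make_instruments(bx, [0.01] * 6, 0.2 * bx + rng.normal(0, 0.01, 6), [0.01] * 6)
        a = mode_estimator(h, n_boot=100, seed=3)
        b = mode_estimator(h, n_boot=100, seed=3)
        assert a.se == b.se


class TestDiagnostics:
    def test_mean_f_unit_ratio(self):
        h = make_instruments([0.1, 0.2, 0.05], [0.1, 0.2, 0.05], [0.0] * 3, [0.01] * 3)
        assert mean_f_statistic(h) == pytest.approx(1.0)

    def test_i2gx_zero_when_no_dispersion(self):
        h = make_instruments([0.1, 0.1, 0.1], [0.01, 0.02, 0.03], [0.0] * 3, [0.01] * 3)
        assert i2_gx(h, weighted=True) == 0.0
        assert i2_gx(h, weighted=False) == 0.0

    def test_i2gx_approaches_one_for_precise_heterogeneous_effects(self):
        rng = np.random.default_rng(31)
        bx = rng.uniform(0.05, 0.5, 50)
        h = make_instruments(bx, np.full(50, 1e-4), np.zeros(50), np.full(50, 0.01))
        assert i2_gx(h, weighted=False) > 0.99


class TestScaling:
    def _est(self, beta=1.0, se=0.5):
        return MREstimate("ivw", beta, se, beta - 1.96 * se, beta + 1.96 * se,
                          0.05, 10, "raw")

    def test_doubling_definition(self):
        out = scale_binary_exposure(self._est(beta=1.0))
        assert out.beta == pytest.approx(0.693)
        assert out.scale == "per_doubling_odds"

    def test_null_fixed_point_p_unchanged(self):
        out = scale_binary_exposure(self._est(beta=0.0))
        assert out.beta == 0.0
        assert out.pval == 0.05

    def test_round_trip(self):
        out = scale_binary_exposure(self._est(beta=0.37))
        assert out.beta / DOUBLING_FACTOR == pytest.approx(0.37, rel=1e-12)

    def test_double_application_guarded(self):
        out = scale_binary_exposure(self._est())
        with pytest.raises(ValueError):
            scale_binary_exposure(out)

    def test_odds_ratio_null_and_monotone(self):
        out = to_odds_ratio(self._est(beta=0.3, se=0.2))
        assert out.ci_low < out.beta < out.ci_high
        null = to_odds_ratio(MREstimate("ivw", 0.0, 0.2, -0.392, 0.392, 0.9, 5,
                                        "per_doubling_odds"))
        assert null.beta == pytest.approx(1.0)

    def test_odds_ratio_binary_exposure_folds_in_doubling(self):
        out = to_odds_ratio(self._est(beta=1.0), binary_exposure=True)
        assert out.beta == pytest.approx(np.exp(0.693))

    def test_odds_ratio_guard(self):
        orat = to_odds_ratio(self._est())
        with pytest.raises(ValueError):
            to_odds_ratio(orat)


@given(c=st.floats(0.1, 10.0))
def test_scale_equivariance(c):
    """Multiplying all outcome effects and SEs by c scales every estimator by c."""
    rng = np.random.default_rng(99)
    bx = rng.uniform(0.1, 0.3, 8)
    by = 0.4 * bx + rng.normal(0, 0.01, 8)
    so = rng.uniform(0.01, 0.03, 8)
    h1 = make_instruments(bx, [0.01] * 8, by, so)
    h2 = make_instruments(bx, [0.01] * 8, c * by, c * so)
    assert ivw(h2).beta == pytest.approx(c * ivw(h1).beta, rel=1e-9)
    assert ivw(h2).se == pytest.approx(c * ivw(h1).se, rel=1e-9)
    s1, i1 = mr_egger(h1)
    s2, i2 = mr_egger(h2)
    assert s2.beta == pytest.approx(c * s1.beta, rel=1e-9)
    assert i2.beta == pytest.approx(c * i1.beta, rel=1e-9)
    assert weighted_median(h2, n_boot=0).beta == pytest.approx(
        c * weighted_median(h1, n_boot=0).beta, rel=1e-6)


def test_ivw_weak_instrument_dilution_shrinks_with_exposure_sample():
    """IVW's regression dilution (~1/F toward the null) vanishes as the
    exposure GWAS grows."""
    from cliffmr import SimulationConfig, gen_two_sample_summary, harmonize

    def mean_estimate(n_exposure, reps=60):
        vals = []
        for rep in range(reps):
            cfg = SimulationConfig(n_snps=50, true_causal_effect=0.1,
                                   n_exposure_sample=n_exposure, seed=3000 + rep)
            exposure, outcome = gen_two_sample_summary(cfg)
            vals.append(ivw(harmonize(exposure, outcome)).beta)
        return np.mean(vals)

    bias_weak = abs(mean_estimate(20_000) - 0.1)
    bias_strong = abs(mean_estimate(2_000_000) - 0.1)
    assert bias_strong < bias_weak
    assert bias_strong < 0.002


def test_run_mr_suite_shape_and_scales():
    from cliffmr import SimulationConfig, gen_two_sample_summary

    cfg = SimulationConfig(n_snps=40, true_causal_effect=0.1, seed=77,
                           allele_swap_fraction=0.2)
    exposure, outcome = gen_two_sample_summary(cfg)
    table = run_mr_suite(exposure, outcome, binary_exposure=True, n_boot=50, seed=1)
    assert set(table["method"]) == {
        "ivw", "egger_slope", "egger_intercept", "weighted_median",
        "simple_mode", "weighted_mode",
    }
    scales = table.set_index("method")["scale"]
    assert (scales.drop("egger_intercept") == "per_doubling_odds").all()
    assert scales["egger_intercept"] == "raw"  # pleiotropy intercept stays native
    assert {"cochran_q", "mean_f", "i2_gx"} <= set(table.columns)
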