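import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.base import clone

from mrpipe.estimators import (
    EggerEstimator,
    IVWEstimator,
    RAPSEstimator,
    SimexSettings,
    egger,
    gsmr,
    i2gx,
    ivw,
    raps,
    raps_profile_score,
    simex_egger,
    wald_ratios,
    weighted_median,
)

from conftest import make_instruments


class TestWaldRatios:
    @pytest.mark.parametrize(
        "g,G,sG,b,se",
        [
            (0.10, 0.0354, 0.005, 0.354, 0.05),
            (-0.10, -0.0354, 0.005, 0.354, 0.05),  # sign cancels
            (0.2, 0.05, 0.01, 0.25, 0.05),
        ],
    )
    def test_ratio_and_first_order_se(self, g, G, sG, b, se):
        out = wald_ratios(make_instruments([g], 0.001, [G], sG))
        assert out.loc[0, "ratio"] == pytest.approx(b)
        assert out.loc[0, "se_ratio"] == pytest.approx(se)

    def test_zero_exposure_effect_names_snp(self):
        inst = make_instruments([0.1, 0.0], 0.001, [0.03, 0.0], 0.01)
        with pytest.raises(ValueError, match="rs0001"):
            wald_ratios(inst)


class TestIVW:
    def test_two_snp_closed_form(self):
        inst = make_instruments([1.0, 1.0], 0.0, [0.3, 0.5], 0.1)
        fixed = ivw(inst, re_model="fixed")
        assert fixed.beta == pytest.approx(0.4)
        assert fixed.se == pytest.approx(math.sqrt(1 / 200))
        mult = ivw(inst, re_model="multiplicative")
        # Q = 2 on 1 df -> SE inflated by sqrt(2)
        assert mult.beta == pytest.approx(0.4)
        assert mult.se == pytest.approx(0.1)

    def test_duplicated_single_snp_equals_wald_ratio(self):
        inst = make_instruments([0.1, 0.1], 0.001, [0.0354, 0.0354], 0.005)
        est = ivw(inst)
        assert est.beta == pytest.approx(0.354)

    def test_single_instrument_rejected(self):
        with pytest.raises(ValueError, match="2 instruments"):
            ivw(make_instruments([0.1], 0.001, [0.03], 0.01))

    def test_simulation_recovery_within_two_se(self):
        rng = np.random.default_rng(42)
        L = 300
        g = rng.uniform(0.05, 0.2, L)
        sG = np.full(L, 0.01)
        G = 0.354 * g + sG * rng.standard_normal(L)
        est = ivw(make_instruments(g, 1e-6, G, sG))
        assert abs(est.beta - 0.354) < 2 * est.se

    def test_agrees_with_weighted_least_squares_oracle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        g = rng.uniform(0.05, 0.3, 40)
        sG = rng.uniform(0.005, 0.05, 40)
        G = 0.2 * g + sG * rng.standard_normal(40)
        mine = ivw(make_instruments(g, 0.001, G, sG), re_model="fixed")
        fit = sm.WLS(G, g, weights=1 / sG**2).fit()
        assert abs(mine.beta - fit.params[0]) < 1e-10


class TestEgger:
    def test_exact_line_recovered(self):
        g = np.array([0.05, 0.1, 0.2, 0.3])
        G = 0.01 + 0.354 * g
        est = egger(make_instruments(g, 0.001, G, np.array([0.01, 0.02, 0.01, 0.03])))
        assert est.beta == pytest.approx(0.354)
        assert est.intercept == pytest.approx(0.01)

    def test_orientation_invariance(self):
        g = np.array([0.05, 0.1, 0.2, 0.3])
        G = 0.01 + 0.354 * g + np.array([0.001, -0.002, 0.0, 0.001])
        a = egger(make_instruments(g, 0.001, G, 0.01))
        g2, G2 = g.copy(), G.copy()
        g2[1], G2[1] = -g2[1], -G2[1]  # re-encoded pair
        b = egger(make_instruments(g2, 0.001, G2, 0.01))
        assert a.beta == pytest.approx(b.beta, abs=1e-14)
        assert a.intercept == pytest.approx(b.intercept, abs=1e-14)

    def test_directional_pleiotropy_intercept_recovery(self):
        from mrpipe.harmonize import harmonize_instruments
        from mrpipe.simulate import scenario_presets, simulate_two_sample

        cfg = scenario_presets("directional_pleiotropy", seed=77)
        exp, out, _ = simulate_two_sample(cfg)
        h, _ = harmonize_instruments(exp, out)
        est = egger(h)
        assert abs(est.intercept - 0.01) < 2 * est.intercept_se

    def test_agrees_with_statsmodels_wls(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        g = rng.uniform(0.05, 0.3, 30)
        sG = rng.uniform(0.005, 0.05, 30)
        G = 0.005 + 0.2 * g + sG * rng.standard_normal(30)
        mine = egger(make_instruments(g, 0.001, G, sG))
        X = sm.add_constant(g)
        fit = sm.WLS(G, X, weights=1 / sG**2).fit()
        assert abs(mine.intercept - fit.params[0]) < 1e-10
        assert abs(mine.beta - fit.params[1]) < 1e-10


class TestI2GX:
    def test_equal_gammas_degenerate_to_zero(self):
        assert i2gx(make_instruments([0.1] * 3, 0.01, [0.03] * 3, 0.01)) == 0.0

    def test_two_snp_hand_arithmetic(self):
        # Q_GX = (0.05² + 0.05²)/0.01² = 50; I² = 49/50
        val = i2gx(make_instruments([0.1, 0.2], 0.01, [0.03, 0.06], 0.01))
        assert val == pytest.approx(0.98)


class TestSimex:
    def test_no_measurement_error_limit_equals_naive_egger(self):
        g = np.array([0.05, 0.1, 0.2, 0.3, 0.15])
        G = 0.01 + 0.354 * g + np.array([0.001, -0.002, 0.0, 0.001, -0.001])
        inst = make_instruments(g, 0.0, G, 0.01)
        naive = egger(inst)
        sx = simex_egger(inst, SimexSettings(n_boot=100, seed=1))
        assert sx.beta == pytest.approx(naive.beta, abs=1e-10)
        assert sx.intercept == pytest.approx(naive.intercept, abs=1e-10)

    def test_deterministic_under_fixed_seed(self, homogeneous_instruments):
        a = simex_egger(homogeneous_instruments, SimexSettings(n_boot=100, seed=3))
        b = simex_egger(homogeneous_instruments, SimexSettings(n_boot=100, seed=3))
        assert a.beta == b.beta and a.se == b.se

    def test_settings_validation(self):
        with pytest.raises(ValueError):
            SimexSettings(lambda_grid=(0.5, 1.0))  # missing 0
        with pytest.raises(ValueError):
            SimexSettings(n_boot=10)


class TestWeightedMedian:
    def test_equal_weights_middle_value(self):
        # ratios 0.1, 0.3, 0.5 with equal weights -> 0.3
        g = np.array([1.0, 1.0, 1.0])
        G = np.array([0.1, 0.3, 0.5])
        est = weighted_median(make_instruments(g, 0.001, G, 1.0), n_boot=100)
        assert est.beta == pytest.approx(0.3)

    def test_interpolation_rule_hand_computed(self):
        # weights (0.25, 0.25, 0.5): cumulative midpoints (.125, .375, .75);
        # interpolating to 0.5 gives 0.3 + (0.5-0.375)/(0.75-0.375)*0.2
        g = np.array([1.0, 1.0, math.sqrt(2.0)])
        G = np.array([0.1, 0.3, 0.5 * math.sqrt(2.0)])
        est = weighted_median(make_instruments(g, 0.001, G, 1.0), n_boot=100)
        assert est.beta == pytest.approx(0.3 + (0.5 - 0.375) / 0.375 * 0.2)

    def test_needs_three_instruments(self):
        with pytest.raises(ValueError):
            weighted_median(make_instruments([0.1, 0.2], 0.001, [0.03, 0.06], 0.01))


class TestRAPS:
    def test_zero_exposure_error_reduces_to_fixed_ivw(self, homogeneous_instruments):
        inst = homogeneous_instruments.copy()
        inst["se_gamma"] = 0.0
        assert raps(inst).beta == pytest.approx(
            ivw(inst, re_model="fixed").beta, abs=1e-9
        )

    def test_profile_score_zero_at_estimate(self, homogeneous_instruments):
        est = raps(homogeneous_instruments)
        df = homogeneous_instruments
        score = raps_profile_score(
            est.beta,
            df["gamma_hat"].to_numpy(),
            df["se_gamma"].to_numpy(),
            df["big_gamma_hat"].to_numpy(),
            df["se_big_gamma"].to_numpy(),
        )
        assert abs(score) < 1e-8

    def test_corrects_attenuation_better_than_ivw(self):
        """With material exposure-side noise, the profile score removes the
        regression-dilution bias that IVW keeps (average over 50 draws)."""
        errs_ivw, errs_raps = [], []
        for k in range(50):
            r = np.random.default_rng(900 + k)
            L = 100
            gt = r.normal(0.02, 0.008, L)
            sg = np.full(L, 0.005)
            sG = np.full(L, 0.003)
            inst = make_instruments(
                gt + sg * r.standard_normal(L), sg,
                0.354 * gt + sG * r.standard_normal(L), sG,
            )
            errs_ivw.append(ivw(inst).beta - 0.354)
            errs_raps.append(raps(inst).beta - 0.354)
        assert abs(np.mean(errs_raps)) < abs(np.mean(errs_ivw))
        assert np.mean(np.abs(errs_raps)) < np.mean(np.abs(errs_ivw))


class TestGSMR:
    def test_zero_exposure_error_reduces_to_fixed_ivw(self, homogeneous_instruments):
        inst = homogeneous_instruments.copy()
        inst["se_gamma"] = 0.0
        est = gsmr(inst, heidi_threshold=0.0)
        assert est.beta == pytest.approx(ivw(inst, re_model="fixed").beta, rel=1e-12)

    def test_heidi_outlier_removed_before_estimation(self, rng):
        L = 20
        g = rng.uniform(0.1, 0.3, L)
        sG = np.full(L, 0.01)
        G = 0.354 * g + 0.001 * rng.standard_normal(L)
        G[4] += 0.1  # gross single-instrument deviation
        inst = make_instruments(g, 0.001, G, sG)
        est = gsmr(inst, heidi_threshold=0.01)
        assert est.n_snps < L
        no_filter = gsmr(inst, heidi_threshold=0.0)
        assert abs(est.beta - 0.354) < abs(no_filter.beta - 0.354)

    def test_recovery_within_two_se(self):
        r = np.random.default_rng(11)
        L = 300
        g = r.uniform(0.05, 0.2, L)
        sg = np.full(L, 0.002)
        sG = np.full(L, 0.01)
        inst = make_instruments(
            g + sg * r.standard_normal(L), sg,
            0.354 * g + sG * r.standard_normal(L), sG,
        )
        est = gsmr(inst)
        assert abs(est.beta - 0.354) < 2 * est.se


class TestCommonInvariants:
    @pytest.fixture
    def all_estimates(self, homogeneous_instruments):
        h = homogeneous_instruments
        return [
            ivw(h),
            egger(h),
            weighted_median(h, n_boot=200, seed=0),
            raps(h),
            gsmr(h),
            simex_egger(h, SimexSettings(n_boot=100, seed=0)),
        ]

    def test_or_and_ci_are_exact_transforms(self, all_estimates):
        for e in all_estimates:
            assert e.or_ == math.exp(e.beta)
            assert e.ci_low == math.exp(e.beta - 1.96 * e.se)
            assert e.ci_high == math.exp(e.beta + 1.96 * e.se)
            assert e.ci_low < e.or_ < e.ci_high
            assert 0 < e.pval <= 1

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.floats(0.05, 20.0))
    def test_scale_equivariance_in_outcome_units(self, c):
        rng = np.random.default_rng(77)
        g = rng.uniform(0.05, 0.2, 30)
        sG = np.full(30, 0.01)
        G = 0.354 * g + sG * rng.standard_normal(30)
        base = make_instruments(g, 0.002, G, sG)
        scaled = base.copy()
        scaled["big_gamma_hat"] *= c
        scaled["se_big_gamma"] *= c
        for fn in (
            lambda X: ivw(X).beta,
            lambda X: egger(X).beta,
            lambda X: weighted_median(X, n_boot=100, seed=1).beta,
            lambda X: raps(X).beta,
            lambda X: gsmr(X).beta,
        ):
            assert fn(scaled) == pytest.approx(c * fn(base), rel=1e-6)

    def test_sklearn_protocol(self, homogeneous_instruments):
        est = IVWEstimator(re_model="fixed")
        assert est.get_params() == {"re_model": "fixed"}
        est2 = clone(est).set_params(re_model="multiplicative")
        est2.fit(homogeneous_instruments)
        assert hasattr(est2, "beta_") and hasattr(est2, "se_")
        egg = EggerEstimator().fit(homogeneous_instruments)
        assert egg.result_.intercept is not None
        rp = RAPSEstimator().fit(homogeneous_instruments)
        assert rp.result_.method == "RAPS"
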