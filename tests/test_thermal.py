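"""Thermal-time model: fits, cardinal temperatures, predictions."""

import numpy as np
import pytest

from pbtgerm.errors import FitError, UndefinedPercentileError
from pbtgerm.records import extract_all, germination_indices, pool_replicates
from pbtgerm.simulate import paper_design, simulate_dataset
from pbtgerm.thermal import (
    CardinalTemperatures,
    SubThermalParams,
    SupraThermalParams,
    cardinal_temperatures,
    fit_suboptimal_tt,
    fit_supraoptimal_tt,
    observed_optimum_temperature,
    predict_tt_time_course,
    tt_percentile_curve,
    tt_quantile_times,
)

from .conftest import GRID_9, SUB_TT, SUPRA_TT


class TestSubOptimalFit:
    def test_noise_free_closed_loop_recovers_parameters(self, sub_tt):
        curves = [tt_percentile_curve(sub_tt, T, GRID_9) for T in (10, 15, 20)]
        fit = fit_suboptimal_tt(curves)
        assert fit.Tb == pytest.approx(sub_tt.Tb, abs=1e-3)
        assert fit.theta_T50 == pytest.approx(sub_tt.theta_T50, abs=1e-3)
        assert fit.sigma_thetaT == pytest.approx(sub_tt.sigma_thetaT, abs=1e-3)
        assert fit.r2 == pytest.approx(1.0, abs=1e-6)

    def test_single_temperature_unidentifiable(self, sub_tt):
        with pytest.raises(FitError, match="single temperature"):
            fit_suboptimal_tt([tt_percentile_curve(sub_tt, 15, GRID_9)])

    def test_identical_curves_at_all_temperatures_degenerate(self):
        # same t(g) at every T: no Tb can linearise this, fit must not
        # silently return something
        from pbtgerm.records import PercentileCurve

        times = (10.0, 20.0, 30.0)
        curves = [
            PercentileCurve((T, 0.0), (0.2, 0.5, 0.8), times, 1.0) for T in (10, 15, 20)
        ]
        fit = fit_suboptimal_tt(curves)
        assert fit.r2 < 0.999  # cannot be a perfect thermal-time population

    def test_recovery_from_simulated_counts(self):
        """Binomial-noise simulation at the factorial design (sub-optimal
        temperatures, 250 seeds/treatment): mean recovered Tb within 0.5 °C,
        θT(50) and σθT within 10%, across 20 seeded replicates."""
        true = paper_design("tt-sub").params
        ests = []
        for rep in range(20):
            design = paper_design("tt-sub", rng_seed=300 + rep)
            groups = pool_replicates(simulate_dataset(design))
            fit = fit_suboptimal_tt(extract_all(groups))
            ests.append((fit.theta_T50, fit.Tb, fit.sigma_thetaT))
        theta, tb, sigma = np.mean(ests, axis=0)
        assert tb == pytest.approx(true.Tb, abs=0.5)
        assert theta == pytest.approx(true.theta_T50, rel=0.10)
        assert sigma == pytest.approx(true.sigma_thetaT, rel=0.10)


class TestSupraOptimalFit:
    def test_noise_free_closed_loop_recovers_parameters(self, supra_tt):
        curves = [tt_percentile_curve(supra_tt, T, GRID_9) for T in (25, 30, 35)]
        fit = fit_supraoptimal_tt(curves)
        assert fit.theta_T2 == pytest.approx(supra_tt.theta_T2, abs=1e-3)
        assert fit.Tc50 == pytest.approx(supra_tt.Tc50, abs=1e-3)
        assert fit.sigma_Tc == pytest.approx(supra_tt.sigma_Tc, abs=1e-3)
        assert fit.r2 == pytest.approx(1.0, abs=1e-6)

    def test_median_rate_vanishes_at_ceiling(self, supra_tt):
        # t(50) → ∞ as T → Tc50: GR(50) at the ceiling is zero
        eps = 1e-9
        t50 = tt_quantile_times(supra_tt, supra_tt.Tc50 - eps, [0.5])[0]
        assert 1.0 / t50 == pytest.approx(0.0, abs=1e-9)
        with pytest.raises(UndefinedPercentileError):
            tt_quantile_times(supra_tt, supra_tt.Tc50, [0.5])


class TestCardinalTemperatures:
    def test_intersection_of_gr50_lines(self, sub_tt, supra_tt):
        card = cardinal_temperatures(
            fit_suboptimal_tt([tt_percentile_curve(sub_tt, T, GRID_9) for T in (10, 15, 20)]),
            fit_supraoptimal_tt([tt_percentile_curve(supra_tt, T, GRID_9) for T in (25, 30, 35)]),
        )
        assert card.Tb == pytest.approx(7.2, abs=1e-3)
        assert card.Tc == pytest.approx(42.8, abs=1e-3)
        # (42.8·3.01 + 7.2·3.21)/(3.01 + 3.21)
        assert card.To == pytest.approx(24.43, abs=0.01)

    def test_symmetric_constants_put_optimum_midway(self):
        sub = SubThermalParams(theta_T50=100.0, Tb=5.0, sigma_thetaT=10.0)
        supra = SupraThermalParams(theta_T2=100.0, Tc50=45.0, sigma_Tc=1.0)
        card = cardinal_temperatures(sub, supra)
        assert card.To == pytest.approx((5.0 + 45.0) / 2)

    def test_ordering_enforced(self):
        with pytest.raises(FitError):
            CardinalTemperatures(Tb=20.0, To=10.0, Tc=40.0)

    def test_observed_optimum_is_argmax_germination(self):
        design = paper_design("tt-sub", rng_seed=5)
        groups = pool_replicates(simulate_dataset(design))
        by_T = {g.temperature: germination_indices(g) for g in groups}
        t_opt = observed_optimum_temperature(by_T)
        best = max(by_T.values(), key=lambda i: i.final_germination_pct)
        assert by_T[t_opt].final_germination_pct == best.final_germination_pct


class TestPrediction:
    def test_median_identity_at_characteristic_time(self, sub_tt):
        t50 = sub_tt.theta_T50 / (20.0 - sub_tt.Tb)  # 3.01/12.8 ≈ 0.2352 h
        g = predict_tt_time_course(sub_tt, 20.0, [t50])
        assert g[0] == pytest.approx(0.5, abs=1e-12)

    def test_below_base_temperature_predicts_zero_with_flag(self, sub_tt):
        with pytest.warns(UserWarning, match="Tb"):
            g = predict_tt_time_course(sub_tt, 7.0, [1.0, 10.0, 100.0])
        assert np.all(g == 0.0)

    @pytest.mark.parametrize("params, T", [(SUB_TT, 12.0), (SUPRA_TT, 30.0)])
    def test_time_course_monotone_nondecreasing(self, params, T):
        t = np.linspace(0.01, 50.0, 400)
        g = predict_tt_time_course(params, T, t)
        assert np.all(np.diff(g) >= 0)

    def test_gr_linear_in_temperature_with_intercept_tb(self, sub_tt):
        # GR(g) = (T − Tb)/θT(g): linear in T, zero exactly at Tb, every g
        for g in (0.2, 0.5, 0.8):
            temps = np.array([10.0, 14.0, 18.0])
            rates = np.array(
                [1.0 / tt_quantile_times(sub_tt, T, [g])[0] for T in temps]
            )
            slope, intercept = np.polyfit(temps, rates, 1)
            assert -intercept / slope == pytest.approx(sub_tt.Tb, abs=1e-9)

    def test_closed_loop_predict_extract_fit(self, sub_tt):
        # evaluate the forward model on a grid, read back the attained
        # fractions as percentiles, refit
        from pbtgerm.records import PercentileCurve

        curves = []
        for T in (10, 15, 20):
            t = np.linspace(0.05, 1.2, 30) * sub_tt.theta_T50 / (T - sub_tt.Tb) + 0.02
            g = predict_tt_time_course(sub_tt, T, t)
            keep = (g > 0.01) & (g < 0.99)
            curves.append(
                PercentileCurve(
                    (T, 0.0),
                    tuple(g[keep]),
                    tuple(t[keep]),
                    1.0,
                )
            )
        fit = fit_suboptimal_tt(curves)
        assert fit.Tb == pytest.approx(sub_tt.Tb, abs=1e-3)
        assert fit.theta_T50 == pytest.approx(sub_tt.theta_T50, abs=1e-3)
        assert fit.r2 == pytest.approx(1.0, abs=1e-6)
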