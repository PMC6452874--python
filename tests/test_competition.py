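"""Selection-coefficient estimation, qPCR calibration and doubling times."""

import math

import numpy as np
import pytest

from phasefit import (
    EnvironmentCondition,
    GeneratorParams,
    SelectionModel,
    doubling_time_from_growth_curve,
    estimate_selection_coefficient,
    fit_standard_curve,
    quantify_copies,
    simulate_competition_series,
)
from phasefit.competition import ct_from_copies, per_replicate_estimates

LN2 = math.log(2.0)
ENV = EnvironmentCondition("30C", "PLUS_URA", 2.7)


class TestStandardCurve:
    def test_perfect_dilution_series(self):
        # one decade per 3.3219 cycles corresponds to exact doubling (100%)
        x = np.array([2.0, 3.0, 4.0, 5.0, 6.0])
        ct = 40.0 - 3.3219 * x
        curve = fit_standard_curve(x, ct)
        assert curve.r2 == pytest.approx(1.0, abs=1e-12)
        assert curve.efficiency == pytest.approx(1.0, abs=1e-4)

    def test_efficiency_from_slope(self):
        x = np.array([2.0, 3.0, 4.0])
        curve = fit_standard_curve(x, 40.0 - 3.5 * x)
        assert curve.efficiency == pytest.approx(0.9307, abs=1e-4)

    def test_rejects_degenerate_input(self):
        with pytest.raises(ValueError):
            fit_standard_curve([1, 2], [30, 27])
        with pytest.raises(ValueError):
            fit_standard_curve([3, 3, 3], [30, 30.1, 29.9])

    def test_positive_slope_flagged_invalid(self):
        curve = fit_standard_curve([1, 2, 3], [10, 12, 14])
        assert not curve.valid
        with pytest.raises(ValueError):
            quantify_copies(20.0, curve)


class TestQuantifyCopies:
    def setup_method(self):
        self.curve = fit_standard_curve([2.0, 4.0, 6.0],
                                        40.0 - 3.3219 * np.array([2.0, 4.0, 6.0]))

    def test_ct_at_intercept_is_one_copy(self):
        assert quantify_copies(self.curve.intercept, self.curve) == pytest.approx(1.0)

    def test_printed_example(self):
        assert quantify_copies(20.0, self.curve) == pytest.approx(1.049e6, rel=1e-3)

    def test_one_slope_unit_is_tenfold(self):
        a = quantify_copies(25.0, self.curve)
        b = quantify_copies(25.0 + self.curve.slope, self.curve)
        assert b / a == pytest.approx(10.0, rel=1e-12)

    def test_round_trip_identity(self):
        copies = np.array([10.0, 1e3, 2.5e6])
        back = quantify_copies(ct_from_copies(copies, self.curve), self.curve)
        assert np.allclose(back, copies, rtol=1e-9)


class TestSelectionEstimate:
    def test_collinear_points(self):
        res = estimate_selection_coefficient([0.0, 10.0, 20.0], [0.0, 1.0, 2.0])
        assert res.slope_log2 == pytest.approx(0.1, abs=1e-12)
        assert res.S == pytest.approx(0.1 * LN2, abs=1e-12)
        assert res.r2 == pytest.approx(1.0)

    def test_flat_ratios_give_zero_s(self):
        res = estimate_selection_coefficient([0.0, 10.0, 20.0, 30.0], [0.0] * 4)
        assert res.S == pytest.approx(0.0, abs=1e-14)
        assert res.se_S == pytest.approx(0.0, abs=1e-12)

    def test_s_is_ln2_times_slope(self):
        res = estimate_selection_coefficient([0, 5, 10, 20], [0.1, 0.6, 0.9, 2.1])
        assert res.S == res.slope_log2 * LN2
        assert res.se_S == res.se_slope * LN2

    def test_generator_round_trip(self):
        # noiseless series with a 0.0793 doublings/h growth-rate gap
        p = GeneratorParams(omega_agg=0.4793, omega_sol=0.4, noise_sd_log2=0.0)
        res = SelectionModel.from_series(simulate_competition_series(p, ENV)).fit()
        assert res.S == pytest.approx(0.0550, abs=1e-4)
        assert abs(res.S - LN2 * 0.0793) < 1e-10

    def test_exact_recovery_noise_free(self):
        for d_omega in (0.25, -0.05, 0.0, 0.0793):
            p = GeneratorParams(omega_agg=0.4 + d_omega, omega_sol=0.4,
                                noise_sd_log2=0.0)
            res = SelectionModel.from_series(simulate_competition_series(p, ENV)).fit()
            assert abs(res.S - LN2 * d_omega) < 1e-10

    def test_scale_equivariance_minutes_vs_hours(self):
        t_h = np.array([0.0, 17.0, 34.0, 51.0])
        y = np.array([0.0, 1.4, 2.9, 4.4])
        per_h = estimate_selection_coefficient(t_h, y).S
        per_min = estimate_selection_coefficient(t_h * 60.0, y).S
        assert per_min * 60.0 == pytest.approx(per_h, rel=1e-12)

    def test_pooling_replicates(self):
        p1 = GeneratorParams(omega_agg=0.5, omega_sol=0.4, noise_sd_log2=0.05, seed=1)
        p2 = GeneratorParams(omega_agg=0.5, omega_sol=0.4, noise_sd_log2=0.05, seed=2)
        series = [simulate_competition_series(p1, ENV, replicate=0),
                  simulate_competition_series(p2, ENV, replicate=1)]
        pooled = SelectionModel.from_series(series).fit()
        assert pooled.n_points == 14
        per_rep = per_replicate_estimates(series)
        assert len(per_rep) == 2
        assert per_rep["S_mean"].iloc[0] == pytest.approx(per_rep["S_per_h"].mean())

    def test_rejects_degenerate_times(self):
        with pytest.raises(ValueError):
            SelectionModel([5.0, 5.0], [0.0, 1.0])

    def test_statistical_recovery_across_seeds(self):
        # with log2 noise sd 0.1 on the 7-point grid, the estimator is
        # unbiased and its reported se matches the sampling spread
        d_omega = 0.0793
        true_s = LN2 * d_omega
        est, ses = [], []
        for seed in range(200):
            p = GeneratorParams(omega_agg=0.4 + d_omega, omega_sol=0.4,
                                noise_sd_log2=0.1, seed=seed)
            r = SelectionModel.from_series(simulate_competition_series(p, ENV)).fit()
            est.append(r.S)
            ses.append(r.se_S)
        est = np.array(est)
        se_of_mean = est.std(ddof=1) / np.sqrt(est.size)
        assert abs(est.mean() - true_s) < 2 * se_of_mean
        assert abs(np.mean(ses) - est.std(ddof=1)) < 0.25 * est.std(ddof=1)


class TestDoublingTime:
    def test_exact_exponential(self):
        t = np.arange(0.0, 12.5, 1.0)
        res = doubling_time_from_growth_curve(t, 0.02 * 2 ** (t / 2.7))
        assert res.grew
        assert res.tau == pytest.approx(2.7, rel=0.01)

    def test_logistic_exponential_phase_rate(self):
        t = np.arange(0.0, 14.0, 0.5)
        K, r = 1.0, LN2 / 2.0
        od = 0.02 * K / (0.02 + (K - 0.02) * np.exp(-r * t))
        res = doubling_time_from_growth_curve(t, od)
        assert res.tau == pytest.approx(2.0, rel=0.05)

    def test_flat_curve_flags_no_growth(self):
        t = np.arange(0.0, 10.0, 1.0)
        res = doubling_time_from_growth_curve(t, np.full_like(t, 0.3))
        assert not res.grew and res.tau is None

    def test_input_validation(self):
        with pytest.raises(ValueError):
            doubling_time_from_growth_curve([0, 1, 2], [0.1, 0.2, 0.4])
        with pytest.raises(ValueError):
            doubling_time_from_growth_curve(np.arange(6.0), [0.1, 0.2, 0.0, 0.4, 0.5, 0.6])
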