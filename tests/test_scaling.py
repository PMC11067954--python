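import numpy as np
import pytest

from cellmotion import (FitError, InsufficientDataError, ScalingCurve,
                        correlation_regime, dfa_curve, fit_powerlaw, msd_curve,
                        rmsf_curve, shuffle_surrogate)
from cellmotion.simulate import WalkerSpec, generate_fgn, generate_walker
from conftest import dfa_bruteforce


class TestFitPowerlaw:
    def test_recovers_planted_exponent_exactly(self):
        lags = np.unique(np.logspace(0, 2, 20).astype(int))
        curve = ScalingCurve(lags=lags, fluctuation=3.0 * lags**0.7, method="rmsf")
        fit = fit_powerlaw(curve)
        assert fit.exponent == pytest.approx(0.7, abs=1e-9)
        assert fit.intercept == pytest.approx(np.log10(3.0), abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_flat_curve_has_zero_exponent(self):
        lags = np.arange(1, 11, dtype=float)
        curve = ScalingCurve(lags=lags, fluctuation=np.full(10, 2.5), method="msd")
        assert fit_powerlaw(curve).exponent == pytest.approx(0.0, abs=1e-12)

    def test_zero_entries_excluded(self):
        lags = np.unique(np.logspace(0, 2, 15).astype(int))
        f = 2.0 * lags**0.5
        f[3] = 0.0
        fit = fit_powerlaw(ScalingCurve(lags=lags, fluctuation=f, method="rmsf"))
        assert fit.n_points == len(lags) - 1
        assert fit.exponent == pytest.approx(0.5, abs=1e-9)

    def test_all_zero_curve_rejected(self):
        curve = ScalingCurve(lags=np.arange(1, 11, dtype=float),
                             fluctuation=np.zeros(10), method="dfa")
        with pytest.raises(FitError):
            fit_powerlaw(curve)


class TestRmsf:
    def test_pure_drift_gives_zero_fluctuation(self):
        ramp = 0.3 * np.arange(512.0)
        curve = rmsf_curve(ramp)
        np.testing.assert_allclose(curve.fluctuation, 0.0, atol=1e-9)

    def test_uncorrelated_walk_alpha_near_half(self):
        exps = []
        for seed in range(30):
            w = generate_walker(WalkerSpec(kind="brownian", n_frames=3600, seed=seed))
            exps.append(fit_powerlaw(rmsf_curve(w.x)).exponent)
        assert abs(np.median(exps) - 0.5) <= 0.1

    def test_fbm_alpha_matches_hurst(self):
        exps = []
        for seed in range(20):
            w = generate_walker(WalkerSpec(kind="fbm", hurst=0.75, n_frames=3600,
                                           seed=seed))
            exps.append(fit_powerlaw(rmsf_curve(w.x)).exponent)
        assert abs(np.median(exps) - 0.75) <= 0.1

    def test_short_series_rejected(self):
        with pytest.raises(InsufficientDataError):
            rmsf_curve(np.arange(32.0))


class TestMsd:
    def test_ballistic_slope_two(self):
        w = generate_walker(WalkerSpec(kind="ballistic", heading=1.1, seed=0))
        assert fit_powerlaw(msd_curve(w)).exponent == pytest.approx(2.0, abs=0.02)

    def test_brownian_slope_one(self):
        exps = []
        for seed in range(30):
            w = generate_walker(WalkerSpec(kind="brownian", n_frames=3600, seed=seed))
            exps.append(fit_powerlaw(msd_curve(w)).exponent)
        assert abs(np.median(exps) - 1.0) <= 0.1

    def test_position_shuffled_slope_near_zero(self):
        w = generate_walker(WalkerSpec(kind="fbm", hurst=0.75, seed=2))
        rng = np.random.default_rng(0)
        pos = np.column_stack([shuffle_surrogate(w.x, rng),
                               shuffle_surrogate(w.y, rng)])
        assert abs(fit_powerlaw(msd_curve(pos)).exponent) <= 0.05


class TestDfa:
    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(8)
        series = np.cumsum(rng.standard_normal(1024))
        for order in (1, 2):
            curve = dfa_curve(series, detrend_order=order)
            ref = dfa_bruteforce(series, curve.lags, order=order)
            np.testing.assert_allclose(curve.fluctuation, ref, atol=1e-10)

    def test_iid_gamma_near_half(self):
        rng = np.random.default_rng(3)
        exps = [fit_powerlaw(dfa_curve(rng.standard_normal(3600))).exponent
                for _ in range(30)]
        assert abs(np.median(exps) - 0.5) <= 0.1

    def test_fbm_positions_gamma_is_hurst_plus_one(self):
        exps = []
        for seed in range(20):
            w = generate_walker(WalkerSpec(kind="fbm", hurst=0.8, seed=seed))
            exps.append(fit_powerlaw(dfa_curve(w.x)).exponent)
        assert abs(np.median(exps) - 1.8) <= 0.15

    def test_constant_series_fit_rejected(self):
        curve = dfa_curve(np.full(512, 1.23))
        with pytest.raises(FitError):
            fit_powerlaw(curve)

    def test_short_series_rejected(self):
        with pytest.raises(InsufficientDataError):
            dfa_curve(np.arange(128.0))


class TestCorrelationRegime:
    def test_noiseless_powerlaw_spans_whole_curve(self):
        lags = np.unique(np.logspace(0, 3, 40).astype(int))
        curve = ScalingCurve(lags=lags, fluctuation=lags**0.7, method="rmsf")
        fit = fit_powerlaw(curve, fit_range=(1, 30))
        l_max, minutes = correlation_regime(curve, fit, dt=0.5)
        assert l_max == lags[-1]
        assert minutes == pytest.approx(lags[-1] * 0.5 / 60)

    def test_piecewise_curve_crossover_detected(self):
        lags = np.unique(np.logspace(0, 3.5, 60).astype(int))
        f = np.where(lags <= 1000, lags**0.7, 1000.0**0.7)  # power law then flat
        curve = ScalingCurve(lags=lags, fluctuation=f, method="rmsf")
        fit = fit_powerlaw(curve, fit_range=(1, 100))
        l_max, _ = correlation_regime(curve, fit, dt=0.5)
        assert 900 <= l_max <= 1300

    def test_move_step_to_minutes_arithmetic(self):
        # 1125 steps at dt = 0.5 s is 9.375 min
        lags = np.unique(np.logspace(0, np.log10(1125), 30).astype(int))
        curve = ScalingCurve(lags=lags, fluctuation=lags**0.72, method="rmsf")
        fit = fit_powerlaw(curve, fit_range=(1, 50))
        l_max, minutes = correlation_regime(curve, fit, dt=0.5)
        assert l_max == 1125
        assert minutes == pytest.approx(9.375)


class TestShuffleCollapse:
    def test_surrogate_exponents_in_null_regimes(self):
        w = generate_walker(WalkerSpec(kind="fbm", hurst=0.8, seed=17))
        rng = np.random.default_rng(99)
        alphas, gammas, betas = [], [], []
        inc = np.diff(w.x)
        for _ in range(10):
            path = np.concatenate([[w.x[0]], w.x[0] + np.cumsum(shuffle_surrogate(inc, rng))])
            alphas.append(fit_powerlaw(rmsf_curve(path)).exponent)
            pos = np.column_stack([shuffle_surrogate(w.x, rng),
                                   shuffle_surrogate(w.y, rng)])
            betas.append(fit_powerlaw(msd_curve(pos)).exponent)
            gammas.append(fit_powerlaw(dfa_curve(shuffle_surrogate(w.x, rng))).exponent)
        assert abs(np.median(alphas) - 0.5) <= 0.15
        assert abs(np.median(gammas) - 0.5) <= 0.15
        assert abs(np.median(betas)) <= 0.05
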