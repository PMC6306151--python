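import numpy as np
import pytest
from statsmodels.stats.diagnostic import acorr_ljungbox

from itsmc.arima_forecast import (
    ArimaFit,
    ArimaOrder,
    default_grid,
    fit_arima,
    fitted_values,
    forecast,
    log_transform,
    one_step_rmse,
    sample_acf,
    sample_pacf,
    select_order,
)
from itsmc.synthetic_data import SyntheticConfig, simulate_latent


def simulate_ar1(phi, n, rng, sigma=1.0, mean=0.0):
    c = SyntheticConfig(
        n_periods=n,
        intervention_index=n // 2,
        baseline_log_level=mean,
        ar_coefs=(phi,),
        innovation_sd=sigma,
    )
    return simulate_latent(c, rng)


class TestLogTransform:
    def test_ones(self):
        assert np.allclose(log_transform([1, 1, 1]), [0, 0, 0])

    def test_hundred(self):
        assert log_transform([100])[0] == pytest.approx(np.log(100))

    def test_zero_without_shift_errors(self):
        with pytest.raises(ValueError, match="positive shift"):
            log_transform([0, 5])

    def test_zero_with_shift(self):
        out = log_transform([0, 5], shift=0.5)
        assert np.allclose(out, [np.log(0.5), np.log(5.5)])


class TestAcfPacf:
    def test_acf_lag0_is_one(self, rng):
        x = rng.normal(size=50)
        assert sample_acf(x, 10)[0] == 1.0
        assert sample_pacf(x, 10)[0] == 1.0

    def test_ar1_acf_matches_theory(self, rng):
        x = simulate_ar1(0.6, 5000, rng)
        acf = sample_acf(x, 3)
        for k in (1, 2, 3):
            assert abs(acf[k] - 0.6**k) < 0.05

    def test_ar1_pacf_cuts_off_after_lag1(self, rng):
        x = simulate_ar1(0.6, 5000, rng)
        pacf = sample_pacf(x, 5)
        assert abs(pacf[1] - 0.6) < 0.05
        assert np.all(np.abs(pacf[2:]) < 0.05)

    def test_white_noise_within_bartlett_bands(self):
        # pooled over replicates: ~95% of white-noise ACF lags fall inside
        # the 2/sqrt(n) Bartlett band, comfortably above the 90% threshold
        n = 2000
        inside = []
        for seed in range(10):
            x = np.random.default_rng(seed).normal(size=n)
            acf = sample_acf(x, 20)
            inside.extend(np.abs(acf[1:]) < 2 / np.sqrt(n))
        assert np.mean(inside) >= 0.90

    def test_constant_series_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            out = sample_acf(np.ones(30), 5)
        assert out[0] == 1.0
        assert np.isnan(out[1:]).all()

    def test_short_series_rejected(self, rng):
        with pytest.raises(ValueError, match="max_lag"):
            sample_acf(rng.normal(size=5), 10)


class TestFitArima:
    def test_arima000_is_mean_and_biased_variance(self, rng):
        y = rng.normal(5.0, 2.0, 80)
        fit = fit_arima(y, (0, 0, 0))
        assert fit.converged
        assert fit.constant == pytest.approx(y.mean(), rel=1e-4)
        assert fit.sigma2 == pytest.approx(y.var(), rel=1e-3)

    def test_arima010_residuals_are_first_differences(self, rng):
        y = rng.normal(size=40).cumsum()
        fit = fit_arima(y, (0, 1, 0))
        assert fit.constant is None  # no drift when d = 1
        assert np.allclose(fit.residuals, np.diff(y), atol=1e-10)
        assert fit.sigma2 == pytest.approx(np.mean(np.diff(y) ** 2), rel=1e-3)

    def test_ar1_parameter_recovery_averaged(self):
        # average over a few long series: SE of the mean ~0.0075, so +-0.04
        # is a >5 sigma bound
        estimates = [
            fit_arima(simulate_ar1(0.7, 3000, np.random.default_rng(s)), (1, 0, 0)).ar_coefs[0]
            for s in (0, 1, 2)
        ]
        assert abs(np.mean(estimates) - 0.7) < 0.04

    def test_series_too_short_errors(self):
        with pytest.raises(ValueError, match="too short"):
            fit_arima([1.0, 2.0, 3.0], (1, 1, 1))

    def test_fitted_values_complement_residuals(self, rng):
        y = rng.normal(size=30).cumsum()
        fit = fit_arima(y, (0, 1, 1))
        assert np.allclose(fitted_values(fit) + fit.residuals, y[1:])

    def test_refit_is_deterministic(self, rng):
        y = simulate_ar1(0.4, 60, rng)
        a = fit_arima(y, (1, 0, 1))
        b = fit_arima(y, (1, 0, 1))
        assert np.array_equal(a.ar_coefs, b.ar_coefs)
        assert np.array_equal(a.ma_coefs, b.ma_coefs)
        assert a.sigma2 == b.sigma2


class TestOneStepRmse:
    def _fit_with_residuals(self, resid):
        return ArimaFit(
            order=ArimaOrder(0, 0, 0),
            ar_coefs=np.array([]),
            ma_coefs=np.array([]),
            constant=0.0,
            sigma2=1.0,
            residuals=np.asarray(resid, dtype=float),
            loglik=0.0,
            converged=True,
            log_series=np.asarray(resid, dtype=float),
        )

    def test_zero_residuals(self):
        assert one_step_rmse(self._fit_with_residuals([0.0, 0.0])) == 0.0

    def test_analytic_value(self):
        assert one_step_rmse(self._fit_with_residuals([3.0, 4.0])) == pytest.approx(
            np.sqrt(12.5)
        )

    def test_matches_brute_force_on_real_fit(self, rng):
        y = simulate_ar1(0.5, 60, rng)
        fit = fit_arima(y, (1, 0, 0))
        oracle = np.sqrt(np.mean(np.asarray(fit.residuals) ** 2))
        assert one_step_rmse(fit) == pytest.approx(oracle)

    def test_nonconverged_rejected(self):
        fit = self._fit_with_residuals([1.0])
        fit.converged = False
        with pytest.raises(ValueError, match="non-converged"):
            one_step_rmse(fit)


class TestSelectOrder:
    def test_default_grid_has_17_candidates(self):
        grid = default_grid()
        assert len(grid) == 17
        assert ArimaOrder(0, 0, 0) not in grid
        assert ArimaOrder(1, 1, 0) in grid
        assert ArimaOrder(0, 1, 2) in grid

    def test_single_candidate_chosen(self, rng):
        y = simulate_ar1(0.3, 40, rng)
        result = select_order(y, [ArimaOrder(1, 0, 0)])
        assert result.chosen == ArimaOrder(1, 0, 0)
        assert len(result.candidates) == 1

    def test_chosen_minimizes_rmse(self, rng):
        y = simulate_ar1(0.5, 50, rng)
        result = select_order(y, [(1, 0, 0), (0, 1, 1), (2, 0, 0)])
        converged = [c for c in result.candidates if c.converged]
        best = min(c.rmse for c in converged)
        chosen_rmse = next(
            c.rmse for c in result.candidates if c.order == result.chosen
        )
        assert chosen_rmse <= best + 1e-9

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            select_order(simulate_ar1(0.3, 40, rng), [])

    def test_report_table_is_reproducible(self, rng):
        y = simulate_ar1(0.4, 45, rng)
        grid = [(1, 0, 0), (0, 1, 1), (1, 1, 0)]
        a = select_order(y, grid).to_frame()
        b = select_order(y, grid).to_frame()
        assert a.equals(b)

    def test_selection_detects_differencing(self):
        # series simulated from ARIMA(1,1,0): d=1 candidates should win
        # in most replicates (reduced grid keeps runtime reasonable)
        grid = [(1, 0, 0), (0, 0, 1), (1, 1, 0), (0, 1, 1)]
        hits = 0
        n_rep = 100
        for seed in range(n_rep):
            r = np.random.default_rng(1000 + seed)
            increments = simulate_ar1(0.5, 200, r)
            y = np.cumsum(increments)
            result = select_order(y, grid)
            hits += result.chosen.d == 1
        assert hits / n_rep >= 0.80


class TestForecast:
    def test_random_walk_closed_form(self, rng):
        y = rng.normal(size=40).cumsum()
        fit = fit_arima(y, (0, 1, 0))
        path = forecast(fit, y, horizon=6)
        sigma = np.sqrt(fit.sigma2)
        assert np.allclose(path.log_means, y[-1], atol=1e-8)
        assert np.allclose(path.log_ses, sigma * np.sqrt(np.arange(1, 7)), atol=1e-8)

    def test_white_noise_closed_form(self, rng):
        y = rng.normal(3.0, 1.0, 60)
        fit = fit_arima(y, (0, 0, 0))
        path = forecast(fit, y, horizon=5)
        assert np.allclose(path.log_means, fit.constant, atol=1e-8)
        assert np.allclose(path.log_ses, np.sqrt(fit.sigma2), atol=1e-8)

    def test_ar1_matches_iterated_oracle(self, rng):
        y = simulate_ar1(0.5, 100, rng, mean=2.0)
        fit = fit_arima(y, (1, 0, 0))
        path = forecast(fit, y, horizon=8)
        # brute-force iterated one-step forecasts
        c, phi = fit.constant, fit.ar_coefs[0]
        level = y[-1]
        oracle = []
        for _ in range(8):
            level = c + phi * (level - c)
            oracle.append(level)
        assert np.allclose(path.log_means, oracle, atol=1e-8)

    def test_ses_nondecreasing_for_d1_models(self, rng):
        y = rng.normal(size=50).cumsum()
        for order in [(0, 1, 0), (1, 1, 0), (0, 1, 2)]:
            fit = fit_arima(y, order)
            path = forecast(fit, y, horizon=10)
            assert np.all(np.diff(path.log_ses) >= -1e-12)

    def test_median_counts_is_exp_of_means(self, rng):
        y = rng.normal(3.0, 0.5, 40)
        fit = fit_arima(y, (0, 0, 0))
        path = forecast(fit, y, horizon=3)
        assert np.allclose(path.median_counts, np.exp(path.log_means))

    def test_apply_to_new_series(self, rng):
        y = simulate_ar1(0.5, 80, rng, mean=1.0)
        fit = fit_arima(y, (1, 0, 0))
        other = simulate_ar1(0.5, 40, rng, mean=1.0)
        path = forecast(fit, other, horizon=3)
        c, phi = fit.constant, fit.ar_coefs[0]
        expected = [c + phi**h * (other[-1] - c) for h in (1, 2, 3)]
        assert np.allclose(path.log_means, expected, atol=1e-8)

    def test_invalid_horizon(self, rng):
        fit = fit_arima(rng.normal(size=30), (0, 0, 0))
        with pytest.raises(ValueError, match="horizon"):
            forecast(fit, None, horizon=0)


class TestResidualWhiteness:
    def test_well_specified_model_passes_ljung_box(self):
        # spec-level property: on data simulated from the fitted order, the
        # residuals should show no autocorrelation in >= 90% of replicates
        passes = 0
        n_rep = 50
        for seed in range(n_rep):
            r = np.random.default_rng(seed)
            y = simulate_ar1(0.5, 100, r)
            fit = fit_arima(y, (1, 0, 0))
            lb = acorr_ljungbox(fit.residuals, lags=[8])
            passes += lb["lb_pvalue"].iloc[0] > 0.05
        assert passes / n_rep >= 0.90


class TestCoefficientRecovery:
    def test_arma_coefficients_within_three_mc_ses(self):
        # mean of replicate estimates within 3 MC standard errors of truth
        phi_true = 0.6
        estimates = []
        for seed in range(60):
            r = np.random.default_rng(2000 + seed)
            y = simulate_ar1(phi_true, 300, r)
            fit = fit_arima(y, (1, 0, 0))
            estimates.append(fit.ar_coefs[0])
        estimates = np.array(estimates)
        mc_se = estimates.std(ddof=1) / np.sqrt(len(estimates))
        assert abs(estimates.mean() - phi_true) < 3 * mc_se + 0.01
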