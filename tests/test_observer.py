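"""Observer stage: probit GLM, psychometric fits, PSS/WSS, sampling."""

import numpy as np
import pytest
from scipy.stats import norm

from mcd.observer import (
    GLMFit,
    extract_pss_wss,
    fit_probit_glm,
    fit_sin_psychometric,
    fit_sj_curve,
    fit_toj_curve,
    predict_prob,
    sample_responses,
)


def _binomial_data(x, a, b, n, seed):
    rng = np.random.default_rng(seed)
    p = norm.cdf(a + b * np.asarray(x))
    k = rng.binomial(n, p)
    return k, np.full(len(x), n)


class TestProbitGLM:
    def test_recovers_known_coefficients_within_3se(self):
        x = np.linspace(-2, 2, 15)
        a, b = 0.3, 1.2
        k, n = _binomial_data(x, a, b, 40, seed=11)  # 600 trials
        fit = fit_probit_glm(x, k, n)
        assert abs(fit.intercept - a) < 3 * fit.se_intercept
        assert abs(fit.slope - b) < 3 * fit.se_slope

    def test_negating_regressor_negates_slope_only(self):
        x = np.linspace(-2, 2, 15)
        k, n = _binomial_data(x, 0.2, 0.9, 50, seed=5)
        f1 = fit_probit_glm(x, k, n)
        f2 = fit_probit_glm(-x, k, n)
        assert f2.slope == pytest.approx(-f1.slope, rel=1e-6)
        assert f2.intercept == pytest.approx(f1.intercept, rel=1e-6)

    def test_separated_data_stays_finite(self):
        x = np.array([-1.0, -0.5, 0.5, 1.0])
        k = np.array([0, 0, 20, 20])
        n = np.full(4, 20)
        fit = fit_probit_glm(x, k, n)
        assert np.isfinite(fit.intercept) and np.isfinite(fit.slope)
        assert fit.slope > 0

    def test_invalid_counts_error(self):
        with pytest.raises(ValueError):
            fit_probit_glm([0.0, 1.0], [5, 3], [4, 4])
        with pytest.raises(ValueError):
            fit_probit_glm([1.0, 1.0], [1, 1], [4, 4])

    def test_predict_prob_properties(self):
        glm = GLMFit(intercept=0.4, slope=2.0)
        assert predict_prob(glm, -0.2) == pytest.approx(0.5)
        xs = np.linspace(-3, 3, 50)
        p = predict_prob(glm, xs)
        assert np.all(np.diff(p) > 0) and np.all((p > 0) & (p < 1))
        flat = GLMFit(intercept=0.4, slope=0.0)
        assert np.ptp(predict_prob(flat, xs)) == 0


class TestTOJCurve:
    def test_parameter_recovery(self):
        lags = np.linspace(-0.4, 0.4, 15)
        mu, sigma = 0.03, 0.12
        p = 0.02 + 0.96 * norm.cdf((lags - mu) / sigma)
        rng = np.random.default_rng(3)
        k = rng.binomial(40, p)
        fit = fit_toj_curve(lags, k / 40, np.full(15, 40))
        assert fit.params["mu"] == pytest.approx(mu, abs=0.03)
        assert fit.params["sigma"] == pytest.approx(sigma, rel=0.3)
        assert fit.r_squared > 0.9

    def test_no_lapse_midpoint_at_half(self):
        lags = np.linspace(-0.4, 0.4, 15)
        p = norm.cdf(lags / 0.1)
        fit = fit_toj_curve(lags, p, np.full(15, 200))
        assert fit.predict(np.array([fit.params["mu"]]))[0] == pytest.approx(0.5, abs=0.01)

    def test_too_few_levels_error(self):
        with pytest.raises(ValueError):
            fit_toj_curve([0, 0.1, 0.2, 0.3], [0.1, 0.4, 0.6, 0.9], [10] * 4)


class TestSJCurve:
    def test_symmetric_components_peak_at_midpoint(self):
        lags = np.linspace(-0.5, 0.5, 21)
        mu1, mu2, s = -0.2, 0.2, 0.08
        p = norm.cdf((lags - mu1) / s) - norm.cdf((lags - mu2) / s)
        fit = fit_sj_curve(lags, p, np.full(21, 200))
        summary = extract_pss_wss(fit)
        assert summary.pss == pytest.approx((mu1 + mu2) / 2, abs=0.02)

    def test_recovery_from_binomial_samples(self):
        lags = np.linspace(-0.5, 0.5, 15)
        p = norm.cdf((lags + 0.15) / 0.07) - norm.cdf((lags - 0.25) / 0.12)
        rng = np.random.default_rng(9)
        k = rng.binomial(40, p)
        fit = fit_sj_curve(lags, k / 40, np.full(15, 40))
        assert fit.r_squared > 0.85

    def test_flat_profile_errors(self):
        lags = np.linspace(-0.5, 0.5, 15)
        with pytest.raises(ValueError):
            fit_sj_curve(lags, np.full(15, 0.4), np.full(15, 20))


class TestSinusoidCurve:
    def test_recovery_at_experiment_scale_within_3se(self):
        phases = np.arange(40) * 2 * np.pi / 40
        alpha, beta = 0.3, 1.1
        p = norm.cdf(alpha + beta * np.sin(2 * phases - 0.441))
        rng = np.random.default_rng(21)
        k = rng.binomial(15, p)  # 600 trials: the periodic-design count
        fit = fit_sin_psychometric(phases, k / 15, np.full(40, 15))
        assert abs(fit.params["alpha"] - alpha) < 3 * fit.se["alpha"]
        assert abs(fit.params["beta"] - beta) < 3 * fit.se["beta"]

    def test_zero_beta_gives_flat_curve(self):
        phases = np.arange(40) * 2 * np.pi / 40
        p = norm.cdf(0.25 * np.ones(40))
        fit = fit_sin_psychometric(phases, p, np.full(40, 500))
        pred = fit.predict(phases)
        assert np.ptp(pred) < 0.02
        assert fit.params["alpha"] == pytest.approx(0.25, abs=0.02)

    def test_fitted_curve_has_period_pi(self):
        phases = np.arange(40) * 2 * np.pi / 40
        p = norm.cdf(0.2 + 0.8 * np.sin(2 * phases - 0.441))
        fit = fit_sin_psychometric(phases, p, np.full(40, 100))
        grid = np.linspace(0, np.pi, 200)
        np.testing.assert_allclose(fit.predict(grid), fit.predict(grid + np.pi), atol=1e-12)

    def test_partial_cycle_errors(self):
        phases = np.linspace(0, 1.0, 20)
        with pytest.raises(ValueError):
            fit_sin_psychometric(phases, np.full(20, 0.5), np.full(20, 10))


class TestPSSWSS:
    def test_cumulative_gaussian_closed_form(self):
        from mcd.observer import PsychFit

        fit = PsychFit(family="toj_cum_gauss", params={"mu": 0.05, "sigma": 0.2, "gamma": 0.0, "lambda": 0.0})
        s = extract_pss_wss(fit)
        assert s.pss == pytest.approx(0.05)
        assert s.wss == pytest.approx(norm.ppf(0.75) * 0.2, rel=1e-6)

    def test_sj_half_width_at_half_maximum(self):
        from mcd.observer import PsychFit

        fit = PsychFit(
            family="sj_diff_gauss",
            params={"mu1": -0.1, "mu2": 0.1, "sigma1": 0.05, "sigma2": 0.05},
        )
        s = extract_pss_wss(fit)
        assert s.pss == pytest.approx(0.0, abs=1e-3)
        assert s.wss > 0

    def test_flat_fit_errors(self):
        from mcd.observer import PsychFit

        fit = PsychFit(family="toj_cum_gauss", params={"mu": 0, "sigma": 1, "gamma": 0.5, "lambda": 0.5})
        with pytest.raises(ValueError):
            extract_pss_wss(fit)


class TestSampleResponses:
    def test_degenerate_probabilities(self):
        t0 = sample_responses([0.0] * 5, 20, seed=1)
        t1 = sample_responses([1.0] * 5, 20, seed=1)
        assert t0["response"].sum() == 0
        assert t1["response"].sum() == len(t1)

    def test_empirical_rate_matches_probability(self):
        table = sample_responses([0.3], 10_000, seed=4)
        rate = table["response"].mean()
        assert abs(rate - 0.3) < 3 * np.sqrt(0.3 * 0.7 / 10_000)

    def test_reproducible_by_seed(self):
        a = sample_responses([0.5, 0.7], [50, 50], seed=9, levels=[0.0, 1.0])
        b = sample_responses([0.5, 0.7], [50, 50], seed=9, levels=[0.0, 1.0])
        assert a.equals(b)
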