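"""Fourier, bootstrap, reverse-correlation and rate-normalization analyses."""

import numpy as np
import pytest

from mcd.analysis import (
    bootstrap_spectrum_ci,
    classification_image,
    discretize_model_output,
    normalize_by_rate,
    permutation_null_sd,
    psychometric_spectrum,
)
from mcd.detector import mcd_respond
from mcd.stimuli import ImpulseSeqSpec, gen_impulse_pair


class TestSpectrum:
    def test_single_tone_recovered_exactly(self):
        phi = np.arange(40) * 2 * np.pi / 40
        curve = 0.5 + 0.3 * np.sin(2 * phi)
        spec = psychometric_spectrum(curve)
        assert spec.dominant_nondc() == 2
        assert spec.amplitudes[2] == pytest.approx(0.3, abs=1e-12)
        others = np.delete(spec.amplitudes[1:], 1)
        assert np.all(others < 1e-9)

    def test_constant_curve_has_no_ac_power(self):
        spec = psychometric_spectrum(np.full(40, 0.7))
        assert np.all(spec.amplitudes[1:] < 1e-12)
        assert spec.amplitudes[0] == pytest.approx(0.7)

    def test_dft_invertibility(self):
        rng = np.random.default_rng(2)
        curve = rng.random(40)
        X = np.fft.rfft(curve)
        np.testing.assert_allclose(np.fft.irfft(X, n=40), curve, atol=1e-9)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            psychometric_spectrum([0.5, 0.5])


class TestBootstrapCI:
    @staticmethod
    def _curve():
        phi = np.arange(40) * 2 * np.pi / 40
        from scipy.stats import norm

        return norm.cdf(0.3 + 1.0 * np.sin(2 * phi - 0.441))

    def test_point_estimate_inside_own_ci(self):
        p = self._curve()
        spec = psychometric_spectrum(p)
        lo, hi = bootstrap_spectrum_ci(p, n_per_phase=15, n_boot=500, seed=1)
        k = 2
        assert lo[k] <= spec.amplitudes[k] <= hi[k]

    def test_width_shrinks_like_sqrt_n(self):
        p = self._curve()
        lo15, hi15 = bootstrap_spectrum_ci(p, 15, n_boot=1500, seed=2)
        lo60, hi60 = bootstrap_spectrum_ci(p, 60, n_boot=1500, seed=3)
        ratio = (hi15[2] - lo15[2]) / (hi60[2] - lo60[2])
        assert ratio == pytest.approx(2.0, rel=0.3)

    def test_ci_monotone_in_level(self):
        p = self._curve()
        lo99, hi99 = bootstrap_spectrum_ci(p, 15, n_boot=1500, level=0.99, seed=4)
        lo95, hi95 = bootstrap_spectrum_ci(p, 15, n_boot=1500, level=0.95, seed=4)
        assert np.all(lo99 <= lo95 + 1e-12) and np.all(hi99 >= hi95 - 1e-12)

    def test_invalid_level_errors(self):
        with pytest.raises(ValueError):
            bootstrap_spectrum_ci(self._curve(), 15, level=1.5)


def _impulse_trials(n_trials, seed0=0, fs=1000.0):
    return [
        gen_impulse_pair(ImpulseSeqSpec(rng_seed=seed0 + i), fs)
        for i in range(n_trials)
    ]


class TestClassificationImage:
    def test_random_responses_give_flat_image(self):
        pairs = _impulse_trials(60)
        rng = np.random.default_rng(8)
        responses = rng.integers(0, 2, 60)
        if responses.min() == responses.max():
            responses[0] = 1 - responses[0]
        img = classification_image(pairs, responses, max_lag=0.3, smoothing_bins=3)
        sd = permutation_null_sd(pairs, responses, max_lag=0.3, n_permutations=200, seed=1, smoothing_bins=3)
        frac_extreme = np.mean(np.abs(img.weights) > 3 * sd)
        assert frac_extreme < 0.05

    def test_planted_synchrony_observer_recovered_at_zero_lag(self):
        pairs = _impulse_trials(300)
        # observer says "common cause" when clicks and flashes co-occur within 25 ms
        scores = []
        for v, a in pairs:
            c = np.correlate(a.values, v.values, mode="full")
            mid = len(v) - 1
            scores.append(c[mid - 25 : mid + 26].sum())
        responses = discretize_model_output(scores, "median")
        img = classification_image(pairs, responses, max_lag=0.3, smoothing_bins=3)
        peak_lag = img.lags[np.argmax(img.weights)]
        assert abs(peak_lag) <= 0.03

    def test_label_flip_negates_image(self):
        pairs = _impulse_trials(40)
        responses = np.r_[np.ones(20, int), np.zeros(20, int)]
        img = classification_image(pairs, responses, max_lag=0.2)
        flipped = classification_image(pairs, 1 - responses, max_lag=0.2)
        np.testing.assert_allclose(flipped.weights, -img.weights, atol=1e-12)

    def test_single_class_errors(self):
        pairs = _impulse_trials(10)
        with pytest.raises(ValueError):
            classification_image(pairs, np.ones(10, int), max_lag=0.2)

    def test_mcd_driven_responses_have_central_peak(self):
        # impulse-train regime: faster constants than the step-stimulus
        # defaults (the detector is retuned for high-rate stimuli)
        from mcd.detector import MCDParams

        params = MCDParams(tau_v=0.025, tau_a=0.02, tau_av=0.15)
        pairs = _impulse_trials(150)
        outs = [mcd_respond(v, a, params).corr_mean for v, a in pairs]
        responses = discretize_model_output(outs, "median")
        img = classification_image(pairs, responses, max_lag=0.4, smoothing_bins=3)
        center = np.abs(img.lags) <= 0.1
        assert abs(img.lags[np.argmax(img.weights)]) <= 0.1
        assert img.weights[center].mean() > img.weights.mean()


class TestDiscretize:
    def test_median_split_balanced(self):
        labels = discretize_model_output(np.arange(10.0), "median")
        assert labels.sum() == 5

    def test_all_equal_errors(self):
        with pytest.raises(ValueError):
            discretize_model_output(np.ones(10), "median")

    def test_threshold_matches_glm_criterion(self):
        from mcd.observer import GLMFit, predict_prob

        glm = GLMFit(intercept=-1.0, slope=2.0)
        x = np.linspace(-2, 2, 21)
        labels = discretize_model_output(x, criterion=-glm.intercept / glm.slope)
        np.testing.assert_array_equal(labels, (predict_prob(glm, x) >= 0.5).astype(int))


class TestRateNormalization:
    def test_identity_and_scaling(self):
        assert normalize_by_rate(3.0, 1.0) == 3.0
        assert normalize_by_rate(3.0, 2.0) == pytest.approx(normalize_by_rate(3.0, 1.0) / 2)
        with pytest.raises(ValueError):
            normalize_by_rate(1.0, 0.0)

    def test_equalizes_across_stimulus_rates(self):
        # matched correlation structure: the auditory train is the visual
        # train delayed by 10 ms; impulse-regime constants keep the
        # per-event responses sparse so output grows linearly with rate
        from mcd.detector import MCDParams

        params = MCDParams(tau_v=0.015, tau_a=0.015, tau_av=0.05)
        outs = {}
        for rate in (8.0, 14.0):
            vals = []
            for seed in range(12):
                v, _ = gen_impulse_pair(ImpulseSeqSpec(duration=2.0, rate=rate, rng_seed=seed), 1000.0)
                a = v.with_values(np.roll(v.values, 10))
                vals.append(mcd_respond(v, a, params).corr_mean)
            outs[rate] = normalize_by_rate(float(np.mean(vals)), rate)
        hi, lo = max(outs.values()), min(outs.values())
        assert (hi - lo) / hi < 0.25
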