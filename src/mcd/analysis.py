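"""Model-free analyses: Fourier spectra, bootstrap CIs, classification
images, and rate normalization.

A periodic psychometric curve sampled at equally spaced phase lags over
one full cycle is naturally summarized by its discrete Fourier spectrum:
the frequency (in cycles per period, cpp) of the dominant non-DC
component diagnoses frequency doubling without assuming any curve shape.
Confidence intervals on the amplitudes come from a parametric bootstrap
that resamples the per-phase binomial counts.

Reverse correlation turns trial-by-trial stochastic stimuli plus binary
responses into a classification image: the difference between the mean
audiovisual cross-correlogram of "yes" and "no" trials, as a function of
audiovisual lag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .timeseries import TimeSeries

__all__ = [
    "Spectrum",
    "ClassificationImage",
    "psychometric_spectrum",
    "bootstrap_spectrum_ci",
    "classification_image",
    "permutation_null_sd",
    "discretize_model_output",
    "normalize_by_rate",
]


@dataclass
class Spectrum:
    """One-sided amplitude/phase spectrum of a periodic curve.

    frequencies are integer cycles per period (0 = DC); amplitudes are
    sinusoid amplitudes (2|X_k|/N for interior bins), phases radians.
    """

    frequencies: np.ndarray
    amplitudes: np.ndarray
    phases: np.ndarray

    def dominant_nondc(self) -> int:
        """Frequency (cpp) of the largest non-DC amplitude."""
        return int(self.frequencies[1:][np.argmax(self.amplitudes[1:])])


@dataclass
class ClassificationImage:
    """Reverse-correlation weights over the audiovisual lag axis."""

    lags: np.ndarray  # seconds, symmetric about 0
    weights: np.ndarray


def _amplitudes(curves: np.ndarray) -> np.ndarray:
    """Sinusoid amplitudes of the rfft of curves along the last axis."""
    n = curves.shape[-1]
    X = np.fft.rfft(curves, axis=-1)
    amp = np.abs(X) / n
    amp[..., 1:] *= 2.0
    if n % 2 == 0:
        amp[..., -1] /= 2.0  # Nyquist bin is not doubled
    return amp


def psychometric_spectrum(p_by_phase) -> Spectrum:
    """DFT of a psychometric curve over one full cycle of phase lags.

    The curve must be sampled at equally spaced phases covering exactly
    one cycle (the grid itself is implicit; points are assumed
    consecutive), so the DFT bins fall on integer cycles per period.
    """
    p = np.asarray(p_by_phase, dtype=float)
    if p.ndim != 1 or len(p) < 4:
        raise ValueError("need a 1-D curve with at least 4 phase samples")
    if not np.all(np.isfinite(p)):
        raise ValueError("curve contains non-finite values")
    X = np.fft.rfft(p)
    return Spectrum(
        frequencies=np.arange(len(X)),
        amplitudes=_amplitudes(p[None, :])[0],
        phases=np.angle(X),
    )


def bootstrap_spectrum_ci(
    p_by_phase,
    n_per_phase: int,
    n_boot: int = 2000,
    level: float = 0.99,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Percentile bootstrap CIs for the per-frequency amplitudes.

    At each phase the observed proportion is treated as a binomial rate
    with n_per_phase trials; counts are resampled n_boot times, spectra
    recomputed, and the (1−level)/2 percentile bounds returned per
    frequency bin.
    """
    if not (0 < level < 1):
        raise ValueError("level must be in (0, 1)")
    if n_per_phase < 1:
        raise ValueError("n_per_phase must be >= 1")
    p = np.asarray(p_by_phase, dtype=float)
    rng = np.random.default_rng(seed)
    counts = rng.binomial(n_per_phase, p, size=(n_boot, len(p)))
    amps = _amplitudes(counts / n_per_phase)
    alpha = (1.0 - level) / 2.0
    lo = np.quantile(amps, alpha, axis=0)
    hi = np.quantile(amps, 1.0 - alpha, axis=0)
    return lo, hi


def _cross_correlogram(v: np.ndarray, a: np.ndarray, max_bins: int) -> np.ndarray:
    """Cross-correlogram of two equally long trains for lags −max..+max bins.

    Positive lag means the auditory train is shifted later than the
    visual one (matching the package-wide lag sign convention).
    """
    full = np.correlate(a, v, mode="full")  # index len-1 is zero lag
    c = len(v) - 1
    return full[c - max_bins : c + max_bins + 1]


def classification_image(
    stim_pairs: list[tuple[TimeSeries, TimeSeries]],
    responses,
    max_lag: float,
    smoothing_bins: int | None = None,
) -> ClassificationImage:
    """Reverse-correlation classification image from stochastic stimuli.

    image(lag) = mean(correlogram | response=1) − mean(correlogram | response=0)

    smoothing_bins, if given, applies a moving average of that many bins
    (odd; used for low-rate designs; high-rate analyses leave it None).
    """
    responses = np.asarray(responses, dtype=int)
    if len(stim_pairs) != len(responses):
        raise ValueError("one response per stimulus pair required")
    if len(np.unique(responses)) < 2:
        raise ValueError("need at least 2 trials in each response class")
    fs = stim_pairs[0][0].sample_rate
    max_bins = int(round(max_lag * fs))
    grams = np.array([
        _cross_correlogram(v.values, a.values, max_bins) for v, a in stim_pairs
    ])
    img = grams[responses == 1].mean(axis=0) - grams[responses == 0].mean(axis=0)
    if smoothing_bins is not None:
        if smoothing_bins < 1 or smoothing_bins % 2 == 0:
            raise ValueError("smoothing_bins must be a positive odd integer")
        kernel = np.ones(smoothing_bins) / smoothing_bins
        img = np.convolve(img, kernel, mode="same")
    lags = np.arange(-max_bins, max_bins + 1) / fs
    return ClassificationImage(lags=lags, weights=img)


def permutation_null_sd(
    stim_pairs: list[tuple[TimeSeries, TimeSeries]],
    responses,
    max_lag: float,
    n_permutations: int = 1000,
    seed: int = 0,
    smoothing_bins: int | None = None,
) -> np.ndarray:
    """Per-lag standard deviation of the classification image under
    response-label shuffling (a flatness null)."""
    rng = np.random.default_rng(seed)
    responses = np.asarray(responses, dtype=int)
    images = []
    for _ in range(n_permutations):
        perm = rng.permutation(responses)
        if len(np.unique(perm)) < 2:
            continue
        images.append(classification_image(stim_pairs, perm, max_lag, smoothing_bins).weights)
    return np.std(np.array(images), axis=0)


def discretize_model_output(values, criterion="median") -> np.ndarray:
    """Binarize continuous model outputs per trial.

    criterion='median' splits at the sample median; a float splits at
    that threshold (labels are 1 where value >= threshold).
    """
    v = np.asarray(values, dtype=float)
    if criterion == "median":
        if np.ptp(v) == 0:
            raise ValueError("all model outputs equal: median split undefined")
        thr = float(np.median(v))
        labels = (v > thr).astype(int)
        if labels.min() == labels.max():
            # ties at the median: put exact-median trials in the lower class
            labels = (v >= thr).astype(int)
        return labels
    thr = float(criterion)
    return (v >= thr).astype(int)


def normalize_by_rate(corr_mean: float, rate: float) -> float:
    """Divide the detector's correlation output by the stimulus event rate.

    Equalizes responses across sequences that differ in total stimulus
    energy (the detector output grows with the number of events).
    """
    if not (rate > 0):
        raise ValueError("rate must be positive")
    return corr_mean / rate
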