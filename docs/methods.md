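# Methods

## Model

The detector is a temporal correlator for audiovisual intensity
envelopes. Each modality's envelope is filtered by a unimodal front-end;
the two filtered signals are combined by two mirror-symmetric subunits,
each multiplying one modality by a low-pass-filtered copy of the other;
the subunit outputs are multiplied (and square-rooted) into a
correlation trace and subtracted into a signed lag trace; both traces
are averaged over a temporal window into scalar decision variables; a
probit GLM turns a decision variable into a response probability.

Front-end variants:

* **biphasic** (default): `f(t) = (t/τ)·e^{−t/τ}·(1 − t²/(n!τ²))` with
  n = 3, followed by squaring. The bracketed term is divided by n!; with
  n = 3 this makes the kernel integrate to exactly zero, which the
  transient-channel semantics require (constants must be invisible).
  For n ≠ 3 the analytic kernel is not zero-DC and is used as written.
* **quadrature**: the full transient detector — two band-pass kernels
  `f_n(t) = (t/τ)^n·e^{−t/τ}·[1/n! − (t/τ)²/(n+2)!]` with n = 6 (fast)
  and n = 9 (slow), 90° out of phase; the two filtered signals are
  squared, summed, and square-root compressed. Zero-DC for every n.
* **sustained**: low-pass `(t/τ)·e^{−t/τ}` (DC gain τ), no squaring.
  Used as the contrast model: it tracks intensity, so it distinguishes
  step polarity where the transient variants cannot.

Sign conventions, fixed package-wide and pinned by golden tests:
positive stimulus lag means the auditory event occurs later; with
`u1 = Sf_V·(Sf_A ∗ f_av)` and `u2 = Sf_A·(Sf_V ∗ f_av)`, the mean of
`u2 − u1` is positive when vision leads (auditory event later).

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| τ_V | 0.070 | s | visual band-pass constant (step/periodic regime) |
| τ_A | 0.055 | s | auditory band-pass constant |
| τ_av | 0.674 | s | subunit low-pass (binding window scale) |
| n | 3 | — | biphasic negative-lobe exponent |
| sample rate | 1000 | Hz | simulation grid (configurable everywhere) |

The unimodal constants are stimulus-regime dependent: the defaults suit
step and periodic envelopes. For impulse-train stimuli (clicks/flashes
at 5–14 events/s) the detector is retuned to faster constants — the
tests and examples use τ_V = 0.025, τ_A = 0.020, τ_av = 0.15 s for
classification images, and τ = 0.015/0.015/0.05 s for cross-rate
comparisons, where per-event responses stay sparse and the output grows
linearly with event rate (the regime in which dividing the correlation
output by stimulus rate equalizes responses across rates).

## Numerical choices

* **Convolution.** Causal, `dt`-scaled (sample-rate-invariant
  approximation of the continuous integral), with steady-state
  initial-condition padding: the signal is assumed to have sat at its
  first value since long before recording began. This mirrors the
  experiments (baseline/pedestal on during the intertrial interval) and
  is what makes polarity invariance and baseline-blindness hold to
  machine precision rather than approximately.
* **Kernel truncation and DC.** Low-pass kernels are truncated at 10τ;
  band-pass kernels decay like `t^{n+2}e^{−t/τ}` and get 32τ (biphasic)
  and 45τ (quadrature). The residual discrete DC of a sampled, truncated
  band-pass kernel is removed by rescaling its negative lobe, which
  preserves the kernel's zero start, lobe structure and zero-crossing
  while making the discrete filter exactly band-pass.
* **Kernels are unnormalized** (used as printed); absolute gain is
  absorbed by the fitted GLM, so decision variables are z-scored across
  stimulus levels before entering the observer.
* **Subunit products** clamp the (analytically non-negative) low-pass
  outputs at zero to remove FFT round-off of order 1e-24.
* **Averaging window** defaults to the full stimulus duration;
  per-experiment windows are a parameter of `mcd_respond`.

## Stimuli

The generators are deterministic given their spec (plus a seed where
events are random) and produce intensity envelopes, not carrier
waveforms (the detector operates on envelopes).

* **Step design**: 15 lags in [−0.4, 0.4] s × 4 polarity conditions
  (on/off steps in each modality; off-steps mirror on-steps about the
  baseline) × 10 repetitions. Trial extent is 1.5 s on each side of the
  step so the slowest kernel (τ_av) has decayed.
* **Periodic design**: square wave, period 2 s, three cycles in 6 s,
  oscillating symmetrically about the pedestal with a shared
  raised-cosine window ramping the modulation depth; 40 crossmodal phase
  shifts over a full cycle × 15 repetitions, with the global phase of
  the stimulus rotating across repetitions. The symmetric-about-pedestal
  construction makes a π phase shift an exact mirror about the pedestal,
  so the half-period symmetry c(φ) = c(φ+π) of the model synchrony curve
  is exact up to edge-sample quantization (~0.2% of the curve range).
* **Impulse trains**: uniform event times (low-rate, e.g. 5 clicks +
  5 flashes in 1 s) or jittered regular grids at a target rate
  (high-rate, 8–14 events/s over 2 s).
* **Onset/offset, detection, and AM stimuli**: step envelopes lagged at
  one named edge; pedestals with brief increments at a parametric SOA;
  and pedestal-plus-ramps envelopes with small (6% of pedestal)
  sinusoidal amplitude modulation whose frequency/phase is manipulated.
  AM ramp/plateau defaults (0.1 s ramps, 1 s plateau, pedestal 1.0) are
  package choices; they reproduce the qualitative regime in which all
  frequency/phase cells remain strongly positively correlated once
  pedestal and ramps are included.

## Observer and psychometrics

The observer is a binomial probit GLM fitted by IRLS (statsmodels); on
perfect separation it falls back to a lightly ridge-penalized (1e-6)
maximum-likelihood fit so estimates stay finite. Descriptive
psychometric families, all fitted by binomial maximum likelihood with
multi-start L-BFGS-B:

* TOJ: cumulative Gaussian with two lapse asymptotes (bounds [0, 0.1]).
  PSS = lag at chance; WSS = half the distance between the 25% and 75%
  lags (0.6745σ without lapses).
* SJ: difference of two cumulative Gaussians (asymmetric bell),
  parameterized with an ordered pair of means. PSS = lag of the maximum;
  WSS = half-width at half-maximum, both evaluated numerically.
* Periodic SJ: `p(synch|φ) = Φ(α + β·sin(f·φ + θ))` with f and θ fixed
  (per the Fourier-first procedure: estimate f and θ from the amplitude
  spectrum of the observed curve, then fit only α and β). This is a
  probit GLM on the regressor `sin(fφ+θ)`, and is fitted as one.

Goodness of fit is the squared Pearson correlation between fitted and
observed proportions. The adaptive-Bayesian fitting procedure used in
the experimental literature is not re-implemented; parameter recovery,
not optimizer identity, is the criterion, and the recovery tests check
coefficients against 3 standard errors at the designs' native trial
counts (600 per participant).

## Analyses

* **Spectra**: one-sided DFT amplitudes (sinusoid convention, 2|X_k|/N
  interior bins) of a psychometric curve sampled at equally spaced
  phases over exactly one cycle; frequencies are integer cycles per
  period.
* **Bootstrap CIs**: percentile intervals from binomial resampling of
  the per-phase counts (default 2000 resamples). Nominal 99% intervals
  for the 2 cpp amplitude achieve ≈98.5% empirical coverage at the
  periodic design's 15 trials/phase (measured over 2000 synthetic
  repetitions in the acceptance suite).
* **Classification images**: per-trial audiovisual cross-correlograms
  (positive lag = audition later), mean difference between response
  classes; an optional moving-average smoothing (3 bins by default for
  low-rate designs, none for high-rate analyses); a permutation null
  (label shuffling) provides a flatness reference.
* **Rate normalization**: correlation output divided by event rate,
  appropriate in the sparse-response regime described above.

## Fitting

Temporal constants are estimated by maximizing a profile objective:
for each candidate (τ_V, τ_A, τ_av), decision variables are recomputed
for every stimulus cell, the per-(task, condition) GLMs are refit, and
the summed binomial log-likelihood (or the Pearson correlation between
observed and predicted proportions, for reverse-correlation datasets)
scores the candidate. The landscape over (τ_V, τ_A) is irregular with a
ridge of near-equivalent solutions, so the optimizer is a
derivative-free simplex search restarted from ≥4 log-spaced starts, and
the meaningful recovery criterion is reaching the generating model's
objective (within 1%), not matching individual constants.

## Population demo

Spatial cue integration uses a population of detector units on an
azimuth grid. Reliability is carried by the width of each cue's spatial
likelihood profile plus trial-to-trial jitter of the cue center; the
receptive-field width (0.5° default) adds in quadrature and is kept
small relative to cue widths. Input gains are the square roots of the
intended likelihood profiles because the front-end squaring doubles
exponents; the correlation output then factorizes exactly into
(temporal correlation of the shared envelope) × (product of spatial
likelihoods), an identity validated against explicit per-unit runs.
After divisive normalization the population activity is the
grid-discretized bimodal posterior, and the population-vector decode
reproduces the closed-form optimal-integration predictions: the decoded
mean is the reliability-weighted average of the cue locations and the
decoded spread² is σ_V²σ_A²/(σ_V²+σ_A²), both within 5% over 2000
seeded trials at the default geometry (cues at ±10°, σ_V = 3°,
σ_A = 4°).

## What the synthetic data do and do not show

The fixture generator reproduces the factorial *designs* (lags, phases,
conditions, repetition counts) and samples responses from the model
observer itself. Passing recovery tests therefore demonstrates that the
pipeline is self-consistent — parameters that generated the data are
recovered at the stated trial counts — not that the model fits any
empirical dataset. Real-data features not emulated: lapses and response
biases beyond the GLM, participant heterogeneity, serial dependencies,
and sensory noise upstream of the decision stage (noise is late,
entering only through the GLM).

## Known limitations

* The synchrony maxima of the periodic design sit at +9°/+189° on the
  40-point grid, not 0°/180°: with τ_V > τ_A the visual transient
  response lags the auditory one by ≈ √6·(τ_V−τ_A) ≈ 37 ms, so peak
  synchrony requires a compensating auditory delay. The idealized
  0°/180° description holds exactly only for matched unimodal filters;
  the displacement is the same mechanism by which the model predicts a
  nonzero point of subjective simultaneity.
* Temporal constants are regime-dependent and must be chosen (or
  refitted) per stimulus family; no single setting spans step stimuli
  and high-rate impulse trains.
* The quadrature variant shares the simplified variant's temporal
  constants per modality; no independent calibration is provided.
* Spatial parameters of the population demo (grid extent, RF width) are
  package choices; the demo is a computational existence proof, not a
  fit to localization data.
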