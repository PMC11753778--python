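"""Unimodal temporal front-ends: sustained and transient channels.

Sustained channels track stimulus intensity and are modelled as causal
low-pass filters with impulse response ``(t/τ)·exp(−t/τ)``. Transient
channels respond only to *changes* in intensity: a biphasic band-pass
filter followed by a squaring nonlinearity yields an unsigned response,
blind to the polarity of the change. The "quadrature" variant is the
full Adelson–Bergen transient detector: two band-pass filters 90° out
of phase, squared, summed and square-root compressed.

All kernels are returned unnormalized; absolute gain is absorbed by
the observer-stage GLM downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial

import numpy as np
from scipy.signal import fftconvolve

from .timeseries import TimeSeries

__all__ = [
    "ChannelParams",
    "biphasic_irf",
    "lowpass_irf",
    "quadrature_irfs",
    "transient_transform",
    "sustained_transform",
    "causal_convolve",
]

#: default sampling rate (Hz) used throughout when none is given
DEFAULT_SAMPLE_RATE = 1000.0

#: low-pass kernels are truncated at this many time constants
KERNEL_SUPPORT_TAUS = 10.0

#: band-pass kernels decay like t^(n+2)·exp(−t/τ); they need a longer
#: support before the residual tail mass is negligible
BIPHASIC_SUPPORT_TAUS = 32.0
QUADRATURE_SUPPORT_TAUS = 45.0


@dataclass(frozen=True)
class ChannelParams:
    """Parameters of a unimodal temporal channel.

    tau : filter time constant in seconds (> 0)
    n_exponent : integer controlling the negative lobe of the biphasic
        kernel (default 3; the default makes the simplified biphasic
        kernel integrate to exactly zero)
    variant : 'sustained', 'biphasic' or 'quadrature'
    """

    tau: float
    n_exponent: int = 3
    variant: str = "biphasic"

    def __post_init__(self) -> None:
        if not (self.tau > 0):
            raise ValueError("tau must be positive")
        if self.n_exponent < 1:
            raise ValueError("n_exponent must be >= 1")
        if self.variant not in ("sustained", "biphasic", "quadrature"):
            raise ValueError(f"unknown channel variant {self.variant!r}")


def _zero_dc(values: np.ndarray) -> np.ndarray:
    """Rescale the negative lobe so the sampled kernel sums to zero.

    The analytic kernels integrate to zero, but sampling and truncation
    leave a small DC residual that would let constants leak through the
    band-pass stage. Scaling the negative lobe preserves the kernel's
    start at zero, its lobe structure and zero-crossing location.
    """
    pos = values[values > 0].sum()
    neg = -values[values < 0].sum()
    if pos > 0 and neg > 0:
        values = np.where(values < 0, values * (pos / neg), values)
    return values


def _kernel_grid(tau: float, duration: float | None, sample_rate: float) -> np.ndarray:
    if not (tau > 0):
        raise ValueError("tau must be positive")
    if not (sample_rate > 0):
        raise ValueError("sample_rate must be positive")
    if duration is None:
        duration = KERNEL_SUPPORT_TAUS * tau
    n = int(round(duration * sample_rate))
    if n < 1:
        raise ValueError("kernel duration shorter than one sample")
    return np.arange(n) / sample_rate


def biphasic_irf(
    params: ChannelParams | float,
    duration: float | None = None,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
) -> TimeSeries:
    """Biphasic (band-pass) impulse response of the simplified transient channel.

    f(t) = (t/τ)·exp(−t/τ)·(1 − t²/(n!·τ²))

    One positive lobe followed by one negative lobe, zero crossing at
    t = τ·√(n!). At the default exponent n = 3 the kernel has exactly
    zero DC gain, so constant inputs are annihilated; the residual DC
    of the sampled, truncated kernel is removed so the discrete filter
    is exactly band-pass (see the methods note).
    """
    if not isinstance(params, ChannelParams):
        params = ChannelParams(tau=float(params), variant="biphasic")
    if duration is None:
        duration = BIPHASIC_SUPPORT_TAUS * params.tau
    t = _kernel_grid(params.tau, duration, sample_rate)
    x = t / params.tau
    values = x * np.exp(-x) * (1.0 - x**2 / factorial(params.n_exponent))
    if params.n_exponent == 3:
        values = _zero_dc(values)  # analytic DC is zero only for n = 3
    return TimeSeries(values=values, sample_rate=sample_rate)


def lowpass_irf(
    tau: float,
    duration: float | None = None,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
) -> TimeSeries:
    """Low-pass impulse response (t/τ)·exp(−t/τ); DC gain τ, maximum at t = τ."""
    t = _kernel_grid(tau, duration, sample_rate)
    x = t / tau
    return TimeSeries(values=x * np.exp(-x), sample_rate=sample_rate)


def _quadrature_kernel(t: np.ndarray, tau: float, n: int) -> np.ndarray:
    x = t / tau
    return x**n * np.exp(-x) * (1.0 / factorial(n) - x**2 / factorial(n + 2))


def quadrature_irfs(
    tau_bp: float,
    duration: float | None = None,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
) -> tuple[TimeSeries, TimeSeries]:
    """Fast (n=6) and slow (n=9) quadrature band-pass kernels.

    f_n(t) = (t/τ)^n·exp(−t/τ)·[1/n! − (t/τ)²/(n+2)!]

    Both integrate to zero for any n (the two gamma integrals cancel),
    and the slow kernel peaks later than the fast one. As with the
    simplified biphasic kernel, residual discrete DC is removed.
    """
    # the n=9 kernel peaks near t = 9τ, so quadrature kernels need more room
    if duration is None:
        duration = QUADRATURE_SUPPORT_TAUS * tau_bp
    t = _kernel_grid(tau_bp, duration, sample_rate)
    fast = TimeSeries(values=_zero_dc(_quadrature_kernel(t, tau_bp, 6)), sample_rate=sample_rate)
    slow = TimeSeries(values=_zero_dc(_quadrature_kernel(t, tau_bp, 9)), sample_rate=sample_rate)
    return fast, slow


def causal_convolve(signal: TimeSeries, kernel: TimeSeries) -> TimeSeries:
    """Causal convolution of a signal with an impulse-response kernel.

    The signal is assumed to have sat at its initial value since long
    before recording began (steady-state initial condition): the array
    is left-padded with values[0] over the kernel support before the
    full convolution, then trimmed back to the input grid. This mirrors
    the experimental situation — the baseline/pedestal is on during the
    intertrial interval — and makes the band-pass channels exactly blind
    to the pre-stimulus baseline. The dt scaling makes the result a
    sample-rate-invariant approximation of the continuous integral.
    """
    if not np.isclose(signal.sample_rate, kernel.sample_rate):
        raise ValueError("signal and kernel sample rates differ")
    k = len(kernel)
    ext = np.concatenate([np.full(k - 1, signal.values[0]), signal.values])
    full = fftconvolve(ext, kernel.values)
    return signal.with_values(full[k - 1 : k - 1 + len(signal)] * signal.dt)


def transient_transform(signal: TimeSeries, params: ChannelParams) -> TimeSeries:
    """Unsigned transient response of a unimodal channel.

    biphasic:   Sf = (s ∗ f_bp)²
    quadrature: Sf = sqrt((s ∗ f₆)² + (s ∗ f₉)²)

    Output is non-negative everywhere and identical for intensity
    increments and decrements of equal size (polarity invariance).
    """
    if params.variant == "sustained":
        raise ValueError("sustained channels have no transient transform; use sustained_transform")
    if params.variant == "biphasic":
        kernel = biphasic_irf(params, sample_rate=signal.sample_rate)
        out = causal_convolve(signal, kernel).values ** 2
    else:  # quadrature
        fast, slow = quadrature_irfs(params.tau, sample_rate=signal.sample_rate)
        rf = causal_convolve(signal, fast).values
        rs = causal_convolve(signal, slow).values
        out = np.sqrt(rf**2 + rs**2)
    return signal.with_values(out)


def sustained_transform(signal: TimeSeries, tau: float) -> TimeSeries:
    """Sustained-channel response: low-pass filtering of the envelope.

    Steady-state response to a constant input c approaches c·τ (the
    kernel is used unnormalized, DC gain τ).
    """
    kernel = lowpass_irf(tau, sample_rate=signal.sample_rate)
    return causal_convolve(signal, kernel)
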