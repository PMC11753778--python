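"""The multisensory correlation detector (MCD) unit.

Two mirror-symmetric subunits each multiply one modality's transient
response with the low-pass-filtered transient response of the other
modality. Because of this asymmetric filtering each subunit is tuned
to one temporal order of the signals. The subunit outputs are combined
into

* a correlation trace  MCD_corr(t) = sqrt(u1·u2)  (magnitude of the
  local audiovisual correlation), and
* a lag trace          MCD_lag(t)  = u2 − u1      (signed temporal order).

Both traces are averaged over a temporal window to give the two scalar
decision variables feeding the observer stage.

Sign convention: with u1 = Sf_v·(Sf_a ∗ f_av) and u2 = Sf_a·(Sf_v ∗ f_av),
the delayed branch of u2 carries vision, so the mean lag output is
positive when vision leads (i.e. the auditory event comes later).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .channels import ChannelParams, lowpass_irf, causal_convolve, sustained_transform, transient_transform
from .timeseries import TimeSeries

__all__ = ["MCDParams", "MCDOutput", "mcd_subunits", "mcd_corr", "mcd_lag", "mcd_respond"]


@dataclass(frozen=True)
class MCDParams:
    """Temporal constants and front-end variant of an MCD unit.

    Defaults are the step/periodic-stimulus constants:
    τ_v = 0.070 s, τ_a = 0.055 s, τ_av = 0.674 s, n = 3.
    """

    tau_v: float = 0.070
    tau_a: float = 0.055
    tau_av: float = 0.674
    n_exponent: int = 3
    variant: str = "biphasic"

    def __post_init__(self) -> None:
        for name in ("tau_v", "tau_a", "tau_av"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be positive")
        if self.variant not in ("biphasic", "quadrature", "sustained"):
            raise ValueError(f"unknown MCD variant {self.variant!r}")

    def channel(self, modality: str) -> ChannelParams:
        tau = {"v": self.tau_v, "a": self.tau_a}[modality]
        return ChannelParams(tau=tau, n_exponent=self.n_exponent, variant=self.variant)

    def replace(self, **kw) -> "MCDParams":
        from dataclasses import replace

        return replace(self, **kw)


@dataclass
class MCDOutput:
    """Time-resolved MCD responses and their window means."""

    corr_trace: TimeSeries
    lag_trace: TimeSeries
    corr_mean: float
    lag_mean: float
    window_samples: int

    def to_csv(self, path) -> None:
        arr = np.column_stack([self.corr_trace.times, self.corr_trace.values, self.lag_trace.values])
        np.savetxt(path, arr, delimiter=",", header="time,corr,lag", comments="")


def front_end(signal: TimeSeries, params: MCDParams, modality: str) -> TimeSeries:
    """Apply the unimodal front-end named by ``params.variant``."""
    if params.variant == "sustained":
        tau = {"v": params.tau_v, "a": params.tau_a}[modality]
        return sustained_transform(signal, tau)
    return transient_transform(signal, params.channel(modality))


def mcd_subunits(sf_v: TimeSeries, sf_a: TimeSeries, tau_av: float) -> tuple[TimeSeries, TimeSeries]:
    """The two subunits of the correlator.

    u1(t) = Sf_v(t) · [Sf_a ∗ f_av](t)
    u2(t) = Sf_a(t) · [Sf_v ∗ f_av](t)
    """
    sf_v.require_same_grid(sf_a)
    kernel = lowpass_irf(tau_av, sample_rate=sf_v.sample_rate)
    # low-pass of a non-negative signal is non-negative; clamp fft roundoff
    a_delayed = np.clip(causal_convolve(sf_a, kernel).values, 0.0, None)
    v_delayed = np.clip(causal_convolve(sf_v, kernel).values, 0.0, None)
    u1 = sf_v.with_values(sf_v.values * a_delayed)
    u2 = sf_a.with_values(sf_a.values * v_delayed)
    return u1, u2


def mcd_corr(u1: TimeSeries, u2: TimeSeries) -> TimeSeries:
    """Correlation output sqrt(u1·u2), pointwise, non-negative."""
    u1.require_same_grid(u2)
    # tiny negative values can only come from a signed (non-transient) front-end
    if np.min(u1.values) < -1e-12 or np.min(u2.values) < -1e-12:
        raise ValueError("negative subunit values: correlation output requires a transient front-end")
    return u1.with_values(np.sqrt(np.clip(u1.values * u2.values, 0.0, None)))


def mcd_lag(u1: TimeSeries, u2: TimeSeries) -> TimeSeries:
    """Lag output u2 − u1; its sign encodes the temporal order of the signals."""
    u1.require_same_grid(u2)
    return u1.with_values(u2.values - u1.values)


def mcd_respond(
    stim_v: TimeSeries,
    stim_a: TimeSeries,
    params: MCDParams | None = None,
    window: tuple[float, float] | None = None,
) -> MCDOutput:
    """Run the full detector on an audiovisual stimulus pair.

    Parameters
    ----------
    stim_v, stim_a : TimeSeries
        Visual and auditory intensity envelopes on a shared grid.
    params : MCDParams
        Temporal constants and front-end variant (defaults used if None).
    window : (start, end) in seconds, optional
        Temporal window over which the traces are averaged; defaults to
        the full stimulus duration. Must lie inside the signal support.

    Returns
    -------
    MCDOutput with corr/lag traces and their window means.
    """
    if params is None:
        params = MCDParams()
    stim_v.require_same_grid(stim_a)
    sf_v = front_end(stim_v, params, "v")
    sf_a = front_end(stim_a, params, "a")
    u1, u2 = mcd_subunits(sf_v, sf_a, params.tau_av)
    if params.variant == "sustained":
        # signed front-end: the product under the sqrt may be negative,
        # use the signed square root so the correlation trace keeps its sign
        prod = u1.values * u2.values
        corr = u1.with_values(np.sign(prod) * np.sqrt(np.abs(prod)))
    else:
        corr = mcd_corr(u1, u2)
    lag = mcd_lag(u1, u2)

    t0, t1 = stim_v.start_time, stim_v.start_time + stim_v.duration
    if window is None:
        window = (t0, t1)
    w0, w1 = window
    if w0 < t0 - 1e-9 or w1 > t1 + 1e-9 or w1 <= w0:
        raise ValueError(f"window {window} outside signal support [{t0}, {t1}]")
    times = stim_v.times
    mask = (times >= w0 - 1e-12) & (times < w1 - 1e-12)
    n = int(mask.sum())
    if n < 1:
        raise ValueError("averaging window contains no samples")
    return MCDOutput(
        corr_trace=corr,
        lag_trace=lag,
        corr_mean=float(corr.values[mask].mean()),
        lag_mean=float(lag.values[mask].mean()),
        window_samples=n,
    )
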