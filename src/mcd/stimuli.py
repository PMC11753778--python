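"""Parametric audiovisual stimulus generators.

Every generator returns a pair of :class:`TimeSeries` (visual, auditory)
on a shared grid. Stimuli are intensity *envelopes*: carrier noise is
not modelled, since the detector operates on envelopes.

Families
--------
* step pairs        — intensity increments/decrements in all four polarity
                      combinations, with a parametric audiovisual lag
* periodic pairs    — square-wave modulation (period 2 s, three cycles)
                      under a shared raised-cosine window, with a
                      parametric crossmodal phase shift
* impulse sequences — random click/flash trains (low-rate uniform or
                      high-rate jittered-grid variants)
* onset/offset      — noise envelopes with step on- and offsets, lag
                      applied at one named edge
* detection pairs   — pedestal plus brief near-synchronous increments
* AM pairs          — pedestal with ramps and near-threshold sinusoidal
                      amplitude modulation (frequency/phase manipulated)

Sign convention: positive lag means the auditory event occurs later.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .channels import DEFAULT_SAMPLE_RATE
from .timeseries import TimeSeries

__all__ = [
    "StepStimSpec",
    "PeriodicStimSpec",
    "ImpulseSeqSpec",
    "AMStimSpec",
    "gen_step_pair",
    "gen_periodic_pair",
    "gen_impulse_pair",
    "gen_onset_offset_pair",
    "gen_detection_pair",
    "gen_am_pair",
    "pearson_corr",
]

STEP_CONDITIONS = ("on-on", "off-off", "on-off", "off-on")


@dataclass(frozen=True)
class StepStimSpec:
    """Step-pair stimulus: polarity condition and audiovisual lag.

    condition is '<visual>-<auditory>' with each part 'on' (increment)
    or 'off' (decrement); off steps mirror on steps about the baseline.
    Trial extent defaults to 1.5 s either side of the visual step so the
    slowest detector kernel (τ_av = 0.674 s) has decayed.
    """

    condition: str = "on-on"
    lag: float = 0.0
    baseline: float = 1.0
    amplitude: float = 1.0
    pre_duration: float = 1.5
    post_duration: float = 1.5

    def __post_init__(self) -> None:
        if self.condition not in STEP_CONDITIONS:
            raise ValueError(f"condition must be one of {STEP_CONDITIONS}")
        if abs(self.lag) >= min(self.pre_duration, self.post_duration):
            raise ValueError("durations must exceed |lag|")


@dataclass(frozen=True)
class PeriodicStimSpec:
    """Square-wave pair under a shared raised-cosine window.

    Defaults follow the periodic design: period 2 s, total duration 6 s
    (three full cycles), raised-cosine window of 6 s, and a crossmodal
    phase shift applied to the auditory square wave. A positive
    phase_shift delays the auditory wave. global_phase_offset rotates
    both square waves together (the window stays put).

    The square wave oscillates symmetrically about the pedestal and the
    raised-cosine window ramps the modulation *depth*: outside the
    window the signal sits at the pedestal (the intertrial state), and a
    π phase shift mirrors the signal exactly about the pedestal.
    """

    period: float = 2.0
    total_duration: float = 6.0
    phase_shift: float = 0.0
    global_phase_offset: float = 0.0
    pedestal: float = 0.5
    amplitude: float = 1.0
    window_duration: float = 6.0

    def __post_init__(self) -> None:
        cycles = self.total_duration / self.period
        if abs(cycles - round(cycles)) > 1e-9:
            raise ValueError("total_duration must be an integer multiple of period")


@dataclass(frozen=True)
class ImpulseSeqSpec:
    """Random click/flash trains.

    With rate=None event times are drawn uniformly over the duration
    (low-rate variant: e.g. five clicks and five flashes in 1 s). With a
    rate, events sit on a jittered regular grid at that rate
    (high-rate variant, 8–14 impulses/s over 2 s).
    """

    n_events_v: int = 5
    n_events_a: int = 5
    duration: float = 1.0
    rate: float | None = None
    rng_seed: int = 0
    pulse_width: float | None = None  # seconds; None = single sample

    def __post_init__(self) -> None:
        if self.n_events_v < 0 or self.n_events_a < 0:
            raise ValueError("event counts must be non-negative")
        if not (self.duration > 0):
            raise ValueError("duration must be positive")


@dataclass(frozen=True)
class AMStimSpec:
    """Sinusoidal amplitude-modulation pair with pedestal and ramps.

    Visual modulation frequency fixed (default 6 Hz, phase 0); auditory
    frequency 6–7 Hz and phase 0–360° manipulated. Modulation depth is
    a small fraction of the pedestal (default 6%).
    """

    f_v: float = 6.0
    f_a: float = 6.0
    phase_deg: float = 0.0
    pedestal: float = 1.0
    depth_fraction: float = 0.06
    ramp_duration: float = 0.1
    plateau_duration: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.depth_fraction < 1):
            raise ValueError("depth_fraction must be in [0, 1)")


def _grid(duration: float, sample_rate: float) -> np.ndarray:
    n = int(round(duration * sample_rate))
    if n < 1:
        raise ValueError("stimulus duration shorter than one sample")
    return np.arange(n) / sample_rate


def _step_trace(t: np.ndarray, t_step: float, polarity: str, baseline: float, amplitude: float) -> np.ndarray:
    on = np.where(t >= t_step, baseline + amplitude, baseline)
    if polarity == "on":
        return on
    return 2.0 * baseline - on  # mirror about the baseline


def gen_step_pair(spec: StepStimSpec, sample_rate: float = DEFAULT_SAMPLE_RATE) -> tuple[TimeSeries, TimeSeries]:
    """Step pair: visual step at pre_duration, auditory at pre_duration + lag."""
    t = _grid(spec.pre_duration + spec.post_duration, sample_rate)
    pol_v, pol_a = spec.condition.split("-")
    v = _step_trace(t, spec.pre_duration, pol_v, spec.baseline, spec.amplitude)
    a = _step_trace(t, spec.pre_duration + spec.lag, pol_a, spec.baseline, spec.amplitude)
    return TimeSeries(v, sample_rate), TimeSeries(a, sample_rate)


def _square(theta: np.ndarray) -> np.ndarray:
    """Unit square wave of a phase angle: 1 on the first half cycle, 0 on the second."""
    return (np.sin(theta) >= 0).astype(float)


def _raised_cosine(t: np.ndarray, duration: float) -> np.ndarray:
    w = np.zeros_like(t)
    inside = (t >= 0) & (t < duration)
    w[inside] = 0.5 * (1.0 - np.cos(2.0 * np.pi * t[inside] / duration))
    return w


def gen_periodic_pair(spec: PeriodicStimSpec, sample_rate: float = DEFAULT_SAMPLE_RATE) -> tuple[TimeSeries, TimeSeries]:
    """Windowed square-wave pair; the window is identical across modalities."""
    t = _grid(spec.total_duration, sample_rate)
    omega = 2.0 * np.pi / spec.period
    theta_v = omega * t + spec.global_phase_offset
    theta_a = theta_v - spec.phase_shift  # positive shift delays audition
    window = _raised_cosine(t, spec.window_duration)
    v = spec.pedestal + spec.amplitude * window * (_square(theta_v) - 0.5)
    a = spec.pedestal + spec.amplitude * window * (_square(theta_a) - 0.5)
    return TimeSeries(v, sample_rate), TimeSeries(a, sample_rate)


def _render_events(times: np.ndarray, duration: float, sample_rate: float, pulse_width: float | None) -> np.ndarray:
    n = int(round(duration * sample_rate))
    out = np.zeros(n)
    idx = np.clip(np.round(times * sample_rate).astype(int), 0, n - 1)
    if len(np.unique(idx)) < len(idx):
        raise ValueError("events denser than the sample grid")
    width = 1 if pulse_width is None else max(1, int(round(pulse_width * sample_rate)))
    for i in idx:
        out[i : i + width] = 1.0
    return out


def _uniform_times(rng: np.random.Generator, n: int, duration: float, min_sep: float) -> np.ndarray:
    # rejection-sample until all events are at least one sample apart
    for _ in range(1000):
        times = np.sort(rng.uniform(0.0, duration, size=n))
        if n < 2 or np.min(np.diff(times)) >= min_sep:
            return times
    raise ValueError("could not place events with the required separation")


def gen_impulse_pair(
    spec: ImpulseSeqSpec, sample_rate: float = DEFAULT_SAMPLE_RATE
) -> tuple[TimeSeries, TimeSeries]:
    """Random impulse trains; deterministic given the spec (seed included)."""
    rng = np.random.default_rng(spec.rng_seed)
    min_sep = 2.0 / sample_rate
    if spec.rate is None:
        tv = _uniform_times(rng, spec.n_events_v, spec.duration, min_sep)
        ta = _uniform_times(rng, spec.n_events_a, spec.duration, min_sep)
    else:
        n = int(round(spec.rate * spec.duration))
        grid = (np.arange(n) + 0.5) * spec.duration / n
        jitter = spec.duration / n / 2.0 - min_sep
        tv = grid + rng.uniform(-jitter, jitter, size=n)
        ta = grid + rng.uniform(-jitter, jitter, size=n)
    v = _render_events(tv, spec.duration, sample_rate, spec.pulse_width)
    a = _render_events(ta, spec.duration, sample_rate, spec.pulse_width)
    return TimeSeries(v, sample_rate), TimeSeries(a, sample_rate)


def gen_onset_offset_pair(
    lag: float,
    edge: str,
    plateau: float = 1.0,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    margin: float = 1.5,
    amplitude: float = 1.0,
) -> tuple[TimeSeries, TimeSeries]:
    """Envelopes that step up, hold, and step down; lag applied at one edge.

    edge='onset' lags the auditory onset (offsets synchronous);
    edge='offset' lags the auditory offset (onsets synchronous).
    Positive lag = the auditory edge occurs later.
    """
    if edge not in ("onset", "offset"):
        raise ValueError("edge must be 'onset' or 'offset'")
    if plateau <= abs(lag):
        raise ValueError("plateau must exceed |lag|")
    total = 2 * margin + plateau
    t = _grid(total, sample_rate)
    v_on, v_off = margin, margin + plateau
    a_on = v_on + (lag if edge == "onset" else 0.0)
    a_off = v_off + (lag if edge == "offset" else 0.0)
    v = amplitude * ((t >= v_on) & (t < v_off)).astype(float)
    a = amplitude * ((t >= a_on) & (t < a_off)).astype(float)
    return TimeSeries(v, sample_rate), TimeSeries(a, sample_rate)


def gen_detection_pair(
    soa: float,
    v_increment: float = 0.2,
    a_increment: float = 1.0,
    pedestal: float = 1.0,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    increment_duration: float = 0.01,
    margin: float = 1.5,
) -> tuple[TimeSeries, TimeSeries]:
    """Pedestal pair with brief intensity increments; auditory at t0 + soa."""
    if v_increment < 0 or a_increment < 0:
        raise ValueError("increments must be non-negative")
    total = 2 * margin + abs(soa) + increment_duration
    t = _grid(total, sample_rate)
    t0 = margin + max(0.0, -soa)
    v = np.full_like(t, pedestal)
    a = np.full_like(t, pedestal)
    v[(t >= t0) & (t < t0 + increment_duration)] += v_increment
    a[(t >= t0 + soa) & (t < t0 + soa + increment_duration)] += a_increment
    return TimeSeries(v, sample_rate), TimeSeries(a, sample_rate)


def _am_trace(
    t: np.ndarray, f: float, phase_rad: float, spec: AMStimSpec
) -> np.ndarray:
    r, p = spec.ramp_duration, spec.plateau_duration
    env = np.clip(t / r, 0.0, 1.0) * np.clip((r + p + r - t) / r, 0.0, 1.0)
    env = np.clip(env, 0.0, 1.0)
    mod = 1.0 + spec.depth_fraction * np.sin(2.0 * np.pi * f * (t - r) + phase_rad) * ((t >= r) & (t < r + p))
    return spec.pedestal * env * mod


def gen_am_pair(spec: AMStimSpec, sample_rate: float = DEFAULT_SAMPLE_RATE) -> tuple[TimeSeries, TimeSeries]:
    """AM pair: linear ramps, pedestal, and sinusoidal modulation on the plateau."""
    total = 2 * spec.ramp_duration + spec.plateau_duration
    t = _grid(total, sample_rate)
    v = _am_trace(t, spec.f_v, 0.0, spec)
    a = _am_trace(t, spec.f_a, np.deg2rad(spec.phase_deg), spec)
    return TimeSeries(v, sample_rate), TimeSeries(a, sample_rate)


def pearson_corr(a: TimeSeries, b: TimeSeries) -> float:
    """Product-moment correlation of two equally long signals."""
    if len(a) != len(b):
        raise ValueError("signals must have equal length")
    av, bv = a.values, b.values
    if np.std(av) == 0 or np.std(bv) == 0:
        raise ValueError("correlation undefined for constant input")
    return float(np.corrcoef(av, bv)[0, 1])
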