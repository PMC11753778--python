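"""Canonical experimental designs and their model simulations.

Two in-house designs drive most of the package:

* the step design — four polarity conditions (on-on, off-off, on-off,
  off-on) × 15 audiovisual lags in [−0.4, 0.4] s × 10 repetitions,
  judged by temporal order (TOJ) or simultaneity (SJ);
* the periodic design — windowed square waves with 40 crossmodal phase
  shifts spanning one full cycle × 15 repetitions, judged by
  simultaneity; the global phase offset of the whole stimulus rotates
  across repetitions.

The functions here map those designs through the detector to per-level
decision variables. Decision variables are z-scored across levels before
entering the observer GLM, so observer coefficients live on a common
scale regardless of the arbitrary units of the detector output.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .detector import MCDParams, mcd_respond
from .stimuli import (
    STEP_CONDITIONS,
    PeriodicStimSpec,
    StepStimSpec,
    gen_periodic_pair,
    gen_step_pair,
)

__all__ = [
    "exp1_lag_grid",
    "exp2_phase_grid",
    "simulate_step_design",
    "simulate_periodic_design",
    "synchrony_phase_curve",
    "curve_peaks_deg",
    "zscore",
]

N_LAGS_EXP1 = 15
LAG_RANGE_EXP1 = 0.4
N_PHASES_EXP2 = 40
N_REPS_EXP1 = 10
N_REPS_EXP2 = 15


def exp1_lag_grid() -> np.ndarray:
    """15 lags, equally spaced in [−0.4, 0.4] s."""
    return np.linspace(-LAG_RANGE_EXP1, LAG_RANGE_EXP1, N_LAGS_EXP1)


def exp2_phase_grid() -> np.ndarray:
    """One full cycle of crossmodal phase shifts in 40 equal steps, [0, 2π)."""
    return np.arange(N_PHASES_EXP2) * 2.0 * np.pi / N_PHASES_EXP2


def zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    s = x.std()
    if s == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / s


def simulate_step_design(
    params: MCDParams | None = None,
    lags: np.ndarray | None = None,
    conditions=STEP_CONDITIONS,
    sample_rate: float = 1000.0,
) -> pd.DataFrame:
    """Run the detector over the full step design.

    Returns a tidy frame with one row per (condition, lag) and the two
    window-averaged decision variables.
    """
    if params is None:
        params = MCDParams()
    if lags is None:
        lags = exp1_lag_grid()
    rows = []
    for cond in conditions:
        for lag in lags:
            v, a = gen_step_pair(StepStimSpec(condition=cond, lag=float(lag)), sample_rate)
            out = mcd_respond(v, a, params)
            rows.append((cond, float(lag), out.corr_mean, out.lag_mean))
    return pd.DataFrame(rows, columns=["condition", "lag", "corr_mean", "lag_mean"])


def simulate_periodic_design(
    params: MCDParams | None = None,
    phases: np.ndarray | None = None,
    global_phase_offset: float = 0.0,
    sample_rate: float = 1000.0,
) -> pd.DataFrame:
    """Run the detector over the periodic design at one global phase offset."""
    if params is None:
        params = MCDParams()
    if phases is None:
        phases = exp2_phase_grid()
    rows = []
    for phi in phases:
        v, a = gen_periodic_pair(
            PeriodicStimSpec(phase_shift=float(phi), global_phase_offset=global_phase_offset),
            sample_rate,
        )
        out = mcd_respond(v, a, params)
        rows.append((float(phi), out.corr_mean, out.lag_mean))
    return pd.DataFrame(rows, columns=["phase_shift", "corr_mean", "lag_mean"])


def synchrony_phase_curve(
    params: MCDParams | None = None,
    n_phases: int = N_PHASES_EXP2,
    global_phase_offset: float = 0.0,
    sample_rate: float = 1000.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Window-averaged correlation output vs. crossmodal phase shift.

    The model's synchrony curve over one full cycle; under transient
    front-ends it peaks at 0 and π (frequency doubling).
    """
    phases = np.arange(n_phases) * 2.0 * np.pi / n_phases
    df = simulate_periodic_design(params, phases, global_phase_offset, sample_rate)
    return phases, df["corr_mean"].to_numpy()


def curve_peaks_deg(phases: np.ndarray, curve: np.ndarray) -> tuple[float, float]:
    """Primary and secondary maxima (degrees) of a periodic curve.

    Local maxima are found on the circular grid; the primary peak is the
    one with the largest value, the secondary the largest remaining
    local maximum.
    """
    c = np.asarray(curve, dtype=float)
    deg = np.degrees(np.asarray(phases, dtype=float)) % 360.0
    prev = np.roll(c, 1)
    nxt = np.roll(c, -1)
    is_max = (c > prev) & (c > nxt)
    if is_max.sum() < 2:
        raise ValueError("curve does not have two local maxima")
    idx = np.flatnonzero(is_max)
    order = idx[np.argsort(c[idx])[::-1]]
    return float(deg[order[0]]), float(deg[order[1]])
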