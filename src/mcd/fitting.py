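"""Estimation of detector temporal constants from trial data.

The detector has three temporal constants (τ_v, τ_a, τ_av). Given a
trial table and a stimulus generator that can reproduce each trial's
stimulus, the fit maximizes a profile objective: for candidate
constants, the detector's decision variables are computed per stimulus
level, the observer GLM is refit per (task, condition), and the summed
binomial log-likelihood (or the Pearson correlation between observed
and predicted response proportions) scores the candidate.

The likelihood landscape over (τ_v, τ_a) is known to be irregular, so
the optimizer is a derivative-free simplex search restarted from
multiple log-spaced starting points. Optimizer identity is not part of
the model; any robust ML search is acceptable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detector import MCDParams, mcd_respond
from .observer import GLMFit, fit_probit_glm, predict_prob
from .stimuli import STEP_CONDITIONS, PeriodicStimSpec, StepStimSpec, gen_periodic_pair, gen_step_pair
from .experiments import zscore

__all__ = ["FitResult", "fit_mcd", "goodness_landscape", "default_stimulus_fn"]

_FREE_NAMES = ("tau_v", "tau_a", "tau_av")


@dataclass
class FitResult:
    """Outcome of a temporal-constant fit."""

    params: MCDParams
    glm_per_condition: dict[tuple[str, str], GLMFit]
    objective_value: float
    objective_kind: str  # 'binomial' (log-likelihood) or 'pearson'
    n_evaluations: int = 0
    starts: list = field(default_factory=list)

    def report(self) -> str:
        lines = [
            "MCD fit result",
            f"  objective ({self.objective_kind}): {self.objective_value:.6g}",
            f"  tau_v  = {self.params.tau_v:.4f} s",
            f"  tau_a  = {self.params.tau_a:.4f} s",
            f"  tau_av = {self.params.tau_av:.4f} s",
            f"  evaluations: {self.n_evaluations}",
        ]
        for (task, cond), glm in sorted(self.glm_per_condition.items()):
            lines.append(f"  GLM[{task},{cond}]: intercept={glm.intercept:.3f} slope={glm.slope:.3f}")
        return "\n".join(lines)


def default_stimulus_fn(condition: str, level: float, sample_rate: float):
    """Map a (condition, level) trial cell to its stimulus pair.

    Step-polarity condition names take the level as an audiovisual lag
    in seconds; the 'periodic' condition takes it as a crossmodal phase
    shift in radians.
    """
    if condition in STEP_CONDITIONS:
        return gen_step_pair(StepStimSpec(condition=condition, lag=level), sample_rate)
    if condition == "periodic":
        return gen_periodic_pair(PeriodicStimSpec(phase_shift=level), sample_rate)
    raise ValueError(f"no stimulus generator for condition {condition!r}")


def _aggregate(trials: pd.DataFrame) -> pd.DataFrame:
    g = (
        trials.groupby(["task", "condition", "lag_or_phase"], sort=True)["response"]
        .agg(successes="sum", totals="count")
        .reset_index()
    )
    return g


def _decision_variable(out, task: str) -> float:
    return out.lag_mean if task == "TOJ" else out.corr_mean


class _Objective:
    """Profile objective over detector constants with stimulus caching."""

    def __init__(self, trials, stimulus_fn, base_params, objective, sample_rate):
        if len(trials) == 0:
            raise ValueError("empty trial table")
        self.agg = _aggregate(trials)
        self.base = base_params
        self.kind = objective
        self.sample_rate = sample_rate
        self.n_evaluations = 0
        # stimuli do not depend on the detector constants: generate once
        self.cells = self.agg[["condition", "lag_or_phase"]].drop_duplicates().itertuples(index=False)
        self.stimuli = {
            (c, l): stimulus_fn(c, l, sample_rate) for c, l in self.cells
        }

    def evaluate(self, params: MCDParams) -> tuple[float, dict]:
        self.n_evaluations += 1
        dv_cache = {
            key: mcd_respond(v, a, params) for key, (v, a) in self.stimuli.items()
        }
        total = 0.0
        glms: dict = {}
        all_obs, all_pred = [], []
        for (task, cond), grp in self.agg.groupby(["task", "condition"], sort=True):
            levels = grp["lag_or_phase"].to_numpy()
            dv = np.array([_decision_variable(dv_cache[(cond, l)], task) for l in levels])
            k = grp["successes"].to_numpy()
            n = grp["totals"].to_numpy()
            z = zscore(dv)
            if np.ptp(z) == 0:
                # degenerate decision variable: chance-level GLM
                glm = GLMFit(intercept=0.0, slope=0.0)
                p = np.full(len(levels), 0.5)
            else:
                glm = fit_probit_glm(z, k, n)
                p = predict_prob(glm, z)
            glms[(task, cond)] = glm
            p = np.clip(p, 1e-9, 1 - 1e-9)
            total += float((k * np.log(p) + (n - k) * np.log1p(-p)).sum())
            all_obs.append(k / n)
            all_pred.append(p)
        if self.kind == "pearson":
            obs = np.concatenate(all_obs)
            pred = np.concatenate(all_pred)
            score = 0.0 if np.std(obs) == 0 or np.std(pred) == 0 else float(np.corrcoef(obs, pred)[0, 1])
            return score, glms
        return total, glms


def _make_params(base: MCDParams, free: tuple[str, ...], values: np.ndarray) -> MCDParams:
    return base.replace(**{name: float(v) for name, v in zip(free, values)})


def fit_mcd(
    trials: pd.DataFrame,
    stimulus_fn=default_stimulus_fn,
    params0: MCDParams | None = None,
    free: tuple[str, ...] = ("tau_v", "tau_a"),
    bounds: dict | None = None,
    objective: str = "binomial",
    n_starts: int = 8,
    sample_rate: float = 200.0,
    seed: int = 0,
) -> FitResult:
    """Fit the detector's temporal constants to a trial table.

    Parameters named in ``free`` are optimized within ``bounds``
    (log-spaced multi-start simplex search); the rest stay at
    ``params0``. With an empty ``free`` mask the fit reduces to
    per-condition GLM estimation at ``params0``.
    """
    if params0 is None:
        params0 = MCDParams()
    for name in free:
        if name not in _FREE_NAMES:
            raise ValueError(f"unknown free parameter {name!r}")
    if objective not in ("binomial", "pearson"):
        raise ValueError("objective must be 'binomial' or 'pearson'")
    obj = _Objective(trials, stimulus_fn, params0, objective, sample_rate)

    if not free:
        value, glms = obj.evaluate(params0)
        return FitResult(params0, glms, value, objective, obj.n_evaluations)

    if bounds is None:
        bounds = {}
    lo = np.array([bounds.get(n, (0.005, 1.0))[0] for n in free])
    hi = np.array([bounds.get(n, (0.005, 1.0))[1] for n in free])

    from scipy import optimize

    def neg(logtau):
        tau = np.exp(np.clip(logtau, np.log(lo), np.log(hi)))
        value, _ = obj.evaluate(_make_params(params0, free, tau))
        return -value

    rng = np.random.default_rng(seed)
    # deterministic log-spaced starts plus mild jitter for extra starts
    base_starts = np.exp(np.linspace(np.log(lo), np.log(hi), max(2, min(n_starts, 4))))
    starts = list(base_starts)
    while len(starts) < n_starts:
        starts.append(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    best = None
    for s in starts:
        res = optimize.minimize(
            neg,
            np.log(np.asarray(s)),
            method="Nelder-Mead",
            options={"xatol": 1e-3, "fatol": 1e-6, "maxiter": 200},
        )
        if best is None or res.fun < best.fun:
            best = res
    tau = np.exp(np.clip(best.x, np.log(lo), np.log(hi)))
    params_hat = _make_params(params0, free, tau)
    value, glms = obj.evaluate(params_hat)
    return FitResult(params_hat, glms, value, objective, obj.n_evaluations, starts=[list(map(float, s)) for s in starts])


def goodness_landscape(
    trials: pd.DataFrame,
    tau_v_grid,
    tau_a_grid,
    stimulus_fn=default_stimulus_fn,
    params0: MCDParams | None = None,
    objective: str = "pearson",
    sample_rate: float = 200.0,
) -> np.ndarray:
    """Objective evaluated on a Cartesian grid of (τ_v, τ_a).

    Returns a matrix with shape (len(tau_v_grid), len(tau_a_grid));
    τ_av stays fixed at ``params0.tau_av``.
    """
    if params0 is None:
        params0 = MCDParams()
    obj = _Objective(trials, stimulus_fn, params0, objective, sample_rate)
    tau_v_grid = np.asarray(tau_v_grid, dtype=float)
    tau_a_grid = np.asarray(tau_a_grid, dtype=float)
    Z = np.empty((len(tau_v_grid), len(tau_a_grid)))
    for i, tv in enumerate(tau_v_grid):
        for j, ta in enumerate(tau_a_grid):
            Z[i, j], _ = obj.evaluate(params0.replace(tau_v=float(tv), tau_a=float(ta)))
    return Z
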