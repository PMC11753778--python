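"""Trial-table I/O, run configuration and synthetic fixtures.

Trial tables are plain CSV with the columns
``participant, task, condition, lag_or_phase, response`` — one row per
trial, response binary. The fixture generator instantiates the full
factorial designs of the two in-house experiments and samples responses
from the detector-driven observer, so a complete synthetic dataset is a
function call away.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .detector import MCDParams
from .experiments import (
    N_REPS_EXP1,
    N_REPS_EXP2,
    exp1_lag_grid,
    exp2_phase_grid,
    simulate_periodic_design,
    simulate_step_design,
    zscore,
)
from .observer import predict_prob, GLMFit
from .stimuli import STEP_CONDITIONS

__all__ = [
    "TRIAL_COLUMNS",
    "read_trials",
    "write_trials",
    "validate_trials",
    "make_fixture",
    "load_config",
    "config_hash",
]

TRIAL_COLUMNS = ["participant", "task", "condition", "lag_or_phase", "response"]
VALID_TASKS = {"TOJ", "SJ", "causal", "2IFC"}


def validate_trials(df: pd.DataFrame) -> pd.DataFrame:
    """Validate the trial-table schema with informative errors."""
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table is missing column(s): {', '.join(missing)}")
    bad_tasks = set(df["task"].unique()) - VALID_TASKS
    if bad_tasks:
        raise ValueError(f"unknown task value(s): {sorted(bad_tasks)}")
    resp = df["response"].unique()
    if not set(np.asarray(resp).tolist()) <= {0, 1}:
        raise ValueError("responses must be binary (0/1)")
    return df


def write_trials(df: pd.DataFrame, path) -> None:
    """Write a validated trial table as CSV (lossless round trip)."""
    validate_trials(df)
    out = df[TRIAL_COLUMNS].copy()
    out.to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial-table CSV."""
    df = pd.read_csv(
        path,
        dtype={"participant": str, "task": str, "condition": str, "lag_or_phase": float, "response": int},
    )
    return validate_trials(df)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

#: default observer coefficients applied to z-scored decision variables
DEFAULT_OBSERVER = {"TOJ": GLMFit(0.0, 1.8), "SJ": GLMFit(0.0, 1.5)}


def _sample_block(rng, participant, task, condition, levels, p):
    rows = []
    for lvl, pi in zip(levels, p):
        rows.append((participant, task, condition, float(lvl), int(rng.random() < pi)))
    return rows


def make_fixture(
    design: str,
    params: MCDParams | None = None,
    seed: int = 0,
    n_participants: int | None = None,
    observer: dict | None = None,
    sample_rate: float = 1000.0,
) -> pd.DataFrame:
    """Synthesize a full behavioural dataset from the model observer.

    design:
      'exp1_toj' — 15 lags × 10 reps × 4 polarity conditions = 600
                   TOJ trials per participant,
      'exp1_sj'  — the same factorial with SJ responses,
      'exp2'     — 40 phase shifts × 15 reps = 600 SJ trials per
                   participant; the global phase offset of the stimulus
                   rotates across the 15 repetitions.

    Responses are binomial draws from Φ(a + b·z) where z is the
    z-scored decision variable of the detector for that task.
    """
    if params is None:
        params = MCDParams()
    if observer is None:
        observer = DEFAULT_OBSERVER
    if design not in ("exp1_toj", "exp1_sj", "exp2"):
        raise ValueError(f"unknown design {design!r}; valid: exp1_toj, exp1_sj, exp2")
    rng = np.random.default_rng(seed)
    rows: list = []
    if design in ("exp1_toj", "exp1_sj"):
        task = "TOJ" if design == "exp1_toj" else "SJ"
        n_participants = 8 if n_participants is None else n_participants
        lags = exp1_lag_grid()
        sim = simulate_step_design(params, lags, sample_rate=sample_rate)
        glm = observer[task]
        for cond in STEP_CONDITIONS:
            sub = sim[sim["condition"] == cond]
            dv = sub["lag_mean"].to_numpy() if task == "TOJ" else sub["corr_mean"].to_numpy()
            p = predict_prob(glm, zscore(dv))
            for s in range(n_participants):
                pid = f"S{s + 1}"
                for _ in range(N_REPS_EXP1):
                    rows.extend(_sample_block(rng, pid, task, cond, lags, p))
    else:
        n_participants = 5 if n_participants is None else n_participants
        phases = exp2_phase_grid()
        glm = observer["SJ"]
        offsets = np.arange(N_REPS_EXP2) * 2.0 * np.pi / N_REPS_EXP2
        # decision variables per (repetition offset, phase shift)
        p_by_offset = []
        for off in offsets:
            sim = simulate_periodic_design(params, phases, global_phase_offset=float(off), sample_rate=sample_rate)
            p_by_offset.append(predict_prob(glm, zscore(sim["corr_mean"].to_numpy())))
        for s in range(n_participants):
            pid = f"S{s + 1}"
            for rep in range(N_REPS_EXP2):
                rows.extend(_sample_block(rng, pid, "SJ", "periodic", phases, p_by_offset[rep]))
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    """Load a YAML run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a mapping")
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_run_info(outdir, cfg: dict, seed: int) -> Path:
    """Record config hash and seed next to a run's outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    info = {"config_hash": config_hash(cfg), "seed": seed, "config": cfg}
    path = outdir / "run_info.json"
    path.write_text(json.dumps(info, indent=2, default=str))
    return path
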