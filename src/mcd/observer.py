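"""The late decision stage: from detector outputs to binary responses.

The detector's window-averaged output is a continuous decision variable
in arbitrary units. The observer corrupts it with late additive Gaussian
noise and compares it to an internal criterion, which is equivalent to a
binomial GLM with a probit link: p = Φ(intercept + slope·x).

The module also provides the descriptive psychometric families used for
model-free summaries of behaviour:

* temporal order judgments (TOJ): cumulative Gaussian with two lapse
  asymptotes; PSS = lag at chance, WSS = half-distance between the 25%
  and 75% lags,
* simultaneity judgments (SJ): difference of two cumulative Gaussians
  (asymmetric bell); PSS = lag of maximal perceived simultaneity,
  WSS = half-width at half-maximum,
* periodic SJ: p(synch|φ) = Φ(α + β·sin(f·φ + θ)) with the oscillation
  frequency f and phase offset θ fixed, α (bias) and β (sensitivity) free.

All fits maximize the binomial likelihood; multi-start guards against
local optima. Goodness of fit is reported as the squared Pearson
correlation between fitted and observed proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize
from scipy.stats import norm

__all__ = [
    "GLMFit",
    "PsychFit",
    "PsychSummary",
    "fit_probit_glm",
    "predict_prob",
    "fit_toj_curve",
    "fit_sj_curve",
    "fit_sin_psychometric",
    "extract_pss_wss",
    "sample_responses",
]

_EPS = 1e-9


@dataclass
class GLMFit:
    """Probit GLM coefficients (decision variable → response probability)."""

    intercept: float
    slope: float
    se_intercept: float = np.nan
    se_slope: float = np.nan
    converged: bool = True
    regularized: bool = False

    def __post_init__(self) -> None:
        if not (np.isfinite(self.intercept) and np.isfinite(self.slope)):
            raise ValueError("GLM coefficients must be finite")


@dataclass
class PsychFit:
    """A fitted descriptive psychometric function."""

    family: str  # toj_cum_gauss | sj_diff_gauss | sj_sinusoid
    params: dict = field(default_factory=dict)
    r_squared: float = np.nan
    log_likelihood: float = np.nan
    se: dict = field(default_factory=dict)

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        p = self.params
        if self.family == "toj_cum_gauss":
            lo, hi = p["gamma"], p["lambda"]
            return lo + (1.0 - lo - hi) * norm.cdf((x - p["mu"]) / p["sigma"])
        if self.family == "sj_diff_gauss":
            return np.clip(
                norm.cdf((x - p["mu1"]) / p["sigma1"]) - norm.cdf((x - p["mu2"]) / p["sigma2"]),
                0.0,
                1.0,
            )
        if self.family == "sj_sinusoid":
            return norm.cdf(p["alpha"] + p["beta"] * np.sin(p["f"] * x + p["theta"]))
        raise ValueError(f"unknown family {self.family!r}")


@dataclass
class PsychSummary:
    """Point and window of subjective simultaneity (seconds, or radians
    for periodic designs)."""

    pss: float
    wss: float

    def __post_init__(self) -> None:
        if self.wss < 0:
            raise ValueError("wss must be non-negative")


# ---------------------------------------------------------------------------
# probit GLM
# ---------------------------------------------------------------------------

def _ridge_probit(x: np.ndarray, k: np.ndarray, n: np.ndarray, ridge: float = 1e-6) -> tuple[np.ndarray, np.ndarray]:
    """Penalized binomial probit ML; keeps estimates finite under separation."""

    def nll(beta):
        eta = beta[0] + beta[1] * x
        p = np.clip(norm.cdf(eta), _EPS, 1 - _EPS)
        ll = k * np.log(p) + (n - k) * np.log1p(-p)
        return -ll.sum() + ridge * (beta @ beta)

    best = None
    for start in ([0.0, 0.0], [0.0, 1.0], [0.0, -1.0]):
        res = optimize.minimize(nll, np.asarray(start), method="Nelder-Mead", options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000})
        if best is None or res.fun < best.fun:
            best = res
    # standard errors from a numerical Hessian of the unpenalized likelihood
    h = 1e-4 * (1.0 + np.abs(best.x))
    H = np.zeros((2, 2))
    for i in range(2):
        for j in range(2):
            bpp = best.x.copy(); bpp[i] += h[i]; bpp[j] += h[j]
            bpm = best.x.copy(); bpm[i] += h[i]; bpm[j] -= h[j]
            bmp = best.x.copy(); bmp[i] -= h[i]; bmp[j] += h[j]
            bmm = best.x.copy(); bmm[i] -= h[i]; bmm[j] -= h[j]
            H[i, j] = (nll(bpp) - nll(bpm) - nll(bmp) + nll(bmm)) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.array([np.nan, np.nan])
    return best.x, se


def fit_probit_glm(decision_vars, successes, totals) -> GLMFit:
    """Maximum-likelihood binomial probit regression p = Φ(a + b·x).

    Uses statsmodels' IRLS fit; on perfect separation or non-convergence
    falls back to a lightly ridge-penalized (1e-6) ML fit so estimates
    stay finite on degenerate inputs.
    """
    x = np.asarray(decision_vars, dtype=float)
    k = np.asarray(successes, dtype=float)
    n = np.asarray(totals, dtype=float)
    if np.any(k < 0) or np.any(k > n):
        raise ValueError("need 0 <= successes <= totals")
    if len(np.unique(x)) < 2:
        raise ValueError("need at least 2 distinct decision-variable values")
    X = sm.add_constant(x)
    try:
        with np.errstate(all="ignore"):
            res = sm.GLM(np.column_stack([k, n - k]), X, family=sm.families.Binomial(link=sm.families.links.Probit())).fit()
        params, bse = np.asarray(res.params), np.asarray(res.bse)
        if np.all(np.isfinite(params)) and np.max(np.abs(params)) < 1e3 and np.all(np.isfinite(bse)):
            return GLMFit(intercept=float(params[0]), slope=float(params[1]),
                          se_intercept=float(bse[0]), se_slope=float(bse[1]))
    except Exception:
        pass
    beta, se = _ridge_probit(x, k, n)
    return GLMFit(intercept=float(beta[0]), slope=float(beta[1]),
                  se_intercept=float(se[0]), se_slope=float(se[1]), regularized=True)


def predict_prob(glm: GLMFit, decision_var) -> np.ndarray | float:
    """Φ(intercept + slope·x), elementwise."""
    x = np.asarray(decision_var, dtype=float)
    out = norm.cdf(glm.intercept + glm.slope * x)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# descriptive psychometric fits
# ---------------------------------------------------------------------------

def _binom_nll(p: np.ndarray, k: np.ndarray, n: np.ndarray) -> float:
    p = np.clip(p, _EPS, 1 - _EPS)
    return float(-(k * np.log(p) + (n - k) * np.log1p(-p)).sum())


def _r_squared(p_hat: np.ndarray, k: np.ndarray, n: np.ndarray) -> float:
    obs = k / n
    if np.std(obs) == 0 or np.std(p_hat) == 0:
        return 0.0
    return float(np.corrcoef(obs, p_hat)[0, 1] ** 2)


def _ml_multistart(nll, starts, bounds):
    best = None
    for s in starts:
        res = optimize.minimize(nll, np.asarray(s, dtype=float), method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    return best


def fit_toj_curve(lags, p_audio_first, n, lapse_max: float = 0.1) -> PsychFit:
    """Cumulative Gaussian with lower/upper asymptotes, fit by binomial ML.

    p(lag) = γ + (1 − γ − λ)·Φ((lag − μ)/σ); γ, λ ∈ [0, lapse_max].
    """
    x = np.asarray(lags, dtype=float)
    n = np.asarray(n, dtype=float)
    k = np.asarray(p_audio_first, dtype=float) * n
    if len(np.unique(x)) < 5:
        raise ValueError("need at least 5 stimulus levels to fit a TOJ curve")
    span = x.max() - x.min()

    def nll(theta):
        mu, log_sigma, g, l = theta
        sigma = np.exp(log_sigma)
        p = g + (1 - g - l) * norm.cdf((x - mu) / sigma)
        return _binom_nll(p, k, n)

    starts = [
        (np.median(x), np.log(span / 4), 0.02, 0.02),
        (0.0, np.log(span / 8), 0.01, 0.01),
        (np.median(x), np.log(span / 2), 0.05, 0.05),
    ]
    bounds = [(x.min() - span, x.max() + span), (np.log(span / 200), np.log(span * 5)), (0, lapse_max), (0, lapse_max)]
    best = _ml_multistart(nll, starts, bounds)
    mu, log_sigma, g, l = best.x
    fit = PsychFit(
        family="toj_cum_gauss",
        params={"mu": float(mu), "sigma": float(np.exp(log_sigma)), "gamma": float(g), "lambda": float(l)},
        log_likelihood=-float(best.fun),
    )
    fit.r_squared = _r_squared(fit.predict(x), k, n)
    return fit


def fit_sj_curve(lags, p_synch, n) -> PsychFit:
    """Difference of two cumulative Gaussians (asymmetric bell), binomial ML.

    p(lag) = Φ((lag − μ1)/σ1) − Φ((lag − μ2)/σ2), with μ1 < μ2.
    """
    x = np.asarray(lags, dtype=float)
    n = np.asarray(n, dtype=float)
    k = np.asarray(p_synch, dtype=float) * n
    if len(np.unique(x)) < 5:
        raise ValueError("need at least 5 stimulus levels to fit an SJ curve")
    span = x.max() - x.min()
    obs = k / n
    if np.max(obs) - np.min(obs) < 1e-3:
        raise ValueError("flat response profile: SJ fit is degenerate")

    def nll(theta):
        mu1, log_gap, ls1, ls2 = theta
        mu2 = mu1 + np.exp(log_gap)
        p = norm.cdf((x - mu1) / np.exp(ls1)) - norm.cdf((x - mu2) / np.exp(ls2))
        return _binom_nll(p, k, n)

    peak = x[np.argmax(obs)]
    starts = [
        (peak - span / 4, np.log(span / 2), np.log(span / 6), np.log(span / 6)),
        (x.min(), np.log(span), np.log(span / 4), np.log(span / 4)),
        (peak - span / 8, np.log(span / 4), np.log(span / 10), np.log(span / 10)),
    ]
    bounds = [
        (x.min() - 2 * span, x.max() + span),
        (np.log(span / 100), np.log(4 * span)),
        (np.log(span / 200), np.log(2 * span)),
        (np.log(span / 200), np.log(2 * span)),
    ]
    best = _ml_multistart(nll, starts, bounds)
    mu1, log_gap, ls1, ls2 = best.x
    fit = PsychFit(
        family="sj_diff_gauss",
        params={
            "mu1": float(mu1),
            "mu2": float(mu1 + np.exp(log_gap)),
            "sigma1": float(np.exp(ls1)),
            "sigma2": float(np.exp(ls2)),
        },
        log_likelihood=-float(best.fun),
    )
    fit.r_squared = _r_squared(fit.predict(x), k, n)
    return fit


def fit_sin_psychometric(phases, p_synch, n, f_fixed: float = 2.0, theta_fixed: float = -0.441) -> PsychFit:
    """Sinusoidal psychometric function with fixed frequency and phase offset.

    p(synch|φ) = Φ(α + β·sin(f·φ + θ)); α, β fitted by binomial ML. This
    is a probit GLM on the regressor sin(f·φ + θ), so the GLM machinery
    (including its separation handling) is reused, and the returned
    standard errors are the GLM's.
    """
    phi = np.asarray(phases, dtype=float)
    if phi.max() - phi.min() < np.pi:
        raise ValueError("phases must span a full cycle")
    n = np.asarray(n, dtype=float)
    k = np.asarray(p_synch, dtype=float) * n
    reg = np.sin(f_fixed * phi + theta_fixed)
    glm = fit_probit_glm(reg, k, n)
    fit = PsychFit(
        family="sj_sinusoid",
        params={"alpha": glm.intercept, "beta": glm.slope, "f": f_fixed, "theta": theta_fixed},
        se={"alpha": glm.se_intercept, "beta": glm.se_slope},
    )
    fit.log_likelihood = -_binom_nll(fit.predict(phi), k, n)
    fit.r_squared = _r_squared(fit.predict(phi), k, n)
    return fit


def extract_pss_wss(fit: PsychFit) -> PsychSummary:
    """Family-dispatched point and window of subjective simultaneity.

    TOJ: PSS is the lag at chance (p = 0.5); WSS is half the distance
    between the lags giving p = 0.25 and p = 0.75 (0.6745·σ without
    lapses). SJ (bell or sinusoid): PSS is the location of maximal
    perceived simultaneity; WSS the half-width at half-maximum,
    evaluated numerically.
    """
    p = fit.params
    if fit.family == "toj_cum_gauss":
        g, l = p["gamma"], p["lambda"]
        scale = 1.0 - g - l
        if scale <= 0:
            raise ValueError("flat TOJ fit: summary undefined")
        def inv(q):
            u = (q - g) / scale
            if not (0 < u < 1):
                raise ValueError(f"asymptotes do not bracket p={q}: summary undefined")
            return p["mu"] + p["sigma"] * norm.ppf(u)
        pss = inv(0.5)
        wss = 0.5 * (inv(0.75) - inv(0.25))
        return PsychSummary(pss=pss, wss=wss)
    if fit.family in ("sj_diff_gauss", "sj_sinusoid"):
        if fit.family == "sj_diff_gauss":
            span = p["mu2"] - p["mu1"] + 4 * (p["sigma1"] + p["sigma2"])
            grid = np.linspace(p["mu1"] - span, p["mu2"] + span, 20001)
        else:
            # one oscillation period centred on zero phase lag
            half = np.pi / p["f"]
            grid = np.linspace(-half, half, 20001)
        y = fit.predict(grid)
        ymax, ymin = float(y.max()), float(y.min())
        if ymax - ymin < 1e-9:
            raise ValueError("flat fit: summary undefined")
        i = int(np.argmax(y))
        pss = float(grid[i])
        half = ymin + 0.5 * (ymax - ymin)
        above = y >= half
        # half width of the region around the peak that stays above half-maximum
        left = i
        while left > 0 and above[left - 1]:
            left -= 1
        right = i
        while right < len(grid) - 1 and above[right + 1]:
            right += 1
        wss = 0.5 * float(grid[right] - grid[left])
        return PsychSummary(pss=pss, wss=wss)
    raise ValueError(f"unknown family {fit.family!r}")


# ---------------------------------------------------------------------------
# synthetic observers
# ---------------------------------------------------------------------------

def sample_responses(
    p,
    n_per_level,
    seed: int,
    levels=None,
    participant: str = "S1",
    task: str = "SJ",
    condition: str = "default",
) -> pd.DataFrame:
    """Binomial response sampling: one row per trial, reproducible by seed."""
    p = np.atleast_1d(np.asarray(p, dtype=float))
    n_per_level = np.broadcast_to(np.asarray(n_per_level, dtype=int), p.shape)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must be in [0, 1]")
    if levels is None:
        levels = np.arange(len(p), dtype=float)
    levels = np.asarray(levels, dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    for lvl, pi, ni in zip(levels, p, n_per_level):
        resp = (rng.random(ni) < pi).astype(int)
        for r in resp:
            rows.append((participant, task, condition, float(lvl), int(r)))
    return pd.DataFrame(rows, columns=["participant", "task", "condition", "lag_or_phase", "response"])
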