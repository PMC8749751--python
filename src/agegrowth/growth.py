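"""Candidate growth functions and maximum-likelihood fitting under
multiplicative lognormal error.

Models (lengths in cm, ages in years):

* ``VBG3``  L(t) = L_inf * (1 - exp(-k (t - t0)))
* ``VBG2``  L(t) = L_inf - (L_inf - L0) * exp(-k t), L0 fixed (default
  14.5 cm, the largest near-term embryo length)
* ``GG3``   L(t) = L_inf * exp(-exp(-k (t - t0)))     (t0 = inflection age)
* ``LG3``   L(t) = L_inf / (1 + exp(-k (t - t0)))     (t0 = inflection age)

The error scale sigma is concentrated out of the lognormal likelihood
analytically: sigma_hat is the RMS of log-residuals, and the concentrated
negative log-likelihood is n/2 ln(2 pi) + n ln sigma_hat + n/2. The
log-likelihood reported (and fed to AIC) is the negative of that.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize

MODEL_NAMES = ("VBG3", "VBG2", "GG3", "LG3")

#: Fixed length-at-birth for the 2-parameter von Bertalanffy form, cm TL.
DEFAULT_L0 = 14.5

#: Free growth parameters per model (sigma excluded, see aic()).
N_PARAMS = {"VBG3": 3, "VBG2": 2, "GG3": 3, "LG3": 3}

_PENALTY = 1e10


@dataclass(frozen=True)
class GrowthParams:
    model: str
    l_inf: float
    k: float
    t0: float | None = None       # None for VBG2
    l0_fixed: float | None = None  # VBG2 only

    def __post_init__(self) -> None:
        if self.model not in MODEL_NAMES:
            raise ValueError(f"model must be one of {MODEL_NAMES}")
        if self.model == "VBG2":
            if self.l0_fixed is None:
                object.__setattr__(self, "l0_fixed", DEFAULT_L0)
        elif self.t0 is None:
            raise ValueError(f"{self.model} requires t0")

    @property
    def n_free(self) -> int:
        return N_PARAMS[self.model]

    def free_values(self) -> np.ndarray:
        if self.model == "VBG2":
            return np.array([self.l_inf, self.k])
        return np.array([self.l_inf, self.k, self.t0])


def predict_length(params: GrowthParams, age) -> np.ndarray | float:
    """Model-predicted total length at ``age`` (vectorized)."""
    t = np.asarray(age, dtype=float)
    m = params.model
    if m == "VBG3":
        out = params.l_inf * (1.0 - np.exp(-params.k * (t - params.t0)))
    elif m == "VBG2":
        out = params.l_inf - (params.l_inf - params.l0_fixed) * np.exp(-params.k * t)
    elif m == "GG3":
        out = params.l_inf * np.exp(-np.exp(-params.k * (t - params.t0)))
    else:  # LG3
        out = params.l_inf / (1.0 + np.exp(-params.k * (t - params.t0)))
    return out if out.ndim else float(out)


def sigma_analytic(observed, predicted) -> float:
    """Maximizing sigma: root mean square of log-residuals."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must be equal length")
    if np.any(obs <= 0) or np.any(pred <= 0):
        raise ValueError("lengths must be positive for the lognormal likelihood")
    resid = np.log(obs) - np.log(pred)
    return float(np.sqrt(np.mean(resid**2)))


def concentrated_nll(sigma: float, n: int) -> float:
    """Lognormal NLL at the analytic sigma: n/2 ln(2 pi) + n ln sigma + n/2."""
    if sigma <= 0:
        raise ValueError("degenerate likelihood: sigma must be > 0 (perfect fit?)")
    return 0.5 * n * np.log(2.0 * np.pi) + n * np.log(sigma) + 0.5 * n


def nll_at_sigma(sigma: float, observed, predicted) -> float:
    """Unconcentrated lognormal NLL at an arbitrary sigma (oracle for the
    concentration identity; not used by the fitter)."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    resid = np.log(obs) - np.log(pred)
    n = obs.size
    return float(
        0.5 * n * np.log(2.0 * np.pi)
        + n * np.log(sigma)
        + np.sum(resid**2) / (2.0 * sigma**2)
    )


def negative_log_likelihood(params: GrowthParams, ages, lengths) -> tuple[float, float]:
    """Concentrated NLL and its analytic sigma for one parameter set."""
    pred = predict_length(params, ages)
    sigma = sigma_analytic(lengths, pred)
    n = np.asarray(lengths).size
    return concentrated_nll(sigma, n), sigma


@dataclass(frozen=True)
class LikelihoodResult:
    params: GrowthParams
    sigma: float
    log_likelihood: float   # maximized (positive of -NLL), the AIC input
    n: int
    converged: bool
    n_starts: int = 1

    @property
    def nll(self) -> float:
        return -self.log_likelihood


def _objective(model: str, ages: np.ndarray, log_lengths: np.ndarray, l0_fixed: float):
    """Concentrated NLL as a plain function of the free-parameter vector,
    with a smooth penalty wherever predictions are non-positive."""
    n = ages.size

    def fun(theta: np.ndarray) -> float:
        l_inf, k = theta[0], theta[1]
        if l_inf <= 0 or k <= 0:
            return _PENALTY
        if model == "VBG3":
            pred = l_inf * (1.0 - np.exp(-k * (ages - theta[2])))
        elif model == "VBG2":
            pred = l_inf - (l_inf - l0_fixed) * np.exp(-k * ages)
        elif model == "GG3":
            pred = l_inf * np.exp(-np.exp(-k * (ages - theta[2])))
        else:
            pred = l_inf / (1.0 + np.exp(-k * (ages - theta[2])))
        if np.any(pred <= 0) or not np.all(np.isfinite(pred)):
            return _PENALTY
        resid = log_lengths - np.log(pred)
        ms = np.mean(resid**2)
        if ms == 0:
            return _PENALTY  # degenerate; handled by the caller on exact data
        return 0.5 * n * np.log(2.0 * np.pi) + 0.5 * n * np.log(ms) + 0.5 * n

    return fun


def _starts(model: str, ages: np.ndarray, lengths: np.ndarray, multistart: int, seed: int):
    """Deterministic heuristic starts plus seeded jitters."""
    l_inf0 = float(lengths.max()) * 1.05
    base = []
    for k0 in (0.1, 0.3):
        for t00 in (-2.0, 0.0):
            base.append([l_inf0, k0, t00])
    if model == "LG3" or model == "GG3":
        # sigmoids inflect at positive ages on these data
        base = [[l, k, max(t, 0.5)] for l, k, t in base]
    if model == "VBG2":
        base = [[l, k] for l, k, _ in base]
    base = base[: max(multistart, 1)]
    rng = np.random.default_rng(seed)
    while len(base) < multistart:
        ref = base[len(base) % 4]
        jitter = rng.normal(0.0, [0.1 * l_inf0, 0.1, 1.0][: len(ref)])
        cand = np.array(ref) + jitter
        cand[0] = abs(cand[0])
        cand[1] = abs(cand[1]) + 1e-3
        base.append(list(cand))
    return base


def fit_model(
    model: str,
    ages,
    lengths,
    init=None,
    multistart: int = 8,
    seed: int = 0,
    l0_fixed: float = DEFAULT_L0,
) -> LikelihoodResult:
    """Maximum-likelihood fit of one growth model.

    Best of ``multistart`` local optimizations (Nelder-Mead polished by
    BFGS), deterministic for a given seed and data. Raises on total
    non-convergence.
    """
    if model not in MODEL_NAMES:
        raise ValueError(f"model must be one of {MODEL_NAMES}")
    ages = np.asarray(ages, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if ages.shape != lengths.shape or ages.ndim != 1:
        raise ValueError("ages and lengths must be equal-length 1-D arrays")
    if np.any(lengths <= 0):
        raise ValueError("lengths must be positive")
    n = ages.size
    if n < N_PARAMS[model] + 1:
        raise ValueError(f"need at least {N_PARAMS[model] + 1} observations")
    log_lengths = np.log(lengths)
    fun = _objective(model, ages, log_lengths, l0_fixed)
    starts = _starts(model, ages, lengths, multistart, seed)
    if init is not None:
        starts = [list(init)] + starts
    best = None
    any_ok = False
    for x0 in starts:
        res = minimize(fun, x0, method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 5000})
        res2 = minimize(fun, res.x, method="BFGS")
        cand = res2 if res2.fun <= res.fun else res
        if cand.fun < _PENALTY:
            any_ok = True
        if best is None or cand.fun < best.fun:
            best = cand
    if best is None or not any_ok:
        raise RuntimeError(f"{model}: no start converged to a valid optimum")
    theta = best.x
    if model == "VBG2":
        params = GrowthParams(model, float(theta[0]), float(theta[1]), l0_fixed=l0_fixed)
    else:
        params = GrowthParams(model, float(theta[0]), float(theta[1]), float(theta[2]))
    nll, sigma = negative_log_likelihood(params, ages, lengths)
    return LikelihoodResult(
        params=params,
        sigma=sigma,
        log_likelihood=-nll,
        n=n,
        converged=bool(best.fun < _PENALTY),
        n_starts=len(starts),
    )
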