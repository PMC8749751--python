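"""Likelihood-based confidence machinery and AIC multimodel comparison.

Profile CIs use the 1-df chi-square 95% cutoff (3.84); joint (L_inf, k)
contour regions use the 2-df cutoff (5.99). Profiling re-optimizes all
nuisance parameters at each evaluation point (a true profile, not a
slice).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq, minimize

from .growth import (
    GrowthParams,
    LikelihoodResult,
    N_PARAMS,
    negative_log_likelihood,
    predict_length,
)

#: 95% chi-square quantiles used as deviance cutoffs.
PROFILE_THRESHOLD = 3.84   # 1 df
CONTOUR_THRESHOLD = 5.99   # 2 df

_FREE = {"VBG3": ("l_inf", "k", "t0"), "VBG2": ("l_inf", "k"), "GG3": ("l_inf", "k", "t0"),
         "LG3": ("l_inf", "k", "t0")}


@dataclass(frozen=True)
class ProfileCI:
    parameter: str
    mle: float
    lower: float
    upper: float
    threshold: float = PROFILE_THRESHOLD
    lower_bounded: bool = True   # False when the profile never crossed
    upper_bounded: bool = True


@dataclass
class ContourRegion:
    l_inf_grid: np.ndarray
    k_grid: np.ndarray
    deviance: np.ndarray         # shape (len(l_inf_grid), len(k_grid))
    threshold: float
    mle_l_inf: float
    mle_k: float

    @property
    def inside(self) -> np.ndarray:
        return self.deviance <= self.threshold

    def marginal_bounds(self, parameter: str) -> tuple[float, float]:
        """Bounding-box CI of the region along one axis."""
        mask = self.inside
        if not mask.any():
            raise ValueError("empty confidence region on this grid")
        if parameter == "l_inf":
            vals = self.l_inf_grid[mask.any(axis=1)]
        elif parameter == "k":
            vals = self.k_grid[mask.any(axis=0)]
        else:
            raise ValueError("parameter must be 'l_inf' or 'k'")
        return float(vals.min()), float(vals.max())

    def to_frame(self) -> pd.DataFrame:
        ll, kk = np.meshgrid(self.l_inf_grid, self.k_grid, indexing="ij")
        return pd.DataFrame(
            {"l_inf": ll.ravel(), "k": kk.ravel(), "deviance": self.deviance.ravel(),
             "inside": self.inside.ravel()}
        )


def _params_from_mapping(model: str, values: dict, l0_fixed) -> GrowthParams:
    return GrowthParams(
        model,
        values["l_inf"],
        values["k"],
        values.get("t0"),
        l0_fixed=l0_fixed,
    )


def _profile_nll(fit: LikelihoodResult, ages, lengths, fixed: dict) -> float:
    """NLL with the parameters in ``fixed`` pinned and the rest re-optimized
    starting from the MLE."""
    model = fit.params.model
    free = [p for p in _FREE[model] if p not in fixed]
    mle = {"l_inf": fit.params.l_inf, "k": fit.params.k, "t0": fit.params.t0}

    def fun(theta):
        values = dict(fixed)
        values.update(zip(free, theta))
        if values["l_inf"] <= 0 or values["k"] <= 0:
            return 1e10
        params = _params_from_mapping(model, values, fit.params.l0_fixed)
        pred = predict_length(params, np.asarray(ages, dtype=float))
        if np.any(np.asarray(pred) <= 0):
            return 1e10
        try:
            nll, _ = negative_log_likelihood(params, ages, lengths)
        except ValueError:
            return 1e10
        return nll

    if not free:
        return fun(())
    x0 = [mle[p] for p in free]
    res = minimize(fun, x0, method="Nelder-Mead",
                   options={"xatol": 1e-9, "fatol": 1e-10, "maxiter": 4000})
    return float(res.fun)


def profile_deviance(fit: LikelihoodResult, ages, lengths, parameter: str, value: float) -> float:
    """2 (logL_max - logL_profile(value)) for one parameter."""
    nll_prof = _profile_nll(fit, ages, lengths, {parameter: value})
    return 2.0 * (nll_prof - fit.nll)


def likelihood_interval(
    deviance_fun,
    mle: float,
    threshold: float = PROFILE_THRESHOLD,
    scale: float | None = None,
    positive: bool = False,
    max_expansions: int = 40,
    xtol: float = 1e-4,
) -> tuple[float, float, bool, bool]:
    """Bounds where ``deviance_fun`` (0 at the MLE) crosses ``threshold``.

    Steps outward from the MLE, doubling the step until the deviance
    exceeds the threshold, then bisects the crossing to ``xtol``. Returns
    (lower, upper, lower_crossed, upper_crossed); a side that never
    crosses is reported at the last point probed.
    """

    def excess(value: float) -> float:
        return deviance_fun(value) - threshold

    if scale is None:
        scale = max(abs(mle) * 0.05, 0.01)
    bounds = {}
    crossed_flags = {}
    for side in (-1, +1):
        step = scale
        prev = mle
        crossed = False
        for _ in range(max_expansions):
            cand = mle + side * step
            if positive and cand <= 0:
                cand = prev / 2.0  # shrink toward zero, stay positive
                if cand <= 0 or cand == prev:
                    break
            if excess(cand) > 0:
                lo, hi = sorted((prev, cand))
                root = brentq(excess, lo, hi, xtol=xtol)
                bounds[side] = float(root)
                crossed = True
                break
            prev = cand
            step *= 2.0
        if not crossed:
            warnings.warn(
                f"deviance did not cross the threshold on side {side:+d}; "
                "reporting a one-sided interval"
            )
            bounds[side] = float(prev)
        crossed_flags[side] = crossed
    return bounds[-1], bounds[+1], crossed_flags[-1], crossed_flags[+1]


def profile_ci(
    fit: LikelihoodResult,
    ages,
    lengths,
    parameter: str = "t0",
    threshold: float = PROFILE_THRESHOLD,
    xtol: float = 1e-4,
) -> ProfileCI:
    """Profile-likelihood CI for one growth parameter, nuisance parameters
    re-optimized at every profile point."""
    if parameter not in _FREE[fit.params.model]:
        raise ValueError(f"{parameter!r} is not a free parameter of {fit.params.model}")
    mle = getattr(fit.params, parameter)
    lower, upper, lb, ub = likelihood_interval(
        lambda v: profile_deviance(fit, ages, lengths, parameter, v),
        float(mle),
        threshold=threshold,
        positive=parameter in ("l_inf", "k"),
        xtol=xtol,
    )
    return ProfileCI(parameter, float(mle), lower, upper, threshold,
                     lower_bounded=lb, upper_bounded=ub)


def _approx_se(fit: LikelihoodResult, ages, lengths) -> dict[str, float]:
    """Rough SEs from the numerical Hessian of the concentrated NLL."""
    names = list(_FREE[fit.params.model])
    x = np.array([getattr(fit.params, p) for p in names], dtype=float)
    h = np.maximum(np.abs(x) * 1e-4, 1e-5)

    def f(theta):
        values = dict(zip(names, theta))
        params = _params_from_mapping(fit.params.model, values, fit.params.l0_fixed)
        try:
            nll, _ = negative_log_likelihood(params, ages, lengths)
        except (ValueError, FloatingPointError):
            return np.inf
        return nll

    dim = len(x)
    hess = np.empty((dim, dim))
    f0 = f(x)
    for i in range(dim):
        for j in range(i, dim):
            ei = np.zeros(dim); ei[i] = h[i]
            ej = np.zeros(dim); ej[j] = h[j]
            if i == j:
                val = (f(x + ei) - 2 * f0 + f(x - ei)) / h[i] ** 2
            else:
                val = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4 * h[i] * h[j])
            hess[i, j] = hess[j, i] = val
    try:
        cov = np.linalg.inv(hess)
        ses = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        ses = np.abs(x) * 0.05 + 0.01
    out = dict(zip(names, ses))
    for p in names:
        if not np.isfinite(out[p]) or out[p] == 0:
            out[p] = abs(getattr(fit.params, p) or 1.0) * 0.05 + 0.01
    return out


def deviance_at(fit: LikelihoodResult, ages, lengths, l_inf: float, k: float) -> float:
    """Joint deviance at (l_inf, k) with remaining parameters re-optimized.

    This is the quantity compared against the 2-df cutoff; a point is
    inside the 95% contour region iff it is <= 5.99.
    """
    nll_prof = _profile_nll(fit, ages, lengths, {"l_inf": l_inf, "k": k})
    return 2.0 * (nll_prof - fit.nll)


def contour_ci(
    fit: LikelihoodResult,
    ages,
    lengths,
    n_grid: int = 201,
    span_se: float = 6.0,
    threshold: float = CONTOUR_THRESHOLD,
) -> ContourRegion:
    """Deviance surface over an (l_inf, k) grid centred on the MLE.

    Grid spans MLE +/- ``span_se`` approximate standard errors. Warns if
    the region touches the grid boundary.
    """
    ses = _approx_se(fit, ages, lengths)
    li, kk = fit.params.l_inf, fit.params.k
    l_grid = np.linspace(max(li - span_se * ses["l_inf"], 1e-6),
                         li + span_se * ses["l_inf"], n_grid)
    k_grid = np.linspace(max(kk - span_se * ses["k"], 1e-6),
                         kk + span_se * ses["k"], n_grid)
    dev = np.empty((n_grid, n_grid))
    for i, lv in enumerate(l_grid):
        for j, kv in enumerate(k_grid):
            dev[i, j] = deviance_at(fit, ages, lengths, lv, kv)
    region = ContourRegion(l_grid, k_grid, dev, threshold, li, kk)
    inside = region.inside
    if inside[0, :].any() or inside[-1, :].any() or inside[:, 0].any() or inside[:, -1].any():
        warnings.warn("confidence region touches the grid boundary; expand the grid")
    return region


# ---------------------------------------------------------------------------
# AIC multimodel comparison


def aic(log_likelihood: float, n_params: int) -> float:
    """AIC = 2p - 2 logL, p counting growth parameters only (not sigma)."""
    return 2.0 * n_params - 2.0 * log_likelihood


def aicc(log_likelihood: float, n_params: int, n: int) -> float:
    """Small-sample corrected AIC (optional column; AIC is primary)."""
    base = aic(log_likelihood, n_params)
    return base + 2.0 * n_params * (n_params + 1) / (n - n_params - 1)


def akaike_weights(aics) -> np.ndarray:
    """exp(-delta/2), normalized to sum to one."""
    a = np.asarray(aics, dtype=float)
    delta = a - a.min()
    w = np.exp(-0.5 * delta)
    return w / w.sum()


def support_class(delta: float) -> str:
    """Qualitative support band for a delta-AIC value."""
    if delta < 0:
        raise ValueError("delta-AIC must be >= 0")
    if delta <= 2:
        return "substantial"
    if 4 <= delta <= 7:
        return "less"
    if delta > 10:
        return "none"
    return "intermediate"


def aic_table(fits: list[LikelihoodResult], include_aicc: bool = False) -> pd.DataFrame:
    """Model-comparison table: AIC, delta-AIC, Akaike weights, support.

    All fits must be on identical data (checked via n).
    """
    if not fits:
        raise ValueError("no fits supplied")
    ns = {f.n for f in fits}
    if len(ns) > 1:
        raise ValueError(f"fits are on different data (n = {sorted(ns)})")
    rows = []
    for f in fits:
        p = N_PARAMS[f.params.model]
        rows.append(
            {
                "model": f.params.model,
                "p": p,
                "log_likelihood": f.log_likelihood,
                "aic": aic(f.log_likelihood, p),
            }
        )
    table = pd.DataFrame(rows)
    table["delta_aic"] = table["aic"] - table["aic"].min()
    table["akaike_weight"] = akaike_weights(table["aic"].to_numpy())
    table["support"] = table["delta_aic"].map(support_class)
    if include_aicc:
        n = fits[0].n
        table["aicc"] = [aicc(r.log_likelihood, r.p, n) for r in table.itertuples()]
    return table.sort_values("aic").reset_index(drop=True)
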