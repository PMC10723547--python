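"""Grouped Poisson linear relative-risk likelihood, ML fitting and profile CIs.

The grouped model has Poisson case counts ``c_k`` with means

    mu_k = n_k * exp(kappa) * (1 + alpha*D_k + beta*D_k^2)

where ``n_k`` is the person count (offset) and ``D_k`` the assigned dose of
group ``k``.  The linear relative-risk factor must stay positive; parameter
vectors violating that are assigned log-likelihood ``-inf`` (a rejected region,
not an exception).  For fixed (alpha, beta) the baseline has the closed-form
maximiser ``exp(kappa) = sum(c_k) / sum(n_k*(1+alpha*D_k+beta*D_k^2))``, so ML
fitting is a 2-D search over (alpha, beta) with kappa profiled out — robust
near the linear-RR feasibility boundary.

Confidence intervals are profile-likelihood based: a 95% bound solves
``2*(loglik_max - profile_loglik(b)) = chi2_1(0.95) = 3.841``, located by
bracket doubling followed by bisection to 1e-4 on the deviance scale; a side
whose profile never crosses the threshold is reported as an infinite sentinel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Optional, Tuple

import numpy as np
from scipy import optimize
from scipy.special import gammaln
from scipy.stats import chi2

from .cohort import DoseEnsemble, CohortDesign, calibrated_group_doses
from .outcomes import GroupedData, RiskParameters, collapse_to_groups

__all__ = [
    "FitResult",
    "log_likelihood",
    "fit_ml",
    "profile_ci",
    "fit_unadjusted",
    "fit_regcal",
    "CHI2_95_1DF",
]

CHI2_95_1DF = float(chi2.ppf(0.95, 1))  # 3.841...

_DEFAULT_START = (0.1, 1.0)
_INFEASIBLE = 1e10


@dataclass
class FitResult:
    """Point estimates, 95% intervals and convergence metadata for one fit."""

    alpha_hat: float
    beta_hat: float
    kappa_hat: float
    loglik_max: float
    converged: bool
    method_tag: str
    ci_alpha: Optional[Tuple[float, float]] = None
    ci_beta: Optional[Tuple[float, float]] = None
    message: str = ""


def log_likelihood(data: GroupedData, params: RiskParameters) -> float:
    """Grouped Poisson log-likelihood (full, including the log-factorial terms)."""
    d = data.doses
    q = 1.0 + params.alpha * d + params.beta * d * d
    if np.any(q <= 0.0):
        return -math.inf
    mu = data.persons * math.exp(params.kappa) * q
    c = data.cases
    return float(np.sum(c * np.log(mu) - mu) - np.sum(gammaln(c + 1.0)))


def _profile_kappa(data: GroupedData, alpha: float, beta: float) -> float:
    """Closed-form kappa maximiser for fixed (alpha, beta)."""
    d = data.doses
    q = 1.0 + alpha * d + beta * d * d
    s = float(np.sum(data.persons * q))
    c_tot = float(data.cases.sum())
    if c_tot <= 0.0:
        return -math.inf
    return math.log(c_tot / s)


def _profiled_nll(data: GroupedData) -> Callable[[np.ndarray], float]:
    """Negative log-likelihood over (alpha, beta) with kappa profiled out."""
    d = data.doses
    d2 = d * d
    n = data.persons.astype(float)
    c = data.cases.astype(float)
    c_tot = c.sum()
    log_fact = float(np.sum(gammaln(data.cases + 1.0)))

    def nll(x: np.ndarray) -> float:
        a, b = float(x[0]), float(x[1])
        q = 1.0 + a * d + b * d2
        if np.any(q <= 0.0):
            # Smooth-ish barrier growing with the violation keeps Nelder-Mead moving.
            return _INFEASIBLE * (1.0 - float(np.minimum(q, 0.0).sum()))
        s = float(np.sum(n * q))
        if c_tot <= 0.0:
            return log_fact
        k = math.log(c_tot / s)
        ll = float(np.sum(c * (np.log(n * q) + k))) - c_tot - log_fact
        return -ll

    return nll


def fit_ml(
    data: GroupedData,
    init: Optional[RiskParameters] = None,
    method_tag: str = "ml",
) -> FitResult:
    """Maximum-likelihood fit of the grouped linear-quadratic relative-risk model.

    Nelder-Mead over (alpha, beta) with kappa profiled in closed form, restarted
    from a fixed set of perturbed starts; the best local maximum is polished by a
    second Nelder-Mead pass.  ``converged`` is False if every start failed or
    only infeasible points were found.
    """
    nll = _profiled_nll(data)
    a0, b0 = (init.alpha, init.beta) if init is not None else _DEFAULT_START
    starts = [
        (a0, b0),
        (a0 + 0.5, b0 + 1.0),
        (max(a0 - 0.09, 0.01), max(b0 - 0.9, 0.1)),
        (a0 + 2.0, b0 + 5.0),
        (0.0, 0.0),
    ]
    best = None
    for s in starts:
        res = optimize.minimize(
            nll,
            np.asarray(s, dtype=float),
            method="Nelder-Mead",
            options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    # Polish from the best point found.
    res = optimize.minimize(
        nll,
        best.x,
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-11, "maxiter": 2000},
    )
    if res.fun > best.fun:
        res = best
    ok = bool(res.fun < _INFEASIBLE / 2) and np.all(np.isfinite(res.x))
    a_hat, b_hat = float(res.x[0]), float(res.x[1])
    k_hat = _profile_kappa(data, a_hat, b_hat) if ok else math.nan
    return FitResult(
        alpha_hat=a_hat,
        beta_hat=b_hat,
        kappa_hat=k_hat,
        loglik_max=-float(res.fun) if ok else -math.inf,
        converged=ok,
        method_tag=method_tag,
        message="" if ok else "no feasible maximum found",
    )


def profile_interval(
    profile_loglik: Callable[[float], float],
    mle: float,
    loglik_max: float,
    level: float = 0.95,
    deviance_tol: float = 1e-4,
    max_doublings: int = 60,
) -> Tuple[float, float]:
    """Generic profile-likelihood interval by bracket doubling + bisection.

    ``profile_loglik(v)`` must return the log-likelihood maximised over all
    other parameters with the target parameter fixed at ``v``.  A side where
    the deviance never crosses the chi-square threshold within the doubling cap
    is reported as +/-inf.
    """
    thr = float(chi2.ppf(level, 1))

    def deviance(v: float) -> float:
        return 2.0 * (loglik_max - profile_loglik(v))

    bounds = []
    for sign in (-1.0, 1.0):
        step = max(0.25 * abs(mle), 0.25)
        inner = mle
        outer = None
        for _ in range(max_doublings):
            cand = mle + sign * step
            if deviance(cand) > thr:
                outer = cand
                break
            inner = cand
            step *= 2.0
        if outer is None:
            bounds.append(sign * math.inf)
            continue
        lo, hi = inner, outer
        mid = 0.5 * (lo + hi)
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            dm = deviance(mid)
            if abs(dm - thr) < deviance_tol:
                break
            if dm > thr:
                hi = mid
            else:
                lo = mid
        bounds.append(mid)
    return (min(bounds), max(bounds))


def profile_ci(
    data: GroupedData,
    fit: FitResult,
    which: str = "alpha",
    level: float = 0.95,
    deviance_tol: float = 1e-4,
) -> Tuple[float, float]:
    """Profile-likelihood CI for one coefficient of a converged grouped-Poisson fit."""
    if which not in ("alpha", "beta"):
        raise ValueError("which must be 'alpha' or 'beta'")
    if not fit.converged:
        raise ValueError("profile_ci requires a converged fit")
    d = data.doses
    d2 = d * d
    n = data.persons.astype(float)
    c = data.cases.astype(float)
    c_tot = c.sum()
    log_fact = float(np.sum(gammaln(data.cases + 1.0)))
    other0 = fit.beta_hat if which == "alpha" else fit.alpha_hat
    state = {"other": other0}

    def nll_other(o: float, v: float) -> float:
        a, b = (v, o) if which == "alpha" else (o, v)
        q = 1.0 + a * d + b * d2
        if np.any(q <= 0.0):
            return _INFEASIBLE * (1.0 - float(np.minimum(q, 0.0).sum()))
        s = float(np.sum(n * q))
        if c_tot <= 0.0:
            return log_fact
        k = math.log(c_tot / s)
        return -(float(np.sum(c * (np.log(n * q) + k))) - c_tot - log_fact)

    def prof(v: float) -> float:
        res = optimize.minimize(
            lambda x: nll_other(float(x[0]), v),
            np.array([state["other"]]),
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-11, "maxiter": 1000},
        )
        if np.isfinite(res.x[0]) and res.fun < _INFEASIBLE / 2:
            state["other"] = float(res.x[0])
        return -float(res.fun)

    mle = fit.alpha_hat if which == "alpha" else fit.beta_hat
    interval = profile_interval(
        prof, mle, fit.loglik_max, level=level, deviance_tol=deviance_tol
    )
    state["other"] = other0
    return interval


def _fit_with_cis(data: GroupedData, method_tag: str, compute_ci: bool) -> FitResult:
    fit = fit_ml(data, method_tag=method_tag)
    if compute_ci and fit.converged:
        ci_a = profile_ci(data, fit, "alpha")
        ci_b = profile_ci(data, fit, "beta")
        fit = replace(fit, ci_alpha=ci_a, ci_beta=ci_b)
    return fit


def fit_unadjusted(
    ensemble: DoseEnsemble,
    case_counts: np.ndarray,
    design: CohortDesign,
    compute_ci: bool = True,
) -> FitResult:
    """Unadjusted fit: grouped doses are group means of the single surrogate draw."""
    if ensemble.surrogate_doses is None:
        raise ValueError("ensemble has no surrogate doses")
    grouped = collapse_to_groups(
        case_counts, ensemble.surrogate_doses, ensemble.group_index, design
    )
    return _fit_with_cis(grouped, "unadjusted", compute_ci)


def fit_regcal(
    ensemble: DoseEnsemble,
    case_counts: np.ndarray,
    design: CohortDesign,
    compute_ci: bool = True,
) -> FitResult:
    """Regression-calibration fit: grouped doses are ensemble-averaged true group means."""
    cases_g = np.bincount(
        ensemble.group_index, weights=np.asarray(case_counts), minlength=design.n_groups
    ).astype(int)
    grouped = GroupedData(
        persons=design.persons.copy(),
        cases=cases_g,
        doses=calibrated_group_doses(ensemble),
    )
    return _fit_with_cis(grouped, "regcal", compute_ci)
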