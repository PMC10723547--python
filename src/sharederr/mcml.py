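"""Monte Carlo maximum likelihood over a dose-realization ensemble.

MCML propagates dosimetry uncertainty by averaging the grouped Poisson
likelihood — on the natural scale, not the log scale — over the R realizations
of per-group mean true doses, and then maximising that averaged likelihood:

    L_avg(alpha, beta, kappa) = (1/R) * sum_r L(alpha, beta, kappa; D_r)

The log of the average is computed with a max-shift (log-sum-exp), and
realizations for which the linear relative-risk factor goes non-positive
contribute likelihood zero (all infeasible => -inf).  Unlike the single-dataset
fit, kappa has no closed-form profile under the average, so fitting is a 3-D
Nelder-Mead search over (kappa, alpha, beta); profile confidence intervals are
computed on the averaged-likelihood surface.
"""

from __future__ import annotations

import math
from dataclasses import replace
from typing import Optional, Tuple

import numpy as np
from scipy import optimize
from scipy.special import gammaln

from .likelihood import FitResult, profile_interval, _INFEASIBLE
from .outcomes import RiskParameters

__all__ = ["averaged_log_likelihood", "fit_mcml"]


def _ensemble_logliks(
    cases: np.ndarray,
    dose_ensemble: np.ndarray,
    persons: np.ndarray,
    alpha: float,
    beta: float,
    kappa: float,
) -> np.ndarray:
    """Per-realization grouped Poisson log-likelihoods, -inf where infeasible."""
    d = np.asarray(dose_ensemble, dtype=float)  # (G, R)
    n = np.asarray(persons, dtype=float)[:, None]
    c = np.asarray(cases, dtype=float)[:, None]
    q = 1.0 + alpha * d + beta * d * d
    bad = (q <= 0.0).any(axis=0)
    q_safe = np.where(q > 0.0, q, 1.0)
    ek = math.exp(kappa)
    ll = (
        (c * (np.log(n * q_safe) + kappa)).sum(axis=0)
        - ek * (n * q_safe).sum(axis=0)
        - float(np.sum(gammaln(np.asarray(cases) + 1.0)))
    )
    ll[bad] = -math.inf
    return ll


def averaged_log_likelihood(
    cases: np.ndarray,
    group_dose_ensemble: np.ndarray,
    persons: np.ndarray,
    params: RiskParameters,
) -> float:
    """log[(1/R) * sum_r exp(loglik_r)] with log-sum-exp stabilisation.

    ``group_dose_ensemble`` is the (n_groups, R) matrix of per-realization
    group-mean doses; ``cases`` and ``persons`` are the grouped case and person
    counts shared by all realizations.
    """
    d = np.atleast_2d(np.asarray(group_dose_ensemble, dtype=float))
    if d.shape[0] != np.asarray(cases).size:
        d = d.T
    ll = _ensemble_logliks(cases, d, persons, params.alpha, params.beta, params.kappa)
    m = ll.max()
    if not np.isfinite(m):
        return -math.inf
    return float(m + np.log(np.exp(ll - m).sum()) - np.log(ll.size))


def fit_mcml(
    cases: np.ndarray,
    group_dose_ensemble: np.ndarray,
    persons: np.ndarray,
    init: Optional[RiskParameters] = None,
    compute_ci: bool = True,
) -> FitResult:
    """Maximise the ensemble-averaged likelihood and profile (alpha, beta) on it."""
    d = np.atleast_2d(np.asarray(group_dose_ensemble, dtype=float))
    if d.shape[0] != np.asarray(cases).size:
        d = d.T
    cases = np.asarray(cases)
    persons = np.asarray(persons, dtype=float)
    c_tot = float(cases.sum())

    def nll(x: np.ndarray) -> float:
        k, a, b = float(x[0]), float(x[1]), float(x[2])
        val = averaged_log_likelihood(cases, d, persons, RiskParameters(a, b, k))
        if not np.isfinite(val):
            dbar = d.mean(axis=1)
            viol = -float(np.minimum(1.0 + a * dbar + b * dbar * dbar, 0.0).sum())
            return _INFEASIBLE * (1.0 + viol)
        return -val

    if init is not None:
        a0, b0, k0 = init.alpha, init.beta, init.kappa
    else:
        a0, b0 = 0.1, 1.0
        dbar = d.mean(axis=1)
        s0 = float(np.sum(persons * (1.0 + a0 * dbar + b0 * dbar * dbar)))
        k0 = math.log(max(c_tot, 1.0) / s0)
    starts = [(k0, a0, b0), (k0, a0 + 0.5, b0 + 1.0), (k0 - 0.5, a0, b0 + 3.0)]
    best = None
    for s in starts:
        res = optimize.minimize(
            nll,
            np.asarray(s, dtype=float),
            method="Nelder-Mead",
            options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 4000},
        )
        if best is None or res.fun < best.fun:
            best = res
    res = optimize.minimize(
        nll,
        best.x,
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-11, "maxiter": 4000},
    )
    if res.fun > best.fun:
        res = best
    ok = bool(res.fun < _INFEASIBLE / 2) and np.all(np.isfinite(res.x))
    k_hat, a_hat, b_hat = (float(v) for v in res.x)
    fit = FitResult(
        alpha_hat=a_hat,
        beta_hat=b_hat,
        kappa_hat=k_hat,
        loglik_max=-float(res.fun) if ok else -math.inf,
        converged=ok,
        method_tag="mcml",
        message="" if ok else "no feasible maximum found",
    )
    if not (compute_ci and ok):
        return fit
    cis = {}
    for which in ("alpha", "beta"):
        mle = a_hat if which == "alpha" else b_hat
        other0 = b_hat if which == "alpha" else a_hat
        state = {"x": np.array([k_hat, other0])}

        def nll_inner(y: np.ndarray, v: float, which=which) -> float:
            k, o = float(y[0]), float(y[1])
            a, b = (v, o) if which == "alpha" else (o, v)
            return nll(np.array([k, a, b]))

        def prof(v: float) -> float:
            res_in = optimize.minimize(
                lambda y: nll_inner(y, v),
                state["x"],
                method="Nelder-Mead",
                options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 2000},
            )
            if res_in.fun < _INFEASIBLE / 2 and np.all(np.isfinite(res_in.x)):
                state["x"] = res_in.x
            return -float(res_in.fun)

        cis[which] = profile_interval(prof, mle, fit.loglik_max)
    return replace(fit, ci_alpha=cis["alpha"], ci_beta=cis["beta"])
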