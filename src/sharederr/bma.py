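"""Bayesian 2DMC-with-BMA fitter: blocked Metropolis-Hastings over (alpha, beta, kappa, lambda).

The two-dimensional Monte Carlo (2DMC) dosimetry ensemble supplies R candidate
dose "scenarios" — the per-realization group-mean true-dose vectors.  Bayesian
model averaging (BMA) assumes exactly one scenario is the correct one and mixes
the grouped Poisson likelihoods at the whole-dataset level with softmax
scenario weights

    p_j = exp(lambda_j) / (1 + sum_{k<R} exp(lambda_k)),   p_R = 1 / (1 + sum exp(lambda_k))

so that the sampler can reweight scenarios by goodness of fit.  The posterior
is therefore

    log [ sum_j p_j(lambda) * L_j(alpha, beta, kappa) ] + log priors

with independent N(0, 1000^2) priors on alpha, beta, kappa and every lambda_k.
Unlike the frequentist fits, kappa is a free parameter here.

Sampling uses symmetric normal random-walk proposals: kappa, alpha and beta are
updated singly (proposal SDs 0.2, 1, 1) and the lambdas in blocks of 10 with a
joint accept/reject per block (proposal SD 2).  Two chains are run — the second
initialised with overdispersed (+1) offsets on the main parameters — with 1000
burn-in sweeps discarded and 1000 kept, and convergence is monitored with the
Brooks-Gelman-Rubin potential-scale-reduction statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.special import gammaln
from scipy.stats import norm

from .outcomes import RiskParameters

__all__ = [
    "McmcSettings",
    "McmcResult",
    "PosteriorSummary",
    "scenario_probabilities",
    "posterior_log_density",
    "mh_sample",
    "metropolis_step",
    "bgr_statistic",
    "summarize_posterior",
]


@dataclass(frozen=True)
class McmcSettings:
    """Sampler configuration; defaults match the simulation-study protocol."""

    prior_sd: float = 1000.0
    proposal_sd_kappa: float = 0.2
    proposal_sd_alpha_beta: float = 1.0
    proposal_sd_lambda: float = 2.0
    lambda_block: int = 10
    n_chains: int = 2
    burn_in: int = 1000
    keep: int = 1000

    def __post_init__(self) -> None:
        for name in ("prior_sd", "lambda_block", "n_chains", "keep"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("proposal_sd_kappa", "proposal_sd_alpha_beta", "proposal_sd_lambda"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.burn_in < 0:
            raise ValueError("burn_in must be non-negative")


@dataclass
class McmcResult:
    """Retained draws (n_chains x keep) for the main parameters plus bookkeeping."""

    alpha: np.ndarray
    beta: np.ndarray
    kappa: np.ndarray
    acceptance: Dict[str, float]
    mean_scenario_probs: np.ndarray
    settings: McmcSettings

    @property
    def n_chains(self) -> int:
        return self.alpha.shape[0]

    def to_file(self, path) -> None:
        """Export retained draws as a delimited table (iteration, chain, alpha, beta, kappa)."""
        import pandas as pd

        rows = []
        for chain in range(self.n_chains):
            for it in range(self.alpha.shape[1]):
                rows.append(
                    (it, chain, self.alpha[chain, it], self.beta[chain, it], self.kappa[chain, it])
                )
        pd.DataFrame(
            rows, columns=["iteration", "chain", "alpha", "beta", "kappa"]
        ).to_csv(path, sep="\t", index=False)


@dataclass
class PosteriorSummary:
    """Pooled posterior means, equal-tailed 95% intervals and diagnostics."""

    mean_alpha: float
    ci_alpha: Tuple[float, float]
    mean_beta: float
    ci_beta: Tuple[float, float]
    acceptance: Dict[str, float] = field(default_factory=dict)
    bgr: Dict[str, float] = field(default_factory=dict)


def scenario_probabilities(lambdas: np.ndarray) -> np.ndarray:
    """Softmax-with-reference-category scenario weights (length R = len(lambdas)+1)."""
    lam = np.asarray(lambdas, dtype=float)
    logits = np.append(lam, 0.0)
    m = logits.max()
    e = np.exp(logits - m)
    return e / e.sum()


def _logsumexp(x: np.ndarray) -> float:
    m = x.max()
    if not np.isfinite(m):
        return -math.inf
    return float(m + np.log(np.exp(x - m).sum()))


class _MixtureModel:
    """Cached pieces of the scenario-mixture likelihood for one dataset.

    Per-scenario log-likelihood splits as ``l_j = kappa*C + A_j - exp(kappa)*S_j - lf``
    with ``A_j = sum_k c_k log(n_k q_jk)`` and ``S_j = sum_k n_k q_jk`` depending
    only on (alpha, beta), so kappa and lambda updates reuse cached (A, S).
    """

    def __init__(self, cases, group_dose_ensemble, persons):
        d = np.atleast_2d(np.asarray(group_dose_ensemble, dtype=float))
        if d.shape[0] == np.asarray(cases).size and d.shape[1] != np.asarray(cases).size:
            d = d.T  # store as (R, G)
        elif d.shape[1] != np.asarray(cases).size:
            raise ValueError("dose ensemble shape inconsistent with case vector")
        self.D = d
        self.D2 = d * d
        self.n = np.asarray(persons, dtype=float)
        self.c = np.asarray(cases, dtype=float)
        self.c_tot = float(self.c.sum())
        self.log_fact = float(np.sum(gammaln(np.asarray(cases) + 1.0)))
        self.n_scenarios = d.shape[0]

    def parts(self, alpha: float, beta: float):
        q = 1.0 + alpha * self.D + beta * self.D2
        bad = (q <= 0.0).any(axis=1)
        q_safe = np.where(q > 0.0, q, 1.0)
        a_part = (self.c * np.log(self.n * q_safe)).sum(axis=1)
        s_part = (self.n * q_safe).sum(axis=1)
        return a_part, s_part, bad

    def scenario_logliks(self, kappa: float, a_part, s_part, bad) -> np.ndarray:
        ll = kappa * self.c_tot + a_part - math.exp(kappa) * s_part - self.log_fact
        if bad.any():
            ll = np.where(bad, -math.inf, ll)
        return ll


def posterior_log_density(
    params: RiskParameters,
    lambdas: np.ndarray,
    cases: np.ndarray,
    group_dose_ensemble: np.ndarray,
    persons: np.ndarray,
    prior_sd: float = 1000.0,
) -> float:
    """Log posterior (mixture likelihood + normal log-priors), fully normalised."""
    model = _MixtureModel(cases, group_dose_ensemble, persons)
    lam = np.asarray(lambdas, dtype=float)
    if lam.size != model.n_scenarios - 1:
        raise ValueError("lambdas must have length n_scenarios - 1")
    a_part, s_part, bad = model.parts(params.alpha, params.beta)
    ell = model.scenario_logliks(params.kappa, a_part, s_part, bad)
    logits = np.append(lam, 0.0)
    logp = logits - _logsumexp(logits)
    mix = _logsumexp(logp + ell)
    if not np.isfinite(mix):
        return -math.inf
    prior = float(
        norm.logpdf(params.alpha, 0.0, prior_sd)
        + norm.logpdf(params.beta, 0.0, prior_sd)
        + norm.logpdf(params.kappa, 0.0, prior_sd)
        + norm.logpdf(lam, 0.0, prior_sd).sum()
    )
    return mix + prior


def metropolis_step(
    x: float,
    logpost_x: float,
    logpost_fn,
    proposal_sd: float,
    rng: np.random.Generator,
) -> Tuple[float, float, bool]:
    """One symmetric normal random-walk Metropolis update of a scalar parameter."""
    x_new = x + proposal_sd * rng.standard_normal()
    lp_new = logpost_fn(x_new)
    if math.log(rng.uniform()) < lp_new - logpost_x:
        return x_new, lp_new, True
    return x, logpost_x, False


def mh_sample(
    settings: McmcSettings,
    cases: np.ndarray,
    group_dose_ensemble: np.ndarray,
    persons: np.ndarray,
    rng: np.random.Generator,
    init: Optional[RiskParameters] = None,
) -> McmcResult:
    """Run the blocked Metropolis-Hastings sampler and return retained draws.

    Each sweep updates kappa, alpha and beta singly and the lambdas in blocks
    (joint accept/reject per block); the final block may be short.  Infeasible
    proposals (relative-risk factor non-positive in every scenario) are simply
    rejected.  Scenario weights are accumulated over retained sweeps into
    ``mean_scenario_probs``.
    """
    model = _MixtureModel(cases, group_dose_ensemble, persons)
    r = model.n_scenarios
    n_lam = r - 1
    block = int(settings.lambda_block)
    blocks = [np.arange(i, min(i + block, n_lam)) for i in range(0, n_lam, block)]
    inv2p = 0.5 / settings.prior_sd**2
    sd_k = settings.proposal_sd_kappa
    sd_ab = settings.proposal_sd_alpha_beta
    sd_lam = settings.proposal_sd_lambda

    n_iter = settings.burn_in + settings.keep
    alpha_draws = np.empty((settings.n_chains, settings.keep))
    beta_draws = np.empty_like(alpha_draws)
    kappa_draws = np.empty_like(alpha_draws)
    prob_accum = np.zeros(r)
    n_prob = 0
    acc = {"alpha": 0, "beta": 0, "kappa": 0, "lambda": 0}
    prop = {"alpha": 0, "beta": 0, "kappa": 0, "lambda": 0}

    chain_rngs = rng.spawn(settings.n_chains)
    for chain, crng in enumerate(chain_rngs):
        if init is not None:
            a, b = init.alpha, init.beta
            k = init.kappa
        else:
            a, b = 0.1, 1.0
            dbar = model.D.mean(axis=0)
            s0 = float(np.sum(model.n * (1.0 + a * dbar + b * dbar * dbar)))
            k = math.log(max(model.c_tot, 1.0) / s0)
        if chain > 0:
            a, b, k = a + 1.0, b + 1.0, k + 1.0
        lam = np.zeros(n_lam)
        a_part, s_part, bad = model.parts(a, b)
        ell = model.scenario_logliks(k, a_part, s_part, bad)
        logits = np.append(lam, 0.0)
        logp = logits - _logsumexp(logits)
        mix = _logsumexp(logp + ell)
        if not np.isfinite(mix):
            raise RuntimeError("infeasible chain initialisation")

        for it in range(n_iter):
            # kappa: reuse cached (A, S)
            k2 = k + sd_k * crng.standard_normal()
            ell2 = model.scenario_logliks(k2, a_part, s_part, bad)
            mix2 = _logsumexp(logp + ell2)
            prop["kappa"] += 1
            if math.log(crng.uniform()) < (mix2 - mix) - inv2p * (k2 * k2 - k * k):
                k, ell, mix = k2, ell2, mix2
                acc["kappa"] += 1
            # alpha
            a2 = a + sd_ab * crng.standard_normal()
            prop["alpha"] += 1
            ap2, sp2, bad2 = model.parts(a2, b)
            if not bad2.all():
                ell2 = model.scenario_logliks(k, ap2, sp2, bad2)
                mix2 = _logsumexp(logp + ell2)
                if math.log(crng.uniform()) < (mix2 - mix) - inv2p * (a2 * a2 - a * a):
                    a, a_part, s_part, bad, ell, mix = a2, ap2, sp2, bad2, ell2, mix2
                    acc["alpha"] += 1
            # beta
            b2 = b + sd_ab * crng.standard_normal()
            prop["beta"] += 1
            ap2, sp2, bad2 = model.parts(a, b2)
            if not bad2.all():
                ell2 = model.scenario_logliks(k, ap2, sp2, bad2)
                mix2 = _logsumexp(logp + ell2)
                if math.log(crng.uniform()) < (mix2 - mix) - inv2p * (b2 * b2 - b * b):
                    b, a_part, s_part, bad, ell, mix = b2, ap2, sp2, bad2, ell2, mix2
                    acc["beta"] += 1
            # lambda blocks: likelihood pieces fixed, only the weights move
            for idx in blocks:
                prop["lambda"] += 1
                lam2 = lam.copy()
                lam2[idx] = lam[idx] + sd_lam * crng.standard_normal(idx.size)
                logits2 = np.append(lam2, 0.0)
                logp2 = logits2 - _logsumexp(logits2)
                mix2 = _logsumexp(logp2 + ell)
                dprior = inv2p * float((lam2[idx] ** 2 - lam[idx] ** 2).sum())
                if math.log(crng.uniform()) < (mix2 - mix) - dprior:
                    lam, logp, mix = lam2, logp2, mix2
                    acc["lambda"] += 1
            if it >= settings.burn_in:
                j = it - settings.burn_in
                alpha_draws[chain, j] = a
                beta_draws[chain, j] = b
                kappa_draws[chain, j] = k
                prob_accum += np.exp(logp)
                n_prob += 1

    acceptance = {name: acc[name] / max(prop[name], 1) for name in acc}
    return McmcResult(
        alpha=alpha_draws,
        beta=beta_draws,
        kappa=kappa_draws,
        acceptance=acceptance,
        mean_scenario_probs=prob_accum / max(n_prob, 1),
        settings=settings,
    )


def bgr_statistic(chains: np.ndarray) -> float:
    """Brooks-Gelman-Rubin potential scale reduction factor for one parameter.

    ``chains`` is (n_chains, n_draws).  Returns NaN (flagged sentinel) when the
    within-chain variance is zero.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need >= 2 chains of equal length >= 2")
    n = x.shape[1]
    w = x.var(axis=1, ddof=1).mean()
    b_over_n = x.mean(axis=1).var(ddof=1)
    if w <= 0.0:
        return float("nan")
    v_hat = (n - 1) / n * w + b_over_n
    return float(math.sqrt(v_hat / w))


def summarize_posterior(result: McmcResult) -> PosteriorSummary:
    """Pooled-chain means, equal-tailed 95% credible intervals and diagnostics."""
    a = result.alpha.ravel()
    b = result.beta.ravel()
    qa = np.percentile(a, [2.5, 97.5])
    qb = np.percentile(b, [2.5, 97.5])
    bgr = {}
    if result.n_chains >= 2 and result.alpha.shape[1] >= 2:
        bgr = {
            "alpha": bgr_statistic(result.alpha),
            "beta": bgr_statistic(result.beta),
            "kappa": bgr_statistic(result.kappa),
        }
    return PosteriorSummary(
        mean_alpha=float(a.mean()),
        ci_alpha=(float(qa[0]), float(qa[1])),
        mean_beta=float(b.mean()),
        ci_beta=(float(qb[0]), float(qb[1])),
        acceptance=dict(result.acceptance),
        bgr=bgr,
    )
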