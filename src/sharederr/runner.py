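"""Orchestration of the factorial dose-error simulation study.

A scenario is one cell of the error grid (four GSDs).  For each of its
replications the runner draws a fresh true-dose ensemble and surrogate vector,
generates the case distribution from realization 0 of the true doses, runs each
requested correction method, and accumulates point estimates and 95%-interval
coverage indicators.  Scenario rows aggregate to coverage percentages, mean
coefficients, predicted-relative-risk bias at the configured prediction doses,
and the same-group true-dose correlation — the layout of the study's three
report tables.

Randomness is organised as named, independently seeded streams per replication
(Berkson shared/unshared, classical shared/unshared, outcome, MCMC), so that
changing the classical error settings leaves every dose-error-adjusted method's
results bit-identical, and any scenario or method can be re-run in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .bma import McmcSettings, mh_sample, summarize_posterior
from .cohort import (
    CohortDesign,
    ErrorModel,
    group_mean_doses,
    shared_dose_correlation,
    simulate_dose_ensemble,
)
from .likelihood import fit_regcal, fit_unadjusted
from .mcml import fit_mcml
from .outcomes import allocate_cases, case_probabilities

__all__ = [
    "ScenarioSpec",
    "EvaluationReport",
    "replication_rngs",
    "run_replication",
    "run_scenario",
    "coverage",
    "rr_bias",
    "write_reports",
    "read_report",
    "full_error_grid",
    "STREAM_NAMES",
]

STREAM_NAMES = (
    "berkson_shared",
    "berkson_unshared",
    "classical_shared",
    "classical_unshared",
    "outcome",
    "mcmc",
)

#: Known correction methods; "erc" is a plug-in slot with no shipped implementation.
KNOWN_METHODS = ("unadjusted", "regcal", "mcml", "bma")

#: Registry for externally provided methods (e.g. an extended-regression-
#: calibration likelihood adjustment).  A plug-in receives
#: (ensemble, case_counts, design, group_dose_ensemble) and returns a FitResult.
METHOD_PLUGINS: Dict[str, object] = {}


def replication_rngs(master_seed: int, replication: int) -> Dict[str, np.random.Generator]:
    """Independent named RNG streams for one replication of one master seed."""
    return {
        name: np.random.default_rng(
            np.random.SeedSequence([int(master_seed), int(replication), i])
        )
        for i, name in enumerate(STREAM_NAMES)
    }


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the simulation study: error settings plus run sizes."""

    error: ErrorModel = field(default_factory=ErrorModel)
    n_replications: int = 500
    n_realizations: int = 1000
    n_cases: int = 250
    methods: Tuple[str, ...] = ("unadjusted", "regcal", "mcml", "bma")
    master_seed: int = 1
    alpha_true: float = 0.25
    beta_true: float = 2.0
    prediction_doses: Tuple[float, ...] = (0.1, 1.0)
    mcmc: McmcSettings = field(default_factory=McmcSettings)

    def __post_init__(self) -> None:
        if self.n_replications < 1 or self.n_realizations < 1:
            raise ValueError("replications and realizations must be >= 1")
        for m in self.methods:
            if m not in KNOWN_METHODS and m not in METHOD_PLUGINS:
                raise ValueError(f"unknown method {m!r}")

    @property
    def label(self) -> str:
        e = self.error
        return "bu{:g}_bs{:g}_cu{:g}_cs{:g}".format(
            100 * e.sigma_unshare_berkson,
            100 * e.sigma_share_berkson,
            100 * e.sigma_unshare_class,
            100 * e.sigma_share_class,
        )


def full_error_grid() -> List[ErrorModel]:
    """The 20-cell study grid: Berkson in {(0,0)} u {0.2,0.5}^2, classical in {0.2,0.5}^2."""
    grid = []
    for bu, bs in [(0.0, 0.0), (0.2, 0.2), (0.2, 0.5), (0.5, 0.2), (0.5, 0.5)]:
        for cu, cs in [(0.2, 0.2), (0.2, 0.5), (0.5, 0.2), (0.5, 0.5)]:
            grid.append(
                ErrorModel(
                    sigma_share_berkson=bs,
                    sigma_unshare_berkson=bu,
                    sigma_share_class=cs,
                    sigma_unshare_class=cu,
                )
            )
    return grid


def coverage(intervals: Sequence[Tuple[float, float]], truth: float) -> float:
    """Percentage of closed intervals containing the truth (endpoints count)."""
    ints = list(intervals)
    if not ints:
        raise ValueError("need at least one interval")
    hits = sum(1 for lo, hi in ints if lo <= truth <= hi)
    return 100.0 * hits / len(ints)


def rr_bias(
    alpha_mean: float,
    beta_mean: float,
    d_pred: float,
    alpha_true: float = 0.25,
    beta_true: float = 2.0,
) -> float:
    """Percentage bias of the predicted relative risk at dose ``d_pred``.

    100 * [ (1 + a_mean*D + b_mean*D^2) / (1 + a_true*D + b_true*D^2) - 1 ].
    """
    num = 1.0 + alpha_mean * d_pred + beta_mean * d_pred**2
    den = 1.0 + alpha_true * d_pred + beta_true * d_pred**2
    if num <= 0.0 or den <= 0.0:
        raise ValueError("relative-risk factor must be positive at the prediction dose")
    return 100.0 * (num / den - 1.0)


def run_replication(
    design: CohortDesign,
    spec: ScenarioSpec,
    replication: int,
) -> Dict[str, object]:
    """Simulate one replication and run every requested method on it.

    Returns a dict with the ensemble correlation inputs and per-method results:
    FitResult for the frequentist methods, PosteriorSummary for "bma".
    """
    rngs = replication_rngs(spec.master_seed, replication)
    ensemble = simulate_dose_ensemble(design, spec.error, spec.n_realizations, rngs)
    probs, _ = case_probabilities(
        ensemble.true_doses[:, 0], spec.alpha_true, spec.beta_true
    )
    case_counts = allocate_cases(probs, spec.n_cases, rngs["outcome"])
    group_ens = None
    results: Dict[str, object] = {"ensemble": ensemble, "case_counts": case_counts}
    for method in spec.methods:
        if method in ("mcml", "bma") and group_ens is None:
            group_ens = group_mean_doses(
                ensemble.true_doses, ensemble.group_index, design.n_groups
            )
        if method == "unadjusted":
            results[method] = fit_unadjusted(ensemble, case_counts, design)
        elif method == "regcal":
            results[method] = fit_regcal(ensemble, case_counts, design)
        elif method == "mcml":
            cases_g = np.bincount(
                ensemble.group_index, weights=case_counts, minlength=design.n_groups
            ).astype(int)
            results[method] = fit_mcml(cases_g, group_ens, design.persons)
        elif method == "bma":
            cases_g = np.bincount(
                ensemble.group_index, weights=case_counts, minlength=design.n_groups
            ).astype(int)
            draws = mh_sample(
                spec.mcmc, cases_g, group_ens, design.persons, rngs["mcmc"]
            )
            results[method] = summarize_posterior(draws)
        else:
            results[method] = METHOD_PLUGINS[method](
                ensemble, case_counts, design, group_ens
            )
    return results


@dataclass
class EvaluationReport:
    """Long-format per-scenario, per-method evaluation rows."""

    rows: List[Dict[str, object]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


def _finite_interval(ci: Optional[Tuple[float, float]]) -> Tuple[float, float]:
    if ci is None:
        return (-np.inf, np.inf)
    lo, hi = ci
    lo = -np.inf if lo is None or not np.isfinite(lo) else lo
    hi = np.inf if hi is None or not np.isfinite(hi) else hi
    return (lo, hi)


def run_scenario(
    spec: ScenarioSpec,
    design: Optional[CohortDesign] = None,
    progress: bool = False,
) -> EvaluationReport:
    """Run every replication of one scenario and aggregate the evaluation row set."""
    design = design if design is not None else CohortDesign.default()
    acc: Dict[str, Dict[str, list]] = {
        m: {"alpha": [], "beta": [], "ci_alpha": [], "ci_beta": [], "extras": []}
        for m in spec.methods
    }
    n_failed = {m: 0 for m in spec.methods}
    corr = np.nan
    for rep in range(spec.n_replications):
        results = run_replication(design, spec, rep)
        if rep == 0 and spec.n_realizations >= 2:
            corr = shared_dose_correlation(results["ensemble"])
        for m in spec.methods:
            res = results[m]
            if hasattr(res, "converged") and not res.converged:
                n_failed[m] += 1
                continue
            if hasattr(res, "alpha_hat"):
                acc[m]["alpha"].append(res.alpha_hat)
                acc[m]["beta"].append(res.beta_hat)
                acc[m]["ci_alpha"].append(_finite_interval(res.ci_alpha))
                acc[m]["ci_beta"].append(_finite_interval(res.ci_beta))
            else:  # PosteriorSummary
                acc[m]["alpha"].append(res.mean_alpha)
                acc[m]["beta"].append(res.mean_beta)
                acc[m]["ci_alpha"].append(_finite_interval(res.ci_alpha))
                acc[m]["ci_beta"].append(_finite_interval(res.ci_beta))
                acc[m]["extras"].append(
                    {
                        "acceptance_alpha": res.acceptance.get("alpha", np.nan),
                        "acceptance_beta": res.acceptance.get("beta", np.nan),
                        "acceptance_kappa": res.acceptance.get("kappa", np.nan),
                        "bgr_alpha": res.bgr.get("alpha", np.nan),
                        "bgr_beta": res.bgr.get("beta", np.nan),
                        "bgr_kappa": res.bgr.get("kappa", np.nan),
                    }
                )
        if progress and (rep + 1) % 25 == 0:
            print(f"[{spec.label}] replication {rep + 1}/{spec.n_replications}")
    report = EvaluationReport()
    e = spec.error
    for m in spec.methods:
        a = np.asarray(acc[m]["alpha"])
        b = np.asarray(acc[m]["beta"])
        if a.size == 0:
            raise RuntimeError(f"method {m!r} failed in every replication")
        row: Dict[str, object] = {
            "scenario": spec.label,
            "berkson_unshared": e.sigma_unshare_berkson,
            "berkson_shared": e.sigma_share_berkson,
            "classical_unshared": e.sigma_unshare_class,
            "classical_shared": e.sigma_share_class,
            "method": m,
            "n_replications": spec.n_replications,
            "n_realizations": spec.n_realizations,
            "n_cases": spec.n_cases,
            "n_failed": n_failed[m],
            "dose_correlation": corr,
            "coverage_alpha": coverage(acc[m]["ci_alpha"], spec.alpha_true),
            "coverage_beta": coverage(acc[m]["ci_beta"], spec.beta_true),
            "mean_alpha": float(a.mean()),
            "mean_beta": float(b.mean()),
            "se_alpha": float(a.std(ddof=1) / np.sqrt(a.size)) if a.size > 1 else np.nan,
            "se_beta": float(b.std(ddof=1) / np.sqrt(b.size)) if b.size > 1 else np.nan,
        }
        for d_pred in spec.prediction_doses:
            row[f"rr_bias_{d_pred:g}Gy"] = rr_bias(
                float(a.mean()), float(b.mean()), d_pred, spec.alpha_true, spec.beta_true
            )
        if acc[m]["extras"]:
            ex = pd.DataFrame(acc[m]["extras"]).mean()
            row.update({k: float(v) for k, v in ex.items()})
        report.rows.append(row)
    return report


def run_study(
    specs: Sequence[ScenarioSpec],
    design: Optional[CohortDesign] = None,
    progress: bool = False,
) -> EvaluationReport:
    """Run several scenarios and concatenate their report rows."""
    report = EvaluationReport()
    for spec in specs:
        if progress:
            print(f"scenario {spec.label}: methods {','.join(spec.methods)}")
        report.rows.extend(run_scenario(spec, design=design, progress=progress).rows)
    return report


def write_reports(report: EvaluationReport, out_dir, manifest: Optional[dict] = None) -> None:
    """Write coverage / coefficient / RR-bias tables, the long file and a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = report.to_frame()
    df.to_csv(out / "report_long.csv", index=False)
    scenario_cols = [
        "scenario",
        "berkson_unshared",
        "berkson_shared",
        "classical_unshared",
        "classical_shared",
    ]
    if not df.empty:
        for name, values in (
            ("coverage", ["coverage_alpha", "coverage_beta"]),
            ("coefficients", ["mean_alpha", "mean_beta"]),
            ("rr_bias", [c for c in df.columns if c.startswith("rr_bias_")]),
        ):
            wide = df.pivot_table(
                index=scenario_cols + ["dose_correlation"],
                columns="method",
                values=values,
                sort=False,
            )
            wide.columns = [f"{v}_{m}" for v, m in wide.columns]
            wide.reset_index().to_csv(out / f"table_{name}.csv", sep="\t", index=False)
    else:
        for name in ("coverage", "coefficients", "rr_bias"):
            (out / f"table_{name}.csv").write_text("scenario\n")
    if manifest is not None:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def read_report(long_csv) -> EvaluationReport:
    """Re-parse a written long-format report file."""
    df = pd.read_csv(long_csv)
    return EvaluationReport(rows=df.to_dict(orient="records"))


def manifest_for(specs: Sequence[ScenarioSpec]) -> dict:
    """Machine-readable run manifest (seeds and settings; reproducibility record)."""
    from . import __version__

    return {
        "package_version": __version__,
        "scenarios": [
            {
                **asdict(s.error),
                "label": s.label,
                "n_replications": s.n_replications,
                "n_realizations": s.n_realizations,
                "n_cases": s.n_cases,
                "methods": list(s.methods),
                "master_seed": s.master_seed,
                "mcmc": asdict(s.mcmc),
            }
            for s in specs
        ],
    }
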