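"""Steering-file configuration: YAML -> scenario specifications.

A steering file looks like::

    defaults:
      replications: 500
      realizations: 1000
      cases: 250
      seed: 1
      methods: [unadjusted, regcal, mcml, bma]
      prediction_doses: [0.1, 1.0]
    mcmc:
      burn_in: 1000
      keep: 1000
    scenarios: full-grid        # or an explicit list of error settings:
    # scenarios:
    #   - {berkson_unshared: 0.2, berkson_shared: 0.5,
    #      classical_unshared: 0.2, classical_shared: 0.2}

GSD values are log-scale standard deviations (0.2 for "20%").
"""

from __future__ import annotations

from typing import List, Optional

import yaml

from .bma import McmcSettings
from .cohort import ErrorModel
from .runner import ScenarioSpec, full_error_grid

__all__ = ["load_config", "specs_from_dict"]


def _error_from_dict(d: dict) -> ErrorModel:
    return ErrorModel(
        sigma_share_berkson=float(d.get("berkson_shared", 0.0)),
        sigma_unshare_berkson=float(d.get("berkson_unshared", 0.0)),
        sigma_share_class=float(d.get("classical_shared", 0.0)),
        sigma_unshare_class=float(d.get("classical_unshared", 0.0)),
    )


def specs_from_dict(cfg: dict) -> List[ScenarioSpec]:
    """Build scenario specs from a parsed steering dictionary."""
    defaults = cfg.get("defaults", {})
    mcmc = McmcSettings(**cfg.get("mcmc", {}))
    scenarios = cfg.get("scenarios", "full-grid")
    if scenarios == "full-grid":
        errors = full_error_grid()
    else:
        errors = [_error_from_dict(s) for s in scenarios]
    common = dict(
        n_replications=int(defaults.get("replications", 500)),
        n_realizations=int(defaults.get("realizations", 1000)),
        n_cases=int(defaults.get("cases", 250)),
        methods=tuple(defaults.get("methods", ("unadjusted", "regcal", "mcml", "bma"))),
        master_seed=int(defaults.get("seed", 1)),
        alpha_true=float(defaults.get("alpha_true", 0.25)),
        beta_true=float(defaults.get("beta_true", 2.0)),
        prediction_doses=tuple(defaults.get("prediction_doses", (0.1, 1.0))),
        mcmc=mcmc,
    )
    return [ScenarioSpec(error=e, **common) for e in errors]


def load_config(path) -> List[ScenarioSpec]:
    """Read a YAML steering file into a list of scenario specifications."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return specs_from_dict(cfg)
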