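"""Grouped cohort design and multiplicative Berkson/classical dose-error simulation.

The cohort is a small grouped design: every individual belongs to one of a
handful of dose groups, each with a central (nominal) dose estimate.  True and
surrogate (measured) doses scatter multiplicatively around the central estimate
with lognormal errors split into a component shared by every individual within
one realization (a systematic dosimetry-system draw) and an individual-specific
unshared component::

    D_true,i,r = D_cent,k(i) * exp(-(s_sh^2 + s_un^2)/2) * exp(s_sh*e_r + s_un*d_ir)

where ``e_r`` and ``d_ir`` are independent standard normals, ``s_sh`` and
``s_un`` are the shared/unshared Berkson log-scale standard deviations (the
"geometric standard deviations", 0.2 for "20%"), and the leading factor makes
the theoretical mean of each dose equal its central estimate.  The surrogate
dose follows the same construction with the classical-error standard deviations
and its own shared/unshared draws, so it is conditionally independent of the
true dose given the dose group — a pure multiplicative classical-error
surrogate.

Setting all four standard deviations to zero recovers the error-free design
exactly; setting only the classical pair to zero gives a pure (shared +
unshared) Berkson model, and vice versa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

__all__ = [
    "CohortDesign",
    "ErrorModel",
    "DoseEnsemble",
    "simulate_true_doses",
    "simulate_surrogate_doses",
    "simulate_dose_ensemble",
    "group_mean_doses",
    "calibrated_group_doses",
    "shared_dose_correlation",
    "pairwise_correlation_closed_form",
]

#: Default grouped design: central doses (Gy) and scaled person counts per group.
DEFAULT_CENTRAL_DOSES = (0.01, 0.1, 0.5, 1.5, 2.0)
DEFAULT_PERSONS = (2591, 334, 438, 102, 6)


@dataclass(frozen=True)
class CohortDesign:
    """Ordered dose groups with central dose estimates and person counts."""

    central_doses: np.ndarray
    persons: np.ndarray

    def __post_init__(self) -> None:
        cd = np.atleast_1d(np.asarray(self.central_doses, dtype=float))
        pp = np.atleast_1d(np.asarray(self.persons, dtype=int))
        if cd.shape != pp.shape or cd.ndim != 1:
            raise ValueError("central_doses and persons must be 1-D and of equal length")
        if np.any(pp <= 0):
            raise ValueError("every dose group must contain at least one person")
        if np.any(cd <= 0) or np.any(np.diff(cd) <= 0):
            raise ValueError("central doses must be positive and strictly increasing")
        object.__setattr__(self, "central_doses", cd)
        object.__setattr__(self, "persons", pp)

    @property
    def n_groups(self) -> int:
        return self.central_doses.size

    @property
    def n_persons(self) -> int:
        return int(self.persons.sum())

    def group_index(self) -> np.ndarray:
        """Per-individual group membership, individuals ordered by group."""
        return np.repeat(np.arange(self.n_groups), self.persons)

    def person_central_doses(self) -> np.ndarray:
        """Per-individual central dose (Gy)."""
        return self.central_doses[self.group_index()]

    @classmethod
    def default(cls) -> "CohortDesign":
        """The built-in 5-group, 3471-person leukaemia-cohort-like design."""
        return cls(np.array(DEFAULT_CENTRAL_DOSES), np.array(DEFAULT_PERSONS))

    @classmethod
    def from_file(cls, path) -> "CohortDesign":
        """Read a delimited design file with columns group, central_dose_Gy, persons."""
        df = pd.read_csv(path, sep=None, engine="python")
        df = df.sort_values("group")
        return cls(df["central_dose_Gy"].to_numpy(float), df["persons"].to_numpy(int))

    def to_file(self, path) -> None:
        pd.DataFrame(
            {
                "group": np.arange(1, self.n_groups + 1),
                "central_dose_Gy": self.central_doses,
                "persons": self.persons,
            }
        ).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class ErrorModel:
    """Log-scale error standard deviations (GSDs: 0.2 means sigma = 0.2).

    ``*_berkson`` act on the true dose (true scatters around nominal),
    ``*_class`` on the surrogate dose (measurement scatters around nominal,
    independently of the true dose given the group).
    """

    sigma_share_berkson: float = 0.0
    sigma_unshare_berkson: float = 0.0
    sigma_share_class: float = 0.0
    sigma_unshare_class: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "sigma_share_berkson",
            "sigma_unshare_berkson",
            "sigma_share_class",
            "sigma_unshare_class",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class DoseEnsemble:
    """Per-individual true-dose realizations and one surrogate-dose draw.

    ``true_doses`` has shape (n_individuals, n_realizations); the surrogate is
    a single vector because the unadjusted method uses one sampled dose per
    individual per replication.  Group membership is fixed by design and never
    changes with the realized dose.
    """

    true_doses: np.ndarray
    group_index: np.ndarray
    surrogate_doses: Optional[np.ndarray] = None

    @property
    def n_individuals(self) -> int:
        return self.true_doses.shape[0]

    @property
    def n_realizations(self) -> int:
        return self.true_doses.shape[1]

    def to_file(self, path) -> None:
        """Export the true-dose matrix (one row per individual) for debugging."""
        np.savetxt(path, self.true_doses, delimiter="\t")


def _lognormal_field(
    central: np.ndarray,
    sigma_shared: float,
    sigma_unshared: float,
    n_realizations: int,
    rng_shared: np.random.Generator,
    rng_unshared: np.random.Generator,
) -> np.ndarray:
    """Mean-preserving multiplicative error field, shape (n, n_realizations)."""
    n = central.size
    bias = math.exp(-0.5 * (sigma_shared**2 + sigma_unshared**2))
    if sigma_shared == 0.0 and sigma_unshared == 0.0:
        # Degenerate lognormal: every dose equals its central estimate.
        return np.broadcast_to(central[:, None], (n, n_realizations))
    if sigma_unshared > 0.0:
        log_err = sigma_unshared * rng_unshared.standard_normal((n, n_realizations))
        if sigma_shared > 0.0:
            log_err += sigma_shared * rng_shared.standard_normal(n_realizations)[None, :]
    else:
        eps = sigma_shared * rng_shared.standard_normal(n_realizations)
        log_err = np.broadcast_to(eps[None, :], (n, n_realizations)).copy()
    return central[:, None] * bias * np.exp(log_err)


def simulate_true_doses(
    design: CohortDesign,
    err: ErrorModel,
    n_realizations: int,
    rng: np.random.Generator,
    rng_unshared: Optional[np.random.Generator] = None,
) -> DoseEnsemble:
    """Draw a true-dose ensemble under the shared/unshared Berkson model.

    One shared draw per realization (common to all individuals in all groups)
    and one unshared draw per individual per realization.  ``rng`` supplies the
    shared draws; pass a distinct ``rng_unshared`` to keep the two streams
    independent (the experiment runner does).
    """
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    true = _lognormal_field(
        design.person_central_doses(),
        err.sigma_share_berkson,
        err.sigma_unshare_berkson,
        n_realizations,
        rng,
        rng_unshared if rng_unshared is not None else rng,
    )
    return DoseEnsemble(true_doses=true, group_index=design.group_index())


def simulate_surrogate_doses(
    design: CohortDesign,
    err: ErrorModel,
    rng: np.random.Generator,
    rng_unshared: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Draw one surrogate-dose vector under the shared/unshared classical model."""
    surr = _lognormal_field(
        design.person_central_doses(),
        err.sigma_share_class,
        err.sigma_unshare_class,
        1,
        rng,
        rng_unshared if rng_unshared is not None else rng,
    )
    return np.array(surr[:, 0])


def simulate_dose_ensemble(
    design: CohortDesign,
    err: ErrorModel,
    n_realizations: int,
    rngs: Mapping[str, np.random.Generator],
) -> DoseEnsemble:
    """Full ensemble (true-dose matrix + surrogate vector) from named RNG streams.

    ``rngs`` must provide the keys ``berkson_shared``, ``berkson_unshared``,
    ``classical_shared`` and ``classical_unshared`` (see
    :func:`sharederr.replication_rngs`); the four streams are independent so
    that varying the classical error settings leaves the true doses — and hence
    every dose-error-adjusted fit — bit-identical.
    """
    ens = simulate_true_doses(
        design, err, n_realizations, rngs["berkson_shared"], rngs["berkson_unshared"]
    )
    ens.surrogate_doses = simulate_surrogate_doses(
        design, err, rngs["classical_shared"], rngs["classical_unshared"]
    )
    return ens


def group_mean_doses(
    doses: np.ndarray,
    group_index: np.ndarray,
    n_groups: Optional[int] = None,
) -> np.ndarray:
    """Arithmetic mean dose per group, per realization.

    ``doses`` may be a vector (n,) or a matrix (n, R); the result is (G,) or
    (G, R) respectively.
    """
    d = np.asarray(doses, dtype=float)
    gi = np.asarray(group_index)
    one_d = d.ndim == 1
    d2 = d[:, None] if one_d else d
    if d2.shape[0] != gi.size:
        raise ValueError("doses and group_index have inconsistent lengths")
    g = int(n_groups) if n_groups is not None else int(gi.max()) + 1
    counts = np.bincount(gi, minlength=g)
    if np.any(counts == 0):
        raise ValueError("every group must contain at least one individual")
    if np.all(np.diff(gi) >= 0):
        starts = np.searchsorted(gi, np.arange(g))
        sums = np.add.reduceat(d2, starts, axis=0)
    else:
        sums = np.zeros((g, d2.shape[1]))
        np.add.at(sums, gi, d2)
    means = sums / counts[:, None]
    return means[:, 0] if one_d else means


def calibrated_group_doses(ensemble: DoseEnsemble) -> np.ndarray:
    """Regression-calibration doses: per-group means averaged over realizations."""
    return group_mean_doses(ensemble.true_doses, ensemble.group_index).mean(axis=1)


def shared_dose_correlation(ensemble: DoseEnsemble) -> float:
    """Sample Pearson correlation between true doses of distinct same-group individuals.

    Within each group, individuals are paired off disjointly; each pair
    contributes one (x, y) point per realization, with both coordinates scaled
    by the group's overall mean dose so that pairs from different dose groups
    are identically distributed and can be pooled.  Returns NaN when the doses
    are degenerate (zero variance, e.g. no Berkson error).
    """
    d = ensemble.true_doses
    gi = ensemble.group_index
    if d.shape[1] < 2:
        raise ValueError("need at least 2 realizations to estimate a correlation")
    sx = sy = sxx = syy = sxy = 0.0
    n_pts = 0
    for g in np.unique(gi):
        idx = np.flatnonzero(gi == g)
        if idx.size < 2:
            continue
        k = idx.size // 2
        scale = float(np.mean(d[idx, :]))
        x = d[idx[0 : 2 * k : 2], :] / scale
        y = d[idx[1 : 2 * k : 2], :] / scale
        sx += float(x.sum())
        sy += float(y.sum())
        sxx += float((x * x).sum())
        syy += float((y * y).sum())
        sxy += float((x * y).sum())
        n_pts += x.size
    if n_pts < 2:
        raise ValueError("need at least one group with 2 or more individuals")
    vx = sxx - sx * sx / n_pts
    vy = syy - sy * sy / n_pts
    cxy = sxy - sx * sy / n_pts
    if vx <= 0.0 or vy <= 0.0:
        return float("nan")
    return cxy / math.sqrt(vx * vy)


def pairwise_correlation_closed_form(sigma_shared: float, sigma_unshared: float) -> float:
    """Theoretical same-group dose correlation, (e^{s_sh^2}-1)/(e^{s_sh^2+s_un^2}-1)."""
    denom = math.exp(sigma_shared**2 + sigma_unshared**2) - 1.0
    if denom == 0.0:
        return float("nan")
    return (math.exp(sigma_shared**2) - 1.0) / denom
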