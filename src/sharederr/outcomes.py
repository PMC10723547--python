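"""Synthetic cancer-case generation under the linear-quadratic relative-risk model.

Each individual's probability of being one of the N observed cases is
proportional to the relative-risk factor ``1 + alpha*D + beta*D^2`` evaluated
at that individual's true dose, normalised to sum to one over the cohort by the
scaling constant ``exp(kappa)``.  A fixed total of N cases (default 250) is
then distributed over individuals by a multinomial draw, and the individual
data are collapsed (summing cases, averaging doses) back to the design's dose
groups for grouped Poisson fitting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
import pandas as pd

from .cohort import CohortDesign, group_mean_doses

__all__ = [
    "RiskParameters",
    "GroupedData",
    "case_probabilities",
    "allocate_cases",
    "collapse_to_groups",
]


@dataclass(frozen=True)
class RiskParameters:
    """Linear-quadratic excess-relative-risk coefficients.

    ``alpha`` is the excess relative risk per Gy, ``beta`` per Gy^2, and
    ``kappa`` the log baseline scaling.  The relative-risk factor
    ``1 + alpha*D + beta*D^2`` must stay positive over the doses at hand.
    """

    alpha: float
    beta: float
    kappa: float = 0.0


@dataclass
class GroupedData:
    """Collapsed per-group data: person counts (offsets), cases, assigned dose (Gy)."""

    persons: np.ndarray
    cases: np.ndarray
    doses: np.ndarray

    def __post_init__(self) -> None:
        self.persons = np.asarray(self.persons, dtype=int)
        self.cases = np.asarray(self.cases, dtype=int)
        self.doses = np.asarray(self.doses, dtype=float)
        if not (self.persons.shape == self.cases.shape == self.doses.shape):
            raise ValueError("persons, cases and doses must have equal shapes")
        if np.any(self.cases < 0):
            raise ValueError("case counts must be non-negative")

    @property
    def n_groups(self) -> int:
        return self.persons.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": np.arange(1, self.n_groups + 1),
                "persons": self.persons,
                "cases": self.cases,
                "dose_Gy": self.doses,
            }
        )

    def to_file(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_file(cls, path) -> "GroupedData":
        df = pd.read_csv(path, sep=None, engine="python").sort_values("group")
        return cls(
            df["persons"].to_numpy(int),
            df["cases"].to_numpy(int),
            df["dose_Gy"].to_numpy(float),
        )


def case_probabilities(
    true_doses: np.ndarray, alpha: float, beta: float
) -> Tuple[np.ndarray, float]:
    """Per-individual case probabilities and the normalising constant kappa.

    Returns ``p_i = exp(kappa) * (1 + alpha*D_i + beta*D_i^2)`` with
    ``kappa = -log sum_i (1 + alpha*D_i + beta*D_i^2)`` so the probabilities
    sum to one.
    """
    d = np.asarray(true_doses, dtype=float)
    q = 1.0 + alpha * d + beta * d * d
    if np.any(q <= 0.0):
        raise ValueError("relative-risk factor 1 + alpha*D + beta*D^2 must be positive")
    total = float(q.sum())
    kappa = -np.log(total)
    return q / total, float(kappa)


def allocate_cases(
    probabilities: np.ndarray, n_cases: int, rng: np.random.Generator
) -> np.ndarray:
    """Distribute a fixed total of cases over individuals by a multinomial draw."""
    p = np.asarray(probabilities, dtype=float)
    if np.any(p < 0.0):
        raise ValueError("probabilities must be non-negative")
    if n_cases < 0:
        raise ValueError("n_cases must be non-negative")
    total = p.sum()
    if not np.isfinite(total) or total <= 0.0:
        raise ValueError("probabilities must have a positive finite sum")
    return rng.multinomial(int(n_cases), p / total)


def collapse_to_groups(
    case_counts: np.ndarray,
    doses: np.ndarray,
    group_index: np.ndarray,
    design: CohortDesign,
) -> GroupedData:
    """Collapse individual data to the design groups (summing cases, averaging doses).

    ``doses`` is whichever per-individual dose vector the downstream method
    uses (e.g. the surrogate draw for the unadjusted fit).
    """
    cc = np.asarray(case_counts)
    gi = np.asarray(group_index)
    if cc.size != gi.size:
        raise ValueError("case_counts and group_index have inconsistent lengths")
    cases_g = np.bincount(gi, weights=cc, minlength=design.n_groups).astype(int)
    dose_g = group_mean_doses(doses, gi, design.n_groups)
    return GroupedData(persons=design.persons.copy(), cases=cases_g, doses=dose_g)
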