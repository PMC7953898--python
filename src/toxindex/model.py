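"""Generative models for sparse toxicity data.

Under an i.i.d. categorical model for a profile of ``d`` AEs, the grade
frequency vector is multinomial; dropping the grade-0 class gives the
``Mult|0>`` distribution for the RFV.  In the sparse regime — large ``d``
with per-grade probabilities ``lambda_r / d`` — the RFV converges in
distribution to a product of independent Poissons, ``Poi(lambda)``.  That
*Poisson-Limit model* is the basis of all analytic moments and tests in
this package.

This module provides the rate-vector container, samplers for both the
finite-``d`` multinomial model and its Poisson limit, the pooled maximum-
likelihood rate estimate (the coordinatewise mean of the RFVs), and the
ten-patient worked example that recurs throughout the documentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .summaries import RFV

__all__ = [
    "RateVector",
    "Cohort",
    "sample_mult0",
    "sample_poisson",
    "sample_two_arm",
    "fit_rate",
    "table1_fixture",
]


@dataclass(frozen=True)
class RateVector:
    """Poisson-Limit rates ``lambda = (lambda_1, ..., lambda_K)``.

    ``total`` is ``lambda_+ = sum_r lambda_r`` — the expected number of
    nonzero-grade AEs per patient.  ``normalized`` is the probability
    distribution ``lambda / lambda_+`` over grades 1..K (all-zero when
    ``lambda_+ = 0``).  Exact zero coordinates are allowed everywhere.
    """

    rates: tuple[float, ...]

    def __init__(self, rates: Iterable[float]) -> None:
        rates = tuple(float(r) for r in rates)
        if not rates:
            raise ValueError("a rate vector needs at least one grade")
        for k, r in enumerate(rates, start=1):
            if not np.isfinite(r) or r < 0:
                raise ValueError(f"rate {r!r} at grade {k} is not a finite nonnegative real")
        object.__setattr__(self, "rates", rates)

    @property
    def K(self) -> int:
        return len(self.rates)

    @property
    def total(self) -> float:
        return float(sum(self.rates))

    @property
    def normalized(self) -> np.ndarray:
        tot = self.total
        arr = self.as_array()
        return arr / tot if tot > 0 else np.zeros_like(arr)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.rates, dtype=float)


def _as_rates(lam: "RateVector | Sequence[float]") -> RateVector:
    return lam if isinstance(lam, RateVector) else RateVector(lam)


@dataclass
class Cohort:
    """A treatment arm: one RFV per patient, all sharing the same K."""

    rfvs: list[RFV]
    treatment_label: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rfvs = [x if isinstance(x, RFV) else RFV(x) for x in self.rfvs]
        ks = {x.K for x in self.rfvs}
        if len(ks) > 1:
            raise ValueError(f"cohort mixes RFVs of different K: {sorted(ks)}")

    @property
    def K(self) -> int:
        if not self.rfvs:
            raise ValueError("empty cohort has no K")
        return self.rfvs[0].K

    def __len__(self) -> int:
        return len(self.rfvs)

    def to_matrix(self) -> np.ndarray:
        """(n, K) count matrix, one row per patient."""
        return np.array([x.counts for x in self.rfvs], dtype=float)

    @classmethod
    def from_matrix(cls, X: np.ndarray, treatment_label: str = "", **metadata) -> "Cohort":
        rfvs = [RFV(row) for row in np.asarray(X, dtype=int)]
        return cls(rfvs, treatment_label, dict(metadata))


def sample_mult0(
    d: int,
    lam: "RateVector | Sequence[float]",
    n: int,
    seed: "int | np.random.Generator | None" = None,
    treatment_label: str = "",
) -> Cohort:
    """Draw ``n`` RFVs from the finite-d multinomial model ``Mult|0>(d, lam/d)``.

    Each patient has ``d`` AEs, each independently at grade ``r`` with
    probability ``lambda_r / d`` (and grade 0 otherwise); the grade-0
    count is dropped.  Requires ``d >= lambda_+`` so the grade-0
    probability is nonnegative — the model is meant for sparse profiles
    where ``d`` is large relative to the total rate.
    """
    lam = _as_rates(lam)
    if n < 1:
        raise ValueError("need at least one patient")
    if d < lam.total:
        raise ValueError(
            f"d={d} is smaller than the total rate {lam.total}: the Mult|0> model "
            "requires d >= sum(rates) so that the grade-0 probability is nonnegative"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = np.concatenate([[1.0 - lam.total / d], lam.as_array() / d])
    full = rng.multinomial(d, p, size=n)
    return Cohort.from_matrix(full[:, 1:], treatment_label, model="mult0", d=d, rates=lam.rates)


def sample_poisson(
    lam: "RateVector | Sequence[float]",
    n: int,
    seed: "int | np.random.Generator | None" = None,
    treatment_label: str = "",
) -> Cohort:
    """Draw ``n`` RFVs from the Poisson-Limit model ``Poi(lambda)``."""
    lam = _as_rates(lam)
    if n < 1:
        raise ValueError("need at least one patient")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = rng.poisson(lam.as_array(), size=(n, lam.K))
    return Cohort.from_matrix(X, treatment_label, model="poisson", rates=lam.rates)


def sample_two_arm(
    lam: "RateVector | Sequence[float]",
    gam: "RateVector | Sequence[float]",
    n: int,
    m: int,
    seed: int | None = None,
) -> tuple[Cohort, Cohort]:
    """Draw paired treatment arms ``X ~ Poi(lam)^n`` and ``Y ~ Poi(gam)^m``.

    Child seeds for the two arms are derived deterministically from one
    seed, so the pair is reproducible from a single integer.
    """
    ss = np.random.SeedSequence(seed)
    rng_x, rng_y = (np.random.default_rng(s) for s in ss.spawn(2))
    return (
        sample_poisson(lam, n, rng_x, treatment_label="1"),
        sample_poisson(gam, m, rng_y, treatment_label="2"),
    )


def fit_rate(*cohorts: Cohort) -> RateVector:
    """Pooled rate estimate: the coordinatewise mean of all RFVs.

    This is the maximum-likelihood estimate of ``lambda`` under the
    Poisson-Limit model, and the variance anchor of the two-sample test
    when cohorts from both arms are pooled.
    """
    if not cohorts:
        raise ValueError("need at least one cohort")
    rows = [x.as_array() for c in cohorts for x in c.rfvs]
    if not rows:
        raise ValueError("cannot fit a rate vector to zero patients")
    return RateVector(np.mean(rows, axis=0))


# Ten-patient two-arm worked example (K=5, n=m=5), generated from
# Poisson-Limit models with rates (0,5,1,5,0) and (0,1,1,1.5,0) and listed
# in decreasing T-rank.  Used throughout the docs and tests.
_TABLE1 = {
    "1": [(0, 3, 0, 7, 0), (0, 5, 1, 6, 0), (0, 8, 1, 4, 0), (0, 4, 3, 3, 0), (0, 4, 2, 3, 0)],
    "2": [(0, 1, 0, 3, 0), (0, 1, 3, 1, 0), (0, 4, 1, 1, 0), (0, 2, 0, 1, 0), (0, 1, 0, 0, 0)],
}


def table1_fixture() -> tuple[Cohort, Cohort]:
    """The hypothetical two-arm trial: 5 patients per arm, K=5."""
    return (
        Cohort([RFV(x) for x in _TABLE1["1"]], treatment_label="1"),
        Cohort([RFV(x) for x in _TABLE1["2"]], treatment_label="2"),
    )
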