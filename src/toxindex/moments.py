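"""Closed-form moments of the summary measures under the Poisson-Limit model.

For ``X ~ Poi(lambda)`` (independent coordinates, coordinate ``r`` Poisson
with mean ``lambda_r``), each summary ``g`` in {TI, mx, avg} admits exact
expressions for its mean ``M_g(lambda)`` and variance ``sigma^2_g(lambda)``:

* **avg** uses the first two moments ``m1, m2`` of the normalized rate
  distribution and the special function
  ``Er(t) = int_0^1 (e^{t s} - 1)/s ds = Ei(t) - log t - gamma_EM``.
* **mx** telescopes over the upper-tail sums ``W_k = sum_{r>=k} lambda_r``.
* **TI** telescopes over the discounted tails ``U_k = sum_{i>=k} a_i lambda_i``
  with ``a_i = i/(i+1)``, and its variance is a double telescoping sum of
  ``Gamma_{k,l} = e^{-V_{k,l}} - e^{-(U_k+U_l)}`` where ``V_{k,l}`` mixes
  ``a_i`` below the larger index and ``b_i = i(i+2)/(i+1)^2`` above it.

All formulas honor the empty-sum convention (``U_{K+1} = W_{K+1} = 0``) and
tolerate exact-zero rate coordinates.  A vectorized Monte-Carlo oracle
(:func:`mc_moments`) provides an independent check on every formula.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import expi

from .model import RateVector, _as_rates
from .summaries import measure_function

__all__ = [
    "Measure",
    "GradeMoments",
    "MomentResult",
    "grade_moments",
    "er_function",
    "xi_function",
    "moments_avg",
    "moments_mx",
    "moments_ti",
    "moments",
    "mc_moments",
]

# Below this argument Er's power series converges in a few dozen terms and
# avoids the cancellation in Ei(t) - log t at small t; above it the scipy
# exponential-integral route is used.  Branch agreement at the crossover is
# asserted in the tests.
_ER_SERIES_CUTOFF = 30.0

# Variances more negative than this signal a formula bug rather than
# round-off, and raise instead of clamping.
_NEGATIVE_VARIANCE_TOL = 1e-10


class Measure(enum.Enum):
    TI = "ti"
    MX = "mx"
    AVG = "avg"


@dataclass(frozen=True)
class GradeMoments:
    """Total rate and the first two moments of the normalized grade distribution."""

    total: float
    m1: float
    m2: float


@dataclass(frozen=True)
class MomentResult:
    """Mean and variance of a summary measure under ``Poi(lambda)``.

    ``mean_se``/``variance_se`` are filled only by the Monte-Carlo oracle.
    """

    mean: float
    variance: float
    measure: Measure
    mean_se: float | None = None
    variance_se: float | None = None


def grade_moments(lam: "RateVector | Sequence[float]") -> GradeMoments:
    """``lambda_+`` and the moments ``m1, m2`` of ``lambda / lambda_+``.

    The degenerate all-zero rate vector returns (0, 0, 0) — the limit as
    the rates vanish — so downstream formulas avoid 0/0.
    """
    lam = _as_rates(lam)
    tot = lam.total
    if tot == 0:
        return GradeMoments(0.0, 0.0, 0.0)
    grades = np.arange(1, lam.K + 1, dtype=float)
    nb = lam.normalized
    return GradeMoments(tot, float(grades @ nb), float((grades**2) @ nb))


def er_function(t: float) -> float:
    """``Er(t) = int_0^1 (e^{t s} - 1)/s ds``, the avg-variance special function.

    Equal to ``Ei(t) - log(t) - gamma_EM`` for ``t > 0``; ``Er(0) = 0``;
    strictly increasing.  Evaluated by the power series
    ``sum_{k>=1} t^k / (k * k!)`` for small arguments and via the
    exponential integral for large ones.
    """
    t = float(t)
    if t < 0:
        raise ValueError(f"Er is defined for nonnegative arguments, got {t}")
    if t == 0:
        return 0.0
    if t <= _ER_SERIES_CUTOFF:
        total = 0.0
        term = 1.0  # t^k / k! at k=0
        for k in range(1, 200):
            term *= t / k
            contrib = term / k
            total += contrib
            if contrib < 1e-16 * total:
                break
        return total
    return float(expi(t) - math.log(t) - np.euler_gamma)


def xi_function(z: Sequence[float]) -> float:
    """``xi(z) = sum_i (1 - e^{-z_i})`` over the K leading coordinates.

    The telescoped form of ``sum_k k [e^{-z_{k+1}} - e^{-z_k}]``; it is the
    canonical one here (the boundary convention of the un-telescoped form
    is ambiguous, and this form reproduces every worked value).
    """
    z = np.asarray(z, dtype=float)
    return float(np.sum(1.0 - np.exp(-z)))


def _clamped_variance(v: float, measure: Measure) -> float:
    if v < -_NEGATIVE_VARIANCE_TOL:
        raise ArithmeticError(
            f"analytic variance for {measure.value} came out {v}, far below zero; "
            "this indicates a formula error, not round-off"
        )
    return max(v, 0.0)


def moments_avg(lam: "RateVector | Sequence[float]") -> MomentResult:
    """Mean and variance of the average grade under ``Poi(lambda)``.

    ``M = (1 - e^{-l+}) m1`` and
    ``sigma^2 = e^{-l+} [ m1^2 (1 - e^{-l+}) + Er(l+) (m2 - m1^2) ]``.
    """
    gm = grade_moments(lam)
    if gm.total == 0:
        return MomentResult(0.0, 0.0, Measure.AVG)
    decay = math.exp(-gm.total)
    mean = (1.0 - decay) * gm.m1
    var = decay * (gm.m1**2 * (1.0 - decay) + er_function(gm.total) * (gm.m2 - gm.m1**2))
    return MomentResult(mean, _clamped_variance(var, Measure.AVG), Measure.AVG)


def _tail_sums(weights: np.ndarray) -> np.ndarray:
    """Suffix sums S_k = sum_{i=k..K} w_i for k = 1..K+1 (S_{K+1} = 0)."""
    return np.concatenate([np.cumsum(weights[::-1])[::-1], [0.0]])


def moments_mx(lam: "RateVector | Sequence[float]") -> MomentResult:
    """Mean and variance of the max grade under ``Poi(lambda)``.

    With tail sums ``W_k``, ``P(mx < k) = e^{-W_k}``, giving
    ``M = sum_k (1 - e^{-W_k})`` and a telescoping second moment.
    """
    lam = _as_rates(lam)
    K = lam.K
    W = _tail_sums(lam.as_array())
    mean = xi_function(W[:K])
    ks = np.arange(1, K + 1, dtype=float)
    second = float(np.sum(ks**2 * (np.exp(-W[1:]) - np.exp(-W[:K]))))
    return MomentResult(mean, _clamped_variance(second - mean**2, Measure.MX), Measure.MX)


def _ti_tails(lam: RateVector) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    arr = lam.as_array()
    i = np.arange(1, lam.K + 1, dtype=float)
    a = i / (i + 1.0)
    b = i * (i + 2.0) / (i + 1.0) ** 2
    return _tail_sums(a * arr), a * arr, b * arr


def moments_ti(lam: "RateVector | Sequence[float]") -> MomentResult:
    """Mean and variance of the toxicity index under ``Poi(lambda)``.

    Mean: ``M = (1 - e^{-U_1}) + sum_{k=1..K} (1 - e^{-U_k})``.
    Variance: a double telescoping sum of ``k l`` times second differences
    of ``Gamma_{k,l} = e^{-V_{k,l}} - e^{-(U_k + U_l)}``, for k, l = 2..K+1.
    """
    lam = _as_rates(lam)
    K = lam.K
    U, a_lam, b_lam = _ti_tails(lam)
    mean = (1.0 - math.exp(-U[0])) + xi_function(U[:K])

    a_tail = _tail_sums(a_lam)  # sum_{i=k..K} a_i lam_i, index k-1
    b_tail = _tail_sums(b_lam)

    def gamma(k: int, ell: int) -> float:
        lo, hi = min(k, ell), max(k, ell)
        # V_{k,l} = sum_{i=lo..hi-1} a_i lam_i + sum_{i=hi..K} b_i lam_i
        v = (a_tail[lo - 1] - a_tail[hi - 1]) + b_tail[hi - 1]
        return math.exp(-v) - math.exp(-(U[k - 1] + U[ell - 1]))

    var = 0.0
    for k in range(2, K + 2):
        for ell in range(2, K + 2):
            var += k * ell * (
                gamma(k, ell)
                - gamma(k - 1, ell)
                - gamma(k, ell - 1)
                + gamma(k - 1, ell - 1)
            )
    return MomentResult(mean, _clamped_variance(var, Measure.TI), Measure.TI)


_MOMENT_FUNCS = {
    Measure.TI: moments_ti,
    Measure.MX: moments_mx,
    Measure.AVG: moments_avg,
}


def moments(measure: "Measure | str", lam: "RateVector | Sequence[float]") -> MomentResult:
    """Dispatch to the analytic moment formula for a named measure."""
    measure = Measure(measure.lower()) if isinstance(measure, str) else measure
    return _MOMENT_FUNCS[measure](lam)


def mc_moments(
    measure: "Measure | str",
    lam: "RateVector | Sequence[float]",
    reps: int,
    seed: "int | np.random.Generator | None" = None,
) -> MomentResult:
    """Monte-Carlo estimate of a measure's moments under ``Poi(lambda)``.

    An oracle for the analytic formulas: draws ``reps`` RFVs, evaluates the
    measure on each, and reports the sample mean and variance with their
    standard errors (the variance SE uses the fourth-moment formula).
    """
    measure = Measure(measure.lower()) if isinstance(measure, str) else measure
    if reps < 1:
        raise ValueError("need at least one replicate")
    lam = _as_rates(lam)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = rng.poisson(lam.as_array(), size=(reps, lam.K))
    vals = measure_function(measure.value, vectorized=True)(X)
    mean = float(vals.mean())
    var = float(vals.var(ddof=1)) if reps > 1 else 0.0
    mean_se = math.sqrt(var / reps) if reps > 1 else None
    var_se = None
    if reps > 1:
        centered = vals - mean
        m4 = float(np.mean(centered**4))
        var_se = math.sqrt(max(m4 - var**2, 0.0) / reps)
    return MomentResult(mean, var, measure, mean_se=mean_se, variance_se=var_se)
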