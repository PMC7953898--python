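"""Patient-level summaries of adverse-event grade data.

A patient's toxicity record over a treatment period is a *toxicity profile*:
a vector of CTCAE grades, one entry per adverse event (AE), each grade an
integer in ``{0, ..., K}`` (K=5 under CTCAE, with 0 = no symptom and 5 =
death).  Because grade-0 entries carry no toxicity information beyond the
number of AEs assessed, analysis works with the *reduced frequency vector*
(RFV) ``x = (x_1, ..., x_K)``, where ``x_k`` counts the AEs observed at
grade ``k``.

Three scalar summaries of an RFV are provided:

* ``toxicity_index`` (TI) — preserves the maximum grade while strictly
  increasing with the burden of lower-grade events; for a nonzero RFV,
  ``mx(x) <= TI(x) < mx(x) + 1``.
* ``max_grade`` (mx) — the conventional phase-III summary.
* ``avg_grade`` (avg) — the count-weighted mean grade of nonzero-grade AEs.

The module also implements the *T-order*: a total order on RFVs that
compares two vectors at the highest grade on which they differ.  The
induced ranking of a cohort (the *T-rank*) orders patients by how often
they exhibit extreme toxicities; the TI is the unique summary among the
three that strictly preserves it.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ToxicityProfile",
    "RFV",
    "Relation",
    "TOrderResult",
    "rfv_from_profile",
    "toxicity_index",
    "ti_closed_form_k5",
    "truncated_ti",
    "max_grade",
    "avg_grade",
    "t_compare",
    "t_rank_sort",
    "t_ranks",
    "ti_values",
    "mx_values",
    "avg_values",
    "measure_function",
    "MEASURES",
]

# Large per-grade counts would underflow direct products of (1+i)^{-x_i};
# beyond this total count the TI accumulates the products in log space.
_LOG_SPACE_COUNT_THRESHOLD = 50


@dataclass(frozen=True)
class ToxicityProfile:
    """All observed AE grades for one patient.

    Parameters
    ----------
    grades
        One integer grade per AE, each in ``[0, K]``.  May be empty.
    K
        Maximum possible grade (CTCAE: 5).
    """

    grades: tuple[int, ...]
    K: int = 5

    def __init__(self, grades: Iterable[int], K: int = 5) -> None:
        grades = tuple(int(g) if float(g) == int(g) else g for g in grades)
        if K < 1:
            raise ValueError(f"K must be a positive integer, got {K}")
        for j, g in enumerate(grades):
            if not isinstance(g, int) or not (0 <= g <= K):
                raise ValueError(
                    f"grade {g!r} at position {j} is not an integer in [0, {K}]"
                )
        object.__setattr__(self, "grades", grades)
        object.__setattr__(self, "K", int(K))

    def __len__(self) -> int:
        return len(self.grades)


@dataclass(frozen=True)
class RFV:
    """Reduced frequency vector: AE counts at each nonzero grade 1..K.

    Grade 0 is not stored; the number of grade-0 AEs is recoverable only
    when the profile length ``d`` is known (``x_0 = d - sum(counts)``).
    """

    counts: tuple[int, ...]

    def __init__(self, counts: Iterable[int]) -> None:
        counts = tuple(counts)
        clean = []
        for k, c in enumerate(counts, start=1):
            if float(c) != int(c) or c < 0:
                raise ValueError(
                    f"count {c!r} at grade {k} is not a nonnegative integer"
                )
            clean.append(int(c))
        if not clean:
            raise ValueError("an RFV needs at least one grade")
        object.__setattr__(self, "counts", tuple(clean))

    @property
    def K(self) -> int:
        return len(self.counts)

    @property
    def total(self) -> int:
        """Total number of nonzero-grade AEs (X+)."""
        return sum(self.counts)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)


class Relation(enum.Enum):
    LESS = -1
    EQUAL = 0
    GREATER = 1


@dataclass(frozen=True)
class TOrderResult:
    """Outcome of a T-order comparison.

    ``pivot_grade`` is the (1-based) highest grade on which the two RFVs
    differ — the position where the order was decided; ``None`` for EQUAL.
    """

    relation: Relation
    pivot_grade: int | None = None


def _counts(x: "RFV | Sequence[int] | np.ndarray") -> np.ndarray:
    if isinstance(x, RFV):
        return x.as_array()
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("an RFV must be a nonempty 1-d vector of counts")
    if np.any(arr < 0) or np.any(arr != np.floor(arr)):
        bad = arr[(arr < 0) | (arr != np.floor(arr))][0]
        raise ValueError(f"count {bad!r} is not a nonnegative integer")
    return arr


def rfv_from_profile(profile: ToxicityProfile) -> RFV:
    """Tally a profile's grades into its reduced frequency vector.

    Grade-0 entries are dropped: they contribute to the profile length
    only, never to the RFV.
    """
    counts = [0] * profile.K
    for g in profile.grades:
        if g > 0:
            counts[g - 1] += 1
    return RFV(counts)


def _g_factors(x: np.ndarray) -> np.ndarray:
    """Suffix products g_k(x) = prod_{i=k..K} (1+i)^{-x_i} for k = 1..K+1.

    g_{K+1} = 1 by convention.  Computed in log space whenever the total
    count is large enough for direct products to underflow.
    """
    K = x.size
    log_terms = x * np.log(np.arange(2, K + 2, dtype=float))
    if x.sum() > _LOG_SPACE_COUNT_THRESHOLD:
        suffix = np.concatenate([np.cumsum(log_terms[::-1])[::-1], [0.0]])
        return np.exp(-suffix)
    # direct product is exact for small counts
    factors = np.arange(2, K + 2, dtype=float) ** (-x)
    out = np.ones(K + 1)
    out[:K] = np.cumprod(factors[::-1])[::-1]
    return out


def toxicity_index(x: "RFV | Sequence[int]") -> float:
    """Toxicity index of an RFV.

    Closed form:  ``TI(x) = sum_{k=2}^{K+1} k * g_k(x) * (1 - k^{-x_{k-1}})``
    with ``g_k(x) = prod_{i=k}^{K} (1+i)^{-x_i}`` and ``g_{K+1} = 1``.

    Equivalently the TI of the underlying profile: the grades sorted in
    decreasing order, each discounted by the reciprocal product of
    ``(1 + grade)`` over all larger-or-equal grades that precede it, so
    a single grade-k event scores exactly ``k`` and lower-grade events
    refine the value within ``[mx, mx+1)`` without ever overtaking a
    higher maximum grade.
    """
    arr = _counts(x)
    K = arr.size
    g = _g_factors(arr)
    ks = np.arange(2, K + 2, dtype=float)
    return float(np.sum(ks * g[1:] * (1.0 - ks ** (-arr))))


def ti_closed_form_k5(x: "RFV | Sequence[int]") -> float:
    """TI specialization for K=5 written as a single nested expression.

    Algebraically identical to :func:`toxicity_index`; useful as an
    independent code path and occasionally faster.
    """
    arr = _counts(x)
    if arr.size != 5:
        raise ValueError("this specialization requires K = 5")
    x1, x2, x3, x4, x5 = arr
    return float(
        6.0
        - 6.0 ** (-x5) * (1.0 + 5.0 ** (-x4))
        - 2.0 ** (-2 * x3 - x5)
        * 3.0 ** (-x2 - x5)
        * 5.0 ** (-x4)
        * (1.0 + 3.0**x2 + 2.0 ** (1 - x1))
    )


def truncated_ti(x: "RFV | Sequence[int]", k: int) -> float:
    """TI restricted to grades ``<= k``, via the recursive increments.

    ``tau_0 = 0`` and ``tau_k - tau_{k-1} = (k+1) g_{k+1}(x) [1 - (1+k)^{-x_k}]``;
    at ``k = K`` this recovers the full toxicity index.
    """
    arr = _counts(x)
    K = arr.size
    if not 0 <= k <= K:
        raise ValueError(f"truncation grade {k} outside [0, {K}]")
    g = _g_factors(arr)
    total = 0.0
    for j in range(1, k + 1):
        total += (j + 1) * g[j] * (1.0 - (1.0 + j) ** (-arr[j - 1]))
    return total


def max_grade(x: "RFV | Sequence[int]") -> int:
    """Highest grade with a positive count; 0 for the all-zero RFV."""
    arr = _counts(x)
    nz = np.nonzero(arr)[0]
    return int(nz[-1] + 1) if nz.size else 0


def avg_grade(x: "RFV | Sequence[int]") -> float:
    """Count-weighted mean grade; 0 when no nonzero-grade AE was observed."""
    arr = _counts(x)
    total = arr.sum()
    if total == 0:
        return 0.0
    grades = np.arange(1, arr.size + 1)
    return float((grades * arr).sum() / total)


# ---------------------------------------------------------------------------
# T-order and T-rank

def t_compare(x: "RFV | Sequence[int]", y: "RFV | Sequence[int]") -> TOrderResult:
    """Compare two RFVs under the T-order.

    ``x`` exceeds ``y`` when, at the largest grade where the two vectors
    differ, ``x`` has the larger count.  Returns the decided relation and
    the 1-based pivot grade where the decision was made.
    """
    ax, ay = _counts(x), _counts(y)
    if ax.size != ay.size:
        raise ValueError(
            f"cannot T-compare RFVs with different K ({ax.size} vs {ay.size})"
        )
    diff = np.nonzero(ax != ay)[0]
    if diff.size == 0:
        return TOrderResult(Relation.EQUAL)
    pivot = int(diff[-1])
    rel = Relation.GREATER if ax[pivot] > ay[pivot] else Relation.LESS
    return TOrderResult(rel, pivot_grade=pivot + 1)


def _t_key(x: "RFV | Sequence[int]") -> tuple:
    # T-order == lexicographic order on the grade-reversed count tuple
    return tuple(_counts(x)[::-1])


def t_rank_sort(
    cohort: Sequence["RFV | Sequence[int]"], descending: bool = False
) -> list[int]:
    """Indices that sort a cohort of RFVs by T-rank.

    Stable: patients with identical RFVs keep their input order.  All
    RFVs must share the same K.
    """
    ks = {len(_counts(x)) for x in cohort}
    if len(ks) > 1:
        raise ValueError(f"cohort mixes RFVs of different K: {sorted(ks)}")
    order = sorted(range(len(cohort)), key=lambda i: _t_key(cohort[i]))
    if descending:
        # reverse while preserving stability within tied keys
        groups: dict[tuple, list[int]] = {}
        for i in order:
            groups.setdefault(_t_key(cohort[i]), []).append(i)
        order = [i for key in sorted(groups, reverse=True) for i in groups[key]]
    return order


def t_ranks(cohort: Sequence["RFV | Sequence[int]"]) -> list[int]:
    """1-based T-ranks, rank 1 = most toxic; identical RFVs share a rank."""
    order = t_rank_sort(cohort, descending=True)
    ranks = [0] * len(cohort)
    rank = 0
    prev_key = None
    for pos, i in enumerate(order):
        key = _t_key(cohort[i])
        if key != prev_key:
            rank = pos + 1
            prev_key = key
        ranks[i] = rank
    return ranks


# ---------------------------------------------------------------------------
# Vectorized evaluation over count matrices (rows = patients)

def ti_values(X: np.ndarray) -> np.ndarray:
    """Toxicity index of each row of an (n, K) count matrix.

    Uses the telescoped representation ``TI = 2(1-g_1) + sum_{k=2..K}(1-g_k)``
    with suffix log-sums, an independent algebraic route from the scalar
    closed form (the two are cross-checked in the test suite).
    """
    X = np.asarray(X, dtype=float)
    K = X.shape[-1]
    log_terms = X * np.log(np.arange(2, K + 2, dtype=float))
    suffix = np.cumsum(log_terms[..., ::-1], axis=-1)[..., ::-1]
    g = np.exp(-suffix)
    return 2.0 * (1.0 - g[..., 0]) + np.sum(1.0 - g[..., 1:], axis=-1)


def mx_values(X: np.ndarray) -> np.ndarray:
    """Max grade of each row of an (n, K) count matrix."""
    X = np.asarray(X)
    grades = np.arange(1, X.shape[-1] + 1)
    return np.max((X > 0) * grades, axis=-1).astype(float)


def avg_values(X: np.ndarray) -> np.ndarray:
    """Average grade of each row of an (n, K) count matrix (0 for zero rows)."""
    X = np.asarray(X, dtype=float)
    grades = np.arange(1, X.shape[-1] + 1, dtype=float)
    totals = X.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = (X * grades).sum(axis=-1) / totals
    return np.where(totals > 0, vals, 0.0)


#: measure name -> (scalar function on an RFV, vectorized function on rows)
MEASURES = {
    "ti": (toxicity_index, ti_values),
    "mx": (max_grade, mx_values),
    "avg": (avg_grade, avg_values),
}


def measure_function(measure: str, vectorized: bool = False):
    """Look up a summary measure by name ('ti', 'mx' or 'avg')."""
    key = measure.lower()
    if key not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; expected one of {sorted(MEASURES)}")
    return MEASURES[key][1 if vectorized else 0]
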