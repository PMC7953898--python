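"""Summary measures, the T-order, and T-rank sorting."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from toxindex import (
    RFV,
    Relation,
    ToxicityProfile,
    avg_grade,
    avg_values,
    max_grade,
    mx_values,
    rfv_from_profile,
    t_compare,
    t_rank_sort,
    t_ranks,
    ti_closed_form_k5,
    ti_values,
    toxicity_index,
    truncated_ti,
)


def ti_from_profile(grades):
    """Independent oracle: the original recursive definition on sorted grades.

    Each grade, taken in decreasing order, is discounted by the reciprocal
    product of (1 + g) over the grades already consumed.
    """
    total, weight = 0.0, 1.0
    for g in sorted(grades, reverse=True):
        total += g * weight
        weight /= 1.0 + g
    return total


profiles = st.lists(st.integers(min_value=0, max_value=5), max_size=30)
rfvs_k5 = st.lists(st.integers(min_value=0, max_value=6), min_size=5, max_size=5)


class TestRFVConstruction:
    def test_table1_patient1(self):
        p = ToxicityProfile((2, 2, 2, 4, 4, 4, 4, 4, 4, 4), K=5)
        assert rfv_from_profile(p).counts == (0, 3, 0, 7, 0)

    def test_all_zero_profile(self):
        assert rfv_from_profile(ToxicityProfile((0, 0, 0))).counts == (0,) * 5

    def test_random_profile_matches_brute_force(self, rng):
        grades = rng.integers(0, 6, size=50)
        counts = rfv_from_profile(ToxicityProfile(grades)).counts
        assert counts == tuple(int(np.sum(grades == k)) for k in range(1, 6))

    def test_out_of_range_grade_named_in_error(self):
        with pytest.raises(ValueError, match="7"):
            ToxicityProfile((1, 7), K=5)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            RFV((1, -1, 0))
        with pytest.raises(ValueError):
            toxicity_index([0.5, 0, 0, 0, 0])


class TestToxicityIndex:
    @pytest.mark.parametrize(
        "x, expected",
        [
            ((0, 1, 3, 1, 0), 4.79375),
            ((0, 1, 0, 0, 0), 2.0),
            ((0, 2, 0, 0, 0), 8.0 / 3.0),
            ((0, 0, 0, 0, 0), 0.0),
        ],
    )
    def test_known_values(self, x, expected):
        assert toxicity_index(x) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("k", [1, 2, 3, 4, 5])
    def test_single_toxicity_scores_its_grade(self, k):
        x = [0] * 5
        x[k - 1] = 1
        assert toxicity_index(x) == pytest.approx(k, rel=1e-12)

    @settings(max_examples=200, deadline=None)
    @given(profiles)
    def test_closed_form_matches_recursive_definition(self, grades):
        x = rfv_from_profile(ToxicityProfile(grades))
        assert toxicity_index(x) == pytest.approx(ti_from_profile(grades), rel=1e-12, abs=1e-12)

    @settings(max_examples=200, deadline=None)
    @given(rfvs_k5)
    def test_k5_specialization_and_vectorized_agree(self, x):
        ref = toxicity_index(x)
        assert ti_closed_form_k5(x) == pytest.approx(ref, rel=1e-12, abs=1e-12)
        assert ti_values(np.array([x]))[0] == pytest.approx(ref, rel=1e-12, abs=1e-12)

    def test_log_space_branch_consistent(self):
        # totals above the threshold switch to log-space accumulation
        x = (40, 30, 25, 10, 5)
        assert toxicity_index(x) == pytest.approx(ti_values(np.array([x]))[0], rel=1e-12)

    @settings(max_examples=100, deadline=None)
    @given(rfvs_k5)
    def test_range_nesting(self, x):
        if sum(x) == 0:
            assert toxicity_index(x) == 0.0
        else:
            mx = max_grade(x)
            assert mx <= toxicity_index(x) < mx + 1

    def test_padding_invariance(self):
        x = (1, 0, 2)
        padded = (1, 0, 2, 0, 0, 0)
        assert toxicity_index(x) == pytest.approx(toxicity_index(padded), rel=1e-12)
        assert max_grade(x) == max_grade(padded)
        assert avg_grade(x) == pytest.approx(avg_grade(padded))


class TestTruncatedTI:
    def test_zero_truncation_is_zero(self, rng):
        for _ in range(5):
            assert truncated_ti(rng.integers(0, 5, 5), 0) == 0.0

    def test_full_truncation_recovers_ti(self):
        assert truncated_ti((0, 1, 3, 1, 0), 5) == pytest.approx(4.79375, rel=1e-12)

    def test_increments_nonnegative_and_sum_to_ti(self, rng):
        for _ in range(100):
            x = rng.integers(0, 6, 5)
            prev = 0.0
            for k in range(1, 6):
                cur = truncated_ti(x, k)
                assert cur >= prev - 1e-14
                prev = cur
            assert prev == pytest.approx(toxicity_index(x), rel=1e-12, abs=1e-12)

    def test_out_of_range_truncation(self):
        with pytest.raises(ValueError):
            truncated_ti((0, 0, 0, 0, 0), 6)


class TestMaxAndAvg:
    @pytest.mark.parametrize(
        "x, expected", [((0, 1, 3, 1, 0), 4), ((0, 0, 0, 0, 0), 0), ((1, 0, 0, 0, 0), 1)]
    )
    def test_max_grade(self, x, expected):
        assert max_grade(x) == expected

    @pytest.mark.parametrize(
        "x, expected", [((6, 2), 1.25), ((2, 1), 4.0 / 3.0), ((0, 0, 0, 0, 0), 0.0)]
    )
    def test_avg_grade(self, x, expected):
        assert avg_grade(x) == pytest.approx(expected)

    def test_vectorized_forms_match_scalar(self, rng):
        X = rng.integers(0, 5, size=(50, 5))
        assert np.allclose(mx_values(X), [max_grade(r) for r in X])
        assert np.allclose(avg_values(X), [avg_grade(r) for r in X])


class TestTOrder:
    def test_pivot_at_grade_three(self):
        res = t_compare((0, 1, 3, 1, 0), (0, 4, 1, 1, 0))
        assert res.relation is Relation.GREATER and res.pivot_grade == 3

    def test_counterexample_pair(self):
        res = t_compare((6, 2), (2, 1))
        assert res.relation is Relation.GREATER and res.pivot_grade == 2

    def test_equal_iff_identical(self):
        res = t_compare((1, 2, 3), (1, 2, 3))
        assert res.relation is Relation.EQUAL and res.pivot_grade is None

    def test_mismatched_k_rejected(self):
        with pytest.raises(ValueError):
            t_compare((1, 2), (1, 2, 3))

    @settings(max_examples=100, deadline=None)
    @given(rfvs_k5, rfvs_k5)
    def test_antisymmetry(self, x, y):
        fwd, bwd = t_compare(x, y), t_compare(y, x)
        assert fwd.relation.value == -bwd.relation.value
        assert fwd.pivot_grade == bwd.pivot_grade

    @settings(max_examples=100, deadline=None)
    @given(rfvs_k5, rfvs_k5, rfvs_k5)
    def test_transitivity(self, x, y, z):
        order = {Relation.GREATER, Relation.EQUAL}
        if t_compare(x, y).relation in order and t_compare(y, z).relation in order:
            assert t_compare(x, z).relation in order


class TestTRankPreservation:
    """Strict monotonicity of TI, and the failures of mx and avg."""

    GRID = list(itertools.product(range(5), repeat=3))  # K=3, counts 0..4

    def test_ti_strictly_monotone_on_grid(self):
        ranked = sorted(self.GRID, key=lambda x: tuple(reversed(x)))
        tis = [toxicity_index(x) for x in ranked]
        assert all(b > a for a, b in zip(tis, tis[1:]))

    def test_ti_injective_on_grid(self):
        tis = [toxicity_index(x) for x in self.GRID]
        assert len(set(tis)) == len(tis)

    def test_mx_nondecreasing_but_not_injective(self):
        ranked = sorted(self.GRID, key=lambda x: tuple(reversed(x)))
        mxs = [max_grade(x) for x in ranked]
        assert all(b >= a for a, b in zip(mxs, mxs[1:]))
        assert len(set(mxs)) < len(mxs)

    @pytest.mark.parametrize(
        "x, y, cmp",
        [
            ((6, 2), (2, 1), "lt"),   # x > y in T-order yet avg(x) < avg(y)
            ((2, 2), (2, 1), "gt"),
            ((4, 2), (2, 1), "eq"),
        ],
    )
    def test_avg_not_monotone(self, x, y, cmp):
        assert t_compare(x, y).relation is Relation.GREATER
        ax, ay = avg_grade(x), avg_grade(y)
        assert {"lt": ax < ay, "gt": ax > ay, "eq": ax == pytest.approx(ay)}[cmp]


class TestTRankSort:
    def test_table1_descending_order_is_printed_order(self, table1):
        c1, c2 = table1
        cohort = c1.rfvs + c2.rfvs
        assert t_rank_sort(cohort, descending=True) == list(range(10))

    def test_single_element(self):
        assert t_rank_sort([(1, 2, 3)]) == [0]

    def test_no_adjacent_inversions(self, rng):
        for _ in range(20):
            cohort = [tuple(rng.integers(0, 4, 4)) for _ in range(15)]
            order = t_rank_sort(cohort)
            for i, j in zip(order, order[1:]):
                assert t_compare(cohort[i], cohort[j]).relation is not Relation.GREATER
            desc = t_rank_sort(cohort, descending=True)
            for i, j in zip(desc, desc[1:]):
                assert t_compare(cohort[i], cohort[j]).relation is not Relation.LESS

    def test_stable_on_ties_both_directions(self):
        cohort = [(0, 1), (2, 0), (0, 1), (2, 0)]
        assert t_rank_sort(cohort) == [1, 3, 0, 2]
        assert t_rank_sort(cohort, descending=True) == [0, 2, 1, 3]

    def test_shared_ranks(self):
        assert t_ranks([(0, 1), (2, 0), (0, 1)]) == [1, 3, 1]

    def test_mixed_k_rejected(self):
        with pytest.raises(ValueError):
            t_rank_sort([(1, 2), (1, 2, 3)])
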