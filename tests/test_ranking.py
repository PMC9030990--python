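from fractions import Fraction
from itertools import permutations, product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synthutil import (
    RankMatrix,
    aggregate_ranking,
    assign_groups,
    bonferroni,
    build_rank_matrix,
    footrule,
    monte_carlo_pvalue,
    page_exact_pvalue,
    page_l,
    page_null_distribution,
    page_test,
)


def _rm(rows) -> RankMatrix:
    return RankMatrix(ranks=np.array(rows, dtype=float),
                      dataset_names=[f"d{i}" for i in range(len(rows))])


class TestGrouping:
    def test_ordering_by_metric_value(self):
        (h, m, l), tie = assign_groups({"A": 0.1, "B": 0.2, "C": 0.3})
        assert (h, m, l) == ("A", "B", "C") and not tie

    def test_tie_broken_lexicographically_and_flagged(self):
        (h, m, l), tie = assign_groups({"A": 0.2, "B": 0.2, "C": 0.3})
        assert (h, m, l) == ("A", "B", "C") and tie

    def test_input_order_irrelevant(self):
        a = assign_groups({"A": 0.3, "B": 0.1, "C": 0.2})
        b = assign_groups({"C": 0.2, "A": 0.3, "B": 0.1})
        assert a == b

    def test_wrong_method_count_rejected(self):
        with pytest.raises(ValueError):
            assign_groups({"A": 1.0, "B": 2.0})


class TestRankMatrix:
    def test_agreement_and_disagreement_rows(self):
        groups = {"d": ("a", "b", "c")}
        rm = build_rank_matrix(groups, {"d": {"a": 0.01, "b": 0.05, "c": 0.10}})
        np.testing.assert_array_equal(rm.ranks, [[1, 2, 3]])
        rm = build_rank_matrix(groups, {"d": {"a": 0.10, "b": 0.05, "c": 0.01}})
        np.testing.assert_array_equal(rm.ranks, [[3, 2, 1]])

    def test_ties_get_mid_ranks_and_flag(self):
        rm = build_rank_matrix({"d": ("a", "b", "c")},
                               {"d": {"a": 0.05, "b": 0.05, "c": 0.10}})
        np.testing.assert_array_equal(rm.ranks, [[1.5, 1.5, 3]])
        assert rm.has_ties

    def test_missing_cell_rejected(self):
        with pytest.raises(ValueError):
            build_rank_matrix({"d": ("a", "b", "c")}, {})


class TestPageStatistic:
    @pytest.mark.parametrize(
        "rows, expected",
        [
            ([[1, 2, 3], [1, 2, 3]], 28.0),  # maximum 14n
            ([[3, 2, 1], [3, 2, 1]], 20.0),  # minimum 10n
            ([[2, 3, 1]], 11.0),             # 2 + 6 + 3
        ],
    )
    def test_l_statistic(self, rows, expected):
        assert page_l(_rm(rows)) == expected

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.permutations([1, 2, 3]), min_size=1, max_size=8))
    def test_l_bounds(self, rows):
        L = page_l(_rm(rows))
        n = len(rows)
        assert 10 * n <= L <= 14 * n


class TestExactPValue:
    def test_single_row_maximum(self):
        assert page_exact_pvalue(14, 1) == Fraction(1, 6)

    def test_two_rows_maximum(self):
        assert page_exact_pvalue(28, 2) == Fraction(1, 36)

    @pytest.mark.parametrize("n", [1, 2, 3, 5])
    def test_minimum_l_has_pvalue_one(self, n):
        assert page_exact_pvalue(10 * n, n) == 1

    @pytest.mark.parametrize("n", [1, 2, 3, 4])
    def test_matches_brute_force_enumeration(self, n):
        contribs = [10, 11, 11, 13, 13, 14]
        counts: dict[int, int] = {}
        for combo in product(contribs, repeat=n):
            s = sum(combo)
            counts[s] = counts.get(s, 0) + 1
        for L in range(10 * n, 14 * n + 1):
            expected = Fraction(sum(c for v, c in counts.items() if v >= L), 6**n)
            assert page_exact_pvalue(L, n) == expected

    def test_null_mean_is_twelve_n(self):
        for n in (1, 4, 10, 30):
            dist = page_null_distribution(n)
            total = sum(dist.values())
            mean = sum(Fraction(v * c, total) for v, c in dist.items())
            assert mean == 12 * n

    def test_pvalue_non_increasing_in_l(self):
        n = 6
        ps = [page_exact_pvalue(L, n) for L in range(10 * n, 14 * n + 1)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestMonteCarlo:
    def test_agrees_with_exact_on_tie_free_matrix(self):
        rng = np.random.default_rng(0)
        rows = [rng.permutation([1, 2, 3]) for _ in range(6)]
        rm = _rm(rows)
        exact = float(page_exact_pvalue(page_l(rm), rm.n_rows))
        reps = 20000
        mc = monte_carlo_pvalue(rm, reps=reps, seed=1)
        se = np.sqrt(exact * (1 - exact) / reps)
        assert abs(mc - exact) < 3 * se + 1 / reps

    def test_all_tied_matrix_has_pvalue_one(self):
        rm = _rm([[2, 2, 2], [2, 2, 2]])
        assert monte_carlo_pvalue(rm, reps=500, seed=0) == 1.0

    def test_seeded_determinism(self):
        rm = _rm([[1, 2, 3], [2, 1, 3], [1, 3, 2]])
        assert monte_carlo_pvalue(rm, 2000, seed=7) == monte_carlo_pvalue(
            rm, 2000, seed=7
        )


class TestDecisions:
    def test_bonferroni_six_tests(self):
        assert bonferroni([0.001], alpha=0.05, m=6) == [True]
        assert bonferroni([0.01], alpha=0.05, m=6) == [False]

    def test_m_one_reduces_to_unadjusted(self):
        assert bonferroni([0.04], alpha=0.05, m=1) == [True]

    def test_page_test_routes_ties_to_monte_carlo(self):
        rm = build_rank_matrix({"d": ("a", "b", "c"), "e": ("a", "b", "c")},
                               {"d": {"a": 0.1, "b": 0.1, "c": 0.2},
                                "e": {"a": 0.1, "b": 0.2, "c": 0.3}})
        res = page_test(rm, mc_reps=2000)
        assert not res.exact
        res2 = page_test(_rm([[1, 2, 3]] * 2))
        assert res2.exact


class TestFootrule:
    def test_examples(self):
        assert footrule((1, 2, 3), (1, 2, 3)) == 0
        assert footrule((1, 2, 3), (3, 2, 1)) == 4

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.permutations([1, 2, 3, 4]), st.permutations([1, 2, 3, 4]))
    def test_symmetry_and_nonnegativity(self, a, b):
        assert footrule(a, b) == footrule(b, a) >= 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            footrule((1, 2), (1, 2, 3))


class TestAggregateRanking:
    def test_unanimous_inputs_cost_zero(self):
        r = {"a": 1, "b": 2, "c": 3}
        agg = aggregate_ranking([r, r, r, r, r])
        assert agg.ranking == r and agg.total_cost == 0

    def test_majority_example(self):
        inputs = [{"a": 1, "b": 2, "c": 3}, {"a": 1, "b": 2, "c": 3},
                  {"a": 2, "b": 1, "c": 3}]
        agg = aggregate_ranking(inputs)
        assert agg.ranking == {"a": 1, "b": 2, "c": 3}
        assert agg.total_cost == 2

    def test_result_is_enumeration_optimal(self):
        rng = np.random.default_rng(11)
        methods = ["a", "b", "c"]
        for _ in range(20):
            inputs = [dict(zip(methods, rng.permutation([1, 2, 3])))
                      for _ in range(5)]
            agg = aggregate_ranking(inputs)
            for perm in permutations([1, 2, 3]):
                cand = dict(zip(methods, perm))
                cost = sum(
                    footrule([r[m] for m in methods], [cand[m] for m in methods])
                    for r in inputs
                )
                assert agg.total_cost <= cost + 1e-12
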