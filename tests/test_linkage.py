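"""Contingency construction, hypergeometric tails, BH correction, flat testing."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact

import synlink as sl
from synlink.linkage import format_pvalue

from conftest import shuffled_table


def tail_by_enumeration(k, N, K_in, K_out):
    """Oracle: enumerate every possible draw of K_out genes from N and count
    those sharing >= k genes with a fixed K_in-subset."""
    hits = 0
    total = 0
    success = set(range(K_in))
    for draw in itertools.combinations(range(N), K_out):
        total += 1
        if len(success.intersection(draw)) >= k:
            hits += 1
    return hits / total


def bh_stepup_oracle(pvals):
    """Textbook BH step-up adjusted values."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_end, i in enumerate(reversed(order)):
        rank = m - rank_from_end
        val = min(prev, pvals[i] * m / rank)
        adj[i] = val
        prev = val
    return adj


def _table_with_counts():
    """10-row, 2-species toy with k=2, K_out=4, K_in=3 for (c1, d1)."""
    a_chroms = ["c1", "c1", "c1", "c2", "c2", "c2", "c2", "c3", "c3", "c3"]
    b_chroms = ["d1", "d1", "d2", "d1", "d1", "d2", "d2", "d2", "d3", "d3"]
    rows = []
    import collections

    pos = {"A": collections.Counter(), "B": collections.Counter()}
    for i, (ca, cb) in enumerate(zip(a_chroms, b_chroms)):
        rows.append({
            "A": sl.GeneLocation(f"a{i}", ca, pos["A"][ca]),
            "B": sl.GeneLocation(f"b{i}", cb, pos["B"][cb]),
        })
        pos["A"][ca] += 1
        pos["B"][cb] += 1
    return sl.make_table(["A", "B"], rows, outgroup="B")


class TestBuildContingency:
    def test_hand_counted_toy(self):
        t = _table_with_counts()
        combo = sl.ChromCombination(ingroup=(("A", "c1"),), outgroup=("B", "d1"))
        ct = sl.build_contingency(t, combo)
        assert (ct.k, ct.K_out, ct.K_in, ct.N) == (2, 4, 3, 10)
        assert ct.cells == ((2, 2), (1, 5))

    def test_combo_covering_all_rows_degenerates(self):
        rows = [{"A": sl.GeneLocation(f"a{i}", "c1", i),
                 "B": sl.GeneLocation(f"b{i}", "d1", i)} for i in range(4)]
        t = sl.make_table(["A", "B"], rows, outgroup="B")
        combo = sl.ChromCombination(ingroup=(("A", "c1"),), outgroup=("B", "d1"))
        ct = sl.build_contingency(t, combo)
        assert ct.cells == ((4, 0), (0, 0))

    def test_unobserved_combo_rejected(self):
        t = _table_with_counts()
        combo = sl.ChromCombination(ingroup=(("A", "c3"),), outgroup=("B", "d1"))
        with pytest.raises(ValueError, match="never observed"):
            sl.build_contingency(t, combo)

    def test_published_quartet_counts_give_published_cells(self):
        ct = sl.ContingencyTable(k=15, K_out=182, K_in=27, N=1874)
        assert ct.cells == ((15, 167), (12, 1680))


class TestHypergeomTail:
    def test_published_worked_example(self):
        ct = sl.ContingencyTable(k=15, K_out=182, K_in=27, N=1874)
        assert format_pvalue(sl.hypergeom_tail(ct)) == "2.3e-09"

    def test_k_zero_covers_whole_support(self):
        assert sl.hypergeom_tail(sl.ContingencyTable(k=0, K_out=5, K_in=3, N=10)) == 1.0

    def test_exact_half_case(self):
        # P(X >= 2), population 10, 3 successes, 5 draws = 1/2 exactly
        ct = sl.ContingencyTable(k=2, K_out=5, K_in=3, N=10)
        assert sl.hypergeom_tail(ct) == pytest.approx(0.5, abs=1e-12)
        assert tail_by_enumeration(2, 10, 3, 5) == pytest.approx(0.5, abs=1e-12)

    def test_degenerate_margins_return_one(self):
        assert sl.hypergeom_tail(sl.ContingencyTable(k=0, K_out=0, K_in=3, N=10)) == 1.0
        assert sl.hypergeom_tail(sl.ContingencyTable(k=0, K_out=5, K_in=0, N=10)) == 1.0

    def test_symmetric_in_margin_swap(self):
        for k, K_out, K_in, N in [(3, 8, 5, 20), (1, 4, 9, 15), (7, 12, 10, 40)]:
            a = sl.hypergeom_tail(sl.ContingencyTable(k, K_out, K_in, N))
            b = sl.hypergeom_tail(sl.ContingencyTable(k, K_in, K_out, N))
            assert a == pytest.approx(b, rel=1e-12)

    def test_matches_enumeration_oracle_small_grid(self):
        # exhaustive check on a sub-grid; the full N <= 12 sweep runs in the
        # acceptance suite
        for N in range(1, 9):
            for K_in in range(N + 1):
                for K_out in range(N + 1):
                    k_lo = max(1, K_in + K_out - N)
                    for k in range(k_lo, min(K_in, K_out) + 1):
                        ct = sl.ContingencyTable(k, K_out, K_in, N)
                        assert sl.hypergeom_tail(ct) == pytest.approx(
                            tail_by_enumeration(k, N, K_in, K_out), abs=1e-12
                        ), (k, N, K_in, K_out)

    def test_equals_one_sided_fisher(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            N = int(rng.integers(2, 400))
            K_in = int(rng.integers(1, N + 1))
            K_out = int(rng.integers(1, N + 1))
            k_lo = max(1, K_in + K_out - N)
            k_hi = min(K_in, K_out)
            if k_lo > k_hi:
                continue
            k = int(rng.integers(k_lo, k_hi + 1))
            ct = sl.ContingencyTable(k, K_out, K_in, N)
            _, p_fisher = fisher_exact(ct.cells, alternative="greater")
            assert sl.hypergeom_tail(ct) == pytest.approx(p_fisher, rel=1e-10)

    def test_monotone_decreasing_in_population_size(self):
        # rows touching neither margin dilute the overlap expectation
        k, K_out, K_in = 5, 20, 15
        tails = [sl.hypergeom_tail(sl.ContingencyTable(k, K_out, K_in, N))
                 for N in range(40, 400, 40)]
        assert all(a >= b for a, b in zip(tails, tails[1:]))


class TestBhCorrect:
    def test_hand_computed_step_up(self):
        q, rej = sl.bh_correct([0.01, 0.02, 0.03, 0.04], alpha=0.05)
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])
        assert rej.all()

    def test_all_ones(self):
        q, rej = sl.bh_correct([1.0, 1.0, 1.0])
        assert np.allclose(q, 1.0)
        assert not rej.any()

    def test_single_p_at_alpha(self):
        q, rej = sl.bh_correct([0.05], alpha=0.05)
        assert q[0] == pytest.approx(0.05)
        assert rej[0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sl.bh_correct([0.5, 1.5])
        with pytest.raises(ValueError):
            sl.bh_correct([-0.1])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0,
                              allow_nan=False), min_size=1, max_size=40))
    @settings(max_examples=300, deadline=None)
    def test_matches_textbook_step_up(self, pvals):
        q, _ = sl.bh_correct(pvals)
        assert np.allclose(q, bh_stepup_oracle(pvals), atol=1e-12)


class TestTestAllCombinations:
    def test_planted_synteny_significant_background_not(self, planted_sim):
        tests = sl.test_all_combinations(planted_sim.table, alpha=0.05)
        sig = [t for t in tests if t.significant]
        assert len(sig) == 3
        assert all(t.table.k >= 15 for t in sig)
        scores = sl.truth_evaluate(tests, planted_sim)
        assert scores.precision == 1.0 and scores.recall == 1.0

    def test_single_row_table_not_rejected(self):
        rows = [{"A": sl.GeneLocation("a0", "c1", 0), "B": sl.GeneLocation("b0", "d1", 0)}]
        t = sl.make_table(["A", "B"], rows, outgroup="B")
        tests = sl.test_all_combinations(t)
        assert len(tests) == 1
        assert tests[0].p_raw <= 1.0
        assert not tests[0].significant

    def test_min_count_floor_shrinks_family(self, planted_sim):
        all_tests = sl.test_all_combinations(planted_sim.table, min_count=1)
        floored = sl.test_all_combinations(planted_sim.table, min_count=3)
        assert len(floored) < len(all_tests)
        assert all(t.table.k >= 3 for t in floored)

    def test_merged_id_joins_ingroup_chromosomes(self, planted_sim):
        t = sl.test_all_combinations(planted_sim.table)[0]
        parts = t.combination.merged_id.split("_")
        assert len(parts) == 3  # RES, EMU, HCA
        assert parts[0].startswith("RES")

    def test_shuffled_table_rarely_rejects(self):
        # a light version of the null-FDR check (full version in acceptance)
        total_rej = 0
        total_tests = 0
        for seed in range(10):
            t = shuffled_table(seed=seed + 100)
            tests = sl.test_all_combinations(t, alpha=0.05)
            total_rej += sum(x.significant for x in tests)
            total_tests += len(tests)
        assert total_rej <= 0.05 * total_tests
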