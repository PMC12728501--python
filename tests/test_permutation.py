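"""Shuffle semantics, group-size histograms, and the shuffle-based FDR estimate."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import synlink as sl

from conftest import planted_simulation, shuffled_table


def _table_from_chroms(per_species_chroms):
    """Build a table from {tag: [chrom per row]} with distinct positions."""
    species = list(per_species_chroms)
    rows = []
    pos_counter = {t: Counter() for t in species}
    n = len(next(iter(per_species_chroms.values())))
    for i in range(n):
        row = {}
        for t in species:
            c = per_species_chroms[t][i]
            row[t] = sl.GeneLocation(f"{t}_g{i}", c, pos_counter[t][c])
            pos_counter[t][c] += 1
        rows.append(row)
    return sl.make_table(species, rows, outgroup=species[-1])


class TestCountLinkedGroups:
    def test_hand_enumerated_counts(self):
        t = _table_from_chroms({"A": ["c1", "c1", "c1", "c2"],
                                "B": ["d1", "d1", "d2", "d2"]})
        counts = sl.count_linked_groups(t)
        assert counts == {("c1", "d1"): 2, ("c1", "d2"): 1, ("c2", "d2"): 1}
        assert sum(counts.values()) == t.n_rows

    def test_single_row(self):
        t = _table_from_chroms({"A": ["c1"], "B": ["d9"]})
        assert sl.count_linked_groups(t) == {("c1", "d9"): 1}

    def test_duplicated_species_pairs_each_chromosome_with_its_copy(self):
        chroms = ["c1", "c2", "c1", "c3", "c2"]
        t = _table_from_chroms({"A": chroms, "B": [c.replace("c", "d") for c in chroms]})
        for (ca, cb), _ in sl.count_linked_groups(t).items():
            assert cb == ca.replace("c", "d")


class TestShuffleTable:
    @pytest.mark.parametrize("mode,target", [("all_species", None), ("single_species", "COW")])
    def test_per_chromosome_gene_counts_conserved(self, planted_sim, mode, target):
        strat = sl.ShuffleStrategy(mode, target, n_reps=1, seed=5)
        shuf = sl.shuffle_table(planted_sim.table, strat, rep_index=0)
        assert shuf.n_rows == planted_sim.table.n_rows
        for tag in planted_sim.table.species:
            before = Counter(Counter(planted_sim.table.chroms(tag)).values())
            after = Counter(Counter(shuf.chroms(tag)).values())
            assert before == after

    def test_unshuffled_species_untouched(self, planted_sim):
        strat = sl.ShuffleStrategy("single_species", "COW", n_reps=1, seed=5)
        shuf = sl.shuffle_table(planted_sim.table, strat, 0)
        for tag in ("RES", "EMU", "HCA"):
            assert (shuf.chroms(tag) == planted_sim.table.chroms(tag)).all()

    def test_deterministic_given_seed_and_rep(self, planted_sim):
        strat = sl.ShuffleStrategy("all_species", n_reps=1, seed=7)
        a = sl.shuffle_table(planted_sim.table, strat, 3)
        b = sl.shuffle_table(planted_sim.table, strat, 3)
        assert a == b
        c = sl.shuffle_table(planted_sim.table, strat, 4)
        assert not (a.chroms("RES") == c.chroms("RES")).all()

    def test_single_chromosome_species_unchanged_up_to_order(self):
        t = _table_from_chroms({"A": ["c1"] * 6, "B": ["d1", "d1", "d2", "d2", "d3", "d3"]})
        strat = sl.ShuffleStrategy("single_species", "A", n_reps=1, seed=1)
        shuf = sl.shuffle_table(t, strat, 0)
        assert (shuf.chroms("A") == "c1").all()
        assert sorted(shuf.positions("A")) == sorted(t.positions("A"))

    def test_unknown_target_species_rejected(self, planted_sim):
        strat = sl.ShuffleStrategy("single_species", "XXX", n_reps=1, seed=1)
        with pytest.raises(ValueError, match="XXX"):
            sl.shuffle_table(planted_sim.table, strat, 0)

    @given(seed=st.integers(0, 2**20), rep=st.integers(0, 50))
    @settings(max_examples=20, deadline=None)
    def test_conservation_property_over_seeds(self, seed, rep):
        sim = planted_simulation(seed=1, alg_sizes=(10, 10, 10))
        strat = sl.ShuffleStrategy("all_species", n_reps=1, seed=seed)
        shuf = sl.shuffle_table(sim.table, strat, rep)
        for tag in sim.table.species:
            assert (Counter(Counter(sim.table.chroms(tag)).values())
                    == Counter(Counter(shuf.chroms(tag)).values()))


class TestNullHistogram:
    def test_one_chromosome_everywhere_concentrates_at_row_count(self):
        n = 9
        t = _table_from_chroms({"A": ["c1"] * n, "B": ["d1"] * n})
        hist = sl.null_histogram(t, sl.ShuffleStrategy("all_species", n_reps=1, seed=0))
        assert hist.counts == {n: 1}

    def test_histogram_reproducible_from_seed(self, planted_sim):
        strat = sl.ShuffleStrategy("single_species", "COW", n_reps=50, seed=12)
        h1 = sl.null_histogram(planted_sim.table, strat)
        h2 = sl.null_histogram(planted_sim.table, strat)
        assert h1.counts == h2.counts

    def test_histogram_matches_explicit_shuffle_and_count(self, planted_sim):
        # the fast tally must agree with shuffle_table + count_linked_groups
        strat = sl.ShuffleStrategy("single_species", "COW", n_reps=5, seed=12)
        hist = sl.null_histogram(planted_sim.table, strat)
        expected = Counter()
        for rep in range(strat.n_reps):
            shuf = sl.shuffle_table(planted_sim.table, strat, rep)
            expected.update(sl.count_linked_groups(shuf).values())
        assert hist.counts == dict(expected)

    def test_all_species_tail_lighter_than_single_on_duplicated_trio(self):
        anc = sl.AncestralGenome([25] * 6)
        params = {"AAA": sl.EvolutionParams(),
                  "BBB": sl.EvolutionParams(),
                  "CCC": sl.EvolutionParams(translocation_rate=1.0)}
        trio = sl.simulate(anc, params, seed=2, copy_of={"BBB": "AAA"}).table
        reps = 1000
        h_one = sl.null_histogram(trio, sl.ShuffleStrategy("single_species", "CCC", reps, seed=5))
        h_all = sl.null_histogram(trio, sl.ShuffleStrategy("all_species", None, reps, seed=6))
        top = max(max(h_one.counts), max(h_all.counts))
        assert any(h_all.tail_mass(s, normalized=True) < h_one.tail_mass(s, normalized=True)
                   for s in range(top))


class TestFdrByGroupSize:
    def test_null_never_reaching_observed_size_gives_zero(self):
        null = sl.GroupSizeHistogram(counts={1: 100, 2: 40}, n_reps=10)
        observed = {("c1", "d1"): 5, ("c2", "d2"): 1}
        fdr = sl.fdr_by_group_size(observed, null)
        assert fdr[5] == 0.0

    def test_structureless_table_self_consistent_fdr_near_one(self):
        t = shuffled_table(seed=21, n_genes_per_alg=25, n_algs=8)
        observed = sl.count_linked_groups(t)
        hist = sl.null_histogram(t, sl.ShuffleStrategy("all_species", n_reps=400, seed=3))
        fdr = sl.fdr_by_group_size(observed, hist)
        # shuffling a structureless table reproduces its own group sizes
        small = [v for s, v in fdr.items() if s <= 2]
        assert small and all(v > 0.5 for v in small)

    def test_absent_sizes_not_reported(self):
        null = sl.GroupSizeHistogram(counts={1: 10}, n_reps=10)
        fdr = sl.fdr_by_group_size({("c1", "d1"): 3}, null)
        assert set(fdr) == {3}

    def test_planted_sizes_all_species_fdr_not_above_single_species(self):
        sim = planted_simulation(seed=17, translocation=0.02, loss=0.0)
        observed = sl.count_linked_groups(sim.table)
        reps = 1000
        h_all = sl.null_histogram(sim.table, sl.ShuffleStrategy("all_species", n_reps=reps, seed=8))
        h_one = sl.null_histogram(
            sim.table, sl.ShuffleStrategy("single_species", "COW", n_reps=reps, seed=9))
        fdr_all = sl.fdr_by_group_size(observed, h_all)
        fdr_one = sl.fdr_by_group_size(observed, h_one)
        planted_sizes = [s for s in observed.values() if s >= 15]
        assert planted_sizes
        for s in planted_sizes:
            assert fdr_all[s] <= fdr_one[s]


class TestStrategyValidation:
    def test_single_species_requires_target(self):
        with pytest.raises(ValueError):
            sl.ShuffleStrategy("single_species", None, n_reps=1, seed=0)

    def test_bad_mode_rejected(self):
        with pytest.raises(ValueError):
            sl.ShuffleStrategy("both", None, n_reps=1, seed=0)
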