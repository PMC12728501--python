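"""Permutation null models for linked-ortholog group sizes.

Two shuffle strategies are implemented and contrasted:

``all_species``
    The gene-to-chromosome assignment is independently permuted in every
    species.  This treats all genomes as statistically independent — a poor
    null when species are phylogenetically correlated, since it makes large
    random chromosome combinations rarer than the evolutionary process allows
    and thereby inflates the apparent significance of observed combinations.

``single_species``
    Only one designated species (typically the outgroup) is shuffled, leaving
    the correlated structure of the remaining genomes intact.

A shuffle permutes the multiset of (chromosome, position) location labels
over the species' genes, so every chromosome keeps exactly its original gene
count.  Group sizes — the number of orthologs supporting each distinct
combination of per-species chromosomes — are tallied over many randomized
tables into a histogram; all observed combinations are binned, not just the
largest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import OrthologTable

__all__ = [
    "ShuffleStrategy",
    "GroupSizeHistogram",
    "count_linked_groups",
    "shuffle_table",
    "null_histogram",
    "fdr_by_group_size",
]


@dataclass(frozen=True)
class ShuffleStrategy:
    """Which species to shuffle, how many randomizations, and the RNG root seed."""

    mode: str  # "all_species" | "single_species"
    target_species: str | None = None
    n_reps: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("all_species", "single_species"):
            raise ValueError(f"unknown shuffle mode {self.mode!r}")
        if self.mode == "single_species" and not self.target_species:
            raise ValueError("single_species mode requires target_species")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


@dataclass
class GroupSizeHistogram:
    """Frequency of each linked-ortholog group size over all randomizations."""

    counts: dict[int, int]
    n_reps: int
    strategy: ShuffleStrategy | None = None

    @property
    def total_groups(self) -> int:
        return sum(self.counts.values())

    def tail_mass(self, s: int, normalized: bool = False) -> float:
        """Mass of groups of size > s: mean count per randomization, or, if
        ``normalized``, the fraction of all tallied groups."""
        tail = sum(f for size, f in self.counts.items() if size > s)
        return tail / self.total_groups if normalized else tail / self.n_reps

    def to_frame(self) -> pd.DataFrame:
        sizes = sorted(self.counts)
        return pd.DataFrame({"size": sizes, "frequency": [self.counts[s] for s in sizes]})


def _rng_for_rep(seed: int, rep_index: int) -> np.random.Generator:
    # one root seed; each rep gets an independent, order-free child stream
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(rep_index,)))


def _shuffled_species(table: OrthologTable, strategy: ShuffleStrategy) -> list[str]:
    if strategy.mode == "all_species":
        return list(table.species)
    if strategy.target_species not in table.species:
        raise ValueError(
            f"target species {strategy.target_species!r} not in table {table.species}"
        )
    return [strategy.target_species]


def count_linked_groups(table: OrthologTable) -> dict[tuple[str, ...], int]:
    """Count orthologs supporting each distinct combination of per-species chromosomes.

    Returns a map from the tuple of chromosome ids (in table species order) to
    the number of rows exhibiting exactly that tuple; counts sum to the row
    count.
    """
    cols = [f"{t}_scaf" for t in table.species]
    grouped = table.df.groupby(cols, sort=False).size()
    if len(cols) == 1:  # pandas returns scalar keys for single-column groupby
        return {(k,): int(v) for k, v in grouped.items()}
    return {tuple(map(str, k)): int(v) for k, v in grouped.items()}


def shuffle_table(
    table: OrthologTable, strategy: ShuffleStrategy, rep_index: int = 0
) -> OrthologTable:
    """Return a copy of the table with location labels permuted over genes.

    For each shuffled species the (chromosome, position) pairs are permuted
    among that species' genes, preserving every chromosome's gene count
    exactly.  Deterministic given ``(strategy.seed, rep_index)``.
    """
    rng = _rng_for_rep(strategy.seed, rep_index)
    df = table.df.copy()
    n = len(df)
    for tag in _shuffled_species(table, strategy):
        perm = rng.permutation(n)
        for part in ("scaf", "pos"):
            col = f"{tag}_{part}"
            df[col] = df[col].to_numpy()[perm]
    return OrthologTable(list(table.species), df, table.outgroup)


def _chrom_codes(table: OrthologTable) -> list[np.ndarray]:
    codes = []
    for tag in table.species:
        c, _ = pd.factorize(table.df[f"{tag}_scaf"])
        codes.append(c.astype(np.int64))
    return codes


def _group_sizes_from_codes(codes: list[np.ndarray], n_chroms: list[int]) -> np.ndarray:
    key = codes[0].copy()
    for c, m in zip(codes[1:], n_chroms[1:]):
        key *= m
        key += c
    _, counts = np.unique(key, return_counts=True)
    return counts


def null_histogram(table: OrthologTable, strategy: ShuffleStrategy) -> GroupSizeHistogram:
    """Aggregate linked-group sizes over ``strategy.n_reps`` shuffled tables.

    All observed chromosome combinations of every randomization are binned by
    the number of orthologs supporting them.  Reproducible from the strategy's
    seed.
    """
    codes = _chrom_codes(table)
    n_chroms = [int(c.max()) + 1 if len(c) else 0 for c in codes]
    shuffled_idx = [table.species.index(t) for t in _shuffled_species(table, strategy)]
    hist = np.zeros(len(table.df) + 2, dtype=np.int64)
    for rep in range(strategy.n_reps):
        rng = _rng_for_rep(strategy.seed, rep)
        rep_codes = list(codes)
        for i in shuffled_idx:
            rep_codes[i] = codes[i][rng.permutation(len(codes[i]))]
        sizes = _group_sizes_from_codes(rep_codes, n_chroms)
        hist += np.bincount(sizes, minlength=len(hist))
    counts = {int(s): int(f) for s, f in enumerate(hist) if f > 0}
    return GroupSizeHistogram(counts=counts, n_reps=strategy.n_reps, strategy=strategy)


def fdr_by_group_size(
    observed: dict[tuple[str, ...], int], null: GroupSizeHistogram
) -> dict[int, float]:
    """False-discovery-rate estimate per group size, in the shuffle-and-count style.

    For each group size N present in the observed data, the FDR estimate is
    the expected number of random combinations supported by >= N orthologs per
    randomization, divided by the observed number of combinations supported by
    >= N orthologs, clamped to [0, 1].  Sizes with no observed combination are
    absent from the result.

    This reconstructs the shuffle-based FDR-per-group-size statistic from its
    published description; the exact original formula is not printed, so this
    module documents its own.
    """
    obs_sizes = np.array(sorted(observed.values()))
    null_sizes = np.array(sorted(null.counts))
    null_freqs = np.array([null.counts[s] for s in null_sizes])
    out: dict[int, float] = {}
    for n_size in sorted(set(observed.values())):
        obs_ge = int((obs_sizes >= n_size).sum())
        null_ge = int(null_freqs[null_sizes >= n_size].sum())
        expected_per_rep = null_ge / null.n_reps
        out[n_size] = float(min(1.0, expected_per_rep / obs_ge))
    return out
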