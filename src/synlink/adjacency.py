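"""Detection of conserved adjacent ortholog pairs.

Two genes immediately neighbouring on a chromosome whose orthologs remain
neighbours (or at least co-chromosomal) across species are strong small-scale
evidence of shared descent — even a single conserved adjacent pair is very
unlikely to arise in several species other than by common ancestry.

Adjacency is computed on gene ranks within the ortholog table's own gene set:
after restriction to single-copy orthologs, two rows are adjacent in a
species if their genes sit on the same chromosome with consecutive ranks
among the retained genes.  Full-genome ranks can be used instead by supplying
tables whose positions are genome-wide gene indices and setting
``rerank=False``.  Intervening non-orthologous genes therefore do not break
adjacency in the default mode; how strict to be is exposed through the two
threshold knobs rather than fixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import OrthologTable, ValidationError

__all__ = ["AdjacentPairHit", "find_conserved_adjacent_pairs"]

ADJACENT = "adjacent"
SAME_CHROM = "same_chromosome"
DIFF_CHROM = "different_chromosome"


@dataclass
class AdjacentPairHit:
    """A pair of ortholog rows conserved as neighbours/co-chromosomal across species."""

    row_a: int
    row_b: int
    status: dict[str, str]     # species tag -> ADJACENT | SAME_CHROM | DIFF_CHROM
    chroms: dict[str, tuple[str, str]]  # species tag -> (chrom of a, chrom of b)

    @property
    def n_adjacent(self) -> int:
        return sum(s == ADJACENT for s in self.status.values())

    @property
    def n_cochrom(self) -> int:
        # adjacency implies co-chromosomality
        return sum(s in (ADJACENT, SAME_CHROM) for s in self.status.values())


def _ranks(table: OrthologTable, tag: str, rerank: bool) -> np.ndarray:
    pos = table.positions(tag).to_numpy()
    if not rerank:
        return pos.astype(int)
    ranks = table.df.groupby(f"{tag}_scaf", sort=False)[f"{tag}_pos"].rank(method="first")
    return ranks.to_numpy().astype(int) - 1


def find_conserved_adjacent_pairs(
    table: OrthologTable,
    require_adjacent_in: int,
    require_cochrom_in: int,
    rerank: bool = True,
) -> list[AdjacentPairHit]:
    """Find every unordered pair of ortholog rows adjacent in at least
    ``require_adjacent_in`` species and co-chromosomal (including adjacent) in
    at least ``require_cochrom_in`` species.

    Raises ValidationError if either threshold exceeds the species count.
    """
    n_sp = len(table.species)
    for name, thr in (("require_adjacent_in", require_adjacent_in),
                      ("require_cochrom_in", require_cochrom_in)):
        if thr > n_sp:
            raise ValidationError(f"{name}={thr} exceeds species count {n_sp}")
        if thr < 0:
            raise ValidationError(f"{name} must be non-negative")

    chroms = {t: table.chroms(t).astype(str).to_numpy() for t in table.species}
    ranks = {t: _ranks(table, t, rerank) for t in table.species}

    # candidates: pairs adjacent in >=1 species (or co-chromosomal if no
    # adjacency is demanded)
    candidates: set[tuple[int, int]] = set()
    for t in table.species:
        order = np.lexsort((ranks[t], chroms[t]))
        for i, j in zip(order[:-1], order[1:]):
            if chroms[t][i] == chroms[t][j]:
                candidates.add((min(i, j), max(i, j)))
    if require_adjacent_in == 0:
        for t in table.species:
            from collections import defaultdict

            by_chrom: dict[str, list[int]] = defaultdict(list)
            for i, c in enumerate(chroms[t]):
                by_chrom[c].append(i)
            for members in by_chrom.values():
                for ii, a in enumerate(members):
                    for b in members[ii + 1 :]:
                        candidates.add((a, b))

    hits: list[AdjacentPairHit] = []
    for a, b in sorted(candidates):
        status: dict[str, str] = {}
        pair_chroms: dict[str, tuple[str, str]] = {}
        for t in table.species:
            ca, cb = chroms[t][a], chroms[t][b]
            pair_chroms[t] = (ca, cb)
            if ca != cb:
                status[t] = DIFF_CHROM
            elif abs(int(ranks[t][a]) - int(ranks[t][b])) == 1:
                status[t] = ADJACENT
            else:
                status[t] = SAME_CHROM
        hit = AdjacentPairHit(row_a=a, row_b=b, status=status, chroms=pair_chroms)
        if hit.n_adjacent >= require_adjacent_in and hit.n_cochrom >= require_cochrom_in:
            hits.append(hit)
    return hits
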