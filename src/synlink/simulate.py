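"""Chromosome-evolution simulator for multi-species ortholog tables.

An ancestral genome is a set of genes partitioned into ancestral linkage
groups (ALGs), one per ancestral chromosome.  Each descendant species starts
with one chromosome per ALG and then undergoes, in a fixed order:

1. fusions — two chromosomes are joined end to end;
2. mixing — a fraction of each fused chromosome's genes is repositioned
   uniformly along it, interleaving the two ALGs ("fusion with mixing";
   mixing 0 leaves a plain concatenation);
3. fissions — a chromosome is split at a uniform internal point;
4. translocations — each gene independently moves to a uniformly chosen
   other chromosome with a given per-gene probability;
5. losses — each gene is independently absent with a given probability.

Genes lost in any species drop the whole ortholog row, mirroring the
single-copy filtering of reciprocal-best-hit clustering.  The output carries
ground-truth labels (gene -> ALG, and per species chromosome -> ALG content)
so that recovered chromosome combinations can be scored for precision and
recall.
"""

from __future__ import annotations

import zlib
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import OrthologTable
from .linkage import LinkageTest

__all__ = [
    "AncestralGenome",
    "EvolutionParams",
    "EvolvedGenomeSet",
    "TruthScores",
    "simulate",
    "truth_evaluate",
]


@dataclass
class AncestralGenome:
    """An ancestor of ``n_genes`` genes partitioned into ALGs of the given sizes."""

    alg_sizes: Sequence[int]

    def __post_init__(self) -> None:
        self.alg_sizes = list(self.alg_sizes)
        if not self.alg_sizes or any(s < 1 for s in self.alg_sizes):
            raise ValueError("every ALG needs at least one gene")

    @property
    def n_genes(self) -> int:
        return sum(self.alg_sizes)

    @property
    def n_algs(self) -> int:
        return len(self.alg_sizes)

    @property
    def alg_assignment(self) -> np.ndarray:
        """ALG index per ancestral gene (genes 0..n_genes-1 in ALG order)."""
        return np.repeat(np.arange(self.n_algs), self.alg_sizes)


@dataclass(frozen=True)
class EvolutionParams:
    """Per-species rearrangement and loss parameters.

    mixing is the fraction of each fused chromosome's genes repositioned
    uniformly after a fusion; translocation_rate and loss_rate are per-gene
    probabilities.
    """

    n_fusions: int = 0
    mixing: float = 0.0
    n_fissions: int = 0
    translocation_rate: float = 0.0
    loss_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_fusions < 0 or self.n_fissions < 0:
            raise ValueError("event counts must be >= 0")
        for name in ("mixing", "translocation_rate", "loss_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class EvolvedGenomeSet:
    """Simulator output: the ortholog table plus ground-truth ALG labels."""

    table: OrthologTable
    gene_alg: dict[str, int]                       # ancestral gene key -> ALG
    chrom_algs: dict[str, dict[str, Counter]]      # species -> chrom -> ALG counts
    params: dict[str, EvolutionParams] = field(default_factory=dict)

    def majority_algs(self, species: str, chrom: str) -> set[int]:
        """ALG(s) with the plurality of surviving genes on one chromosome."""
        counts = self.chrom_algs[species][chrom]
        if not counts:
            return set()
        top = max(counts.values())
        return {a for a, c in counts.items() if c == top}


def _evolve_species(
    chrom_lists: list[list[int]], params: EvolutionParams, rng: np.random.Generator
) -> tuple[list[list[int]], np.ndarray]:
    """Apply fusion -> mixing -> fission -> translocation -> loss to one species.

    ``chrom_lists`` holds ancestral gene indices in order along each
    chromosome.  Returns the evolved chromosome lists and a boolean `lost`
    mask over ancestral genes.
    """
    chroms = [list(c) for c in chrom_lists]
    n_genes = sum(len(c) for c in chroms)

    # fusions (each joins two uniformly chosen chromosomes), then mixing
    if params.n_fusions > len(chroms) - 1:
        raise ValueError(
            f"{params.n_fusions} fusions impossible with {len(chroms)} chromosomes"
        )
    for _ in range(params.n_fusions):
        i, j = rng.choice(len(chroms), size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        fused = chroms[i] + chroms[j]
        if params.mixing > 0 and len(fused) > 1:
            m = int(round(params.mixing * len(fused)))
            movers = list(rng.choice(len(fused), size=m, replace=False))
            moved_genes = [fused[x] for x in movers]
            remaining = [g for x, g in enumerate(fused) if x not in set(movers)]
            for g in moved_genes:
                remaining.insert(int(rng.integers(0, len(remaining) + 1)), g)
            fused = remaining
        chroms = [c for x, c in enumerate(chroms) if x not in (i, j)] + [fused]

    # fissions
    for _ in range(params.n_fissions):
        splittable = [x for x, c in enumerate(chroms) if len(c) >= 2]
        if not splittable:
            break
        x = int(rng.choice(splittable))
        cut = int(rng.integers(1, len(chroms[x])))
        left, right = chroms[x][:cut], chroms[x][cut:]
        chroms = [c for y, c in enumerate(chroms) if y != x] + [left, right]

    # translocations: per-gene jump to a uniformly drawn chromosome (drawing
    # the source chromosome is a no-op, so rate 1 scatters genes uniformly,
    # independent of their ancestral linkage group)
    if params.translocation_rate > 0 and len(chroms) > 1:
        jump = rng.random(n_genes) < params.translocation_rate
        gene_chrom = {}
        for x, c in enumerate(chroms):
            for g in c:
                gene_chrom[g] = x
        for g in sorted(g for g in gene_chrom if jump[g]):
            src = gene_chrom[g]
            dst = int(rng.integers(0, len(chroms)))
            if dst == src:
                continue
            chroms[src].remove(g)
            chroms[dst].insert(int(rng.integers(0, len(chroms[dst]) + 1)), g)
            gene_chrom[g] = dst
        chroms = [c for c in chroms if c]

    # losses
    lost = rng.random(n_genes) < params.loss_rate
    if lost.any():
        chroms = [[g for g in c if not lost[g]] for c in chroms]
        chroms = [c for c in chroms if c]
    return chroms, lost


def simulate(
    ancestor: AncestralGenome,
    params: Mapping[str, EvolutionParams],
    seed: int = 0,
    outgroup: str | None = None,
    copy_of: Mapping[str, str] | None = None,
) -> EvolvedGenomeSet:
    """Evolve the ancestor into one genome per species and emit the ortholog table.

    Parameters
    ----------
    ancestor
        The ancestral gene set partitioned into ALGs.
    params
        Species tag -> :class:`EvolutionParams`; tag order fixes the table's
        species order.
    seed
        Root seed; each species draws from an independent child stream, so a
        species' genome does not depend on which other species are simulated.
    outgroup
        Optional tag to mark as the table's outgroup.
    copy_of
        Optional map ``{tag: other_tag}``: the species is an exact copy of
        another's gene locations under fresh chromosome names and gene ids
        (the duplicated-species construction used to probe shuffle nulls).

    Chromosomes are named ``<TAG>1, <TAG>2, ...``; gene ids are
    ``<TAG>_g<ancestral index>``.  Deterministic given the seed.
    """
    copy_of = dict(copy_of or {})
    tags = list(params.keys())
    for tag, src in copy_of.items():
        if src not in tags:
            raise ValueError(f"copy_of[{tag!r}] = {src!r} is not a simulated species")

    alg = ancestor.alg_assignment
    base_chroms = [list(np.flatnonzero(alg == a)) for a in range(ancestor.n_algs)]

    per_species: dict[str, list[list[int]]] = {}
    lost_any = np.zeros(ancestor.n_genes, dtype=bool)
    for tag in tags:
        if tag in copy_of:
            continue
        # stream keyed by the tag itself, so a species' genome is the same
        # whichever other species are simulated alongside it
        rng = np.random.default_rng(
            np.random.SeedSequence(seed, spawn_key=(zlib.crc32(tag.encode()),))
        )
        chroms, lost = _evolve_species(base_chroms, params[tag], rng)
        per_species[tag] = chroms
        lost_any |= lost
    for tag, src in copy_of.items():
        per_species[tag] = [list(c) for c in per_species[src]]

    survivors = np.flatnonzero(~lost_any)
    surv_set = set(int(g) for g in survivors)

    # per-species location of each surviving gene: chrom name + rank among
    # that species' surviving genes
    loc: dict[str, dict[int, tuple[str, int]]] = {}
    chrom_algs: dict[str, dict[str, Counter]] = {}
    for tag in tags:
        loc[tag] = {}
        chrom_algs[tag] = {}
        for ci, genes in enumerate(per_species[tag]):
            name = f"{tag}{ci + 1}"
            kept = [g for g in genes if g in surv_set]
            chrom_algs[tag][name] = Counter(int(alg[g]) for g in kept)
            for rank, g in enumerate(kept):
                loc[tag][g] = (name, rank)

    rows = []
    gene_alg: dict[str, int] = {}
    for g in survivors:
        g = int(g)
        rec = {}
        for tag in tags:
            chrom, rank = loc[tag][g]
            gid = f"{tag}_g{g:05d}"
            rec[f"{tag}_gene"] = gid
            rec[f"{tag}_scaf"] = chrom
            rec[f"{tag}_pos"] = rank
            gene_alg[gid] = int(alg[g])
        rows.append(rec)
    cols = [f"{t}_{p}" for t in tags for p in ("gene", "scaf", "pos")]
    df = pd.DataFrame(rows, columns=cols)
    table = OrthologTable(species=tags, df=df, outgroup=outgroup)
    return EvolvedGenomeSet(
        table=table, gene_alg=gene_alg, chrom_algs=chrom_algs, params=dict(params)
    )


@dataclass
class TruthScores:
    """Precision/recall of recovered chromosome combinations against planted ALGs."""

    precision: float | None
    recall: float
    true_positives: int
    false_positives: int
    recovered_algs: set[int]


def truth_evaluate(
    tests: Sequence[LinkageTest],
    truth: EvolvedGenomeSet,
    significant_only: bool = True,
) -> TruthScores:
    """Score recovered combinations: a combination is a true positive iff all
    its chromosomes share a common majority ALG; recall is the fraction of
    planted ALGs recovered by at least one true-positive combination."""
    for t in truth.table.species:
        if t not in truth.chrom_algs:
            raise ValueError(f"ground truth missing species {t}")
    combos = [t.combination for t in tests if t.significant or not significant_only]
    for t in tests:
        for tag, chrom in t.combination.chromosomes:
            if tag not in truth.chrom_algs:
                raise ValueError(f"test references unknown species {tag!r}")
            if chrom not in truth.chrom_algs[tag]:
                raise ValueError(f"test references unknown chromosome {tag}:{chrom}")

    tp = 0
    recovered: set[int] = set()
    for combo in combos:
        common: set[int] | None = None
        for tag, chrom in combo.chromosomes:
            maj = truth.majority_algs(tag, chrom)
            common = maj if common is None else (common & maj)
        if common:
            tp += 1
            recovered |= common
    fp = len(combos) - tp
    n_algs = len(set(truth.gene_alg.values()))
    precision = tp / len(combos) if combos else None
    recall = len(recovered) / n_algs if n_algs else 0.0
    return TruthScores(
        precision=precision,
        recall=recall,
        true_positives=tp,
        false_positives=fp,
        recovered_algs=recovered,
    )
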