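"""Reading, writing, validating and cross-referencing multi-species ortholog tables.

The on-disk format is a tab-separated table with one row per single-copy
ortholog group and, for each species tag ``TAG``, three columns:
``TAG_gene`` (gene identifier), ``TAG_scaf`` (chromosome/scaffold id) and
``TAG_pos`` (gene position).  Positions may be base-pair coordinates or gene
indices; on read they are rank-transformed to 0-based gene ranks per
chromosome, since only order and adjacency matter downstream.  Unknown extra
columns are preserved on round-trip but otherwise ignored.

A custom column layout can be supplied via ``column_map`` to adapt to other
dialects of the format.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneLocation",
    "OrthologTable",
    "PairwiseHits",
    "FormatError",
    "ValidationError",
    "read_rbh_table",
    "write_rbh_table",
    "cross_reference_clusters",
]


class FormatError(ValueError):
    """Raised when a file does not conform to the expected column layout."""


class ValidationError(ValueError):
    """Raised when table contents violate the single-copy ortholog invariants."""


@dataclass(frozen=True)
class GeneLocation:
    """A gene's location: chromosome/scaffold id and gene rank along it."""

    gene_id: str
    chrom: str
    pos: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chromosome id must be non-empty")
        if self.pos < 0:
            raise ValidationError(f"position must be non-negative, got {self.pos}")


def _columns_for(tag: str, column_map: Mapping[str, Mapping[str, str]] | None) -> tuple[str, str, str]:
    if column_map and tag in column_map:
        m = column_map[tag]
        return m["gene"], m["scaf"], m["pos"]
    return f"{tag}_gene", f"{tag}_scaf", f"{tag}_pos"


@dataclass
class OrthologTable:
    """A table of fully consistent single-copy ortholog groups.

    Each row maps every species tag to exactly one gene with a chromosomal
    location.  One species may be designated the outgroup; the remainder form
    the ingroup.  Backed by a :class:`pandas.DataFrame` with the column layout
    described in the module docstring.
    """

    species: list[str]
    df: pd.DataFrame
    outgroup: str | None = None

    def __post_init__(self) -> None:
        self.species = list(self.species)
        if len(self.species) < 2:
            raise ValidationError("an ortholog table needs at least 2 species")
        if self.outgroup is not None and self.outgroup not in self.species:
            raise ValidationError(
                f"outgroup {self.outgroup!r} not among species {self.species}"
            )
        self.validate()

    # -- accessors ---------------------------------------------------------

    @property
    def n_rows(self) -> int:
        return len(self.df)

    @property
    def ingroup(self) -> list[str]:
        return [s for s in self.species if s != self.outgroup]

    def chroms(self, tag: str) -> pd.Series:
        """Chromosome id per row for one species."""
        return self.df[f"{tag}_scaf"]

    def positions(self, tag: str) -> pd.Series:
        return self.df[f"{tag}_pos"]

    def genes(self, tag: str) -> pd.Series:
        return self.df[f"{tag}_gene"]

    def location(self, tag: str, row: int) -> GeneLocation:
        r = self.df.iloc[row]
        return GeneLocation(str(r[f"{tag}_gene"]), str(r[f"{tag}_scaf"]), int(r[f"{tag}_pos"]))

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        """Check single-copy invariants; raise ValidationError listing offenders."""
        for tag in self.species:
            for part in ("gene", "scaf", "pos"):
                col = f"{tag}_{part}"
                if col not in self.df.columns:
                    raise FormatError(f"missing column {col!r} for species {tag!r}")
            genes = self.df[f"{tag}_gene"]
            dup = genes[genes.duplicated()]
            if len(dup):
                raise ValidationError(
                    f"duplicate gene ids for species {tag!r}: {sorted(set(dup.astype(str)))[:10]}"
                )
            if (self.df[f"{tag}_scaf"].astype(str) == "").any():
                raise ValidationError(f"empty chromosome id in species {tag!r}")
            pos = self.df[f"{tag}_pos"]
            if (pos < 0).any():
                raise ValidationError(f"negative position in species {tag!r}")
            dup_pos = self.df.duplicated(subset=[f"{tag}_scaf", f"{tag}_pos"])
            if dup_pos.any():
                bad = self.df.loc[dup_pos, [f"{tag}_scaf", f"{tag}_pos"]].head(10)
                raise ValidationError(
                    f"duplicate (chromosome, position) for species {tag!r}:\n{bad}"
                )

    def copy(self) -> "OrthologTable":
        return OrthologTable(list(self.species), self.df.copy(), self.outgroup)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OrthologTable):
            return NotImplemented
        if self.species != other.species or self.outgroup != other.outgroup:
            return False
        cols = [f"{t}_{p}" for t in self.species for p in ("gene", "scaf", "pos")]
        a = self.df[cols].reset_index(drop=True)
        b = other.df[cols].reset_index(drop=True)
        return a.equals(b)


@dataclass
class PairwiseHits:
    """Directional best-hit candidates between two species.

    ``hits`` holds (gene_a, gene_b, evalue) rows pooled over both search
    directions; a pair is a reciprocal best hit iff each gene is the other's
    unique minimum-E-value target.
    """

    species_a: str
    species_b: str
    hits: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for ga, gb, ev in self.hits:
            if ev < 0:
                raise ValidationError(f"negative E-value for ({ga}, {gb}): {ev}")


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------


def _rank_transform(df: pd.DataFrame, species: Sequence[str]) -> pd.DataFrame:
    """Convert per-species positions to 0-based gene ranks within each chromosome."""
    df = df.copy()
    for tag in species:
        scaf, pos = f"{tag}_scaf", f"{tag}_pos"
        ranks = df.groupby(scaf, sort=False)[pos].rank(method="first").astype(int) - 1
        # ties in raw coordinates are ambiguous orderings
        dup = df.duplicated(subset=[scaf, pos])
        if dup.any():
            raise ValidationError(
                f"tied positions within a chromosome for species {tag!r}; gene order is ambiguous"
            )
        df[pos] = ranks
    return df


def read_rbh_table(
    path: str | Path,
    species_tags: Sequence[str] | None = None,
    outgroup_tag: str | None = None,
    column_map: Mapping[str, Mapping[str, str]] | None = None,
) -> OrthologTable:
    """Read a tab-separated ortholog table (.rbh dialect).

    Parameters
    ----------
    path
        TSV file with a header row.
    species_tags
        Species to load.  If omitted, inferred from columns named ``*_gene``.
    outgroup_tag
        Species to mark as outgroup (must be among the tags).
    column_map
        Optional per-species mapping ``{tag: {"gene": col, "scaf": col,
        "pos": col}}`` for non-default column names.

    Positions are rank-transformed to 0-based gene ranks per chromosome.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if species_tags is None:
        species_tags = [c[: -len("_gene")] for c in df.columns if c.endswith("_gene")]
        if not species_tags:
            raise FormatError(f"no '*_gene' columns found in {path}")
    species_tags = list(species_tags)

    rename = {}
    for tag in species_tags:
        gcol, scol, pcol = _columns_for(tag, column_map)
        for src, dst in ((gcol, f"{tag}_gene"), (scol, f"{tag}_scaf"), (pcol, f"{tag}_pos")):
            if src not in df.columns:
                raise FormatError(f"missing column {src!r} for species {tag!r} in {path}")
            if src != dst:
                rename[src] = dst
    if rename:
        df = df.rename(columns=rename)

    for tag in species_tags:
        df[f"{tag}_pos"] = pd.to_numeric(df[f"{tag}_pos"])
    df = _rank_transform(df, species_tags)
    return OrthologTable(species=species_tags, df=df, outgroup=outgroup_tag)


def write_rbh_table(table: OrthologTable, path: str | Path) -> None:
    """Write a table as TSV; ``read_rbh_table(write_rbh_table(t)) == t``.

    Extra (non per-species) columns present in the frame are preserved.
    """
    table.validate()
    table.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# cross-referencing pairwise best hits into N-way clusters
# ---------------------------------------------------------------------------


def _best_hits(hits: Iterable[tuple[str, str, float]], evalue_max: float) -> dict[str, str]:
    """Unique best target per query at E-value < evalue_max; ties yield no best hit."""
    best: dict[str, tuple[str, float, bool]] = {}  # query -> (target, ev, tied)
    for ga, gb, ev in hits:
        if ev >= evalue_max:
            continue
        cur = best.get(ga)
        if cur is None or ev < cur[1]:
            best[ga] = (gb, ev, False)
        elif ev == cur[1] and gb != cur[0]:
            best[ga] = (cur[0], cur[1], True)
    return {q: t for q, (t, _, tied) in best.items() if not tied}


def _reciprocal_map(ph: PairwiseHits, evalue_max: float) -> dict[str, str]:
    """Reciprocal best-hit pairs species_a -> species_b from a pooled hit list."""
    fwd = _best_hits(((ga, gb, ev) for ga, gb, ev in ph.hits), evalue_max)
    rev = _best_hits(((gb, ga, ev) for ga, gb, ev in ph.hits), evalue_max)
    return {x: y for x, y in fwd.items() if rev.get(y) == x}


def cross_reference_clusters(
    hits: Sequence[PairwiseHits],
    locations: Mapping[str, Mapping[str, tuple[str, int]]],
    evalue_max: float = 0.1,
    outgroup: str | None = None,
) -> OrthologTable:
    """Cross-reference pairwise reciprocal best hits into fully consistent N-way clusters.

    A cluster is a set of N genes, one per species, in which every pair is a
    reciprocal best hit (a clique in the RBH graph).  Each gene joins at most
    one cluster.  ``locations`` supplies ``(chromosome, position)`` for every
    clustered gene, keyed by species then gene id.

    Raises a :class:`FormatError` if any species pair is missing from ``hits``.
    """
    species = list(locations.keys())  # insertion order fixes the species order
    pair_index: dict[tuple[str, str], PairwiseHits] = {}
    for ph in hits:
        pair_index[(ph.species_a, ph.species_b)] = ph
        pair_index[(ph.species_b, ph.species_a)] = ph
    for i, a in enumerate(species):
        for b in species[i + 1 :]:
            if (a, b) not in pair_index:
                raise FormatError(f"missing pairwise hits for species pair ({a}, {b})")

    # reciprocal best-hit partner maps: (sp_a, sp_b) -> {gene_a: gene_b}
    recip: dict[tuple[str, str], dict[str, str]] = {}
    for i, a in enumerate(species):
        for b in species[i + 1 :]:
            ph = pair_index[(a, b)]
            r_ab = _reciprocal_map(ph, evalue_max)
            if ph.species_a == b:  # stored in the other orientation
                r_ab = {y: x for x, y in r_ab.items()}
            recip[(a, b)] = r_ab
            recip[(b, a)] = {y: x for x, y in r_ab.items()}

    anchor = species[0]
    rows = []
    for g0 in sorted(locations[anchor]):
        cand = {anchor: g0}
        ok = True
        for b in species[1:]:
            partner = recip[(anchor, b)].get(g0)
            if partner is None:
                ok = False
                break
            cand[b] = partner
        if not ok:
            continue
        # verify the full clique
        for i, a in enumerate(species):
            for b in species[i + 1 :]:
                if recip[(a, b)].get(cand[a]) != cand[b]:
                    ok = False
                    break
            if not ok:
                break
        if not ok:
            continue
        row = {}
        for sp, gid in cand.items():
            if gid not in locations[sp]:
                continue
            chrom, pos = locations[sp][gid]
            row[f"{sp}_gene"] = gid
            row[f"{sp}_scaf"] = chrom
            row[f"{sp}_pos"] = int(pos)
        if len(row) == 3 * len(species):
            rows.append(row)

    cols = [f"{t}_{p}" for t in species for p in ("gene", "scaf", "pos")]
    df = pd.DataFrame(rows, columns=cols)
    if len(df) == 0:
        df = df.astype({f"{t}_pos": int for t in species} | {f"{t}_gene": str for t in species} | {f"{t}_scaf": str for t in species})
    return OrthologTable(species=list(species), df=df, outgroup=outgroup)


def make_table(
    species: Sequence[str],
    rows: Sequence[Mapping[str, GeneLocation]],
    outgroup: str | None = None,
) -> OrthologTable:
    """Build an OrthologTable from per-row {species: GeneLocation} mappings."""
    recs = []
    for r in rows:
        rec = {}
        for tag in species:
            loc = r[tag]
            rec[f"{tag}_gene"] = loc.gene_id
            rec[f"{tag}_scaf"] = loc.chrom
            rec[f"{tag}_pos"] = loc.pos
        recs.append(rec)
    cols = [f"{t}_{p}" for t in species for p in ("gene", "scaf", "pos")]
    df = pd.DataFrame(recs, columns=cols)
    return OrthologTable(species=list(species), df=df, outgroup=outgroup)
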