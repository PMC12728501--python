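"""Hierarchical buildup of multi-species chromosome combinations.

Rather than testing every N-way chromosome combination at once, candidate
ancestral chromosomes are assembled level by level: the first two ingroup
species are compared pairwise; each further species is then tested only
against combinations judged significant at the previous level; finally the
surviving combinations are tested against the outgroup.  Restricting each
level to extensions of previous survivors shrinks the testing family for the
BH correction, which is the point of the scheme — the final-level statistic
for a given combination is identical to the flat test's, only the family
(and hence the adjusted values) changes.

Two counting bases are supported: by default all levels share the single
N-way ortholog table; alternatively per-level tables (e.g. from pairwise
ortholog runs, which retain more orthologs) can be supplied.

Standardized Pearson residuals of the observed-count matrices are computed
for heatmap rendering of each level.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import OrthologTable
from .linkage import ChromCombination, ContingencyTable, LinkageTest, bh_correct, hypergeom_tail

__all__ = [
    "HierarchyLevel",
    "ResidualMatrix",
    "build_hierarchy",
    "standardized_residuals",
    "export_heatmap",
]


@dataclass
class HierarchyLevel:
    """One level of the buildup: the species added, its tests, and the survivors."""

    level_index: int
    species_added: str
    tests: list[LinkageTest]

    @property
    def survivors(self) -> list[ChromCombination]:
        return [t.combination for t in self.tests if t.significant]


@dataclass
class ResidualMatrix:
    """Observed counts with standardized Pearson residuals under independence.

    ``residuals[i, j] = (O_ij - E_ij) / sqrt(E_ij (1 - r_i/N)(1 - c_j/N))``
    with ``E_ij = r_i c_j / N``; cells whose row or column margin is zero (or
    saturates the grand total) are NaN and excluded from the omnibus
    chi-squared statistic ``sum (O - E)^2 / E``.
    """

    observed: pd.DataFrame
    expected: pd.DataFrame
    residuals: pd.DataFrame
    chi2: float


def _level_tests(
    counts: pd.Series,
    prefix_tags: list[str],
    new_tag: str,
    n_total: int,
    allowed_prefixes: set[tuple[str, ...]] | None,
    min_count: int,
    is_outgroup_level: bool,
) -> list[LinkageTest]:
    """Enrichment tests of (prefix combination) x (new species chromosome)."""
    df = counts.rename("n").reset_index()
    prefix_cols = [f"{t}_scaf" for t in prefix_tags]
    new_col = f"{new_tag}_scaf"
    df["_prefix"] = list(map(tuple, df[prefix_cols].astype(str).to_numpy()))
    if allowed_prefixes is not None:
        df = df[df["_prefix"].isin(allowed_prefixes)]
    prefix_totals = df.groupby("_prefix")["n"].sum().to_dict()
    new_totals = counts.rename("n").reset_index().groupby(new_col)["n"].sum().to_dict()

    tests = []
    for _, row in df.iterrows():
        n = int(row["n"])
        if n < min_count:
            continue
        prefix = row["_prefix"]
        new_chrom = str(row[new_col])
        ct = ContingencyTable(
            k=n,
            K_out=int(new_totals[new_chrom]),
            K_in=int(prefix_totals[prefix]),
            N=n_total,
        )
        if is_outgroup_level:
            combo = ChromCombination(
                ingroup=tuple(zip(prefix_tags, prefix)),
                outgroup=(new_tag, new_chrom),
            )
        else:
            combo = ChromCombination(
                ingroup=tuple(zip(prefix_tags, prefix)) + ((new_tag, new_chrom),)
            )
        tests.append(LinkageTest(combination=combo, table=ct, p_raw=hypergeom_tail(ct)))
    return tests


def build_hierarchy(
    table: OrthologTable,
    species_order: Sequence[str] | None = None,
    alpha: float = 0.05,
    min_count: int = 1,
    level_tables: Sequence[OrthologTable] | None = None,
) -> list[HierarchyLevel]:
    """Build combinations level by level, testing only extensions of prior survivors.

    Parameters
    ----------
    table
        The N-way ortholog table (used for every level in single-table mode).
    species_order
        Permutation of the table's species ending with the outgroup; defaults
        to ingroup order followed by the outgroup.
    alpha
        BH threshold, shared across levels.
    min_count
        Minimum shared orthologs for a combination to enter a level's family.
    level_tables
        Optional per-level ortholog tables (pairwise-ortholog mode): entry L-1
        must cover at least the first L+1 species of ``species_order`` and is
        used to count that level's contingency tables.

    Returns one :class:`HierarchyLevel` per added species; level L's surviving
    combinations, projected onto the first L+1 species, are by construction a
    subset of level L-1's survivors.
    """
    if species_order is None:
        if table.outgroup is None:
            raise ValueError("species_order or a designated outgroup is required")
        species_order = table.ingroup + [table.outgroup]
    species_order = list(species_order)
    if sorted(species_order) != sorted(table.species):
        raise ValueError(
            f"species_order {species_order} is not a permutation of {table.species}"
        )
    if len(species_order) < 2:
        raise ValueError("hierarchy needs at least 2 species")
    n_levels = len(species_order) - 1
    if level_tables is not None and len(level_tables) != n_levels:
        raise ValueError(f"expected {n_levels} level tables, got {len(level_tables)}")

    levels: list[HierarchyLevel] = []
    allowed: set[tuple[str, ...]] | None = None
    for li in range(1, n_levels + 1):
        prefix_tags = species_order[:li]
        new_tag = species_order[li]
        tbl = level_tables[li - 1] if level_tables is not None else table
        cols = [f"{t}_scaf" for t in prefix_tags + [new_tag]]
        counts = tbl.df.groupby(cols, sort=False).size()
        tests = _level_tests(
            counts, prefix_tags, new_tag, tbl.n_rows, allowed, min_count,
            is_outgroup_level=(li == n_levels),
        )
        if tests:
            q, rej = bh_correct([t.p_raw for t in tests], alpha=alpha)
            for t, qi, ri in zip(tests, q, rej):
                t.q_bh = float(qi)
                t.significant = bool(ri)
        tests.sort(key=lambda t: (t.q_bh, t.p_raw, t.combination.merged_id))
        level = HierarchyLevel(level_index=li, species_added=new_tag, tests=tests)
        levels.append(level)
        allowed = {
            tuple(c for _, c in t.combination.chromosomes)
            for t in tests
            if t.significant
        }
        # de-duplicate identical combinations reached via different parents
        if allowed is not None:
            allowed = set(allowed)
    return levels


def standardized_residuals(
    observed: pd.DataFrame | np.ndarray,
) -> ResidualMatrix:
    """Standardized Pearson residuals and omnibus chi-squared for a count matrix.

    Cells in a zero (or saturating) margin have undefined residuals, reported
    as NaN and excluded from the chi-squared statistic.  A matrix with a
    non-positive grand total is rejected.
    """
    obs = pd.DataFrame(observed).astype(float)
    if obs.size == 0:
        raise ValueError("empty count matrix")
    if (obs.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    n = obs.to_numpy().sum()
    if n <= 0:
        raise ValueError("count matrix must have a positive grand total")
    r = obs.sum(axis=1).to_numpy()
    c = obs.sum(axis=0).to_numpy()
    expected = np.outer(r, c) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.sqrt(expected * np.outer(1 - r / n, 1 - c / n))
        resid = (obs.to_numpy() - expected) / denom
    resid[~np.isfinite(resid)] = np.nan
    mask = expected > 0
    chi2 = float((((obs.to_numpy() - expected) ** 2 / np.where(mask, expected, 1.0)))[mask].sum())
    idx, cols = obs.index, obs.columns
    return ResidualMatrix(
        observed=obs,
        expected=pd.DataFrame(expected, index=idx, columns=cols),
        residuals=pd.DataFrame(resid, index=idx, columns=cols),
        chi2=chi2,
    )


def level_count_matrix(
    table: OrthologTable, row_tags: Sequence[str], col_tag: str,
    row_combos: Sequence[tuple[str, ...]] | None = None,
) -> pd.DataFrame:
    """Shared-ortholog count matrix: rows are (merged) chromosome combinations of
    ``row_tags``, columns are chromosomes of ``col_tag``."""
    cols = [f"{t}_scaf" for t in row_tags]
    key = table.df[cols].astype(str).agg("_".join, axis=1)
    if row_combos is not None:
        wanted = {"_".join(rc) for rc in row_combos}
        keep = key.isin(wanted)
    else:
        keep = pd.Series(True, index=table.df.index)
    mat = pd.crosstab(key[keep], table.df.loc[keep, f"{col_tag}_scaf"].astype(str))
    mat.index.name = "_".join(row_tags)
    mat.columns.name = col_tag
    return mat


def export_heatmap(
    matrix: ResidualMatrix, path: str | Path, image: str | Path | None = None
) -> None:
    """Write a residual matrix as TSV (one row per matrix row; count and
    residual columns side by side), optionally also rendering a PNG heatmap."""
    if matrix.observed.size == 0:
        raise ValueError("cannot export an empty matrix")
    obs = matrix.observed.add_prefix("count_")
    res = matrix.residuals.add_prefix("resid_")
    out = pd.concat([obs, res], axis=1)
    out.index.name = matrix.observed.index.name or "row"
    out.to_csv(path, sep="\t")
    if image is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 5))
        data = matrix.residuals.to_numpy()
        vmax = np.nanmax(np.abs(data)) if np.isfinite(data).any() else 1.0
        im = ax.imshow(data, cmap="RdBu_r", vmin=-vmax, vmax=vmax)
        ax.set_xticks(range(len(matrix.residuals.columns)), matrix.residuals.columns,
                      rotation=90, fontsize=6)
        ax.set_yticks(range(len(matrix.residuals.index)), matrix.residuals.index, fontsize=6)
        fig.colorbar(im, ax=ax, label="standardized Pearson residual")
        fig.tight_layout()
        fig.savefig(image, dpi=150)
        plt.close(fig)
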