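"""Exact enrichment tests for chromosome combinations.

Each observed combination of an ingroup chromosome set with an outgroup
chromosome is a hypothesis of shared ancestral linkage.  Given k orthologs on
the full combination, K_out orthologs on the outgroup chromosome, K_in on the
ingroup combination (with any outgroup chromosome), and N orthologs in total,
the 2x2 contingency table is::

    ((k,        K_out - k),
     (K_in - k, N - K_out - K_in + k))

and the upper-tail probability P(X >= k) of the hypergeometric distribution
(population N, K_in successes, K_out draws) is the one-sided Fisher exact
p-value for enrichment.  The chromosome's ortholog count serves as a proxy
for its size, so the test is bespoke to the chromosomes involved rather than
a single threshold on group size.  Benjamini-Hochberg correction is applied
across all combinations tested, since each counts as a hypothesis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import OrthologTable

__all__ = [
    "ChromCombination",
    "ContingencyTable",
    "LinkageTest",
    "build_contingency",
    "hypergeom_tail",
    "bh_correct",
    "test_all_combinations",
]


@dataclass(frozen=True)
class ChromCombination:
    """An ingroup chromosome combination, optionally paired with an outgroup chromosome.

    ``ingroup`` lists (species tag, chromosome id) in the configured species
    order; the merged identifier joins the ingroup chromosome ids with "_"
    (e.g. HCA7, RES2, EMU19 -> "HCA7_RES2_EMU19").
    """

    ingroup: tuple[tuple[str, str], ...]
    outgroup: tuple[str, str] | None = None

    @property
    def merged_id(self) -> str:
        return "_".join(chrom for _, chrom in self.ingroup)

    @property
    def chromosomes(self) -> tuple[tuple[str, str], ...]:
        return self.ingroup + ((self.outgroup,) if self.outgroup else ())

    def __str__(self) -> str:
        s = self.merged_id
        if self.outgroup:
            s += f" | {self.outgroup[1]}"
        return s


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table of ortholog counts for one (ingroup combination, outgroup chromosome) pair."""

    k: int      # orthologs on ingroup combination AND outgroup chromosome
    K_out: int  # total orthologs on the outgroup chromosome
    K_in: int   # total orthologs on the ingroup combination
    N: int      # total orthologs in the dataset

    def __post_init__(self) -> None:
        for name, v in self.cells_flat:
            if v < 0:
                raise ValueError(f"negative contingency cell {name} = {v} "
                                 f"(k={self.k}, K_out={self.K_out}, K_in={self.K_in}, N={self.N})")

    @property
    def cells(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return (
            (self.k, self.K_out - self.k),
            (self.K_in - self.k, self.N - self.K_out - self.K_in + self.k),
        )

    @property
    def cells_flat(self) -> list[tuple[str, int]]:
        return [
            ("k", self.k),
            ("K_out - k", self.K_out - self.k),
            ("K_in - k", self.K_in - self.k),
            ("N - K_out - K_in + k", self.N - self.K_out - self.K_in + self.k),
        ]


@dataclass
class LinkageTest:
    """Result of the exact enrichment test for one chromosome combination."""

    combination: ChromCombination
    table: ContingencyTable
    p_raw: float
    q_bh: float = float("nan")
    significant: bool = False


def build_contingency(table: OrthologTable, combo: ChromCombination) -> ContingencyTable:
    """Count the four contingency quantities for a combination observed in the table.

    Raises ValueError if the combination (including its outgroup chromosome)
    is never observed.
    """
    if combo.outgroup is None:
        raise ValueError("combination must carry an outgroup chromosome")
    in_mask = np.ones(table.n_rows, dtype=bool)
    for tag, chrom in combo.ingroup:
        in_mask &= (table.chroms(tag) == chrom).to_numpy()
    out_tag, out_chrom = combo.outgroup
    out_mask = (table.chroms(out_tag) == out_chrom).to_numpy()
    k = int((in_mask & out_mask).sum())
    if k == 0:
        raise ValueError(f"combination {combo} never observed in the table")
    return ContingencyTable(k=k, K_out=int(out_mask.sum()), K_in=int(in_mask.sum()),
                            N=table.n_rows)


def hypergeom_tail(ct: ContingencyTable) -> float:
    """P(X >= k): upper-tail hypergeometric probability (one-sided Fisher exact).

    X ~ Hypergeometric(population N, K_in successes, K_out draws); the
    parameterization is symmetric in (K_in, K_out).  Degenerate margins
    (K_in = 0 or K_out = 0) and k = 0 return 1.
    """
    if ct.k <= 0 or ct.K_in == 0 or ct.K_out == 0:
        return 1.0
    return float(hypergeom.sf(ct.k - 1, ct.N, ct.K_in, ct.K_out))


def bh_correct(
    pvals: Sequence[float], alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment.

    Returns (adjusted values, rejection flags); a hypothesis is rejected iff
    its adjusted value is <= alpha.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, q <= alpha


def combination_counts(
    table: OrthologTable,
) -> dict[ChromCombination, int]:
    """Observed (ingroup combination, outgroup chromosome) pairs with their ortholog counts."""
    if table.outgroup is None:
        raise ValueError("table has no designated outgroup")
    ingroup = table.ingroup
    cols = [f"{t}_scaf" for t in ingroup] + [f"{table.outgroup}_scaf"]
    out: dict[ChromCombination, int] = {}
    for key, n in table.df.groupby(cols, sort=False).size().items():
        key = (key,) if len(cols) == 1 else key
        combo = ChromCombination(
            ingroup=tuple((t, str(c)) for t, c in zip(ingroup, key[:-1])),
            outgroup=(table.outgroup, str(key[-1])),
        )
        out[combo] = int(n)
    return out


def test_all_combinations(
    table: OrthologTable, alpha: float = 0.05, min_count: int = 1
) -> list[LinkageTest]:
    """Flat enrichment test of every observed combination against the outgroup.

    One test per observed (ingroup-combination, outgroup-chromosome) pair with
    at least ``min_count`` shared orthologs; BH correction is applied across
    exactly that family.  Results are sorted by adjusted value.
    """
    counts = combination_counts(table)
    # margins shared across tests
    in_counts: dict[tuple[str, ...], int] = {}
    out_counts: dict[str, int] = {}
    for combo, n in counts.items():
        ikey = tuple(c for _, c in combo.ingroup)
        in_counts[ikey] = in_counts.get(ikey, 0) + n
        out_counts[combo.outgroup[1]] = out_counts.get(combo.outgroup[1], 0) + n

    tests: list[LinkageTest] = []
    for combo, n in counts.items():
        if n < min_count:
            continue
        ct = ContingencyTable(
            k=n,
            K_out=out_counts[combo.outgroup[1]],
            K_in=in_counts[tuple(c for _, c in combo.ingroup)],
            N=table.n_rows,
        )
        tests.append(LinkageTest(combination=combo, table=ct, p_raw=hypergeom_tail(ct)))

    if tests:
        q, rej = bh_correct([t.p_raw for t in tests], alpha=alpha)
        for t, qi, ri in zip(tests, q, rej):
            t.q_bh = float(qi)
            t.significant = bool(ri)
    tests.sort(key=lambda t: (t.q_bh, t.p_raw, t.combination.merged_id))
    return tests


def format_pvalue(p: float) -> str:
    """Scientific notation with two significant figures, e.g. 2.3e-09."""
    return f"{p:.1e}"
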