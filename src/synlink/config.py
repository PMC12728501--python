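"""Run configuration and the end-to-end reanalysis driver."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .hierarchy import build_hierarchy
from .io import OrthologTable, read_rbh_table
from .linkage import LinkageTest, format_pvalue, test_all_combinations
from .permutation import ShuffleStrategy, null_histogram

log = logging.getLogger("synlink")

__all__ = ["RunConfig", "run_full_reanalysis", "tests_to_frame"]


@dataclass
class RunConfig:
    """Configuration of a full reanalysis run.

    species lists all tags in ingroup order; the outgroup must be among them.
    """

    rbh_path: str
    species: list[str]
    outgroup: str
    alpha: float = 0.05
    min_count: int = 1
    shuffle_mode: str = "single_species"
    n_reps: int = 10_000
    seed: int = 0
    out_dir: str = "synlink_out"

    def __post_init__(self) -> None:
        if self.outgroup not in self.species:
            raise ValueError(f"outgroup {self.outgroup!r} not in species {self.species}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.shuffle_mode not in ("all_species", "single_species"):
            raise ValueError(f"unknown shuffle mode {self.shuffle_mode!r}")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def tests_to_frame(tests: list[LinkageTest]) -> pd.DataFrame:
    """Tabulate linkage tests: merged ingroup id, outgroup chromosome, the four
    contingency quantities, raw and BH-adjusted p-values, significance flag."""
    rows = []
    for t in tests:
        out_chrom = t.combination.outgroup[1] if t.combination.outgroup else ""
        rows.append(
            {
                "ingroup_combination": t.combination.merged_id,
                "outgroup_chrom": out_chrom,
                "k_shared": t.table.k,
                "K_ingroup": t.table.K_in,
                "K_outgroup": t.table.K_out,
                "N_total": t.table.N,
                "p_raw": format_pvalue(t.p_raw),
                "q_bh": format_pvalue(t.q_bh),
                "significant": t.significant,
            }
        )
    cols = ["ingroup_combination", "outgroup_chrom", "k_shared", "K_ingroup",
            "K_outgroup", "N_total", "p_raw", "q_bh", "significant"]
    return pd.DataFrame(rows, columns=cols)


def run_full_reanalysis(config: RunConfig, table: OrthologTable | None = None) -> dict:
    """Run flat tests, hierarchical tests and the permutation null on one table.

    Writes ``flat_tests.tsv``, ``hierarchy_level<L>.tsv``, a hierarchy summary
    with an explicit status column ("x" marks flat-significant combinations
    whose metazoan combination is not supported hierarchically),
    ``null_histogram.tsv`` and ``manifest.json`` into the output directory.
    Identical config (hence identical manifest) yields identical outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if table is None:
        log.info("ingest: reading %s", config.rbh_path)
        table = read_rbh_table(config.rbh_path, config.species, config.outgroup)
    log.info("ingest: %d ortholog rows, %d species", table.n_rows, len(table.species))

    flat = test_all_combinations(table, alpha=config.alpha, min_count=config.min_count)
    log.info("flat test family: %d combinations, %d significant",
             len(flat), sum(t.significant for t in flat))
    flat_df = tests_to_frame(flat)
    flat_df.to_csv(out / "flat_tests.tsv", sep="\t", index=False)

    levels = build_hierarchy(
        table, species_order=table.ingroup + [table.outgroup],
        alpha=config.alpha, min_count=config.min_count,
    )
    for lv in levels:
        log.info("hierarchy level %d (+%s): family %d, survivors %d",
                 lv.level_index, lv.species_added, len(lv.tests), len(lv.survivors))
        tests_to_frame(lv.tests).to_csv(
            out / f"hierarchy_level{lv.level_index}.tsv", sep="\t", index=False
        )

    final_ids = {
        (t.combination.merged_id, t.combination.outgroup[1])
        for t in levels[-1].tests
        if t.significant and t.combination.outgroup
    }
    summary = flat_df[flat_df["significant"]].copy()
    summary["metazoan_status"] = [
        "supported" if (r.ingroup_combination, r.outgroup_chrom) in final_ids else "x"
        for r in summary.itertuples()
    ]
    summary.to_csv(out / "summary.tsv", sep="\t", index=False)

    strat = ShuffleStrategy(
        mode=config.shuffle_mode,
        target_species=config.outgroup if config.shuffle_mode == "single_species" else None,
        n_reps=config.n_reps,
        seed=config.seed,
    )
    hist = null_histogram(table, strat)
    hist.to_frame().to_csv(out / "null_histogram.tsv", sep="\t", index=False)

    manifest = {
        "synlink_version": __version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "n_rows": table.n_rows,
        "flat_family_size": len(flat),
        "hierarchy_family_sizes": [len(lv.tests) for lv in levels],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
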