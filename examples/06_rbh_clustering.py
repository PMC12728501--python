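"""Cross-referencing pairwise best hits into N-way ortholog clusters.

Pairwise reciprocal best hits (E-value < 0.1) are cross-referenced so that a
cluster is kept only when the genes from all species are each other's best
hits — a clique in the RBH graph, guaranteeing fully consistent single-copy
ortholog groups.
"""

import synlink as sl

# toy hits: genes g1/g2 form clean cliques; g3's hits conflict across pairs
hits = [
    sl.PairwiseHits("SRO", "EMU", [("s1", "e1", 1e-8), ("s2", "e2", 1e-6),
                                   ("s3", "e3", 1e-4), ("s3", "e1", 2e-4)]),
    sl.PairwiseHits("SRO", "HCA", [("s1", "h1", 1e-7), ("s2", "h2", 1e-5),
                                   ("s3", "h1", 1e-4)]),
    sl.PairwiseHits("EMU", "HCA", [("e1", "h1", 1e-9), ("e2", "h2", 1e-6),
                                   ("e3", "h2", 1e-3)]),
]
locations = {
    "SRO": {f"s{i}": (f"SRO{i}", 0) for i in (1, 2, 3)},
    "EMU": {f"e{i}": (f"EMU{i}", 0) for i in (1, 2, 3)},
    "HCA": {f"h{i}": (f"HCA{i}", 0) for i in (1, 2, 3)},
}
table = sl.cross_reference_clusters(hits, locations, evalue_max=0.1)
print(table.df.to_string(index=False))
print(f"\n{table.n_rows} fully consistent 3-way clusters "
      "(g3's inconsistent best hits keep it out of any cluster)")
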