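# Methods

## Data model

The unit of analysis is a table of fully consistent single-copy ortholog
groups: one row per group, and for each species a gene id, a chromosome (or
scaffold) id, and a position. Positions are 0-based gene ranks within each
chromosome; base-pair coordinates are rank-transformed on read, since every
statistic in the package depends only on gene order and co-chromosomality,
never on physical distance. Tables designate one species as the outgroup
(here, a unicellular relative of animals); the rest form the ingroup.

Ortholog tables can be ingested directly (tab-separated, columns
`TAG_gene / TAG_scaf / TAG_pos` per species, adaptable via a column map) or
built by cross-referencing pairwise best-hit lists: a cluster is retained
only when its N genes are pairwise reciprocal best hits (a clique in the RBH
graph) at E-value < 0.1. Ties for "best hit" disqualify the gene — a
conservative rule that keeps clusters strictly single-copy. Alignment itself
is out of scope; the package consumes hit tables.

## Permutation null models

A shuffle permutes the multiset of (chromosome, position) labels over a
species' genes, so each chromosome retains exactly its gene count. Two
strategies are provided:

- **shuffle-one** randomizes a single designated species (typically the
  outgroup) against the intact ingroup;
- **shuffle-all** randomizes every species independently.

For each randomized table, the sizes of *all* observed chromosome
combinations (the number of orthologs supporting each distinct tuple of
per-species chromosomes) are tallied into a group-size histogram. Shuffle-all
treats correlated genomes as independent: on a trio in which one species is
an exact copy of another, shuffle-one reproduces the pair's histogram
(the copy adds no randomness), while shuffle-all produces far fewer large
random groups — which, used as a null, overstates the significance of
observed groups. The test suite checks both behaviors at 10,000
randomizations, comparing histograms with a pooled two-sample chi-squared
test and the right tails via the normalized tail mass (the fraction of
tallied groups exceeding each size).

A shuffle-and-count FDR estimate per group size is included for comparison
with the permutation-based approach it replaces: for size n, the expected
number of random combinations of size ≥ n per randomization divided by the
observed number of combinations of size ≥ n, clamped to [0, 1]. The original
statistic is only described in prose in the literature this reconstructs, so
the formula here is documented as this package's own reconstruction.

Randomization uses one root seed; replicate r draws from an independent
child stream keyed by r, so results are reproducible and independent of
evaluation order. The conventional number of randomizations is 100,000; the
test suite uses 10,000 (and down to 400 for self-consistency checks), which
keeps Monte-Carlo error well below the effects being tested while keeping
the default suite fast.

## Exact enrichment test

Each observed (ingroup combination, outgroup chromosome) pair is one
hypothesis. With k shared orthologs, K_out orthologs on the outgroup
chromosome, K_in on the ingroup combination and N in total, the p-value is
the hypergeometric upper tail P(X ≥ k), X ~ Hypergeom(N, K_in, K_out) —
identical to a one-sided Fisher exact test, symmetric in K_in/K_out, and
computed as the survival function at k−1 ("k or more"). Degenerate margins
return p = 1. Benjamini–Hochberg step-up correction (alpha 0.05 by default)
is applied across the family of all observed combinations with at least
`min_count` shared orthologs; `min_count` defaults to 1 because every
observed combination counts as a tested hypothesis, and is exposed only for
sensitivity analysis. P-values are reported at two significant figures;
full precision is kept internally.

## Hierarchical buildup

Testing every N-way combination at once charges the BH correction with a
large family, much of it noise. The hierarchical mode instead tests
chromosome pairs of the first two ingroup species, then extends only the
significant pairs by the next species' chromosomes, and finally tests the
surviving ingroup combinations against the outgroup. BH is applied within
each level; alpha is shared across levels. The final-level statistic for a
combination equals the flat test's raw p-value — the hierarchy changes the
testing family, not the statistic. Species order is user-chosen (no general
ordering rule exists); identical final combinations reached via different
parents are de-duplicated. By default all levels count from the single N-way
table; per-level tables (e.g. from pairwise ortholog runs, which retain more
orthologs at shallow levels) can be supplied instead.

For rendering, each level's observed count matrix is summarized by
standardized Pearson residuals r_ij = (O_ij − E_ij) / sqrt(E_ij (1 −
r_i/N)(1 − c_j/N)) with E_ij = r_i c_j / N, plus the omnibus chi-squared
Σ(O−E)²/E. Cells in zero or saturating margins are reported as NaN and
excluded from the statistic. The residuals are computed directly from this
formula (statsmodels' equivalent method serves as an independent oracle in
the tests) and are not used in any significance decision.

## Conserved adjacent pairs

Two ortholog rows are adjacent in a species when their genes sit on the same
chromosome at consecutive ranks *within the table's gene set*; intervening
genes absent from the table do not break adjacency. A pair is reported when
it is adjacent in at least `require_adjacent_in` species and co-chromosomal
(adjacency included) in at least `require_cochrom_in`. Both knobs are
explicit because published usage tolerates one species in which the pair is
merely co-chromosomal; the package does not fix a single rule. Full-genome
ranks can be used instead by disabling re-ranking. Strand and orientation
are ignored. No per-pair significance is computed: the evidential force of a
conserved adjacency is argued combinatorially, not tested.

## Simulator

The generator plants ancestral linkage groups and evolves one genome per
species, applying events in a fixed order for reproducibility: fusions →
mixing → fissions → translocations → losses.

- **Fusion** joins two uniformly chosen chromosomes end to end. **Mixing**
  then repositions a fraction `mixing` of the fused chromosome's genes at
  uniform positions — `mixing=0` is a clean concatenation (one ALG's ranks
  all precede the other's), `mixing=1` a full interleaving; this is the
  simplest model that separates "fusion" from "fusion with mixing".
- **Fission** splits a chromosome at a uniform internal point.
- **Translocation** moves each gene, with probability `translocation_rate`,
  to a uniformly drawn chromosome (drawing the source is a no-op), so a rate
  of 1 scatters genes independently of their ALG.
- **Loss** removes each gene independently with probability `loss_rate`;
  rows missing in any species are dropped, mirroring single-copy RBH
  filtering.

Each species draws from an RNG stream keyed by (root seed, species tag), so
a species' genome is identical whichever other species are simulated — this
is what makes the duplicated-species control well-posed. A species can also
be declared an exact copy of another (fresh chromosome names and gene ids,
one-to-one gene mapping).

Ground truth records each gene's ALG and each chromosome's ALG content. A
recovered combination counts as a true positive when all its chromosomes
share a common plurality ALG; recall is the fraction of planted ALGs covered
by at least one true positive, precision the true-positive fraction of
significant combinations (undefined when nothing is significant).

Default study conditions used in the tests: four species, three 30-gene
ALGs, per-gene translocation rate 0.03–0.05 and loss rate 0.05 —
chromosome-scale linkage with mild scrambling, the regime in which ALG
recovery should be unambiguous. The simulator does not model realistic
chromosome size distributions, sequence evolution, or ortholog
misidentification; passing tests show the statistics behave correctly under
the stated rearrangement model, not that any particular empirical dataset's
groups are real.

## Numerical and design notes

- The fast histogram tally encodes chromosomes as integers and bin-counts
  combination keys; it is asserted equal to the explicit
  shuffle-then-group-by path in the tests.
- BH adjustment delegates to statsmodels' step-up implementation behind the
  package's `bh_correct` surface and is property-tested against the textbook
  formula.
- Exactness of the tail probability is established against brute-force
  enumeration of all C(N, K_out) draws for every table with N ≤ 12 and
  against one-sided Fisher exact on random tables (relative error < 1e-10).
- Ties, degenerate inputs: empty families return empty results; a
  combination covering all rows yields the degenerate table ((N,0),(0,0))
  with p computed as usual; 1×1 residual matrices have undefined residuals
  and a zero omnibus statistic.
- Known limitations: the hierarchical mode's power depends on the chosen
  species order; the adjacency definition is deliberately parameterized
  rather than canonical; the FDR-by-group-size statistic is a documented
  reconstruction; and chromosome "size" is always measured in orthologs, not
  base pairs.
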