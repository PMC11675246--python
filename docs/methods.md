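# Methods

## Conservation scoring

The alignment is held as an (species × columns) character matrix with a
designated reference row (human F8-202 precursor, 2351 aa including the
signal peptide; variant labels such as E2023K use this numbering, never the
legacy mature-chain numbering). Residue comparison is case-insensitive and
`X` never matches.

**Species filter.** A species is removed when it has a contiguous run of
more than `max_gap_run` (default 10) gap characters over the columns where
the reference is non-gap. The rule is applied per contiguous run, not per
total gap count, because it targets *large missing regions*; insertions
private to other species do not count as missing reference coverage, and
gaps flanking a reference insertion merge into one run in reference
coordinates. The reference row is always retained. A run of exactly 10 is
retained; 11 is removed.

**Score.** At each ungapped reference position, the score is the fraction of
retained species whose aligned character equals the reference residue. Gaps
and `X` count in the denominator as mismatches, keeping the reading "1 means
100% of species conserved". Because published per-column conservation
formulas sometimes exclude gapped species from the denominator, an
`exclude_gaps=True` mode is exposed; the inclusive definition is the
default.

## Variant harmonization

Variant identity is the protein-level amino-acid change only; nucleotide
representations are out of scope. Merging takes the union of source groups
per change; allele frequencies and zygosity counts come exclusively from
gnomAD rows; phenotype text is carried verbatim and never parsed. Two
sources disagreeing on the reference residue at a position is an error, not
a silent overwrite. The conserved-and-common filter uses strict
inequalities (conservation > 0.7, max population AF > 0.001) per its
definition; both thresholds are parameters. Several rows of the packaged
conserved/common reference table sit below 1e-3 max AF (e.g. E1690G,
8.28e-4), so that table is reproduced in tests with the threshold at 1e-4;
the default remains 1e-3.

Population labels are free strings matched exactly (gnomAD v4 group names in
the fixtures); no controlled vocabulary is enforced.

## Additive score

The total score is conservation (∈ [0, 1]) + a binary PTM/cleavage-site
annotation + one normalized score per prediction tool. Normalization maps
are affine with clipping, oriented damaging-high, derived from each tool's
published range: CADD PHRED /40, 1 − SIFT, PolyPhen as-is,
MutationAssessor /5.5, GERP++ RS as (x + 12.3)/18.5, PROVEAN as
(2.5 − x)/16.5, and ClinPred/DANN/GenoCanyon/LIST-S2/MVP/REVEL as-is. All
maps are overridable per run. With twelve tools the total lies in [0, 14];
the shipped reference shortlist (built with an external scoring convention)
tops out at 15.31, so **rank agreement, not absolute totals, is the
contract** of this stage. Missing tool scores contribute 0 — the total is
then a lower bound — and flag the record, rather than being imputed.

The pathogenic-range threshold is the 5th percentile (linear interpolation)
of the known-pathogenic total-score distribution: the reference shortlist's
floor sits near the low tail of the pathogenic range and no exact rule is
published, so the quantile is a parameter. Shortlist eligibility defaults to
membership in ClinVar-VUS or Geno2MP and never ClinVar-pathogenic; the
eligible set is a parameter (UniProt-only disease variants can be added).
Sorting is by total descending, ties by position ascending.

## Trajectory analysis

All dynamics work is Cα-only: per-residue movement and correlation are the
quantities of interest and Cα is the standard residue proxy. Superposition
is least-squares rigid-body (Kabsch, proper rotations only, batched over
frames with the reflection case handled by the determinant sign); the
default target is the mean structure after one alignment pass to frame 0,
which removes the arbitrary choice of the first frame as the orientation
anchor. Snapshot bookkeeping counts the frame at t = 0, so an 80-ns run
sampled every 100 ps has 801 frames.

The cross-correlation is the standard vector-dot normalized covariance of
residue displacement vectors, in [−1, 1]. Per-axis correlation variants
exist in some analysis packages; the vector-dot form is implemented as it
matches the printed correlation magnitudes (e.g. 0.984 between adjacent
residues). Residues with zero fluctuation get NaN rows/columns and an
explicit flag — never a silent 0. The vectorized implementation is tested
against a naive double-loop oracle at 1e-10 on small instances.

Note that common-mode removal during superposition dilutes the apparent
correlation of a co-moving block by roughly a factor (1 − m/N)²ρ / ((1 −
m/N)²ρ + 1 − ρ) for a block of m among N residues, which is why recovery
tests use blocks that are a small fraction (≤10%) of the system.

Spatial clustering of the top VUS uses single-linkage connected components
at a Cα-distance cutoff (default 12 Å, a parameter) on the reference
structure. The published grouping of VUS clusters was visual; the cutoff
makes it reproducible.

## eQTL block detection

A co-inherited block is a maximal set of variants whose −log10 *p* values
and effect sizes agree pairwise within tolerances and whose effect signs
agree. Pairwise agreement over a set equals range ≤ tolerance, so the
largest set is found exactly by anchoring a −log10 *p* window at each
observed value and sweeping a two-pointer window over sorted effect sizes;
blocks are extracted greedily largest-first, making the output disjoint, and
reported sorted by span descending. Tolerances are required inputs with no
defaults: membership is meaningless without a stated similarity scale.
Span is the end − start base difference (not inclusive length), which
matches the published arithmetic and is invariant under genome-build
coordinate shifts.

## Synthetic data

The generators define the test conditions:

- **Alignments**: mismatching species draw uniformly from the 19
  non-reference residues — the conservation score depends only on
  match/mismatch, so the substitution model is irrelevant. Match counts are
  rounded to the nearest achievable fraction, so realized conservation is
  within 1/n of target. Corrupted species carry exactly one contiguous gap.
- **Trajectories**: block-correlated Gaussian displacements about fixed mean
  positions on a jittered 10 Å grid. No physics is simulated; DCC is a pure
  second-moment statistic, so this exercises it fully. A block with target ρ
  shares a latent 3-D Gaussian factor with weight √|ρ|; for ρ < 0 the block
  leader moves against the rest (all-pairs negative correlation is
  infeasible for blocks larger than two). What this does **not** emulate:
  autocorrelated dynamics, anisotropic fluctuations, or actual global
  rigid-body drift — passing tests show the estimator is correct, not that
  any particular protein behaves this way.
- **Variant tables**: positions sampled without replacement; per-population
  allele frequencies log-normal (median 1e-4, one decade SD, clipped at
  0.5); hemizygote/homozygote counts Poisson with configurable occupancy
  rates. Tool scores are drawn on the normalized scale around 0.85 for
  ground-truth pathogenic variants, shifted down by `separation_sd` pooled
  SDs (default 3, SD 0.08) for benign-like VUS, then mapped back through the
  inverse normalization to raw tool ranges.
- **eQTL tables**: one embedded block with tiny jitter (SD 0.01 in −log10
  *p*, 0.002 in effect size) spanning an exact base count; background
  variants are spread on a coarse grid (0.8 apart in −log10 *p*, alternating
  effect signs, kept ≥1 away from the block) so no reasonable tolerance can
  group them.

All generators are deterministic given a seed; identical seeds produce
byte-identical files.

## Problem sizes and numerical choices

The end-to-end pipeline default is a 200-position reference, 100 species,
2,000 trajectory frames of 40 residues, and a 12-member block among 50
background eQTLs — sizes at which every statistic is well-resolved while a
full run takes about a second. Recovery tests use up to 10,000 frames and
500 variants per class. Quantiles use linear interpolation; DCC values are
clipped to [−1, 1] against floating-point overshoot; cluster ids are
renumbered by first appearance for determinism; shortlist ties break by
position. At 100 variants per class the 5th-percentile threshold estimate
is itself noisy, so the small-scale sensitivity check uses a looser bound
(0.8) than the full-scale one (0.9).

## Known limitations

- Absolute total scores depend on the normalization maps; only ranks are
  comparable across scoring conventions.
- The block detector's greedy largest-first extraction is exact for the
  largest block but can split remaining records differently from a global
  optimum when groups overlap in tolerance space.
- Negative-correlation trajectory blocks larger than two residues realize
  leader-vs-rest structure, not all-pairs negative correlation.
- Real ortholog alignments, population AF spectra, and MD trajectories are
  richer than the generators; conclusions about real data require real
  inputs through the same interfaces (aligned FASTA, TSV tables, multi-model
  PDB).
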