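# Methods

This note documents the models and procedures implemented in `loopkit`, the
parameters that matter, the design choices made where the design was
genuinely open, what the synthetic-data generators do and do not emulate,
and the package's known limitations. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Coordinates and overlap semantics

All intervals are 0-based half-open (`[start, end)`, BED convention).
1-based inputs — SNP positions in association tables — are shifted on parse
and stored as width-1 intervals `[pos-1, pos)`. Overlap means at least one
shared base pair; "slack" expands the query interval on both sides before
testing. Loops are canonicalized on construction (upstream anchor first) and
restricted to one chromosome; inter-chromosomal BEDPE records are counted
and skipped at parse rather than erroring, since cis-only loop callers can
still be fed trans artefacts. TSSs are width-1: the first base of the gene
body on the plus strand, the last base (`[end-1, end)`) on the minus strand.

The interval engine (`intersect_with_slack`, `pair_feature_overlap`,
`pair_pair_overlap`, `exclude_blacklisted`) is the single overlap path used
by every stage; the test suite holds it to exact agreement with an O(n·m)
brute-force scan on randomized fixtures, so the downstream statistics
inherit bedtools-equivalent semantics (`pairtobed` = per-anchor feature
hits; `pairtopair` = pair members on opposing anchors, both orientations).

## QC scoring

Each metric is mapped to [0, 10] by affine interpolation through the points
(min, 0), (t₁, 6), (t₂, 8), (upper, 10). The published description scales
values by per-interval slopes only; applied literally that map does not pass
through the stated band boundaries unless min = 0, so the package implements
the interpolation those bands imply — the two agree exactly for metrics with
min = 0, which covers the rate and count metrics in practice. Band edges are
left-closed (a score of exactly 6 is Warning, exactly 8 is Good). The upper
bound is the metric's own maximum for bounded metrics (percentages, NRF,
PBC1) and the cohort upper-outlier fence Q₃ + 1.5·IQR otherwise, resolved
against whatever cohort of raw values is supplied. For "lower is better"
metrics the complement 10 − score is returned, which makes the map
monotonically non-increasing — the complement of the value-side map, not a
re-derivation.

Default thresholds (`DEFAULT_METRIC_SPECS`) follow field-standard QC
guidance (ENCODE library-complexity fences, Hi-C valid-pair expectations)
and ship as an overridable table plus a YAML loader, because appropriate
thresholds depend on depth and protocol. The final flag is Good only when
every stage flag is Good; every other combination takes the worst stage flag
(any Poor → Poor, else Warning). Worst-of is the documented stand-in for
mixed-flag cases; it is conservative and monotone in each stage.

## Stratum-adjusted correlation (SCC)

Both matrices are smoothed with a (2h+1)×(2h+1) uniform mean filter
(`h = 0` disables smoothing); for each diagonal offset d up to
`max_dist_bins`, the Pearson correlation r_d of the two diagonals is taken
where both have nonzero variance (constant strata are skipped and counted),
and the SCC is Σ w_d r_d / Σ w_d with w_d = N_d σ_{a,d} σ_{b,d}. The
smoothing half-width is an input, as in practice it is trained per dataset;
`train_h` provides a diminishing-returns grid search (stop when the SCC gain
drops below 0.01, cap 25) for convenience. Merging requires *every* pairwise
SCC in a replicate group to exceed 0.8 strictly; a singleton group merges
vacuously (flagged by the caller). SCC inherits Pearson's invariance to
positive scaling of either matrix, which the tests assert to 1e-9.

## SNP-to-gene links

GWAS mapping crosses each SNP with *all* TSSs: a (SNP, gene, loop) triple
qualifies when SNP and TSS overlap opposing anchors in either orientation.
eQTL mapping deliberately differs: only the variant's own paired gene
counts, so the (SNP, target-TSS) pair must straddle the loop. This asymmetry
mirrors the two underlying intersection tools (pairtobed vs pairtopair) and
is part of the contract, not an implementation accident.

Distinct SGLs are keyed on (rsid, gene_id, chrom, anchor starts, resolution)
pooled across samples; deduplication is idempotent. Multiplicity summaries
report distinct genes per SNP and SNPs per gene with medians and singleton
fractions. The nearby-gene null links each SNP to every gene whose *body*
overlaps the closed window ±1 Mb around the SNP position; the boundary is
closed on both sides (a gene starting exactly at pos + 1 Mb counts). The
specificity test is a left-sided Mann–Whitney U (`scipy.stats.mannwhitneyu`,
`alternative='less'`, asymptotic method with tie correction) of SGL link
counts against null link counts; both-samples-constant-and-equal input is
degenerate and returns p = 1 with a warning rather than a spurious signal.

## Motif analysis

Conserved anchors: unique anchors pooled across a sample set, kept when they
appear in at least ⌈0.8·n⌉ samples (44/54, 22/27, 9/11 at the documented
set sizes); the non-conserved complement is the background pool. GC matching
assigns pool sequences to 0.5 % GC bins and draws one pool sequence per
foreground sequence from the matching bin — with replacement across draws,
since a bin may hold fewer pool than foreground sequences; an empty bin
falls back to the nearest non-empty bin with a warning. Scanning itself
(FIMO/SEA) and repeat masking are external: the module emits
foreground/background sequence sets and consumes occurrence tables.

Anchor annotation goes through representative peaks: per anchor, the
highest-signal overlapping ChIP-seq peak (ties broken by leftmost start,
then end, for determinism), deduplicated because one peak may represent
several anchors. A loop exhibits unordered pair (a, b) — self-pairs allowed
— when a is on one anchor and b on the opposing one; each loop contributes
at most once per pair. Loop-level counting is used throughout (an anchor in
several loops contributes once per loop).

The block bootstrap redraws, per simulation, every loop's two anchors
uniformly with replacement from the same chromosome's pool of unique
observed anchors, annotations travelling with the anchors, and recounts
pairs; p = (1 + #{simulated count ≥ observed}) / (1 + n_sims). The add-one
(Davison–Hinkley) form keeps finite-simulation p-values valid and nonzero;
the plain fraction is available behind a flag. Anchors are drawn from the
sample's own anchor universe rather than all genomic bins — the shuffle then
preserves per-chromosome loop counts and the per-chromosome annotation
multiset, which is the null of interest (which anchors pair up, not where
anchors sit). "Top-50 motifs" filtering ranks motifs by how often they
appear across the sample's observed pairs and keeps pairs with both members
in the top k (configurable) before Benjamini–Hochberg adjustment of exactly
the retained p-values.

Because the statistic is discrete and all pairs in a sample share the same
loops, single-sample false-positive fractions fluctuate well beyond binomial
error; the calibration checks therefore pool pairs across 12 independently
generated null scenarios, which is also how the acceptance script reports
the null fraction at p ≤ 0.05.

## Networks and communities

Nodes are unique anchors; labels are promoter (any TSS within ±2.5 kb of
the anchor — applied as anchor expansion, equivalent under half-open overlap
to expanding the TSS), else enhancer (peak overlap, no slack), else other.
Edge weight is −log₁₀(q) capped at 20, scaled by /20 into [0, 1]; parallel
loops keep the strongest edge. Graphs are built and partitioned per
chromosome: Louvain (networkx implementation, explicit seed, fixed
node-order initialisation) gives the high-level partition, and a second
Louvain pass inside each community gives subcommunities; the level-1
modularity per chromosome is reported.

Community prioritization does not replicate CRank's likelihood-based
aggregation; a documented surrogate ranks communities by Borda aggregation
of three connectivity properties — internal edge density, conductance
complement, and mean internal edge weight — normalized to [0, 1] per level,
with metrics rounded to 9 decimals so floating-point accumulation cannot
break genuine ties. The ranking method is stamped into each community's
metadata so downstream consumers can tell the surrogate from the original.

## 2D embeddings, Moran's I, APA

Contact transform: t = log₁₀(count); entries with t below the assay floor
(0.1 for HiChIP, 1.0 for Hi-C — HiChIP's sparser normalized counts need the
lower floor) are zeroed; distance d = 1/t for surviving entries, no edge
otherwise. The Kamada–Kawai layout runs on the largest connected component
(dropped bins reported) from a deterministic circular initialisation ordered
by genomic position, making coordinates reproducible without a seed.

Voronoi weights: the tessellation is computed on the layout points plus a
ring of 16 distant guard points at ~2.1× the coordinate span, so every data
cell is a finite polygon; w_ij = 1 when cells share a ridge of positive
length (degenerate zero-length ridges from cocircular layouts are dropped,
giving rook contiguity on grids), then rows are standardized to sum to 1.
Collinear or duplicate point sets are deterministically jittered.

Global Moran's I = (N/S₀)·Σ w_ij z_i z_j / Σ z_i² with z centred and S₀ the
total weight; expectation −1/(N−1). Significance is a one-sided (clustering)
permutation test, 999 permutations by default, add-one p — the sidedness is
a package choice (dispersion is rarely the question for overlaid ChIP
signal). Local I_i = (z_i/m₂)·Σ_j w_ij z_j with m₂ = Σ z²/N, conditional
permutation per bin (the other N−1 values permuted without replacement onto
the bin's neighbours), same sidedness; quadrants HH/HL/LH/LL from the signs
of z_i and its spatial lag. The algebraic identity mean(local I) = global I
under row-standardized weights is asserted to 1e-9.

APA: submatrices of half-width 10 bins centred on each loop's bin pair are
averaged; score = centre pixel over the mean of the corner block 15–30 kb
downstream of the upstream anchor × 15–30 kb upstream of the downstream
anchor (bin offsets ⌊15k/res⌋..⌊30k/res⌋, i.e. +3..+6 rows and −6..−3
columns at 5 kb); ratio = centre over all non-centre pixels. Loops whose
window would leave the matrix are skipped and counted. Both quantities are
invariant to global scaling of the matrix.

## Synthetic data

The default genome is two 10-Mb chromosomes at 5 kb resolution — large
enough for distance strata, loop-span sampling and ±1 Mb windows, small
enough that every stage runs in seconds. Generators are bit-reproducible
under a fixed seed (every generator derives its stream from (seed, salt))
and emit truth records sufficient to verify the downstream answer without
re-deriving it.

- **Loops**: spans from a discrete power law d^(−α) truncated to
  [20 kb, 2 Mb] (α = 1 by default; the truncated-power-law span histogram is
  verified by log-log regression), anchors on the bin grid, q-values from a
  significant/background mixture (70 % significant at mean −log₁₀ q = 6).
- **SGL scenario**: planted triples are built from *disjoint* anchor bins
  allocated by a cursor, so exactly K triples satisfy the opposing-anchor
  rule and none can arise by collision; distractors violate the rule each
  way it can be violated (SNP+TSS in one anchor, SNP or TSS facing an empty
  anchor, SNPs on the chromosome tail), and feature-free background loops
  fill the set on the second chromosome.
- **Motif scenario**: a pool of grid anchors per chromosome with independent
  per-anchor motif presence (frequency 0.25 over 20 motifs), loops drawn
  uniformly with replacement from the pool — i.e. the block bootstrap's own
  sampling model, which is what makes the null calibration check meaningful.
  Planting draws extra loops between anchors carrying the two planted
  motifs, raising that pair's expected count to ~multiplier × independence.
- **Contact windows**: deterministic distance-decay background
  50·(d+1)^(−0.3) with optional lognormal noise, planted loop pixels
  multiplied by the enrichment factor at distances of 60–150 bins (where the
  corner background tracks the centre within a few percent, so APA recovers
  the planted factor); companion signal = unit noise with one contiguous
  +4σ block for Moran tests.
- **Replicates**: A = s·S + (1−s)·N_A with a common structured field S and
  independent structured noise fields, so SCC rises monotonically in s.

What the generators do **not** emulate: genomic sequence composition (GC
matching is tested on synthetic sequence strings), ICE normalization
artefacts, copy-number and mappability biases, realistic anchor reuse
topology across samples, or LD structure among SNPs. Passing tests
demonstrate correctness of the computations and calibration of the
statistics under their own modelling assumptions, not robustness to every
artefact of real HiChIP data.

## Problem sizes and numerical choices

The test and acceptance runs use scaled problem sizes chosen to exercise the
asymptotic behaviour of each statistic while keeping the whole suite in the
minutes range: 400×400 matrices for the SCC null, 300 loops × 20 motifs ×
1000–2000 bootstrap simulations (pooled over 12 scenarios for calibration),
100-bin contact windows for Moran calibration (500 null signals × 999
permutations), 50-node planted partitions over 20 seeds. The bootstrap
default of 100,000 simulations remains the production setting
(`--n-sims`).

Ties and degeneracies are handled deterministically throughout: peak-signal
ties break to the leftmost peak, Borda ranks share means under ties,
Louvain takes an explicit seed, Kamada–Kawai a fixed initialisation, and
Voronoi degeneracy a seeded jitter. Empirical p-values use add-one
estimators; Mann–Whitney uses the asymptotic normal approximation with tie
correction (exact enumeration is unnecessary at the n ≥ 50 sizes used and
ill-defined under heavy ties).

## Limitations

- Mixed-stage flag combinations beyond "all Good" use worst-of; deployments
  with their own flag tables can override metric specs but not (yet) the
  combination rule.
- Community ranking is a connectivity surrogate, not CRank; rankings agree
  on clear-cut cases (dense vs sparse) but are not expected to reproduce
  CRank scores numerically.
- The 1D motif enrichment statistic itself (SEA) and PWM scanning (FIMO) are
  consumed, not reimplemented; the package prepares inputs and analyses
  outputs.
- `.hic`/`.cool`/BAM binary formats are out of scope; contact matrices
  arrive as triplet TSV, loops as BEDPE, peaks as narrowPeak.
- Local-Moran p-values are per-bin conditional-permutation values without
  multiplicity adjustment, matching common exploratory practice.
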