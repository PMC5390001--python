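# Methods

This note records the statistical procedures, the tunable parameters and
their defaults, the numerical choices, and what the synthetic-data
generators do and do not emulate.

## Tag quantification

Raw reads are trimmed to their first 17 bases and the NlaIII recognition
sequence CATG is prepended, giving 21-bp tags (reads shorter than 17 bases
are discarded into a QC tally).  Samples may be filtered by a minimum raw
read count before quantification (`min_reads`; production tag-seq studies
use 10⁷, synthetic runs use 0).

Tags are placed on the reference by a deterministic **best-stratum unique
matcher**: the exact stratum is searched first and, only if it is empty,
the 1-mismatch stratum; the tag is used iff the winning stratum contains
exactly one placement, otherwise it is tallied as *ambiguous* (>1) or
*unplaced* (0).  This emulates a short-read aligner run with
best/strata/unique options as a fully specified contract.  N bases never
match (an N consumes the mismatch allowance).  Reverse-strand placements
are indexed through the reverse complement of each reference window, so
one lookup covers both strands.  The 1-mismatch stratum is searched over
the whole 21-mer; seed-restricted mismatch semantics of specific aligners
are deliberately not reproduced.

A placement is counted for a gene iff its 21-bp interval lies entirely
within one exon of that gene and its strand matches the gene's strand;
counts are summed over all positions within a gene.  A placement inside
sense exons of several genes credits each of them by default
(`multi_gene="count_all"`); `"discard"` drops such placements instead.
Internal coordinates are 0-based half-open; GFF3 input is converted from
1-based inclusive on read.

## Normalization

TMM (trimmed mean of M-values): the reference sample is the one whose
75th-percentile count fraction is closest to the mean of those fractions.
Per sample, log2 ratios M and average abundances A are computed over genes
expressed in both the sample and the reference, doubly trimmed (30 % of M
on each side, 5 % of A), and the factor is 2^(precision-weighted mean of
the retained M), with inverse asymptotic variances of M as weights.
Factors are rescaled to geometric mean 1.  Exact invariance to multiplying
a column by a constant holds when M is constant (pure depth scaling); with
heterogeneous M the precision weights depend on depth, so invariance is
approximate — the tests check both regimes.

## The negative-binomial factorial model

Each gene is fitted by iteratively reweighted least squares under a log
link with offsets `log(library_size × TMM factor)`; the IRLS is vectorized
across genes because all genes share one design matrix.  Convergence is
declared when the deviance changes by less than 10⁻⁸ (relative), with a
cap of 100 iterations; non-converged genes are flagged and their p-values
set missing.  The linear predictor is clipped to [−15, 30] to keep the
weighted least-squares system well conditioned when a whole group is
near zero.

Two models are fitted. Model A is additive (intercept + genotype +
treatment); each main effect is tested by a likelihood-ratio test dropping
its column.  Whether the original analysis's main-effect model carried an
intercept is not documented; the additive parameterization is this
package's choice and is likelihood-equivalent to a no-intercept group-mean
coding.  Model B is the full factorial with intercept; the product column
tests the interaction.  Fold changes are reported in log2 units
(coefficient / ln 2).  All-zero genes are excluded from fitting and
reported separately.

### Dispersion estimation

For a candidate dispersion φ, the Cox–Reid adjusted profile log-likelihood
of gene *g* is `APL_g(φ) = ll_g(β̂(φ), φ) − ½ log det(X'WX)`, evaluated at
the IRLS fit.  On a log-spaced grid (19 points, 10⁻⁴ to 5):

* **common** φ maximizes `Σ_g APL_g` with golden-section refinement of the
  bracketing grid interval;
* **trended** φ: genes are sorted into equal-size average-log-CPM bins
  (G/100 bins, capped at 20); each gene's *local APL curve* is the
  abundance-interpolated mean APL of its two neighbouring bins, and the
  trended dispersion is that curve's maximizer (quadratic interpolation
  around the grid argmax);
* **tagwise** φ_g maximizes `APL_g + prior_n · APL_local,g`.

The published description of tag-wise shrinkage ("a linear combination of
the trended and tag-wise dispersion" with a *prior n* weight) is circular
and version-specific; the weighted-APL objective above is this package's
concrete contract.  It has the right limits by construction — `prior_n →
∞` returns exactly the trended value (both are maximizers of the same
local curve), `prior_n = 0` gives the unshrunk tagwise estimate — and
recovers planted dispersions in simulation (common φ̂ ≈ 0.0995 at true
φ = 0.1, n = 6/group, 2000 genes).  `prior_n` defaults to 10.  Dispersion
is estimated once, on the full factorial design, and reused for both
models.

### Effect lists

Genes enter a list at nominal p ≤ α (α = 0.005, inclusive).  Genes on
excluded chromosomes (default "8" — a strain-background artifact region in
the motivating design) are removed from the genotype list only; genes
passing the interaction threshold are removed from both main-effect lists
because their main-effect estimates are not interpretable as pure effects.
Benjamini–Hochberg FDR is written alongside for users but never used in
list assembly.

## Pattern clustering

TMM-scaled log2 CPM (prior count 0.5) is averaged per experimental group
in the fixed order WT-Sham, WT-CSD, MUT-Sham, MUT-CSD; each gene's
4-vector is standardized to mean 0 and unit sample variance (ddof 1;
constant rows are dropped with a warning).  K-means uses correlation
distance `1 − r` — equivalent to cosine distance after centering — with
centroids re-standardized after every update so the distance stays well
defined.  Empty clusters are re-seeded from the point farthest from its
centroid.  The best of `restarts` k-means++ initializations (default 50,
seeded, deterministic) by total within-cluster distance is kept, and
labels are renumbered in decreasing cluster size.  k defaults to 4; it is
not chosen automatically.  Whether to average on the log or raw normalized
scale is not documented upstream; log-CPM is this package's default.

## Over-representation statistics

The 2×2 overlap table of a study list (n genes) against an annotation set
(K genes inside the universe of N) is tested exactly: two-sided p sums the
hypergeometric probabilities of all overlap values no more probable than
the observed one; one-sided p is the corresponding tail.  For universes up
to N = 2000 the enumeration uses exact integer arithmetic (so ties are
decided exactly); beyond that, a log-pmf enumeration with a 10⁻⁹ relative
tie tolerance.  The odds ratio defaults to the unconditional cross-product
`ad/bc`, with Haldane–Anscombe +0.5 on all cells iff any cell is zero
(reported in a separate field); a conditional-MLE estimator is available.
The two-sided default reflects that both enrichment and depletion are of
interest; the universe defaults to all genes detected in the count matrix
and is configurable, since the appropriate universe is study-specific.

Term screening retains a term iff overlap ≥ 5 **and** one-sided p < 0.05.
Cell-type marker lists are sharpened by removing any gene occurring in two
or more lists from all of them (within-list duplicates merely collapse).

## Promoter-motif over-representation

Promoters are the 1000 bp immediately 5′ of a gene's first exon (reverse
complemented for minus-strand genes; clipped at reference edges with a
flag).  A background of 3000 promoters is drawn without replacement from a
user-supplied pool so that its GC histogram (bin width 0.05) is
proportional to the study set's, with largest-remainder rounding; a bin
the pool cannot fill raises an error naming the bin.

Motifs are 4×L position frequency matrices, normalized with pseudocount
0.01; a window scores the sum of log2 odds against a background base
distribution (default uniform), and a promoter is a hit if any window on
either strand reaches 80 % of the maximal achievable score (N-containing
windows never hit).  Per motif, hit frequencies in study and background
are compared; motifs below 10 % background frequency are dropped; p is a
one-sided Fisher test on the hit/no-hit table (the upstream tool's test is
undocumented, so this is a recorded package choice; a two-proportion
z-test is available for comparison).  Threshold fraction, pseudocount and
bin width are configuration keys.

## Spatial co-expression

Voxels with **more than** 75 % missing entries are removed (a voxel at
exactly 75 % is kept); the same rule can optionally be applied to probe
rows.  Cosine similarity between probes is computed pairwise-complete over
jointly observed voxels; pairs with fewer than `min_overlap` (default 10)
shared voxels, or a zero-norm vector on the overlap, are undefined and
excluded downstream.  The gene-gene network entry is the mean over all
defined probe pairs spanning the two genes.  The test statistic for a gene
set is the mean similarity over its unordered within-set pairs; the null
is `B` same-size sets drawn uniformly without replacement from the network
universe, and `p = (1 + exceedances)/(B + 1)` — never zero, deterministic
given the seed.  `B` defaults to 10 000 (1000 in the pipeline driver);
the default tail is "lower" (the motivating question is whether a gene set
is *less* spatially co-expressed than random sets), with "upper" and
"two-sided" available.  Pairwise-complete handling of missing data is a
package decision; upstream descriptions do not state one.

## Synthetic data

The count generator draws NB counts under the exact model the pipeline
fits: `mu = base_mean × (L_k / mean L) × 2^(x'beta)`, with log-uniform
library sizes (default 5×10⁴–10⁵ — desk-scale, far below production
depth, chosen for runtime), log-uniform base means (20–500), a fixed or
log-normal-spread dispersion (default 0.1), and disjoint planted effect
genes.  Interaction genes are planted with the rising shape (treatment
effect = half the interaction effect, both positive), i.e. up after
treatment and more strongly in the mutant.  Main effects get random signs.
Chromosome labels are drawn uniformly from 1–19.

The read generator emits 17-bp reads 3′ of the 3′-most CATG per transcript
(NlaIII/MmeI chemistry; "all sites" available since genome-wide placement
would see every site), with optional per-base substitution errors.
Synthetic transcripts guarantee a usable anchor and, by default, reference-
wide tag uniqueness so that error-free round trips are exact.

The atlas generator gives module genes one shared smooth profile
(random Fourier series, exponentiated to keep values nonnegative) plus
independent noise, background genes independent profiles, MCAR missing
entries, and one or two probes per gene.  The promoter generator draws
i.i.d. sequences with per-promoter GC and plants a motif consensus in a
configured fraction of study (and optionally pool) promoters.

What the generators do **not** emulate: the expression-level distribution
of real tag-seq libraries (undocumented; defaults chosen for testability),
read quality scores, genome-scale reference size, anatomical voxel
geometry, and promoter sequence composition beyond GC content.  Passing
tests therefore demonstrate correctness of the statistical machinery under
its stated model, not robustness to real-data violations of it.

## Problem sizes and verified behaviour

The test suite and the acceptance script run at desk scale: 2000 genes ×
24 samples for type-I error (empirical fraction of interaction p ≤ 0.005
on null data ≈ 0.005–0.007) and power (planted log2FC 1.5 at base mean
100, φ = 0.1: ≈ 78–85 % at p ≤ 0.005, |bias| < 0.1); 400 genes for
clustering recovery (ARI 1.0 at noise SD 0.3); exhaustive exact-test
verification over all 2×2 tables with N ≤ 60; 95 study vs 3000 GC-matched
background promoters for motif power; 200-gene atlases with a 20-gene
planted module for the spatial test (p ≈ 10⁻³ at B = 1000).  All of these
are recomputed, not stored.

## Known limitations

* The best-stratum matcher is a contract, not a re-implementation of any
  specific aligner; seed-region mismatch rules differ.
* Tagwise shrinkage follows this package's weighted-APL definition; exact
  numerical agreement with any particular release of other NB-GLM
  packages is not claimed.
* Quasi-likelihood tests, robust dispersion variants and exact two-group
  tests are out of scope.
* The spatial module consumes a prepared probes × voxels matrix; atlas
  acquisition, hemisphere selection and 3-D visualization are upstream of
  this package.
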