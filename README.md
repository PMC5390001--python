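# deeptag

Factorial analysis of tag-based expression profiling (NlaIII-anchored
tag-seq / SAGE-style) experiments, built for 2×2 designs — genotype
(WT vs mutant) crossed with treatment (sham vs stimulus) — together with
the downstream analyses such a study needs: expression-pattern clustering,
gene-set and promoter-motif over-representation, and a voxel-atlas spatial
co-expression permutation test.  Every stage runs end-to-end on synthetic
data with ground truth, so the whole pipeline is testable at desk scale.

## Who this is for

Groups quantifying gene expression with short anchored tags (17-bp cDNA
fragments 3′ of the NlaIII site CATG) rather than full-length RNA-seq, and
anyone who wants a transparent, reproducible reference implementation of
the classic tag-seq analysis chain: unique-placement quantification → TMM
normalization → negative-binomial GLM with interaction testing → pattern
clustering → enrichment statistics.

## The model

Counts `y_gk` for gene *g* in sample *k* follow a negative binomial with
log link,

    y_gk ~ NB(mu_gk, phi_g),    Var = mu + phi mu^2
    log mu_gk = offset_k + x_k' beta_g,
    offset_k = log(N_k * TMM_k)

where `x_k` encodes the factorial design.  Two parameterizations are
fitted: an additive model (intercept + genotype + treatment) whose
coefficients are dropped one at a time to test each main effect, and a full
factorial model with intercept whose product term tests the interaction
(does the treatment response differ by genotype?).  Each test is a
likelihood-ratio chi-square on nested designs.

Dispersions `phi_g` are estimated by maximizing the Cox–Reid adjusted
profile likelihood (APL): a common value across genes, a trend over
average-abundance bins, and tagwise values that maximize
`APL_g + prior_n * APL_local,g` — empirical-Bayes shrinkage towards the
local trend with weight `prior_n` (default 10).

Gene lists are assembled at nominal p ≤ 0.005 (configurable), genes on an
excluded chromosome (default "8", for strain-background artifacts) are
removed from the genotype list, and genes passing the interaction
threshold are removed from both main-effect lists.  Interaction genes are
then clustered (k-means, k = 4, correlation distance) on their
standardized four-group mean profiles.

Downstream statistics: Fisher exact tests of gene-set overlaps (exact
integer enumeration, two-sided by default, cross-product and conditional
odds-ratio estimators); promoter-motif over-representation by PWM log-odds
scanning against a GC-matched random-promoter background (3000 promoters,
≥10 % background hit frequency filter); and a spatial co-expression test
that reduces a probes × voxels atlas to a gene–gene mean-cosine network
(voxels > 75 % missing dropped, pairwise-complete cosine) and compares a
gene set's mean within-set similarity to a permutation null of random
same-size sets, `p = (1 + exceedances) / (B + 1)`.

## Worked example

```python
from deeptag import synth
from deeptag.model import TagCountModel

cfg = synth.SimConfig(n_genes=2000, frac_genotype=0.02, frac_treatment=0.03,
                      frac_interaction=0.05, dispersion=0.1, rng_seed=7)
counts, truth = synth.simulate_counts(cfg)
results = TagCountModel(counts).fit(alpha=0.005, prior_n=10)
print(results.summary())
```

```
Factorial NB tag-count analysis
===============================================
genes fitted:          2000
all-zero genes:        0
samples:               24
common dispersion:     0.09948
tagwise dispersion:    median 0.1003 (prior n = 10)
significance level:    p <= 0.005 (nominal)
genotype effect:       128 genes at p <= 0.005
csd effect:            175 genes at p <= 0.005
interaction effect:    86 genes at p <= 0.005
after list assembly (chromosome 8 and interaction-overlap removal):
  genotype list:       59
  csd list:            93
  interaction list:    86
```

The true dispersion (0.1) is recovered as 0.0995; the planted effects
drive the three lists.  Clustering the interaction genes:

```python
patterns, assignment = results.cluster_interaction_patterns(k=4, seed=0)
assignment.labels.value_counts().sort_index()
# cluster sizes: {1: 41, 2: 40, 3: 3, 4: 2}
assignment.centroids.loc[1].round(3)
# WT.SHAM -0.564, WT.CSD 0.025, MUT.SHAM -0.857, MUT.CSD 1.396
```

The dominant clusters carry the planted rising pattern — up after
treatment, strongest in the treated mutant group.

The same pipeline runs from the shell:

```bash
deeptag run-all --outdir my_run --seed 7
deeptag de --counts counts.tsv --samples samples.tsv --alpha 0.005 --prior-n 10
```

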