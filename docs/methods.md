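# Methods

## NE score

A sample's neuroendocrine score is half the difference between its Pearson
correlation with the NE centroid and with the non-NE centroid of a 50-gene
signature, computed on log2-scale expression. Both correlations lie in
[−1, 1], so the score lies in [−1, +1]; a positive score calls NE, a
negative one non-NE, and exactly 0 is reported as `indeterminate` rather
than silently binned. Because Pearson correlation is invariant to affine
per-sample transforms with positive slope, per-sample z-scoring (or any
rescaling) leaves the score unchanged — a property the suite asserts.

Decisions where the procedure itself leaves room:

- **Scale.** Scoring assumes log2 input; matrices carry a `scale` tag and a
  linear-scale matrix is log2(x+1)-transformed with a logged warning before
  scoring. The default log2 offset is 1.0 (configurable).
- **Missing genes.** Correlations run over the intersection of profile and
  signature genes; the default `min_genes` is 40 of 50 (80%), configurable,
  and `n_genes_used` is always reported. NaNs drop a gene pairwise rather
  than failing the sample.
- **Failures.** Samples that cannot be scored (insufficient overlap,
  zero-variance restricted profile) are reported per sample and the batch
  run continues; a batch with no scoreable sample is an error.
- The signature file is authoritative: centroids are consumed as given and
  never re-derived from cell-line cohorts.

## Pre-ranked GSEA

Genes are ranked by the Pearson correlation of their expression with the
NE score (constant genes excluded and counted; metric ties broken by
ascending gene id so rankings are reproducible). A set's enrichment score
is the signed extremum of the weighted Kolmogorov–Smirnov running sum:
hits step up by `|r|^p` normalized over hits (default weight exponent
p = 1), misses step down by `1/(N − N_hit)`. When the maximum and minimum
deviations tie in magnitude the positive sign wins; the comparison carries
a 1e-12 tolerance because cumulative-sum rounding can otherwise flip a
knife-edge case. The leading edge collects hits at or before the maximum
(at or after the minimum for negative ES).

The null is **gene-label permutation**: size-matched random gene sets
drawn from the ranking with one explicit seeded generator, cached per set
size. P-values use the `(1 + n_more_extreme_same_sign)/(1 + n_same_sign)`
estimator, so they are never 0 and floor at `1/(n_perm+1)`; NES divides
the observed ES by the mean absolute same-sign null ES. If a set draws no
same-sign nulls (unreachable at n_perm ≥ 100), p = 1 and NES = 0 with a
diagnostic. BH adjustment runs within one collection at a time, mirroring
per-library reporting. Sample-label permutation is not implemented: the
cohorts it would apply to are not shipped, and the gene-label scheme is the
acceptance-bearing mode for synthetic data.

Null ES values are computed by a closed form over sorted hit positions,
vectorized across permutations (the extrema of the running sum can only
occur at a hit or just before one); a unit test pins this fast path to the
reference walker on explicit permuted sets.

## ssGSEA

Per sample, genes are ranked by expression (average ranks on ties; the top
gene has rank N) and the score sums, over all ranking positions, the
weighted ECDF of in-set genes (weights `rank^alpha`, normalized within the
set) minus the ECDF of out-of-set genes. Defaults are alpha = 0.25 and
division of the final matrix by its global range, matching the common
implementation's conventions; both are recorded in the output object.
With alpha = 0 the statistic reduces to the unweighted ECDF difference,
which the suite checks against a closed-form small case.

## Association statistics

Correlation screens report Pearson r with exact two-sided p-values from
the t transform with n − 2 df, pairwise-complete per gene with n recorded.
The two-group comparison defaults to Welch's unequal-variance t-test
(pooled-variance mode behind a flag). The sign-proportion test builds the
2×2 table (in-set vs background) × (negative r vs nonnegative r) and
applies Pearson's chi-squared without continuity correction (Yates behind
a flag); by default a gene counts as "negative" by the sign of r alone,
with a `significant_only` mode restricting to padj-filtered genes.
Benjamini–Hochberg adjustment uses the standard step-up procedure and the
significance convention is p ≤ 0.05. Sample standard deviations use the
n − 1 convention throughout.

## Quantification arithmetic

- H-score: `3·%strong + 2·%moderate + 1·%weak`, valid on the simplex where
  each percentage is in [0, 100] and their sum is ≤ 100 (the unstained
  remainder is implicit), giving the 0–300 range.
- Cell density: count / area (mm²), additive over pooled regions.
- qPCR: the default reading of "median of triplicates" takes the median Ct
  per gene first (target and control separately), then
  `2^(Ct_control − Ct_target)`, then divides by the median of the parental
  samples' normalized values. The alternative reading — median of
  per-replicate ΔCt — is available as `mode="delta_ct_median"`.

## Synthetic data

The generator emulates the statistical skeleton the analysis assumes, not
a full transcriptome model. For sample i with latent state sᵢ drawn
uniform on [−1, 1] (or from a two-group mixture):

- signature genes: `(1+sᵢ)/2 · NE_centroid + (1−sᵢ)/2 · nonNE_centroid`
  plus N(0, σ) noise, with centroids rejection-sampled until their Pearson
  correlation is ≤ 0 (an exact −1 reflection mode exists for exercising
  the score's extremes);
- immune genes: per-gene baseline + (−2)·sᵢ + noise;
- REST targets: baseline + (+2)·sᵢ + noise;
- background: baseline + noise.

Defaults are 200 samples, 50/100/100/750 genes per block, σ = 1, baselines
N(6, 1.5²) clipped positive (log2 units) so quantile normalization has
heterogeneity to act on. All randomness flows through one explicit seeded
generator; identical configs are bitwise-reproducible. Planted sets
(IMMUNE_PROGRAM, REST_TARGETS, size-matched RANDOM_K from the background)
give GSEA, ssGSEA and the sign-proportion test ground truth to recover.

The convex-blend construction makes the noise-free NE score strictly
increasing in the latent state but not linear in it, so at vanishing noise
the score's rank order matches the state exactly (Spearman 1) while the
Pearson correlation plateaus around 0.99; the suite asserts the rank-order
identity and r ≥ 0.99 at σ = 10⁻⁶, and r ≥ 0.9 at default noise. What the
generator deliberately omits — count-level (negative binomial) noise,
dropout, batch effects, correlated gene-gene structure beyond the planted
programs — means passing tests demonstrate correctness of the procedures,
not robustness to every artifact of real cohorts.

## Problem sizes and numerics

The default validation dataset is 200 samples × 1,000 genes; permutation
GSEA uses 500–2,000 permutations in tests and analyses, and the p-value
calibration check uses 150 null sets of 20 genes on a 2,000-gene ranking —
sizes at which every statistic is stable and the whole suite runs in
seconds. Degenerate inputs follow one policy everywhere: constant vectors
are either excluded with a count (ranking, correlation screens) or mapped
to a defined value with a warning (z-score, min–max scaling), and
correlations against constant vectors raise rather than return NaN.
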