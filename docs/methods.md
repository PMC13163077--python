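# Methods

## Differential expression model

Each analyzed brain region is modeled separately. For gene *g* and sample
*s*, counts are negative binomial with mean `mu_gs` and dispersion `phi_g`
(variance `mu + phi mu^2`), and

```
log mu_gs = offset_s + x_s' beta_g
```

where `x_s` indexes the four condition × side groups (a means
parameterization; the factorial coding with reference levels condition =
Sham/control and side = Right is available as a derived view). Left and
right hemisphere samples from the same animal are treated as independent
observations; subject identity is carried as a label only. Offsets are
`log(library_size × TMM factor)`.

Every reported contrast is a 1-df linear combination `c'beta` of the group
means: condition main effect (average over sides), side main effect,
condition × side interaction, and condition within each hemisphere. Signs
follow the "case vs control" and "Left vs Right" orders, so positive
condition log2FC means up in the case group.

### Fitting and dispersion

Coefficients are fitted by iteratively reweighted least squares, vectorized
across genes, with deviance-based convergence (relative change < 1e−8, at
most 50 iterations, step-halving on deviance increase; non-converged genes
are flagged, not dropped). Per-gene dispersion maximizes the Cox–Reid
adjusted profile likelihood `loglik − ½ log det(X'WX)` on a 12-point log
grid over [1e−4, 5] with quadratic interpolation at the optimum. Raw
dispersions are shrunk toward an abundance trend — the mean dispersion in 10
equal-occupancy bins of mean log2 count, linearly interpolated — with prior
weight equivalent to 10 residual df:

```
phi_shrunk = (d · phi_hat + d0 · trend) / (d + d0),   d = residual df, d0 = 10
```

### Testing

Each contrast is tested with a quasi-likelihood F statistic: the deviance
(likelihood-ratio) statistic for the 1-df null `c'beta = 0` — obtained by
refitting on the design restricted to the null space of `c` — divided by a
gene-wise quasi-dispersion. The quasi-dispersion is residual deviance /
residual df, shrunk toward its own abundance trend with prior df 10; the
denominator df of the F reference distribution is residual df + prior df.
The deviance form was preferred over the squared Wald statistic because it
is better calibrated at small per-cell sample sizes (n = 6); the contract of
this module is calibration and recovery on synthetic truth, not numerical
agreement with any particular reference implementation, whose internal trend
fitting is more elaborate.

The signed t-value of a 1-df contrast is `sign(log2FC) · sqrt(F)`; with
denominator df ≥ 20 the conventional per-gene line |t| > 2 agrees closely
with p < 0.05. DEGs are defined by nominal p < 0.05 throughout; BH FDR is
computed (standard step-up with cumulative minima from the largest p) and
reported but never used for gating. Interaction follow-up recomputes BH
within the restricted gene list.

Degenerate inputs: a gene with all counts equal yields zero effect estimates
and p = 1; fitted means are floored at 1e−8 and coefficients clipped to
±40 on the natural-log scale so empty groups cannot produce non-finite
statistics.

### Expression filter, normalization, PCA

Genes are kept iff they have ≥ 1 count in ≥ 40% of the region's samples
(threshold ceil'd; the boundary case "exactly 40%" is kept). TMM factors are
computed against the reference sample whose 75th-percentile of
library-size-scaled counts is closest to the mean of those percentiles;
log2 ratios (M) and average abundances (A) over genes nonzero in both
samples are double-trimmed by rank (30% on M, 5% on A two-sided), averaged
with inverse delta-method-variance weights, and the factors rescaled to
geometric mean 1. PCA QC runs on gene-centered log2(CPM + 0.5) with
TMM-effective library sizes, via SVD.

## Over-representation analysis

All enrichment tests share one kernel: the upper-tail hypergeometric
probability `P(X ≥ k)` with `X ~ Hypergeom(N, K, n)`. For functional ORA the
universe is the region's detected (filter-passing) genes intersected with
the annotation, term sizes outside [5, 500] after intersection are skipped
(conventional hygiene; not prescribed by any input), and BH adjustment runs
across tested terms. Up/down membership of overlapping genes is recorded as
annotation. The inter-region DEG overlap test uses the genes detected in
both regions as background and ignores direction.

## Cell-type analysis

Markers are derived from a cluster-labeled reference: counts are
depth-normalized per cell (counts per 10,000 — the target is configurable
and cancels in the share), averaged per cell type, and each gene's
specificity is its largest type share `s_g = max_c m_gc / sum_c m_gc`. A
gene is assigned to its argmax type iff `s_g ≥ 0.6` and its mean there is
positive; ties leave the gene unassigned. Because 0.6 > 0.5 a gene belongs
to at most one type. The 0.6 "expression/enrichment" cutoff is interpreted
as this share-of-expression statistic; that is one defensible reading of an
under-specified filter and is therefore configurable.

Cell-type ORA tests up- and down-regulated DEGs separately per type, with
Bonferroni control across the types actually tested (13 types →
p < 0.05/13 ≈ 0.00385, −log10 ≈ 2.41). The distribution-shift test takes all
markers of a type that have condition-contrast results (only 1-df condition
contrasts are accepted, since multi-df contrasts have no signed t), and runs
a two-sided one-sample t-test of their mean signed-t against zero, Bonferroni
corrected across tested types; a type needs ≥ 3 scored markers, and a
zero-variance marker set falls back to an exact sign test. The types
submitted to the shift test default to those over-represented in either
direction.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, with
defaults echoing the study design it was built around: 2 regions × 2
conditions × 2 sides × 6 subjects, 2,000 genes, 13 reference cell types with
40 markers each.

- **Bulk counts**: NB with gene-shared dispersion φ = 0.1 (per-gene
  log-normal variation optional), gene baselines log-normal (sdlog 1.0)
  around 50 expected counts, library-size factors log-normal with CV 0.3.
  These magnitudes are conventional for 3'-tag bulk profiling of brain
  tissue at desk scale; no empirical dispersion estimates were available to
  copy, so they are stated assumptions.
- **Planted effects**: genes of configured cell types receive ±1 log2FC
  under the case condition in configured regions (defaults: an
  oligodendrocyte-like type down in both regions, a glutamatergic-like type
  up in one); a configurable number of additional genes receive
  opposite-signed per-side condition effects (±1 log2FC), which is an
  interaction phenotype, not a side main effect. Ground truth records every
  planted per-side log2FC.
- **Reference**: markers are expressed `marker_fold` times higher in their
  own type. The default fold is 50, giving an expected specificity share of
  50/(50+12) ≈ 0.81 with 13 types — comfortably above the 0.6 filter, which
  is what "strong canonical marker" means here. (A 20× fold with 13 types
  would sit at 0.625, within noise of the filter; with 3 types, 20× gives
  0.91 and is used in the small recovery experiments.)

What the simulator does **not** model: per-subject random effects (matching
the analysis assumption of independent hemispheres), batch effects, ambient
RNA or droplet artifacts, transcript-level structure, and region-specific
baseline expression. Passing tests therefore demonstrate correctness of the
statistical machinery under its own assumptions, not robustness to the
unmodeled features of real tissue data.

## Problem sizes and calibration checks

The test suite and the acceptance script validate, at sizes chosen to run in
seconds per fit: type-I error of the condition contrast within
[0.035, 0.065] at nominal 0.05 on null simulations (2,000 genes, 24
samples); ≥ 80% sign-correct DEG recovery of planted |log2FC| = 1 main
effects at n = 6/group; ≥ 80% opposite-significant classification of planted
interaction genes at the same stated conditions with all genes at the
baseline mean (the abundance spread otherwise mixes low-count genes into
that power statement); exact agreement of the hypergeometric kernel with
combinatorial enumeration for N ≤ 30; TMM agreement to 1e−6 with an
independent naive implementation of the published formula; and full-pipeline
recovery of the planted cell-type structure in ≥ 90% of 20 seeds.

## Known limitations

- The quasi-likelihood moderation (10-bin trend, fixed prior df 10) is
  deliberately simple; it does not estimate the prior df empirically.
- The denominator df of the F-test (residual + prior df) is a documented
  package choice; other moderated-NB implementations derive it differently.
- Exact-string gene identifiers only; no symbol mapping.
- The marker-specificity reading of the 0.6 filter is one of several
  possible definitions (expression fraction of cells and fold-enrichment
  quantiles being alternatives).
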