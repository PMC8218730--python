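# Methods

This note documents the statistical models, the synthetic-data generator
and the numerical choices behind `lnmacs`.

## Study design and data model

The analysis targets a 16-sample factorial design of sorted lymph-node
macrophage subsets: 4 biological pools (each pooling lymph nodes from two
mice; a blocking factor) x tumor-draining status (TD = 1 tumor-draining,
0 non-draining) x sorting phenotype (CD11c+ "+" = medullary sinus
macrophages, MSM; CD11c- "-" = sub-capsular sinus macrophages, SSM). Counts
live in an `ExpressionMatrix` (genes x samples) tagged with a value kind:
raw `counts` (non-negative integers), `log2_intensity` (microarray-scale,
missing cells allowed) or `standardized` (per-sample z-scores; the class
enforces column mean 0, sd 1 to 1e-9).

## Gene filtering and size factors

Genes are kept when their total count is >= 10 *and* they are detected
(count > 0) in >= 2 samples; both thresholds are configurable and both
rules are applied as stated (the boundary gene (5,5,0,...) is kept).
Size factors are median-of-ratios: over the reference set of genes with
strictly positive counts in all samples, `sf_j = median_g count_gj /
geomean_g`, rescaled so the size factors have geometric mean 1. The
rescaling is a convention; the likelihood-ratio statistic is invariant to a
common rescaling of all size factors.

## Negative-binomial likelihood-ratio testing

Per gene, counts follow NB(mu, alpha) with `Var = mu + alpha mu^2` and
`log mu = log sf + X beta`. Coefficients use treatment coding (first pool
level, TD = 0 and phenotype "-" as references) and are fitted by IRLS to a
relative tolerance of 1e-8 (max 100 iterations, step-halving on likelihood
decreases, coefficients bounded at +/-30 on the natural-log scale to tame
separation). Comparison C1 tests the phenotype column (full:
intercept + pool + TD + phenotype; reduced drops phenotype); C2 tests the
TD column. The statistic `2 (ll_full - ll_reduced)` is clamped at zero and
referred to chi-square with df = 1. Reported `log2_fc` is the tested
coefficient divided by log 2, sign-flipped for C1 so positive values mean
higher in SSMs.

### Dispersion estimation and moderation

The dispersion is estimated under the full model and held fixed for the
reduced fit, so the test compares mean structure only. Gene-wise estimates
maximize the Cox-Reid adjusted profile likelihood (the NB log likelihood
minus `0.5 log det(X' W X)`), searched over `alpha` in [1e-8, 50] on the
log scale (bounded Brent, xatol 5e-3 on log alpha).

With 16 samples and a 6-column design the gene-wise estimate has roughly
10 residual degrees of freedom; plugging it into a chi-square LRT behaves
like treating a t(10) statistic as normal and inflates the type-I error
(measured: ~0.15 at nominal 0.05 with plain ML dispersion, ~0.08 with
Cox-Reid). The default `dispersion_method="map"` therefore moderates the
estimates across genes, in the spirit of the standard NB-GLM RNA-seq
tools:

1. a mean-dispersion trend `alpha(mu) = a0 + a1/mu` is fitted to the
   gene-wise estimates by iteratively reweighted least squares with
   constant-CV weights, trimming genes whose ratio to the trend leaves
   [0.01, 10]; with fewer than 20 usable genes the trend falls back to the
   median dispersion;
2. the prior width on log dispersion is the robust (MAD) variance of the
   log residuals around the trend, computed over interior estimates only
   (estimates stuck at the search bounds carry no spread information),
   minus the expected sampling variance `trigamma((n - p)/2)`, floored at
   0.25^2;
3. each gene's final dispersion maximizes the Cox-Reid adjusted profile
   likelihood plus the normal log-prior centred on its trend value (MAP).

Measured on 2000 null genes at n = 16, alpha = 0.05: rejection rate 0.048
at nominal 0.05 and Kolmogorov-Smirnov uniformity p = 0.61 for the raw
p-values. Unmoderated estimation remains available
(`dispersion_method="cox-reid"` or `"ml"`) for users who want strictly
per-gene estimates; it is anticonservative at this sample size.

### Multiplicity and DEG selection

Raw p-values are Holm step-down adjusted across all tested genes of one
comparison (adjusted_(i) = max_{j<=i} min(1, (m-j+1) p_(j)) along the
ascending sort, stable tie-break). The adjustment is per comparison; C1
and C2 each carry their own family. DEGs require strict inequalities:
`p_holm < 0.01` and base mean > 100, where base mean is the arithmetic
mean over samples of count/size factor. Genes whose IRLS fit fails to
converge are excluded from testing and reported separately; they do not
enter the Holm family.

## Cross-platform harmonization

Microarray probes are averaged per gene (arithmetic mean on the log2
scale, the scale arrays are reported on); unmapped probes are dropped with
a logged count. RNA-seq counts become `log2(1e6 count / colsum + 1)`
(log2-CPM with pseudocount 1; `log2count1` is available as an alternative)
— CPM removes depth before the per-sample z-score, and the z-score absorbs
any remaining multiplicative constant. Genes detected on only one platform
are removed (detection: count > 0 in >= 1 sample for counts, a non-missing
cell for intensities); intersection precedes standardization, matching the
workflow order. Each sample column is standardized ((x - mean)/sd, n-1
denominator; a constant column is an error naming the sample). Platform
comparability is summarized by the Pearson correlation between the
per-gene means of the two standardized platforms.

## Lineage signatures and contamination testing

Four marker panels ship verbatim (mouse symbols, ImmPort-derived): B cell
(9 genes), T cell (11), housekeeping (8) and macrophage (9). A sample's
signature for a panel is the sum of its (standardized) expression over the
panel genes found in the matrix; missing markers are skipped with a
warning and `n_markers_found` is reported. Because z-scores can be
negative, the default `shift="minzero"` subtracts the global matrix
minimum before summing — this guarantees positive signatures while
preserving the sample ordering; when two datasets are compared, the joint
minimum over both matrices is used so their signatures share one scale
(the shift is recorded in every report). Contamination ratios divide each
lineage signature by the housekeeping signature, whose low variability
makes it a stable reference.

Ratio distributions between two datasets are compared with the two-sided
Mann-Whitney U test. For `min(n1, n2) <= 8` the exact permutation null of
the observed midranks is enumerated (all C(n, n1) assignments; the
two-sided p is twice the smaller tail probability, capped at 1 — the
{1,2} vs {3,4} case gives exactly 1/3); larger groups use the
tie-corrected, continuity-corrected normal approximation. `mode="auto"`
picks the exact test whenever feasible, including single-sample groups.

## Synthetic data generator

The generator emulates the study conditions so every downstream stage can
be validated against known truth. Per gene g and sample s the expected
expression is a convex mixture of two compartment profiles, formed before
NB sampling:

    mu[g, s] = L_s ((1 - f_s) m_g 2^(pool + phenotype + TD effects) + f_s l_g)

* `f_s` is the per-sample lymphocyte contamination fraction — the fraction
  of the sorted event's material contributed by adherent lymphocyte blebs;
* `m_g` is the macrophage-compartment mean (baseline log2 means uniform on
  (1, 9) by default);
* `l_g` is the lymphocyte-compartment mean: high for B/T marker genes
  (2^8 by default, against a near-silent 2^2 macrophage level) and equal
  to `m_g` for housekeeping genes, background genes and — by default — the
  macrophage panel, whose genes (Cd45, H2-k1, Cd48, Ly6e, Fos, ...) are
  broadly hematopoietic rather than macrophage-exclusive; the ratio is
  exposed as `macrophage_lymph_ratio` for users who want a
  macrophage-restricted panel (set it near 0 to make contamination dilute
  the panel);
* `L_s` is a log-uniform library factor on (0.7, 1.4), folded into mu so
  median-of-ratios recovery is testable;
* pool effects are gene-wise normal perturbations (sd 0.05 log2) shared
  within a pool, giving the C1/C2 pool adjustment something real to
  absorb;
* counts are NB with dispersion alpha = 0.05 (scalar or per-gene).

All draws consume one generator seeded once, in the documented order
(gene baselines, pool perturbations, library factors, counts), so outputs
are bit-reproducible. `gene_seed` optionally drives the gene-level draws
from their own generator: two datasets sharing a `gene_seed` share one
"biology" (baselines, pool structure) while being sampled independently —
this is how paired clean/contaminated cohorts are built, since comparing
datasets with unrelated baselines confounds every signature.

The microarray twin re-measures a counts dataset at probe level: each gene
receives k probes (k uniform on 1..4), probe value = the gene's log2-CPM
abundance + a fixed probe offset (N(0, 0.3)) + cell noise (N(0, 0.25)).
With zero offsets and noise the aggregated twin reproduces the RNA-seq
log2 abundances exactly, so the full harmonization chain returns a
cross-platform Pearson r of 1 — the identity that anchors the chain's
correctness; correlation decreases monotonically in the probe noise.

### What the generator does and does not emulate

It reproduces the factorial design, NB overdispersion, library-size
variation, pool structure, additive lymphocyte contamination and a
probe-level microarray view. It does not model read-level artifacts (no
FASTQ), GC/length bias, probe cross-hybridization or platform-specific
chemistry beyond offsets + Gaussian noise, dispersion heterogeneity beyond
a user-supplied per-gene vector, or correlated gene modules. Passing tests
therefore certify the statistical machinery under the stated model, not
performance on any particular real dataset; on real data the DE stage will
also differ from DESeq2 in detail (no independent filtering, no outlier
handling, different moderation details).

## Problem sizes used by the test suite and acceptance script

Simulation-based checks run at desk scale, chosen as the package's own
test conditions: null calibration on 2000 genes; familywise-error check
over 100 permuted-label replicates of 150 genes; effect recovery (100
planted log2FC = 2 effects among 1900 nulls) over 10 seeds;
signature-comparison null calibration over 1000 replicates of 150 genes;
contamination power (f = 0.02 vs 0.25, 8 vs 8 samples) over 100 seeds; the
exact Mann-Whitney enumeration is verified exhaustively for all group
sizes up to 8 vs 8.

## Known limitations

* The chi-square reference for the LRT is asymptotic; even with moderation
  the far-tail calibration at n = 16 is approximate (the familywise-error
  simulation measures it directly).
* The minzero shift that makes standardized signatures positive is a
  pragmatic device: ratios depend (weakly) on the shift origin, so reports
  always record the shift used, and comparisons across runs should share
  one origin.
* Cross-platform probe offsets do not cancel within small panels; with
  only ~9 genes per panel a platform-specific bias of order
  `offset_sd/sqrt(k)` per gene survives harmonization. Same-platform
  comparisons are free of this; cross-platform signature comparisons
  should be read with it in mind.
* The exact Mann-Whitney enumerates C(n1+n2, n1) tables and is limited to
  min(n1, n2) <= 8; beyond that the normal approximation is used.
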