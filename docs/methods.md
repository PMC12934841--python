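# Methods

This note documents the models implemented in `peaktag`, the conventions and
numerical choices behind them, what the bundled synthetic generator does and
does not emulate, and the known limitations.

## Scores

All scores are sums of bias-corrected squared Pearson correlations computed
across units (metacells by default, single cells if supplied). For peak *j*:

- co-accessibility `x_j = Σ_{k∈K_j} (r²_jk − b_x)` — `K_j` = cis peaks whose
  centers lie strictly within 1 Mb of peak *j*'s center (center-to-center
  distance), including peak *j* itself; the self term contributes `1 − b_x`.
- co-activity `y_j = Σ_{g∈G_j} (r²_jg − b_y)` — `G_j` = genes with TSS
  strictly within 1 Mb of the peak center; no self term.

Gene mirrors: co-expression `x_i` over genes with TSS <1 Mb of gene *i*'s TSS
(self term included, bias `b_e`), and gene co-activity `y_i` over peaks
centered <1 Mb of the TSS (bias `b_y`, shared with peak co-activity).
Genome-wide variants drop the distance restriction.

Conventions:

- Coordinates are BED-style 0-based half-open; a peak center is
  `floor((start+end)/2)`; a TSS is `start` (+ strand) or `end − 1`
  (− strand).
- Peaks within 1 kb of any TSS (minimum distance from any base of the peak
  interval to the TSS) are excluded from every analysis — as focal elements
  and as partners — restricting attention to enhancer-like peaks. The
  exclusion is idempotent.
- Correlations are plain Pearson on the matrices as given (no log
  transform); constant columns get r = 0 with a warning so sums stay finite.
  Negative correlations are squared, never clipped.
- With per-unit covariates (e.g. cell-subtype proportions within each
  metacell), all correlations can be computed as partial correlations after
  residualizing both columns on the covariates with an intercept.

### Finite-sample bias

An `r²` between independent columns has expectation `1/(n−1)`, so score sums
are biased upward. The estimator samples pairs of columns uniformly without
replacement (default 100,000 pairs, capped at the number available),
computes the mean `r²` on all units and on a uniformly drawn 50% of units
(rounded down), and reports the difference: halving the sample size doubles
the noise bias, so the difference estimates the full-sample bias. One scalar
is estimated per modality pair (`b_x` ATAC–ATAC, `b_y` ATAC–RNA, `b_e`
RNA–RNA) per dataset, not per distance bin. On Gaussian nulls the estimator
matches the analytic value `1/(n/2−1) − 1/(n−1)` (checked in the acceptance
suite).

## Stratified score regression (S-CASC / S-CESC)

Model: `E[y_j] = τ₀ + Σ_C τ_C x_{j,C} + γ G_j`, with stratified scores
`x_{j,C} = Σ_{k∈K_j} (I_Ck r²_jk − b_x)` for membership values
`I_Ck ∈ [0,1]` (binary or probabilistic categories) and the covariate `G_j`
= number of genes with TSS <1 Mb (the same window as `y_j`). The gene-side
analogue regresses gene co-activity on stratified co-expression scores with
the peak count `K_i` as covariate.

- The stratified-score formula is implemented literally: the bias is
  subtracted once per partner within *every* category, so summing `x_{j,C}`
  over a partition of categories over-subtracts relative to `x_j`. A
  `partition_consistent` option subtracts the bias once per pair
  (`I_Ck (r² − b_x)`) for users who need additivity.
- The fit is ordinary (unweighted) least squares; heteroskedasticity is
  acknowledged and handled only through the block jackknife on the final
  enrichments.
- Derived quantities: per-element causal effect-size variance
  `Var(β_j) = Σ_C I_Cj τ̂_C`; category totals `v_C = Σ_k I_Ck Var(β_k)`;
  enrichment `E_C = (v_C/v_all)/(M_C/M_all)` with `M_C = Σ_j I_Cj`. The
  "all" category (always 1, added automatically) has `E_all = 1` exactly.
  Negative enrichments are reported as-is: `Var(β)` estimates can be
  negative under noise, and depletions below 1 are meaningful.
- Rank-deficiency is detected on the column-normalized design
  (tolerance 1e−8) and reported with the names of the collinear categories
  (via pivoted QR). Note that a set of binary categories that partitions the
  elements is collinear with "all" — categories should overlap, as real
  functional annotations do.
- Genome-wide stratified scores are refused by default: without the cis
  restriction the per-category scores become nearly proportional across
  categories and the regression uninformative (an override flag exists).

### Jackknife

Standard errors come from a delete-one-block jackknife over chromosomes (or
k-means blocks on the peak × unit accessibility matrix, default 200,
seeded). Each leave-one-block-out replicate re-runs the entire pipeline
(τ̂ → Var → v → E). Because blocks have unequal sizes, the delete-m_j
variance formula of Busing et al. (1999) is used; it reduces to the standard
delete-one-group jackknife for equal blocks. Two-sided p-values test
`H₀: E_C = 1` with a normal approximation; significance stars at
0.05/0.01/0.001. A category wholly contained in one block has an undefined
leave-out enrichment; its SE is flagged unstable. Simulation shows the
jackknife SE within a few percent of the empirical SD of the estimator over
independent replicates at the bundled study conditions (ratio ≈ 1.0, checked
in the acceptance suite against the [0.7, 1.4] band).

### Meta-analysis

Enrichments are pooled across datasets by DerSimonian–Laird random-effects
meta-analysis: between-dataset variance `τ²_meta = max(0, (Q − k + 1 − 2)/C)`
truncated at zero, inverse-variance weights `1/(se² + τ²_meta)`. A single
input is passed through with a warning.

### Built-in categories

Binary categories from interval files use any-overlap under half-open
semantics. "TSS±10kb"/"TSS±100kb" use the union of windows over all genes
(half-open, so a peak starting exactly at a window end does not overlap).
"Closest to TSS" marks, for each gene, the peak whose center is nearest the
TSS (ties broken toward the lower peak index); the probabilistic
"Constraint" annotation is the fraction of peak bases covered by the merged
constrained-region union. Gene-side: "Peak±10kb" and "Closest to peak" are
the mirrors. Empty categories are kept with a warning.

## Fine-mapping

The sum-of-single-effects (SuSiE) model is fit by iterative Bayesian
stepwise selection (IBSS). Inputs are the standardized trait (expression of
the focal gene, or accessibility of the focal peak for the gene-level
mirror) and standardized candidate columns within 1 Mb; constant columns are
dropped with a warning.

- Configurations: SCP (L = 1) and MCP (L = min(10, #candidates)); flat
  priors or functional priors ∝ `max(Var(β_j), ε)` with
  `ε = 1e−9 ×` mean prior mass, falling back to flat (with a warning) when
  no candidate has positive mass.
- Each single-effect regression optimizes its prior effect variance by
  maximizing the SER marginal likelihood (bounded scalar optimization on
  log V, with the V = 0 null as fallback). Effects whose prior variance
  collapses to zero contribute their diffuse α to PIPs
  (`PIP_j = 1 − Π_l (1 − α_lj)`).
- The residual variance σ² is re-estimated each iteration from the expected
  residual sum of squares. Convergence is declared when the largest change
  in any α entry falls below 1e−3 (max 100 iterations; non-convergence is
  reported on the result, not raised). The evidence lower bound is tracked
  per iteration and is non-decreasing (within 1e−6 numerical slack); at
  convergence the reported σ², prior variances, and α are mutually
  consistent, so an L = 1 fit reproduces the closed-form single-effect
  posterior exactly.
- The fine-mapped linking score of a candidate is its marginal `r²` × PIP;
  it is bounded above by the marginal score. A cross-source mode applies
  PIPs from one unit level (e.g. metacells) to marginal scores from another
  (e.g. single cells). A top-peak baseline (keep only each gene's
  highest-correlated peak; ties to the lowest peak id) is provided for
  comparison.
- Measurement noise in the candidate matrix is *not* modelled beyond the
  Gaussian residual: the fine-mapper assumes its predictors are accurate, as
  genotype-oriented fine-mapping software does. This is a known limitation —
  with very noisy accessibility readouts the causal peak's observed column
  can be no more informative than its taggers, and no reranking method can
  recover it.

## Evaluation framework

Candidate links are peak–gene pairs with peak-center-to-TSS distance <1 Mb,
restricted to genes with ≥1 true link, and (for CRISPR-style sets) to
experimentally tested pairs. At each unique score threshold c (descending;
ties enter the predicted set together):

```
enrichment(c) = (|pred ∩ true| / |true|) / (|pred| / |universe|)
recall(c)     = |pred ∩ true| / |true|
```

*Average enrichment across recall values* truncates all methods at the
common maximum recall R and averages `enrichment_i (1 − recall_i)` over the
curve points at which the i-th true link is first recovered,
i = 1..n_R = floor(R × n_true). The metric depends only on the ranking, so
it is invariant to monotone transformations of scores. Under random scores
the enrichment at any fixed prediction size has expectation exactly 1
(hypergeometric); note that the enrichment *at true-link recovery points* is
upward-biased under the null (the recovering link is true by construction),
which is why the permutation checks compare against an independent
rank-based recomputation rather than a naive "enrichment = 1" expectation.

Gene bootstrap: genes are resampled with replacement (all links of a
resampled gene enter together, repeats count repeatedly), the curve and the
common-recall truncation are recomputed per replicate, SEs are bootstrap
standard deviations, and the two-sided p-value on a difference is the
bootstrap tail fraction with a +1 continuity correction. The exact two-sided
construction is not standardized in the literature; the percentile form was
chosen and is stated here.

The CRISPR tagging diagnostic restricts to focal genes with a validated
causal (true) peak whose peak–gene correlation exceeds 0.45 (configurable)
and ≥1 tested non-causal (false) peak, and tabulates each negative peak's
correlation with the causal peak against its correlation with the gene; a
strong correlation across pairs is the tagging signature. The gene-level
mirror swaps peaks and genes.

## TFBS analyses

A TF binds a peak if any of its intervals overlaps the peak (half-open); a
gene's promoter is TSS±1kb clipped at the chromosome start. Shared-TF counts
are dot products of binary rows. The pioneer comparison is an OLS of a score
on (pioneer count, non-pioneer count) with an intercept; the difference
p-value is a Wald test using the coefficient covariance. The optional
binding/expression covariates default to quartile bins of TF column sums
(the definition of those bins is not standardized; quartiles are this package's
choice).

## Synthetic generator: study conditions

Defaults (one place, used by the whole test suite): 500 metacell-like
units, 400 peaks (width 500 bp, spaced ~25 kb with ±5 kb jitter over 4
chromosomes, so a 1 Mb window holds ~40 cis neighbours — a scaled-down
version of the ~130 cis peaks typical of real data), 80 genes with TSS
placed midway between adjacent peaks (in cis but never
promoter-overlapping), 10 TF factors of which 2 are pioneer factors
touching a random 30% of peaks genome-wide while ordinary factors load on
contiguous 25-peak blocks; per-peak loading scales are lognormal
(σ = 0.6), giving the tagging-intensity heterogeneity that the
co-accessibility score should recover (rank correlation > 0.8 at these
conditions). Each gene receives 2 causal cis peaks with N(0, σ²_C) effects
(category-dependent variance), plus a trans leakage of factor activity into
expression (leakage SD 0.45, pioneer factors weighted 3×) and unit-specific
noise. Observed matrices apply an exponential link with multiplicative
lognormal measurement noise (SD 0.3); an optional Poisson layer produces
cell-like counts. The `shuffle_loadings` control permutes units
independently within each peak column of the latent signal — destroying all
cross-peak correlation while preserving marginals and causal links — which
removes the score coupling (the no-tagging control).

The generator emulates: factor-driven cis- and trans-co-accessibility,
pioneer-dominated distal correlation, sparse category-concentrated causal
effects, gene–gene co-expression induced by shared causal peaks and shared
factors, and multiplicative/count measurement noise. It does not emulate:
fragment-level ATAC data, read-depth variation across units, doublets,
batch effects, or realistic genome annotation — so passing tests demonstrate
correctness of the estimators under the assumed mechanism, not performance
on any real dataset.

Two focused simulations complement the full generator:

- `stratified_model_sim` draws stratified scores and responses directly
  under the regression model (Poisson(40)+1 cis partners, Exp(0.05) r²
  values clipped to [0,1], self term, 20 blocks, default τ_cat = 0.4 with
  noise SD 0.15). The closed-form enrichment is
  `(τ_all + τ_cat)/(τ_all + f τ_cat)` (= 1/f when the category carries all
  causal variance). The SNR was fixed so that the enrichment ratio — a
  nonlinear function of two noisy totals — is estimated with ~2% relative
  precision at 20,000 elements; at low SNR the denominator `v_all` can
  approach zero and the estimator becomes heavy-tailed, which is a property
  of the ratio, not of the fit.
- `tagging_scenario` builds one focal gene with a single causal peak among
  20 tagging peaks at n = 400 units: a latent TF activity drives a tight
  tagger cluster (pairwise r = 0.97) and, more weakly, the causal peak
  (calibrated so corr(causal, tagger) = 0.7); expression is
  `√0.3 · causal + √0.3 · factor + noise`. The direct trans leakage makes
  individual taggers marginal near-ties with the causal peak, while
  conditioning on the tagger cluster (which proxies the factor) exposes the
  causal peak — the regime in which multi-effect fine-mapping beats marginal
  ranking. With leakage removed, the causal peak's marginal correlation
  dominates by construction and both rankings are equivalent; the cluster
  tightness and the 30% leakage share are the package's calibration of
  "pervasive tagging" at desk scale.

## Numerical choices and degenerate inputs

- Window comparisons are strict (`< 1 Mb`, `< 1 kb`); interval overlap is
  half-open everywhere.
- kNN metacells: seed cells drawn without replacement from the given RNG;
  distance ties broken by unit index; covariates averaged, counts summed.
  This is a simplified stand-in for iterative-LSI kNN aggregation; real
  metacell matrices can be supplied directly.
- Scores of isolated elements: an isolated peak scores `1 − b_x`
  (self term only); a peak with no cis gene scores 0 (empty sum).
- Jackknife with a single block, evaluation sets without true links,
  fine-mapping with non-finite inputs, and zero-variance regression
  predictors are all fatal errors with specific messages rather than NaNs.
- All stochastic steps (bias pair sampling, unit downsampling, k-means,
  bootstrap, generator) take explicit seeds; reruns are bit-identical.

## Problem sizes

The test and acceptance runs use the scaled-down conditions above (400–800
peaks, 500 units, 20,000 score-level elements, 50–200 simulation
replicates), chosen so the full suite exercises every pipeline stage —
generation, scoring, stratified regression with jackknife, fine-mapping,
evaluation with bootstrap — at well-powered but desk-scale sizes.
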