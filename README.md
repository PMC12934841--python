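# peaktag

Tagging-aware peak–gene linking for single-cell RNA+ATAC multiome data.

## The problem

Peak–gene linking methods correlate the accessibility of ATAC peaks with gene
expression across cells (or metacells) to nominate enhancer–gene regulatory
links. But ATAC peaks are themselves strongly correlated — shared
transcription-factor activity, especially of *pioneer* TFs that open closed
chromatin, drives co-accessibility across both nearby and distal peaks. A
non-causal peak that is correlated with a causal peak therefore inherits the
causal peak's association with the gene, exactly as an LD-tagging SNP
inherits a GWAS association. These *tagging* peak–gene links implicate the
wrong regulatory element.

`peaktag` quantifies tagging and corrects for it. For each peak *j* it
defines, across units *u* (metacells or cells):

- **co-accessibility score** — the LD-score analogue:
  `x_j = Σ_{k∈K_j} (r²_jk − b_x)`, where `K_j` is the set of cis peaks
  centered <1 Mb from peak *j* (including *j* itself), `r_jk` is the Pearson
  correlation of the two peaks' accessibility, and `b_x` estimates the
  finite-sample upward bias of `r²`;
- **co-activity score** — the association analogue:
  `y_j = Σ_{g∈G_j} (r²_jg − b_y)` over genes with TSS <1 Mb.

Gene-side mirrors (**gene co-expression** and **gene co-activity** scores)
quantify gene–gene tagging. Peaks within 1 kb of any TSS are excluded
throughout, focusing the analysis on enhancers.

On top of the scores the package provides:

- **S-CASC / S-CESC** — stratified score regression
  `E[y_j] = τ₀ + Σ_C τ_C x_{j,C} + γ G_j`, the single-cell analogue of
  stratified LD-score regression: `x_{j,C}` stratifies the co-accessibility
  score by functional peak category `C`, `τ_C` is the per-peak contribution
  of the category to causal peak→gene effect-size variance, and the category
  enrichment `E_C = (v_C / v_all) / (M_C / M_all)` is reported with
  delete-one-block jackknife standard errors (chromosome or k-means blocks)
  and DerSimonian–Laird random-effects meta-analysis across datasets.
- **SuSiE fine-mapping** of peak–gene links: a sum-of-single-effects
  regression of standardized expression on candidate peak accessibility
  (L = 1 "single causal peak" or L = min(10, #candidates) "multiple causal
  peaks"; flat or functional priors from S-CASC), producing per-candidate
  posterior inclusion probabilities. The **fine-mapped linking score** is
  the marginal squared correlation × PIP, which shrinks tagging links.
- **Enrichment–recall evaluation** against true/false link sets (CRISPR- or
  eQTL-style), with the (1−recall)-weighted *average enrichment* summary and
  gene-bootstrap comparisons between methods.
- **TFBS analyses**: binarized TF-binding matrices, shared-TF counts for
  element pairs, and pioneer vs non-pioneer bivariate regressions.
- A **synthetic multiome generator** embodying the assumed generative
  mechanism (latent TF factors with pioneer/ordinary structure, sparse
  category-dependent causal effects, trans leakage, multiplicative
  measurement noise) with full ground truth, used by the entire test suite.

## Worked example

```python
import numpy as np
from peaktag import (
    SynthConfig, generate, estimate_bias,
    co_accessibility_scores, co_activity_scores, score_correlation,
    StratifiedScoreRegression, finemapped_linking_scores,
    enrichment_recall, average_enrichment,
)

# 1. a synthetic multiome with TF-factor-driven tagging and known causal links
dataset, truth, categories, tfbs, links = generate(
    SynthConfig(seed=0, enriched_effect_multiplier=6.0))
dataset = dataset.without_promoter_peaks()

# 2. bias-corrected co-accessibility and co-activity scores
b_x = estimate_bias(dataset.atac, n_pairs=20_000, seed=1)
b_y = estimate_bias(dataset.atac, dataset.rna, n_pairs=20_000, seed=2)
x = co_accessibility_scores(dataset, b_x)
y = co_activity_scores(dataset, b_y)
r, cond_r = score_correlation(x, y, condition_on=["covariate"])
print(f"r(co-accessibility, co-activity) = {r:.2f} (conditional {cond_r:.2f})")

# 3. stratified score regression: which peak categories carry causal variance?
model = StratifiedScoreRegression.from_dataset(dataset, categories, bias_x=b_x, bias_y=b_y)
result = model.fit()
result.jackknife()
print(result.summary())

# 4. fine-mapped linking scores vs marginal correlations
table = finemapped_linking_scores(dataset, mode="scp", priors="flat", level="peak")
curves = {
    "marginal": enrichment_recall(table.rename(columns={"marginal_r2": "score"}), links),
    "fine-mapped": enrichment_recall(table.rename(columns={"finemapped_score": "score"}), links),
}
print(average_enrichment(curves).to_string(index=False))
```

Output:

```
r(co-accessibility, co-activity) = 0.82 (conditional 0.81)
Stratified score regression
  elements: 400   categories: 3
  intercept tau0 = -0.1273   covariate gamma = 0.006581

  category                         tau       M_C  enrichment        se           p
  all                            0.123     400.0           1  1.03e-15       0.914
  enriched                     0.01429     106.0       1.084     0.221       0.704
  decoy                       -0.02272     180.0       0.895     0.191       0.583
     method  average_enrichment  n_R  common_recall
   marginal            7.804866  160            1.0
fine-mapped           11.723959  160            1.0
```

What the numbers mean: the strong correlation between co-accessibility and
co-activity scores (r = 0.82, and 0.81 after conditioning on the number of
nearby genes) is the tagging signature — peaks that correlate with many
peaks also correlate with many genes. The stratified regression recovers the
"all" category at exactly 1 by construction; at this desk scale (400 peaks)
the enriched category's estimate is noisy (1.08 ± 0.22) — the large-scale
recovery checks live in `tests/test_acceptance.py`. Fine-mapped linking
scores, which multiply each marginal `r²` by its PIP, rank true links above
tagging links substantially better than marginal scores (average enrichment
11.7 vs 7.8 on the generator's ground-truth link set).

The same workflow is scriptable from the shell:

```bash
peaktag synth --config cfg.yaml --out data/ --seed 3
peaktag scores --data data/ --out scores/
peaktag scasc --data data/ --categories data/categories.tsv --out scasc/
peaktag finemap --data data/ --mode scp --out fm/links.tsv
peaktag evaluate --links data/links.tsv --scores scp=fm/links.tsv --out eval/eval
```

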