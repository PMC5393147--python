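# hypoxamir

Tools for dissecting hypoxia-responsive microRNAs and metabolites in cancer
cell-line panels, and for relating them to tissue markers and treatment
outcome.

Solid tumours contain steep oxygen gradients, and hypoxia blunts the response
of colorectal cancer (CRC) to 5-fluorouracil (5-FU). A standard experimental
design profiles a panel of cell lines (e.g. six CRC lines) at three oxygen
tensions — normoxia (20.9% O₂) and two hypoxic tensions (1% and 0.2%) — on a
large miRNA array, together with quantified metabolite levels, qPCR
validation, predicted miRNA→gene target tables, and a small
responder/non-responder tumour cohort with survival follow-up. The analytical
difficulty is that cell-line identity dominates the variance, so the oxygen
signal has to be isolated statistically. This package implements that
analysis as a tested, reusable library for computational biologists working
with multi-factor expression panels.

## What it computes

- **PLS-DA factor dissection** (`plsda`). A NIPALS PLS2 model regresses the
  centered one-hot class indicator **Y** on the centered feature matrix
  **X**, giving scores **T**, weights **W**, loadings **P**, **Q** with
  **X** ≈ **T Pᵀ**. The component count A* is chosen by stratified
  cross-validated Q² = 1 − PRESS/SS. The dissection trick: supervise on one
  factor (cell line), then quantify *unsupervised* separation of another
  factor (oxygen tension) along each latent axis via one-way ANOVA F and a
  Spearman trend statistic, Bonferroni-corrected across axes. Because an
  unsupervised factor cannot help class prediction, its signature surfaces
  just beyond the supervised structure — typically the (C−1)+1-th axis for C
  well-separated classes.
- **Per-feature linear models** (`feature_lm`). For each feature,
  OLS of log2 expression on the ordinal oxygen covariate t ∈ {0, 1, 2}
  (decreasing O₂) plus cell line as a categorical nuisance:
  x<sub>f</sub> = β₀ + β₁t + Σᵢγᵢ·line + ε, with a two-sided t-test on β₁.
  Group-mean log2 fold changes versus normoxia, Benjamini–Hochberg
  adjustment, and Welch's t for two-group (responder vs non-responder)
  comparisons.
- **Pathway enrichment** (`enrichment`). Hypergeometric over-representation
  (ORA) of altered metabolites, and a permutation test for miRNA-target
  enrichment: targets are filtered to confident predictions
  (mirSVR score < −1.25), the distinct pathway genes targeted by the
  significant miRNA set are counted, and compared against B = 1000
  size-matched miRNA sets drawn from the non-significant pool;
  fold enrichment FE = k_obs/mean(k_b), empirical
  p = (#{k_b ≥ k_obs}+1)/(B+1).
- **Rank-correlation association** (`association`). Spearman's ρ with
  average-rank tie handling and, for tie-free data with n ≤ 12, an *exact*
  two-sided p from the full permutation distribution of Σd² (computed by a
  subset dynamic program, not sampling) — appropriate at the n = 11–13 sizes
  of marker and survival correlations.
- **Preprocessing** (`preprocess`). Array background correction and
  plate-mean scaling, log2 transform, qPCR 2^−ΔΔCT quantification (multi-
  control geometric mean handled on the cycle scale), and 5-FU survival-assay
  normalization (percent of untreated; fold survival vs vehicle and
  transfection control).
- **Synthetic data with ground truth** (`synthetic`). Seeded generators that
  plant known oxygen slopes, cell-line effects, pathway-target enrichment and
  survival coupling, so every stage of the pipeline can be benchmarked by
  parameter recovery.

## Worked example

```python
import hypoxamir as hx

# a 1896-feature panel, 6 cell lines x 3 tensions x 3 replicates,
# with 41 planted oxygen-responsive miRNAs (1 log2 unit per tension step)
matrix, meta, truth = hx.simulate_mirna_panel(seed=1)

# supervise on cell line, inspect oxygen tension unsupervised
model, report = hx.dissect_factors(
    matrix, [m.cell_line for m in meta], [m.oxygen_code for m in meta],
    max_components=8, folds=3, seed=1,
)
best = report[0]
print(f"axes fitted: {model.n_components}; oxygen separation on axis {best.axis} "
      f"(trend rho = {best.trend_rho:.3f}, p = {best.trend_pvalue:.3g})")

# univariate confirmation: per-feature regression on tension + cell line
results = hx.fit_feature_models(matrix, meta)
n_sig = sum(r.significant for r in results)
print("oxygen-associated:", hx.format_significant_fraction(n_sig, matrix.n_features))

top = hx.results_frame(results).iloc[0]
print(f"top hit {top.feature_id}: beta = {top.beta_oxygen:.2f} log2/step, "
      f"p = {top.p:.2e}, log2FC(0.2% vs 20.9%) = {top['log2fc_0.2pct']:.2f}")
```

prints

```
axes fitted: 6; oxygen separation on axis 6 (trend rho = 0.940, p = 5.91e-26)
oxygen-associated: 6.8% (128/1896)
top hit miR-sim-1768: beta = 1.08 log2/step, p = 2.11e-19, log2FC(0.2% vs 20.9%) = 2.16
```

The first line is the factor dissection: six latent axes separate the cell
lines, and the sixth — unsupervised with respect to oxygen — orders the
samples by oxygen tension almost perfectly. The second line counts features
whose oxygen slope is significant at p < 0.05 (all 41 planted features are
recovered; the excess over 41 reflects the ~5% false-positive rate among the
1855 null features at unadjusted α = 0.05). The third line shows the
strongest hit: its fitted slope (≈1 log2 per tension step) and its fold
change at severe hypoxia (≈2 log2 units vs normoxia, i.e. ≈4-fold) match the
planted effect.

The same objects drive the command line:

```sh
hypoxamir simulate --kind mirna --out-dir sim --seed 1
hypoxamir lm --expression sim/expression.tsv --metadata sim/metadata.tsv --out lm.tsv
hypoxamir plsda --expression sim/expression.tsv --metadata sim/metadata.tsv --out-prefix pls
```

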