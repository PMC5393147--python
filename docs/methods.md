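# Methods

This note records the models, conventions and design choices behind
`hypoxamir`, and what the synthetic benchmarks do and do not establish.

## Study design and data model

The pipeline targets a multi-factor expression design: a feature panel
(miRNA array intensities, or metabolite levels in fmol/cell) measured across
C cell lines × 3 oxygen tensions × r replicates. Oxygen tension is handled
as an ordinal covariate t with 0 = 20.9% (normoxia), 1 = 1%, 2 = 0.2%,
i.e. the rank of *decreasing* oxygen. Expression grids must be complete and
finite — no imputation rule is assumed, so missing values are input errors.
Identifiers are opaque case-sensitive strings; no miRBase-version lifting or
gene-symbol translation is attempted (panels from different annotation
releases must be mapped upstream), and ingestion starts at tables already
collapsed from probe level to mature-feature level — the probe-collapse rule
(mean/median/max) belongs to the upstream vendor pipeline. Delimiters follow the file extension
(.tsv → tab, .csv → comma) with no content sniffing, and result tables are
written with six significant digits.

## Preprocessing

* **Background correction** subtracts the per-sample mean of negative-control
  features and floors the result at ε = half the smallest positive corrected
  value in the matrix. The floor keeps a subsequent log2 transform defined
  without inventing a detection-limit model; negative-control rows are
  dropped from the output.
* **Plate-mean normalization** rescales every sample multiplicatively so its
  mean equals the grand mean of sample means. Scaling to the grand mean
  (rather than to 1) preserves intensity magnitude for the log transform.
  The operation is idempotent and preserves within-sample rank order.
* **qPCR quantification** uses plain 2^−ΔΔCT with no amplification-efficiency
  correction. With several endogenous controls, the control CT is the
  *arithmetic mean of CT cycles*, which equals the geometric mean of the
  linear 2^−CT quantities; a naive geometric mean of the cycle values would
  be wrong and is deliberately not offered. Fold change is invariant to
  adding a constant to all of a sample's CTs.
* **Survival assays** report percent survival = 100 × (5-FU count)/(untreated
  count), and fold survival = the transfection's 5-FU/vehicle ratio divided
  by its non-targeting control's. Significance testing of survival contrasts
  (t-tests/ANOVA) is left to standard routines; only the normalization
  arithmetic is implemented here.

## PLS-DA factor dissection

The model is NIPALS PLS2 on column-centered X (samples × features) and a
column-centered one-hot class indicator Y. No unit-variance autoscaling is
applied by default (the data are log-transformed intensities on a common
scale); an explicit standardization step can be applied upstream if wanted.
Per component, the weight/score iteration runs to a relative change of 1e-10
with a cap of 10000 sweeps. The cap matters: with balanced, well-separated
classes the cross-product matrix XᵀY has *near-tied* leading singular
values, and the power iteration's convergence rate degrades as the ratio
approaches 1. When the iterate has stalled below a per-sweep change of 1e-6
at the cap it is accepted — any direction within a (near-)tied singular
subspace is an equally valid component and later deflation is unaffected —
while a larger residual change raises a non-convergence error naming the
component. Signs are fixed deterministically (the largest-|w| element of
each weight vector is made positive) so runs are comparable.

Component count: stratified k-fold CV predicts the held-out indicator with
regression coefficients W(PᵀW)⁻¹Qᵀ; Q²(a) = 1 − PRESS(a)/SS(Y), and
A* is the largest a with Q²(a) − Q²(a−1) > 0.01 (Q²(0) ≡ 0, fallback
A* = 1). The 0.01 increment is a pragmatic threshold: it stops adding axes
once held-out prediction has effectively saturated.

Factor dissection supervises on one factor and quantifies separation of a
second, unseen factor on every axis: one-way ANOVA F across factor levels
plus, for ordinal factors, a Spearman trend of scores against the factor
codes, both with nominal p; the report is ranked by trend p (ties by F) and
a Bonferroni-corrected minimum across axes is used for calibration checks.
Separation is thereby made explicit and testable rather than judged from
score plots. The dissection fits `extra_axes = 1` components beyond A*:
a factor the supervision never saw cannot improve class prediction, so its
signature appears just beyond the supervised structure (with C cleanly
separated classes, on axis (C−1)+1) — examining only the A* supervised axes
would systematically miss it. Both X and Y are centered; the PLS2 (single
multi-class model) variant is used rather than per-class PLS1.

## Per-feature linear models

Every feature is regressed on [intercept, oxygen covariate, C−1 cell-line
indicators] by OLS; all features share the design matrix, so the normal
equations are solved once (tests verify equivalence against statsmodels per
feature). The oxygen coefficient's two-sided t-test identifies
oxygen-associated features. The default covariate coding is ordinal 0/1/2;
`percent` (literal 20.9/1/0.2) and `log-percent` are offered because the two
readings are *not* affinely equivalent for three unequally spaced tensions —
slopes and p-values differ, and the choice is a surfaced flag. Main effects
only; no interaction terms. Features with numerically zero residual variance
(exact fits) are flagged degenerate with p = 0.

Conventions: the in vitro screen reports **raw** p < 0.05 — a deliberate
screening choice (the downstream permutation enrichment and validation stages
absorb the multiplicity), while the tissue two-group comparison applies
Welch's t (unequal variances, the safer default for small uneven groups)
with Benjamini–Hochberg adjustment and calls significance at q < 0.05.
Fold changes are differences of group-mean log2 expression versus the
normoxia (20.9%) reference, non-responders minus responders in the cohort
comparison. The BH step-up is implemented directly (q_(i) = p_(i)·n/i with a
running minimum from the top, capped at 1) and cross-checked against
statsmodels.

## Enrichment

ORA is the upper-tail hypergeometric probability P(X ≥ k) with the universe
defined by the measured features; pathway members outside the universe are
dropped with a warning (error in strict mode).

The permutation test for miRNA-target enrichment filters the target table to
mirSVR score **strictly below −1.25**, counts k_obs = distinct pathway genes
targeted by ≥1 significant miRNA (genes, not miRNA-gene edges, so a gene hit
by several miRNAs counts once), and draws B size-matched miRNA sets without
replacement from the non-significant pool. Fold enrichment is
k_obs/mean(k_b), with FE = +∞ when the null mean is 0 but k_obs > 0 and
FE = 1 when both are 0. The empirical p uses the add-one convention
(#{k_b ≥ k_obs}+1)/(B+1), which is conservative and never 0 — at B = 1000
the smallest attainable p is 1/1001 ≈ 0.001, so quoted values below that
resolution cannot arise from this procedure. Null sets are sampled uniformly;
a per-miRNA degree-matched permutation scheme would be a stricter null but is
not implemented.

## Rank correlation

Spearman's ρ is the Pearson correlation of average-rank vectors, reducing to
ρ = 1 − 6Σd²/(n(n²−1)) for tie-free data (Σd² is reported on that path,
which also lets data consistent with a printed ρ be reconstructed from its
sufficient statistic). Exact two-sided p-values come from the full
permutation distribution of D = Σd², built by a dynamic program over subsets
of assigned ranks — O(2ⁿ·n·max D) time, practical through n = 12 — with
two-sided p = min(1, 2 × one-sided tail), the observed D included in its
tail, and the tail direction chosen by the sign of the observed correlation.
Beyond n = 12 or with ties, the Student-t approximation
t = ρ√((n−2)/(1−ρ²)) on n−2 df is used (the two agree within 0.02 for
|ρ| ≤ 0.5 at n = 12). Exact-p conventions differ across software; printed
p-values from other tools at these sample sizes need not match to the last
digit even when ρ does.

## Synthetic-data generators

All generators are pure functions of (parameters, seed) with a single
explicit NumPy generator per call, and return the planted truth alongside
the data.

* **Expression panels**: x = μ_f + c_{f,line} + β_f·t + ε on the log2 scale,
  with baselines μ_f ~ N(8, 2²), cell-line offsets c ~ N(0, 2.0²), noise
  ε ~ N(0, 0.5²) and β_f = 1.0 log2/step on a randomly drawn responsive
  subset (41/1896 features by default; the metabolite variant plants 92/200).
  The cell-line SD of 2.0 ≫ the oxygen effect makes cell line the dominant
  variance source, matching the regime the dissection is designed for; with
  3 replicates the per-feature regression has ≈0.9+ power at α = 0.05,
  giving a usable recovery benchmark.
* **Target networks**: miRNA→gene edges are independent Bernoulli draws
  (baseline probability 0.02); for planted pathways, edges from the
  designated significant set to the pathway's genes use an elevated
  probability (0.10), and mirSVR scores are uniform in (−3.0, −1.3) so all
  edges pass the −1.25 filter unless configured otherwise. Pathways are
  disjoint gene sets by default (an overlapping mode exists).
* **Tissue cohorts**: 11 tumours (six non-responders, five responders);
  responder survival ~ Uniform(5.5, 10) years and non-responder
  ~ Uniform(0.5, 4.5), encoding the 5-year split without inventing a hazard
  model. Planted features (33/800) are shifted +2.0 log2 units in
  non-responders — chosen so Welch-t/BH recovery at these group sizes is
  high — and, with survival coupling on, carry an additional
  −(effect/5)·survival term, making them exactly anti-monotone with survival
  at zero noise.

What the generators deliberately do **not** emulate: probe-level array
chemistry and spatial artefacts, mass-spectrometry peak processing,
count-type noise of digital hybridization platforms, heavy-tailed or
correlated noise, and miRNA co-regulation structure. Passing recovery tests
therefore demonstrates correctness of the statistical machinery under the
assumed additive-Gaussian, independent-feature regime — not robustness to
every artefact of real array data.

## Problem sizes used in the automated checks

The test-suite calibration loops use scaled problem sizes chosen as a
sensible benchmark budget: type-I error on a 1000-feature null panel;
permutation-p uniformity over 500 replicates of a 50-miRNA/100-gene network
at B = 99; dissection null calibration over 100 runs of a 300-feature,
2-replicate panel; planted-pathway power over 100 networks at B = 199.
Library defaults are unchanged by these choices (B = 1000; full panel
1896 × 54).

## Known limitations

* The exact Spearman p is limited to tie-free data with n ≤ 12.
* Percent-style oxygen codings treat tension as a linear dose; no monotone
  spline or isotonic alternative is provided.
* The permutation null is uniform over miRNAs and ignores target-count
  degree; highly connected miRNAs make it slightly liberal for pathways
  enriched in promiscuous targets.
* ORA assumes a fixed, fully measured universe; results are sensitive to
  universe choice.
* No mixed-effects, robust-regression or survival-regression variants; the
  cohort association is rank correlation only.
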