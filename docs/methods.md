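# Methods

This note documents the statistical model behind `breathdx`, the choices
made where the protocol left the design open, what the synthetic cohort
generator does and does not emulate, and the package's known limitations.

## Data model

The unit of analysis is a breath sample measured by TD-GC-MS and reduced
upstream to a peak-area matrix `A` (samples × compounds, arbitrary area
units) and an SNR matrix of identical shape. Measurement noise in
chromatographic peak areas is multiplicative, so areas are treated as
log-normal: all modelling happens on the log10 scale.

### Quality control

A measurement is *valid* iff SNR > 10, strictly; missing SNR is invalid.
Response rates gate retention in a fixed order: samples first (valid
fraction over **all** compounds, keep ≥ 0.80), compounds second (valid
fraction over **retained** samples, keep ≥ 0.50). Boundary values are
retained; the order matters and is deliberate — a failing sample should not
drag compounds below their gate. Invalid entries of the retained table are
marked missing. Applying the filter to its own output is a no-op on
typical data (tested), though this is an empirical property, not an
algebraic guarantee: response rates are recomputed on the restricted axes.

### Normalization

Fixed order, each step with a reason:

1. **Half-minimum imputation** — each missing entry takes half the minimum
   valid area of its compound. Invalid measurements are low-abundance by
   construction (the SNR gate), so a low constant is the honest fill; it is
   the standard metabolomics convention for left-censored peak data.
2. **log10** — stabilizes the multiplicative variance.
3. **Per-sample median centering** — subtracting each sample's median
   log-area removes sample-loading and instrument-response offsets
   (a per-sample multiplicative factor on the raw scale). The median is
   robust to the handful of disease-shifted compounds. A total-signal
   variant (mean centering, equivalent to dividing by total signal) is
   available via `normalize(..., method="total")`.
4. **Per-compound z-scaling** — mean/sd estimated on the *reference*
   (training) samples only and applied to all samples.

All learned constants — imputation minima included — come from the
reference subset, so the training representation never depends on test
samples. This is stricter than the minimal reading of the protocol but is
required for the leakage guard the modeling stage asserts.

## Screening

Two complementary criteria, both strict inequalities:

* **Rank-sum p < 0.05.** Exact enumeration when the smaller group has ≤ 8
  observations and there are no ties; otherwise the normal approximation
  with tie-corrected variance and continuity correction
  (`scipy.stats.mannwhitneyu`). Identical constant groups return p = 1
  (no evidence) rather than erroring.
* **OPLS-DA VIP > 1.** The OPLS model is fit by NIPALS orthogonal signal
  correction: compute the PLS weight w ∝ Xᵀy (y encoded ±1, centered);
  for each orthogonal component take the part of the current loading
  orthogonal to w, extract its score, deflate X, and refit w; finish with
  a single predictive component. With zero orthogonal components the model
  is exactly one-component PLS-DA (tested). Predictive scores are exactly
  orthogonal to every extracted orthogonal score. One orthogonal
  component is the default (binary y supports one predictive component;
  more orthogonal components are available, 0–3). VIP is computed on the
  predictive component only — the standard OPLS-DA convention, stated
  explicitly because VIP variants differ — giving VIP_j = √p·|w_j|/‖w‖ and
  the identity ΣVIP² = p, which is asserted on every fit.

Whether VIP should come from a cross-validated or single-fit OPLS-DA is a
known ambiguity in the field; this package uses a single fit on the
training samples. The literature-curation step that narrows statistical
candidates to biologically plausible ones is inherently manual and is
modelled as a user-supplied exclusion list only.

## Model development

* **Split.** Only pre-operative samples are eligible (post-operative
  samples are reserved for monitoring). |train| = ⌊0.6·n⌋ with per-class
  largest-remainder allocation: the total is exact and each class is
  within one sample of the stratified ideal.
* **Ranking.** Univariate training AUC, direction-folded (max(a, 1−a));
  ties break by smaller screening p-value, then compound id — a total,
  deterministic order.
* **Forward selection.** At step k the top-k features are scored by mean
  out-of-fold AUC under stratified 5-fold CV. A single 5-fold split at
  n ≈ 79 has step-to-step noise (sd ≈ 0.03) far larger than any sensible
  improvement threshold, so the score averages `cv_repeats = 10`
  re-randomized fold assignments. The walk stops when improvement over the
  running best is ≤ δ = 0.005 for 2 consecutive steps ("no further
  significant improvement" needs a number; δ of half an AUC point with
  patience 2 is that number); the chosen size is the argmax of the
  recorded trace, smallest on ties. Subset scoring uses a fixed ridge
  logistic (C = 0.1): moderately strong shrinkage keeps fold fits stable
  when k approaches the per-fold class counts. Hyperparameter freedom is
  deferred to the next stage.
* **Grid search.** Exhaustive, over penalty ∈ {L1, L2} × C ∈ {0.01, 0.1,
  1, 10} × class weights ∈ {uniform, inverse-frequency} × iteration cap ∈
  {100, 1000}, scored by mean stratified-CV AUC with identical folds per
  cell; ties break by grid order. The iteration cap is itself a searched
  hyperparameter (an early-stopping criterion), so hitting it is an
  admissible model, not a convergence failure. L2 fits use lbfgs (intercept
  unpenalized, matching the textbook penalized likelihood); L1 uses
  liblinear.
* **Youden threshold.** Candidate cutoffs are midpoints between
  consecutive distinct training scores plus ±∞ sentinels; the returned
  cutoff maximizes J = sensitivity + specificity − 1, ties resolved toward
  higher specificity, then the lower threshold. The published cutoff of
  such workflows (e.g. 0.64) is data-derived, not a constant of the
  method. If all scores coincide, J = 0 everywhere and a sentinel is
  returned with a warning.

The whole path split → screen → rank → select → tune → fit → threshold
reads discovery samples only; a test poisons the held-out rows and asserts
the fitted model is bit-identical. A master seed fans out to fixed
per-stage seeds (split: seed, selection folds: seed+1, grid folds:
seed+2), making every artifact reproducible from config + seed.

Alternative classifier families (random forest, k-NN, SVM, boosting) slot
behind the same fit/predict-proba contract via scikit-learn estimators and
are compared with the DeLong test; re-implementing them is out of scope.

## Evaluation statistics

* **AUC** by mid-ranks — exactly the pairwise probability with ties
  counting ½ (property-tested against enumeration).
* **Binomial intervals** are Wilson score intervals; this is the "binomial
  distribution" interval that reproduces published subgroup intervals of
  this workflow at extreme proportions (e.g. 3/3 → 44–100 %), which
  Clopper–Pearson does not (its 3/3 lower bound is 29 %). Clopper–Pearson
  is available via `method="beta"`. F1 intervals treat F1 as the ratio
  2TP/(2TP+FP+FN). The AUC interval uses the DeLong placement-value
  variance with a normal approximation.
* **DeLong test** for two correlated AUCs from placement values V10/V01
  and their empirical covariance; var(ΔAUC) = (s10_aa + s10_bb − 2s10_ab)/n⁺
  + (s01_aa + s01_bb − 2s01_ab)/n⁻. Zero variance with zero difference
  (e.g. a model against itself) gives p = 1; zero variance with a nonzero
  difference is a degenerate pairing and raises.
* **McNemar's test** on discordant correctness counts (b, c): exact
  two-sided binomial when b + c ≤ 25 (enumeration-tested), else chi-square
  with continuity correction. The cutoff is a convention; the exact branch
  is what matters at these cohort sizes.
* **Serum panel.** A marker is positive strictly above the upper limit of
  its normal range (the lower limit of an 0–X range is vacuous); the panel
  is positive if any available marker is. Samples with all markers missing
  are excluded and reported, not counted negative.
* **Monitoring.** Paired two-sided t-test on per-pair (post − pre)
  predicted risk, per diagnosis subgroup. Predicted probabilities are
  bounded, so the t assumption is approximate; a Wilcoxon signed-rank
  alternative is available by flag.

## The synthetic cohort generator

What it emulates — the data structure the analysis assumes:

* compound-specific log-normal areas (baseline mean U(4.5, 6.5), sd
  U(0.3, 0.5) log10 units);
* a planted marker subset (default 13 of 200) with mean log10 area shifted
  by `effect_size` in malignant pre-op samples — all planted markers
  elevated, matching the reported direction of such panels;
* SNR proportional to area over a compound-level noise draw (median log10
  SNR 1.8 above the gate, compound noise sd 0.3), so invalidity correlates
  with low abundance, plus a per-compound forced-invalid probability drawn
  from `missing_rate_range`;
* cohort labels mirroring a 132-participant thoracic-lesion study: 97
  malignant (lung cancer : thymoma : esophageal ≈ 77:13:7), 35 benign
  (nodules vs other ≈ 20:15), AJCC stages in the observed proportions;
* paired post-operative samples for ~55 % of subjects with the planted
  shift attenuated by `postop_effect_removal` (default 0.8) — attenuation,
  not removal, so the monitoring contrast is reproducible but not forced;
* serum markers as binary exceedance of the printed normal ranges with
  per-marker sensitivities (0.061–0.242) in malignant and 2 % in benign —
  sufficient for the McNemar comparison, deliberately not a continuous
  assay model.

**Effect-size default.** `effect_size = 0.3` log10 units gives observed
per-compound training AUCs of ≈ 0.60–0.66 after missingness — the range
such studies report for individual VOC markers — while the 13-marker panel
reaches a Bayes-level AUC near 0.85, the headline performance such
workflows report. These two anchors pin the default jointly; per-compound
effects much weaker than this cannot produce a working multi-marker panel
at n ≈ 130 at all (see Limitations).

**design_auc.** The recorded "design separability" is estimated by
internal Monte-Carlo: a 3 000-sample balanced cohort of the planted
features is drawn with the same missingness and half-minimum imputation,
z-scaled, and scored by LDA fit on one half, AUC on the other. This is
the ceiling any classifier could reach on the generated data; an analytic
independent-Gaussian formula overestimates it by ≈ 0.02–0.03 because
imputation makes the columns non-Gaussian.

What it does **not** emulate: chromatographic raw signal, retention-time
drift, batch effects, between-compound correlation (markers are
independent given class), diet/smoking covariates, or continuous serum
assays. Passing tests therefore demonstrate the pipeline's statistical
correctness and its behaviour under realistic effect sizes and dropout —
not robustness to batch structure or correlated biology.

## Validation experiments and their expected outcomes

`breathdx.validation` ships the experiments the test suite and
`scripts/acceptance.py` run: type-I error of rank-sum and DeLong under
their nulls (nominal 5 %), brute-force oracle agreement for AUC, Youden,
McNemar and DeLong-vs-bootstrap, planted-marker recovery, and the
end-to-end pattern over ten cohorts. Problem sizes (500 Monte-Carlo
replicates, 2 000 bootstrap resamples, ten seeds of 132-subject cohorts)
were chosen as the smallest that make the checks statistically meaningful.

Two outcomes deserve honesty rather than adjustment:

* **Screening recovery is power-limited.** At n = 59 vs 20 the rank-sum
  test needs a realized AUC ≳ 0.69 for p < 0.05, so markers with true
  observed AUC ≈ 0.65 are each detected with probability ≈ 0.5; the dual
  criterion recovers a median of ~8 of 13 planted markers, not all of
  them. No defensible effect size consistent with per-marker AUCs near
  0.6 can push this to near-complete recovery — a screening list at this
  scale necessarily mixes true markers with lucky noise, which is exactly
  why downstream curation and selection exist.
* **The fitted model sits below the design ceiling.** With 13 weak
  features and 79 training samples, estimation loss costs ≈ 0.05–0.10 AUC
  against the Bayes-level design_auc (median held-out AUC ≈ 0.75–0.82 vs a
  ceiling of ≈ 0.82–0.85, seed-dependent). The forward-selected panel size
  hovers around 6–9 of the 13 informative features for the same reason:
  the marginal CV gain of the k-th weak marker shrinks as √k and falls
  under the stopping δ. Larger cohorts, not different code, close both
  gaps.

## Limitations

* Pairwise-complete alternatives to imputation are not offered; every
  downstream statistic sees the imputed matrix.
* The OPLS-DA implementation targets single-response (binary) problems
  only; multi-class discrimination is out of scope.
* Wilson intervals on F1 are a pragmatic convention; F1 is not a binomial
  proportion of independent trials.
* The monitoring t-test treats paired probabilities as interval-scaled;
  for heavily saturated models (risks near 0/1) prefer the signed-rank
  flag.
* The CLI re-trains deterministically rather than deserializing a stored
  model for evaluation; with fixed seeds the two are equivalent, and the
  stored `model.json` is the authoritative artifact.
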