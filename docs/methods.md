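# Methods

## Problem and data model

The pipeline analyses a birth cohort in which children are followed to 18
months and labelled non-allergic (`NONALL`), non-IgE-mediated allergic or
uncertain (`NONIGE_OR_UNCERTAIN`), or IgE-mediated allergic (`IGE`); the
default class sizes are 86/30/15 (131 children). Features are of two
kinds:

- **Cytokine conditions** (288): net secretion (stimulated minus
  unstimulated well, pg/ml) of 18 analytes after LPS or PHA stimulation
  for 24 h or 96 h, measured on mononuclear cells sampled at cord blood,
  2, 6 and 18 months. Continuous, right-skewed, with values that can be
  slightly negative after background subtraction.
- **Clinical factors** (8): number of allergic first-degree relatives
  (ordinal count), maternal tobacco exposure, exclusive breastfeeding at
  the birth/2 m/6 m/12 m visits, delivery mode, pets during pregnancy
  (binary/nominal).

Two binary tasks are derived from the three classes: `ALLERGY`
(IgE- and non-IgE-mediated allergic vs non-allergic; whether the
"uncertain" children count as allergic is configurable and defaults to
yes, mirroring the pooled 30-child class) and `IGE` (IgE-mediated vs
everyone else).

## Preprocessing

- **Background subtraction** is a plain difference; negative net values
  are kept by default (an optional clamp at zero exists for consumers
  that require non-negative concentrations).
- **Inter-plate QC**: per cytokine, positive-control values across plates
  are screened with 1.5×IQR fences, and the cytokine is kept iff the
  max/min ratio of the survivors is finite and ≤ 5. The outlier rule is a
  deliberate, configurable choice: the fence rule is standard and
  parameter-free. An all-zero control series has an undefined ratio and
  is reported as dropped rather than raising.
- **Sparse features**: a variable must have *strictly more than* 50 %
  available data to survive (`> 0.5`, the boundary is tested).
- **Imputation** is deliberately asymmetric to prevent leakage:
  training-fold missing cells are replaced class-conditionally (mean for
  continuous, mode for discrete variables, ties toward the smallest
  value for determinism; a class with no observed value falls back to
  the global training statistic, logged), while test-fold cells only
  ever receive the *global* training statistic. Test labels are never
  consulted and test rows cannot influence one another — both properties
  are enforced by mutation tests.

## Univariate screening

Variable type drives the test: continuous → unpaired two-sample t-test
(classical equal-variance by default; Welch is a config switch so the
sensitivity of conclusions to the variance assumption can be checked);
ordinal → Mann–Whitney U (exact null when the combined sample is ≤ 20
without ties, otherwise the tie-corrected normal approximation); binary
and nominal → χ² without Yates correction (configurable), switching to
Fisher's exact test when any expected cell count is below 5. All tests
are two-sided; missing values are excluded pairwise. A group with fewer
than two observations yields an undefined result that ranks last.

The descriptive report adjusts p-values with the Benjamini–Hochberg
step-up rule. The correction deliberately counts **all m = 296
variables** even when a subset is tabulated, so `bh_adjust` accepts an
external m ≥ the vector length. Inside the resampling loop the raw
p-value order alone defines the ranking (BH is monotone, so adjusted and
raw orderings coincide); ties break lexicographically on the variable
name for bit-reproducibility.

## Classifiers and kernels

- **Random forest**: 500 trees, √p candidate features per split
  (scikit-learn). Training rows are put into a canonical (lexicographic)
  order before fitting so that predictions cannot depend on the order in
  which training samples are supplied.
- **SVM**: soft margin, C = 1, on a *precomputed* Gram matrix so the
  clinical kernel is honoured exactly.
- **1-nearest-neighbour**: implemented directly on the kernel-induced
  distance d² = k(x,x) + k(z,z) − 2k(x,z); distance ties go to the
  smallest training-sample index. Any strictly increasing transform of d
  leaves predictions unchanged.

The kernel combines a cosine-normalised linear part on
training-standardised cytokine features (zero-variance features are
excluded with a warning) with the clinical kernel — per variable,
(r − |x−z|)/r on the training range r (clipped into [0,1] for
out-of-range test values, contributing 1 when r = 0) for
continuous/ordinal variables, an equality indicator for binary/nominal —
averaged unweighted over variables. When a signature mixes blocks the two
parts are averaged; the unweighted average keeps both parts on the [0,1]
scale. Ordinal variables are treated as continuous on their observed
training range. Train×train matrices are symmetric, unit-diagonal and
positive semi-definite (checked to eigenvalue −1e−10).

Performance is the Balanced Classification Rate, BCR = (Se + Sp)/2,
undefined (and guarded against by stratified splits) when a truth class
is absent from the test fold.

## Resampling protocol

`ResamplingEvaluation(cohort, ProtocolConfig(...)).fit()` repeats J = 200
times: stratified 90/10 split (with only 15 positives in the IgE task an
unstratified 10 % test set would often contain no positives; an
unstratified mode with degenerate-split redraws exists), class-conditional
training imputation, training-fold-only ranking, signature = the s best,
global-statistic test imputation, train, predict, record BCR. One master
seed spawns J independent substreams, and each repeat's classifier seed is
drawn regardless of which classifiers are enabled, so adding classifiers
or signature sizes never perturbs the splits. Ranking is computed on the
raw (pairwise-deleted) training fold rather than the imputed matrix:
filling cells with class means before a two-group test would manufacture
separation the data do not contain.

The confidence interval uses the resampling-corrected variance
V = (1/J + n_test/n_train)·s², CI = mean ± t₍J−1,0.975₎·√V, clipped to
[0,1]. The interval is symmetric by construction and never narrower than
the naive t interval. Signature-frequency tables count how often each
variable entered the signature across repeats; the best configuration is
the highest mean BCR with ties to smaller s then classifier name, and the
report notes competitors whose intervals overlap.

Default signature-size grid: {1, 2, 3, 4, 6, 8, 12, 16, 24, 32}; sizes
exceeding a feature set's variable count (clinical has only 8) are
skipped with a log message.

## Synthetic cohort generator

The generator is the package's test bed: it reproduces the data
*structure* the analysis assumes, not any real child's data.

- **Concentrations** are drawn from a shifted log-normal,
  X = LogN(μ,σ) − δ with δ = 1 pg/ml: right-skewed, strictly positive
  before shifting, and able to produce the small near-zero net values
  seen after background subtraction (group means as low as 0.71 pg/ml).
  Per-group moments (m, s) are matched on the shifted scale.
- **Effects** are per-variable, per-group (mean, SD) overrides. Default
  means are the published group means of the discriminant conditions
  (e.g. IL-15 PHA 24 h cord blood: 5.30 pg/ml in IgE-mediated children
  vs 19.21 in the rest; IL-12p70 LPS 96 h: 0.71 vs 2.34; TNF-α LPS 24 h:
  3115 vs 6060 for allergic vs non-allergic). One condition (IL-15 PHA
  96 h CB) is discriminant under both groupings; its three per-class
  means are solved from the two published contrasts jointly (the two
  printed tables are mutually inconsistent by ~0.5 pg/ml on the pooled
  side; the allergic-pooled contrast is honoured exactly).
- **Dispersions** are not published. The generator uses multiplicative
  noise (per-group SD proportional to the group mean — the natural noise
  model for log-normal concentration data), and each effect variable's
  CV is calibrated *by simulation* so that the median realised
  equal-variance t statistic under the full data model (including block
  missingness) equals the t value implied by the published significance
  level of that condition (raw p for the allergy contrasts; corrected p
  with its step-up rank for the IgE contrasts). The calibrated CVs fall
  in 0.37–0.86, typical for multiplex immunoassay panels; non-effect
  (baseline) conditions use the median calibrated CV (σ_log = 0.62)
  around ~24 pg/ml.
- **Missingness** is block-structured: each (child, timepoint) pair is
  missing with probability 0.435, wiping all 72 conditions of that
  timepoint, which puts the median complete-case count per condition at
  ≈ 74 of 131 — the study's reported analysable sample. Clinical
  variables are fully observed.
- **Clinical model**: family history ~ Poisson (mean 0.88 non-allergic
  vs 1.37 allergic), caesarean delivery 19.1 % vs 27.9 %, pets during
  pregnancy 17 % vs 2 %, breastfeeding at 6/12 m 14.5/6 % vs 7.1/1 %;
  factors with no published contrast are class-independent. These are
  the only published clinical effect sizes; the IgE-task clinical signal
  is therefore weak by construction.
- `without_effects()` produces a *global null* configuration: one shared
  distribution per variable and a class-flattened clinical model.
- Same seed ⇒ bit-identical cohort. `generate_raw_wells` emits paired
  stimulated/unstimulated wells whose difference equals the net cohort
  of the same seed cell-for-cell (the unstimulated background is
  log-normal, inflated where needed to keep the stimulated well
  non-negative), so background subtraction can be tested compositionally.

### What the generator does and does not emulate

It emulates class imbalance, mixed variable types, effect directions and
magnitudes calibrated to the published significance levels, realistic
skew, and block missingness. It does **not** model inter-cytokine
correlation (variables are independent given class), plate effects,
limit-of-detection censoring, or missingness that is informative of the
label. Passing tests therefore demonstrate that the *pipeline* behaves
correctly under the study's data structure — not that the biological
findings generalise.

## Monte-Carlo problem sizes and numerical conventions

- Signal-recovery checks use 100 generated cohorts for the univariate
  stage and 50 protocol runs of J = 50 repeats for the signature stage;
  the best-model check uses 10–25 protocol runs of J = 50. These sizes
  give stable pass/fail margins for the ≥ 80 % / ≥ 70 % expectations
  while keeping the whole suite fast.
- Null calibration of the protocol runs J = 200 on one label-permuted
  cohort with all three classifiers. Mean BCR on a *single fixed*
  permutation has an intrinsic spread of several points around 0.5:
  in-loop selection finds whatever chance feature–label association the
  fixed permutation contains, and that association (or its overfitted
  anti-image) persists in the complementary test folds of the same
  finite sample. The Nadeau interval is wide enough to cover 0.5, but
  point estimates a few points from 0.5 are expected behaviour of the
  protocol, not leakage — re-running without missingness (no imputation
  at all) reproduces them.
- The no-effect BH calibration is asserted as calibration (the fraction
  of null cohorts with ≥ 1 BH discovery at q < 0.05 must not exceed the
  nominal 5 % by more than 3 binomial standard errors), since under the
  global null BH flags ≥ 1 variable in ~5 % of cohorts by design.
- Mode ties break toward the smallest value; ranking ties break on the
  variable name; 1-NN distance ties take the smallest training index —
  all for exact reproducibility. All stochastic components derive from
  explicit integer seeds via independent substreams.

## Known limitations

- The published 95 % CI of the study's best allergy model is asymmetric
  around its mean; the corrected-variance interval implemented here is
  symmetric by construction (then clipped to [0,1]), so the asymmetry is
  not imitated.
- Fisher's exact fallback exists only for 2×2 tables; an r×2 nominal
  variable with small expected counts falls back to χ² (the default
  clinical variables are all binary-coded, so this path is exercised
  only by user data).
- No nested hyperparameter tuning, no alternative cross-validation
  schemes, and no formal test between classifiers beyond CI-overlap
  reporting — the protocol estimates each configuration's performance,
  not pairwise contrasts.
- Headline performance numbers obtained on synthetic cohorts characterise
  the pipeline under the generator's assumptions; they are not estimates
  of any real cohort's predictability.
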