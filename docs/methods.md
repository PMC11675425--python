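# Methods

## Model

The analysis treats the binary outcome (history of peripartum depression,
coded PPD = 1) with a *linear* single-response PLS regression — no logistic
link. This mirrors common chemometrics-style practice for PLS-based
discrimination: the latent variable t₁ = Xw₁ is the classifier score, R²Y
is the variance of the scaled 0/1 outcome explained on training data, and
sensitivity/specificity come from sweeping a cutpoint over t₁.

Both X and y are autoscaled (mean 0, unit variance, SD with ddof = 1).
Unit-variance scaling is what makes the VIP > 1 threshold meaningful — it
puts all scores, which come from different publications with arbitrary
units, on a common footing. Scaling vectors are stored in the fitted model
and reapplied to new data at prediction time.

NIPALS extracts components with deflation of both blocks. For a single
response the algorithm converges in one pass per component; the iteration
loop (tolerance 1e-12 on the weight-vector change, max 500 iterations) is
kept for generality and iteration counts are logged in the run report. If
the deflated cross-covariance or response is numerically exhausted before
the requested number of components, the decomposition truncates with a
warning rather than failing — relevant when A approaches rank(X).

Sign convention: each component is flipped so that its largest-magnitude
weight entry is positive. This makes fits bitwise reproducible while
preserving the relative signs of all weights, so reported directions
(positive weight = predicts presence of PPD) are deterministic.

Diagnosis covariate: PLS has no native covariate slot. The MDD/BD label
enters the predictor block as one ordinary autoscaled 0/1 column (BD = 1),
flagged so that VIP ranking and category tables exclude it. It is used only
in the whole-sample analysis; subgroup analyses drop it (it would be
constant) and re-autoscale all scores within the subgroup.

Constant predictor columns are dropped with a warning instead of raising —
subgroup splits can legitimately make a score constant. They still count in
category denominators.

## Component selection

A is chosen by k-fold cross-validation with k = 7, stratified by outcome
(unstratified 7-fold on a 62/116 design can produce single-class training
splits; if an unstratified draw does, it is redrawn with a shifted
sub-seed). Scaling parameters are re-estimated inside every training split
so held-out subjects leak no information. PRESS accumulates on the raw 0/1
outcome scale and Q²(A) = 1 − PRESS(A)/Σ_folds Σ(y_held − ȳ_train)².

The selection rule — the smallest A whose Q² is within 0.01 of the maximum,
floored at A = 1 — is classical parsimony practice; when every Q² is
negative the result is A = 1 with an explicit `no_predictive_component`
flag rather than a failure, since the importance ranking of a
one-component model is still interpretable. The CV seed is a required,
logged run parameter.

The report labels in-sample R²Y and cross-validated Q² separately and
always shows both, as it does for in-sample versus cross-validated AUC:
at n ≈ 178 and p = 341 the optimism gap between them is large, and
conflating the two is the main interpretive hazard of this design.

## VIP scores

The y-variance-weighted form is used: SSY_a = q_a² t_aᵀt_a weights each
component's contribution, and VIP_j = √(p · Σ_a SSY_a (w_aj/‖w_a‖)² / Σ_a
SSY_a). With one component (the usual outcome here) all common VIP variants
coincide and the VIP ranking equals the |w| ranking. Mean VIP² = 1 exactly,
so VIP > 1 (strict — a boundary value of exactly 1.0 is not selected) marks
an above-average contribution. When a covariate is present, p counts only
ranked predictors and weights are renormalised within them, so the
normalisation identity holds for the reported table. Ties in VIP are broken
by |weight| descending, then score id, making ranks deterministic.

## ROC/AUC

AUC is trapezoidal integration over the ROC of the first latent variable,
which equals the Mann–Whitney pairwise-concordance probability with ties
counted ½ (the test suite checks the two routes agree to 1e-12). Scores are
oriented so cases tend to score higher (AUC ≥ 0.5), with the flip recorded.
Cross-validated AUC pools first-latent-variable scores of held-out subjects
across folds; per-fold scalings differ slightly, which is the standard
compromise of pooled CV ROC curves.

## Cohort statistics

Continuous variables: pooled-variance (Student) two-sample t with Cohen's d
= (m₁−m₂)/s_pooled; categorical: uncorrected Pearson χ² with Cramér's V.
These exact variants were chosen because they reproduce the published
demographic table of the emulated study from its printed summaries (age
t = −3.976, menopause χ² = 9.223, etc.); Welch's t and Yates-corrected χ²
do not. Summary-statistics and raw-data paths share one code path so they
agree to machine precision when summaries are exact. A few published rows
(smoking, alcohol, BMI, mood/manic episode counts) are internally
inconsistent or use unprinted subgroup denominators and are not asserted
anywhere.

## Synthetic data generator

What it emulates: the study conditions — 178 subjects (62 cases / 116
controls, 72 MDD / 106 BD, all margins exact by construction), 341 scores
in categories 67/89/131/54, near-duplicate score blocks (sizes cycled
1–4 per phenotype) with within-block correlation ρ = 0.9 induced by a
shared factor (x = √ρ·f + √(1−ρ)·ε, guaranteeing a valid correlation
structure), and a sparse planted liability signal.

Defaults, with units and rationale:

* `rho = 0.9` within-phenotype block correlation — near-duplicate scoring
  files for one trait are highly correlated; no empirical value is
  published for this panel, so this is a stated assumption, not an
  estimate.
* cross-category correlation defaults to 0; an optional global factor
  loading γ mixes in shared variance (within-block correlation becomes
  γ + (1−γ)ρ) to mimic pleiotropy, for which no quantitative target exists.
* default planted signal: 20 causal scores in 8 blocks spread over all four
  categories, per-score liability effect |β| = 0.5 (sleep/circadian blocks
  negative, the rest positive, matching the qualitative direction pattern
  of the motivating analysis).
* `noise_sd = 2.0` (liability units): the genetic component of the default
  signal has variance ≈ 14.7, so the liability is ≈ 79% genetic — a strong
  planted effect, consistent with a panel of traits pre-selected for
  plausible relevance to the outcome, while keeping the outcome
  non-deterministic.
* outcome by rank-thresholding the liability (top 62 = cases) rather than
  Bernoulli draws: prevalence is exact and matches the fixed case/control
  sampling design being emulated.
* diagnosis labels are assigned independently of outcome by default; a
  signal entry may be restricted to one diagnosis group to simulate
  diagnosis-specific architecture.

What it does **not** emulate: genotypes, allele dosages, linkage
disequilibrium, imputation artifacts, ancestry structure, realistic
cross-trait genetic correlation magnitudes, or score-specific
distributional quirks. Passing tests therefore demonstrate that the
pipeline recovers structure it is pointed at under the stated statistical
conditions — not that any particular real-data result would replicate.
The published analysis's own numbers (R²Y of 27.12%/56.73%/43.96%, AUCs of
0.823/0.948/0.904, 106/107/98 selected scores) depend on a genotype-derived
score matrix that is not deposited; the test suite covers the pipeline
statistically (oracle equivalence, planted-signal recovery, null
calibration) rather than asserting those values.

## Numerical and design notes

* The per-model scalar "coefficient" sometimes quoted alongside R²X/R²Y in
  this kind of report has no unambiguous definition; the run report exposes
  two candidates — the first-component y-loading q₁ on the autoscaled scale
  and the slope of the 0/1 outcome on t₁ in original units — and asserts
  neither.
* No per-score hypothesis tests and no multiple-testing correction are
  performed anywhere: the single selection device is the VIP > 1 rule,
  documented as such.
* Problem sizes in the test suite and acceptance script (study-shaped
  178 × 341 panels, 10–20 simulation replicates, candidate A ≤ 3) were
  chosen to exercise the p ≫ n regime the method exists for while keeping
  a full run in seconds.
* Degenerate inputs: single-class outcomes, all-constant panels, zero
  count-table margins and zero pooled variances raise typed errors;
  empty panels cannot be written to fixtures.
* Reports contain no timestamps, so identical config + seed yields
  byte-identical `run_report.json` — checked by test.

## Known limitations

* Linear PLS on a 0/1 outcome is a pragmatic, not probabilistic, model:
  R²Y and predicted values are not calibrated probabilities.
* Q² of a pooled-PRESS CV under strong class imbalance can be pessimistic;
  no permutation test of Q² is provided.
* VIP with A > 1 depends on the variant chosen (documented above); with the
  A = 1 models this analysis selects, the choice is immaterial.
* The generator's correlation structure is block-homogeneous; real PRS
  panels have heavier cross-block correlation tails.
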