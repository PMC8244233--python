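# Methods

## Scope and model

`vitdmr` implements a one-sample Mendelian randomization (MR) analysis of
serum 25-hydroxyvitamin D (25(OH)D, nmol/L) against binary cardiometabolic
outcomes — metabolic syndrome (MS), type 2 diabetes (T2D) and abnormal
systolic/diastolic blood pressure — in a single cohort with individual-level
data. Four SNPs in vitamin-D pathway genes serve as instruments: two
synthesis variants (*DHCR7/NADSYN1* rs12785878, *CYP2R1* rs10741657), one
transport variant (*GC* rs2282679) and one catabolism variant (*CYP24A1*
rs6013897). The causal diagram has three arrows: instrument → exposure
(β_ZX), instrument → outcome (β_ZY) and the observational exposure → outcome
association (β_XY), which is confounded; MR recovers the causal effect from
the first two under the usual IV assumptions (relevance, independence from
confounders, exclusion restriction).

### Estimators

* **Instrument strength.** Cragg-Donald F = R²(n−2)/(1−R²), with R² the
  exposure variance explained by the instrument. For a GRS with covariates
  the incremental R² over the covariate-only model is used; for a single
  SNP the simple regression R². F > 10 is flagged as adequate; weaker
  instruments yield a prominent warning, never an error.
* **Wald ratio** per SNP: β_IV = β_ZY/β_ZX with the two-term delta-method
  SE √(se²_ZY/β²_ZX + β²_ZY·se²_ZX/β⁴_ZX). The one-sample covariance
  between numerator and denominator is ignored — a documented limitation;
  the two-stage estimator provides the alternative uncertainty.
* **Fixed-effect IVW pooling** of Wald ratios with weights ω_j = 1/var(β_IV,j),
  pooled SE (Σω)^(−1/2).
* **MR-Egger**: weighted least squares of β_ZY on β_ZX (weights 1/se²_ZY),
  all β_ZX oriented to the 25(OH)D-increasing allele. The intercept
  estimates average directional pleiotropy; its two-sided p-value uses a t
  reference with n_SNPs − 2 degrees of freedom (4 SNPs → 2 df), with the
  residual scale estimated as in ordinary WLS. With fewer than 3 SNPs the
  regression is reported as undefined, not as numbers; the same applies
  when sampling noise makes an estimated β_ZX non-positive.
* **Wald-type GRS estimator**: OR_IV = exp(ln(OR_GRS→outcome)/β_GRS→VD),
  rescaled to a per-25 nmol/L (configurable) decrease. The CI maps the CI
  of ln(OR_ZY) through the same monotone transform with β_GRS→VD treated
  as fixed (endpoints re-ordered when the map is decreasing).
* **Two-stage estimator** (sensitivity analysis): stage 1 regresses
  25(OH)D on the GRS (+ covariates) by OLS; stage 2 is a logistic
  regression of the outcome on the fitted exposure (+ covariates); the
  reported OR per 25 nmol/L decrease is exp(−25 × stage-2 coefficient)
  with a naive Wald CI. No generated-regressor correction is applied:
  under the causal null the naive test is asymptotically valid (which the
  calibration study verifies), and away from the null the Wald-type CI is
  the companion. Without covariates the two routes coincide algebraically
  (stage 2 is a linear reparametrization of the GRS), so their agreement
  check is only informative in adjusted analyses.

### Orientation convention

Each SNP records which direction its counted allele moves 25(OH)D. GRS
scoring re-orients all SNPs to a single analysis direction, by default
25(OH)D-*decreasing*, so "per unit higher GRS" means genetically lower
vitamin D and causal odds ratios are naturally read per 25 nmol/L
decrease (OR > 1 = harm from low vitamin D). Per-SNP regressions (Wald
ratios, Egger) use the increasing orientation so all β_ZX share a sign.
Because re-orientation happens before any regression, flipping a stored
coding (g → 2−g together with its orientation tag) reproduces bit-identical
estimates — a tested invariant.

## Phenotype definitions

* MS: ≥ 3 of 5 abnormalities with Asian waist cutoffs — WC ≥ 85 cm (men) /
  ≥ 80 cm (women); TG ≥ 1.7 mmol/L or TG-lowering medication; HDL-c
  < 1.0 (men) / < 1.3 (women) mmol/L or HDL-raising treatment; SBP ≥ 130
  or DBP ≥ 85 mmHg or antihypertensive medication; FBG ≥ 5.6 mmol/L or
  anti-diabetic medication. Thresholds written "≥" are inclusive; the HDL
  rule is a strict "<". Medication makes the component abnormal even when
  the measured value is normal.
* T2D: FBG ≥ 7.0 mmol/L, 2-h OGTT ≥ 11.1 mmol/L, anti-diabetic medication
  or prior physician diagnosis. OGTT may be missing.
* Abnormal SBP/DBP: the blood-pressure cutoffs applied separately
  (SBP ≥ 130; DBP ≥ 85). Whether medication alone makes both outcomes
  abnormal is a flag (`bp_med_rule`, default "include") because the
  criteria leave it open; both modes are available end to end.
* Vitamin-D status: half-open intervals [0,25) severe deficiency, [25,50)
  deficiency, [50,75) insufficiency, [75,∞) sufficiency; cohort quintiles
  use empirical 20/40/60/80th percentiles, labelled Q1 (highest
  concentration, the reference) to Q5, with boundary ties assigned to the
  lower-concentration group.
* Repeated measurements: two readings within tolerance (1 cm
  circumference, 1 kg weight, 10 mmHg blood pressure) are averaged; three
  readings average the two closest, and an exactly equidistant third
  reading is paired with the earlier one (deterministic tie-break).
* HOMA-IR = FBG (mmol/L) × insulin (μIU/mL) / 22.5; a pmol/L → μIU/mL
  helper uses 1 μIU/mL = 6.945 pmol/L.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, at
the study's size (n = 2393 middle-aged and elderly participants):

* Genotypes: independent per SNP, Hardy-Weinberg proportions
  ((1−p)², 2p(1−p), p²) at default frequencies 0.45/0.40/0.30/0.25
  (chosen to give realistic instrument strength; only a > 0.05 floor is
  externally constrained).
* Exposure: vitd = 36.4 + Σ effect_j·g_j + 5·U + ε, with per-allele
  effects 2.14/1.10/2.94/0.74 nmol/L, U ~ N(0,1) a latent confounder and
  ε ~ N(0, 16.3²), truncated at 1 nmol/L (truncations logged). The
  intercept, confounder loading and noise SD were set analytically so the
  marginal distribution is ≈ N(41.3, 17.2²), whose 20/40/60/80th
  percentiles match the published cohort's quintile cutpoints
  (28.4/36.7/45.9/57.4 nmol/L) and whose median is ≈ 41 nmol/L — the only
  published constraints on the distribution.
* Outcome: Bernoulli with logit = −0.63 − 0.004·vitd + 0.2·U + Σ κ_j·g_j,
  i.e. a default causal OR ≈ 1.105 per 25 nmol/L decrease and κ_j = 0
  (no pleiotropy) unless injected.
* Biomarkers: normal or lognormal bases with linear loadings on
  (vitd − 41.3) and on U, clipped at physiological floors (clips logged).
  Centres reproduce the published per-quintile medians (FBG ~5.6 mmol/L,
  insulin ~12 μIU/mL, TG ~1.15, HDL ~1.4, WC ~80 cm) and the loadings
  reproduce the qualitative gradient across 25(OH)D quintiles, yielding
  derived prevalences of ≈ 31% MS and ≈ 16% T2D. Covariates (age, sex,
  income band, smoking, alcohol, activity, family history) and medication
  flags are drawn independently of the causal chain.
* Reproducibility: one global seed; each variable draws from a substream
  keyed by (seed, CRC32 of the variable name), so adding a variable never
  perturbs existing draws and identical configs give byte-identical
  cohorts. The latent confounder stays in memory and is excluded from CSV
  export unless explicitly requested.

What the generator does **not** emulate: linkage disequilibrium between
instruments, genotype-covariate correlations (population structure),
realistic correlation between medication flags and biomarker values,
missing-data mechanisms beyond optional OGTT missingness, and longitudinal
follow-up. Passing tests therefore demonstrate correctness of the
estimators under the model's own assumptions, not robustness to violations
real cohorts can exhibit.

## Regression backbone and numerics

OLS and maximum-likelihood logistic regression are delegated to
statsmodels (Logit with Newton scoring, parameter tolerance 1e-10, at most
100 iterations). The wrapper enforces the error contract: rank-deficient
designs raise naming the collinear columns (QR with column pivoting);
fitted probabilities at the 0/1 boundary raise a separation error (the MLE
does not exist); and an iteration cap without convergence raises unless
the first-order conditions already hold to machine precision
(max |score| ≤ 1e-6·n), which distinguishes a Newton oscillation on a
float plateau from genuine non-convergence. Confidence intervals are Wald
(β ± 1.96·se) throughout; categorical covariates (income band, smoking,
alcohol, sex) enter as indicator contrasts against a documented first
level. Observational models use per-outcome covariate presets (MS models
adjust for age, BMI, WHR, income, smoking, alcohol, activity and family
history of MS; T2D models drop smoking and use family history of
diabetes), overridable per call.

## Calibration studies and problem sizes

`vitdmr.studies` packages the Monte-Carlo designs the acceptance checks
run; the sizes are package defaults chosen to estimate each operating
characteristic with useful precision:

* Null calibration: 500 cohorts of n = 2393 with zero causal effect;
  the two-stage Wald test's rejection rate at α = 0.05 is compared with
  exact binomial 95% bounds.
* Parameter recovery: 100 cohorts of n = 100,000 with causal OR 1.105 per
  25 nmol/L decrease and combined-GRS F well above 30; mean two-stage OR
  and per-replicate two-stage vs Wald-type agreement.
* Confounding robustness: 40 cohorts of n = 50,000, zero causal effect,
  confounder moving 25(OH)D by 10 nmol/L/SD and the outcome by 0.5
  log-odds/SD (analytic observational bias ≈ 1.4 per 25 nmol/L); the
  observational OR leaves [0.95, 1.05] while the IV CI keeps covering 1.
* Egger studies: 500 cohorts of n = 20,000 per arm. With κ = 0.03
  log-odds/allele injected into all four SNPs the mean intercept recovers
  κ; with κ = 0 the intercept test's type-I error sits within binomial
  bounds. n = 20,000 keeps every per-SNP β_ZX estimate positive (the
  orientation precondition) and the summary statistics in the normal
  regime the t reference assumes.
* Re-coding invariance: one cohort of n = 2393; every IV quantity is
  compared before and after flipping each SNP's coding, singly and
  jointly (exact equality is expected and observed).

## Known limitations

* Wald-ratio SEs ignore the one-sample β_ZX/β_ZY covariance, and the
  Wald-type CI treats β_GRS→VD as fixed; both understate uncertainty
  slightly in adjusted analyses.
* MR-Egger with four instruments has very low power and its InSIDE
  assumption is untestable at this panel size.
* The GRS weights are external inputs; the shipped equal-weight default
  is for testing, and the example config's weights are illustrative.
* No weighted-median/modal estimators, no two-sample MR, no LD modelling,
  no pseudo-R² reporting for logistic models (the appropriate variant is
  ambiguous, so reports omit it).
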