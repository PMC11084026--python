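# Methods

This package re-implements, at desk scale, a classification of acute
kidney injury (AKI) in critically ill patients with sepsis by the shape
of the early serum-creatinine trajectory, together with the clinical
phenotyping that defines the cohort and the outcome models that give the
classes prognostic meaning.  The real analyses of this kind run on
credential-gated ICU databases (MIMIC-IV-style development data, an
eICU-style external validation set); everything here runs instead on a
synthetic cohort whose statistical structure is calibrated to the
published development-cohort summaries, so that every stage is testable
offline and end to end.

## Clinical phenotyping

All event times live on one numeric axis, hours since hospital
admission; a day is exactly 24 h and every window comparison is closed
on both ends.

**Suspected infection** is the co-occurrence of intravenous antibiotics
and culture collection: a culture within 24 h after antibiotics, or
antibiotics within 72 h after a culture; the suspicion time is the
earlier member of the earliest qualifying pair.  A simplified
repeated-administration variant (suspicion at the second distinct
antibiotic within 72 h) is available behind a switch for feeds that
under-record body-fluid sampling.

**Sepsis onset** follows Sepsis-3: the first time the SOFA score rises
by ≥ 2 within a trailing 24-h window (the pre-ICU score is assumed
zero, so the assumed 0 enters any window reaching back past ICU
admission), paired with the suspicion time when the SOFA time falls in
[suspicion − 24 h, suspicion + 12 h]; onset is the earlier of the two.

**Reference creatinine** is `min(baseline, first admission value)`,
where baseline is the median outpatient creatinine of the previous 12
months or, when absent, the creatinine solving the 4-variable MDRD
equation (coefficient 175, sex factor 0.742, race factor 1.212) at an
assumed eGFR of 75 mL/min/1.73 m².  The inverse is the closed-form
exponent solution; the test suite cross-checks it by scalar bisection
on the monotone MDRD curve.

**AKI detection and staging** are creatinine-only KDIGO: onset at the
earliest measurement with either a ≥ 0.3 mg/dL rise over the minimum
value in the trailing 48 h (a rolling-minimum comparator, since the
guideline does not fix one) or a value ≥ 1.5× reference within 7 days
of the detection-window start.  Stages: ≥ 1.5× (or the 48-h delta)
→ 1, ≥ 2.0× → 2, ≥ 3.0× or an absolute 4.0 mg/dL → 3, boundaries
inclusive.  The maximum stage is taken over the first 96 h after ICU
admission — the same window as the trajectory, since the original
window is not stated.

**Cohort selection** applies, in order: age ≥ 18; sepsis onset within
24 h of ICU admission; AKI onset within 48 h; then exclusions — ESKD or
prior transplant, baseline creatinine > 4 mg/dL, AKI before ICU
admission (evaluated on in-hospital pre-ICU creatinine only), kidney
replacement therapy in the first 96 h, discharge or death before 96 h —
and first ICU stay only.  Each excluded patient gets exactly one
reason, the first failing rule, so the consort ledger sums to the
excluded count.

**Trajectories** are percent change,
`100 × (creatinine − reference)/reference`, one point per measurement
in the first 96 h of ICU stay, no interpolation.

**Outcomes.**  Acute kidney disease (AKD) at day 7: the patient is
alive 7 days after AKI onset and the first creatinine at/after that
time still meets the 1.5× criterion; the value is looked for in days
7–8 and then out to day 10 before a surviving patient is declared
indeterminate (indeterminate patients leave the AKD denominator).  The
7-day composite counts death before day 7 as an event at the death
time and AKD as an event at exactly day 7, censoring everyone else at
day 7; the discharge composite re-assesses AKD at discharge and
censors there, with times measured from AKI onset in both cases.

## The latent class mixed model

Subject *i* in latent class *g* has

    y_i = X_i β_g + Z_i b_i + ε_i,   b_i ~ N(0, D),  ε_i ~ N(0, σ² I),
    P(class = g) = π_g = softmax(ξ)_g ,

with class-specific cubic fixed effects of normalized time (t/96 ∈
[0,1] for conditioning), a random intercept shared across classes
(intercept+slope available behind a configuration switch) and a shared
residual variance.  Cubic is the lowest degree that produces the
single interior peaks and nadirs the eight published shapes describe;
the shared-variance choice keeps the parameter count linear in G.

The observed-data log-likelihood Σ_i log Σ_g π_g N(y_i; X_iβ_g,
Z_iDZ_i' + σ²I) is maximized by EM treating the class label and the
random effects as missing data; each conditional maximization (β by
weighted least squares against the posterior random-effect means, D and
σ² by their expected complete-data updates, π by mean responsibility)
keeps the observed likelihood non-decreasing, which the tests assert on
the recorded iteration history.  Per-subject Gaussian terms use the
Woodbury identity on the q-dimensional random effect and are evaluated
for all subjects at once with segment reductions, so a fit scales
linearly in the total number of measurements.  A brute-force
dense-covariance likelihood lives in the test suite as an independent
oracle (agreement to 1e-8 on small instances).

**Starts.**  Half of the `n_starts` EM runs are seeded by k-means on
per-subject binned trajectory summaries (four bins of normalized time),
the rest by random perturbations of a single-class fit — a
heterogeneous grid of starting points in the spirit of the
growth-mixture "gridsearch" convention.  Pure random perturbations
alone recover eight well-separated classes unreliably within the
iteration caps used here, which is why the k-means starts exist.
Convergence: relative log-likelihood change < `tol` (default 1e-8) or
`max_iter` (default 500); a start that empties a class (all
responsibilities < 1e-6) is discarded and redrawn.  Ties in the
posterior argmax break to the lowest class index, and fitted classes
are relabeled in ascending order of the fitted mean at t = 0 so labels
are stable across runs.  Note this ordering is a labeling convention
only; it need not coincide with any published class numbering.

**Selection and discrimination.**  Models with G = 2…10 classes are
compared by BIC = −2·loglik + k·log(n_subjects), with k counting
G·(degree+1) fixed effects, the free entries of D, σ², and G−1
membership logits; the subject count (not the observation count) is the
sample size, following the latent-class-trajectory literature default.
Discrimination is summarized by the mean posterior class-membership
probability (MPCMP) of each class's assigned members.  A trained model
serializes to versioned JSON and can be applied to an external cohort
with frozen parameters — posteriors only, no refitting — which
reproduces the training assignments exactly when applied to the
training data.

## Association models

Analysis rows join assigned class (class 1, the lowest-t=0 class, as
reference) with outcomes and adjustment covariates.  Covariate columns
missing in more than 40% of rows (strictly) are dropped; the remainder
are completed m = 5 times by chained-equations predictive mean matching
(statsmodels' MICE machinery with `k_pmm` donors behind the package's
`impute_pmm` surface; columns with fewer observed values than donors
fall back to mean imputation with a warning).  AKD uses logistic
regression on class indicators (IRLS on the binomial GLM, so separation
inflates a class's standard error and flags it non-estimable rather
than aborting the fit); the composites use Cox partial likelihood with
Efron tie handling and Kaplan–Meier curves per class.  Coefficients are
pooled across imputations on the log scale by Rubin's rules — total
variance = within + (1 + 1/m)·between, t reference with
(m−1)(1 + W/((1+1/m)B))² degrees of freedom — and exponentiated to
ORs/HRs.  The adjusted models use the fixed covariate set (age, sex,
race, comorbidities, labs surviving the 40% filter, baseline
creatinine, SOFA, initial and maximum AKI stage).  No multiple-testing
correction is applied across classes.  Adjusted estimates pool over the
imputations by default; complete-case analysis is available by passing
a single table.

## The synthetic cohort

The generator draws, per patient: a latent class from the configured
mixture; a reference creatinine (log-normal, median 1.0 mg/dL,
σ = 0.30, matching the reported baseline distribution) — patients
without pre-admission values (15%) instead take their MDRD
back-calculated value as the true reference, so downstream reference
recovery is exact for them; measurement times from a Poisson process at
4 draws/24 h plus one guaranteed draw in hours 0–6 (an admission value
the pipeline needs); percent-change observations as class-mean cubic +
patient random intercept (SD 7 percent-points) + independent Gaussian
noise (SD 10 percent-points); and creatinine reconstructed as
reference × (1 + pct/100).  The noise scale was chosen once as a
plausible ICU regime: against class-mean gaps of ~15–25 percent-points
it yields posterior discrimination in the high range of what such
cohorts report, while leaving adjacent classes genuinely confusable.

Event streams are generated backwards from the intended phenotype:
septic patients (95%) receive an antibiotic 1 h and a culture 4 h after
ICU admission and a first SOFA score of 3–10 at 2 h, which triggers the
suspicion, pairing and onset rules by construction; the remainder lack
cultures and are excluded by the sepsis rule.  A hospital-admission
creatinine near the true reference (2% noise) is placed before ICU
entry, anchoring the min(baseline, first admission) reference without
triggering pre-ICU AKI — deterioration begins at ICU admission, which
is also why elevated-onset classes do not violate the pre-ICU AKI
exclusion.  Hospital stay after ICU admission is log-normal (median
9.2 days), so a realistic fraction of patients is excluded by the 96-h
survival rule.

Outcomes are class-conditional: AKD is Bernoulli with per-class
log-odds calibrated to the published univariate odds ratios (class-1
intercept −2.65, reproducing the reported 16% overall AKD rate under
the published class mix); death is exponential with class-scaled hazard
censored at discharge, with multipliers ranked like the published
discharge-composite hazard ratios.  A follow-up creatinine 7.2 days
after the detected AKI onset (and one just before discharge) is placed
above or below the 1.5× line according to the drawn AKD flag, so the
outcome stage recovers the truth for survivors.

**What the generator does not emulate:** urine output, realistic
pharmacology or care processes, SOFA constructed from organ subscores,
informative measurement timing, class-dependent measurement rates, and
covariate–class correlations beyond a mild severity gradient in the
labs.  Passing tests therefore demonstrate correctness of the rules and
estimators under the stated observation model, not clinical validity on
real EHR streams — in particular, real reference-creatinine error is
larger and more structured than the 2% admission-draw noise here, and
inflates the apparent number of trajectory classes.

## Problem sizes and numerical choices

The bundled analyses run at scaled-down sizes chosen for a laptop-class
budget: the worked analysis cohort is n = 2000 patients (~1600 after
selection); class-count selection in the acceptance checks uses n = 600
subjects with 4 EM starts and 400 iterations capped at tol 1e-7; class
agreement uses n = 800; odds-ratio recovery simulates outcomes for
n = 600 000 labels (outcome simulation needs no trajectories, so large
n is cheap).  At these sizes BIC selection recovers the eight-class
truth and the adjusted Rand index of modal assignments against truth is
~0.85–0.90.  Other numerical conventions: D is jittered by 1e-10 on its
diagonal each M-step; σ² is floored at 1e-10; posterior rows are exact
softmax outputs and sum to 1 by construction; empty-class starts are
redrawn at most 3×n_starts times before the fit aborts.

## Known limitations

- The published per-class BIC values and class shapes are not
  reproducible without the gated source data; the preset's cubic
  anchors are a qualitative reconstruction of the described shapes.
- The composite hazard ratios are emergent (death-time events mixed
  with AKD point events at day 7), so the generator reproduces their
  rank pattern, not their printed magnitudes.
- Cox row-duplication invariance holds only up to the Efron tie
  correction that duplication itself introduces.
- MPCMP in the synthetic preset runs higher than real cohorts report,
  a direct consequence of the noise level needed for reliable
  class-count recovery at desk-scale n.
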