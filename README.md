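# akitraj

Early serum-creatinine trajectory classes in sepsis-associated acute
kidney injury (AKI).

Critically ill patients with sepsis who develop AKI are usually
stratified by the *severity* of the injury alone — the maximum
creatinine rise, staged 1–3 under KDIGO.  That ignores the *shape* of
the early course: a transient stage-1 bump that resolves by day 4 and a
relentless rise to the same peak carry very different risks of acute
kidney disease (AKD, continued AKI beyond day 7) and death.  This
package implements the full pipeline for classifying patients by that
shape and quantifying its prognostic value, for clinical data
scientists working with ICU EHR extracts:

1. **Phenotyping** — Sepsis-3 (suspected infection: antibiotics and
   cultures co-occurring within 24 h/72 h windows, paired with a SOFA
   rise ≥ 2) and creatinine-only KDIGO AKI (Δ ≥ 0.3 mg/dL within 48 h
   or ≥ 1.5× the reference creatinine within 7 days), reference
   creatinine as min(pre-admission median, first admission value) with
   MDRD back-calculation at eGFR 75 when no prior values exist, cohort
   selection with a consort ledger, and AKD/composite outcomes.
2. **Trajectory classification** — a latent class mixed model (LCMM)
   on percent change, 100·(SCr − SCr_ref)/SCr_ref, over the first 96 h
   of ICU stay:

       y_i | class g  =  X_i β_g + Z_i b_i + ε_i ,   b_i ~ N(0, D),
       π_g = softmax(ξ)_g ,

   fitted by EM with multiple starts, class count selected from G =
   2…10 by BIC = −2ℓ + k·log N, discrimination reported as per-class
   mean posterior class-membership probability (MPCMP), and trained
   models serializable for frozen-parameter application to an external
   validation cohort.
3. **Association** — logistic models for AKD and Cox/Kaplan–Meier for
   the AKD-or-death composites versus the reference class, unadjusted
   and covariate-adjusted, over predictive-mean-matching multiple
   imputation pooled by Rubin's rules.
4. **Synthetic cohorts** — a generator that emulates the relational
   structure of ICU extracts (five long-format CSV tables) with a
   configurable latent-class trajectory mixture and class-dependent
   outcome risks, calibrated by default to published development-cohort
   summaries, so the whole pipeline runs and is tested without any
   credential-gated data.

## Worked example

The numbered scripts under `analysis/` run the pipeline stage by stage
on the eight-class synthetic preset (2000 patients, seed 1):

```sh
python analysis/01_simulate.py      # inputs + truth sidecar
python analysis/02_phenotype.py     # cohort.csv, trajectories.csv
python analysis/03_fit_lcmm.py      # BIC sweep, model.json, assignments
python analysis/04_associate.py     # OR/HR tables, KM curves
python analysis/05_report.py        # report.md
```

which prints, in order:

```
included 1612 / 2000 patients
exclusions: {'discharge_or_death_before_96h': 269,
             'no_aki_within_48h_of_icu': 33,
             'no_sepsis_within_24h_of_icu': 86}

selected G=8 (BIC 201056.0); loglik -100376.6
class sizes: [120, 372, 335, 108, 163, 297, 126, 91]
MPCMP: [0.998, 0.915, 0.904, 0.986, 0.998, 1.0, 1.0, 1.0]

unadjusted AKD odds ratios vs class 1:
 class  estimate  ci_low  ci_high
     1      1.00    1.00     1.00
     2      1.26    0.56     2.82
     3      1.86    0.84     4.10
     4      5.99    2.58    13.87
     5      1.34    0.54     3.32
     6      3.35    1.54     7.26
     7      5.93    2.62    13.40
     8      8.83    3.83    20.34
```

Reading this: 388 of 2000 synthetic patients fail the selection rules
(died/discharged before 96 h, no qualifying sepsis or AKI window);
lowest-BIC selection over 2–10 classes recovers the generator's eight
trajectory classes; posterior discrimination is high; and the classes
carry strongly graded AKD risk — classes are labeled in ascending
order of their fitted mean at t = 0, so the steadily worsening and
severe-onset shapes (here labels 4, 7, 8) show the largest odds ratios
against the low-trajectory reference class, recovering the generator's
configured risk ordering.  The same `model.json` can be applied
unchanged to a second simulated cohort with `akitraj apply` to mimic
external validation.

The `akitraj` console script exposes the same stages
(`simulate | phenotype | fit | apply | associate | report | run-all`)
behind a YAML config, e.g.
`akitraj run-all --outdir results/run --seed 1`.

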