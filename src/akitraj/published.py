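"""Reference summary values from the published derivation analysis.

These constants are the printed cohort summaries of the MIMIC-IV
development cohort and the eICU external validation cohort that this
pipeline re-implements at desk scale: outcome counts, univariate
class-vs-outcome effect sizes, and the observed class mix.  The
synthetic-cohort preset calibrates its truth values to them, and the
reporting layer uses the counts for its worked-percentage arithmetic.
"""

# development (MIMIC-IV-derived) cohort -------------------------------------

DEV_N = 4197
VAL_N = 3963

#: outcome event counts, development cohort
DEV_OUTCOME_COUNTS = {
    "akd_day7": 674,
    "death_by_day7": 198,
    "in_hospital_mortality": 591,
    "composite_day7": 872,
    "composite_discharge": 772,
}

#: outcome event counts, external validation cohort
VAL_OUTCOME_COUNTS = {
    "akd_day7": 1000,
}

#: univariate odds ratios for AKD at day 7, class 1 = reference
DEV_AKD_OR = {1: 1.0, 2: 0.99, 3: 3.99, 4: 1.30,
              5: 2.52, 6: 7.11, 7: 5.59, 8: 9.02}

#: univariate hazard ratios, composite of AKD or death by day 7
DEV_COMPOSITE7_HR = {1: 1.0, 2: 0.99, 3: 2.31, 4: 0.85,
                     5: 1.92, 6: 4.98, 7: 3.02, 8: 3.38}

#: univariate hazard ratios, composite of AKD at discharge or mortality
DEV_COMPOSITE_DISCHARGE_HR = {1: 1.0, 2: 1.14, 3: 1.51, 4: 0.57,
                              5: 1.32, 6: 3.48, 7: 1.79, 8: 1.93}

#: reported class mix: class 1 23.5%, class 5 22%, class 3 17%; the
#: remainder spread over the five other classes (not individually printed)
DEV_CLASS_PROPORTIONS = (0.235, 0.08, 0.17, 0.10, 0.22, 0.065, 0.08, 0.05)

#: MPCMP discrimination range reported for the development cohort (%)
DEV_MPCMP_RANGE = (62.0, 89.0)


def outcome_percent(count: int, n: int) -> int:
    """Percentage as printed in cohort outcome tables: integer-rounded."""
    return round(100.0 * count / n)
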