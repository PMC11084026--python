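"""Rule-based clinical phenotyping for sepsis-associated AKI.

Implements Sepsis-3 suspected infection and sepsis onset, reference serum
creatinine (pre-admission median or MDRD back-calculation), KDIGO
creatinine-based AKI detection and staging, cohort selection with an
exclusion ledger, percent-change trajectory construction over the first
96 h of ICU stay, and AKD / composite outcome determination.

Conventions
-----------
All event times live on one numeric axis: **hours since hospital
admission** (floats).  A day is exactly 24 h.  Window comparisons are
closed on both ends.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

HOURS_PER_DAY = 24.0

#: trailing window for the KDIGO absolute-delta criterion (h)
DELTA_WINDOW_H = 48.0
#: absolute creatinine increase triggering stage-1 AKI (mg/dL per 48 h)
DELTA_THRESHOLD = 0.3
#: ratio criterion window relative to its anchor (h)
RATIO_WINDOW_H = 7 * HOURS_PER_DAY
#: trajectory / maximum-stage window after ICU admission (h)
TRAJECTORY_WINDOW_H = 96.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class PatientTimeline:
    """One patient's demographics, covariates and timestamped event streams.

    ``creatinine`` holds in-hospital measurements as ``(time_h, mg/dL)``
    pairs sorted by time; ``prior_creatinine`` holds outpatient values from
    the 12 months before hospital admission (times are negative hours and
    only used for bookkeeping).  ``covariates`` carries adjustment
    variables (labs, vasopressor use/duration, nephrotoxin flag, ...)
    which phenotyping passes through untouched.
    """

    patient_id: str
    age: float
    sex: str                      # "M" | "F"
    race: str                     # "white" | "black" | "hispanic" | "other"
    icu_admit: float
    icu_discharge: Optional[float] = None
    hospital_discharge: Optional[float] = None
    death_time: Optional[float] = None
    creatinine: list = field(default_factory=list)        # [(t_h, mg/dL)]
    antibiotics: list = field(default_factory=list)       # [t_h]
    cultures: list = field(default_factory=list)          # [t_h]
    sofa: list = field(default_factory=list)              # [(t_h, score)]
    prior_creatinine: list = field(default_factory=list)  # [(t_h, mg/dL)]
    comorbidities: dict = field(default_factory=dict)
    covariates: dict = field(default_factory=dict)
    eskd_or_transplant: bool = False
    krt_first_96h: bool = False
    first_icu_stay: bool = True

    def __post_init__(self):
        self.creatinine = sorted(self.creatinine)
        self.antibiotics = sorted(self.antibiotics)
        self.cultures = sorted(self.cultures)
        self.sofa = sorted(self.sofa)
        if any(v <= 0 for _, v in self.creatinine):
            raise ValueError(f"{self.patient_id}: non-positive creatinine")
        if (self.icu_discharge is not None
                and self.icu_discharge < self.icu_admit):
            raise ValueError(f"{self.patient_id}: ICU discharge before admit")


@dataclass
class SepsisEpisode:
    suspicion_time: float
    sofa_time: float
    onset_time: float


@dataclass
class ReferenceCreatinine:
    baseline: float
    baseline_source: str          # "measured-median" | "mdrd-imputed"
    first_admission: float
    reference: float


@dataclass
class AKIEpisode:
    onset_time: float
    stage_at_onset: int
    max_stage: int
    criterion_triggered: str      # "delta-48h" | "ratio-7d"


@dataclass
class TrajectorySeries:
    patient_id: str
    points: list                  # [(t_hours_since_icu_admit, pct_change)]


@dataclass
class OutcomeRecord:
    patient_id: str
    akd_day7: Optional[bool]
    death_in_hospital: bool
    composite7_event: Optional[bool]
    composite7_time: Optional[float]          # days since AKI onset
    composite_discharge_event: Optional[bool]
    composite_discharge_time: Optional[float]
    akd_indeterminate: bool = False


# ---------------------------------------------------------------------------
# suspected infection & sepsis onset
# ---------------------------------------------------------------------------

def detect_suspected_infection(antibiotics: Sequence[float],
                               cultures: Sequence[float]) -> Optional[float]:
    """Earliest qualifying antibiotic-culture pair; Sepsis-3 convention.

    If intravenous antibiotics come first, a culture must follow within
    24 h; if the culture comes first, antibiotics must follow within
    72 h.  The suspicion time is the earlier member of the pair.
    """
    best = None
    cultures = sorted(cultures)
    antibiotics = sorted(antibiotics)
    for a in antibiotics:
        if any(a <= c <= a + 24.0 for c in cultures):
            best = a if best is None else min(best, a)
            break  # antibiotics sorted: later ones cannot improve
    for c in cultures:
        if any(c <= a <= c + 72.0 for a in antibiotics):
            best = c if best is None else min(best, c)
            break
    return best


def detect_suspected_infection_multiabx(antibiotics: Sequence[float],
                                        window_h: float = 72.0
                                        ) -> Optional[float]:
    """Alternative infection rule for feeds with sparse culture data.

    Suspicion is the time of the second distinct antibiotic
    administration falling within ``window_h`` of an earlier one — a
    simplified variant of the repeated-administration definition used
    for multicenter ICU feeds that under-record body-fluid sampling.
    """
    abx = sorted(set(antibiotics))
    for first, second in zip(abx, abx[1:]):
        if second - first <= window_h:
            return second
    return None


def _sofa_rise_time(timeline: PatientTimeline) -> Optional[float]:
    """First time the SOFA increase within a trailing 24-h window is >= 2.

    The pre-ICU score is taken to be zero, so the assumed 0 enters any
    window that reaches back past ICU admission.
    """
    sofa = timeline.sofa
    for k, (t, s) in enumerate(sofa):
        window = [sv for tv, sv in sofa[:k + 1] if tv >= t - 24.0]
        if t - 24.0 <= timeline.icu_admit:
            window.append(0.0)
        if window and s - min(window) >= 2.0:
            return t
    return None


def detect_sepsis_onset(timeline: PatientTimeline,
                        infection_rule: str = "abx-culture"
                        ) -> Optional[SepsisEpisode]:
    """Sepsis-3 onset: suspected infection paired with an acute SOFA rise.

    The pairing window requires the SOFA time to fall no more than 24 h
    before or 12 h after the suspicion time; the onset is the earlier of
    the two.
    """
    if infection_rule == "abx-culture":
        suspicion = detect_suspected_infection(timeline.antibiotics,
                                               timeline.cultures)
    elif infection_rule == "multi-abx":
        suspicion = detect_suspected_infection_multiabx(timeline.antibiotics)
    else:
        raise ValueError(f"unknown infection rule: {infection_rule!r}")
    if suspicion is None:
        return None
    sofa_time = _sofa_rise_time(timeline)
    if sofa_time is None:
        return None
    if not (suspicion - 24.0 <= sofa_time <= suspicion + 12.0):
        return None
    return SepsisEpisode(suspicion_time=suspicion, sofa_time=sofa_time,
                         onset_time=min(suspicion, sofa_time))


# ---------------------------------------------------------------------------
# reference creatinine
# ---------------------------------------------------------------------------

def mdrd_egfr(scr: float, age: float, sex: str, race: str) -> float:
    """4-variable re-expressed MDRD eGFR (mL/min/1.73 m^2), coefficient 175."""
    g = 175.0 * scr ** -1.154 * age ** -0.203
    if sex == "F":
        g *= 0.742
    if race == "black":
        g *= 1.212
    return g


def mdrd_baseline_creatinine(age: float, sex: str, race: str,
                             egfr: float = 75.0) -> float:
    """Back-calculate the creatinine at which MDRD eGFR equals ``egfr``.

    Used to impute a baseline for patients with no pre-admission
    creatinine, at the conventional assumed eGFR of 75 mL/min/1.73 m^2.
    The MDRD curve is monotone in creatinine so the inverse is the
    closed-form exponent solution.
    """
    if not (age and sex in ("M", "F")):
        raise ValueError("age and sex required for MDRD back-calculation")
    f = 175.0 * age ** -0.203
    if sex == "F":
        f *= 0.742
    if race == "black":
        f *= 1.212
    return (f / egfr) ** (1.0 / 1.154)


def compute_reference_creatinine(timeline: PatientTimeline
                                 ) -> ReferenceCreatinine:
    """Reference = min(baseline, first admission creatinine).

    Baseline is the median pre-admission creatinine over the previous 12
    months when any exists, otherwise the MDRD back-calculated value.
    """
    if not timeline.creatinine:
        raise ValueError(f"{timeline.patient_id}: no admission creatinine")
    first_adm = timeline.creatinine[0][1]
    if timeline.prior_creatinine:
        baseline = float(np.median([v for _, v in timeline.prior_creatinine]))
        source = "measured-median"
    else:
        baseline = mdrd_baseline_creatinine(timeline.age, timeline.sex,
                                            timeline.race)
        source = "mdrd-imputed"
    return ReferenceCreatinine(baseline=baseline, baseline_source=source,
                               first_admission=first_adm,
                               reference=min(baseline, first_adm))


# ---------------------------------------------------------------------------
# KDIGO staging & AKI detection
# ---------------------------------------------------------------------------

def stage_creatinine(value: float, reference: float,
                     delta48_met: bool = False) -> int:
    """KDIGO creatinine stage (0 = no AKI).

    Stage 3: >= 3.0x reference or an absolute value >= 4.0 mg/dL;
    stage 2: >= 2.0x; stage 1: >= 1.5x, or any value when the 0.3 mg/dL
    48-h delta criterion is met.  Boundaries inclusive.
    """
    if value <= 0 or reference <= 0:
        raise ValueError("creatinine and reference must be positive")
    ratio = value / reference
    if ratio >= 3.0 or value >= 4.0:
        return 3
    if ratio >= 2.0:
        return 2
    if ratio >= 1.5 or delta48_met:
        return 1
    return 0


def _delta48_met(creat: list, k: int) -> bool:
    """0.3 mg/dL rise of measurement k over the rolling 48-h minimum."""
    t, v = creat[k]
    window_min = min((vv for tt, vv in creat[:k + 1] if tt >= t - DELTA_WINDOW_H),
                     default=v)
    return v - window_min >= DELTA_THRESHOLD


def detect_aki(timeline: PatientTimeline, ref: ReferenceCreatinine,
               window_start: float) -> Optional[AKIEpisode]:
    """KDIGO creatinine-based AKI detection.

    Onset is the earliest measurement at or after ``window_start``
    satisfying either (a) a rise >= 0.3 mg/dL over the minimum value in
    the trailing 48 h, or (b) a value >= 1.5x the reference creatinine
    within 7 days of ``window_start``.  The maximum stage is evaluated
    over the first 96 h after ICU admission.
    """
    creat = timeline.creatinine
    onset_idx = None
    criterion = None
    for k, (t, v) in enumerate(creat):
        if t < window_start:
            continue
        delta = _delta48_met(creat, k)
        ratio = (v >= 1.5 * ref.reference
                 and t <= window_start + RATIO_WINDOW_H)
        if delta or ratio:
            onset_idx = k
            criterion = "delta-48h" if delta else "ratio-7d"
            break
    if onset_idx is None:
        return None
    t0, v0 = creat[onset_idx]
    stage_onset = stage_creatinine(v0, ref.reference,
                                   delta48_met=_delta48_met(creat, onset_idx))
    max_stage = stage_onset
    for k, (t, v) in enumerate(creat):
        if timeline.icu_admit <= t <= timeline.icu_admit + TRAJECTORY_WINDOW_H:
            max_stage = max(max_stage,
                            stage_creatinine(v, ref.reference,
                                             delta48_met=_delta48_met(creat, k)))
    return AKIEpisode(onset_time=t0, stage_at_onset=stage_onset,
                      max_stage=max_stage, criterion_triggered=criterion)


# ---------------------------------------------------------------------------
# cohort selection
# ---------------------------------------------------------------------------

def _first_failing_rule(timeline: PatientTimeline,
                        infection_rule: str) -> Optional[str]:
    if timeline.age < 18:
        return "age<18"
    sepsis = detect_sepsis_onset(timeline, infection_rule=infection_rule)
    if sepsis is None or not (timeline.icu_admit <= sepsis.onset_time
                              <= timeline.icu_admit + 24.0):
        return "no_sepsis_within_24h_of_icu"
    ref = compute_reference_creatinine(timeline)
    aki = detect_aki(timeline, ref, window_start=timeline.icu_admit)
    if aki is None or aki.onset_time > timeline.icu_admit + 48.0:
        return "no_aki_within_48h_of_icu"
    if timeline.eskd_or_transplant:
        return "eskd_or_prior_transplant"
    if ref.baseline > 4.0:
        return "baseline_creatinine>4"
    pre_icu = detect_aki(timeline, ref, window_start=0.0)
    if pre_icu is not None and pre_icu.onset_time < timeline.icu_admit:
        return "aki_before_icu_admission"
    if timeline.krt_first_96h:
        return "krt_within_96h"
    end_of_stay = min(x for x in (timeline.hospital_discharge,
                                  timeline.death_time) if x is not None) \
        if (timeline.hospital_discharge is not None
            or timeline.death_time is not None) else None
    if end_of_stay is not None and \
            end_of_stay < timeline.icu_admit + TRAJECTORY_WINDOW_H:
        return "discharge_or_death_before_96h"
    if not timeline.first_icu_stay:
        return "not_first_icu_stay"
    return None


def select_cohort(patients: Sequence[PatientTimeline],
                  infection_rule: str = "abx-culture"):
    """Apply inclusion/exclusion rules in order; one reason per exclusion.

    Returns ``(included_ids, ledger)`` where ledger maps patient_id ->
    first failing rule, plus a ``counts`` entry aggregating reasons.
    """
    included, reasons = [], {}
    for tl in patients:
        rule = _first_failing_rule(tl, infection_rule)
        if rule is None:
            included.append(tl.patient_id)
        else:
            reasons[tl.patient_id] = rule
    counts = {}
    for r in reasons.values():
        counts[r] = counts.get(r, 0) + 1
    return included, {"reasons": reasons, "counts": counts,
                      "n_included": len(included),
                      "n_excluded": len(reasons)}


# ---------------------------------------------------------------------------
# trajectories & outcomes
# ---------------------------------------------------------------------------

def percent_change(value: float, reference: float) -> float:
    return 100.0 * (value - reference) / reference


def build_trajectory(timeline: PatientTimeline,
                     ref: ReferenceCreatinine) -> TrajectorySeries:
    """Percent-change series over the first 96 h of ICU stay.

    One point per measurement inside the window, no interpolation;
    times are hours since ICU admission.
    """
    pts = [(t - timeline.icu_admit, percent_change(v, ref.reference))
           for t, v in timeline.creatinine
           if timeline.icu_admit <= t <= timeline.icu_admit + TRAJECTORY_WINDOW_H]
    if len(pts) < 2:
        raise ValueError(
            f"{timeline.patient_id}: <2 creatinine values in the 96-h window")
    return TrajectorySeries(patient_id=timeline.patient_id, points=pts)


def _creat_at_or_after(timeline: PatientTimeline, t: float,
                       horizon: float) -> Optional[float]:
    for tt, vv in timeline.creatinine:
        if t <= tt <= horizon:
            return vv
    return None


def determine_outcomes(timeline: PatientTimeline, ref: ReferenceCreatinine,
                       aki: AKIEpisode) -> OutcomeRecord:
    """AKD at day 7 and the two composite outcomes.

    AKD: the patient is alive 7 days after AKI onset and the first
    creatinine at/after that time still meets the 1.5x ratio criterion
    (looked for in days 7-8, extended to day 10 before being declared
    indeterminate).  Composite events: death before day 7 at the death
    time, AKD at exactly day 7; the discharge composite re-assesses AKD
    at discharge and censors there.  Times are days from AKI onset.
    """
    onset = aki.onset_time
    day7 = onset + 7 * HOURS_PER_DAY
    death = timeline.death_time
    discharge = timeline.hospital_discharge
    death_in_hosp = death is not None and (discharge is None
                                           or death <= discharge)

    indeterminate = False
    if death is not None and death <= day7:
        akd_day7 = None
        composite7_event = True
        composite7_time = (death - onset) / HOURS_PER_DAY
    else:
        v7 = _creat_at_or_after(timeline, day7, onset + 8 * HOURS_PER_DAY)
        if v7 is None:
            v7 = _creat_at_or_after(timeline, day7, onset + 10 * HOURS_PER_DAY)
        if v7 is None:
            akd_day7 = None
            indeterminate = True
            composite7_event = None
            composite7_time = None
        else:
            akd_day7 = v7 >= 1.5 * ref.reference
            composite7_event = bool(akd_day7)
            composite7_time = 7.0
    if death_in_hosp and (death is not None and death > day7) \
            and composite7_event is False:
        # died later in hospital: still censored at day 7 for this outcome
        composite7_event, composite7_time = False, 7.0

    if death_in_hosp:
        cd_event = True
        cd_time = (death - onset) / HOURS_PER_DAY
    elif discharge is None:
        cd_event, cd_time = None, None
    else:
        vd = None
        for tt, vv in timeline.creatinine:
            if tt <= discharge:
                vd = vv
        akd_discharge = vd is not None and vd >= 1.5 * ref.reference
        cd_event = bool(akd_discharge)
        cd_time = max((discharge - onset) / HOURS_PER_DAY, 0.0)

    return OutcomeRecord(patient_id=timeline.patient_id,
                         akd_day7=akd_day7,
                         death_in_hospital=death_in_hosp,
                         composite7_event=composite7_event,
                         composite7_time=composite7_time,
                         composite_discharge_event=cd_event,
                         composite_discharge_time=cd_time,
                         akd_indeterminate=indeterminate)
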