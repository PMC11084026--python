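"""Long-format CSV interchange for the pipeline.

The generator writes, and the phenotyping stage reads, five tables
mirroring relational ICU extracts:

- ``patients.csv``    one row per patient: demographics, stay times,
                      comorbidity flags, adjustment covariates
- ``creatinine.csv``  patient_id, time_h, value, phase (prior|hospital)
- ``medications.csv`` patient_id, time_h, kind (antibiotic)
- ``cultures.csv``    patient_id, time_h
- ``sofa.csv``        patient_id, time_h, score

Times are numeric hours since hospital admission.  The generator also
writes a ``truth.json`` sidecar (true class labels and outcome truth)
used only by tests and recovery checks, never by the pipeline itself.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .phenotype import PatientTimeline

COMORBIDITY_COLS = ("diabetes", "chf", "arrhythmia",
                    "chronic_lung_disease", "liver_disease")
COVARIATE_COLS = ("hemoglobin", "wbc", "lactate", "albumin", "ph_arterial",
                  "max_sofa", "vasopressor", "vasopressor_duration_min",
                  "nephrotoxin")


def write_cohort_csvs(cohort, outdir) -> None:
    """Write the five input tables plus the truth sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prows, crows, mrows, curows, srows = [], [], [], [], []
    for tl in cohort.patients:
        row = {"patient_id": tl.patient_id, "age": tl.age, "sex": tl.sex,
               "race": tl.race, "icu_admit": tl.icu_admit,
               "icu_discharge": tl.icu_discharge,
               "hospital_discharge": tl.hospital_discharge,
               "death_time": tl.death_time,
               "eskd_or_transplant": tl.eskd_or_transplant,
               "krt_first_96h": tl.krt_first_96h,
               "first_icu_stay": tl.first_icu_stay}
        for c in COMORBIDITY_COLS:
            row[c] = tl.comorbidities.get(c, False)
        for c in COVARIATE_COLS:
            row[c] = tl.covariates.get(c, np.nan)
        prows.append(row)
        for t, v in tl.prior_creatinine:
            crows.append({"patient_id": tl.patient_id, "time_h": t,
                          "value": v, "phase": "prior"})
        for t, v in tl.creatinine:
            crows.append({"patient_id": tl.patient_id, "time_h": t,
                          "value": v, "phase": "hospital"})
        for t in tl.antibiotics:
            mrows.append({"patient_id": tl.patient_id, "time_h": t,
                          "kind": "antibiotic"})
        for t in tl.cultures:
            curows.append({"patient_id": tl.patient_id, "time_h": t})
        for t, s in tl.sofa:
            srows.append({"patient_id": tl.patient_id, "time_h": t,
                          "score": s})
    pd.DataFrame(prows).to_csv(outdir / "patients.csv", index=False)
    pd.DataFrame(crows).to_csv(outdir / "creatinine.csv", index=False)
    pd.DataFrame(mrows).to_csv(outdir / "medications.csv", index=False)
    pd.DataFrame(curows).to_csv(outdir / "cultures.csv", index=False)
    pd.DataFrame(srows).to_csv(outdir / "sofa.csv", index=False)
    truth = {
        "labels": {p.patient_id: int(c)
                   for p, c in zip(cohort.patients, cohort.truth_labels)},
        "outcomes": json.loads(
            cohort.truth_outcomes.to_json(orient="records")),
    }
    (outdir / "truth.json").write_text(json.dumps(truth))


def read_cohort_csvs(indir) -> list:
    """Read the five input tables back into PatientTimeline objects."""
    indir = Path(indir)
    pats = pd.read_csv(indir / "patients.csv")
    creat = pd.read_csv(indir / "creatinine.csv")
    meds = pd.read_csv(indir / "medications.csv") \
        if (indir / "medications.csv").exists() else pd.DataFrame(
            columns=["patient_id", "time_h", "kind"])
    cults = pd.read_csv(indir / "cultures.csv") \
        if (indir / "cultures.csv").exists() else pd.DataFrame(
            columns=["patient_id", "time_h"])
    sofa = pd.read_csv(indir / "sofa.csv")

    cg = {k: v for k, v in creat.groupby("patient_id")}
    mg = {k: v for k, v in meds.groupby("patient_id")}
    ug = {k: v for k, v in cults.groupby("patient_id")}
    sg = {k: v for k, v in sofa.groupby("patient_id")}
    timelines = []
    for _, row in pats.iterrows():
        pid = row["patient_id"]
        c = cg.get(pid, pd.DataFrame(columns=["time_h", "value", "phase"]))
        hosp = c[c["phase"] == "hospital"]
        prior = c[c["phase"] == "prior"]
        m = mg.get(pid)
        u = ug.get(pid)
        s = sg.get(pid)

        def _opt(x):
            return None if pd.isna(x) else float(x)

        timelines.append(PatientTimeline(
            patient_id=str(pid), age=float(row["age"]), sex=str(row["sex"]),
            race=str(row["race"]), icu_admit=float(row["icu_admit"]),
            icu_discharge=_opt(row.get("icu_discharge")),
            hospital_discharge=_opt(row.get("hospital_discharge")),
            death_time=_opt(row.get("death_time")),
            creatinine=list(zip(hosp["time_h"], hosp["value"])),
            antibiotics=[] if m is None else list(m["time_h"]),
            cultures=[] if u is None else list(u["time_h"]),
            sofa=[] if s is None else list(zip(s["time_h"], s["score"])),
            prior_creatinine=list(zip(prior["time_h"], prior["value"])),
            comorbidities={c2: bool(row[c2]) for c2 in COMORBIDITY_COLS
                           if c2 in row},
            covariates={c2: row[c2] for c2 in COVARIATE_COLS if c2 in row},
            eskd_or_transplant=bool(row.get("eskd_or_transplant", False)),
            krt_first_96h=bool(row.get("krt_first_96h", False)),
            first_icu_stay=bool(row.get("first_icu_stay", True))))
    return timelines


def read_truth(indir) -> dict:
    return json.loads((Path(indir) / "truth.json").read_text())
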