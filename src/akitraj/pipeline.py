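"""End-to-end orchestration: simulate -> phenotype -> fit -> associate -> report.

Every stage reads and writes plain CSV/JSON under the run's output
directory, records its row counts in a consort-style ledger, and the
whole run is reproducible byte-for-byte from the configuration and
seed recorded in ``manifest.json``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, published
from .assoc import (CLASS_COL, filter_missingness, fit_cox_composite,
                    fit_logistic_akd, impute_pmm, km_curves)
from .io import (COMORBIDITY_COLS, COVARIATE_COLS, read_cohort_csvs,
                 write_cohort_csvs)
from .lcmm import (LCMMFit, LCMMSpec, apply_lcmm, assign_classes, fit_lcmm,
                   marginal_trajectories, select_model)
from .phenotype import (build_trajectory, compute_reference_creatinine,
                        detect_aki, detect_sepsis_onset, determine_outcomes,
                        select_cohort)
from .synthetic_cohort import generate_cohort, preset_published_classes


@dataclass
class PipelineConfig:
    preset: str = "published8"          # or None with input_dir set
    input_dir: str = ""
    n_patients: int = 800
    trajectory_window_h: float = 96.0
    aki_window_h: float = 48.0
    G_range: tuple = tuple(range(2, 11))
    fixed_degree: int = 3
    random_structure: str = "intercept"
    n_starts: int = 4
    max_iter: int = 400
    tol: float = 1e-7
    m_imputations: int = 5
    k_donors: int = 5
    infection_rule: str = "abx-culture"
    seed: int = 0
    outdir: str = "results/run"

    def validate(self):
        if not self.G_range:
            raise ValueError("G_range must be non-empty")
        if self.trajectory_window_h <= 0 or self.aki_window_h <= 0:
            raise ValueError("windows must be positive")
        if not self.preset and not self.input_dir:
            raise ValueError("either a preset or an input directory required")
        return self


# ---------------------------------------------------------------------------
# phenotype stage
# ---------------------------------------------------------------------------

def phenotype_cohort(patients, infection_rule: str = "abx-culture"):
    """Select the cohort and flatten per-patient phenotyping into tables.

    Returns ``(cohort_df, trajectories_df, ledger)``; one cohort row per
    included patient with reference creatinine, sepsis and AKI fields,
    and outcomes; trajectories in long format.
    """
    included, ledger = select_cohort(patients, infection_rule=infection_rule)
    keep = set(included)
    rows, trows = [], []
    for tl in patients:
        if tl.patient_id not in keep:
            continue
        ref = compute_reference_creatinine(tl)
        sepsis = detect_sepsis_onset(tl, infection_rule=infection_rule)
        aki = detect_aki(tl, ref, window_start=tl.icu_admit)
        try:
            traj = build_trajectory(tl, ref)
        except ValueError:
            ledger["reasons"][tl.patient_id] = "insufficient_creatinine"
            ledger["counts"]["insufficient_creatinine"] = \
                ledger["counts"].get("insufficient_creatinine", 0) + 1
            continue
        out = determine_outcomes(tl, ref, aki)
        row = {"patient_id": tl.patient_id, "age": tl.age, "sex": tl.sex,
               "race": tl.race,
               "baseline_creatinine": ref.baseline,
               "baseline_source": ref.baseline_source,
               "reference_creatinine": ref.reference,
               "sepsis_onset_h": sepsis.onset_time,
               "aki_onset_h": aki.onset_time,
               "stage_at_onset": aki.stage_at_onset,
               "max_stage": aki.max_stage,
               "akd_day7": out.akd_day7,
               "akd_indeterminate": out.akd_indeterminate,
               "death_in_hospital": out.death_in_hospital,
               "composite7_event": out.composite7_event,
               "composite7_time": out.composite7_time,
               "composite_discharge_event": out.composite_discharge_event,
               "composite_discharge_time": out.composite_discharge_time}
        for c in COMORBIDITY_COLS:
            row[c] = tl.comorbidities.get(c, False)
        for c in COVARIATE_COLS:
            row[c] = tl.covariates.get(c, np.nan)
        rows.append(row)
        for t, p in traj.points:
            trows.append({"patient_id": tl.patient_id,
                          "t_hours": t, "pct": p})
    ledger["n_included"] = len(rows)
    ledger["n_excluded"] = len(ledger["reasons"])
    cohort_df = pd.DataFrame(rows)
    traj_df = pd.DataFrame(trows)
    return cohort_df, traj_df, ledger


def build_analysis_table(cohort_df: pd.DataFrame,
                         assignments_df: pd.DataFrame) -> pd.DataFrame:
    """Join phenotype outcomes/covariates with assigned classes."""
    return cohort_df.merge(
        assignments_df[["patient_id", CLASS_COL]], on="patient_id",
        validate="one_to_one")


# ---------------------------------------------------------------------------
# run
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"config": dataclasses.asdict(config),
                "version": __version__, "counts": {}, "timings_s": {},
                "checksums": {}}
    stage_t0 = time.time()

    def _tick(stage):
        manifest["timings_s"][stage] = round(time.time() - stage_t0, 2)

    # stage 1: inputs ------------------------------------------------------
    if config.input_dir:
        input_dir = Path(config.input_dir)
        patients = read_cohort_csvs(input_dir)
    else:
        if config.preset != "published8":
            raise ValueError(f"unknown preset {config.preset!r}")
        gen = preset_published_classes(n_patients=config.n_patients,
                                   seed=config.seed)
        cohort = generate_cohort(gen)
        input_dir = outdir / "inputs"
        write_cohort_csvs(cohort, input_dir)
        patients = cohort.patients
    manifest["counts"]["patients_in"] = len(patients)
    _tick("simulate")

    # stage 2: phenotype ---------------------------------------------------
    stage_t0 = time.time()
    cohort_df, traj_df, ledger = phenotype_cohort(
        patients, infection_rule=config.infection_rule)
    cohort_df.to_csv(outdir / "cohort.csv", index=False)
    traj_df.to_csv(outdir / "trajectories.csv", index=False)
    (outdir / "consort.json").write_text(json.dumps(
        {"included": ledger["n_included"], "excluded": ledger["counts"]},
        indent=1))
    manifest["counts"]["included"] = ledger["n_included"]
    manifest["counts"]["excluded"] = ledger["n_excluded"]
    manifest["consort"] = ledger["counts"]
    _tick("phenotype")

    # stage 3: LCMM fit + selection ---------------------------------------
    stage_t0 = time.time()
    template = LCMMSpec(G=min(config.G_range),
                        fixed_degree=config.fixed_degree,
                        random_structure=config.random_structure,
                        time_normalization=config.trajectory_window_h)
    fit, bic_table = select_model(traj_df, template,
                                  G_range=config.G_range,
                                  n_starts=config.n_starts, tol=config.tol,
                                  max_iter=config.max_iter, seed=config.seed)
    bic_table.to_csv(outdir / "bic_table.csv", index=False)
    (outdir / "model.json").write_text(fit.to_json())
    manifest["counts"]["selected_G"] = int(fit.spec.G)
    _tick("fit")

    # stage 4: assignment --------------------------------------------------
    stage_t0 = time.time()
    assignments, disc = assign_classes(fit)
    assign_df = pd.DataFrame(
        [{"patient_id": a.patient_id, CLASS_COL: a.assigned_class,
          "max_posterior": a.max_posterior} for a in assignments])
    assign_df.to_csv(outdir / "assignments.csv", index=False)
    mpcmp_df = pd.DataFrame({"class": np.arange(1, fit.spec.G + 1),
                             "mpcmp": disc.mpcmp,
                             "n": disc.class_sizes})
    mpcmp_df.to_csv(outdir / "mpcmp.csv", index=False)
    grid = np.linspace(0, config.trajectory_window_h, 25)
    curves = marginal_trajectories(fit, grid)
    pd.DataFrame(curves.T, columns=[f"class_{g+1}" for g in range(fit.spec.G)],
                 index=pd.Index(grid, name="t_hours")).to_csv(
        outdir / "class_mean_curves.csv")
    _tick("assign")

    # stage 5: association -------------------------------------------------
    stage_t0 = time.time()
    table = build_analysis_table(cohort_df, assign_df)
    filtered, dropped = filter_missingness(table)
    completed = impute_pmm(filtered, m=config.m_imputations,
                           k_donors=config.k_donors, seed=config.seed)
    results = []
    for adjusted in (False, True):
        res_or = fit_logistic_akd(completed, adjusted=adjusted)
        for _, r in res_or.table.iterrows():
            results.append({"outcome": "akd_day7", "effect": "OR",
                            "adjusted": adjusted, **r})
        for outc in ("composite7", "composite_discharge"):
            res_hr = fit_cox_composite(completed, outcome=outc,
                                       adjusted=adjusted)
            for _, r in res_hr.table.iterrows():
                results.append({"outcome": outc, "effect": "HR",
                                "adjusted": adjusted, **r})
    results_df = pd.DataFrame(results)
    results_df.to_csv(outdir / "association_results.csv", index=False)
    km_rows = []
    for outc in ("composite7", "composite_discharge"):
        for g, sf in km_curves(table, outcome=outc).items():
            for _, r in sf.iterrows():
                km_rows.append({"outcome": outc, "class": g,
                                "time": r["time"], "survival": r["survival"]})
    pd.DataFrame(km_rows).to_csv(outdir / "km_curves.csv", index=False)
    manifest["counts"]["analysis_rows"] = len(table)
    manifest["dropped_covariates"] = dropped
    _tick("associate")

    # manifest -------------------------------------------------------------
    for f in sorted(outdir.glob("*.csv")) + [outdir / "model.json",
                                             outdir / "consort.json"]:
        manifest["checksums"][f.name] = _sha256(f)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def _outcome_frequency_table(cohort_df: pd.DataFrame) -> pd.DataFrame:
    n = len(cohort_df)
    rows = []
    events = {
        "AKD at day 7": (cohort_df["akd_day7"] == True).sum(),  # noqa: E712
        "Death by day 7": ((cohort_df["composite7_event"] == True)  # noqa: E712
                           & (cohort_df["akd_day7"].isna())).sum(),
        "In-hospital mortality": cohort_df["death_in_hospital"].sum(),
        "Composite AKD/death by day 7":
            (cohort_df["composite7_event"] == True).sum(),  # noqa: E712
        "Composite AKD/death by discharge":
            (cohort_df["composite_discharge_event"] == True).sum(),  # noqa: E712
    }
    for name, count in events.items():
        rows.append({"outcome": name, "events": int(count), "n": n,
                     "percent": published.outcome_percent(int(count), n)})
    return pd.DataFrame(rows)


def report(outdir) -> str:
    """Assemble a markdown report from a completed run's outputs."""
    outdir = Path(outdir)
    parts = ["# Creatinine-trajectory classification report", ""]
    manifest = json.loads((outdir / "manifest.json").read_text())
    parts += [f"Seed {manifest['config']['seed']}, package version "
              f"{manifest['version']}.", ""]
    parts += ["## Cohort selection", "",
              "```json",
              json.dumps(manifest.get("consort", {}), indent=1),
              "```", ""]

    def _section(title, fname, fmt=None):
        parts.append(f"## {title}\n")
        f = outdir / fname
        if not f.exists():
            parts.append("_unavailable_\n")
            return
        df = pd.read_csv(f)
        parts.append(df.to_markdown(index=False, floatfmt=fmt or ".3f"))
        parts.append("")

    _section("Model selection (BIC by class count)", "bic_table.csv", ".1f")
    _section("Class discrimination (MPCMP)", "mpcmp.csv")
    _section("Class mean trajectories (percent change)",
             "class_mean_curves.csv", ".1f")
    if (outdir / "cohort.csv").exists():
        cohort_df = pd.read_csv(outdir / "cohort.csv")
        parts.append("## Outcome frequencies\n")
        parts.append(_outcome_frequency_table(cohort_df)
                     .to_markdown(index=False))
        parts.append("")
    _section("Class-vs-outcome association", "association_results.csv")
    text = "\n".join(parts) + "\n"
    (outdir / "report.md").write_text(text)
    return text
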