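"""Class-vs-outcome association analysis.

Missingness filtering, predictive-mean-matching multiple imputation
with Rubin pooling, logistic regression for acute kidney disease, Cox
proportional-hazards models (Efron ties) and Kaplan-Meier curves for
the composite outcomes — unadjusted or adjusted for the fixed covariate
set (age, gender, race, comorbidities, labs, baseline creatinine, SOFA,
initial and maximum AKI stage).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from lifelines import CoxPHFitter, KaplanMeierFitter
from statsmodels.imputation.mice import MICEData

CLASS_COL = "assigned_class"
PROTECTED_COLS = ("patient_id", CLASS_COL, "akd_day7",
                  "composite7_event", "composite7_time",
                  "composite_discharge_event", "composite_discharge_time",
                  "death_in_hospital")

#: adjustment covariates (laboratory covariates enter as whatever
#: numeric lab columns survive the missingness filter)
ADJUSTMENT_BASE = ("age", "sex", "race", "diabetes", "chf", "arrhythmia",
                   "chronic_lung_disease", "liver_disease",
                   "baseline_creatinine", "max_sofa",
                   "stage_at_onset", "max_stage")


@dataclass
class AssociationResult:
    outcome: str
    table: pd.DataFrame        # class, estimate, ci_low, ci_high, p, estimable
    adjusted: bool
    m: int
    effect_label: str          # "OR" | "HR"


# ---------------------------------------------------------------------------
# missingness & imputation
# ---------------------------------------------------------------------------

def filter_missingness(table: pd.DataFrame, threshold: float = 0.40):
    """Drop covariate columns whose missing fraction strictly exceeds
    ``threshold``; outcome and class columns are never dropped."""
    dropped = []
    for col in table.columns:
        if col in PROTECTED_COLS:
            continue
        if table[col].isna().mean() > threshold:
            dropped.append(col)
    return table.drop(columns=dropped), dropped


def impute_pmm(table: pd.DataFrame, m: int = 5, k_donors: int = 5,
               seed: int = 0) -> list:
    """Chained-equations predictive mean matching, ``m`` completions.

    Each incomplete numeric column is regressed on the other covariates
    and missing entries copy the observed value of one of ``k_donors``
    nearest-predicted donors, so imputations always live on the observed
    support.  Columns with fewer than ``k_donors`` observed values fall
    back to mean imputation with a warning.  Reproducible by seed.
    """
    if not table.isna().any().any():
        return [table.copy() for _ in range(m)]
    work = table.copy()
    meta = work[[c for c in work.columns if not
                 pd.api.types.is_numeric_dtype(work[c]) or c in PROTECTED_COLS]]
    numeric = work[[c for c in work.columns if c not in meta.columns]]
    bool_cols = [c for c in numeric.columns if numeric[c].dtype == bool]
    numeric = numeric.astype(float)
    for col in numeric.columns:
        n_obs = numeric[col].notna().sum()
        if 0 < n_obs < k_donors and numeric[col].isna().any():
            warnings.warn(f"{col}: only {n_obs} observed values; "
                          "falling back to mean imputation", RuntimeWarning)
            numeric[col] = numeric[col].fillna(numeric[col].mean())
    completed = []
    state = np.random.get_state()
    try:
        np.random.seed(seed % (2 ** 31))
        for _ in range(m):
            mdata = MICEData(numeric.reset_index(drop=True),
                             perturbation_method="gaussian", k_pmm=k_donors)
            if numeric.isna().any().any():
                mdata.update_all(3)
            filled = mdata.data.copy()
            filled.index = table.index
            for c in bool_cols:
                filled[c] = filled[c] > 0.5
            out = pd.concat([meta, filled], axis=1)[table.columns]
            completed.append(out)
    finally:
        np.random.set_state(state)
    return completed


def rubin_pool(estimates: np.ndarray, variances: np.ndarray):
    """Rubin's rules on the coefficient scale.

    Total variance = within + (1 + 1/m) * between; p-values use the
    classical t reference with df = (m-1) * (1 + W / ((1+1/m) B))^2.
    Collapses to the single-fit result when between-imputation
    variance is zero.
    """
    estimates = np.asarray(estimates, float)
    variances = np.asarray(variances, float)
    m = estimates.shape[0]
    qbar = estimates.mean(axis=0)
    within = variances.mean(axis=0)
    if m == 1:
        return qbar, within, np.full_like(qbar, np.inf)
    between = estimates.var(axis=0, ddof=1)
    total = within + (1.0 + 1.0 / m) * between
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (1.0 + 1.0 / m) * between / within
        df = np.where(between > 0, (m - 1) * (1.0 + 1.0 / r) ** 2, np.inf)
    return qbar, total, df


def _pooled_rows(names, estimates, variances, reference_label):
    est, total, df = rubin_pool(estimates, variances)
    se = np.sqrt(total)
    z = scipy.stats.t.ppf(0.975, np.minimum(df, 1e12))
    rows = [{"class": reference_label, "estimate": 1.0, "ci_low": 1.0,
             "ci_high": 1.0, "p": np.nan, "estimable": True}]
    for j, name in enumerate(names):
        finite = np.isfinite(est[j]) and np.isfinite(se[j]) and se[j] < 50
        with np.errstate(over="ignore"):
            p = 2 * scipy.stats.t.sf(abs(est[j]) / se[j],
                                     min(df[j], 1e12)) if finite else np.nan
        rows.append({
            "class": name,
            "estimate": float(np.exp(est[j])) if finite else np.nan,
            "ci_low": float(np.exp(est[j] - z[j] * se[j])) if finite else np.nan,
            "ci_high": float(np.exp(est[j] + z[j] * se[j])) if finite else np.nan,
            "p": float(p) if finite else np.nan,
            "estimable": bool(finite),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model design helpers
# ---------------------------------------------------------------------------

def _class_dummies(table: pd.DataFrame) -> pd.DataFrame:
    """Indicator columns for classes 2..G; class 1 is the reference."""
    classes = sorted(table[CLASS_COL].unique())
    out = pd.DataFrame(index=table.index)
    for g in classes:
        if g == classes[0]:
            continue
        out[f"class_{g}"] = (table[CLASS_COL] == g).astype(float)
    return out


def _adjustment_design(table: pd.DataFrame) -> pd.DataFrame:
    cols = pd.DataFrame(index=table.index)
    lab_cols = [c for c in ("hemoglobin", "wbc", "lactate", "albumin",
                            "ph_arterial", "vasopressor_duration_min")
                if c in table.columns]
    for c in ADJUSTMENT_BASE + tuple(lab_cols):
        if c not in table.columns:
            continue
        v = table[c]
        if c == "sex":
            cols["sex_male"] = (v == "M").astype(float)
        elif c == "race":
            for lev in ("black", "hispanic", "other"):
                cols[f"race_{lev}"] = (v == lev).astype(float)
        else:
            cols[c] = v.astype(float)
    # drop constant columns (no information, break the fit)
    keep = [c for c in cols.columns if cols[c].nunique(dropna=True) > 1]
    return cols[keep]


# ---------------------------------------------------------------------------
# regression models
# ---------------------------------------------------------------------------

def fit_logistic_akd(tables, adjusted: bool = False,
                     outcome_col: str = "akd_day7") -> AssociationResult:
    """Per-class odds ratios for AKD versus the reference class.

    ``tables`` is one completed table or a list of ``m`` imputations;
    coefficients are pooled by Rubin's rules before exponentiation.
    Rows with an indeterminate outcome are excluded.
    """
    if isinstance(tables, pd.DataFrame):
        tables = [tables]
    ests, variances, names = [], [], None
    for tab in tables:
        tab = tab[tab[outcome_col].notna()]
        y = tab[outcome_col].astype(float)
        if y.nunique() < 2:
            raise ValueError("need at least one event and one non-event")
        X = _class_dummies(tab)
        names = list(X.columns)
        if adjusted:
            X = pd.concat([X, _adjustment_design(tab)], axis=1)
        X = sm.add_constant(X.astype(float))
        # IRLS on the binomial GLM: separation inflates the class's SE
        # (flagged non-estimable downstream) instead of killing the fit
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.GLM(y, X, family=sm.families.Binomial()).fit(
                    maxiter=100)
                params = res.params
                cov = np.diag(res.cov_params())
            except Exception:
                params = pd.Series(np.nan, index=X.columns)
                cov = np.full(len(X.columns), np.nan)
        ests.append([params[n] for n in names])
        variances.append([cov[list(X.columns).index(n)] for n in names])
    classes = [int(n.split("_")[1]) for n in names]
    table = _pooled_rows(classes, np.asarray(ests, float),
                         np.asarray(variances, float), reference_label=1)
    return AssociationResult(outcome=outcome_col, table=table,
                             adjusted=adjusted, m=len(tables),
                             effect_label="OR")


def fit_cox_composite(tables, outcome: str = "composite7",
                      adjusted: bool = False) -> AssociationResult:
    """Per-class hazard ratios for a composite outcome vs the reference.

    Uses the partial likelihood with Efron tie handling; event/time
    column pairs follow the outcome-record conventions
    (``<outcome>_event``, ``<outcome>_time`` in days from AKI onset).
    """
    if isinstance(tables, pd.DataFrame):
        tables = [tables]
    ev_col, t_col = f"{outcome}_event", f"{outcome}_time"
    ests, variances, names = [], [], None
    for tab in tables:
        tab = tab[tab[ev_col].notna() & tab[t_col].notna()]
        if tab[ev_col].astype(float).sum() == 0:
            raise ValueError("no events: Cox model cannot be fitted")
        X = _class_dummies(tab)
        names = list(X.columns)
        if adjusted:
            X = pd.concat([X, _adjustment_design(tab)], axis=1)
        df = X.astype(float).copy()
        df["T"] = np.maximum(tab[t_col].astype(float), 1e-6)
        df["E"] = tab[ev_col].astype(float)
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                cph.fit(df, duration_col="T", event_col="E")
                params = cph.params_
                cov = pd.Series(np.diag(cph.variance_matrix_),
                                index=cph.params_.index)
            except Exception:
                params = pd.Series(np.nan, index=X.columns)
                cov = pd.Series(np.nan, index=X.columns)
        ests.append([params.get(n, np.nan) for n in names])
        variances.append([cov.get(n, np.nan) for n in names])
    classes = [int(n.split("_")[1]) for n in names]
    table = _pooled_rows(classes, np.asarray(ests, float),
                         np.asarray(variances, float), reference_label=1)
    return AssociationResult(outcome=outcome, table=table, adjusted=adjusted,
                             m=len(tables), effect_label="HR")


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

def km_curves(table: pd.DataFrame, outcome: str = "composite7") -> dict:
    """Product-limit survival estimates per assigned class.

    Returns {class: DataFrame(time, survival)}; step functions start at
    1 and censoring is handled by the standard Kaplan-Meier estimator.
    """
    ev_col, t_col = f"{outcome}_event", f"{outcome}_time"
    tab = table[table[ev_col].notna() & table[t_col].notna()]
    out = {}
    for g, grp in tab.groupby(CLASS_COL):
        kmf = KaplanMeierFitter()
        kmf.fit(np.maximum(grp[t_col].astype(float), 0.0),
                grp[ev_col].astype(float))
        sf = kmf.survival_function_
        out[int(g)] = pd.DataFrame({"time": sf.index.to_numpy(),
                                    "survival": sf.iloc[:, 0].to_numpy()})
    return out
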