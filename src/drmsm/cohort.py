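"""Reading, validation, cleaning and imputation of longitudinal DR cohorts.

A cohort is a long-format table, one row per clinic visit, carrying the
observed retinopathy stage (1 = no retinopathy ... 5 = PDR), baseline
demographics (age at initial exam, sex, ethnicity, diabetes duration,
hypertension and comorbidity indicators) and per-visit measurements
(annual mean HbA1c, systolic/diastolic blood pressure, anti-VEGF
injection count, best-corrected visual acuity in logMAR).

Cleaning follows the study conventions of the underlying chart-review
design: observed stage regressions are clamped by a running maximum
(progression is treated as irreversible), missing follow-up HbA1c is
carried forward from the last known value and missing baseline HbA1c
carried backward from the next known value, and missing diabetes
durations are imputed by ordinary least squares on baseline labs and
comorbidities.  Patients with fewer than 3 visits or under 2 years of
follow-up, or already in PDR at baseline, are flagged ineligible.
"""

from __future__ import annotations

import dataclasses
import math
import re
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ctmc import CovariateSchedule, ScheduleError

#: Covariates measured per visit (piecewise constant between visits).
TIME_DEPENDENT = ("hba1c", "sbp", "dbp", "anti_vegf_count")

#: Indicator covariates (never mean-centered).
BINARY_COVARIATES = frozenset(
    {"hispanic", "female", "hypertension", "dyslipidemia", "ckd", "mi", "cva"}
)

#: Canonical long-format columns.
VISIT_COLUMNS = ("hba1c", "sbp", "dbp", "anti_vegf_count", "bcva_logmar")
BASELINE_COLUMNS = (
    "age",
    "female",
    "hispanic",
    "dm_duration",
    "hypertension",
    "dyslipidemia",
    "ckd",
    "mi",
    "cva",
)
REQUIRED_COLUMNS = ("patient_id", "t", "stage")

_SNELLEN_CODES = {"CF": 1500.0, "HM": 4000.0, "LP": 8000.0, "NLP": 20000.0}


class SchemaError(ValueError):
    """The input table lacks required columns."""


class ImputationError(ValueError):
    """An imputation rule cannot be applied (e.g. no observed values)."""


class AcuityCodingError(ValueError):
    """Unrecognized visual-acuity token."""


@dataclass(frozen=True)
class VisitRecord:
    """One clinic visit: time in years from baseline, stage and measurements."""

    t: float
    stage: int
    hba1c: float = math.nan
    sbp: float = math.nan
    dbp: float = math.nan
    anti_vegf_count: float = math.nan
    bcva_logmar: float = math.nan


@dataclass
class PatientSeries:
    """One patient's ordered visits plus time-independent covariates."""

    patient_id: str
    visits: list[VisitRecord]
    age: float = math.nan
    female: float = math.nan
    hispanic: float = math.nan
    dm_duration: float = math.nan
    hypertension: float = math.nan
    extras: dict[str, float] = field(default_factory=dict)
    eligible: bool = True
    ineligible_reason: str | None = None
    n_clamped: int = 0
    uninformative: bool = False

    @property
    def times(self) -> np.ndarray:
        return np.array([v.t for v in self.visits])

    @property
    def stages(self) -> np.ndarray:
        return np.array([v.stage for v in self.visits], dtype=int)

    def visit_values(self, name: str) -> np.ndarray:
        return np.array([getattr(v, name) for v in self.visits])

    def baseline_value(self, name: str) -> float:
        if name in BASELINE_COLUMNS[:5]:
            return float(getattr(self, name))
        if name in self.extras:
            return float(self.extras[name])
        raise KeyError(f"unknown baseline covariate {name!r}")

    def has_baseline(self, name: str) -> bool:
        try:
            return not math.isnan(self.baseline_value(name))
        except KeyError:
            return False


@dataclass
class Cohort:
    """A list of patient series plus cohort-level metadata."""

    patients: list[PatientSeries]
    centering: dict[str, float] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)
    row_errors: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            raise ValueError("patient ids must be unique")

    def eligible_patients(self) -> list[PatientSeries]:
        return [p for p in self.patients if p.eligible]

    def __len__(self) -> int:
        return len(self.patients)

    def covariate_values(self, name: str) -> np.ndarray:
        """All observed values of a covariate (per patient, or per visit if time-dependent)."""
        if name in TIME_DEPENDENT:
            vals = np.concatenate([p.visit_values(name) for p in self.patients])
        else:
            vals = np.array(
                [
                    p.baseline_value(name) if p.has_baseline(name) else math.nan
                    for p in self.patients
                ]
            )
        return vals[~np.isnan(vals)]


# ---------------------------------------------------------------------------
# Visual acuity coding
# ---------------------------------------------------------------------------

def snellen_to_logmar(acuity: str) -> float:
    """Convert a Snellen fraction or low-vision code to logMAR.

    ``"20/X"`` maps to log10(X/20); the low-vision codes CF, HM, LP and
    NLP are coded as 20/1500, 20/4000, 20/8000 and 20/20000.
    """
    token = str(acuity).strip().upper()
    if token in _SNELLEN_CODES:
        denom = _SNELLEN_CODES[token]
    else:
        m = re.fullmatch(r"20\s*/\s*(\d+(?:\.\d+)?)", token)
        if not m or float(m.group(1)) <= 0:
            raise AcuityCodingError(f"unrecognized visual acuity token: {acuity!r}")
        denom = float(m.group(1))
    return math.log10(denom / 20.0)


# ---------------------------------------------------------------------------
# Reading and writing
# ---------------------------------------------------------------------------

def _validate_row(row: Mapping) -> str | None:
    try:
        t = float(row.get("t"))
    except (TypeError, ValueError):
        return f"unparseable visit time {row.get('t')!r}"
    if not np.isfinite(t) or t < 0:
        return f"visit time must be finite and >= 0, got {t!r}"
    stage = row.get("stage")
    try:
        s = float(stage)
    except (TypeError, ValueError):
        return f"unparseable stage {stage!r}"
    if not (s.is_integer() and 1 <= s <= 5):
        return f"stage must be an integer in 1..5, got {stage!r}"
    def num(name):
        try:
            v = float(row.get(name))
        except (TypeError, ValueError):
            return math.nan
        return v

    hba1c = num("hba1c")
    if np.isfinite(hba1c) and not 3.0 < hba1c < 25.0:
        return f"HbA1c out of plausible range (3, 25): {hba1c!r}"
    sbp, dbp = num("sbp"), num("dbp")
    if np.isfinite(sbp) and np.isfinite(dbp) and sbp <= dbp:
        return f"systolic BP must exceed diastolic, got {sbp}/{dbp}"
    return None


def _first_observed(series: pd.Series) -> float:
    vals = series.dropna()
    return float(vals.iloc[0]) if len(vals) else math.nan


def read_cohort(path, schema: Mapping[str, str] | None = None) -> Cohort:
    """Read and validate a long-format visit CSV into a :class:`Cohort`.

    Parameters
    ----------
    path : str or file-like
        CSV with one row per visit; empty cells or "NA" mark missing.
    schema : mapping, optional
        Canonical-name -> file-column-name overrides.

    Rows violating the visit invariants are dropped and collected into
    ``cohort.row_errors`` (with 1-based data line numbers); the
    remainder is loaded.  Eligibility requires at least 3 visits, at
    least 2 years of follow-up, and a baseline stage below PDR.
    """
    frame = pd.read_csv(path, na_values=["NA"], keep_default_na=True)
    if schema:
        rename = {file_col: canon for canon, file_col in schema.items()}
        frame = frame.rename(columns=rename)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")

    row_errors: list[dict] = []
    keep = np.ones(len(frame), dtype=bool)
    for i, row in frame.iterrows():
        msg = _validate_row(row)
        if msg is not None:
            row_errors.append({"line": int(i) + 2, "patient_id": row.get("patient_id"), "error": msg})
            keep[i] = False
    frame = frame[keep]

    patients: list[PatientSeries] = []
    for pid, grp in frame.groupby("patient_id", sort=True):
        grp = grp.sort_values("t")
        dup = grp["t"].duplicated()
        for i in grp.index[dup]:
            row_errors.append(
                {"line": int(i) + 2, "patient_id": pid, "error": "duplicate visit time"}
            )
        grp = grp[~dup.values]
        t = grp["t"].to_numpy(dtype=float)
        t = t - t[0]  # re-origin so the first visit is at t = 0
        visits = [
            VisitRecord(
                t=float(t[j]),
                stage=int(grp["stage"].iloc[j]),
                **{
                    c: float(grp[c].iloc[j]) if c in grp.columns and pd.notna(grp[c].iloc[j]) else math.nan
                    for c in VISIT_COLUMNS
                },
            )
            for j in range(len(grp))
        ]
        base = {
            c: _first_observed(grp[c]) if c in grp.columns else math.nan
            for c in BASELINE_COLUMNS
        }
        series = PatientSeries(
            patient_id=str(pid),
            visits=visits,
            age=base["age"],
            female=base["female"],
            hispanic=base["hispanic"],
            dm_duration=base["dm_duration"],
            hypertension=base["hypertension"],
            extras={c: base[c] for c in BASELINE_COLUMNS[5:]},
        )
        _flag_eligibility(series)
        patients.append(series)
    return Cohort(patients=patients, row_errors=row_errors)


def _flag_eligibility(series: PatientSeries) -> None:
    reasons = []
    if len(series.visits) < 3:
        reasons.append("fewer than 3 clinic visits")
    if series.visits and series.visits[-1].t - series.visits[0].t < 2.0:
        reasons.append("under 2 years of follow-up")
    if series.visits and series.visits[0].stage == 5:
        reasons.append("PDR at baseline")
    series.eligible = not reasons
    series.ineligible_reason = "; ".join(reasons) or None


def cohort_to_frame(cohort: Cohort) -> pd.DataFrame:
    rows = []
    for p in cohort.patients:
        for v in p.visits:
            row = {
                "patient_id": p.patient_id,
                "t": v.t,
                "stage": v.stage,
                "age": p.age,
                "female": p.female,
                "hispanic": p.hispanic,
                "dm_duration": p.dm_duration,
                "hypertension": p.hypertension,
            }
            row.update({c: p.extras.get(c, math.nan) for c in BASELINE_COLUMNS[5:]})
            row.update({c: getattr(v, c) for c in VISIT_COLUMNS})
            rows.append(row)
    return pd.DataFrame(rows)


def write_cohort(cohort: Cohort, path) -> None:
    """Write the cohort back to the long-format CSV dialect read_cohort accepts."""
    cohort_to_frame(cohort).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Cleaning and imputation
# ---------------------------------------------------------------------------

def enforce_monotone_stages(series: PatientSeries) -> PatientSeries:
    """Clamp observed stage regressions by the running maximum.

    Progression is treated as irreversible: once a stage is reached the
    patient is considered at least that severe at every later visit.
    The number of modified visits is recorded on the returned series.
    """
    stages = series.stages
    clamped = np.maximum.accumulate(stages)
    n_changed = int(np.sum(clamped != stages))
    visits = [
        dataclasses.replace(v, stage=int(s)) for v, s in zip(series.visits, clamped)
    ]
    return dataclasses.replace(series, visits=visits, n_clamped=series.n_clamped + n_changed)


def impute_hba1c(series: PatientSeries) -> PatientSeries:
    """Fill missing HbA1c: follow-up gaps carried forward, leading gaps carried backward."""
    vals = pd.Series(series.visit_values("hba1c"))
    if vals.isna().all():
        raise ImputationError(f"patient {series.patient_id}: no observed HbA1c value")
    filled = vals.ffill().bfill()
    visits = [
        dataclasses.replace(v, hba1c=float(h)) for v, h in zip(series.visits, filled)
    ]
    return dataclasses.replace(series, visits=visits)


#: Default predictors for the diabetes-duration imputation regression.
DM_IMPUTATION_PREDICTORS = ("hba1c", "sbp", "dbp", "dyslipidemia", "ckd", "mi", "cva")


def impute_dm_duration(
    cohort: Cohort, predictors: Sequence[str] = DM_IMPUTATION_PREDICTORS
) -> Cohort:
    """Impute missing diabetes durations by OLS on baseline labs and comorbidities.

    The regression is fit on complete cases; predictions for missing
    durations are floored at 0 years.  Baseline HbA1c/SBP/DBP are the
    first observed visit values.  Fitted coefficients are logged in
    ``cohort.metadata["dm_imputation"]``.
    """
    import statsmodels.api as sm

    def predictor_row(p: PatientSeries) -> list[float]:
        row = []
        for name in predictors:
            if name in TIME_DEPENDENT:
                vals = p.visit_values(name)
                vals = vals[~np.isnan(vals)]
                row.append(float(vals[0]) if len(vals) else math.nan)
            else:
                row.append(p.baseline_value(name) if p.has_baseline(name) else math.nan)
        return row

    missing = [p for p in cohort.patients if not p.has_baseline("dm_duration")]
    if not missing:
        return cohort

    X_rows, y = [], []
    for p in cohort.patients:
        if p.has_baseline("dm_duration"):
            row = predictor_row(p)
            if not any(math.isnan(v) for v in row):
                X_rows.append(row)
                y.append(p.dm_duration)
    if len(y) < 10:
        raise ImputationError(
            f"only {len(y)} complete cases for the duration regression (need >= 10)"
        )
    X_full = np.asarray(X_rows)
    # Constant predictors (e.g. a comorbidity absent from a small cohort)
    # carry no information and would only make the design singular.
    varying = [j for j in range(X_full.shape[1]) if np.ptp(X_full[:, j]) > 0]
    dropped_constant = [predictors[j] for j in range(X_full.shape[1]) if j not in varying]
    predictors = [predictors[j] for j in varying]
    X = sm.add_constant(X_full[:, varying], has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ImputationError(
            "singular design in duration regression; remove collinear predictors"
        )
    fit = sm.OLS(np.asarray(y), X).fit()

    n_floored = 0
    patients = []
    for p in cohort.patients:
        if not p.has_baseline("dm_duration"):
            row = predictor_row(p)
            if any(math.isnan(v) for v in row):
                raise ImputationError(
                    f"patient {p.patient_id}: incomplete predictors for duration imputation"
                )
            pred = float(fit.predict(np.concatenate([[1.0], row]))[0])
            if pred < 0:
                pred, n_floored = 0.0, n_floored + 1
            p = dataclasses.replace(p, dm_duration=pred)
        patients.append(p)
    out = dataclasses.replace(cohort, patients=patients)
    out.metadata = dict(cohort.metadata)
    out.metadata["dm_imputation"] = {
        "predictors": list(predictors),
        "dropped_constant": dropped_constant,
        "coefficients": fit.params.tolist(),
        "n_complete": len(y),
        "n_imputed": len(missing),
        "n_floored": n_floored,
    }
    return out


def prepare_cohort(cohort: Cohort) -> Cohort:
    """Standard cleaning pipeline: monotone stages, HbA1c fill, duration imputation.

    Returns a new cohort; the total number of clamped visits is stored
    in ``metadata["n_clamped_visits"]``.
    """
    patients = [impute_hba1c(enforce_monotone_stages(p)) for p in cohort.patients]
    out = dataclasses.replace(cohort, patients=patients)
    out.metadata = dict(cohort.metadata)
    out.metadata["n_clamped_visits"] = int(sum(p.n_clamped for p in patients))
    try:
        out = impute_dm_duration(out)
    except ImputationError as err:
        if any(not p.has_baseline("dm_duration") for p in out.patients):
            raise
        warnings.warn(str(err))
    return out


# ---------------------------------------------------------------------------
# Schedules
# ---------------------------------------------------------------------------

DEFAULT_SCHEDULE_COVARIATES = (
    "age",
    "dm_duration",
    "hispanic",
    "female",
    "hypertension",
    "hba1c",
    "sbp",
    "dbp",
    "anti_vegf_count",
)


def build_schedules(
    cohort: Cohort,
    covariates: Sequence[str] = DEFAULT_SCHEDULE_COVARIATES,
    eligible_only: bool = True,
) -> dict[str, CovariateSchedule]:
    """Per-patient piecewise-constant covariate schedules.

    Segment [t_j, t_{j+1}) carries the covariate vector observed at
    t_j; values are on the original scale (centering lives in the
    model).  Single-visit patients yield an empty segment list and are
    flagged ``uninformative``.
    """
    out: dict[str, CovariateSchedule] = {}
    for p in cohort.patients:
        if eligible_only and not p.eligible:
            continue
        times = p.times
        cols = []
        for name in covariates:
            if name in TIME_DEPENDENT:
                col = p.visit_values(name)
            else:
                col = np.full(len(times), p.baseline_value(name))
            if np.isnan(col).any():
                raise ImputationError(
                    f"patient {p.patient_id}: missing {name!r} values; impute before "
                    "building schedules"
                )
            cols.append(col)
        Z = np.column_stack(cols) if cols else np.zeros((len(times), 0))
        try:
            sched = CovariateSchedule.from_visits(times, Z, covariates)
        except ScheduleError as err:
            raise ScheduleError(f"patient {p.patient_id}: {err}") from err
        if sched.is_empty():
            p.uninformative = True
        out[p.patient_id] = sched
    return out
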