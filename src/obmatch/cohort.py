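"""Cohort container, schema, Charlson index and eligibility filtering.

A cohort is a long-format table with one row per subject: baseline
covariates recorded at dialysis initiation (the time origin) and event
times in days since that origin.  Optional times (transplant, death,
major adverse cardiac event) are absent when the event was not observed;
the administrative censoring time is always present.  Observed follow-up
is ``min(death_time, censor_time)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: CSV column order for cohort files.
COHORT_COLUMNS = [
    "id", "age", "sex", "modality", "insurance",
    "dm", "mi", "chf", "pvd", "cvd", "copd", "pud", "liver", "cancer",
    "cci", "tx_time", "death_time", "mace_time", "censor_time",
]

#: The nine recorded comorbidity flags.
COMORBIDITY_COLUMNS = ["dm", "mi", "chf", "pvd", "cvd", "copd", "pud", "liver", "cancer"]

#: Original Charlson weights restricted to the nine recorded conditions.
CHARLSON_WEIGHTS: Mapping[str, int] = {
    "dm": 1, "mi": 1, "chf": 1, "pvd": 1, "cvd": 1,
    "copd": 1, "pud": 1, "liver": 1, "cancer": 2,
}

#: Covariates entering the treatment-hazard (propensity) model.
PROPENSITY_COVARIATES = ["age", "sex", "modality", "insurance"] + COMORBIDITY_COLUMNS + ["cci"]

#: Adjustment set for outcome hazard models (Charlson index excluded to
#: avoid collinearity with its component flags and age).
OUTCOME_COVARIATES = ["age", "sex", "modality", "insurance"] + COMORBIDITY_COLUMNS

_TIME_COLUMNS = ["tx_time", "death_time", "mace_time", "censor_time"]
_OPTIONAL_TIME_COLUMNS = ["tx_time", "death_time", "mace_time"]

_CATEGORY_CODES = {
    "sex": {"F": 0, "M": 1},
    "modality": {"HD": 0, "PD": 1},
    "insurance": {"NHI": 0, "MedicalAid": 1},
}


@dataclass
class CohortTable:
    """A registry cohort: one row per subject plus generation provenance.

    Parameters
    ----------
    df : pandas.DataFrame
        Table with the columns in :data:`COHORT_COLUMNS`.
    meta : dict
        Generation parameters or source-file provenance.
    """

    df: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        validate_cohort_frame(self.df)

    def __len__(self) -> int:
        return len(self.df)

    def copy(self) -> "CohortTable":
        return CohortTable(self.df.copy(), dict(self.meta))

    @property
    def followup(self) -> pd.Series:
        """Observed follow-up in days: min(death_time, censor_time)."""
        return observed_followup(self.df)


def validate_cohort_frame(df: pd.DataFrame) -> None:
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort is missing required columns: {missing}")
    dup = df["id"][df["id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate subject id(s): {sorted(dup.unique().tolist())}")
    for col in _TIME_COLUMNS:
        vals = df[col].dropna()
        if len(vals) and (vals < 0).any():
            raise ValueError(f"negative times in column {col!r}")
    if df["censor_time"].isna().any():
        raise ValueError("censor_time must be present for every subject")


def observed_followup(df: pd.DataFrame) -> pd.Series:
    death = df["death_time"].fillna(np.inf)
    return np.minimum(death, df["censor_time"])


def compute_cci(comorbidities, age):
    """Charlson Comorbidity Index from the nine flags plus age points.

    The score is the sum of the original Charlson weights for the flags
    present (diabetes, MI, CHF, peripheral vascular disease,
    cerebrovascular disease, COPD, peptic ulcer, mild liver disease each
    1 point; any cancer 2 points) plus one age point per decade from age
    50, capped at 4 (50-59 -> 1, 60-69 -> 2, 70-79 -> 3, >=80 -> 4).

    Parameters
    ----------
    comorbidities : mapping or array-like
        Either a mapping ``{flag_name: 0/1}`` covering
        :data:`COMORBIDITY_COLUMNS`, or an array of shape ``(9,)`` or
        ``(n, 9)`` in that column order.
    age : int or array-like
        Age in years, non-negative.

    Returns
    -------
    int or numpy.ndarray
    """
    if isinstance(comorbidities, Mapping):
        flags = np.array([comorbidities[c] for c in COMORBIDITY_COLUMNS])
    else:
        flags = np.asarray(comorbidities)
    age_arr = np.asarray(age)
    if np.any(age_arr < 0):
        raise ValueError("age must be non-negative")
    if not np.isin(flags, (0, 1)).all():
        raise ValueError("comorbidity flags must be binary 0/1")
    weights = np.array([CHARLSON_WEIGHTS[c] for c in COMORBIDITY_COLUMNS])
    comorb_score = flags @ weights if flags.ndim > 1 else int(flags @ weights)
    age_points = np.clip((age_arr - 40) // 10, 0, 4).astype(int)
    score = comorb_score + age_points
    return int(score) if np.isscalar(age) and flags.ndim == 1 else score


def apply_min_survival_filter(cohort: CohortTable, min_days: int = 90) -> CohortTable:
    """Drop subjects whose observed follow-up is below ``min_days``.

    The boundary is inclusive: a subject followed exactly ``min_days``
    days is retained.  The input cohort is not modified and row order is
    preserved.  Subjects transplanted early are retained as long as
    their follow-up reaches the threshold; the filter is defined on
    survival, not on treatment timing.
    """
    if min_days < 0:
        raise ValueError("min_days must be >= 0")
    keep = observed_followup(cohort.df) >= min_days
    out = cohort.df.loc[keep].reset_index(drop=True)
    if out.empty:
        warnings.warn("minimum-survival filter removed every subject", stacklevel=2)
    meta = dict(cohort.meta)
    filters = list(meta.get("filters", []))
    filters.append({"min_survival_days": min_days, "n_removed": int((~keep).sum())})
    meta["filters"] = filters
    return CohortTable(out, meta)


def design_matrix(df: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    """Numeric design matrix for model fitting.

    Category columns are coded M=1/F=0 (sex), PD=1/HD=0 (modality),
    MedicalAid=1/NHI=0 (insurance); flags and numeric columns pass
    through unchanged.
    """
    cols = {}
    for name in covariates:
        if name not in df.columns:
            raise KeyError(f"covariate {name!r} not present in cohort")
        col = df[name]
        if name in _CATEGORY_CODES:
            codes = _CATEGORY_CODES[name]
            if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
                bad = set(col.unique()) - set(codes)
                if bad:
                    raise ValueError(f"unknown level(s) {sorted(bad)} in column {name!r}")
                col = col.map(codes)
        cols[name] = pd.to_numeric(col)
    return pd.DataFrame(cols, index=df.index).astype(float)


def read_cohort_csv(path) -> CohortTable:
    """Read a cohort CSV; empty optional-time fields parse as absent."""
    df = pd.read_csv(path, dtype={"sex": str, "modality": str, "insurance": str})
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df = df[COHORT_COLUMNS]
    for col in _TIME_COLUMNS + ["age", "cci"] + COMORBIDITY_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & coerced.isna()
        if bad.any():
            lines = (df.index[bad] + 2).tolist()  # header is line 1
            raise ValueError(f"{path}: non-numeric value in column {col!r} at line(s) {lines}")
        df[col] = coerced
    validate_cohort_frame(df)
    return CohortTable(df, meta={"source": str(path)})


def write_cohort_csv(cohort: CohortTable, path) -> None:
    """Write a cohort CSV; absent times become empty fields, times as integers."""
    df = cohort.df.copy()
    for col in _TIME_COLUMNS:
        df[col] = df[col].map(lambda v: "" if pd.isna(v) else str(int(v)))
    df.to_csv(path, index=False)
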