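"""Patient-level record schema and flat-file I/O.

A cohort is a :class:`pandas.DataFrame` with one row per patient. The columns
below are the shared vocabulary of every stage of the pipeline; covariate
columns beyond these are allowed and carried through untouched.

Two outcome conventions are stored side by side so that both the on-treatment
and intent-to-treat analyses can be derived from the same records:

* ``followup_months`` / ``event`` / ``censor_reason`` — on-treatment
  observation, i.e. follow-up ends at the earliest of progression-or-death,
  loss to follow-up, the administrative cap, or treatment discontinuation.
* ``itt_followup_months`` / ``itt_event`` / ``itt_censor_reason`` — the same
  patient followed past any non-progression treatment discontinuation.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

SOURCE_TRIAL = "trial"
SOURCE_RWD = "rwd"

CENSOR_NONE = "none"
CENSOR_ADMIN = "admin"
CENSOR_LOST = "lost"
CENSOR_DISCONTINUED = "discontinued"
CENSOR_REASONS = (CENSOR_NONE, CENSOR_ADMIN, CENSOR_LOST, CENSOR_DISCONTINUED)

ID_COLUMNS = ["patient_id", "source", "regimen", "clinic_id"]
OUTCOME_COLUMNS = [
    "followup_months",
    "event",
    "censor_reason",
    "itt_followup_months",
    "itt_event",
    "itt_censor_reason",
]

#: Baseline covariates used by the default membership (propensity) model:
#: demographics plus staging, cytogenetics, performance status, renal
#: function (dichotomized at 60 mL/min) and diagnosis-to-treatment interval.
FULL_COVARIATES = [
    "age",
    "female",
    "race_black",
    "iss_stage",
    "cyto_high",
    "ecog",
    "crcl_le60",
    "months_dx_to_lot1",
]

#: Demographics-only covariate set for the sensitivity analysis that omits
#: clinical covariates with high missingness from the weighting model.
DEMOGRAPHIC_COVARIATES = ["age", "female", "race_black"]

#: Covariates that are categorical with >2 levels (expanded to indicators in
#: design matrices and standardized-difference reports).
CATEGORICAL_COVARIATES = {"iss_stage": ("I", "II", "III"), "ecog": ("0", "1", "2")}

NA_TOKEN = "NA"


def is_categorical(column: str) -> bool:
    return column in CATEGORICAL_COVARIATES


def add_derived_columns(records: pd.DataFrame) -> pd.DataFrame:
    """Add analysis columns derived from raw covariates (in place-safe copy).

    Currently: ``crcl_le60`` (creatinine clearance ≤ 60 mL/min indicator,
    missing when ``crcl`` is missing) and ``age_ge75`` (age ≥ 75 indicator).
    """
    out = records.copy()
    if "crcl" in out.columns:
        crcl = pd.to_numeric(out["crcl"], errors="coerce")
        out["crcl_le60"] = np.where(crcl.isna(), np.nan, (crcl <= 60).astype(float))
    if "age" in out.columns:
        age = pd.to_numeric(out["age"], errors="coerce")
        out["age_ge75"] = np.where(age.isna(), np.nan, (age >= 75).astype(float))
    return out


def validate_records(records: pd.DataFrame, admin_cap_months: float | None = None) -> None:
    """Raise ``ValueError`` on schema violations.

    Checks the event/censor-reason consistency rule (an event implies no
    censoring reason) and, when a cap is given, that no follow-up exceeds it.
    """
    required = ["patient_id", "source", "regimen", "followup_months", "event", "censor_reason"]
    missing = [c for c in required if c not in records.columns]
    if missing:
        raise ValueError(f"records missing required columns: {missing}")
    bad_reason = set(records["censor_reason"].dropna()) - set(CENSOR_REASONS)
    if bad_reason:
        raise ValueError(f"unknown censor_reason values: {sorted(bad_reason)}")
    ev = records["event"].astype(int)
    if ((ev == 1) & (records["censor_reason"] != CENSOR_NONE)).any():
        raise ValueError("records with event=1 must have censor_reason='none'")
    if (records["followup_months"] <= 0).any():
        raise ValueError("followup_months must be positive")
    if admin_cap_months is not None and (records["followup_months"] > admin_cap_months + 1e-9).any():
        raise ValueError("followup_months exceeds admin_cap_months")


def write_cohort(records: pd.DataFrame, path: str | Path, metadata: dict | None = None) -> None:
    """Write a cohort as delimited text with an explicit NA token.

    A JSON side-car (``<path>.meta.json``) records run metadata (e.g. the
    generating seed) so a run is fully reconstructible from its outputs.
    """
    path = Path(path)
    records.to_csv(path, index=False, na_rep=NA_TOKEN)
    if metadata is not None:
        path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(metadata, indent=2, default=str))


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort written by :func:`write_cohort` (or any compatible CSV)."""
    df = pd.read_csv(path, na_values=[NA_TOKEN], keep_default_na=True, dtype={"clinic_id": "object"})
    for col in CATEGORICAL_COVARIATES:
        if col in df.columns:
            df[col] = df[col].astype("object").where(df[col].notna(), np.nan)
            df[col] = df[col].map(lambda v: v if pd.isna(v) else str(v))
    return df
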