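"""Harmonized inclusion/exclusion criteria with attrition accounting.

The same criteria are applied to both cohorts so that the trial and the
real-world source describe comparable populations before any weighting:
age-based transplant-ineligibility proxy, performance status, renal function,
response-assessment availability, lab bounds, comorbidity exclusions, and
(real-world only) restriction to regimens used by at least a minimum share
of patients.

A record missing the covariate a criterion reads is NOT excluded by that
criterion: eligibility precedes imputation, and clinical covariates are
imputed only for included patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .records import SOURCE_RWD

__all__ = ["EligibilityCriteria", "apply_eligibility", "regimen_share_filter"]


@dataclass
class EligibilityCriteria:
    """Criteria are evaluated in the order of the fields below; attrition is
    attributed to the first criterion a record fails."""

    min_age_years: float | None = 65.0
    max_ecog: int | None = 2
    min_crcl_ml_min: float | None = 30.0
    require_response_assessment: bool = False
    exclude_transplant_lot1: bool = False
    lab_bounds: dict[str, tuple[float | None, float | None]] = field(default_factory=dict)
    excluded_comorbidities: tuple[str, ...] = ()
    min_regimen_share: float | None = 0.10

    def __post_init__(self):
        if self.min_regimen_share is not None and not (0 <= self.min_regimen_share <= 1):
            raise ValueError("min_regimen_share must be in [0,1]")
        for lab, (lo, hi) in self.lab_bounds.items():
            if lo is not None and hi is not None and lo > hi:
                raise ValueError(f"lab bound for {lab!r} has lower > upper")


def _passes(records: pd.DataFrame, column: str, predicate) -> pd.Series:
    """Vector of pass flags; missing values pass (see module docstring)."""
    if column not in records.columns:
        raise ValueError(f"eligibility criterion references absent column {column!r}")
    col = records[column]
    ok = predicate(col)
    return ok | col.isna()


def apply_eligibility(
    records: pd.DataFrame, criteria: EligibilityCriteria
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter records; return (eligible records, attrition table).

    The attrition table has one row per active criterion, in application
    order, counting records excluded at their first failing criterion, plus
    'input' and 'eligible' bookend rows. The regimen-share restriction is
    applied last, on the population that passed all clinical criteria, and
    only to real-world records.
    """
    alive = pd.Series(True, index=records.index)
    rows: list[tuple[str, int]] = [("input", len(records))]

    def step(name: str, ok: pd.Series) -> None:
        nonlocal alive
        fail = alive & ~ok
        rows.append((name, int(fail.sum())))
        alive = alive & ok

    if criteria.min_age_years is not None:
        step(
            f"age >= {criteria.min_age_years:g}",
            _passes(records, "age", lambda c: pd.to_numeric(c, errors="coerce") >= criteria.min_age_years),
        )
    if criteria.exclude_transplant_lot1:
        step(
            "no transplant in first-line therapy",
            _passes(records, "transplant_lot1", lambda c: c.astype(float) == 0),
        )
    if criteria.max_ecog is not None:
        step(
            f"ECOG <= {criteria.max_ecog}",
            _passes(records, "ecog", lambda c: pd.to_numeric(c, errors="coerce") <= criteria.max_ecog),
        )
    if criteria.min_crcl_ml_min is not None:
        step(
            f"creatinine clearance >= {criteria.min_crcl_ml_min:g} mL/min",
            _passes(records, "crcl", lambda c: pd.to_numeric(c, errors="coerce") >= criteria.min_crcl_ml_min),
        )
    if criteria.require_response_assessment:
        step(
            ">=1 response assessment",
            _passes(records, "has_response_assessment", lambda c: c.astype(float) == 1),
        )
    for lab, (lo, hi) in criteria.lab_bounds.items():
        def pred(c, lo=lo, hi=hi):
            v = pd.to_numeric(c, errors="coerce")
            ok = pd.Series(True, index=c.index)
            if lo is not None:
                ok &= v >= lo
            if hi is not None:
                ok &= v <= hi
            return ok

        step(f"lab {lab} in bounds", _passes(records, lab, pred))
    for flag in criteria.excluded_comorbidities:
        step(f"no {flag}", _passes(records, flag, lambda c: c.astype(float) == 0))

    if criteria.min_regimen_share is not None and alive.any():
        clinical = records[alive]
        rwd = clinical[clinical["source"] == SOURCE_RWD]
        if len(rwd):
            keep = regimen_share_filter(rwd, criteria.min_regimen_share)
            ok = (records["source"] != SOURCE_RWD) | records["regimen"].isin(keep)
            step(f"regimen share >= {criteria.min_regimen_share:g}", ok)

    rows.append(("eligible", int(alive.sum())))
    attrition = pd.DataFrame(rows, columns=["criterion", "n"])
    return records[alive].copy(), attrition


def regimen_share_filter(records: pd.DataFrame, min_share: float) -> list[str]:
    """Regimen labels used by at least ``min_share`` of the given records."""
    if len(records) == 0:
        raise ValueError("records must be non-empty")
    shares = records["regimen"].value_counts(normalize=True)
    return sorted(shares.index[shares >= min_share])
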