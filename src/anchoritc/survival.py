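"""Outcome derivation and (weighted) Cox proportional-hazards estimation.

Progression-free survival can be analyzed under two conventions: the
on-treatment analysis censors follow-up at treatment discontinuation for
reasons other than progression or death, while the intent-to-treat analysis
ignores discontinuation and follows patients to event, loss to follow-up, or
the administrative cap. Hazard ratios come from Cox regression maximized by
lifelines' Newton scheme (tight convergence, see ``_FIT_OPTIONS``); weighted
fits use a robust sandwich variance with the weights treated as fixed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, CoxTimeVaryingFitter
from scipy import stats

from .weighting import _model_matrix

__all__ = [
    "OutcomeSpec",
    "HREstimate",
    "MonotoneLikelihoodError",
    "derive_outcome",
    "fit_cox",
    "ph_check",
    "subgroup_interaction",
]

Z95 = 1.96
_FIT_OPTIONS = {"precision": 1e-09, "max_steps": 500}


class MonotoneLikelihoodError(ValueError):
    """Cox partial likelihood has no finite maximizer (e.g. an arm without
    events, or a covariate perfectly ordering the event times)."""


@dataclass(frozen=True)
class OutcomeSpec:
    """Outcome convention and follow-up cap (months)."""

    convention: str = "on_treatment"  # or "itt"
    max_followup_months: float = 48.5
    endpoint: str = "pfs"

    def __post_init__(self):
        if self.convention not in ("on_treatment", "itt"):
            raise ValueError("convention must be 'on_treatment' or 'itt'")
        if self.max_followup_months <= 0:
            raise ValueError("max_followup_months must be > 0")


@dataclass(frozen=True)
class HREstimate:
    """One fitted direct comparison on the hazard-ratio scale."""

    comparison: tuple[str, str]  # (treatment, reference)
    source: str
    log_hr: float
    se_log_hr: float
    n: int
    events: int
    model: str
    p: float

    @property
    def hr(self) -> float:
        return float(np.exp(self.log_hr))

    @property
    def ci95(self) -> tuple[float, float]:
        return (
            float(np.exp(self.log_hr - Z95 * self.se_log_hr)),
            float(np.exp(self.log_hr + Z95 * self.se_log_hr)),
        )

    @property
    def anchor(self) -> str:
        return self.comparison[1]


def derive_outcome(records: pd.DataFrame, spec: OutcomeSpec) -> pd.DataFrame:
    """Analysis table with ``time`` and ``event`` columns per the convention.

    On-treatment uses the recorded follow-up (which already ends at
    discontinuation); intent-to-treat uses the extended ``itt_*`` columns.
    Any time beyond the cap is censored at the cap.
    """
    out = records.copy()
    if spec.convention == "on_treatment":
        t = out["followup_months"].astype(float).to_numpy()
        e = out["event"].astype(int).to_numpy()
    else:
        if "itt_followup_months" not in out.columns:
            raise ValueError("records lack itt_* columns required for the intent-to-treat convention")
        t = out["itt_followup_months"].astype(float).to_numpy()
        e = out["itt_event"].astype(int).to_numpy()
    if (t <= 0).any():
        raise ValueError("non-positive follow-up time")
    cap = spec.max_followup_months
    over = t > cap
    e = np.where(over, 0, e)
    t = np.minimum(t, cap)
    out["time"] = t
    out["event"] = e
    return out


def _check_arm_events(table: pd.DataFrame, treat_col: str) -> None:
    for arm, grp in table.groupby(treat_col):
        if grp["event"].sum() < 1:
            raise MonotoneLikelihoodError(f"no events in arm {treat_col}={arm!r}")


def _prepare(table, treat_col, weights, covariates):
    df = pd.DataFrame(
        {"time": table["time"].astype(float), "event": table["event"].astype(int)},
        index=table.index,
    )
    df[treat_col] = pd.to_numeric(table[treat_col]).astype(float)
    if covariates:
        X = _model_matrix(table, list(covariates))
        if X.isna().any().any():
            raise ValueError("covariate adjustment requires complete covariates")
        for c in X.columns:
            df[c] = X[c]
    robust = False
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if (w <= 0).any():
            raise ValueError("weights must be positive")
        df["_w"] = w
        robust = not np.allclose(w, 1.0)
    return df, robust


def fit_cox(
    table: pd.DataFrame,
    treatment: str = "treated",
    weights: pd.Series | np.ndarray | None = None,
    covariates: tuple[str, ...] = (),
    comparison: tuple[str, str] = ("treatment", "reference"),
    source: str = "",
) -> HREstimate:
    """Weighted Cox regression of (time, event) on a binary treatment
    indicator, optionally adjusted for baseline covariates (doubly robust
    when combined with propensity weights).

    The variance is the robust sandwich estimator whenever non-unit weights
    are supplied (weights treated as fixed), else the model-based variance.
    """
    _check_arm_events(table, treatment)
    df, robust = _prepare(table, treatment, weights, covariates)
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(
                df,
                duration_col="time",
                event_col="event",
                weights_col="_w" if "_w" in df else None,
                robust=robust,
                fit_options=_FIT_OPTIONS,
            )
    except Exception as exc:  # lifelines ConvergenceError and kin
        raise MonotoneLikelihoodError(str(exc)) from None
    beta = float(cph.params_[treatment])
    se = float(cph.standard_errors_[treatment])
    if not np.isfinite(beta) or not np.isfinite(se) or abs(beta) > 15:
        raise MonotoneLikelihoodError("Cox coefficient diverged (monotone likelihood)")
    if weights is None and not covariates:
        model = "unadjusted"
    elif covariates:
        model = "doubly_robust" if weights is not None else "adjusted"
    else:
        model = "weighted"
    return HREstimate(
        comparison=comparison,
        source=source,
        log_hr=beta,
        se_log_hr=se,
        n=len(df),
        events=int(df["event"].sum()),
        model=model,
        p=float(2 * stats.norm.sf(abs(beta) / se)),
    )


def _episodic(table: pd.DataFrame, treat_col: str, weights) -> pd.DataFrame:
    """Split each subject at the observed event times so a treatment × log(t)
    interaction can enter a time-varying Cox model."""
    t = table["time"].astype(float).to_numpy()
    e = table["event"].astype(int).to_numpy()
    x = pd.to_numeric(table[treat_col]).astype(float).to_numpy()
    w = np.ones(len(t)) if weights is None else np.asarray(weights, dtype=float)
    cuts = np.unique(t[e == 1])
    rows = []
    for i in range(len(t)):
        bounds = cuts[cuts < t[i]]
        starts = np.r_[0.0, bounds]
        stops = np.r_[bounds, t[i]]
        ev = np.zeros(len(stops), dtype=int)
        ev[-1] = e[i]
        for s0, s1, evk in zip(starts, stops, ev):
            rows.append((i, s0, s1, evk, x[i], x[i] * np.log(s1), w[i]))
    return pd.DataFrame(
        rows, columns=["id", "start", "stop", "event", treat_col, "_treat_logt", "_w"]
    )


def ph_check(
    table: pd.DataFrame,
    treatment: str = "treated",
    weights: pd.Series | np.ndarray | None = None,
) -> float:
    """Proportional-hazards diagnostic: Wald p-value of a treatment × log(time)
    interaction in an extended (episodic) Cox model. Report-only."""
    if table["event"].sum() < 2:
        raise ValueError("proportional-hazards check requires at least two events")
    _check_arm_events(table, treatment)
    long = _episodic(table, treatment, weights)
    ctv = CoxTimeVaryingFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ctv.fit(
            long,
            id_col="id",
            start_col="start",
            stop_col="stop",
            event_col="event",
            weights_col="_w",
            robust=weights is not None,
        )
    return float(ctv.summary.loc["_treat_logt", "p"])


def subgroup_interaction(
    table: pd.DataFrame,
    treatment: str = "treated",
    subgroup: str = "age_ge75",
    weights: pd.Series | np.ndarray | None = None,
    covariates: tuple[str, ...] = (),
    comparison: tuple[str, str] = ("treatment", "reference"),
    source: str = "",
) -> tuple[dict[int, HREstimate], float]:
    """Stratum-specific hazard ratios from a treatment × subgroup interaction
    parameterization, plus the Wald p-value of the interaction.

    Returns ``{0: HR in subgroup==0, 1: HR in subgroup==1}``.
    """
    sub = pd.to_numeric(table[subgroup]).astype(float)
    if sub.isna().any():
        raise ValueError("subgroup indicator must be complete")
    for s in (0, 1):
        stratum = table[sub == s]
        if len(stratum) == 0:
            raise ValueError(f"empty stratum {subgroup}={s}")
        _check_arm_events(stratum, treatment)
    df, robust = _prepare(table, treatment, weights, covariates)
    df["_sub"] = sub
    df["_treat_sub"] = df[treatment] * sub
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(
            df,
            duration_col="time",
            event_col="event",
            weights_col="_w" if "_w" in df else None,
            robust=robust,
            fit_options=_FIT_OPTIONS,
        )
    b = cph.params_
    V = cph.variance_matrix_
    b0 = float(b[treatment])
    se0 = float(np.sqrt(V.loc[treatment, treatment]))
    b1 = float(b[treatment] + b["_treat_sub"])
    se1 = float(
        np.sqrt(
            V.loc[treatment, treatment]
            + V.loc["_treat_sub", "_treat_sub"]
            + 2 * V.loc[treatment, "_treat_sub"]
        )
    )
    bi = float(b["_treat_sub"])
    sei = float(np.sqrt(V.loc["_treat_sub", "_treat_sub"]))
    p_int = float(2 * stats.norm.sf(abs(bi) / sei))
    model = "doubly_robust" if (covariates and weights is not None) else ("weighted" if weights is not None else "unadjusted")

    def mk(s, beta, se):
        stratum = table[sub == s]
        return HREstimate(
            comparison=comparison,
            source=source,
            log_hr=beta,
            se_log_hr=se,
            n=len(stratum),
            events=int(stratum["event"].sum()),
            model=model,
            p=float(2 * stats.norm.sf(abs(beta) / se)),
        )

    return {0: mk(0, b0, se0), 1: mk(1, b1, se1)}, p_int
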