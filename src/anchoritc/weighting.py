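"""Propensity-score weighting of real-world groups to a trial population.

Each real-world treatment group is reweighted to resemble the (pooled-arm)
trial population: a logistic model for trial membership is fit on the pooled
sample of trial patients plus the one group, and each group patient receives
the odds weight w = p/(1-p) of its fitted trial-membership probability — the
weight-to-target-population estimand with the trial as target. Balance is
diagnosed with standardized differences; |SMD| > 0.1 is flagged as a
meaningful imbalance calling for doubly robust estimation downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .records import CATEGORICAL_COVARIATES

__all__ = [
    "WeightSet",
    "BalanceReport",
    "PerfectSeparationError",
    "fit_membership_model",
    "odds_weights",
    "standardized_difference",
    "balance_report",
]


class PerfectSeparationError(ValueError):
    """Membership model separated; carries the offending covariate name."""

    def __init__(self, covariate: str):
        self.covariate = covariate
        super().__init__(f"perfect separation in membership model on covariate {covariate!r}")


@dataclass
class WeightSet:
    """Per-patient weights for one real-world treatment group."""

    group: str
    weights: pd.Series
    normalized: bool
    ess: float

    def __post_init__(self):
        if (self.weights <= 0).any():
            raise ValueError("weights must be positive")


@dataclass
class BalanceReport:
    """Before/after standardized differences per covariate (indicator-expanded)
    per group; ``flagged`` lists covariates with |weighted SMD| > threshold."""

    table: pd.DataFrame  # columns: group, covariate, smd_unweighted, smd_weighted
    flag_threshold: float = 0.1
    flagged: dict[str, list[str]] = field(default_factory=dict)


def expand_covariates(df: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Expand categoricals into one indicator column per level; continuous and
    binary covariates pass through as numeric columns."""
    out = {}
    for col in covariates:
        if col in CATEGORICAL_COVARIATES:
            for lev in CATEGORICAL_COVARIATES[col]:
                out[f"{col}={lev}"] = (df[col] == lev).astype(float)
        else:
            out[col] = pd.to_numeric(df[col], errors="coerce").astype(float)
    return pd.DataFrame(out, index=df.index)


def _model_matrix(df: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Full-rank design (categoricals drop the reference level)."""
    expanded = expand_covariates(df, covariates)
    drop = [f"{c}={CATEGORICAL_COVARIATES[c][0]}" for c in covariates if c in CATEGORICAL_COVARIATES]
    return expanded.drop(columns=drop)


def _find_separating_covariate(X: pd.DataFrame, y: np.ndarray) -> str:
    for col in X.columns:
        x = X[col].to_numpy()
        if len(np.unique(x)) <= 10:  # indicator-like: a level unique to one class
            for v in np.unique(x):
                sel = x == v
                if sel.any() and (y[sel].min() == y[sel].max()) and sel.sum() > 0:
                    if y[sel].min() != y.mean():  # pure level
                        return col.split("=")[0]
        else:  # continuous: disjoint supports
            if x[y == 1].min() > x[y == 0].max() or x[y == 0].min() > x[y == 1].max():
                return col.split("=")[0]
    return X.columns[0].split("=")[0]


def fit_membership_model(
    trial: pd.DataFrame, group: pd.DataFrame, covariates: list[str]
) -> pd.Series:
    """Probability of trial membership for every patient in trial ∪ group.

    Logistic regression of the trial indicator on the covariates over the
    pooled sample; refit per (imputed dataset × real-world group) by callers.
    Raises :class:`PerfectSeparationError` naming the offending covariate when
    the model separates.
    """
    if len(trial) == 0 or len(group) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = pd.concat([trial, group], ignore_index=False)
    X = _model_matrix(pooled, covariates)
    if X.isna().any().any():
        raise ValueError("membership model requires complete covariates (impute first)")
    y = np.r_[np.ones(len(trial)), np.zeros(len(group))]
    design = sm.add_constant(X.to_numpy())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
        except Exception:
            raise PerfectSeparationError(_find_separating_covariate(X, y)) from None
    params = np.asarray(fit.params)
    if not np.all(np.isfinite(params)) or np.abs(params[1:]).max(initial=0.0) > 15:
        raise PerfectSeparationError(_find_separating_covariate(X, y))
    p = np.clip(fit.predict(design), 1e-12, 1 - 1e-12)
    return pd.Series(p, index=pooled.index, name="p_trial")


def odds_weights(
    probabilities: pd.Series, group: str = "", normalize: bool = True, truncate_pct: float | None = None
) -> WeightSet:
    """Odds weights w = p/(1−p) for the real-world group's membership
    probabilities, optionally percentile-truncated, then normalized so the
    weights sum to the group's unweighted n."""
    p = np.asarray(probabilities, dtype=float)
    if not ((p > 0) & (p < 1)).all():
        raise ValueError("membership probabilities must be strictly in (0, 1)")
    w = p / (1 - p)
    if truncate_pct is not None:
        hi = np.percentile(w, truncate_pct)
        w = np.minimum(w, hi)
    if normalize:
        w = w * len(w) / w.sum()
    ess = float(w.sum() ** 2 / (w**2).sum())
    return WeightSet(group=group, weights=pd.Series(w, index=probabilities.index), normalized=normalize, ess=ess)


def standardized_difference(
    target: pd.Series,
    group: pd.Series,
    group_weights: pd.Series | np.ndarray | None = None,
    kind: str = "continuous",
) -> float:
    """Standardized mean difference, target minus group.

    continuous: (m̄_t − m̄_g)/√((s_t² + s_g²)/2), with the group moments
    weighted when weights are given; binary indicators use the two-proportion
    pooled-variance form. Raises on zero pooled variance.
    """
    x_t = pd.to_numeric(target, errors="coerce").to_numpy().astype(float)
    x_g = pd.to_numeric(group, errors="coerce").to_numpy().astype(float)
    w = np.ones(len(x_g)) if group_weights is None else np.asarray(group_weights, dtype=float)
    m_g = np.average(x_g, weights=w)
    if kind == "binary":
        p_t, p_g = x_t.mean(), m_g
        pooled = (p_t * (1 - p_t) + p_g * (1 - p_g)) / 2
    elif kind == "continuous":
        # Σw(x−m)²/(Σw−1): reduces to the ddof=1 sample variance under unit
        # weights, keeping the SMD exactly antisymmetric in that case
        v_g = float((w * (x_g - m_g) ** 2).sum() / (w.sum() - 1))
        pooled = (x_t.var(ddof=1) + v_g) / 2
    else:
        raise ValueError("kind must be 'continuous' or 'binary'")
    if pooled <= 0:
        raise ValueError("zero pooled variance; standardized difference undefined")
    return float((x_t.mean() - m_g) / np.sqrt(pooled))


def _smd_kind(column: str, values: pd.Series) -> str:
    if "=" in column:
        return "binary"
    vals = set(pd.unique(values.dropna()))
    return "binary" if vals <= {0, 1, 0.0, 1.0} else "continuous"


def balance_report(
    trial: pd.DataFrame,
    groups: dict[str, tuple[pd.DataFrame, WeightSet | None]],
    covariates: list[str],
    threshold: float = 0.1,
) -> BalanceReport:
    """Standardized differences of every (indicator-expanded) covariate for
    each group against the trial, unweighted and weighted; flags groups whose
    weighted |SMD| exceeds the threshold on any covariate."""
    t_exp = expand_covariates(trial, covariates)
    rows = []
    flagged: dict[str, list[str]] = {}
    for label, (gdf, wset) in groups.items():
        g_exp = expand_covariates(gdf, covariates)
        w = None if wset is None else wset.weights.loc[gdf.index]
        for col in t_exp.columns:
            kind = _smd_kind(col, t_exp[col])
            smd_u = standardized_difference(t_exp[col], g_exp[col], None, kind)
            smd_w = smd_u if w is None else standardized_difference(t_exp[col], g_exp[col], w, kind)
            rows.append({"group": label, "covariate": col, "smd_unweighted": smd_u, "smd_weighted": smd_w})
            if abs(smd_w) > threshold:
                flagged.setdefault(label, []).append(col)
    return BalanceReport(table=pd.DataFrame(rows), flag_threshold=threshold, flagged=flagged)
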