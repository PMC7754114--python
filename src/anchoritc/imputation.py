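"""Multiple imputation by chained equations and Rubin's-rules pooling.

Missing baseline covariates are imputed m times (default 10) by cycling
through covariates with missing values, each regressed on all other baseline
covariates plus the event indicator and log follow-up time (the standard
predictor set when the downstream analysis is a survival model). Continuous
covariates use predictive-mean matching with k = 5 donors; binary and
multi-level categorical covariates are drawn from fitted (multinomial)
logistic probabilities. Observed cells are never altered.

Downstream estimates computed once per imputed dataset are pooled with
:func:`pool_rubin` on the scale they were estimated on (log hazard ratios in
this pipeline).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LinearRegression, LogisticRegression

from .records import CATEGORICAL_COVARIATES, add_derived_columns

__all__ = ["ImputedDatasets", "PooledEstimate", "mice_impute", "pool_rubin"]


@dataclass
class ImputedDatasets:
    """m completed copies of the input records (identical on observed cells)."""

    m: int
    datasets: list[pd.DataFrame]
    seed: int
    model_spec: dict[str, str] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.datasets)


@dataclass
class PooledEstimate:
    """Rubin's-rules combination of m point estimates and variances.

    total_var = within_var + (1 + 1/m)·between_var; degrees of freedom from
    Rubin's small-sample formula (infinite when between_var = 0, in which
    case the pooled interval collapses to the naive normal interval).
    """

    point: float
    within_var: float
    between_var: float
    total_var: float
    df: float
    ci: tuple[float, float]
    p: float
    m: int

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total_var))


def _design_matrix(df: pd.DataFrame, columns: list[str]) -> np.ndarray:
    """Numeric design matrix: continuous/binary as-is, categoricals one-hot
    (reference level dropped)."""
    parts = []
    for col in columns:
        if col in CATEGORICAL_COVARIATES:
            levels = CATEGORICAL_COVARIATES[col]
            for lev in levels[1:]:
                parts.append((df[col] == lev).astype(float).to_numpy())
        else:
            parts.append(pd.to_numeric(df[col], errors="coerce").to_numpy().astype(float))
    return np.column_stack(parts)


def _pmm_draw(
    pred_obs: np.ndarray, y_obs: np.ndarray, pred_mis: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Type-0 predictive-mean matching: for each missing prediction, draw one
    of the k observed cases with nearest predicted mean."""
    order = np.argsort(pred_obs)
    sorted_pred = pred_obs[order]
    pos = np.searchsorted(sorted_pred, pred_mis)
    k = min(k, len(y_obs))
    out = np.empty(len(pred_mis))
    for i, (pm, p0) in enumerate(zip(pred_mis, pos)):
        lo = max(0, p0 - k)
        hi = min(len(sorted_pred), p0 + k)
        window = order[lo:hi]
        dist = np.abs(pred_obs[window] - pm)
        donors = window[np.argsort(dist)[:k]]
        out[i] = y_obs[donors[rng.integers(len(donors))]]
    return out


def mice_impute(
    records: pd.DataFrame,
    covariates: list[str],
    m: int = 10,
    n_cycles: int = 10,
    seed: int = 0,
    k_pmm: int = 5,
    extra_predictors: list[str] | None = None,
) -> ImputedDatasets:
    """Chained-equations imputation of ``covariates`` in ``records``.

    ``extra_predictors`` are fully observed columns used as predictors only
    (default: ``event`` and log ``followup_months`` when present). Raises on a
    covariate that is entirely missing or a categorical with a single
    observed level (its conditional model would be degenerate).
    """
    for col in covariates:
        if col not in records.columns:
            raise ValueError(f"unknown covariate {col!r}")
    if extra_predictors is None:
        extra_predictors = []
        if "event" in records.columns:
            extra_predictors.append("event")
        if "followup_months" in records.columns:
            records = records.copy()
            records["_log_fu"] = np.log(records["followup_months"].astype(float))
            extra_predictors.append("_log_fu")

    miss_mask = {c: records[c].isna() for c in covariates}
    targets = [c for c in covariates if miss_mask[c].any()]
    for col in targets:
        if miss_mask[col].all():
            raise ValueError(f"covariate {col!r} is entirely missing")
        obs = records.loc[~miss_mask[col], col]
        if col in CATEGORICAL_COVARIATES or obs.nunique() <= 2:
            if obs.nunique() < 2:
                raise ValueError(f"covariate {col!r} has a single observed level")
    if not any((~miss_mask[c]).all() for c in covariates):
        raise ValueError("at least one covariate must be fully observed")

    model_spec = {
        c: ("multinomial" if (c in CATEGORICAL_COVARIATES or records[c].dropna().nunique() <= 2) else f"pmm(k={k_pmm})")
        for c in targets
    }

    datasets = []
    for d in range(m):
        rng = np.random.default_rng([seed, d])
        work = records.copy()
        # initial fill: random draws from the observed marginal
        for col in targets:
            mis = miss_mask[col]
            obs_vals = work.loc[~mis, col].to_numpy()
            work.loc[mis, col] = rng.choice(obs_vals, size=int(mis.sum()))
        for _ in range(n_cycles):
            for col in targets:
                mis = miss_mask[col].to_numpy()
                predictors = [c for c in covariates if c != col] + extra_predictors
                X = _design_matrix(work, predictors)
                y = work[col]
                if model_spec[col].startswith("pmm"):
                    y_num = pd.to_numeric(y, errors="coerce").to_numpy().astype(float)
                    reg = LinearRegression().fit(X[~mis], y_num[~mis])
                    pred = reg.predict(X)
                    work.loc[mis, col] = _pmm_draw(
                        pred[~mis], y_num[~mis], pred[mis], k_pmm, rng
                    )
                else:
                    y_obs = y[~mis].astype(str).to_numpy()
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        clf = LogisticRegression(max_iter=500).fit(X[~mis], y_obs)
                    proba = clf.predict_proba(X[mis])
                    cum = np.cumsum(proba, axis=1)
                    idx = (rng.uniform(size=len(proba))[:, None] > cum).sum(axis=1)
                    drawn = clf.classes_[idx]
                    if col not in CATEGORICAL_COVARIATES:
                        drawn = drawn.astype(float)
                    work.loc[mis, col] = drawn
        work = work.drop(columns=["_log_fu"], errors="ignore")
        datasets.append(add_derived_columns(work))

    return ImputedDatasets(m=m, datasets=datasets, seed=seed, model_spec=model_spec)


def pool_rubin(estimates: list[float], variances: list[float]) -> PooledEstimate:
    """Combine per-imputation estimates and squared SEs by Rubin's rules.

    The confidence interval and two-sided p use a t reference with Rubin's
    degrees of freedom df = (m−1)(1 + W/((1+1/m)B))²; with zero
    between-imputation variance this degenerates to the normal interval.
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    if q.shape != u.shape or q.ndim != 1:
        raise ValueError("estimates and variances must be equal-length 1-D sequences")
    m = len(q)
    if m < 2:
        raise ValueError("Rubin pooling requires m >= 2")
    if (u <= 0).any():
        raise ValueError("variances must be positive")
    point = float(q.mean())
    within = float(u.mean())
    between = float(q.var(ddof=1))
    total = within + (1 + 1 / m) * between
    se = np.sqrt(total)
    if between == 0:
        df = np.inf
        crit = 1.96  # normal-approximation convention used pipeline-wide
        p = 2 * stats.norm.sf(abs(point) / se)
    else:
        r = (1 + 1 / m) * between / within
        df = (m - 1) * (1 + 1 / r) ** 2
        crit = stats.t.ppf(0.975, df)
        p = 2 * stats.t.sf(abs(point) / se, df)
    return PooledEstimate(
        point=point,
        within_var=within,
        between_var=between,
        total_var=float(total),
        df=float(df),
        ci=(point - crit * se, point + crit * se),
        p=float(p),
        m=m,
    )
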