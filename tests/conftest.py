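import numpy as np
import pandas as pd
import pytest

from anchoritc import SimulationConfig, default_config, simulate_cohorts


def breslow_partial_loglik(beta: np.ndarray, t, e, x, w=None) -> np.ndarray:
    """Hand-written weighted Cox partial log-likelihood (Breslow) for a single
    covariate, evaluated on a grid of beta values. Independent oracle for
    fit_cox on tiny datasets."""
    t = np.asarray(t, float)
    e = np.asarray(e, int)
    x = np.asarray(x, float)
    w = np.ones_like(t) if w is None else np.asarray(w, float)
    beta = np.atleast_1d(np.asarray(beta, float))
    ll = np.zeros(len(beta))
    exb = np.exp(np.outer(beta, x))  # (B, n)
    for i in np.flatnonzero(e):
        risk = t >= t[i]
        ll += w[i] * (beta * x[i] - np.log((w[risk] * exb[:, risk]).sum(axis=1)))
    return ll


def grid_cox_mle(t, e, x, w=None, lo=-5.0, hi=5.0, step=1e-4) -> float:
    grid = np.arange(lo, hi + step / 2, step)
    ll = breslow_partial_loglik(grid, t, e, x, w)
    return float(grid[np.argmax(ll)])


@pytest.fixture(scope="session")
def small_sim_config() -> SimulationConfig:
    return default_config(
        n_trial_per_arm=150,
        n_rwd_per_regimen={"VRd": 150, "Rd": 150, "Vd": 120},
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_sim_config) -> pd.DataFrame:
    return simulate_cohorts(small_sim_config)


def toy_records(rows) -> pd.DataFrame:
    """Build a minimal record table from (time, event, censor_reason, itt_time,
    itt_event, itt_reason) tuples plus default identifiers."""
    df = pd.DataFrame(
        rows,
        columns=[
            "followup_months",
            "event",
            "censor_reason",
            "itt_followup_months",
            "itt_event",
            "itt_censor_reason",
        ],
    )
    df.insert(0, "patient_id", [f"x{i}" for i in range(len(df))])
    df.insert(1, "source", "trial")
    df.insert(2, "regimen", "A")
    return df
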