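"""Outcome derivation and Cox estimation against independent oracles."""

import numpy as np
import pandas as pd
import pytest

from anchoritc import (
    MonotoneLikelihoodError,
    OutcomeSpec,
    derive_outcome,
    fit_cox,
    ph_check,
    subgroup_interaction,
)
from conftest import grid_cox_mle, toy_records


def surv_table(t, e, x, **extra):
    df = pd.DataFrame({"time": t, "event": e, "treated": x})
    for k, v in extra.items():
        df[k] = v
    return df


# ---------------------------------------------------------------- outcomes


def test_derive_outcome_rules():
    records = toy_records(
        [
            (10.0, 1, "none", 10.0, 1, "none"),          # event within cap
            (6.0, 0, "discontinued", 20.0, 0, "lost"),   # stops treatment, later lost
            (50.0, 1, "none", 50.0, 1, "none"),          # event beyond cap
        ]
    )
    # records carry a >48.5-month follow-up only to exercise the cap rule
    ot = derive_outcome(records, OutcomeSpec("on_treatment", 48.5))
    assert list(ot["time"]) == [10.0, 6.0, 48.5]
    assert list(ot["event"]) == [1, 0, 0]
    itt = derive_outcome(records, OutcomeSpec("itt", 48.5))
    assert list(itt["time"]) == [10.0, 20.0, 48.5]
    assert list(itt["event"]) == [1, 0, 0]


def test_cap_consistency():
    records = toy_records([(10.0, 1, "none", 10.0, 1, "none"), (30.0, 0, "lost", 30.0, 0, "lost")])
    a = derive_outcome(records, OutcomeSpec("on_treatment", 48.5))
    b = derive_outcome(records, OutcomeSpec("on_treatment", 1000.0))
    pd.testing.assert_frame_equal(a, b)


def test_nonpositive_time_rejected():
    records = toy_records([(0.0, 1, "none", 0.0, 1, "none")])
    with pytest.raises(ValueError, match="non-positive"):
        derive_outcome(records, OutcomeSpec())


# ---------------------------------------------------------------- Cox fits


def test_two_event_closed_form():
    """Treated {event at 1, censored 3}, control {event at 2, censored 3}:
    the partial likelihood is maximized at e^beta = sqrt(2)."""
    table = surv_table([1.0, 3.0, 2.0, 3.0], [1, 0, 1, 0], [1, 1, 0, 0])
    est = fit_cox(table, "treated")
    assert est.log_hr == pytest.approx(np.log(np.sqrt(2)), abs=1e-6)
    assert est.hr == pytest.approx(np.sqrt(2), abs=1e-5)
    lo, hi = est.ci95
    assert lo == pytest.approx(np.exp(est.log_hr - 1.96 * est.se_log_hr))
    assert hi == pytest.approx(np.exp(est.log_hr + 1.96 * est.se_log_hr))


@pytest.mark.parametrize("seed", range(6))
def test_matches_grid_search_oracle(seed):
    """On tiny datasets the fit agrees with a brute-force maximizer of the
    hand-written partial likelihood to 1e-3, with and without weights."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 9))
    t = np.round(rng.exponential(10, n), 3) + 0.5 + np.arange(n) * 1e-3  # tie-free
    e = rng.integers(0, 2, n)
    x = rng.integers(0, 2, n)
    if e[x == 1].sum() == 0 or e[x == 0].sum() == 0:
        e[np.argmax(x)] = 1
        e[np.argmin(x)] = 1
    w = np.round(rng.uniform(0.5, 2.0, n), 2)
    table = surv_table(t, e, x)
    oracle = grid_cox_mle(t, e, x)
    if abs(oracle) > 4.9:  # boundary: no finite maximizer, covered elsewhere
        with pytest.raises(MonotoneLikelihoodError):
            fit_cox(table, "treated")
        return
    assert fit_cox(table, "treated").log_hr == pytest.approx(oracle, abs=1e-3)
    assert fit_cox(table, "treated", weights=w).log_hr == pytest.approx(
        grid_cox_mle(t, e, x, w), abs=1e-3
    )


def test_unit_weights_equal_unweighted():
    rng = np.random.default_rng(7)
    n = 120
    table = surv_table(rng.exponential(12, n), rng.integers(0, 2, n), rng.integers(0, 2, n))
    a = fit_cox(table, "treated")
    b = fit_cox(table, "treated", weights=np.ones(n))
    assert a.log_hr == pytest.approx(b.log_hr, abs=1e-8)
    assert a.se_log_hr == pytest.approx(b.se_log_hr, abs=1e-8)


def test_time_scale_invariance():
    rng = np.random.default_rng(8)
    n = 80
    t = rng.exponential(12, n)
    e = rng.integers(0, 2, n)
    x = rng.integers(0, 2, n)
    a = fit_cox(surv_table(t, e, x), "treated")
    b = fit_cox(surv_table(t * 7.3, e, x), "treated")
    assert a.log_hr == pytest.approx(b.log_hr, abs=1e-8)


def test_monotone_likelihood_signalled():
    # no events in the treated arm
    table = surv_table([1.0, 2.0, 3.0, 4.0], [0, 0, 1, 1], [1, 1, 0, 0])
    with pytest.raises(MonotoneLikelihoodError):
        fit_cox(table, "treated")
    # constant covariate
    table2 = surv_table([1.0, 2.0, 3.0, 4.0], [1, 0, 1, 0], [1, 1, 1, 1])
    with pytest.raises(MonotoneLikelihoodError):
        fit_cox(table2, "treated")


def test_doubly_robust_model_label():
    rng = np.random.default_rng(9)
    n = 150
    table = surv_table(
        rng.exponential(12, n), rng.integers(0, 2, n), rng.integers(0, 2, n),
        age=rng.normal(74, 5, n),
    )
    est = fit_cox(table, "treated", weights=rng.uniform(0.5, 2, n), covariates=("age",))
    assert est.model == "doubly_robust"
    assert np.isfinite(est.se_log_hr)


# ------------------------------------------------------- diagnostics


def test_ph_check_detects_crossing_hazards():
    """Opposite treatment effects before and after t0 inflate the
    treatment x log(time) interaction far beyond noise."""
    rng = np.random.default_rng(10)
    n = 400
    x = np.repeat([0, 1], n // 2)
    # treated: high early hazard, low late hazard
    t = np.where(
        x == 1,
        np.where(rng.uniform(size=n) < 0.5, rng.exponential(2, n), 8 + rng.exponential(30, n)),
        rng.exponential(12, n),
    )
    e = (t < 40).astype(int)
    t = np.minimum(t, 40)
    p = ph_check(surv_table(t, e, x), "treated")
    assert p < 0.01


def test_ph_check_null_calibration():
    """Under proportional hazards the interaction test rejects at roughly its
    nominal 5% level."""
    rejections = 0
    n_rep = 120
    for seed in range(n_rep):
        rng = np.random.default_rng(1000 + seed)
        n = 60
        x = np.repeat([0, 1], n // 2)
        t = rng.exponential(np.where(x == 1, 8.0, 12.0))
        e = (t < 25).astype(int)
        t = np.minimum(t, 25)
        if e[x == 1].sum() < 2 or e[x == 0].sum() < 2:
            continue
        if ph_check(surv_table(t, e, x), "treated") < 0.05:
            rejections += 1
    assert 0.005 < rejections / n_rep < 0.12


def test_ph_check_single_event_rejected():
    table = surv_table([1.0, 2.0, 3.0, 4.0], [1, 0, 0, 0], [1, 1, 0, 0])
    with pytest.raises(ValueError):
        ph_check(table, "treated")


# ------------------------------------------------------- subgroups


def _interaction_data(delta, n=4000, seed=11):
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, n)
    sub = rng.integers(0, 2, n)
    lp = x * (-0.6 + delta * sub)
    t = rng.exponential(np.exp(-lp) * 12)
    e = (t < 40).astype(int)
    return surv_table(np.minimum(t, 40), e, x, age_ge75=sub.astype(float))


def test_subgroup_interaction_recovery():
    """A constructed 0.5 log-HR difference between age strata is recovered
    and flagged by the interaction test at large n."""
    table = _interaction_data(delta=0.5)
    strata, p_int = subgroup_interaction(table, "treated", "age_ge75")
    diff = strata[1].log_hr - strata[0].log_hr
    se = np.sqrt(strata[0].se_log_hr ** 2 + strata[1].se_log_hr ** 2)
    assert diff == pytest.approx(0.5, abs=3 * se)
    assert p_int < 0.01
    assert strata[0].log_hr == pytest.approx(-0.6, abs=3 * strata[0].se_log_hr)


def test_subgroup_null_interaction():
    table = _interaction_data(delta=0.0, seed=12)
    strata, p_int = subgroup_interaction(table, "treated", "age_ge75")
    se = np.sqrt(strata[0].se_log_hr ** 2 + strata[1].se_log_hr ** 2)
    assert abs(strata[1].log_hr - strata[0].log_hr) < 3 * se
    assert p_int > 0.01


def test_subgroup_empty_stratum_rejected():
    table = _interaction_data(delta=0.0, n=100, seed=13)
    table["age_ge75"] = 0.0
    with pytest.raises(ValueError, match="stratum"):
        subgroup_interaction(table, "treated", "age_ge75")
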