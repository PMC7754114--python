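"""Generator checks: determinism, accounting, effect recovery, missingness."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from anchoritc import (
    SimulationConfig,
    apply_missingness,
    default_config,
    fit_cox,
    simulate_cohorts,
)
from anchoritc.records import CENSOR_NONE, SOURCE_RWD, validate_records
from anchoritc.survival import OutcomeSpec, derive_outcome


def test_same_seed_reproduces_exactly(small_sim_config, small_cohort):
    again = simulate_cohorts(small_sim_config)
    pd.testing.assert_frame_equal(small_cohort, again)


def test_record_invariants(small_cohort, small_sim_config):
    validate_records(small_cohort, admin_cap_months=small_sim_config.admin_cap_months)
    # censoring accounting: non-events are partitioned among censor reasons
    non_events = (small_cohort["event"] == 0).sum()
    reasons = small_cohort.loc[small_cohort["event"] == 0, "censor_reason"].value_counts()
    assert reasons.sum() == non_events
    assert CENSOR_NONE not in reasons.index
    # trial records carry only the two randomized arms
    trial_regs = set(small_cohort.loc[small_cohort["source"] == "trial", "regimen"])
    assert trial_regs == {"DRd", "Rd"}


def test_null_config_gives_null_hazard_ratios():
    """With all true effects, shifts and confounding off, every arm's Cox HR
    against the anchor is compatible with 1."""
    cfg = default_config(
        n_trial_per_arm=600,
        n_rwd_per_regimen={"VRd": 600, "Rd": 600, "Vd": 600},
        true_log_hr={"DRd": 0.0, "VRd": 0.0, "Vd": 0.0, "Rd": 0.0},
        prognostic_coefs={},
        prognostic_shift={},
        assignment_coefs={},
        dropout_rate={},
        discontinuation_rate={},
        missing_rates={},
        trial_missing_rates={},
        seed=21,
    )
    df = derive_outcome(simulate_cohorts(cfg), OutcomeSpec())
    for source, reg in [("trial", "DRd"), ("rwd", "VRd"), ("rwd", "Vd")]:
        pair = df[(df["source"] == source) & (df["regimen"].isin([reg, "Rd"]))].copy()
        pair["treated"] = (pair["regimen"] == reg).astype(int)
        est = fit_cox(pair, "treated", comparison=(reg, "Rd"), source=source)
        assert abs(est.log_hr) < 3 * est.se_log_hr


def test_true_hazard_ratio_recovery():
    """A 0.54 conditional HR is recovered by an unweighted Cox fit at large n
    when covariates carry no prognostic weight."""
    cfg = default_config(
        n_trial_per_arm=4000,
        n_rwd_per_regimen={"Rd": 5},
        prognostic_coefs={},
        prognostic_shift={},
        assignment_coefs={},
        discontinuation_rate={},
        missing_rates={},
        trial_missing_rates={},
        seed=33,
    )
    df = derive_outcome(simulate_cohorts(cfg), OutcomeSpec())
    trial = df[df["source"] == "trial"].copy()
    trial["treated"] = (trial["regimen"] == "DRd").astype(int)
    est = fit_cox(trial, "treated", comparison=("DRd", "Rd"), source="trial")
    assert est.log_hr == pytest.approx(np.log(0.54), abs=3 * est.se_log_hr)


def test_monotone_in_true_effect():
    """Raising a regimen's true log HR raises its estimated log HR."""
    ests = []
    for hr in (0.5, 1.0, 1.8):
        cfg = default_config(
            n_trial_per_arm=1500,
            n_rwd_per_regimen={"Rd": 5},
            true_log_hr={"DRd": np.log(hr), "Rd": 0.0},
            prognostic_coefs={},
            prognostic_shift={},
            assignment_coefs={},
            discontinuation_rate={},
            missing_rates={},
            trial_missing_rates={},
            seed=44,
        )
        df = derive_outcome(simulate_cohorts(cfg), OutcomeSpec())
        trial = df[df["source"] == "trial"].copy()
        trial["treated"] = (trial["regimen"] == "DRd").astype(int)
        ests.append(fit_cox(trial, "treated").log_hr)
    assert ests[0] < ests[1] < ests[2]


def test_missingness_zero_rate_is_identity(small_cohort):
    out = apply_missingness(small_cohort, {"age": 0.0, "ecog": 0.0}, "mcar", seed=1)
    pd.testing.assert_frame_equal(out, small_cohort)


def test_mcar_rate_realized():
    """A 47% MCAR rate on stage lands within binomial error at n=10000."""
    cfg = default_config(
        n_trial_per_arm=10,
        n_rwd_per_regimen={"Rd": 10000},
        missing_rates={},
        trial_missing_rates={},
        assignment_coefs={},
        seed=3,
    )
    df = simulate_cohorts(cfg)
    out = apply_missingness(df, {"iss_stage": 0.47}, "mcar", seed=9, source=SOURCE_RWD)
    frac = out.loc[out["source"] == SOURCE_RWD, "iss_stage"].isna().mean()
    assert frac == pytest.approx(0.47, abs=0.01)


def test_mar_missingness_depends_on_age():
    """Under the MAR mechanism, a logistic fit of the missingness indicator
    on age recovers the configured slope sign and the target marginal rate."""
    cfg = default_config(
        n_trial_per_arm=10,
        n_rwd_per_regimen={"Rd": 8000},
        missing_rates={},
        trial_missing_rates={},
        assignment_coefs={},
        seed=4,
    )
    df = simulate_cohorts(cfg)
    out = apply_missingness(
        df, {"ecog": 0.40}, "mar", seed=10, source=SOURCE_RWD, mar_slope=1.0
    )
    rwd = out[out["source"] == SOURCE_RWD]
    miss = rwd["ecog"].isna().astype(int)
    assert miss.mean() == pytest.approx(0.40, abs=0.02)
    fit = sm.Logit(miss.to_numpy(), sm.add_constant(rwd["age"].to_numpy())).fit(disp=0)
    assert fit.params[1] > 0
    assert fit.pvalues[1] < 1e-4


def test_missingness_unknown_covariate_rejected(small_cohort):
    with pytest.raises(ValueError, match="unknown covariate"):
        apply_missingness(small_cohort, {"not_a_column": 0.1}, "mcar", seed=0)


@pytest.mark.parametrize(
    "overrides",
    [
        {"n_trial_per_arm": 0},
        {"admin_cap_months": -1.0},
        {"missing_rates": {"age": 1.0}},
        {"missing_rates": {"nope": 0.1}},
        {"n_rwd_per_regimen": {"VRd": -5}},
        {"dropout_rate": {"rwd": -0.1}},
    ],
)
def test_invalid_configs_rejected(overrides):
    with pytest.raises(ValueError):
        SimulationConfig(**overrides)


def test_anchor_absent_everywhere_rejected():
    with pytest.raises(ValueError, match="anchor"):
        SimulationConfig(anchor="DRd", trial_experimental="DRd", n_rwd_per_regimen={"VRd": 10})
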