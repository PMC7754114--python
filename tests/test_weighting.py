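"""Membership model, odds weights, standardized differences, balance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from anchoritc import (
    PerfectSeparationError,
    balance_report,
    default_config,
    fit_membership_model,
    odds_weights,
    simulate_cohorts,
    standardized_difference,
)
from anchoritc.records import SOURCE_RWD, SOURCE_TRIAL


def binary_frame(n, n_ones):
    return pd.DataFrame({"x": [1.0] * n_ones + [0.0] * (n - n_ones)})


def test_membership_logit_recovers_closed_form():
    """A single binary covariate with prevalence 0.6 (trial) vs 0.4 (group):
    the fitted log-odds difference equals log((0.6/0.4)/(0.4/0.6))."""
    trial = binary_frame(1000, 600)
    group = binary_frame(1000, 400)
    p = fit_membership_model(trial, group, ["x"])
    # recover the slope from two fitted probabilities
    p1 = p.iloc[:600].iloc[0]
    p0 = p.iloc[600:1000].iloc[0]
    slope = np.log(p1 / (1 - p1)) - np.log(p0 / (1 - p0))
    expected = np.log((0.6 / 0.4) / (0.4 / 0.6))
    assert slope == pytest.approx(expected, abs=1e-5)
    assert ((p > 0) & (p < 1)).all()


def test_identical_distributions_give_flat_probabilities():
    rng = np.random.default_rng(0)
    trial = pd.DataFrame({"x": rng.normal(size=800)})
    group = pd.DataFrame({"x": rng.normal(size=400)})
    p = fit_membership_model(trial, group, ["x"])
    prevalence = 800 / 1200
    assert p.mean() == pytest.approx(prevalence, abs=0.02)
    assert p.std() < 0.05


def test_separation_names_the_covariate():
    trial = pd.DataFrame({"x": np.r_[np.zeros(50), np.ones(50)], "sep": np.zeros(100)})
    group = pd.DataFrame({"x": np.r_[np.zeros(30), np.ones(30)], "sep": np.ones(60)})
    with pytest.raises(PerfectSeparationError, match="sep"):
        fit_membership_model(trial, group, ["x", "sep"])


def test_odds_weights_hand_example():
    ws = odds_weights(pd.Series([0.5, 0.8]), group="g")
    assert list(ws.weights) == [pytest.approx(0.4), pytest.approx(1.6)]
    assert ws.ess == pytest.approx(4 / 2.72, abs=5e-3)  # 1.47
    assert ws.normalized
    assert ws.weights.sum() == pytest.approx(2.0)


def test_constant_probabilities_give_unit_weights():
    ws = odds_weights(pd.Series([0.5] * 10))
    assert np.allclose(ws.weights, 1.0)
    assert ws.ess == pytest.approx(10.0)


def test_out_of_range_probabilities_rejected():
    with pytest.raises(ValueError):
        odds_weights(pd.Series([0.5, 1.0]))


@settings(max_examples=60, deadline=None)
@given(st.lists(st.floats(0.01, 0.99), min_size=2, max_size=40))
def test_ess_bounds(probs):
    ws = odds_weights(pd.Series(probs))
    n = len(probs)
    assert ws.ess <= n + 1e-9
    if np.allclose(probs, probs[0]):
        assert ws.ess == pytest.approx(n)


def test_smd_reference_values():
    a = pd.Series([1.0, 2.0, 3.0])
    assert standardized_difference(a, a.copy()) == 0.0
    rng = np.random.default_rng(1)
    t = pd.Series(rng.normal(1.0, 1.0, size=200000))
    g = pd.Series(rng.normal(0.0, 1.0, size=200000))
    assert standardized_difference(t, g) == pytest.approx(1.0, abs=0.01)
    # binary form: p_t=0.6, p_g=0.4 -> 0.2/sqrt(0.24)
    tb = pd.Series([1.0] * 60 + [0.0] * 40)
    gb = pd.Series([1.0] * 40 + [0.0] * 60)
    assert standardized_difference(tb, gb, kind="binary") == pytest.approx(0.2 / np.sqrt(0.24))


def test_smd_antisymmetry_and_zero_variance():
    rng = np.random.default_rng(2)
    t = pd.Series(rng.normal(0.3, 1.2, size=300))
    g = pd.Series(rng.normal(0.0, 0.8, size=200))
    assert standardized_difference(t, g) == pytest.approx(-standardized_difference(g, t))
    with pytest.raises(ValueError, match="variance"):
        standardized_difference(pd.Series([1.0, 1.0]), pd.Series([1.0, 1.0]))


def test_balance_report_flags_shifted_covariate_only():
    rng = np.random.default_rng(3)
    n = 4000
    trial = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
    group = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(0.3, 1, size=n)})
    rep = balance_report(trial, {"g": (group, None)}, ["a", "b"])
    assert rep.flagged == {"g": ["b"]}
    tab = rep.table.set_index("covariate")
    assert abs(tab.loc["b", "smd_unweighted"]) > 0.25
    assert abs(tab.loc["a", "smd_unweighted"]) < 0.1


def test_weighting_reduces_imbalance_across_configs():
    """Over 50 simulated configs with moderate covariate shifts, odds
    weighting reduces the maximum absolute standardized difference on the
    modeled covariates."""
    covs = ["age", "female", "iss_stage", "ecog", "crcl_le60"]
    reduced = 0
    for seed in range(50):
        rng = np.random.default_rng(seed)
        cfg = default_config(
            n_trial_per_arm=200,
            n_rwd_per_regimen={"Rd": 350},
            prognostic_shift={
                "age": rng.uniform(-1.5, 1.5),
                "female": rng.uniform(-0.1, 0.1),
                "crcl": rng.uniform(-6, 6),
            },
            assignment_coefs={},
            missing_rates={},
            trial_missing_rates={},
            seed=seed,
        )
        df = simulate_cohorts(cfg)
        trial = df[df["source"] == SOURCE_TRIAL]
        group = df[df["source"] == SOURCE_RWD]
        p = fit_membership_model(trial, group, covs)
        ws = odds_weights(p.loc[group.index], group="Rd")
        rep = balance_report(trial, {"Rd": (group, ws)}, covs)
        if rep.table["smd_weighted"].abs().max() < rep.table["smd_unweighted"].abs().max():
            reduced += 1
    assert reduced >= 48
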