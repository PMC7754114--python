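"""Paired trial / real-world cohort simulation for anchored comparisons.

The generator emulates the statistical structure that an anchored indirect
treatment comparison of progression-free survival relies on:

* a randomized two-arm trial (experimental regimen vs the anchor doublet) and
  a real-world cohort treated with several regimens including the anchor,
  sharing a common baseline-covariate vocabulary (age, sex, race, ISS stage,
  cytogenetic risk, ECOG performance status, creatinine clearance, months
  from diagnosis to first-line therapy);
* proportional-hazards event times from a Weibull baseline with regimen
  effects and optional treatment × covariate effect modification;
* competing censoring processes — an administrative follow-up cap, loss to
  follow-up, and non-progression treatment discontinuation (more frequent in
  the real-world source, where treat-to-progression protocols do not apply);
* physician-style confounded treatment assignment in the real-world source;
* missing-at-random baseline covariates at configurable per-covariate rates.

All times are continuous months; given a seed, output is reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .records import (
    CENSOR_ADMIN,
    CENSOR_DISCONTINUED,
    CENSOR_LOST,
    CENSOR_NONE,
    SOURCE_RWD,
    SOURCE_TRIAL,
    add_derived_columns,
)

__all__ = [
    "Covariate",
    "WeibullHazard",
    "SimulationConfig",
    "default_covariates",
    "default_config",
    "simulate_cohorts",
    "apply_missingness",
]


@dataclass(frozen=True)
class Covariate:
    """Marginal distribution of one baseline covariate.

    kind 'continuous' draws from a normal (``dist='normal'``, truncated below
    at ``lower``) or gamma (``dist='gamma'``, parameterized by mean/sd);
    'binary' draws Bernoulli(``p``); 'categorical' draws from ``levels`` with
    ``probs``.
    """

    name: str
    kind: str
    mean: float | None = None
    sd: float | None = None
    dist: str = "normal"
    lower: float | None = None
    p: float | None = None
    levels: tuple[str, ...] | None = None
    probs: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.kind not in ("continuous", "binary", "categorical"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        if self.kind == "continuous" and (self.mean is None or self.sd is None or self.sd <= 0):
            raise ValueError(f"continuous covariate {self.name!r} needs mean and sd > 0")
        if self.kind == "binary" and not (self.p is not None and 0 <= self.p <= 1):
            raise ValueError(f"binary covariate {self.name!r} needs p in [0,1]")
        if self.kind == "categorical":
            if not self.levels or not self.probs or len(self.levels) != len(self.probs):
                raise ValueError(f"categorical covariate {self.name!r} needs matching levels/probs")
            if abs(sum(self.probs) - 1.0) > 1e-8:
                raise ValueError(f"categorical covariate {self.name!r} probs must sum to 1")


@dataclass(frozen=True)
class WeibullHazard:
    """Weibull event-time law, S(t) = exp(-(t/scale)^shape · e^lp).

    shape 1 is the exponential special case. Sampling is by closed-form
    inversion: t = scale · (-ln U · e^{-lp})^{1/shape}.
    """

    scale: float = 43.0
    shape: float = 1.0

    def __post_init__(self):
        if self.scale <= 0 or self.shape <= 0:
            raise ValueError("Weibull scale and shape must be positive")

    def sample(self, lp: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        u = rng.uniform(size=lp.shape)
        return self.scale * (-np.log(u) * np.exp(-lp)) ** (1.0 / self.shape)


def default_covariates() -> tuple[Covariate, ...]:
    """Baseline covariate marginals of a transplant-ineligible newly diagnosed
    multiple myeloma population (elderly, mixed staging, mostly ECOG 0-1)."""
    return (
        Covariate("age", "continuous", mean=74.3, sd=5.3, lower=65.0),
        Covariate("female", "binary", p=0.48),
        Covariate("race_black", "binary", p=0.035),
        Covariate("iss_stage", "categorical", levels=("I", "II", "III"), probs=(0.27, 0.44, 0.29)),
        Covariate("cyto_high", "binary", p=0.145),
        Covariate("ecog", "categorical", levels=("0", "1", "2"), probs=(0.35, 0.49, 0.16)),
        Covariate("crcl", "continuous", mean=64.0, sd=22.0, lower=15.0),
        Covariate("months_dx_to_lot1", "continuous", mean=1.4, sd=1.6, dist="gamma"),
    )


@dataclass
class SimulationConfig:
    """Full generative specification of one paired-cohort simulation.

    ``true_log_hr`` is on the log-hazard scale versus the anchor regimen; the
    anchor itself is fixed at 0 by construction. ``effect_modifier_coefs``
    multiply centered covariate codes interacted with "any active treatment
    vs anchor". ``prognostic_coefs`` are main effects of centered covariates
    on the log hazard (needed for confounded real-world assignment to bias
    anything). ``prognostic_shift`` shifts real-world covariate means
    (continuous: additive to the mean; binary: additive to p).

    Rates are per-month hazards of independent exponential processes.
    Categorical coefficient keys use ``"name:level"``, e.g. ``"ecog:2"``.
    """

    n_trial_per_arm: int = 358
    n_rwd_per_regimen: dict[str, int] = field(
        default_factory=lambda: {"VRd": 570, "Rd": 432, "Vd": 358}
    )
    trial_experimental: str = "DRd"
    anchor: str = "Rd"
    covariates: tuple[Covariate, ...] = field(default_factory=default_covariates)
    true_log_hr: dict[str, float] = field(
        default_factory=lambda: {
            "DRd": math.log(0.54),
            "VRd": math.log(0.80),
            "Vd": math.log(1.14),
            "Rd": 0.0,
        }
    )
    effect_modifier_coefs: dict[str, float] = field(default_factory=dict)
    prognostic_coefs: dict[str, float] = field(
        default_factory=lambda: {
            "age": 0.03,
            "iss_stage:II": 0.25,
            "iss_stage:III": 0.50,
            "ecog:1": 0.20,
            "ecog:2": 0.45,
            "cyto_high": 0.50,
        }
    )
    prognostic_shift: dict[str, float] = field(
        default_factory=lambda: {"age": 0.5, "crcl": -3.0}
    )
    assignment_coefs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "VRd": {"age": -0.04, "ecog:2": -0.5},
            "Vd": {"age": 0.02, "crcl": -0.01, "ecog:2": 0.3},
        }
    )
    baseline_hazard: WeibullHazard = field(default_factory=WeibullHazard)
    admin_cap_months: float = 48.5
    dropout_rate: dict[str, float] = field(
        default_factory=lambda: {SOURCE_TRIAL: 0.002, SOURCE_RWD: 0.008}
    )
    discontinuation_rate: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            SOURCE_TRIAL: {"DRd": 0.004, "Rd": 0.004},
            SOURCE_RWD: {"VRd": 0.045, "Rd": 0.025, "Vd": 0.035},
        }
    )
    missing_rates: dict[str, float] = field(
        default_factory=lambda: {
            "race_black": 0.08,
            "cyto_high": 0.30,
            "ecog": 0.40,
            "iss_stage": 0.47,
            "crcl": 0.20,
        }
    )
    trial_missing_rates: dict[str, float] = field(default_factory=lambda: {"cyto_high": 0.13})
    missing_mechanism: str = "mar"
    event_detection_prob: dict[str, float] = field(default_factory=dict)
    clinic_count: int = 25
    clinic_disc_sd: float = 0.4
    jitter: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.n_trial_per_arm <= 0:
            raise ValueError("n_trial_per_arm must be > 0")
        if any(n <= 0 for n in self.n_rwd_per_regimen.values()):
            raise ValueError("real-world regimen counts must be > 0")
        if self.admin_cap_months <= 0:
            raise ValueError("admin_cap_months must be > 0")
        # the anchor arm exists in the trial unless both arms are the same
        # experimental label; in that degenerate case it must appear in the
        # real-world regimen set for any anchored comparison to be possible
        if self.trial_experimental == self.anchor and self.anchor not in self.n_rwd_per_regimen:
            raise ValueError("anchor regimen absent from both sources")
        names = {c.name for c in self.covariates}
        for key in list(self.missing_rates) + list(self.trial_missing_rates):
            if key not in names:
                raise ValueError(f"missing rate for unknown covariate {key!r}")
        for rates in (self.missing_rates, self.trial_missing_rates):
            for k, r in rates.items():
                if not (0 <= r < 1):
                    raise ValueError(f"missing rate for {k!r} must be in [0,1)")
        for src, r in self.dropout_rate.items():
            if r < 0:
                raise ValueError(f"dropout rate for {src!r} must be >= 0")
        for src, per_reg in self.discontinuation_rate.items():
            if any(r < 0 for r in per_reg.values()):
                raise ValueError(f"discontinuation rates for {src!r} must be >= 0")
        if self.missing_mechanism not in ("mcar", "mar"):
            raise ValueError("missing_mechanism must be 'mcar' or 'mar'")
        # the anchor is the reference: its log HR is 0 by construction
        self.true_log_hr = dict(self.true_log_hr)
        self.true_log_hr[self.anchor] = 0.0


def default_config(**overrides) -> SimulationConfig:
    """Study-condition defaults with keyword overrides."""
    return replace(SimulationConfig(), **overrides)


# ---------------------------------------------------------------------------
# covariate drawing and numeric coding


def _draw_covariates(
    covariates: tuple[Covariate, ...],
    n: int,
    rng: np.random.Generator,
    shifts: dict[str, float] | None = None,
) -> pd.DataFrame:
    shifts = shifts or {}
    cols: dict[str, np.ndarray] = {}
    for cov in covariates:
        shift = shifts.get(cov.name, 0.0)
        if cov.kind == "continuous":
            mean = cov.mean + shift
            if cov.dist == "gamma":
                # match mean/sd: shape k = (mean/sd)^2, scale = sd^2/mean
                k = (mean / cov.sd) ** 2
                x = rng.gamma(k, cov.sd**2 / mean, size=n)
            else:
                x = rng.normal(mean, cov.sd, size=n)
            if cov.lower is not None:
                # resample-free truncation: reflect values below the bound
                x = np.where(x < cov.lower, 2 * cov.lower - x, x)
                x = np.maximum(x, cov.lower)
            cols[cov.name] = x
        elif cov.kind == "binary":
            p = min(max(cov.p + shift, 0.0), 1.0)
            cols[cov.name] = (rng.uniform(size=n) < p).astype(float)
        else:
            idx = rng.choice(len(cov.levels), size=n, p=np.asarray(cov.probs))
            cols[cov.name] = np.asarray(cov.levels, dtype=object)[idx]
    return pd.DataFrame(cols)


def _centered_codes(
    df: pd.DataFrame, covariates: tuple[Covariate, ...]
) -> dict[str, np.ndarray]:
    """Numeric codes keyed like coefficient dicts, centered at the generating
    marginals so the anchor-arm baseline linear predictor averages ~0."""
    codes: dict[str, np.ndarray] = {}
    for cov in covariates:
        x = df[cov.name].to_numpy()
        if cov.kind == "continuous":
            codes[cov.name] = x.astype(float) - cov.mean
        elif cov.kind == "binary":
            codes[cov.name] = x.astype(float) - cov.p
        else:
            for lev, p in zip(cov.levels, cov.probs):
                codes[f"{cov.name}:{lev}"] = (x == lev).astype(float) - p
    return codes


def _linear_predictor(codes: dict[str, np.ndarray], coefs: dict[str, float], n: int) -> np.ndarray:
    lp = np.zeros(n)
    for key, beta in coefs.items():
        if key not in codes:
            raise ValueError(f"coefficient references unknown covariate code {key!r}")
        lp += beta * codes[key]
    return lp


def _calibrated_assignment(
    codes: dict[str, np.ndarray],
    regimens: list[str],
    targets: np.ndarray,
    assignment_coefs: dict[str, dict[str, float]],
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Multinomial-logistic assignment with intercepts calibrated so the mean
    assignment probabilities match the target regimen shares."""
    eta = np.column_stack(
        [_linear_predictor(codes, assignment_coefs.get(r, {}), n) for r in regimens]
    )
    alpha = np.log(targets)
    for _ in range(200):
        z = eta + alpha
        z -= z.max(axis=1, keepdims=True)
        p = np.exp(z)
        p /= p.sum(axis=1, keepdims=True)
        shares = p.mean(axis=0)
        if np.max(np.abs(shares - targets)) < 1e-10:
            break
        alpha += np.log(targets / shares)
    draw = rng.uniform(size=n)
    cum = np.cumsum(p, axis=1)
    idx = (draw[:, None] > cum).sum(axis=1)
    return np.asarray(regimens, dtype=object)[idx]


def _exp_or_inf(rate: float, n: int, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return np.full(n, np.inf)
    return rng.exponential(1.0 / rate, size=n)


# ---------------------------------------------------------------------------
# main entry points


def simulate_cohorts(config: SimulationConfig, seed: int | None = None) -> pd.DataFrame:
    """Generate the paired trial + real-world cohort as one record table.

    Trial patients are randomized 1:1 between the experimental regimen and
    the anchor; real-world assignment follows the configured multinomial
    logistic on covariates with intercepts calibrated to the target regimen
    shares (realized counts are therefore multinomial around the targets
    when confounding coefficients are nonzero, exact otherwise).
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    frames = []

    # --- trial: exact 1:1 randomization
    n_tr = 2 * config.n_trial_per_arm
    trial = _draw_covariates(config.covariates, n_tr, rng)
    arms = np.array(
        [config.trial_experimental, config.anchor] * config.n_trial_per_arm, dtype=object
    )
    trial["regimen"] = rng.permutation(arms)
    trial["source"] = SOURCE_TRIAL
    trial["clinic_id"] = np.nan
    frames.append(trial)

    # --- real-world: confounded (or quota) assignment, shifted covariates
    rwd_regimens = list(config.n_rwd_per_regimen)
    n_rw = int(sum(config.n_rwd_per_regimen.values()))
    rwd = _draw_covariates(config.covariates, n_rw, rng, shifts=config.prognostic_shift)
    targets = np.array([config.n_rwd_per_regimen[r] / n_rw for r in rwd_regimens])
    if any(config.assignment_coefs.get(r) for r in rwd_regimens):
        codes = _centered_codes(rwd, config.covariates)
        rwd["regimen"] = _calibrated_assignment(
            codes, rwd_regimens, targets, config.assignment_coefs, n_rw, rng
        )
    else:
        quota = np.repeat(
            np.asarray(rwd_regimens, dtype=object),
            [config.n_rwd_per_regimen[r] for r in rwd_regimens],
        )
        rwd["regimen"] = rng.permutation(quota)
    rwd["source"] = SOURCE_RWD
    clinic_labels = np.array([f"C{i:02d}" for i in range(1, config.clinic_count + 1)], dtype=object)
    rwd["clinic_id"] = rng.choice(clinic_labels, size=n_rw)
    frames.append(rwd)

    df = pd.concat(frames, ignore_index=True)
    n = len(df)
    df.insert(0, "patient_id", [f"P{i:05d}" for i in range(1, n + 1)])

    # --- event times under Weibull proportional hazards
    codes = _centered_codes(df, config.covariates)
    treated = (df["regimen"] != config.anchor).to_numpy().astype(float)
    lp = _linear_predictor(codes, config.prognostic_coefs, n)
    lp += treated * _linear_predictor(codes, config.effect_modifier_coefs, n)
    lp += df["regimen"].map(config.true_log_hr).to_numpy().astype(float)
    event_time = config.baseline_hazard.sample(lp, rng)

    # --- competing censoring processes
    src = df["source"].to_numpy()
    dropout = np.empty(n)
    disc = np.empty(n)
    clinic_mult = np.ones(n)
    if config.clinic_disc_sd > 0:
        per_clinic = np.exp(
            rng.normal(-0.5 * config.clinic_disc_sd**2, config.clinic_disc_sd, size=config.clinic_count)
        )
        clinic_map = dict(zip(clinic_labels, per_clinic))
        is_rw = src == SOURCE_RWD
        clinic_mult[is_rw] = df.loc[is_rw, "clinic_id"].map(clinic_map).to_numpy()
    for source in (SOURCE_TRIAL, SOURCE_RWD):
        m = src == source
        dropout[m] = _exp_or_inf(config.dropout_rate.get(source, 0.0), int(m.sum()), rng)
        per_reg = config.discontinuation_rate.get(source, {})
        for reg in df.loc[m, "regimen"].unique():
            mr = m & (df["regimen"] == reg).to_numpy()
            rate = per_reg.get(reg, 0.0)
            # clinic frailty multiplies the rate, i.e. divides the exponential draw
            disc[mr] = _exp_or_inf(rate, int(mr.sum()), rng) / clinic_mult[mr]

    # optional imperfect event ascertainment: a missed event is recorded as
    # loss to follow-up at the event time
    detected = np.ones(n, dtype=bool)
    for source, prob in config.event_detection_prob.items():
        m = src == source
        detected[m] = rng.uniform(size=int(m.sum())) < prob

    cap = config.admin_cap_months
    if config.jitter > 0:
        event_time = event_time + rng.uniform(0, config.jitter, size=n)

    def _resolve(include_disc: bool):
        times = [event_time, np.full(n, cap), dropout]
        reasons = [CENSOR_NONE, CENSOR_ADMIN, CENSOR_LOST]
        if include_disc:
            times.append(disc)
            reasons.append(CENSOR_DISCONTINUED)
        stacked = np.column_stack(times)
        which = stacked.argmin(axis=1)
        t = stacked[np.arange(n), which]
        ev = (which == 0) & detected
        reason = np.asarray(reasons, dtype=object)[which]
        reason[which == 0] = CENSOR_NONE
        reason[(which == 0) & ~detected] = CENSOR_LOST
        # keep times strictly positive
        t = np.maximum(t, 1e-6)
        return t, ev.astype(int), reason

    t_ot, ev_ot, reason_ot = _resolve(include_disc=True)
    t_itt, ev_itt, reason_itt = _resolve(include_disc=False)
    df["followup_months"] = t_ot
    df["event"] = ev_ot
    df["censor_reason"] = reason_ot
    df["itt_followup_months"] = t_itt
    df["itt_event"] = ev_itt
    df["itt_censor_reason"] = reason_itt

    # --- missingness, per source
    df = apply_missingness(
        df,
        config.missing_rates,
        mechanism=config.missing_mechanism,
        seed=int(rng.integers(2**31)),
        source=SOURCE_RWD,
    )
    df = apply_missingness(
        df,
        config.trial_missing_rates,
        mechanism=config.missing_mechanism,
        seed=int(rng.integers(2**31)),
        source=SOURCE_TRIAL,
    )
    return add_derived_columns(df)


def apply_missingness(
    records: pd.DataFrame,
    missing_rates: dict[str, float],
    mechanism: str = "mcar",
    seed: int = 0,
    source: str | None = None,
    mar_covariate: str = "age",
    mar_slope: float = 1.0,
) -> pd.DataFrame:
    """Blank covariate cells at the given per-covariate rates.

    mechanism 'mcar' blanks uniformly at random; 'mar' makes the missingness
    probability a logistic function of the (always observed) ``mar_covariate``
    z-score with slope ``mar_slope``, with the intercept solved so the
    marginal missing fraction equals the target rate.
    """
    if mechanism not in ("mcar", "mar"):
        raise ValueError("mechanism must be 'mcar' or 'mar'")
    out = records.copy()
    rng = np.random.default_rng(seed)
    mask_rows = (
        np.ones(len(out), dtype=bool)
        if source is None
        else (out["source"] == source).to_numpy()
    )
    idx = np.flatnonzero(mask_rows)
    if len(idx) == 0:
        return out
    if mechanism == "mar":
        z_raw = pd.to_numeric(out.loc[mask_rows, mar_covariate], errors="coerce").to_numpy()
        sd = z_raw.std()
        z = (z_raw - z_raw.mean()) / (sd if sd > 0 else 1.0)
    for name, rate in missing_rates.items():
        if name not in out.columns:
            raise ValueError(f"unknown covariate {name!r}")
        if not (0 <= rate < 1):
            raise ValueError(f"missing rate for {name!r} must be in [0,1)")
        if rate == 0:
            continue
        if mechanism == "mcar":
            hit = rng.uniform(size=len(idx)) < rate
        else:
            alpha = brentq(lambda a: expit(a + mar_slope * z).mean() - rate, -30, 30)
            hit = rng.uniform(size=len(idx)) < expit(alpha + mar_slope * z)
        col = out[name]
        if col.dtype != object and not pd.api.types.is_float_dtype(col):
            out[name] = col.astype(float)
        out.loc[out.index[idx[hit]], name] = np.nan
    return add_derived_columns(out)
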