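"""End-to-end anchored-comparison pipeline and report rendering.

``run_pipeline`` wires the stages together: cohort simulation (or ingestion),
harmonized eligibility, multiple imputation, per-group propensity weighting
against the trial population, outcome derivation under the configured
convention, direct Cox hazard ratios within each source, anchored indirect
combination, and Rubin's-rules pooling across imputed datasets. The analysis
sets mirror a primary on-treatment analysis and its prespecified sensitivity
configurations (intent-to-treat, doubly robust, demographics-only weighting,
follow-up restrictions, age-75 subgroup).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .eligibility import EligibilityCriteria, apply_eligibility
from .imputation import PooledEstimate, mice_impute, pool_rubin
from .itc import ITCResult, bucher_combine
from .records import (
    DEMOGRAPHIC_COVARIATES,
    FULL_COVARIATES,
    SOURCE_RWD,
    SOURCE_TRIAL,
    read_cohort,
)
from .simulate import SimulationConfig, simulate_cohorts
from .survival import HREstimate, OutcomeSpec, derive_outcome, fit_cox, subgroup_interaction
from .weighting import balance_report, fit_membership_model, odds_weights

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "restrict_followup", "render_baseline_table"]

log = logging.getLogger("anchoritc")

ANALYSIS_SETS = (
    "primary_on_treatment",
    "itt",
    "doubly_robust",
    "demographics_only",
    "clinics_ge12mo",
    "patients_ge12mo",
    "subgroup_age75",
)

#: raw covariates entering the imputation model (indicators derived after)
IMPUTATION_COVARIATES = [
    "age",
    "female",
    "race_black",
    "iss_stage",
    "cyto_high",
    "ecog",
    "crcl",
    "months_dx_to_lot1",
]


@dataclass
class RunConfig:
    """One run artifact = one analysis set over one cohort."""

    simulation: SimulationConfig | None = field(default_factory=SimulationConfig)
    input_path: str | None = None
    eligibility: EligibilityCriteria = field(default_factory=EligibilityCriteria)
    m: int = 10
    n_cycles: int = 10
    analysis_set: str = "primary_on_treatment"
    max_followup_months: float = 48.5
    pool_before_combine: bool = False
    output_dir: str | None = None
    seed: int = 0

    def __post_init__(self):
        if self.analysis_set not in ANALYSIS_SETS:
            raise ValueError(f"unknown analysis set {self.analysis_set!r}; choose from {ANALYSIS_SETS}")
        if self.simulation is None and self.input_path is None:
            raise ValueError("need either a simulation config or an input path")

    @property
    def weighting_covariates(self) -> list[str]:
        if self.analysis_set == "demographics_only":
            return list(DEMOGRAPHIC_COVARIATES)
        return list(FULL_COVARIATES)

    @property
    def outcome_spec(self) -> OutcomeSpec:
        convention = "itt" if self.analysis_set == "itt" else "on_treatment"
        return OutcomeSpec(convention=convention, max_followup_months=self.max_followup_months)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        elig = raw.pop("eligibility", None)
        kwargs = dict(raw)
        if sim is not None:
            kwargs["simulation"] = SimulationConfig(**sim)
        if elig is not None:
            if "lab_bounds" in elig:
                elig["lab_bounds"] = {k: tuple(v) for k, v in elig["lab_bounds"].items()}
            if "excluded_comorbidities" in elig:
                elig["excluded_comorbidities"] = tuple(elig["excluded_comorbidities"])
            kwargs["eligibility"] = EligibilityCriteria(**elig)
        return cls(**kwargs)


@dataclass
class PipelineResult:
    """Everything a run produces, with full precision retained."""

    attrition: pd.DataFrame
    balance: pd.DataFrame
    per_imputation: pd.DataFrame
    direct_pooled: dict[str, PooledEstimate]
    itc_pooled: dict[str, PooledEstimate]
    itc_results: dict[str, ITCResult]
    baseline_table: pd.DataFrame
    manifest: dict
    subgroup: dict | None = None

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for label, est in {**self.direct_pooled, **self.itc_pooled}.items():
            lo, hi = est.ci
            rows.append(
                {
                    "comparison": label,
                    "hr": float(np.exp(est.point)),
                    "ci_lower": float(np.exp(lo)),
                    "ci_upper": float(np.exp(hi)),
                    "p": est.p,
                    "log_hr": est.point,
                    "se_log_hr": est.se,
                }
            )
        return pd.DataFrame(rows)


def restrict_followup(records: pd.DataFrame, mode: str) -> pd.DataFrame:
    """Follow-up-based cohort restrictions for sensitivity analyses.

    ``clinic_mean_ge_12`` keeps every patient of real-world clinics whose mean
    on-treatment follow-up is >= 12 months (trial patients are kept);
    ``patient_ge_12`` keeps patients (either source) with >= 12 months of
    on-treatment follow-up.
    """
    if mode == "clinic_mean_ge_12":
        rwd = records[records["source"] == SOURCE_RWD]
        if rwd["clinic_id"].isna().any():
            raise ValueError("clinic restriction requires clinic_id on all real-world records")
        means = rwd.groupby("clinic_id")["followup_months"].mean()
        keep_clinics = set(means.index[means >= 12])
        keep = (records["source"] != SOURCE_RWD) | records["clinic_id"].isin(keep_clinics)
        return records[keep].copy()
    if mode == "patient_ge_12":
        return records[records["followup_months"] >= 12].copy()
    raise ValueError("mode must be 'clinic_mean_ge_12' or 'patient_ge_12'")


def _pool(log_hrs: list[float], ses: list[float]) -> PooledEstimate:
    if len(log_hrs) == 1:
        point, var = float(log_hrs[0]), float(ses[0] ** 2)
        se = float(np.sqrt(var))
        from scipy import stats

        return PooledEstimate(
            point=point,
            within_var=var,
            between_var=0.0,
            total_var=var,
            df=float("inf"),
            ci=(point - 1.96 * se, point + 1.96 * se),
            p=float(2 * stats.norm.sf(abs(point) / se)) if se > 0 else 1.0,
            m=1,
        )
    return pool_rubin(log_hrs, [s**2 for s in ses])


def _pooled_to_hr_estimate(label: str, est: PooledEstimate, anchor: str, source: str) -> HREstimate:
    return HREstimate(
        comparison=(label, anchor),
        source=source,
        log_hr=est.point,
        se_log_hr=est.se,
        n=0,
        events=0,
        model="pooled",
        p=est.p,
    )


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute one analysis set end to end; write artifacts if configured."""
    # --- stage: data
    if config.input_path is not None:
        records = read_cohort(config.input_path)
        sim = None
    else:
        sim = config.simulation
        records = simulate_cohorts(sim, seed=config.seed)
    log.info("cohort: %d records (%d trial, %d real-world)", len(records),
             (records["source"] == SOURCE_TRIAL).sum(), (records["source"] == SOURCE_RWD).sum())

    anchor = sim.anchor if sim is not None else "Rd"
    experimental = sim.trial_experimental if sim is not None else "DRd"

    # --- stage: eligibility
    eligible, attrition = apply_eligibility(records, config.eligibility)
    log.info("eligibility: %d of %d records retained", len(eligible), len(records))

    # --- stage: follow-up restrictions
    if config.analysis_set == "clinics_ge12mo":
        eligible = restrict_followup(eligible, "clinic_mean_ge_12")
        log.info("clinic restriction: %d records retained", len(eligible))
    elif config.analysis_set == "patients_ge12mo":
        eligible = restrict_followup(eligible, "patient_ge_12")
        log.info("patient restriction: %d records retained", len(eligible))

    # --- stage: imputation
    imp_covs = [c for c in IMPUTATION_COVARIATES if c in eligible.columns]
    imputed = mice_impute(eligible, imp_covs, m=config.m, n_cycles=config.n_cycles, seed=config.seed)
    log.info("imputation: m=%d datasets, models %s", imputed.m, imputed.model_spec)

    wcovs = config.weighting_covariates
    dr = config.analysis_set in ("doubly_robust", "subgroup_age75")
    adj_covs = tuple(c for c in FULL_COVARIATES if c != "age_ge75") if dr else ()
    spec = config.outcome_spec

    rwd_regimens = sorted(set(eligible.loc[eligible["source"] == SOURCE_RWD, "regimen"]))
    per_rows = []
    balance_tables = []
    subgroup_acc: dict[str, list] = {}

    for d_idx, dataset in enumerate(imputed):
        trial = dataset[dataset["source"] == SOURCE_TRIAL]
        rwd = dataset[dataset["source"] == SOURCE_RWD]

        weight_sets = {}
        for reg in rwd_regimens:
            group = rwd[rwd["regimen"] == reg]
            p = fit_membership_model(trial, group, wcovs)
            weight_sets[reg] = odds_weights(p.loc[group.index], group=reg)
        balance_tables.append(
            balance_report(
                trial,
                {r: (rwd[rwd["regimen"] == r], weight_sets[r]) for r in rwd_regimens},
                wcovs,
            ).table.assign(imputation=d_idx)
        )

        table = derive_outcome(dataset, spec)
        t_table = table[table["source"] == SOURCE_TRIAL].copy()
        t_table["treated"] = (t_table["regimen"] == experimental).astype(int)

        if config.analysis_set == "subgroup_age75":
            strata, p_int = subgroup_interaction(
                t_table, "treated", "age_ge75", None, adj_covs,
                comparison=(experimental, anchor), source=SOURCE_TRIAL,
            )
            subgroup_acc.setdefault(f"{experimental} vs {anchor} [trial]", []).append((strata, p_int))
        trial_est = fit_cox(
            t_table, "treated", None, adj_covs,
            comparison=(experimental, anchor), source=SOURCE_TRIAL,
        )
        per_rows.append(
            dict(imputation=d_idx, comparison=f"{experimental} vs {anchor} [trial]",
                 log_hr=trial_est.log_hr, se=trial_est.se_log_hr)
        )

        rwd_ests = {}
        for reg in rwd_regimens:
            if reg == anchor:
                continue
            pair = table[(table["source"] == SOURCE_RWD) & (table["regimen"].isin([reg, anchor]))].copy()
            pair["treated"] = (pair["regimen"] == reg).astype(int)
            w = pd.concat([weight_sets[reg].weights, weight_sets[anchor].weights]).loc[pair.index]
            if config.analysis_set == "subgroup_age75":
                strata, p_int = subgroup_interaction(
                    pair, "treated", "age_ge75", w, adj_covs,
                    comparison=(reg, anchor), source=SOURCE_RWD,
                )
                subgroup_acc.setdefault(f"{reg} vs {anchor} [rwd]", []).append((strata, p_int))
            est = fit_cox(pair, "treated", w, adj_covs, comparison=(reg, anchor), source=SOURCE_RWD)
            rwd_ests[reg] = est
            per_rows.append(
                dict(imputation=d_idx, comparison=f"{reg} vs {anchor} [rwd]",
                     log_hr=est.log_hr, se=est.se_log_hr)
            )

        for reg, est in rwd_ests.items():
            itc = bucher_combine(trial_est, est)
            per_rows.append(
                dict(imputation=d_idx, comparison=f"{experimental} vs {reg} [itc]",
                     log_hr=itc.log_hr, se=itc.se)
            )

    per_imputation = pd.DataFrame(per_rows)

    # --- stage: pooling (after combining, unless configured otherwise)
    direct_pooled: dict[str, PooledEstimate] = {}
    itc_pooled: dict[str, PooledEstimate] = {}
    for label, grp in per_imputation.groupby("comparison"):
        pooled = _pool(list(grp["log_hr"]), list(grp["se"]))
        if label.endswith("[itc]"):
            if not config.pool_before_combine:
                itc_pooled[label] = pooled
        else:
            direct_pooled[label] = pooled
    itc_results: dict[str, ITCResult] = {}
    trial_label = f"{experimental} vs {anchor} [trial]"
    for reg in rwd_regimens:
        if reg == anchor:
            continue
        a = _pooled_to_hr_estimate(experimental, direct_pooled[trial_label], anchor, SOURCE_TRIAL)
        b = _pooled_to_hr_estimate(reg, direct_pooled[f"{reg} vs {anchor} [rwd]"], anchor, SOURCE_RWD)
        itc = bucher_combine(a, b)
        itc_results[f"{experimental} vs {reg} [itc]"] = itc
        if config.pool_before_combine:
            itc_pooled[f"{experimental} vs {reg} [itc]"] = _pool([itc.log_hr], [itc.se])

    # --- stage: subgroup summary
    subgroup = None
    if subgroup_acc:
        subgroup = {}
        for label, per_dataset in subgroup_acc.items():
            strata_pooled = {}
            for s in (0, 1):
                ests = [strata[s] for strata, _ in per_dataset]
                strata_pooled[s] = _pool([e.log_hr for e in ests], [e.se_log_hr for e in ests])
            p_ints = [p for _, p in per_dataset]
            subgroup[label] = {"strata": strata_pooled, "p_interaction_median": float(np.median(p_ints))}
        # indirect comparison per stratum
        for reg in rwd_regimens:
            if reg == anchor:
                continue
            key = f"{experimental} vs {reg} [itc]"
            strata = {}
            for s in (0, 1):
                a = _pooled_to_hr_estimate(
                    experimental, subgroup[trial_label]["strata"][s], anchor, SOURCE_TRIAL
                )
                b = _pooled_to_hr_estimate(reg, subgroup[f"{reg} vs {anchor} [rwd]"]["strata"][s], anchor, SOURCE_RWD)
                strata[s] = bucher_combine(a, b)
            # interaction of the indirect contrast: difference of stratum log HRs
            delta = strata[1].log_hr - strata[0].log_hr
            se_delta = float(np.sqrt(strata[0].se ** 2 + strata[1].se ** 2))
            from scipy import stats as _st

            subgroup[key] = {
                "strata": strata,
                "p_interaction": float(2 * _st.norm.sf(abs(delta) / se_delta)),
            }

    # --- stage: rendering
    balance_all = pd.concat(balance_tables, ignore_index=True)
    balance_avg = (
        balance_all.groupby(["group", "covariate"], sort=False)[["smd_unweighted", "smd_weighted"]]
        .mean()
        .reset_index()
    )
    first = imputed.datasets[0]
    trial0 = first[first["source"] == SOURCE_TRIAL]
    rwd0 = first[first["source"] == SOURCE_RWD]
    groups0 = {}
    for reg in rwd_regimens:
        g = rwd0[rwd0["regimen"] == reg]
        p = fit_membership_model(trial0, g, wcovs)
        groups0[reg] = (g, odds_weights(p.loc[g.index], group=reg))
    baseline = render_baseline_table(trial0, groups0, wcovs)

    manifest = {
        "analysis_set": config.analysis_set,
        "seed": config.seed,
        "m": config.m,
        "n_cycles": config.n_cycles,
        "outcome": dataclasses.asdict(config.outcome_spec),
        "weighting_covariates": wcovs,
        "doubly_robust_covariates": list(adj_covs),
        "pool_before_combine": config.pool_before_combine,
        "eligibility": dataclasses.asdict(config.eligibility),
        "simulation": None if sim is None else _jsonable(dataclasses.asdict(sim)),
        "input_path": config.input_path,
        "n_input": int(len(records)),
        "n_eligible": int(len(eligible)),
        "rwd_regimens": rwd_regimens,
        "anchor": anchor,
        "experimental": experimental,
    }

    result = PipelineResult(
        attrition=attrition,
        balance=balance_avg,
        per_imputation=per_imputation,
        direct_pooled=direct_pooled,
        itc_pooled=itc_pooled,
        itc_results=itc_results,
        baseline_table=baseline,
        manifest=manifest,
        subgroup=subgroup,
    )
    if config.output_dir is not None:
        _write_artifact(result, config)
    return result


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _write_artifact(result: PipelineResult, config: RunConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.attrition.to_csv(out / "attrition.csv", index=False)
    result.balance.to_csv(out / "balance.csv", index=False)
    result.per_imputation.to_csv(out / "per_imputation_estimates.csv", index=False)
    result.baseline_table.to_csv(out / "baseline_table.csv")
    result.summary_frame().to_csv(out / "estimates.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(_jsonable(result.manifest), indent=2))
    log.info("artifact written to %s", out)


def render_baseline_table(
    trial: pd.DataFrame,
    groups: dict[str, tuple[pd.DataFrame, "object"]],
    covariates: list[str],
) -> pd.DataFrame:
    """Baseline-characteristics table: weighted means/percentages per group
    with the trial as reference column, plus weighted SMD columns.

    Continuous covariates render as mean (SD); binary and categorical levels
    as percentages. Full precision is kept; round at display time.
    """
    from .weighting import expand_covariates, standardized_difference, _smd_kind

    t_exp = expand_covariates(trial, covariates)
    rows: dict[str, dict[str, float]] = {}

    def describe(exp_df, weights):
        w = np.ones(len(exp_df)) if weights is None else np.asarray(weights, dtype=float)
        desc = {}
        for col in exp_df.columns:
            x = exp_df[col].to_numpy().astype(float)
            mean = float(np.average(x, weights=w))
            if _smd_kind(col, exp_df[col]) == "binary":
                desc[f"{col} (%)"] = 100 * mean
            else:
                var = float(np.average((x - mean) ** 2, weights=w))
                desc[f"{col} mean"] = mean
                desc[f"{col} sd"] = float(np.sqrt(var))
        return desc

    rows["trial"] = describe(t_exp, None)
    for label, (gdf, wset) in groups.items():
        g_exp = expand_covariates(gdf, covariates)
        w = None if wset is None else wset.weights.loc[gdf.index].to_numpy()
        rows[label] = describe(g_exp, w)
        smds = {}
        for col in t_exp.columns:
            kind = _smd_kind(col, t_exp[col])
            smd = standardized_difference(t_exp[col], g_exp[col], w, kind)
            key = f"{col} (%)" if kind == "binary" else f"{col} mean"
            smds[key] = smd
        rows[f"SMD {label}"] = smds
    return pd.DataFrame(rows)
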