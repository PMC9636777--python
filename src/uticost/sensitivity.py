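"""Scenario battery: rebuild cohort, re-classify, re-cost, re-match, re-fit.

Each scenario is a pure function of (tables, scenario definition, seed):
scenarios share no mutable state, so they can run in any order.  The battery
emits one row per scenario with matched sample size, raw and winsorized cost
differences (all-cause and UTI-related) with p-values, and the risk
difference in progression to complicated UTI.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportions_ztest

from . import config as cfgmod
from .classifier import label_cohort
from .cohort import SCENARIOS, CohortScenario, build_cohort, get_scenario
from .costs import baseline_windows, compute_costs, followup_windows, tabulate_hcru, winsorize
from .psm import PerfectSeparationError, estimate_propensity, fit_cost_model, match_1to1
from ._util import days_between
from .classifier import charlson_score

SCENARIO_ORDER = ("baseline", "strict", "loose", "fu30", "fu360", "no_prior_infection", "fq_only")


def build_analysis_frame(
    tables: dict[str, pd.DataFrame],
    scenario: CohortScenario | str = "baseline",
    config: dict | None = None,
) -> pd.DataFrame:
    """Cohort + labels + baseline covariates + follow-up costs for a scenario."""
    cfg = config or cfgmod.DEFAULT_CONFIG
    if isinstance(scenario, str):
        scenario = get_scenario(scenario)
    cohort, _, _ = build_cohort(tables, scenario, cfg)
    if cohort.empty:
        return cohort
    labels = label_cohort(
        cohort, tables["prescriptions"], tables["cultures"], tables["allergies"], cfg
    )
    df = cohort.merge(labels, on="patient_id", validate="1:1")
    df["white"] = (df["race"] == "white").astype(float)
    df["private_insurance"] = (df["insurance"] == "private").astype(float)

    base = tabulate_hcru(
        tables["encounters"],
        tables["prescriptions"],
        baseline_windows(df, scenario.baseline_days),
        cfg["formulary"],
    )
    df = df.merge(
        base.rename(
            columns={
                "inpatient": "baseline_inpatient",
                "emergency": "baseline_emergency",
                "outpatient_clinic": "baseline_outpatient_clinic",
                "outpatient_ambulatory_surgery": "baseline_outpatient_ambulatory_surgery",
                "outpatient_other": "baseline_outpatient_other",
                "drug_orders": "baseline_drug_orders",
                "any_antibiotic": "baseline_any_antibiotic",
            }
        ),
        left_on="patient_id",
        right_index=True,
    )
    df["baseline_outpatient"] = (
        df["baseline_outpatient_clinic"]
        + df["baseline_outpatient_ambulatory_surgery"]
        + df["baseline_outpatient_other"]
    )
    df["baseline_outpatient_clinic_other"] = (
        df["baseline_outpatient_clinic"] + df["baseline_outpatient_other"]
    )
    idx = df.set_index("patient_id")["index_date"]
    df["cci"] = charlson_score(tables["diagnoses"], idx, cfg["charlson"]).to_numpy()

    fu_costs = compute_costs(
        tables["encounters"],
        tables["prescriptions"],
        cfg["fee_schedule"],
        followup_windows(df, scenario.followup_days),
        cfg["code_lists"]["uuti"] + cfg["code_lists"]["cuti"],
        cfgmod.indicated_set(cfg["formulary"]),
    )
    df = df.merge(fu_costs, left_on="patient_id", right_index=True)
    return df


def cuti_progression(
    cohort: pd.DataFrame,
    diagnoses: pd.DataFrame,
    followup_days: int,
    cuti_codes: list[str],
    arm_col: str = "not_susceptible",
) -> dict:
    """Per-arm probability of a cUTI-qualifying event in follow-up.

    An event qualifies if a follow-up diagnosis carries a cUTI code or any
    systemic-symptom flag.  Risk difference is not-susceptible minus
    susceptible; p-value from a two-proportion z-test.
    """
    arms = cohort[arm_col].astype(bool)
    if arms.all() or (~arms).all():
        raise ValueError("both susceptibility arms must be non-empty")
    dx = diagnoses.merge(cohort[["patient_id", "index_date"]], on="patient_id", how="inner")
    offset = days_between(dx["date"], dx["index_date"])
    in_window = (offset >= 0) & (offset < followup_days)
    qualifies = dx["code"].isin(set(cuti_codes)) | dx[
        ["fever_ge_38_3", "nausea", "vomiting", "flank_pain"]
    ].any(axis=1)
    progressed_ids = set(dx.loc[in_window & qualifies, "patient_id"])
    progressed = cohort["patient_id"].isin(progressed_ids)

    n_ns, n_s = int(arms.sum()), int((~arms).sum())
    k_ns = int(progressed[arms].sum())
    k_s = int(progressed[~arms].sum())
    p_ns, p_s = k_ns / n_ns, k_s / n_s
    if k_ns + k_s in (0, n_ns + n_s):  # degenerate: all or none progressed
        pvalue = 1.0
    else:
        _, pvalue = proportions_ztest([k_ns, k_s], [n_ns, n_s])
    return {
        "p_susceptible": p_s,
        "p_not_susceptible": p_ns,
        "risk_difference": p_ns - p_s,
        "pvalue": float(pvalue),
    }


def run_scenario(
    tables: dict[str, pd.DataFrame],
    scenario: CohortScenario | str,
    seed: int = 0,
    config: dict | None = None,
) -> dict:
    """Run the full chain for one scenario; returns the summary-row dict.

    An empty arm yields a flagged result instead of a crash.
    """
    cfg = config or cfgmod.DEFAULT_CONFIG
    if isinstance(scenario, str):
        scenario = get_scenario(scenario)
    df = build_analysis_frame(tables, scenario, cfg)
    result: dict = {"scenario": scenario.name, "followup_days": scenario.followup_days}
    if df.empty or df["not_susceptible"].nunique() < 2:
        result.update(flagged_missing=True, n_matched_per_arm=0)
        return result

    try:
        ps = estimate_propensity(df, "not_susceptible", cfg["psm"]["covariates_susceptibility"])
    except PerfectSeparationError as exc:
        # tiny scenario arms can separate or go singular; flag, don't crash
        result.update(flagged_missing=True, n_matched_per_arm=0, flag_reason=str(exc))
        return result
    matched = match_1to1(
        ps.scores, df["not_susceptible"], caliper=cfg["psm"]["caliper_sd"], seed=seed
    )
    analysis = df.loc[df.index.isin(matched.matched_ids)].copy()
    result["n_matched_per_arm"] = len(matched.pairs)
    if not matched.pairs:
        result["flagged_missing"] = True
        return result

    adjusters = cfg["cost_model"]["adjusters"]
    pctl = cfg["cost_model"]["winsorize_percentile"]
    zero_offset = cfg["cost_model"]["zero_offset"]
    for outcome, tag in (("all_cause_cost", "all_cause"), ("uti_related_cost", "uti_related")):
        fit = fit_cost_model(
            analysis, outcome, "not_susceptible", adjusters, reference="False",
            zero_offset=zero_offset, contrast_name="susceptibility",
        )
        result[f"{tag}_diff"] = fit.differences["True"]
        result[f"{tag}_pvalue"] = fit.pvalues["True"]
        # winsorization is recomputed inside each scenario's analysis sample
        wcol = f"{outcome}_winsorized"
        analysis[wcol] = winsorize(analysis[outcome].to_numpy(), pctl)
        wfit = fit_cost_model(
            analysis, wcol, "not_susceptible", adjusters, reference="False",
            zero_offset=zero_offset, contrast_name="susceptibility",
        )
        result[f"{tag}_winsorized_diff"] = wfit.differences["True"]
        result[f"{tag}_winsorized_pvalue"] = wfit.pvalues["True"]

    prog = cuti_progression(
        analysis, tables["diagnoses"], scenario.followup_days, cfg["code_lists"]["cuti"]
    )
    result["cuti_progression_diff"] = prog["risk_difference"]
    result["cuti_progression_pvalue"] = prog["pvalue"]
    result["flagged_missing"] = False
    return result


def run_battery(
    tables: dict[str, pd.DataFrame],
    seed: int = 0,
    config: dict | None = None,
    scenarios: list[str] | None = None,
) -> pd.DataFrame:
    """Run all (or selected) scenarios; one row per scenario."""
    names = scenarios or list(SCENARIO_ORDER)
    rows = [run_scenario(tables, name, seed=seed, config=config) for name in names]
    return pd.DataFrame(rows)
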