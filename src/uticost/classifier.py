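"""Treatment-appropriateness rule engine and susceptibility aggregation.

The engine mirrors the guideline-derived decision table:

* appropriate  — first-line monotherapy (fosfomycin / nitrofurantoin / SXT)
  at exactly the recommended duration, or an alternate line justified by a
  documented allergy to all first-line agents;
* inappropriate — two first-line agents at once, unjustified second-line or
  other initial therapy, an agent with a resistant/intermediate isolate
  result, or an agent on the patient's allergy list;
* suboptimal   — a switch to a different UTI antibiotic within 28 days, any
  intravenous antibiotic during the episode, or an initial agent the
  isolates were not susceptible to.

Flags are not mutually exclusive; the final binary label is "appropriate"
iff neither inappropriate nor suboptimal fired.  Every true flag carries the
ids of the rules that fired.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import config as cfgmod
from ._util import days_between, percent

#: rule ids -> human-readable clause
RULES = {
    "IA1": "two or more distinct first-line agents as initial therapy",
    "IA2": "second-line/other initial therapy without allergy or resistance justification",
    "IA3": "received an antibiotic with a resistant or intermediate isolate result",
    "IA4": "received an antibiotic recorded in the allergy history",
    "SO1": "switched to a different UTI antibiotic within the switch window",
    "SO2": "received intravenous antibiotics during the episode",
    "SO3": "initial agent not susceptible on the patient's isolates",
    "AP1": "first-line monotherapy at the recommended duration",
    "AP2": "alternate line with documented allergy to all first-line agents",
}

NOT_SUSCEPTIBLE_RESULTS = frozenset({"I", "R"})


class PipelineOrderError(RuntimeError):
    """A patient reached classification without an upstream prerequisite."""


def aggregate_susceptibility(
    cultures: pd.DataFrame,
    indicated_set: list[str] | None = None,
    patient_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Person-level susceptibility: not-susceptible iff ANY isolate shows an
    intermediate or resistant result for an antibiotic in the indicated set.

    Returns one row per patient with ``person_level`` in
    {"susceptible", "not_susceptible"}.  Raises :class:`PipelineOrderError`
    for a requested patient with no tested panel (such patients should have
    been excluded upstream).
    """
    indicated = set(indicated_set if indicated_set is not None else cfgmod.indicated_set())
    tested = cultures.loc[cultures["result"].notna()]
    if patient_ids is None:
        patient_ids = sorted(tested["patient_id"].unique())
    missing = set(patient_ids) - set(tested["patient_id"])
    if missing:
        raise PipelineOrderError(
            f"{len(missing)} patient(s) have no tested susceptibility panel, e.g. "
            f"{sorted(missing)[:3]}"
        )
    relevant = tested.loc[tested["antibiotic"].isin(indicated)]
    ns_ids = set(
        relevant.loc[relevant["result"].isin(NOT_SUSCEPTIBLE_RESULTS), "patient_id"]
    )
    out = pd.DataFrame({"patient_id": list(patient_ids)})
    out["person_level"] = np.where(
        out["patient_id"].isin(ns_ids), "not_susceptible", "susceptible"
    )
    return out


def worst_panel(cultures: pd.DataFrame) -> dict[str, dict[str, str]]:
    """Per patient, antibiotic -> worst result across isolates (S < I < R)."""
    severity = {"S": 0, "I": 1, "R": 2}
    tested = cultures.loc[cultures["result"].notna()]
    panels: dict[str, dict[str, str]] = {}
    for (pid, drug), grp in tested.groupby(["patient_id", "antibiotic"], sort=True):
        worst = max(grp["result"], key=lambda r: severity[r])
        panels.setdefault(pid, {})[drug] = worst
    return panels


def classify_inappropriate(
    initial_drugs: list[str],
    received_drugs: list[str],
    allergy_drugs: set[str],
    panel: dict[str, str],
    formulary: dict | None = None,
    *,
    escape_requires_all_tested: bool = True,
) -> tuple[bool, list[str]]:
    """Inappropriate-treatment clauses (rule ids IA1-IA4)."""
    formulary = formulary or cfgmod.DEFAULT_FORMULARY
    first_line = [d for d, v in formulary.items() if v["line"] == "first"]
    fired: list[str] = []

    for drug in initial_drugs + received_drugs:
        if drug not in formulary:
            raise KeyError(f"drug {drug!r} absent from formulary")

    if len({d for d in initial_drugs if formulary[d]["line"] == "first"}) >= 2:
        fired.append("IA1")

    non_first_initial = [d for d in initial_drugs if formulary[d]["line"] != "first"]
    if non_first_initial:
        allergic_all = set(first_line) <= set(allergy_drugs)
        if escape_requires_all_tested:
            resistant_all = all(panel.get(d) in NOT_SUSCEPTIBLE_RESULTS for d in first_line)
        else:
            tested = [d for d in first_line if d in panel]
            resistant_all = bool(tested) and all(
                panel[d] in NOT_SUSCEPTIBLE_RESULTS for d in tested
            )
        if not (allergic_all or resistant_all):
            fired.append("IA2")

    if any(panel.get(d) in NOT_SUSCEPTIBLE_RESULTS for d in received_drugs):
        fired.append("IA3")
    if any(d in allergy_drugs for d in received_drugs):
        fired.append("IA4")
    return bool(fired), fired


def classify_suboptimal(
    initial_drugs: list[str],
    episode_orders: list[tuple[pd.Timestamp, str, str]],
    panel: dict[str, str],
    index_date: pd.Timestamp,
    *,
    switch_window_days: int = 28,
) -> tuple[bool, list[str]]:
    """Suboptimal-treatment clauses (rule ids SO1-SO3).

    ``episode_orders`` are (date, drug, route) antibiotic orders for the
    episode, including the initial therapy.
    """
    fired: list[str] = []
    initial = set(initial_drugs)
    for date, drug, route in episode_orders:
        offset = (pd.Timestamp(date) - pd.Timestamp(index_date)).days
        if drug not in initial and route == "oral" and 0 < offset <= switch_window_days:
            fired.append("SO1")
            break
    if any(route == "iv" for _, _, route in episode_orders):
        fired.append("SO2")
    if any(panel.get(d) in NOT_SUSCEPTIBLE_RESULTS for d in initial_drugs):
        fired.append("SO3")
    return bool(fired), fired


def classify_appropriate(
    initial: list[tuple[str, int]],
    allergy_drugs: set[str],
    formulary: dict | None = None,
    *,
    duration_tolerance_days: int = 0,
) -> tuple[bool, list[str]]:
    """Strict appropriateness (rule ids AP1-AP2).

    ``initial`` is the initial therapy as (drug, duration_days) tuples.
    """
    formulary = formulary or cfgmod.DEFAULT_FORMULARY
    first_line = {d for d, v in formulary.items() if v["line"] == "first"}
    fired: list[str] = []
    if len(initial) == 1:
        drug, duration = initial[0]
        entry = formulary[drug]
        if entry["line"] == "first":
            rec = entry["recommended_duration_days"]
            if abs(duration - rec) <= duration_tolerance_days:
                fired.append("AP1")
        elif entry["line"] in ("second", "third") and first_line <= set(allergy_drugs):
            fired.append("AP2")
    return bool(fired), fired


def assign_exposure_group(not_susceptible: bool, final_appropriate: bool) -> str:
    """Cross susceptibility x final appropriateness; reference is S_app."""
    if not_susceptible:
        return "NS_app" if final_appropriate else "NS_inapp_sub"
    return "S_app" if final_appropriate else "S_inapp_sub"


@dataclass
class EpisodeInputs:
    """Resolved per-patient inputs for the rule engine (mainly for tests)."""

    patient_id: str
    index_date: pd.Timestamp
    initial: list[tuple[str, int]]
    episode_orders: list[tuple[pd.Timestamp, str, str]]
    allergy_drugs: set[str]
    panel: dict[str, str]


def classify_episode(inputs: EpisodeInputs, formulary=None, classifier_cfg=None) -> dict:
    """Run all three clause families on one episode; returns the label dict."""
    formulary = formulary or cfgmod.DEFAULT_FORMULARY
    ccfg = classifier_cfg or cfgmod.DEFAULT_CONFIG["classifier"]
    initial_drugs = [d for d, _ in inputs.initial]
    received = sorted({d for _, d, _ in inputs.episode_orders} | set(initial_drugs))
    inapp, ia_rules = classify_inappropriate(
        initial_drugs,
        received,
        inputs.allergy_drugs,
        inputs.panel,
        formulary,
        escape_requires_all_tested=ccfg["resistance_escape_requires_all_tested"],
    )
    subopt, so_rules = classify_suboptimal(
        initial_drugs,
        inputs.episode_orders,
        inputs.panel,
        inputs.index_date,
        switch_window_days=ccfg["switch_window_days"],
    )
    strict_app, ap_rules = classify_appropriate(
        inputs.initial,
        inputs.allergy_drugs,
        formulary,
        duration_tolerance_days=ccfg["duration_tolerance_days"],
    )
    final = not inapp and not subopt
    return {
        "patient_id": inputs.patient_id,
        "appropriate": strict_app,
        "inappropriate": inapp,
        "suboptimal": subopt,
        "final_label": "appropriate" if final else "inappropriate_or_suboptimal",
        "fired_rules": ";".join(ia_rules + so_rules + ap_rules),
    }


def label_cohort(
    cohort: pd.DataFrame,
    prescriptions: pd.DataFrame,
    cultures: pd.DataFrame,
    allergies: pd.DataFrame,
    config: dict | None = None,
) -> pd.DataFrame:
    """Adjudicate every cohort patient; returns one TreatmentLabel row each.

    Adds person-level susceptibility and the 4-level exposure group.
    """
    cfg = config or cfgmod.DEFAULT_CONFIG
    formulary = cfg["formulary"]
    ccfg = cfg["classifier"]
    abx = set(cfgmod.antibiotic_drugs(formulary))
    window = cfg["cohort"]["rx_window_days"]
    episode_days = ccfg["episode_window_days"]

    ids = cohort["patient_id"].tolist()
    status = aggregate_susceptibility(cultures, cfgmod.indicated_set(formulary), ids)
    panels = worst_panel(cultures.loc[cultures["patient_id"].isin(set(ids))])

    rx = prescriptions.loc[prescriptions["drug"].isin(abx)].merge(
        cohort[["patient_id", "index_date", "initial_rx_date"]], on="patient_id", how="inner"
    )
    offset = days_between(rx["order_date"], rx["index_date"])
    episode = rx.loc[(offset >= -window) & (offset <= episode_days)]
    episode = episode.sort_values(["patient_id", "order_date", "rx_id"], kind="mergesort")

    if ccfg["allergy_lookback"] == "pre_index":
        al = allergies.merge(cohort[["patient_id", "index_date"]], on="patient_id")
        al = al.loc[al["record_date"] <= al["index_date"]]
    else:
        al = allergies
    allergy_map = al.groupby("patient_id")["drug"].agg(set).to_dict()

    episode_map: dict[str, pd.DataFrame] = dict(tuple(episode.groupby("patient_id")))
    labels = []
    for _, row in cohort.iterrows():
        pid = row["patient_id"]
        grp = episode_map.get(pid)
        if grp is None or grp.empty:
            raise PipelineOrderError(f"patient {pid} has no episode antibiotic orders")
        init = grp.loc[
            (grp["order_date"] == row["initial_rx_date"]) & (grp["route"] == "oral")
        ]
        inputs = EpisodeInputs(
            patient_id=pid,
            index_date=row["index_date"],
            initial=list(zip(init["drug"], init["duration_days"].astype(int))),
            episode_orders=list(zip(grp["order_date"], grp["drug"], grp["route"])),
            allergy_drugs=allergy_map.get(pid, set()),
            panel=panels.get(pid, {}),
        )
        labels.append(classify_episode(inputs, formulary, ccfg))

    out = pd.DataFrame(labels).merge(status, on="patient_id", validate="1:1")
    out["not_susceptible"] = out["person_level"] == "not_susceptible"
    out["exposure_group"] = [
        assign_exposure_group(ns, lab == "appropriate")
        for ns, lab in zip(out["not_susceptible"], out["final_label"])
    ]
    return out


def classification_summary(labels: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages for the adjudication categories.

    Percentages use half-up rounding to 1 decimal of 100*n/cohort_n.
    """
    if labels.empty:
        raise ValueError("empty cohort")
    n = len(labels)
    counts = {
        "suboptimal": int(labels["suboptimal"].sum()),
        "inappropriate": int(labels["inappropriate"].sum()),
        "suboptimal_or_inappropriate": int((labels["suboptimal"] | labels["inappropriate"]).sum()),
        "suboptimal_and_inappropriate": int((labels["suboptimal"] & labels["inappropriate"]).sum()),
        "appropriate": int((labels["final_label"] == "appropriate").sum()),
    }
    return summary_from_counts(counts, n)


def summary_from_counts(counts: dict[str, int], cohort_n: int) -> pd.DataFrame:
    """Worked-example form of :func:`classification_summary`."""
    if cohort_n <= 0:
        raise ValueError("empty cohort")
    rows = [
        {"category": cat, "n": int(cnt), "pct": percent(cnt, cohort_n)}
        for cat, cnt in counts.items()
    ]
    return pd.DataFrame(rows)


def charlson_score(
    diagnoses: pd.DataFrame,
    index_dates: pd.Series,
    charlson_cfg: dict | None = None,
) -> pd.Series:
    """Charlson comorbidity index: weights summed over distinct categories
    coded strictly before the patient's index date.

    ``index_dates`` maps patient_id -> index date; all mapped patients get a
    score (0 when no qualifying codes).
    """
    cfg = charlson_cfg or cfgmod.DEFAULT_CONFIG["charlson"]
    scores = pd.Series(0, index=index_dates.index, dtype=int, name="cci")
    dx = diagnoses.loc[diagnoses["patient_id"].isin(set(index_dates.index))]
    if dx.empty:
        return scores
    dx = dx.assign(index_date=dx["patient_id"].map(index_dates))
    dx = dx.loc[dx["date"] < dx["index_date"]]
    codes = dx["code"].astype(str)
    for category, spec in cfg.items():
        hit = codes.str.startswith(tuple(spec["prefixes"]))
        patients_with = dx.loc[hit, "patient_id"].unique()
        scores.loc[scores.index.isin(patients_with)] += int(spec["weight"])
    return scores


def allergy_summary_from_counts(
    n_allergic_susceptible: int, n_allergic_not_susceptible: int, cohort_n: int
) -> dict:
    """Worked-example allergy accounting: overall prevalence and arm split."""
    n_allergic = n_allergic_susceptible + n_allergic_not_susceptible
    return {
        "n_allergic": n_allergic,
        "overall_pct": percent(n_allergic, cohort_n),
        "susceptible_share_pct": percent(n_allergic_susceptible, n_allergic),
        "not_susceptible_share_pct": percent(n_allergic_not_susceptible, n_allergic),
    }


def allergy_table(
    allergies: pd.DataFrame,
    labels: pd.DataFrame,
    formulary: dict | None = None,
) -> pd.DataFrame:
    """Per-antibiotic allergy proportions by susceptibility arm, with SMDs.

    Mirrors the reporting layout: one row per line-group aggregate and per
    individual indicated antibiotic.
    """
    from .psm import standardized_mean_difference

    formulary = formulary or cfgmod.DEFAULT_FORMULARY
    indicated = cfgmod.indicated_set(formulary)
    merged = allergies.merge(labels[["patient_id", "not_susceptible"]], on="patient_id")
    arms = {
        "susceptible": set(labels.loc[~labels["not_susceptible"], "patient_id"]),
        "not_susceptible": set(labels.loc[labels["not_susceptible"], "patient_id"]),
    }

    def row(name: str, drugs: list[str]) -> dict:
        allergic = set(merged.loc[merged["drug"].isin(drugs), "patient_id"])
        out = {"variable": name}
        vectors = {}
        for arm, members in arms.items():
            n_arm = len(members)
            n_all = len(allergic & members)
            out[f"{arm}_n"] = n_all
            out[f"{arm}_pct"] = percent(n_all, n_arm) if n_arm else float("nan")
            vectors[arm] = np.array([1.0 if pid in allergic else 0.0 for pid in members])
        out["difference_pct"] = round(out["not_susceptible_pct"] - out["susceptible_pct"], 2)
        if len(vectors["susceptible"]) > 1 and len(vectors["not_susceptible"]) > 1:
            out["smd"] = standardized_mean_difference(
                vectors["susceptible"], vectors["not_susceptible"]
            )
        else:
            out["smd"] = float("nan")
        total = len(arms["susceptible"]) + len(arms["not_susceptible"])
        out["overall_n"] = len(allergic & (arms["susceptible"] | arms["not_susceptible"]))
        out["overall_pct"] = percent(out["overall_n"], total) if total else float("nan")
        return out

    lines = {
        "any_uti_antibiotic": indicated,
        "any_first_line": [d for d in indicated if formulary[d]["line"] == "first"],
        "any_second_line": [d for d in indicated if formulary[d]["line"] == "second"],
        "any_third_line": [d for d in indicated if formulary[d]["line"] == "third"],
    }
    rows = [row(name, drugs) for name, drugs in lines.items()]
    rows += [row(drug, [drug]) for drug in sorted(indicated)]
    return pd.DataFrame(rows)
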