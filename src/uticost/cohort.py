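"""Index-event identification and the inclusion/exclusion waterfall.

The waterfall runs in a fixed, configuration-independent order so attrition
attribution is reproducible; because every filter is a pure set predicate the
final cohort does not depend on the order, only the per-filter counts do.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import config as cfgmod
from ._util import age_at, days_between

QUALIFYING_CFU = 1e4

#: exclusion filters in waterfall order for the baseline scenario
BASELINE_EXCLUSIONS = (
    "pregnancy",
    "hiv",
    "prior_antibiotics",
    "catheter",
    "cuti_symptoms",
    "iv_initial",
    "complicating_comorbidity",
    "missing_data",
)

#: reduced list used by the loose-criteria sensitivity scenario
LOOSE_EXCLUSIONS = (
    "pregnancy",
    "catheter",
    "iv_initial",
    "complicating_comorbidity",
    "missing_data",
)


@dataclass(frozen=True)
class CohortScenario:
    """A named cohort-construction variant (baseline + sensitivity rows)."""

    name: str
    followup_days: int = 180
    baseline_days: int = 180
    require_both_basis: bool = False
    exclusions: tuple[str, ...] = BASELINE_EXCLUSIONS
    drop_prior_infection: bool = False
    fq_only: bool = False
    require_days_available: int = 0


SCENARIOS: dict[str, CohortScenario] = {
    "baseline": CohortScenario("baseline"),
    "strict": CohortScenario("strict", require_both_basis=True),
    "loose": CohortScenario("loose", exclusions=LOOSE_EXCLUSIONS),
    "fu30": CohortScenario("fu30", followup_days=30),
    "fu360": CohortScenario("fu360", followup_days=360, require_days_available=360),
    "no_prior_infection": CohortScenario("no_prior_infection", drop_prior_infection=True),
    "fq_only": CohortScenario("fq_only", fq_only=True),
}


def get_scenario(name: str) -> CohortScenario:
    try:
        return SCENARIOS[name]
    except KeyError:
        raise ValueError(f"unknown scenario {name!r}; expected one of {sorted(SCENARIOS)}") from None


def identify_index_events(
    diagnoses: pd.DataFrame, cultures: pd.DataFrame, code_lists: dict
) -> pd.DataFrame:
    """One row per patient at the earliest qualifying uUTI event.

    A diagnosis qualifies when its code is on the uUTI list; a culture
    qualifies at >= 1e4 CFU/mL of a listed uropathogen.  ``basis`` records
    which event(s) fall on the index date; ``has_dx``/``has_culture`` record
    whether each qualifying event type exists at all (used by the strict
    scenario).  Patients with neither event simply yield no row.
    """
    uuti = set(code_lists["uuti"])
    if not uuti:
        raise ValueError("empty uUTI code list")
    uropathogens = set(code_lists["uropathogens"])
    if not uropathogens:
        raise ValueError("empty uropathogen list")

    dx_first = (
        diagnoses.loc[diagnoses["code"].isin(uuti)]
        .groupby("patient_id")["date"]
        .min()
        .rename("dx_date")
    )
    distinct = cultures.drop_duplicates("culture_id")
    qualifying = distinct.loc[
        (distinct["cfu_per_ml"] >= QUALIFYING_CFU) & distinct["organism"].isin(uropathogens)
    ]
    cult_first = (
        qualifying.groupby("patient_id")["collection_date"].min().rename("culture_date")
    )

    events = pd.concat([dx_first, cult_first], axis=1).reset_index()
    for col in ("dx_date", "culture_date"):  # all-NaN columns come back float
        events[col] = pd.to_datetime(events[col])
    if events.empty:
        return pd.DataFrame(
            columns=["patient_id", "index_date", "basis", "has_dx", "has_culture"]
        )
    events["has_dx"] = events["dx_date"].notna()
    events["has_culture"] = events["culture_date"].notna()
    events["index_date"] = events[["dx_date", "culture_date"]].min(axis=1)
    dx_at_index = events["has_dx"] & (events["dx_date"] == events["index_date"])
    cult_at_index = events["has_culture"] & (events["culture_date"] == events["index_date"])
    events["basis"] = np.select(
        [dx_at_index & cult_at_index, dx_at_index], ["both", "diagnosis_code"], "culture"
    )
    return events[["patient_id", "index_date", "basis", "has_dx", "has_culture"]].sort_values(
        "patient_id", kind="mergesort"
    ).reset_index(drop=True)


def _attrition_row(name: str, dropped: int, remaining: int) -> dict:
    return {"filter": name, "n_dropped": int(dropped), "n_remaining": int(remaining)}


def apply_inclusion(
    index_events: pd.DataFrame,
    patients: pd.DataFrame,
    prescriptions: pd.DataFrame,
    cultures: pd.DataFrame,
    config: dict | None = None,
) -> tuple[pd.DataFrame, list[dict], dict[str, list[str]]]:
    """Retain female patients aged >= 12 at index with an oral antibiotic
    order within +/-5 days and a culture with a non-empty S/I/R panel.

    The earliest qualifying oral order becomes the initial therapy; same-day
    ties break by record order then drug id.  Returns the retained events
    (with demographics and initial-rx columns), the attrition rows, and the
    per-filter dropped patient ids.
    """
    cfg = config or cfgmod.DEFAULT_CONFIG
    window = cfg["cohort"]["rx_window_days"]
    formulary = cfg["formulary"]
    abx = set(cfgmod.antibiotic_drugs(formulary))

    events = index_events.merge(patients, on="patient_id", how="left", validate="1:1")
    rows: list[dict] = [_attrition_row("initial", 0, len(events))]
    drops: dict[str, list[str]] = {}

    def drop(mask: pd.Series, name: str):
        nonlocal events
        dropped = events.loc[mask, "patient_id"].tolist()
        drops[name] = dropped
        events = events.loc[~mask].reset_index(drop=True)
        rows.append(_attrition_row(name, len(dropped), len(events)))

    drop(events["sex"] != "female", "sex")
    events["age"] = age_at(events["birth_date"], events["index_date"])
    drop(events["age"] < 12, "age")

    rx = prescriptions.loc[
        (prescriptions["route"] == "oral") & prescriptions["drug"].isin(abx)
    ].merge(events[["patient_id", "index_date"]], on="patient_id", how="inner")
    delta = days_between(rx["order_date"], rx["index_date"])
    rx = rx.loc[(delta >= -window) & (delta <= window)]
    rx = rx.sort_values(["patient_id", "order_date", "rx_id", "drug"], kind="mergesort")
    initial = rx.groupby("patient_id").first()[["order_date", "drug"]]
    initial.columns = ["initial_rx_date", "initial_drug"]
    events = events.merge(initial, on="patient_id", how="left")
    drop(events["initial_rx_date"].isna(), "oral_rx_window")

    tested = set(cultures.loc[cultures["result"].notna(), "patient_id"])
    drop(~events["patient_id"].isin(tested), "culture_panel")

    return events, rows, drops


def _window_hit(
    events: pd.DataFrame, frame: pd.DataFrame, mask: pd.Series, lo: int, hi: int
) -> pd.Series:
    """Boolean per event row: qualifying ``frame`` row in [index+lo, index+hi]."""
    sub = frame.loc[mask, ["patient_id", frame.columns[frame.columns.str.contains("date")][0]]]
    date_col = sub.columns[1]
    merged = sub.merge(events[["patient_id", "index_date"]], on="patient_id", how="inner")
    delta = days_between(merged[date_col], merged["index_date"])
    hit = set(merged.loc[(delta >= lo) & (delta <= hi), "patient_id"])
    return events["patient_id"].isin(hit)


def apply_exclusion(
    events: pd.DataFrame,
    tables: dict[str, pd.DataFrame],
    scenario: CohortScenario | str = "baseline",
    config: dict | None = None,
) -> tuple[pd.DataFrame, list[dict], dict[str, list[str]]]:
    """Apply the scenario's exclusion filters in fixed order.

    Every drop is recorded in the attrition rows; nothing is silent.
    """
    cfg = config or cfgmod.DEFAULT_CONFIG
    if isinstance(scenario, str):
        scenario = get_scenario(scenario)
    cl = cfg["code_lists"]
    co = cfg["cohort"]
    formulary = cfg["formulary"]
    abx = set(cfgmod.antibiotic_drugs(formulary))
    dx = tables["diagnoses"]
    rx = tables["prescriptions"]
    patients = tables["patients"]

    events = events.copy()
    rows: list[dict] = []
    drops: dict[str, list[str]] = {}

    def drop(mask: pd.Series, name: str):
        nonlocal events
        dropped = events.loc[mask, "patient_id"].tolist()
        drops[name] = dropped
        events = events.loc[~mask].reset_index(drop=True)
        rows.append(_attrition_row(name, len(dropped), len(events)))

    if scenario.require_both_basis:
        drop(~(events["has_dx"] & events["has_culture"]), "strict_basis")

    symptom_any = dx[["fever_ge_38_3", "nausea", "vomiting", "flank_pain"]].any(axis=1)
    abx_rx = rx["drug"].isin(abx)

    def startswith_any(codes: pd.Series, prefixes: list[str]) -> pd.Series:
        return codes.astype(str).str.startswith(tuple(prefixes))

    filters = {
        "pregnancy": lambda: _window_hit(
            events, dx, dx["pregnancy_flag"].astype(bool), -co["pregnancy_lookback_days"], 0
        ),
        "hiv": lambda: _window_hit(
            events, dx, startswith_any(dx["code"], cl["hiv_prefixes"]), -(10**5), 0
        ),
        "prior_antibiotics": lambda: _window_hit(
            events, rx, abx_rx, -co["prior_abx_window_days"][0], -co["prior_abx_window_days"][1]
        ),
        "catheter": lambda: _window_hit(
            events, dx, dx["catheter_flag"].astype(bool), 0, co["catheter_window_days"]
        ),
        "cuti_symptoms": lambda: _window_hit(events, dx, symptom_any, 0, co["symptom_window_days"]),
        "iv_initial": lambda: _iv_initial_mask(events, rx, abx, co["rx_window_days"]),
        "complicating_comorbidity": lambda: _window_hit(
            events, dx, dx["code"].isin(set(cl["complicating"])), -(10**5), 0
        ),
        "missing_data": lambda: ~events["patient_id"]
        .map(patients.set_index("patient_id")["cost_data_complete"])
        .fillna(False)
        .astype(bool),
    }

    if co.get("hiv_abx_compound"):
        # compound reading: HIV/AIDS diagnosis AND recent antibiotic use
        hiv_mask = filters.pop("hiv")
        abx_mask = filters.pop("prior_antibiotics")
        compound = {"hiv_with_prior_antibiotics": lambda: hiv_mask() & abx_mask()}
        filters = {**compound, **filters}
        order = ("hiv_with_prior_antibiotics",) + tuple(
            f for f in scenario.exclusions if f not in ("hiv", "prior_antibiotics")
        )
    else:
        order = scenario.exclusions

    for name in order:
        drop(filters[name](), name)

    if scenario.drop_prior_infection:
        infected = _window_hit(
            events,
            dx,
            startswith_any(dx["code"], cl["infection_prefixes"]),
            -scenario.baseline_days,
            -1,
        )
        drop(infected, "prior_infection")

    if scenario.fq_only:
        drug_class = events["initial_drug"].map(lambda d: formulary[d]["class"])
        drop(drug_class != "fluoroquinolone", "non_fluoroquinolone_initial")

    if scenario.require_days_available:
        end = events["patient_id"].map(patients.set_index("patient_id")["observation_end"])
        needed = events["index_date"] + pd.to_timedelta(scenario.require_days_available, unit="D")
        drop(end < needed, "data_availability")

    return events, rows, drops


def _iv_initial_mask(events, rx, abx, window):
    iv = rx.loc[(rx["route"] == "iv") & rx["drug"].isin(abx)]
    merged = iv.merge(
        events[["patient_id", "index_date", "initial_rx_date"]], on="patient_id", how="inner"
    )
    delta = days_between(merged["order_date"], merged["index_date"])
    before_oral = merged["order_date"] < merged["initial_rx_date"]
    hit = set(merged.loc[(delta >= -window) & (delta <= window) & before_oral, "patient_id"])
    return events["patient_id"].isin(hit)


def attrition_waterfall(rows: list[dict]) -> pd.DataFrame:
    """Assemble and validate the attrition report (conservation + monotone)."""
    report = pd.DataFrame(rows, columns=["filter", "n_dropped", "n_remaining"])
    if report.empty:
        return report
    remaining = report["n_remaining"].to_numpy()
    if np.any(np.diff(remaining) > 0):
        raise ValueError("attrition counts must be non-increasing")
    initial = remaining[0] + report["n_dropped"].iloc[0]
    if initial != report["n_dropped"].sum() + remaining[-1]:
        raise ValueError("attrition conservation violated")
    return report


def build_cohort(
    tables: dict[str, pd.DataFrame],
    scenario: CohortScenario | str = "baseline",
    config: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, list[str]]]:
    """Run identification -> inclusion -> exclusion for one scenario.

    Returns (cohort, attrition report, per-filter dropped ids).
    """
    cfg = config or cfgmod.DEFAULT_CONFIG
    if isinstance(scenario, str):
        scenario = get_scenario(scenario)
    events = identify_index_events(tables["diagnoses"], tables["cultures"], cfg["code_lists"])
    events, inc_rows, inc_drops = apply_inclusion(
        events, tables["patients"], tables["prescriptions"], tables["cultures"], cfg
    )
    cohort, exc_rows, exc_drops = apply_exclusion(events, tables, scenario, cfg)
    report = attrition_waterfall(inc_rows + exc_rows)
    return cohort, report, {**inc_drops, **exc_drops}
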