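"""HCRU tabulation, fee-schedule costing, winsorization, currency adjustment.

All windows are half-open ``[start, end)`` in whole calendar days; an event
exactly on the index date belongs to follow-up, not baseline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import config as cfgmod

SETTINGS = (
    "inpatient",
    "emergency",
    "outpatient_clinic",
    "outpatient_ambulatory_surgery",
    "outpatient_other",
)

HCRU_COLUMNS = SETTINGS + ("drug_orders", "any_antibiotic")


def _window_frame(windows: pd.DataFrame) -> pd.DataFrame:
    required = {"patient_id", "start", "end"}
    if not required <= set(windows.columns):
        raise ValueError(f"windows must have columns {sorted(required)}")
    if (pd.to_datetime(windows["end"]) < pd.to_datetime(windows["start"])).any():
        raise ValueError("window end precedes start")
    return windows


def tabulate_hcru(
    encounters: pd.DataFrame,
    prescriptions: pd.DataFrame,
    windows: pd.DataFrame,
    formulary: dict | None = None,
) -> pd.DataFrame:
    """Per-patient event counts by setting within ``[start, end)``.

    ``windows`` has one row per patient (patient_id, start, end).  Returns a
    frame indexed by patient_id with one column per setting plus
    ``drug_orders`` and an ``any_antibiotic`` indicator.
    """
    windows = _window_frame(windows)
    formulary = formulary or cfgmod.DEFAULT_FORMULARY
    abx = set(cfgmod.antibiotic_drugs(formulary))

    if encounters["encounter_id"].duplicated().any():
        raise ValueError("duplicate encounter ids")

    out = pd.DataFrame(
        0, index=pd.Index(windows["patient_id"], name="patient_id"), columns=list(HCRU_COLUMNS)
    )
    enc = encounters.merge(windows, on="patient_id", how="inner")
    enc = enc.loc[(enc["date"] >= enc["start"]) & (enc["date"] < enc["end"])]
    counts = enc.groupby(["patient_id", "setting"]).size().unstack(fill_value=0)
    for setting in SETTINGS:
        if setting in counts:
            out.loc[counts.index, setting] = counts[setting]

    rx = prescriptions.merge(windows, on="patient_id", how="inner")
    rx = rx.loc[(rx["order_date"] >= rx["start"]) & (rx["order_date"] < rx["end"])]
    n_orders = rx.groupby("patient_id").size()
    out.loc[n_orders.index, "drug_orders"] = n_orders
    abx_patients = rx.loc[rx["drug"].isin(abx), "patient_id"].unique()
    out.loc[out.index.isin(abx_patients), "any_antibiotic"] = 1
    return out.astype(int)


def compute_costs(
    encounters: pd.DataFrame,
    prescriptions: pd.DataFrame,
    fee_schedule: dict,
    windows: pd.DataFrame,
    uti_codes: list[str] | None = None,
    uti_drugs: list[str] | None = None,
) -> pd.DataFrame:
    """All-cause and UTI-related cost per patient over ``[start, end)``.

    All-cause = encounter counts x setting unit cost + drug days x per-day
    cost.  UTI attribution: an encounter is UTI-related iff its primary code
    is on the UTI list; a drug order iff the drug is uUTI-indicated.
    """
    windows = _window_frame(windows)
    setting_fees = fee_schedule["settings"]
    drug_fees = fee_schedule["drugs_per_day"]
    uti_codes = set(uti_codes if uti_codes is not None else cfgmod.DEFAULT_CONFIG["code_lists"]["uuti"])
    uti_drugs = set(uti_drugs if uti_drugs is not None else cfgmod.indicated_set())

    enc = encounters.merge(windows, on="patient_id", how="inner")
    enc = enc.loc[(enc["date"] >= enc["start"]) & (enc["date"] < enc["end"])].copy()
    unpriced = set(enc["setting"]) - set(setting_fees)
    if unpriced:
        raise KeyError(f"unpriced encounter settings: {sorted(unpriced)}")
    enc["cost"] = enc["setting"].map(setting_fees).astype(float)
    enc["uti_related"] = enc["primary_code"].isin(uti_codes)

    rx = prescriptions.merge(windows, on="patient_id", how="inner")
    rx = rx.loc[(rx["order_date"] >= rx["start"]) & (rx["order_date"] < rx["end"])].copy()
    unpriced = set(rx["drug"]) - set(drug_fees)
    if unpriced:
        raise KeyError(f"unpriced drugs: {sorted(unpriced)}")
    rx["cost"] = rx["drug"].map(drug_fees).astype(float) * rx["duration_days"].astype(float)
    rx["uti_related"] = rx["drug"].isin(uti_drugs)

    events = pd.concat(
        [enc[["patient_id", "cost", "uti_related"]], rx[["patient_id", "cost", "uti_related"]]]
    )
    out = pd.DataFrame(
        0.0,
        index=pd.Index(windows["patient_id"], name="patient_id"),
        columns=["all_cause_cost", "uti_related_cost"],
    )
    if not events.empty:
        total = events.groupby("patient_id")["cost"].sum()
        out.loc[total.index, "all_cause_cost"] = total
        uti = events.loc[events["uti_related"]].groupby("patient_id")["cost"].sum()
        out.loc[uti.index, "uti_related_cost"] = uti
    return out


def winsorize(values, percentile: float = 98.0) -> np.ndarray:
    """Cap values above the given percentile at that percentile.

    The threshold is the order-statistic ("lower") percentile, so the capped
    threshold is always an observed value and the operation is exactly
    idempotent; an interpolated threshold would drift downward on repeated
    application.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot winsorize an empty vector")
    threshold = np.percentile(arr, percentile, method="lower")
    return np.minimum(arr, threshold)


def adjust_currency(
    cost, source_year: int, index_table: dict[int, float] | None = None, target_year: int = 2020
):
    """Rescale cost(s) from source-year to target-year dollars via the index."""
    table = index_table if index_table is not None else cfgmod.DEFAULT_CONFIG["currency_index"]
    for year in (source_year, target_year):
        if year not in table:
            raise KeyError(f"year {year} missing from currency index table")
    factor = table[target_year] / table[source_year]
    return np.asarray(cost, dtype=float) * factor if np.ndim(cost) else float(cost) * factor


def followup_windows(cohort: pd.DataFrame, followup_days: int) -> pd.DataFrame:
    """[index, index + followup_days) per cohort patient."""
    return pd.DataFrame(
        {
            "patient_id": cohort["patient_id"],
            "start": cohort["index_date"],
            "end": cohort["index_date"] + pd.to_timedelta(followup_days, unit="D"),
        }
    )


def baseline_windows(cohort: pd.DataFrame, baseline_days: int = 180) -> pd.DataFrame:
    """[index - baseline_days, index) per cohort patient."""
    return pd.DataFrame(
        {
            "patient_id": cohort["patient_id"],
            "start": cohort["index_date"] - pd.to_timedelta(baseline_days, unit="D"),
            "end": cohort["index_date"],
        }
    )
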