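"""Default analysis configuration: formulary, code lists, fees, weights.

Everything here is a documented default, overridable from a YAML file via
:func:`load_config`.  Code lists are deliberately short synthetic-friendly
stand-ins — the pipeline never hard-codes them elsewhere.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

#: Antibiotic formulary.  ``line`` drives the appropriateness rules; only
#: first-line agents carry a recommended duration (fosfomycin 1 day,
#: nitrofurantoin 5 days, SXT 3 days).
DEFAULT_FORMULARY: dict[str, dict] = {
    "fosfomycin": {"line": "first", "class": "fosfomycin", "recommended_duration_days": 1},
    "nitrofurantoin": {"line": "first", "class": "nitrofuran", "recommended_duration_days": 5},
    "sxt": {"line": "first", "class": "sulfonamide", "recommended_duration_days": 3},
    "ciprofloxacin": {"line": "second", "class": "fluoroquinolone"},
    "levofloxacin": {"line": "second", "class": "fluoroquinolone"},
    "ofloxacin": {"line": "second", "class": "fluoroquinolone"},
    "amoxicillin": {"line": "second", "class": "beta_lactam"},
    "cefaclor": {"line": "third", "class": "beta_lactam"},
    "cefdinir": {"line": "third", "class": "beta_lactam"},
    "cefpodoxime": {"line": "third", "class": "beta_lactam"},
    "ceftriaxone": {"line": "other", "class": "beta_lactam"},
    # non-antibiotic drug orders count toward pharmacy HCRU only
    "other_med": {"line": "other", "class": "non_antibiotic"},
}

DEFAULT_CONFIG: dict = {
    "formulary": DEFAULT_FORMULARY,
    "code_lists": {
        "uuti": ["N30.0", "N30.00", "N30.01", "N39.0"],
        "cuti": ["N10", "N12", "T83.51"],
        "hiv_prefixes": ["B20", "B21", "B22", "B23", "B24"],
        "complicating": ["E10.65", "C80.1", "D70.9"],
        "infection_prefixes": ["A4", "J18", "B96"],
        "uropathogens": [
            "escherichia_coli",
            "klebsiella_pneumoniae",
            "proteus_mirabilis",
            "enterococcus_faecalis",
        ],
    },
    # Charlson categories: ICD-10-style code prefixes and standard weights.
    "charlson": {
        "myocardial_infarction": {"prefixes": ["I21", "I22"], "weight": 1},
        "congestive_heart_failure": {"prefixes": ["I50"], "weight": 1},
        "peripheral_vascular": {"prefixes": ["I73"], "weight": 1},
        "cerebrovascular": {"prefixes": ["I63"], "weight": 1},
        "dementia": {"prefixes": ["F03"], "weight": 1},
        "copd": {"prefixes": ["J44"], "weight": 1},
        "rheumatic": {"prefixes": ["M05", "M06"], "weight": 1},
        "peptic_ulcer": {"prefixes": ["K27"], "weight": 1},
        "mild_liver": {"prefixes": ["K76.0"], "weight": 1},
        "hemiparesis": {"prefixes": ["G81"], "weight": 2},
        "renal": {"prefixes": ["N18"], "weight": 2},
        "moderate_severe_liver": {"prefixes": ["K72"], "weight": 3},
    },
    # Stand-in fee schedule (real Medicare / WAC files are out of scope).
    "fee_schedule": {
        "settings": {
            "inpatient": 8000.0,
            "emergency": 650.0,
            "outpatient_clinic": 150.0,
            "outpatient_ambulatory_surgery": 1200.0,
            "outpatient_other": 300.0,
        },
        "drugs_per_day": {
            "fosfomycin": 40.0,
            "nitrofurantoin": 2.0,
            "sxt": 1.5,
            "ciprofloxacin": 2.0,
            "levofloxacin": 3.0,
            "ofloxacin": 3.0,
            "amoxicillin": 1.0,
            "cefaclor": 4.0,
            "cefdinir": 5.0,
            "cefpodoxime": 6.0,
            "ceftriaxone": 25.0,
            "other_med": 1.0,
        },
        "currency_year": 2020,
    },
    # Medical-care price index used for currency-year adjustment.
    "currency_index": {2016: 0.928, 2017: 0.948, 2018: 0.971, 2019: 0.988, 2020: 1.0},
    "cohort": {
        "rx_window_days": 5,  # oral antibiotic required within [index-5, index+5]
        "catheter_window_days": 2,  # "within 48 h" = index + 2 calendar days
        "symptom_window_days": 2,
        "prior_abx_window_days": [180, 6],  # [index-180, index-6]
        "pregnancy_lookback_days": 180,
        "hiv_abx_compound": False,  # two independent criteria by default
    },
    "classifier": {
        "episode_window_days": 28,
        "switch_window_days": 28,
        "allergy_lookback": "any",  # or "pre_index"
        "resistance_escape_requires_all_tested": True,
        "duration_tolerance_days": 0,
    },
    "psm": {
        "caliper_sd": 0.2,
        "covariates_susceptibility": [
            "age",
            "white",
            "private_insurance",
            "baseline_inpatient",
            "baseline_outpatient_clinic_other",
        ],
        "covariates_appropriateness": ["age", "white", "private_insurance"],
    },
    "cost_model": {
        "zero_offset": 0.01,
        "winsorize_percentile": 98.0,
        "adjusters": [
            "cci",
            "baseline_inpatient",
            "baseline_emergency",
            "baseline_outpatient",
            "baseline_drug_orders",
        ],
    },
}


def first_line_drugs(formulary: dict | None = None) -> list[str]:
    formulary = formulary or DEFAULT_FORMULARY
    return [d for d, v in formulary.items() if v["line"] == "first"]


def antibiotic_drugs(formulary: dict | None = None) -> list[str]:
    formulary = formulary or DEFAULT_FORMULARY
    return [d for d, v in formulary.items() if v["class"] != "non_antibiotic"]


def indicated_set(formulary: dict | None = None) -> list[str]:
    """uUTI-indicated antibiotics: formulary lines first + second + third."""
    formulary = formulary or DEFAULT_FORMULARY
    return [d for d, v in formulary.items() if v["line"] in ("first", "second", "third")]


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(value, dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Return the default config, deep-merged with a YAML file and/or a dict."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            file_cfg = yaml.safe_load(fh) or {}
        cfg = _deep_merge(cfg, file_cfg)
    if overrides:
        cfg = _deep_merge(cfg, overrides)
    return cfg
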