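import os
import sys

import pandas as pd
import pytest

sys.path.insert(0, os.path.dirname(__file__))  # for tests._oracles-style imports

from uticost.config import DEFAULT_CONFIG
from uticost.synthetic_ehr import SimConfig, generate_population, inject_exclusion_cases

T = pd.Timestamp


@pytest.fixture(scope="session")
def cfg():
    return DEFAULT_CONFIG


@pytest.fixture(scope="session")
def tables_small():
    """A 400-patient population with two planted patients per exclusion reason."""
    sim = SimConfig(n_patients=400, seed=11, followup_days=360)
    tables = generate_population(sim)
    counts = {
        reason: 2
        for reason in (
            "male",
            "age_lt_12",
            "no_oral_rx",
            "no_culture_panel",
            "pregnancy",
            "hiv",
            "prior_antibiotics",
            "catheter",
            "cuti_symptoms",
            "iv_initial",
            "complicating_comorbidity",
            "missing_costs",
        )
    }
    return inject_exclusion_cases(tables, sim, counts), sim, counts


def one_patient_tables(
    pid="P1",
    index=T("2018-03-10"),
    sex="female",
    birth=T("1990-05-01"),
    drug="nitrofurantoin",
    duration=5,
    rx_offset=0,
    cfu=1e5,
    organism="escherichia_coli",
    panel=None,
    dx_code="N39.0",
    with_dx=True,
):
    """Minimal consistent tables for a single clean patient; tests perturb."""
    panel = panel if panel is not None else {"nitrofurantoin": "S", "sxt": "S"}
    patients = pd.DataFrame(
        [
            {
                "patient_id": pid,
                "sex": sex,
                "birth_date": birth,
                "race": "white",
                "ethnicity": "non_hispanic",
                "insurance": "private",
                "observation_end": index + pd.Timedelta(days=400),
                "cost_data_complete": True,
            }
        ]
    )
    dx_rows = []
    if with_dx:
        dx_rows.append(
            {
                "patient_id": pid,
                "date": index,
                "code": dx_code,
                "fever_ge_38_3": False,
                "nausea": False,
                "vomiting": False,
                "flank_pain": False,
                "pregnancy_flag": False,
                "catheter_flag": False,
            }
        )
    diagnoses = pd.DataFrame(
        dx_rows,
        columns=[
            "patient_id",
            "date",
            "code",
            "fever_ge_38_3",
            "nausea",
            "vomiting",
            "flank_pain",
            "pregnancy_flag",
            "catheter_flag",
        ],
    )
    prescriptions = pd.DataFrame(
        [
            {
                "rx_id": "R1",
                "patient_id": pid,
                "order_date": index + pd.Timedelta(days=rx_offset),
                "drug": drug,
                "route": "oral",
                "duration_days": duration,
            }
        ]
    )
    cultures = pd.DataFrame(
        [
            {
                "culture_id": f"{pid}-C1",
                "patient_id": pid,
                "collection_date": index,
                "organism": organism,
                "cfu_per_ml": cfu,
                "antibiotic": abx,
                "result": res,
            }
            for abx, res in panel.items()
        ]
    )
    encounters = pd.DataFrame(
        columns=["encounter_id", "patient_id", "date", "setting", "primary_code"]
    )
    allergies = pd.DataFrame(columns=["patient_id", "drug", "record_date"])
    return {
        "patients": patients,
        "diagnoses": diagnoses,
        "encounters": encounters,
        "prescriptions": prescriptions,
        "cultures": cultures,
        "allergies": allergies,
    }


@pytest.fixture
def toy_tables():
    return one_patient_tables
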