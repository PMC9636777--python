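"""Seeded synthetic EHR generator with planted ground truth.

Produces the six flat tables the pipeline consumes (patients, diagnoses,
encounters, prescriptions, cultures, allergies) plus a per-patient ground
truth record, so every downstream stage can be tested against known answers:
exposure-group assignment, susceptibility status, exclusion reasons, and
expected follow-up cost per group.

Design notes
------------
* Not-susceptibility is confounded with age / race / insurance through a
  logistic index whose intercept is numerically calibrated so the marginal
  prevalence equals the configured value exactly in expectation.
* Follow-up costs are gamma-distributed around ``base_cost x multiplier`` for
  the patient's true exposure group and realized as Poisson numbers of
  priced encounters, so the cost engine's fee-schedule arithmetic recovers
  the planted group means.
* Every "inappropriate or suboptimal" patient is realized through a concrete
  mechanism (initial fluoroquinolone, agent with a resistant isolate, early
  switch, or IV use) so the rule engine reproduces the planted label
  deterministically.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import truncnorm

from . import config as cfgmod
from ._util import sorted_frame, write_csv

EXPOSURE_GROUPS = ("S_app", "S_inapp_sub", "NS_app", "NS_inapp_sub")

#: antibiotics included on every generated susceptibility panel
PANEL_ANTIBIOTICS = ("nitrofurantoin", "sxt", "ciprofloxacin", "levofloxacin", "amoxicillin")

_EPOCH = pd.Timestamp("2017-01-01")

#: exclusion reasons :func:`inject_exclusion_cases` can plant, mapped to the
#: waterfall filter expected to drop them.
PLANT_FILTERS = {
    "male": "sex",
    "age_lt_12": "age",
    "no_oral_rx": "oral_rx_window",
    "no_culture_panel": "culture_panel",
    "pregnancy": "pregnancy",
    "hiv": "hiv",
    "prior_antibiotics": "prior_antibiotics",
    "catheter": "catheter",
    "cuti_symptoms": "cuti_symptoms",
    "iv_initial": "iv_initial",
    "complicating_comorbidity": "complicating_comorbidity",
    "missing_costs": "missing_data",
}


@dataclass
class SimConfig:
    """Parameters of the synthetic population.

    Probability maps over categories must sum to 1; per-condition comorbidity
    probabilities are independent Bernoulli rates.  Defaults echo the shape of
    the reference cohort (mean age ~43.5, ~40% person-level not-susceptible,
    ~5% allergic) without claiming its exact distributions.
    """

    n_patients: int = 1000
    seed: int = 0
    prevalence_not_susceptible: float = 0.40
    p_inappropriate_given_ns: float = 0.48
    p_inappropriate_given_s: float = 0.235
    allergy_prevalence: float = 0.052
    age_mean: float = 43.5
    age_sd: float = 18.0
    race_probs: dict = field(
        default_factory=lambda: {
            "white": 0.595,
            "african_american": 0.250,
            "asian": 0.033,
            "other": 0.060,
            "unknown": 0.062,
        }
    )
    ethnicity_probs: dict = field(
        default_factory=lambda: {
            "hispanic": 0.030,
            "non_hispanic": 0.874,
            "other": 0.004,
            "unknown": 0.092,
        }
    )
    insurance_probs: dict = field(
        default_factory=lambda: {"private": 0.613, "medicare_medicaid": 0.157, "other": 0.230}
    )
    comorbidity_probs: dict = field(
        default_factory=lambda: {
            "copd": 0.022,
            "dementia": 0.007,
            "rheumatic": 0.006,
            "cerebrovascular": 0.004,
            "congestive_heart_failure": 0.002,
            "mild_liver": 0.003,
            "peripheral_vascular": 0.003,
            "peptic_ulcer": 0.001,
            "renal": 0.001,
            "myocardial_infarction": 0.001,
            "hemiparesis": 0.001,
            "moderate_severe_liver": 0.001,
        }
    )
    cost_shape: float = 1.5
    base_cost_allcause: float = 2532.0
    base_cost_uti: float = 945.0
    group_cost_multipliers: dict = field(
        default_factory=lambda: {
            "S_app": 1.00,
            "S_inapp_sub": 1.10,
            "NS_app": 1.25,
            "NS_inapp_sub": 1.40,
        }
    )
    followup_days: int = 180
    baseline_days: int = 180
    # logistic confounding of not-susceptibility on covariates
    conf_age: float = 0.25
    conf_white: float = -0.35
    conf_private: float = -0.45
    # index-event basis mix
    basis_probs: dict = field(
        default_factory=lambda: {"both": 0.70, "diagnosis_code": 0.20, "culture": 0.10}
    )
    p_cuti_progression_s: float = 0.03
    p_cuti_progression_ns: float = 0.09
    p_prior_infection: float = 0.05
    p_long_data: float = 0.85  # fraction with >= 360 days of follow-up data

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        for name in (
            "prevalence_not_susceptible",
            "p_inappropriate_given_ns",
            "p_inappropriate_given_s",
            "allergy_prevalence",
            "p_cuti_progression_s",
            "p_cuti_progression_ns",
            "p_prior_infection",
            "p_long_data",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        for name in ("race_probs", "ethnicity_probs", "insurance_probs", "basis_probs"):
            probs = getattr(self, name)
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1, got {total}")
            if any(p < 0 for p in probs.values()):
                raise ValueError(f"{name} contains a negative probability")
        for p in self.comorbidity_probs.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("comorbidity probabilities must lie in [0, 1]")
        if any(m <= 0 for m in self.group_cost_multipliers.values()):
            raise ValueError("group cost multipliers must be positive")
        if self.cost_shape <= 0:
            raise ValueError("cost_shape must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _calibrated_ns_probability(linear: np.ndarray, prevalence: float) -> np.ndarray:
    """Per-patient P(not-susceptible) with marginal mean == ``prevalence``."""
    if prevalence <= 0.0:
        return np.zeros_like(linear)
    if prevalence >= 1.0:
        return np.ones_like(linear)
    if np.ptp(linear) < 1e-12:
        return np.full_like(linear, prevalence)
    intercept = brentq(lambda c: expit(c + linear).mean() - prevalence, -30.0, 30.0)
    return expit(intercept + linear)


def _choice(rng: np.random.Generator, probs: dict, size: int) -> np.ndarray:
    keys = list(probs.keys())
    p = np.array([probs[k] for k in keys], dtype=float)
    return rng.choice(keys, size=size, p=p / p.sum())


def generate_population(sim: SimConfig, config: dict | None = None) -> dict[str, pd.DataFrame]:
    """Generate the six EHR tables plus a ``ground_truth`` table.

    Every core patient is female, aged >= 12 at index, carries an index uUTI
    diagnosis and/or qualifying culture per ``basis_probs``, has an oral
    antibiotic order inside the +/-5-day window, and a culture with a full
    S/I/R panel.  Identical ``SimConfig`` (including seed) yields identical
    tables.
    """
    sim.validate()
    cfg = config or cfgmod.DEFAULT_CONFIG
    rng = np.random.default_rng(sim.seed)
    n = sim.n_patients
    fees = cfg["fee_schedule"]["settings"]
    uuti_codes = cfg["code_lists"]["uuti"]
    cuti_codes = cfg["code_lists"]["cuti"]
    charlson = cfg["charlson"]

    ids = np.array([f"P{i:06d}" for i in range(n)])
    age = truncnorm.rvs(
        (12.0 - sim.age_mean) / sim.age_sd,
        np.inf,
        loc=sim.age_mean,
        scale=sim.age_sd,
        size=n,
        random_state=rng,
    )
    index_offset = rng.integers(0, 900, n)
    index_date = _EPOCH + pd.to_timedelta(index_offset, unit="D")
    race = _choice(rng, sim.race_probs, n)
    ethnicity = _choice(rng, sim.ethnicity_probs, n)
    insurance = _choice(rng, sim.insurance_probs, n)
    white = (race == "white").astype(float)
    private = (insurance == "private").astype(float)

    z_age = (age - sim.age_mean) / sim.age_sd
    linear = sim.conf_age * z_age + sim.conf_white * white + sim.conf_private * private
    p_ns = _calibrated_ns_probability(linear, sim.prevalence_not_susceptible)
    ns = rng.random(n) < p_ns
    p_inapp = np.where(ns, sim.p_inappropriate_given_ns, sim.p_inappropriate_given_s)
    inapp = rng.random(n) < p_inapp
    group = np.where(
        ns,
        np.where(inapp, "NS_inapp_sub", "NS_app"),
        np.where(inapp, "S_inapp_sub", "S_app"),
    )
    multiplier = pd.Series(group).map(sim.group_cost_multipliers).to_numpy(dtype=float)

    # follow-up cost targets and their encounter realizations
    mean_all = sim.base_cost_allcause * multiplier
    c_all = rng.gamma(sim.cost_shape, mean_all / sim.cost_shape)
    uti_fraction = sim.base_cost_uti / sim.base_cost_allcause
    c_uti = uti_fraction * c_all
    n_uti_enc = rng.poisson(c_uti / fees["outpatient_clinic"])
    n_other_enc = rng.poisson((c_all - c_uti) / fees["outpatient_other"])

    basis = _choice(rng, sim.basis_probs, n)
    allergic = rng.random(n) < sim.allergy_prevalence
    prior_infection = rng.random(n) < sim.p_prior_infection
    long_data = rng.random(n) < sim.p_long_data
    p_cuti = np.where(ns, sim.p_cuti_progression_ns, sim.p_cuti_progression_s)
    progressed = rng.random(n) < p_cuti

    # baseline HCRU rates, mildly imbalanced by susceptibility status
    nsf = ns.astype(float)
    base_counts = {
        "outpatient_clinic": rng.poisson(0.90 + 0.08 * nsf),
        "outpatient_other": rng.poisson(0.115 - 0.035 * nsf),
        "emergency": rng.poisson(0.052 + 0.032 * nsf),
        "inpatient": rng.poisson(0.004 + 0.008 * nsf),
        "outpatient_ambulatory_surgery": rng.poisson(0.010 + 0.004 * nsf),
    }
    base_meds = rng.poisson(1.7 + 0.4 * nsf)

    patients = pd.DataFrame(
        {
            "patient_id": ids,
            "sex": "female",
            "birth_date": index_date - pd.to_timedelta(np.round(age * 365.25).astype(int), unit="D"),
            "race": race,
            "ethnicity": ethnicity,
            "insurance": insurance,
            "observation_end": index_date
            + pd.to_timedelta(np.where(long_data, max(sim.followup_days, 365), 180), unit="D"),
            "cost_data_complete": True,
        }
    )

    dx_rows: list[dict] = []
    rx_rows: list[dict] = []
    cult_rows: list[dict] = []
    allergy_rows: list[dict] = []
    mechanisms = np.full(n, "none", dtype=object)

    first_line = cfgmod.first_line_drugs(cfg["formulary"])
    abx = cfgmod.antibiotic_drugs(cfg["formulary"])
    rec_dur = {d: cfg["formulary"][d].get("recommended_duration_days") for d in first_line}

    def add_dx(pid, date, code, **flags):
        row = {
            "patient_id": pid,
            "date": date,
            "code": code,
            "fever_ge_38_3": False,
            "nausea": False,
            "vomiting": False,
            "flank_pain": False,
            "pregnancy_flag": False,
            "catheter_flag": False,
        }
        row.update(flags)
        dx_rows.append(row)

    for i in range(n):
        pid = ids[i]
        idx = index_date[i]

        # index diagnosis and culture per basis
        if basis[i] in ("both", "diagnosis_code"):
            add_dx(pid, idx, uuti_codes[rng.integers(len(uuti_codes))])
        cfu = 1e5 if basis[i] in ("both", "culture") else 5e3

        # treatment realization -> prescriptions + consistent panel
        panel = {d: "S" for d in PANEL_ANTIBIOTICS}
        received: list[str] = []
        if not inapp[i]:
            drug = rng.choice(["nitrofurantoin", "sxt", "fosfomycin"], p=[0.70, 0.25, 0.05])
            rx_rows.append(
                {
                    "patient_id": pid,
                    "order_date": idx,
                    "drug": drug,
                    "route": "oral",
                    "duration_days": rec_dur[drug],
                }
            )
            received = [drug]
        else:
            if ns[i]:
                mech = rng.choice(["fq_initial", "resistant_rx", "switch", "iv"], p=[0.40, 0.30, 0.15, 0.15])
            else:
                mech = rng.choice(["fq_initial", "switch", "iv"], p=[0.55, 0.225, 0.225])
            mechanisms[i] = mech
            if mech == "fq_initial":
                rx_rows.append(
                    {"patient_id": pid, "order_date": idx, "drug": "ciprofloxacin", "route": "oral", "duration_days": 7}
                )
                received = ["ciprofloxacin"]
            elif mech == "resistant_rx":
                rx_rows.append(
                    {"patient_id": pid, "order_date": idx, "drug": "sxt", "route": "oral", "duration_days": 3}
                )
                received = ["sxt"]
                panel["sxt"] = "R"
            elif mech == "switch":
                rx_rows.append(
                    {"patient_id": pid, "order_date": idx, "drug": "nitrofurantoin", "route": "oral", "duration_days": 5}
                )
                rx_rows.append(
                    {
                        "patient_id": pid,
                        "order_date": idx + pd.Timedelta(days=7),
                        "drug": "sxt",
                        "route": "oral",
                        "duration_days": 3,
                    }
                )
                received = ["nitrofurantoin", "sxt"]
            else:  # iv after the oral start: suboptimal route, not an exclusion
                rx_rows.append(
                    {"patient_id": pid, "order_date": idx, "drug": "nitrofurantoin", "route": "oral", "duration_days": 5}
                )
                rx_rows.append(
                    {
                        "patient_id": pid,
                        "order_date": idx + pd.Timedelta(days=3),
                        "drug": "ceftriaxone",
                        "route": "iv",
                        "duration_days": 3,
                    }
                )
                received = ["nitrofurantoin", "ceftriaxone"]

        if ns[i]:
            # make the person not-susceptible without justifying escalation:
            # keep at least one first-line agent (and everything received) S
            safe = received[0] if received[0] in first_line else "nitrofurantoin"
            candidates = [d for d in PANEL_ANTIBIOTICS if d not in received and d != safe]
            k = 1 + int(rng.random() < 0.4)
            for d in rng.choice(candidates, size=min(k, len(candidates)), replace=False):
                panel[d] = "R" if rng.random() < 0.8 else "I"
            if not any(panel[d] in ("I", "R") for d in PANEL_ANTIBIOTICS):
                panel[candidates[0]] = "R"

        organism = ["escherichia_coli", "klebsiella_pneumoniae", "proteus_mirabilis"][
            rng.integers(3) if rng.random() < 0.35 else 0
        ]
        for drug, result in panel.items():
            cult_rows.append(
                {
                    "culture_id": f"{pid}-C1",
                    "patient_id": pid,
                    "collection_date": idx,
                    "organism": organism,
                    "cfu_per_ml": cfu,
                    "antibiotic": drug,
                    "result": result,
                }
            )

        if allergic[i]:
            options = [d for d in abx if d not in received]
            allergy_rows.append(
                {
                    "patient_id": pid,
                    "drug": options[rng.integers(len(options))],
                    "record_date": idx + pd.Timedelta(days=int(rng.integers(1, 31))),
                }
            )

        # comorbidities (Charlson categories), coded before index
        for cat, p in sim.comorbidity_probs.items():
            if cat in charlson and rng.random() < p:
                add_dx(
                    pid,
                    idx - pd.Timedelta(days=int(rng.integers(30, 171))),
                    charlson[cat]["prefixes"][0],
                )
        if prior_infection[i]:
            add_dx(pid, idx - pd.Timedelta(days=int(rng.integers(30, 171))), "J18.9")
        if progressed[i]:
            add_dx(
                pid,
                idx + pd.Timedelta(days=int(rng.integers(5, 27))),
                cuti_codes[rng.integers(len(cuti_codes))],
            )

        # baseline pharmacy orders (non-antibiotic, so no exclusion fires)
        for _ in range(base_meds[i]):
            rx_rows.append(
                {
                    "patient_id": pid,
                    "order_date": idx - pd.Timedelta(days=int(rng.integers(1, sim.baseline_days))),
                    "drug": "other_med",
                    "route": "oral",
                    "duration_days": 30,
                }
            )

    # encounters, vectorized: baseline per-setting + follow-up priced visits
    enc_pid: list[np.ndarray] = []
    enc_day: list[np.ndarray] = []
    enc_setting: list[np.ndarray] = []
    enc_code: list[np.ndarray] = []

    def extend(counts, setting, day_lo, day_hi, code):
        total = int(counts.sum())
        if total == 0:
            return
        pid_rep = np.repeat(ids, counts)
        base = np.repeat(index_offset, counts)
        days = base + rng.integers(day_lo, day_hi, total)
        enc_pid.append(pid_rep)
        enc_day.append(days)
        enc_setting.append(np.full(total, setting, dtype=object))
        enc_code.append(np.full(total, code, dtype=object))

    for setting, counts in base_counts.items():
        extend(counts, setting, -sim.baseline_days, 0, "Z00.0")
    extend(n_uti_enc, "outpatient_clinic", 0, sim.followup_days, uuti_codes[0])
    extend(n_other_enc, "outpatient_other", 0, sim.followup_days, "Z00.0")

    if enc_pid:
        encounters = pd.DataFrame(
            {
                "patient_id": np.concatenate(enc_pid),
                "date": _EPOCH + pd.to_timedelta(np.concatenate(enc_day), unit="D"),
                "setting": np.concatenate(enc_setting),
                "primary_code": np.concatenate(enc_code),
            }
        )
    else:  # pragma: no cover - degenerate tiny configs
        encounters = pd.DataFrame(columns=["patient_id", "date", "setting", "primary_code"])
    encounters = sorted_frame(encounters, ["patient_id", "date", "setting", "primary_code"])
    encounters.insert(0, "encounter_id", [f"E{i:07d}" for i in range(len(encounters))])

    prescriptions = sorted_frame(
        pd.DataFrame(rx_rows), ["patient_id", "order_date", "drug", "route"]
    )
    prescriptions.insert(0, "rx_id", [f"R{i:07d}" for i in range(len(prescriptions))])

    diagnoses = sorted_frame(pd.DataFrame(dx_rows), ["patient_id", "date", "code"])
    cultures = sorted_frame(pd.DataFrame(cult_rows), ["patient_id", "collection_date", "antibiotic"])
    allergies = sorted_frame(
        pd.DataFrame(allergy_rows, columns=["patient_id", "drug", "record_date"]),
        ["patient_id", "drug"],
    )

    ground_truth = pd.DataFrame(
        {
            "patient_id": ids,
            "index_date": index_date,
            "basis": basis,
            "true_not_susceptible": ns.astype(int),
            "true_exposure_group": group,
            "mechanism": mechanisms,
            "cost_multiplier": multiplier,
            "expected_allcause_cost": mean_all,
            "expected_uti_cost": sim.base_cost_uti * multiplier,
            "progressed_cuti": progressed.astype(int),
            "prior_infection": prior_infection.astype(int),
            "exclusion_reason": pd.Series([pd.NA] * n, dtype="object"),
        }
    )

    return {
        "patients": patients,
        "diagnoses": diagnoses,
        "encounters": encounters,
        "prescriptions": prescriptions,
        "cultures": cultures,
        "allergies": allergies,
        "ground_truth": ground_truth,
    }


def inject_exclusion_cases(
    tables: dict[str, pd.DataFrame], sim: SimConfig, counts: dict[str, int], config: dict | None = None
) -> dict[str, pd.DataFrame]:
    """Append planted patients, each violating exactly one waterfall filter.

    Each planted patient starts from a clean template (susceptible,
    appropriately treated, same-day diagnosis + culture) and receives one
    targeted defect, so it must survive every earlier filter and drop at
    precisely the intended one.  The reason is recorded in ``ground_truth``.
    """
    cfg = config or cfgmod.DEFAULT_CONFIG
    unknown = set(counts) - set(PLANT_FILTERS)
    if unknown:
        raise ValueError(f"unknown exclusion reasons: {sorted(unknown)}")
    if any(c < 0 for c in counts.values()):
        raise ValueError("exclusion counts must be nonnegative")
    total = sum(counts.values())
    if total > sim.n_patients:
        raise ValueError("requested exclusion count exceeds n_patients")
    if total == 0:
        return tables

    template_sim = dataclasses.replace(
        sim,
        n_patients=total,
        seed=sim.seed + 104729,
        prevalence_not_susceptible=0.0,
        p_inappropriate_given_s=0.0,
        p_inappropriate_given_ns=0.0,
        allergy_prevalence=0.0,
        p_prior_infection=0.0,
        p_cuti_progression_s=0.0,
        p_cuti_progression_ns=0.0,
        basis_probs={"both": 1.0, "diagnosis_code": 0.0, "culture": 0.0},
        comorbidity_probs={},
    )
    plants = generate_population(template_sim, cfg)
    rename = {}
    reasons = [r for r, c in sorted(counts.items()) for _ in range(c)]
    for j, old in enumerate(plants["patients"]["patient_id"]):
        rename[old] = f"X{j:05d}"
    for name, frame in plants.items():
        frame["patient_id"] = frame["patient_id"].map(rename)
    # keep row identifiers globally unique after concatenation with the core
    plants["cultures"]["culture_id"] = plants["cultures"]["patient_id"] + "-C1"
    plants["encounters"]["encounter_id"] = "X" + plants["encounters"]["encounter_id"]
    plants["prescriptions"]["rx_id"] = "X" + plants["prescriptions"]["rx_id"]

    gt = plants["ground_truth"].set_index("patient_id")
    gt["exclusion_reason"] = pd.NA
    patients = plants["patients"].set_index("patient_id")
    complicating = cfg["code_lists"]["complicating"]

    def plant_dx(pid, offset_days, code, **flags):
        idx = gt.loc[pid, "index_date"]
        row = {
            "patient_id": pid,
            "date": idx + pd.Timedelta(days=offset_days),
            "code": code,
            "fever_ge_38_3": False,
            "nausea": False,
            "vomiting": False,
            "flank_pain": False,
            "pregnancy_flag": False,
            "catheter_flag": False,
        }
        row.update(flags)
        plants["diagnoses"] = pd.concat(
            [plants["diagnoses"], pd.DataFrame([row])], ignore_index=True
        )

    def plant_rx(pid, offset_days, drug, route, duration):
        idx = gt.loc[pid, "index_date"]
        plants["prescriptions"] = pd.concat(
            [
                plants["prescriptions"],
                pd.DataFrame(
                    [
                        {
                            "rx_id": f"RX-{pid}",
                            "patient_id": pid,
                            "order_date": idx + pd.Timedelta(days=offset_days),
                            "drug": drug,
                            "route": route,
                            "duration_days": duration,
                        }
                    ]
                ),
            ],
            ignore_index=True,
        )

    for j, reason in enumerate(reasons):
        pid = f"X{j:05d}"
        gt.loc[pid, "exclusion_reason"] = reason
        if reason == "male":
            patients.loc[pid, "sex"] = "male"
        elif reason == "age_lt_12":
            patients.loc[pid, "birth_date"] = gt.loc[pid, "index_date"] - pd.Timedelta(days=int(10 * 365.25))
        elif reason == "no_oral_rx":
            rx = plants["prescriptions"]
            plants["prescriptions"] = rx[rx["patient_id"] != pid].reset_index(drop=True)
        elif reason == "no_culture_panel":
            cu = plants["cultures"]
            plants["cultures"] = cu[cu["patient_id"] != pid].reset_index(drop=True)
        elif reason == "pregnancy":
            plant_dx(pid, 0, "Z33.1", pregnancy_flag=True)
        elif reason == "hiv":
            plant_dx(pid, -100, "B20")
        elif reason == "prior_antibiotics":
            plant_rx(pid, -30, "nitrofurantoin", "oral", 5)
        elif reason == "catheter":
            plant_dx(pid, 1, "Z93.6", catheter_flag=True)
        elif reason == "cuti_symptoms":
            plant_dx(pid, 1, "R50.9", fever_ge_38_3=True)
        elif reason == "iv_initial":
            plant_rx(pid, -2, "ceftriaxone", "iv", 3)
        elif reason == "complicating_comorbidity":
            plant_dx(pid, -50, complicating[0])
        elif reason == "missing_costs":
            patients.loc[pid, "cost_data_complete"] = False

    plants["patients"] = patients.reset_index()
    plants["ground_truth"] = gt.reset_index()

    out = {}
    for name in tables:
        parts = [f for f in (tables[name], plants[name]) if not f.empty]
        if not parts:
            out[name] = tables[name]
        elif len(parts) == 1:
            out[name] = parts[0].reset_index(drop=True)
        else:
            out[name] = pd.concat(parts, ignore_index=True)
    return out


def write_tables(tables: dict[str, pd.DataFrame], outdir: str | Path) -> None:
    """Write all tables as UTF-8 CSV with ISO-8601 dates (deterministic)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, frame in tables.items():
        write_csv(frame, outdir / f"{name}.csv")


_DATE_COLS = {
    "patients": ["birth_date", "observation_end"],
    "diagnoses": ["date"],
    "encounters": ["date"],
    "prescriptions": ["order_date"],
    "cultures": ["collection_date"],
    "allergies": ["record_date"],
    "ground_truth": ["index_date"],
}


def read_tables(indir: str | Path) -> dict[str, pd.DataFrame]:
    """Read tables written by :func:`write_tables` (ground_truth optional)."""
    indir = Path(indir)
    tables = {}
    for name, date_cols in _DATE_COLS.items():
        path = indir / f"{name}.csv"
        if not path.exists():
            if name == "ground_truth":
                continue
            raise FileNotFoundError(path)
        tables[name] = pd.read_csv(path, parse_dates=date_cols)
    return tables


def write_sim_config(sim: SimConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(sim.to_dict(), fh, indent=2, default=str)
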