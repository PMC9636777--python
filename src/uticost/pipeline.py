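"""End-to-end orchestration: generate -> cohort -> classify -> cost -> analyze.

Every stage persists its outputs as delimited text so each report can be
rebuilt from the intermediate tables alone; a manifest records the config
hash, seed and package version.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, config as cfgmod
from ._util import write_csv
from .classifier import allergy_table, classification_summary, label_cohort
from .cohort import build_cohort, get_scenario
from .psm import balance_table, estimate_propensity, match_1to1, stratified_cost_report
from .sensitivity import SCENARIO_ORDER, build_analysis_frame, run_battery
from .synthetic_ehr import SimConfig, generate_population, read_tables, write_sim_config, write_tables

REPORT_FILES = (
    "attrition.csv",
    "classification_summary.csv",
    "allergy_table.csv",
    "balance_table.csv",
    "stratified_costs.csv",
    "sensitivity_table.csv",
)


@dataclass
class RunConfig:
    """Inputs for one pipeline run: either a simulation config or a directory
    of pre-existing tables, plus seed/config/output locations."""

    out_dir: Path
    seed: int = 0
    sim: SimConfig | None = None
    input_dir: Path | None = None
    config: dict = field(default_factory=lambda: cfgmod.DEFAULT_CONFIG)
    scenarios: tuple[str, ...] = SCENARIO_ORDER

    def validate(self) -> None:
        if self.sim is None and self.input_dir is None:
            raise ValueError("either sim or input_dir must be provided")


def _config_hash(cfg: dict) -> str:
    canon = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(canon).hexdigest()[:16]


def run_pipeline(rc: RunConfig) -> dict[str, Path]:
    """Execute all stages and write the six report files plus a manifest."""
    rc.validate()
    out = Path(rc.out_dir)
    tables_dir = out / "tables"
    reports_dir = out / "reports"
    reports_dir.mkdir(parents=True, exist_ok=True)
    cfg = rc.config

    if rc.input_dir is not None:
        tables = read_tables(rc.input_dir)
    else:
        tables = generate_population(rc.sim, cfg)
        write_tables(tables, tables_dir)
        write_sim_config(rc.sim, tables_dir / "sim_config.json")

    cohort, attrition, _ = build_cohort(tables, "baseline", cfg)
    write_csv(attrition, reports_dir / "attrition.csv")

    labels = label_cohort(
        cohort, tables["prescriptions"], tables["cultures"], tables["allergies"], cfg
    )
    labels.to_csv(out / "labels.csv", index=False)
    write_csv(classification_summary(labels), reports_dir / "classification_summary.csv")
    write_csv(allergy_table(tables["allergies"], labels, cfg["formulary"]), reports_dir / "allergy_table.csv")

    analysis = build_analysis_frame(tables, "baseline", cfg)
    analysis.to_csv(out / "analysis.csv", index=False)

    covs = cfg["psm"]["covariates_susceptibility"]
    ps = estimate_propensity(analysis, "not_susceptible", covs)
    matched = match_1to1(
        ps.scores, analysis["not_susceptible"], caliper=cfg["psm"]["caliper_sd"], seed=rc.seed
    )
    write_csv(
        balance_table(analysis, covs, "not_susceptible", matched),
        reports_dir / "balance_table.csv",
    )

    strat = stratified_cost_report(
        analysis,
        ["all_cause_cost", "uti_related_cost"],
        exposure="exposure_group",
        adjusters=cfg["cost_model"]["adjusters"],
        zero_offset=cfg["cost_model"]["zero_offset"],
    )
    write_csv(strat, reports_dir / "stratified_costs.csv")

    battery = run_battery(tables, seed=rc.seed, config=cfg, scenarios=list(rc.scenarios))
    write_csv(battery, reports_dir / "sensitivity_table.csv")

    manifest = {
        "version": __version__,
        "seed": rc.seed,
        "config_hash": _config_hash(cfg),
        "sim_config": rc.sim.to_dict() if rc.sim else None,
        "input_dir": str(rc.input_dir) if rc.input_dir else None,
        "n_patients_input": int(len(tables["patients"])),
        "n_cohort": int(len(cohort)),
        "n_matched_pairs": int(len(matched.pairs)),
        "reports": list(REPORT_FILES),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)

    return {name: reports_dir / name for name in REPORT_FILES} | {
        "manifest": out / "manifest.json"
    }
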