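# uticost

Reusable pipeline for studying suboptimal/inappropriate antibiotic
prescribing in uncomplicated urinary tract infection (uUTI) from EHR-style
flat tables: cohort construction with an inclusion/exclusion waterfall,
rule-based treatment-appropriateness adjudication, person-level antimicrobial
susceptibility aggregation, fee-schedule cost construction, 1:1
propensity-score-matched gamma log-link cost models, and a sensitivity
scenario battery — all exercised end-to-end against a seeded synthetic EHR
generator with planted ground truth.

## Layout

| module | responsibility |
| --- | --- |
| `uticost.synthetic_ehr` | seeded synthetic patients/diagnoses/encounters/prescriptions/cultures/allergies tables + ground truth; plants per-filter exclusion cases |
| `uticost.cohort` | index-event identification, inclusion/exclusion waterfall, attrition report, scenario variants (strict/loose/fu30/fu360/…) |
| `uticost.classifier` | appropriate / inappropriate / suboptimal rule engine with rule provenance, person-level S/NS aggregation, 4-level exposure groups, Charlson index |
| `uticost.costs` | HCRU tabulation over half-open windows, fee-schedule costing with UTI attribution, winsorization, currency-year adjustment |
| `uticost.psm` | propensity estimation, greedy 1:1 caliper matching on the logit scale, SMD balance tables, gamma log-link GLMs with recycled-prediction dollar differences |
| `uticost.sensitivity` | scenario battery incl. progression-to-complicated-UTI risk differences |
| `uticost.pipeline` / `uticost.cli` | orchestration, persisted intermediates, report files, manifest |

All inputs and outputs are plain delimited text (UTF-8 CSV, ISO-8601 dates).
Code lists, formulary, fee schedule, Charlson weights and analysis knobs live
in `uticost.config` and can be overridden from YAML.

## CLI

```bash
# full run on a fresh synthetic population
uticost all --n-patients 2000 --seed 7 --out runs/demo

# or stage by stage
uticost generate --n-patients 2000 --seed 7 --out runs/demo/tables
uticost cohort   --tables runs/demo/tables --scenario baseline --out runs/demo
uticost classify --tables runs/demo/tables --cohort-file runs/demo/cohort_baseline.csv --out runs/demo
uticost costs    --tables runs/demo/tables --cohort-file runs/demo/cohort_baseline.csv --out runs/demo
uticost analyze  --tables runs/demo/tables --contrast susceptibility --seed 7 --out runs/demo
uticost sensitivity --tables runs/demo/tables --all --seed 7 --out runs/demo
```

`uticost all` writes six report files (attrition waterfall, classification
summary, allergy tabulation, covariate balance, stratified four-group cost
table, sensitivity table) plus `manifest.json` under `--out`. Identical
config + seed reproduce the reports byte for byte.

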