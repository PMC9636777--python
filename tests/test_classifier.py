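import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import decision_table
from uticost.classifier import (
    EpisodeInputs,
    PipelineOrderError,
    aggregate_susceptibility,
    allergy_summary_from_counts,
    assign_exposure_group,
    charlson_score,
    classification_summary,
    classify_appropriate,
    classify_episode,
    classify_inappropriate,
    classify_suboptimal,
    classification_summary,
    label_cohort,
    summary_from_counts,
)
from uticost.config import DEFAULT_CONFIG

T = pd.Timestamp
INDEX = T("2018-03-10")


def _cultures(rows):
    return pd.DataFrame(
        [
            {
                "culture_id": cid,
                "patient_id": pid,
                "collection_date": INDEX,
                "organism": "escherichia_coli",
                "cfu_per_ml": 1e5,
                "antibiotic": abx,
                "result": res,
            }
            for cid, pid, abx, res in rows
        ]
    )


class TestAggregateSusceptibility:
    def test_discordant_isolates_mean_not_susceptible(self):
        cultures = _cultures(
            [("C1", "P1", "sxt", "S"), ("C1", "P1", "nitrofurantoin", "S"), ("C2", "P1", "sxt", "R")]
        )
        out = aggregate_susceptibility(cultures, ["sxt", "nitrofurantoin"])
        assert out.loc[0, "person_level"] == "not_susceptible"

    def test_all_susceptible(self):
        cultures = _cultures([("C1", "P1", "sxt", "S"), ("C1", "P1", "nitrofurantoin", "S")])
        out = aggregate_susceptibility(cultures)
        assert out.loc[0, "person_level"] == "susceptible"

    def test_intermediate_counts_as_not_susceptible(self):
        cultures = _cultures([("C1", "P1", "nitrofurantoin", "I")])
        out = aggregate_susceptibility(cultures)
        assert out.loc[0, "person_level"] == "not_susceptible"

    def test_result_outside_indicated_set_ignored(self):
        cultures = _cultures([("C1", "P1", "sxt", "S"), ("C1", "P1", "ceftriaxone", "R")])
        out = aggregate_susceptibility(cultures, ["sxt"])
        assert out.loc[0, "person_level"] == "susceptible"

    def test_missing_panel_is_pipeline_order_error(self):
        cultures = _cultures([("C1", "P1", "sxt", "S")])
        with pytest.raises(PipelineOrderError):
            aggregate_susceptibility(cultures, ["sxt"], patient_ids=["P1", "P2"])

    @given(
        panel=st.dictionaries(
            st.sampled_from(["sxt", "nitrofurantoin", "ciprofloxacin"]),
            st.sampled_from(["S", "I", "R"]),
            min_size=1,
        ),
        extra=st.sampled_from(["I", "R"]),
    )
    @settings(max_examples=60, deadline=None)
    def test_adding_resistance_never_flips_to_susceptible(self, panel, extra):
        base = _cultures([("C1", "P1", abx, res) for abx, res in panel.items()])
        before = aggregate_susceptibility(base).loc[0, "person_level"]
        extended = pd.concat(
            [base, _cultures([("C2", "P1", "levofloxacin", extra)])], ignore_index=True
        )
        after = aggregate_susceptibility(extended).loc[0, "person_level"]
        if before == "not_susceptible":
            assert after == "not_susceptible"
        else:
            assert after == "not_susceptible"  # levofloxacin is indicated


class TestInappropriateClauses:
    def test_unjustified_fluoroquinolone(self):
        flag, rules = classify_inappropriate(
            ["ciprofloxacin"], ["ciprofloxacin"], set(), {"ciprofloxacin": "S"}
        )
        assert flag and rules == ["IA2"]

    def test_resistant_received_agent(self):
        flag, rules = classify_inappropriate(
            ["nitrofurantoin"], ["nitrofurantoin"], set(), {"nitrofurantoin": "R"}
        )
        assert flag and "IA3" in rules

    def test_clean_first_line_not_inappropriate(self):
        flag, rules = classify_inappropriate(
            ["nitrofurantoin"], ["nitrofurantoin"], set(), {"nitrofurantoin": "S"}
        )
        assert not flag and rules == []

    def test_two_first_line_agents(self):
        flag, rules = classify_inappropriate(
            ["nitrofurantoin", "sxt"], ["nitrofurantoin", "sxt"], set(), {}
        )
        assert "IA1" in rules

    def test_allergy_to_received(self):
        flag, rules = classify_inappropriate(
            ["nitrofurantoin"], ["nitrofurantoin"], {"nitrofurantoin"}, {"nitrofurantoin": "S"}
        )
        assert "IA4" in rules

    def test_allergy_to_all_first_line_justifies_second_line(self):
        allergy = {"fosfomycin", "nitrofurantoin", "sxt"}
        flag, rules = classify_inappropriate(["ciprofloxacin"], ["ciprofloxacin"], allergy, {})
        assert not flag

    def test_resistance_to_all_first_line_justifies_second_line(self):
        panel = {"fosfomycin": "R", "nitrofurantoin": "R", "sxt": "I", "ciprofloxacin": "S"}
        flag, _ = classify_inappropriate(["ciprofloxacin"], ["ciprofloxacin"], set(), panel)
        assert not flag

    def test_untested_first_line_does_not_justify_escalation(self):
        panel = {"nitrofurantoin": "R", "ciprofloxacin": "S"}  # sxt/fosfomycin untested
        flag, rules = classify_inappropriate(["ciprofloxacin"], ["ciprofloxacin"], set(), panel)
        assert "IA2" in rules

    def test_unknown_drug_rejected(self):
        with pytest.raises(KeyError, match="formulary"):
            classify_inappropriate(["quinine"], ["quinine"], set(), {})


class TestSuboptimalClauses:
    def test_switch_within_window(self):
        orders = [(INDEX, "nitrofurantoin", "oral"), (INDEX + pd.Timedelta(days=10), "sxt", "oral")]
        flag, rules = classify_suboptimal(["nitrofurantoin"], orders, {}, INDEX)
        assert rules == ["SO1"]

    @pytest.mark.parametrize("day,fires", [(28, True), (29, False)])
    def test_switch_window_boundary(self, day, fires):
        orders = [(INDEX, "nitrofurantoin", "oral"), (INDEX + pd.Timedelta(days=day), "sxt", "oral")]
        flag, rules = classify_suboptimal(["nitrofurantoin"], orders, {}, INDEX)
        assert ("SO1" in rules) is fires

    def test_iv_antibiotic(self):
        orders = [(INDEX, "nitrofurantoin", "oral"), (INDEX + pd.Timedelta(days=2), "ceftriaxone", "iv")]
        flag, rules = classify_suboptimal(["nitrofurantoin"], orders, {}, INDEX)
        assert rules == ["SO2"]

    def test_not_susceptible_initial_agent(self):
        orders = [(INDEX, "nitrofurantoin", "oral")]
        flag, rules = classify_suboptimal(["nitrofurantoin"], orders, {"nitrofurantoin": "I"}, INDEX)
        assert rules == ["SO3"]

    def test_clean_course(self):
        orders = [(INDEX, "nitrofurantoin", "oral")]
        flag, rules = classify_suboptimal(["nitrofurantoin"], orders, {"nitrofurantoin": "S"}, INDEX)
        assert not flag and rules == []


class TestAppropriateClauses:
    def test_first_line_recommended_duration(self):
        flag, rules = classify_appropriate([("nitrofurantoin", 5)], set())
        assert flag and rules == ["AP1"]

    def test_wrong_duration(self):
        flag, rules = classify_appropriate([("nitrofurantoin", 7)], set())
        assert not flag

    def test_allergy_escape_to_second_line(self):
        allergy = {"fosfomycin", "nitrofurantoin", "sxt"}
        flag, rules = classify_appropriate([("ciprofloxacin", 7)], allergy)
        assert flag and rules == ["AP2"]

    def test_partial_allergy_no_escape(self):
        flag, _ = classify_appropriate([("ciprofloxacin", 7)], {"nitrofurantoin"})
        assert not flag


class TestExposureGroups:
    @pytest.mark.parametrize(
        "ns,app,expected",
        [
            (False, True, "S_app"),
            (False, False, "S_inapp_sub"),
            (True, True, "NS_app"),
            (True, False, "NS_inapp_sub"),
        ],
    )
    def test_all_four_combinations(self, ns, app, expected):
        assert assign_exposure_group(ns, app) == expected

    def test_groups_partition_cohort(self, tables_small):
        from uticost.cohort import build_cohort

        tables, _, _ = tables_small
        cohort, _, _ = build_cohort(tables, "baseline")
        labels = label_cohort(
            cohort, tables["prescriptions"], tables["cultures"], tables["allergies"]
        )
        assert labels["exposure_group"].value_counts().sum() == len(cohort)
        assert labels["patient_id"].is_unique

    def test_labels_match_planted_ground_truth(self, tables_small):
        from uticost.cohort import build_cohort

        tables, _, _ = tables_small
        cohort, _, _ = build_cohort(tables, "baseline")
        labels = label_cohort(
            cohort, tables["prescriptions"], tables["cultures"], tables["allergies"]
        )
        gt = tables["ground_truth"].set_index("patient_id")
        merged = labels.set_index("patient_id").join(gt[["true_exposure_group"]])
        assert (merged["exposure_group"] == merged["true_exposure_group"]).all()


def test_truth_table_matches_independent_decision_table():
    """Exhaustive grid over the clause drivers vs the hand-written table."""
    grid = itertools.product(
        ["nitrofurantoin", "ciprofloxacin"],
        ["correct", "wrong"],
        ["none", "all_first_line", "initial_drug"],
        ["S", "I", "R"],
        [None, 20, 35],
        [False, True],
    )
    checked = 0
    for drug, dur_kind, allergy_mode, result, switch_day, iv in grid:
        duration = {"nitrofurantoin": 5, "ciprofloxacin": 7}[drug] if dur_kind == "correct" else 9
        orders = [(INDEX, drug, "oral")]
        if switch_day is not None and switch_day <= 28:  # outside = outside episode
            orders.append((INDEX + pd.Timedelta(days=switch_day), "sxt", "oral"))
        if iv:
            orders.append((INDEX + pd.Timedelta(days=2), "ceftriaxone", "iv"))
        allergy = {
            "none": set(),
            "all_first_line": {"fosfomycin", "nitrofurantoin", "sxt"},
            "initial_drug": {drug},
        }[allergy_mode]
        label = classify_episode(
            EpisodeInputs(
                patient_id="P1",
                index_date=INDEX,
                initial=[(drug, duration)],
                episode_orders=orders,
                allergy_drugs=allergy,
                panel={drug: result},
            )
        )
        expected = decision_table(drug, duration, allergy_mode, result, switch_day, iv)
        got = {
            "inappropriate": label["inappropriate"],
            "suboptimal": label["suboptimal"],
            "appropriate": label["appropriate"],
            "final_appropriate": label["final_label"] == "appropriate",
        }
        assert got == expected, (drug, dur_kind, allergy_mode, result, switch_day, iv)
        if any([label["inappropriate"], label["suboptimal"], label["appropriate"]]):
            assert label["fired_rules"], "true flags must carry fired rules"
        checked += 1
    assert checked == 216


class TestClassificationSummary:
    def test_printed_style_percentages(self):
        out = summary_from_counts({"appropriate": 1709, "suboptimal_or_inappropriate": 856}, 2565)
        as_map = dict(zip(out["category"], out["pct"]))
        assert as_map["appropriate"] == 66.6
        assert as_map["suboptimal_or_inappropriate"] == 33.4

    def test_all_appropriate(self):
        labels = pd.DataFrame(
            {
                "suboptimal": [False] * 4,
                "inappropriate": [False] * 4,
                "final_label": ["appropriate"] * 4,
            }
        )
        out = classification_summary(labels).set_index("category")["pct"]
        assert out["appropriate"] == 100.0
        assert out["suboptimal"] == 0.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            classification_summary(pd.DataFrame(columns=["suboptimal"]))

    def test_inclusion_exclusion_identity(self, tables_small):
        from uticost.cohort import build_cohort

        tables, _, _ = tables_small
        cohort, _, _ = build_cohort(tables, "baseline")
        labels = label_cohort(
            cohort, tables["prescriptions"], tables["cultures"], tables["allergies"]
        )
        out = classification_summary(labels).set_index("category")["n"]
        assert (
            out["suboptimal_or_inappropriate"]
            == out["suboptimal"] + out["inappropriate"] - out["suboptimal_and_inappropriate"]
        )
        assert out["appropriate"] == len(labels) - out["suboptimal_or_inappropriate"]


class TestCharlson:
    def test_no_codes_scores_zero(self):
        dx = pd.DataFrame(columns=["patient_id", "date", "code"])
        idx = pd.Series({"P1": INDEX})
        assert charlson_score(dx, idx).loc["P1"] == 0

    def test_singleton_weight(self):
        dx = pd.DataFrame([{"patient_id": "P1", "date": INDEX - pd.Timedelta(days=30), "code": "N18.5"}])
        idx = pd.Series({"P1": INDEX})
        assert charlson_score(dx, idx).loc["P1"] == 2  # renal disease

    def test_three_categories_hand_sum(self):
        # copd (1) + renal (2) + moderate/severe liver (3) = 6, manual sum
        dx = pd.DataFrame(
            [
                {"patient_id": "P1", "date": INDEX - pd.Timedelta(days=10), "code": "J44.9"},
                {"patient_id": "P1", "date": INDEX - pd.Timedelta(days=20), "code": "N18.3"},
                {"patient_id": "P1", "date": INDEX - pd.Timedelta(days=30), "code": "K72.0"},
            ]
        )
        assert charlson_score(dx, pd.Series({"P1": INDEX})).loc["P1"] == 6

    def test_duplicate_category_counted_once(self):
        dx = pd.DataFrame(
            [
                {"patient_id": "P1", "date": INDEX - pd.Timedelta(days=10), "code": "J44.9"},
                {"patient_id": "P1", "date": INDEX - pd.Timedelta(days=40), "code": "J44.1"},
            ]
        )
        assert charlson_score(dx, pd.Series({"P1": INDEX})).loc["P1"] == 1

    def test_codes_on_or_after_index_ignored(self):
        dx = pd.DataFrame([{"patient_id": "P1", "date": INDEX, "code": "J44.9"}])
        assert charlson_score(dx, pd.Series({"P1": INDEX})).loc["P1"] == 0


def test_allergy_counts_worked_example():
    out = allergy_summary_from_counts(77, 56, 2565)
    assert out["overall_pct"] == 5.2
    assert out["susceptible_share_pct"] == 57.9
    assert out["not_susceptible_share_pct"] == 42.1
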