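"""Knowledge base loading and the screening engine."""

import copy

import pytest
import yaml

from optimise_smi.engine import (KnowledgeBaseError, default_kb_path,
                                 detect_monitoring_gaps, evaluate_indicator,
                                 load_knowledge_base, screen_patient,
                                 smoking_cessation_dose_advice,
                                 standard_decision_matrix)
from optimise_smi.patient import PatientRecord


def make_record(**overrides) -> PatientRecord:
    base = dict(patient_id="T1", age=48, sex="male")
    base.update(overrides)
    return PatientRecord.model_validate(base)


class TestKnowledgeBase:
    def test_default_kb_has_62_indicators(self, kb):
        assert len(kb) == 62

    def test_round_split_53_plus_9(self, kb):
        assert len(kb.by_round(1)) == 53
        assert len(kb.by_round(2)) == 9

    def test_decision_surface_expands_to_65_units(self, kb):
        assert len(kb.decision_unit_ids(expand_sub_units=True)) == 65
        assert len(kb.decision_unit_ids(expand_sub_units=False)) == 62

    def test_provenance_mapping_total_and_non_overlapping(self, kb):
        audit = kb.provenance_audit()
        assert audit[1] == list(range(1, 54))
        assert audit[2] == list(range(1, 10))

    def test_every_indicator_spans_all_seven_sections(self, kb):
        sections = {ind.section for ind in kb}
        assert sections == {"cardiovascular", "endocrine", "gastrointestinal",
                            "blood_nutrition", "respiratory",
                            "musculoskeletal", "lifestyle"}

    def test_required_fields_cover_condition_references(self, kb):
        for ind in kb:
            assert ind.required_fields == ind.predicate.referenced_fields()

    def test_duplicate_id_rejected(self, tmp_path):
        payload = yaml.safe_load(default_kb_path().read_text())
        payload["indicators"].append(copy.deepcopy(payload["indicators"][0]))
        bad = tmp_path / "kb.yaml"
        bad.write_text(yaml.safe_dump(payload))
        with pytest.raises(KnowledgeBaseError, match="duplicate"):
            load_knowledge_base(bad)

    def test_indicator_failing_consensus_rule_rejected(self, tmp_path):
        payload = yaml.safe_load(default_kb_path().read_text())
        payload["indicators"][0]["delphi"] = {"median": 1, "p75": 3}
        bad = tmp_path / "kb.yaml"
        bad.write_text(yaml.safe_dump(payload))
        with pytest.raises(KnowledgeBaseError, match="acceptance rule"):
            load_knowledge_base(bad)

    def test_dangling_field_path_rejected(self, tmp_path):
        payload = yaml.safe_load(default_kb_path().read_text())
        payload["indicators"][0]["condition"] = {
            "field": "shoe_size", "op": "ge", "value": 40}
        bad = tmp_path / "kb.yaml"
        bad.write_text(yaml.safe_dump(payload))
        with pytest.raises(KnowledgeBaseError, match="unknown record fields"):
            load_knowledge_base(bad)


class TestIndicatorEvaluation:
    def test_statin_indicator_triggers_at_12_percent_risk(self, kb):
        rec = make_record(cv_risk_10yr=12)
        outcome = evaluate_indicator(kb.get("R1-02"), rec)
        assert outcome.status == "triggered"

    def test_statin_indicator_quiet_when_statin_prescribed(self, kb):
        rec = make_record(cv_risk_10yr=12, medications=[
            {"name": "atorvastatin", "class_tags": ["statin"]}])
        assert evaluate_indicator(kb.get("R1-02"), rec).status == "not_triggered"

    def test_levothyroxine_consideration_at_tsh_12(self, kb):
        rec = make_record(labs={"tsh": {"value": 12, "unit": "mIU/L"}})
        assert evaluate_indicator(kb.get("R1-18"), rec).status == "triggered"

    def test_subclinical_hypothyroidism_repeat_tft(self, kb):
        rec = make_record(labs={"tsh": {"value": 6, "unit": "mIU/L"},
                                "t4_status": "normal"})
        assert evaluate_indicator(kb.get("R1-21"), rec).status == "triggered"

    def test_age_gate_short_circuits_without_unknown(self, kb):
        # 35-year-old with no CV risk score: the age atom is decisively
        # false, so the missing score cannot make the outcome unknown
        rec = make_record(age=35)
        outcome = evaluate_indicator(kb.get("R1-01"), rec)
        assert outcome.status == "not_triggered"

    def test_cv_risk_assessment_prompt_over_40(self, kb):
        assert evaluate_indicator(kb.get("R1-01"), make_record(age=48)
                                  ).status == "triggered"

    def test_prolactin_dependent_rule_insufficient_without_level(self, kb):
        rec = make_record(medications=[{
            "name": "risperidone",
            "class_tags": ["antipsychotic", "prolactin_raising_antipsychotic"]}])
        outcome = evaluate_indicator(kb.get("R1-28"), rec)
        assert outcome.status == "insufficient_data"
        assert "labs.prolactin" in outcome.missing_fields

    def test_severe_dyslipidaemia_referral(self, kb):
        rec = make_record(labs={"triglycerides": {"value": 11, "unit": "mmol/L"}})
        assert evaluate_indicator(kb.get("R1-05"), rec).status == "triggered"

    def test_older_adult_hba1c_ceiling(self, kb):
        labs = {"hba1c": {"value": 55, "unit": "mmol/mol"},
                "fasting_glucose": {"value": 6.0, "unit": "mmol/L"}}
        young = make_record(age=50, diagnoses={"diabetes"}, labs=labs)
        older = make_record(age=70, diagnoses={"diabetes"}, labs=labs)
        assert evaluate_indicator(kb.get("R1-17"), young).status == "triggered"
        assert evaluate_indicator(kb.get("R1-17"), older).status == "not_triggered"

    def test_stage2_hypertension_needs_abpm(self, kb):
        clinic_only = make_record(blood_pressure={
            "clinic_systolic": 170, "clinic_diastolic": 105})
        assert evaluate_indicator(kb.get("R1-08"), clinic_only
                                  ).status == "insufficient_data"
        confirmed = make_record(blood_pressure={
            "clinic_systolic": 170, "clinic_diastolic": 105,
            "abpm_daytime_systolic": 155, "abpm_daytime_diastolic": 97})
        assert evaluate_indicator(kb.get("R1-08"), confirmed).status == "triggered"


class TestScreening:
    @pytest.fixture()
    def smoker_on_clozapine(self):
        return make_record(
            patient_id="demo", age=27,
            diagnoses={"schizophrenia"},
            medications=[{"name": "clozapine",
                          "class_tags": ["antipsychotic", "clozapine"]}],
            lifestyle={"smoking_status": "current", "cigarettes_per_day": 20,
                       "ready_to_quit": True})

    def test_smoking_cessation_bundle_triggers(self, kb, smoker_on_clozapine):
        report = screen_patient(kb, smoker_on_clozapine)
        triggered = set(report.by_status("triggered"))
        # document status, offer advice, offer pharmacotherapy (20/day > 10),
        # and the clozapine dose-interaction advisory
        assert {"R1-38", "R1-39", "R1-40", "R1-42"} <= triggered

    def test_catatonia_inpatient_vte_flow(self, kb):
        rec = make_record(diagnoses={"schizophrenia", "catatonia"},
                          setting="inpatient", mobility_reduced=True,
                          vte_prophylaxis_indicated=True)
        report = screen_patient(kb, rec)
        triggered = set(report.by_status("triggered"))
        assert {"R1-13", "R1-14", "R2-03"} <= triggered
        assert any(g.gap_type ==
                   "missing_vte_risk_assessment_inpatient_reduced_mobility"
                   for g in report.gaps)

    def test_empty_lab_record_propagates_insufficient_data(self, kb):
        rec = make_record()
        report = screen_patient(kb, rec)
        counts = report.counts
        assert counts["insufficient_data"] > 0
        assert sum(counts.values()) == len(kb)
        for lab_rule in ("R1-05", "R1-28"):
            assert report.outcome(lab_rule).status == "insufficient_data"

    def test_screening_is_deterministic(self, kb, default_cohort):
        first = screen_patient(kb, default_cohort[0])
        second = screen_patient(kb, default_cohort[0])
        assert first == second

    def test_completing_data_never_creates_insufficiency(self, kb):
        before = screen_patient(kb, make_record())
        completed = make_record(labs={"hba1c": {"value": 40, "unit": "mmol/mol"},
                                      "tsh": {"value": 2.0, "unit": "mIU/L"}},
                                cv_risk_10yr=5)
        after = screen_patient(kb, completed)
        for b, a in zip(before.outcomes, after.outcomes):
            if b.status in ("triggered", "not_triggered"):
                assert a.status != "insufficient_data"

    def test_standard_matrix_has_expanded_grid(self, kb, default_cohort):
        standard = standard_decision_matrix(kb, default_cohort)
        assert standard.shape == (20, 65)
        assert standard.decisions.to_numpy().sum() > 0


class TestMonitoringGaps:
    def test_prolactin_gap_on_raising_antipsychotic(self):
        rec = make_record(medications=[{
            "name": "olanzapine",
            "class_tags": ["antipsychotic", "prolactin_raising_antipsychotic"]}])
        gaps = {g.gap_type for g in detect_monitoring_gaps(rec)}
        assert "missing_prolactin_on_raising_antipsychotic" in gaps

    def test_recent_hba1c_closes_the_gap(self):
        rec = make_record(record_date="2019-06-01",
                          labs={"hba1c": {"value": 40, "unit": "mmol/mol",
                                          "date": "2019-01-15"}})
        gaps = {g.gap_type for g in detect_monitoring_gaps(rec)}
        assert "missing_HbA1c_annual_screen" not in gaps

    def test_stale_hba1c_reopens_the_gap(self):
        rec = make_record(record_date="2019-06-01",
                          labs={"hba1c": {"value": 40, "unit": "mmol/mol",
                                          "date": "2017-01-15"}})
        gaps = {g.gap_type for g in detect_monitoring_gaps(rec)}
        assert "missing_HbA1c_annual_screen" in gaps

    def test_undocumented_smoking_status_is_a_gap(self):
        gaps = {g.gap_type for g in detect_monitoring_gaps(make_record())}
        assert "missing_smoking_status" in gaps

    def test_cv_risk_gap_only_from_age_40(self):
        young = {g.gap_type for g in detect_monitoring_gaps(make_record(age=39))}
        older = {g.gap_type for g in detect_monitoring_gaps(make_record(age=40))}
        assert "missing_cv_risk_over_40" not in young
        assert "missing_cv_risk_over_40" in older


class TestDoseAdvice:
    def test_clozapine_advisory_with_assay_window(self):
        rec = make_record(
            medications=[{"name": "clozapine",
                          "class_tags": ["antipsychotic", "clozapine"]}],
            lifestyle={"smoking_status": "current", "cigarettes_per_day": 20})
        advisories = smoking_cessation_dose_advice(rec)
        assert [a.advice for a in advisories] == ["reduce_up_to_50pct"]
        assert "3-5 days" in advisories[0].detail

    def test_olanzapine_advisory_is_20_percent(self):
        rec = make_record(
            medications=[{"name": "olanzapine",
                          "class_tags": ["antipsychotic", "olanzapine"]}],
            lifestyle={"smoking_status": "current"})
        assert [a.advice for a in smoking_cessation_dose_advice(rec)] == \
            ["reduce_up_to_20pct"]

    def test_monitor_only_classes_do_not_reduce(self):
        rec = make_record(
            medications=[{"name": "haloperidol",
                          "class_tags": ["antipsychotic", "haloperidol"]},
                         {"name": "mirtazapine", "class_tags": ["mirtazapine"]}],
            lifestyle={"smoking_status": "current"})
        assert {a.advice for a in smoking_cessation_dose_advice(rec)} == \
            {"monitor_only"}

    def test_non_smoker_and_non_interacting_drugs_yield_nothing(self):
        smoker_on_ssri = make_record(
            medications=[{"name": "sertraline", "class_tags": ["ssri"]}],
            lifestyle={"smoking_status": "current"})
        non_smoker = make_record(
            medications=[{"name": "clozapine",
                          "class_tags": ["antipsychotic", "clozapine"]}],
            lifestyle={"smoking_status": "never"})
        assert smoking_cessation_dose_advice(smoker_on_ssri) == []
        assert smoking_cessation_dose_advice(non_smoker) == []
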