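"""The OPTIMISE screening engine.

Loads the declarative indicator knowledge base (62 rules over seven
physiological-system sections), evaluates each rule against a
:class:`~optimise_smi.patient.PatientRecord` under three-valued Kleene
logic, and assembles per-patient screening reports with monitoring-gap
flags (indicated-but-absent measurements such as a missing annual HbA1c).

Outcomes are three-valued by design: ``triggered`` (the rule's condition
holds), ``not_triggered`` (it demonstrably does not), and
``insufficient_data`` (the record lacks the fields needed to decide).
Missing data is a status, never an error.

Three multi-action indicators are additionally split into separately
recordable *decision units* (65 in total over the 62 indicators); this is
the grid used for interrater-reliability exercises, where raters may
record each action of a composite recommendation separately.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .logic import Predicate, Ternary
from .patient import PatientRecord, valid_field_path

__all__ = [
    "Indicator", "IndicatorSet", "IndicatorOutcome", "MonitoringGap",
    "ScreeningReport", "KnowledgeBaseError", "load_knowledge_base",
    "evaluate_indicator", "screen_patient", "detect_monitoring_gaps",
    "smoking_cessation_dose_advice", "DoseAdvisory",
]

SECTIONS = ("cardiovascular", "endocrine", "gastrointestinal",
            "blood_nutrition", "respiratory", "musculoskeletal", "lifestyle")

Action = Literal["initiate", "consider", "refer", "monitor", "counsel",
                 "avoid", "adjust_dose"]


class KnowledgeBaseError(ValueError):
    """The indicator knowledge base failed schema or invariant checks."""


class SubUnit(BaseModel):
    model_config = ConfigDict(extra="forbid")

    suffix: str
    title: str


class Indicator(BaseModel):
    """One machine-evaluable screening rule with its consensus summary."""

    model_config = ConfigDict(extra="forbid", arbitrary_types_allowed=True)

    indicator_id: str
    section: str
    title: str
    action: Action
    recommendation: str
    condition: dict
    delphi_median: float
    delphi_p75: float
    sub_units: list[SubUnit] = Field(default_factory=list)
    _predicate: Optional[Predicate] = None

    @field_validator("section")
    @classmethod
    def _known_section(cls, section: str) -> str:
        if section not in SECTIONS:
            raise ValueError(f"unknown section {section!r}; expected one of {SECTIONS}")
        return section

    @model_validator(mode="after")
    def _compile_and_check(self) -> "Indicator":
        try:
            object.__setattr__(self, "_predicate", Predicate.compile(self.condition))
        except ValueError as exc:
            raise ValueError(f"indicator {self.indicator_id}: {exc}") from exc
        dangling = [f for f in self.predicate.referenced_fields()
                    if not valid_field_path(f)]
        if dangling:
            raise ValueError(
                f"indicator {self.indicator_id}: condition references "
                f"unknown record fields {dangling}")
        # only consensus-accepted rules ship in the tool
        if not (self.delphi_median <= 2 and self.delphi_p75 <= 2):
            raise ValueError(
                f"indicator {self.indicator_id}: Delphi summary "
                f"(median {self.delphi_median}, p75 {self.delphi_p75}) fails "
                "the acceptance rule (median <= 2 and p75 <= 2)")
        return self

    @property
    def predicate(self) -> Predicate:
        assert self._predicate is not None
        return self._predicate

    @property
    def required_fields(self) -> list[str]:
        """Record field paths the condition reads (derived, hence total)."""
        return self.predicate.referenced_fields()

    @property
    def round_number(self) -> int:
        return int(self.indicator_id.split("-")[0].lstrip("R"))

    @property
    def decision_unit_ids(self) -> list[str]:
        if not self.sub_units:
            return [self.indicator_id]
        return [f"{self.indicator_id}{u.suffix}" for u in self.sub_units]


class IndicatorSet(BaseModel):
    model_config = ConfigDict(extra="forbid")

    version: str
    indicators: list[Indicator]

    @model_validator(mode="after")
    def _unique_ids(self) -> "IndicatorSet":
        ids = [i.indicator_id for i in self.indicators]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate indicator ids: {dupes}")
        return self

    def __len__(self) -> int:
        return len(self.indicators)

    def __iter__(self):
        return iter(self.indicators)

    def get(self, indicator_id: str) -> Indicator:
        for ind in self.indicators:
            if ind.indicator_id == indicator_id:
                return ind
        raise KeyError(indicator_id)

    def by_round(self, round_number: int) -> list[Indicator]:
        return [i for i in self.indicators if i.round_number == round_number]

    def by_section(self, section: str) -> list[Indicator]:
        return [i for i in self.indicators if i.section == section]

    def decision_unit_ids(self, expand_sub_units: bool = True) -> list[str]:
        """The flat decision surface: 62 indicator ids, or 65 units when
        composite recommendations are expanded (the interrater grid)."""
        out: list[str] = []
        for ind in self.indicators:
            out.extend(ind.decision_unit_ids if expand_sub_units
                       else [ind.indicator_id])
        return out

    def provenance_audit(self) -> dict[int, list[int]]:
        """Round -> sorted item numbers; proves the id mapping is total
        and non-overlapping (round 1 items 1..53, round 2 items 1..9)."""
        rounds: dict[int, list[int]] = {}
        for ind in self.indicators:
            prefix, item = ind.indicator_id.split("-")
            rounds.setdefault(int(prefix.lstrip("R")), []).append(int(item))
        for numbers in rounds.values():
            numbers.sort()
            if len(set(numbers)) != len(numbers):
                raise KnowledgeBaseError(f"overlapping provenance items: {numbers}")
        return rounds


def default_kb_path() -> Path:
    return Path(importlib.resources.files("optimise_smi") / "kb" / "optimise_kb.yaml")


def load_knowledge_base(kb_source: str | Path | None = None) -> IndicatorSet:
    """Load and validate an indicator knowledge base (YAML or JSON-equivalent).

    With no argument, loads the packaged 62-indicator OPTIMISE rule set.
    Raises :class:`KnowledgeBaseError` on duplicate ids, malformed
    predicate expressions, or an indicator whose Delphi summary fails the
    consensus acceptance rule.
    """
    path = Path(kb_source) if kb_source is not None else default_kb_path()
    try:
        payload = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise KnowledgeBaseError(f"{path}: not valid YAML ({exc})") from exc
    if not isinstance(payload, dict) or "indicators" not in payload:
        raise KnowledgeBaseError(f"{path}: expected a mapping with an 'indicators' list")
    indicators = []
    for entry in payload["indicators"]:
        entry = dict(entry)
        if "id" in entry:
            entry["indicator_id"] = entry.pop("id")
        delphi = entry.pop("delphi", None)
        if delphi is not None:
            entry["delphi_median"] = delphi.get("median")
            entry["delphi_p75"] = delphi.get("p75")
        try:
            indicators.append(Indicator.model_validate(entry))
        except Exception as exc:
            raise KnowledgeBaseError(f"{path}: {exc}") from exc
    try:
        return IndicatorSet(version=str(payload.get("version", "0")), indicators=indicators)
    except Exception as exc:
        raise KnowledgeBaseError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# evaluation


class IndicatorOutcome(BaseModel):
    model_config = ConfigDict(extra="forbid")

    indicator_id: str
    status: Literal["triggered", "not_triggered", "insufficient_data"]
    rationale: list[str] = Field(default_factory=list)
    missing_fields: list[str] = Field(default_factory=list)


class MonitoringGap(BaseModel):
    model_config = ConfigDict(extra="forbid")

    gap_type: Literal[
        "missing_HbA1c_annual_screen",
        "missing_prolactin_on_raising_antipsychotic",
        "missing_cv_risk_over_40",
        "missing_smoking_status",
        "missing_vte_risk_assessment_inpatient_reduced_mobility",
    ]
    detail: str


class ScreeningReport(BaseModel):
    model_config = ConfigDict(extra="forbid")

    patient_id: str
    outcomes: list[IndicatorOutcome]
    gaps: list[MonitoringGap]

    @property
    def counts(self) -> dict[str, int]:
        counts = {"triggered": 0, "not_triggered": 0, "insufficient_data": 0}
        for outcome in self.outcomes:
            counts[outcome.status] += 1
        return counts

    def by_status(self, status: str) -> list[str]:
        return [o.indicator_id for o in self.outcomes if o.status == status]

    def outcome(self, indicator_id: str) -> IndicatorOutcome:
        for o in self.outcomes:
            if o.indicator_id == indicator_id:
                return o
        raise KeyError(indicator_id)

    def render_text(self) -> str:
        lines = [f"Screening report: patient {self.patient_id}",
                 "  counts: " + ", ".join(f"{k}={v}" for k, v in self.counts.items())]
        for o in self.outcomes:
            if o.status == "triggered":
                lines.append(f"  [TRIGGERED] {o.indicator_id}")
        for o in self.outcomes:
            if o.status == "insufficient_data":
                lines.append(f"  [DATA?]     {o.indicator_id} "
                             f"(missing: {', '.join(o.missing_fields)})")
        for gap in self.gaps:
            lines.append(f"  [GAP]       {gap.gap_type}: {gap.detail}")
        return "\n".join(lines)


_STATUS_BY_TERNARY = {
    Ternary.TRUE: "triggered",
    Ternary.FALSE: "not_triggered",
    Ternary.UNKNOWN: "insufficient_data",
}


def evaluate_indicator(indicator: Indicator, record: PatientRecord) -> IndicatorOutcome:
    """Evaluate one rule against one record (deterministic, three-valued)."""
    evaluation = indicator.predicate.evaluate(record)
    return IndicatorOutcome(
        indicator_id=indicator.indicator_id,
        status=_STATUS_BY_TERNARY[evaluation.value],
        rationale=[f"{a.description} -> {a.value.value}" for a in evaluation.atoms],
        missing_fields=evaluation.missing_fields,
    )


def screen_patient(indicators: IndicatorSet, record: PatientRecord) -> ScreeningReport:
    """Apply the whole indicator set to one patient."""
    return ScreeningReport(
        patient_id=record.patient_id,
        outcomes=[evaluate_indicator(ind, record) for ind in indicators],
        gaps=detect_monitoring_gaps(record),
    )


def detect_monitoring_gaps(record: PatientRecord) -> list[MonitoringGap]:
    """Flag indicated-but-absent measurements.

    - HbA1c: every adult with SMI has an annual glycaemic screen, so an
      absent (or > 12-months-stale, when the record carries a reference
      date) HbA1c is a gap.
    - Prolactin: a gap when a prolactin-raising antipsychotic is
      prescribed but no prolactin level is available.
    - CV risk score: a gap from age 40 when no 10-year risk estimate is
      recorded.
    - Smoking status: a gap whenever undocumented.
    - VTE risk assessment: a gap for inpatients with reduced mobility and
      no recorded assessment.
    """
    gaps: list[MonitoringGap] = []
    hba1c = record.labs.entry("hba1c")
    if hba1c is None:
        gaps.append(MonitoringGap(
            gap_type="missing_HbA1c_annual_screen",
            detail="labs.hba1c absent; HbA1c is part of the annual physical "
                   "health screen for adults with SMI"))
    elif (record.record_date is not None and hba1c.date is not None
          and (record.record_date - hba1c.date).days > 365):
        gaps.append(MonitoringGap(
            gap_type="missing_HbA1c_annual_screen",
            detail=f"labs.hba1c dated {hba1c.date} is older than 12 months"))
    if (record.has_medication_tag("prolactin_raising_antipsychotic")
            and record.labs.entry("prolactin") is None):
        gaps.append(MonitoringGap(
            gap_type="missing_prolactin_on_raising_antipsychotic",
            detail="labs.prolactin absent while a prolactin-raising "
                   "antipsychotic is prescribed"))
    if record.age >= 40 and record.cv_risk_10yr is None:
        gaps.append(MonitoringGap(
            gap_type="missing_cv_risk_over_40",
            detail="cv_risk_10yr absent for an adult aged 40 or over"))
    if record.lifestyle.smoking_status == "undocumented":
        gaps.append(MonitoringGap(
            gap_type="missing_smoking_status",
            detail="lifestyle.smoking_status undocumented"))
    if (record.setting == "inpatient" and record.mobility_reduced is True
            and record.vte_risk_assessed is not True):
        gaps.append(MonitoringGap(
            gap_type="missing_vte_risk_assessment_inpatient_reduced_mobility",
            detail="vte_risk_assessed absent/false for an inpatient with "
                   "reduced mobility"))
    return gaps


def standard_decision_matrix(indicators: IndicatorSet,
                             records: list[PatientRecord],
                             rater_id: str = "standard",
                             expand_sub_units: bool = True):
    """Screen a cohort into a binary dataset x decision-unit grid.

    ``triggered`` maps to applied; ``not_triggered`` and
    ``insufficient_data`` both map to not-applied (decisions are strictly
    binary; the three-valued status survives in the screening reports).
    Sub-units of a composite indicator inherit the indicator's outcome.
    """
    import pandas as pd

    from .agreement import DecisionMatrix

    unit_ids = indicators.decision_unit_ids(expand_sub_units=expand_sub_units)
    rows = {}
    for record in records:
        report = screen_patient(indicators, record)
        by_id = {o.indicator_id: o.status == "triggered" for o in report.outcomes}
        row = {}
        for ind in indicators:
            for unit in (ind.decision_unit_ids if expand_sub_units
                         else [ind.indicator_id]):
                row[unit] = by_id[ind.indicator_id]
        rows[record.patient_id] = row
    grid = pd.DataFrame.from_dict(rows, orient="index")[unit_ids]
    return DecisionMatrix(rater_id=rater_id, decisions=grid)


class DoseAdvisory(BaseModel):
    model_config = ConfigDict(extra="forbid")

    drug_class: str
    advice: Literal["reduce_up_to_50pct", "reduce_up_to_20pct", "monitor_only"]
    detail: str


def smoking_cessation_dose_advice(record: PatientRecord,
                                  quitting: bool = False) -> list[DoseAdvisory]:
    """Psychotropic dose advisories around (abrupt) smoking cessation.

    Tobacco smoke induces CYP1A2; quitting raises plasma levels of several
    psychotropics.  Clozapine: consider up to 50% dose reduction with an
    assay 3-5 days after the change.  Olanzapine: up to 20%.  TCAs,
    mirtazapine, haloperidol and benzodiazepines: do not reduce the dose;
    monitor for adverse effects.  Applies to current smokers (or records
    flagged as in a quitting context); otherwise, or with no interacting
    drug, the list is empty.
    """
    if record.lifestyle.smoking_status != "current" and not quitting:
        return []
    advisories: list[DoseAdvisory] = []
    if record.has_medication_tag("clozapine"):
        advisories.append(DoseAdvisory(
            drug_class="clozapine", advice="reduce_up_to_50pct",
            detail="Consider a dose reduction by up to 50% on abrupt smoking "
                   "cessation; perform a clozapine assay 3-5 days after dose "
                   "adjustment or cessation"))
    if record.has_medication_tag("olanzapine"):
        advisories.append(DoseAdvisory(
            drug_class="olanzapine", advice="reduce_up_to_20pct",
            detail="Consider a dose reduction by up to 20% on abrupt smoking "
                   "cessation; monitor for adverse effects"))
    for tag in ("tca", "mirtazapine", "haloperidol", "benzodiazepine"):
        if record.has_medication_tag(tag):
            advisories.append(DoseAdvisory(
                drug_class=tag, advice="monitor_only",
                detail="Do not reduce the dose on smoking cessation; monitor "
                       "for adverse effects"))
    return advisories
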