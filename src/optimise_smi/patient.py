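"""Patient records for medicines-optimisation screening.

One :class:`PatientRecord` describes a single screened adult with severe
mental illness (SMI): demographics, coded diagnoses, the current regular
medication list (tagged with a controlled class vocabulary), a unit-aware
laboratory panel, blood pressure, lifestyle fields and externally computed
risk scores (the engine never computes QRISK/SCORE/FRAX itself — those are
inputs).

Laboratory values are unit-checked at load time against one canonical unit
per analyte (a small synonym table, e.g. ``mU/L`` for ``mIU/L``, is
accepted; anything else is rejected rather than converted, to prevent
silent mg/dL corruption).  Values that were never measured are *absent*,
never zero — the screening engine's three-valued logic depends on that
distinction.

Two dataset formats are supported: one JSON document per patient (primary)
and a linked-table CSV dialect (``patients.csv`` / ``medications.csv`` /
``labs.csv`` / ``weights.csv`` keyed by ``patient_id``) for
spreadsheet-sourced data.  Writing then re-parsing a valid collection
reproduces it field-for-field.
"""

from __future__ import annotations

import datetime as dt
import json
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .logic import Ternary

__all__ = [
    "MEDICATION_CLASS_TAGS", "CANONICAL_LAB_UNITS", "UNIT_SYNONYMS",
    "Medication", "LabEntry", "LabPanel", "BloodPressure", "LifestyleProfile",
    "WeightEntry", "PatientRecord", "DatasetError",
    "bmi_category", "early_weight_gain",
    "parse_patient_dataset", "write_patient_json", "write_patient_csv",
]

#: Controlled vocabulary of medication class tags.  Unknown tags are
#: rejected at load time; drug-name -> class inference is out of scope.
MEDICATION_CLASS_TAGS = frozenset({
    "statin", "statin_lipophilic", "antipsychotic",
    "prolactin_raising_antipsychotic", "clozapine", "olanzapine",
    "ssri", "snri", "tca", "mirtazapine", "haloperidol", "benzodiazepine",
    "nsaid", "aspirin", "antiplatelet", "doac", "low_molecular_weight_heparin",
    "antiepileptic", "valproate", "carbamazepine", "phenytoin", "primidone",
    "lamotrigine", "corticosteroid_systemic", "levothyroxine", "ppi",
    "h2_receptor_antagonist", "dopamine_agonist", "metformin", "nrt",
    "varenicline", "bupropion", "folic_acid", "calcium", "vitamin_d",
    "bisphosphonate", "antihypertensive", "omega_3", "high_acb",
})

#: Canonical unit per numeric analyte.
CANONICAL_LAB_UNITS: dict[str, str] = {
    "total_cholesterol": "mmol/L",
    "non_hdl": "mmol/L",
    "triglycerides": "mmol/L",
    "hba1c": "mmol/mol",
    "fasting_glucose": "mmol/L",
    "tsh": "mIU/L",
    "prolactin": "mIU/L",
    "egfr": "mL/min",
}

#: Accepted spellings, mapped to the canonical unit.
UNIT_SYNONYMS: dict[str, str] = {
    "mmol/l": "mmol/L",
    "mmol/mol": "mmol/mol",
    "miu/l": "mIU/L",
    "mu/l": "mIU/L",  # mU/L is the same unit written without the 'i'
    "ml/min": "mL/min",
    "ml/min/1.73m2": "mL/min",
    "ml/min/1.73m^2": "mL/min",
}


class DatasetError(ValueError):
    """A patient dataset failed to parse or validate."""


_STATUS_FIELDS = ("t4_status", "thyroid_antibodies", "folate_status",
                  "b12_status", "haemoglobin_status")
_BP_FIELDS = ("clinic_systolic", "clinic_diastolic", "abpm_daytime_systolic",
              "abpm_daytime_diastolic", "hypertension_comorbidity_flags")
_LIFESTYLE_FIELDS = ("smoking_status", "cigarettes_per_day",
                     "minutes_to_first_cigarette", "ready_to_quit",
                     "alcohol_units_per_week", "light_exposure_risk")
_TOP_LEVEL_FIELDS = (
    "patient_id", "age", "sex", "diagnoses", "medications", "labs",
    "blood_pressure", "lifestyle", "bmi", "weight_history",
    "treatment_start_date", "cv_risk_10yr", "cv_risk_source",
    "fracture_risk_assessed", "vte_risk_assessed", "vte_prophylaxis_indicated",
    "pregnancy_status", "setting", "mobility_reduced", "record_date",
)


def valid_field_path(path: str) -> bool:
    """Is ``path`` a resolvable PatientRecord field path (dotted)?

    Used to reject knowledge-base rules referencing dangling fields at
    load time rather than silently evaluating them as unknown.
    """
    head, _, rest = path.partition(".")
    if head not in _TOP_LEVEL_FIELDS:
        return False
    if not rest:
        return True
    if head == "labs":
        return rest in CANONICAL_LAB_UNITS or rest in _STATUS_FIELDS
    if head == "blood_pressure":
        return rest in _BP_FIELDS
    if head == "lifestyle":
        return rest in _LIFESTYLE_FIELDS
    return False


def normalise_unit(analyte: str, unit: str) -> str:
    canonical = CANONICAL_LAB_UNITS.get(analyte)
    if canonical is None:
        raise DatasetError(f"unknown analyte {analyte!r}")
    resolved = UNIT_SYNONYMS.get(unit.strip().lower())
    if resolved != canonical:
        raise DatasetError(
            f"analyte {analyte!r}: unit {unit!r} does not match canonical "
            f"{canonical!r} (units are checked, never converted)")
    return canonical


class Medication(BaseModel):
    model_config = ConfigDict(extra="forbid")

    name: str
    class_tags: set[str] = Field(min_length=1)
    dose: Optional[str] = None
    prednisolone_equivalent_mg_per_day: Optional[float] = Field(default=None, ge=0)
    duration_days: Optional[float] = Field(default=None, ge=0)
    start_date: Optional[dt.date] = None

    @field_validator("class_tags")
    @classmethod
    def _known_tags(cls, tags: set[str]) -> set[str]:
        unknown = tags - MEDICATION_CLASS_TAGS
        if unknown:
            raise ValueError(f"unknown medication class tags: {sorted(unknown)}")
        return tags


class LabEntry(BaseModel):
    """One dated, unit-carrying analyte measurement."""

    model_config = ConfigDict(extra="forbid")

    value: float = Field(ge=0)
    unit: str
    date: Optional[dt.date] = None


_NUMERIC_ANALYTES = tuple(CANONICAL_LAB_UNITS)


class LabPanel(BaseModel):
    model_config = ConfigDict(extra="forbid")

    total_cholesterol: Optional[LabEntry] = None
    non_hdl: Optional[LabEntry] = None
    triglycerides: Optional[LabEntry] = None
    hba1c: Optional[LabEntry] = None
    fasting_glucose: Optional[LabEntry] = None
    tsh: Optional[LabEntry] = None
    prolactin: Optional[LabEntry] = None
    egfr: Optional[LabEntry] = None
    # categorical results are recorded as interpreted statuses
    t4_status: Optional[Literal["normal", "low", "high"]] = None
    thyroid_antibodies: Optional[Literal["positive", "negative"]] = None
    folate_status: Optional[Literal["deficient", "normal"]] = None
    b12_status: Optional[Literal["deficient", "normal"]] = None
    haemoglobin_status: Optional[Literal["anaemic", "normal"]] = None

    @model_validator(mode="after")
    def _check_units(self) -> "LabPanel":
        for analyte in _NUMERIC_ANALYTES:
            entry: Optional[LabEntry] = getattr(self, analyte)
            if entry is not None:
                entry.unit = normalise_unit(analyte, entry.unit)
        return self

    def latest_value(self, analyte: str) -> Optional[float]:
        if analyte not in CANONICAL_LAB_UNITS:
            raise DatasetError(f"unknown numeric analyte {analyte!r}")
        entry: Optional[LabEntry] = getattr(self, analyte)
        return None if entry is None else entry.value

    def entry(self, analyte: str) -> Optional[LabEntry]:
        return getattr(self, analyte) if analyte in CANONICAL_LAB_UNITS else None


class BloodPressure(BaseModel):
    model_config = ConfigDict(extra="forbid")

    clinic_systolic: float = Field(gt=0, lt=350)
    clinic_diastolic: float = Field(gt=0, lt=350)
    abpm_daytime_systolic: Optional[float] = Field(default=None, gt=0, lt=350)
    abpm_daytime_diastolic: Optional[float] = Field(default=None, gt=0, lt=350)
    hypertension_comorbidity_flags: set[Literal[
        "target_organ_damage", "established_cv_disease", "renal_disease",
        "diabetes", "cv_risk_ge_20pct"]] = Field(default_factory=set)

    @model_validator(mode="after")
    def _systolic_above_diastolic(self) -> "BloodPressure":
        if self.clinic_systolic <= self.clinic_diastolic:
            raise ValueError("clinic systolic must exceed diastolic")
        if (self.abpm_daytime_systolic is not None
                and self.abpm_daytime_diastolic is not None
                and self.abpm_daytime_systolic <= self.abpm_daytime_diastolic):
            raise ValueError("ABPM systolic must exceed diastolic")
        return self


class LifestyleProfile(BaseModel):
    model_config = ConfigDict(extra="forbid")

    smoking_status: Literal["current", "ex", "never", "undocumented"] = "undocumented"
    cigarettes_per_day: Optional[float] = Field(default=None, ge=0)
    minutes_to_first_cigarette: Optional[float] = Field(default=None, ge=0)
    ready_to_quit: Optional[bool] = None
    alcohol_units_per_week: Optional[float] = Field(default=None, ge=0)
    light_exposure_risk: Optional[bool] = None

    @model_validator(mode="after")
    def _cigarettes_only_for_current(self) -> "LifestyleProfile":
        if self.cigarettes_per_day is not None and self.smoking_status != "current":
            raise ValueError("cigarettes_per_day is only valid for current smokers")
        return self


class WeightEntry(BaseModel):
    model_config = ConfigDict(extra="forbid")

    date: dt.date
    kg: float = Field(gt=0)


class PatientRecord(BaseModel):
    model_config = ConfigDict(extra="forbid")

    patient_id: str
    age: int = Field(ge=18)
    sex: Literal["male", "female"]
    diagnoses: set[str] = Field(default_factory=set)
    medications: list[Medication] = Field(default_factory=list)
    labs: LabPanel = Field(default_factory=LabPanel)
    blood_pressure: Optional[BloodPressure] = None
    lifestyle: LifestyleProfile = Field(default_factory=LifestyleProfile)
    bmi: Optional[float] = Field(default=None, gt=0)
    weight_history: list[WeightEntry] = Field(default_factory=list)
    treatment_start_date: Optional[dt.date] = None
    cv_risk_10yr: Optional[float] = Field(default=None, ge=0, le=100)
    cv_risk_source: Optional[str] = None
    fracture_risk_assessed: Optional[bool] = None
    vte_risk_assessed: Optional[bool] = None
    vte_prophylaxis_indicated: Optional[bool] = None
    pregnancy_status: Literal["pregnant", "planning", "none", "not_applicable"] = "not_applicable"
    setting: Literal["inpatient", "outpatient"] = "outpatient"
    mobility_reduced: Optional[bool] = None
    record_date: Optional[dt.date] = None

    @field_validator("diagnoses")
    @classmethod
    def _normalise_diagnoses(cls, codes: set[str]) -> set[str]:
        return {c.strip().lower().replace(" ", "_") for c in codes}

    @field_validator("weight_history")
    @classmethod
    def _sorted_weights(cls, entries: list[WeightEntry]) -> list[WeightEntry]:
        return sorted(entries, key=lambda e: e.date)

    # -- queries used by the rule engine ---------------------------------

    def has_medication_tag(self, tag: str) -> bool:
        return any(tag in m.class_tags for m in self.medications)

    def high_dose_oral_steroid(self, mg_per_day: float = 7.5,
                               min_days: float = 90) -> Ternary:
        """Any systemic corticosteroid above a prednisolone-equivalent
        threshold sustained for at least ``min_days``.  UNKNOWN when a
        steroid is prescribed but its dose or duration is unrecorded."""
        steroids = [m for m in self.medications
                    if "corticosteroid_systemic" in m.class_tags]
        if not steroids:
            return Ternary.FALSE
        result = Ternary.FALSE
        for med in steroids:
            if med.prednisolone_equivalent_mg_per_day is None or med.duration_days is None:
                result = Ternary.UNKNOWN
                continue
            if (med.prednisolone_equivalent_mg_per_day > mg_per_day
                    and med.duration_days >= min_days):
                return Ternary.TRUE
        return result

    def early_weight_gain(self) -> Optional[bool]:
        if self.treatment_start_date is None:
            return None
        return early_weight_gain(self.weight_history, self.treatment_start_date)


def bmi_category(bmi: float) -> str:
    """WHO body-mass-index category.

    ``underweight`` below 18.5 kg/m2, ``overweight`` from 25 (inclusive)
    to 30, ``obese`` at 30 and above; the categories partition (0, inf).
    """
    if bmi <= 0:
        raise ValueError(f"BMI must be positive, got {bmi}")
    if bmi < 18.5:
        return "underweight"
    if bmi < 25:
        return "normal"
    if bmi < 30:
        return "overweight"
    return "obese"


def early_weight_gain(weight_history: list[WeightEntry],
                      treatment_start: dt.date) -> Optional[bool]:
    """Did the patient gain >=5% of baseline weight within the first month
    (31 calendar days) of treatment?

    Baseline = the latest weight dated on or before ``treatment_start``.
    Returns None (insufficient data, not False) without a baseline or
    without any follow-up weight inside the window.
    """
    baseline = None
    for entry in weight_history:
        if entry.date <= treatment_start:
            baseline = entry
    if baseline is None:
        return None
    window_end = treatment_start + dt.timedelta(days=31)
    followups = [e for e in weight_history
                 if treatment_start < e.date <= window_end]
    if not followups:
        return None
    return any(e.kg >= 1.05 * baseline.kg for e in followups)


# ---------------------------------------------------------------------------
# dataset I/O


def parse_patient_dataset(source: str | Path) -> list[PatientRecord]:
    """Read a patient dataset from JSON or linked CSV tables.

    ``source`` may be a single JSON file (one record or a list), a
    directory of per-patient ``*.json`` documents, or a directory holding
    the CSV tables ``patients.csv`` / ``medications.csv`` / ``labs.csv``
    (plus optional ``weights.csv``).
    """
    path = Path(source)
    if path.is_file():
        return _parse_json_file(path)
    if path.is_dir():
        if (path / "patients.csv").exists():
            return _parse_csv_tables(path)
        files = sorted(path.glob("*.json"))
        if not files:
            raise DatasetError(f"no patients.csv or *.json files in {path}")
        records: list[PatientRecord] = []
        for f in files:
            records.extend(_parse_json_file(f))
        return records
    raise DatasetError(f"dataset source {path} does not exist")


def _parse_json_file(path: Path) -> list[PatientRecord]:
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise DatasetError(f"{path}: not valid JSON ({exc})") from exc
    docs = payload if isinstance(payload, list) else [payload]
    records = []
    for i, doc in enumerate(docs):
        try:
            records.append(PatientRecord.model_validate(doc))
        except Exception as exc:
            pid = doc.get("patient_id", f"#{i}") if isinstance(doc, dict) else f"#{i}"
            raise DatasetError(f"{path}: record {pid}: {exc}") from exc
    return records


def _opt(row: pd.Series, key: str):
    value = row.get(key)
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    return value


def _opt_bool(row: pd.Series, key: str) -> Optional[bool]:
    value = _opt(row, key)
    if value is None:
        return None
    if isinstance(value, str):
        return value.strip().lower() in ("1", "true", "yes")
    return bool(value)


def _split(value) -> list[str]:
    if value is None:
        return []
    return [part for part in str(value).split(";") if part]


def _parse_csv_tables(directory: Path) -> list[PatientRecord]:
    patients = pd.read_csv(directory / "patients.csv", dtype={"patient_id": str})
    meds_path = directory / "medications.csv"
    labs_path = directory / "labs.csv"
    weights_path = directory / "weights.csv"
    meds = pd.read_csv(meds_path, dtype={"patient_id": str}) if meds_path.exists() else None
    labs = pd.read_csv(labs_path, dtype={"patient_id": str}) if labs_path.exists() else None
    weights = pd.read_csv(weights_path, dtype={"patient_id": str}) if weights_path.exists() else None

    records = []
    for _, row in patients.iterrows():
        pid = row["patient_id"]
        try:
            records.append(_record_from_rows(
                row,
                meds[meds.patient_id == pid] if meds is not None else None,
                labs[labs.patient_id == pid] if labs is not None else None,
                weights[weights.patient_id == pid] if weights is not None else None,
            ))
        except DatasetError:
            raise
        except Exception as exc:
            raise DatasetError(f"patients.csv: patient {pid}: {exc}") from exc
    return records


_STATUS_ANALYTES = ("t4_status", "thyroid_antibodies", "folate_status",
                    "b12_status", "haemoglobin_status")


def _record_from_rows(row: pd.Series, meds: Optional[pd.DataFrame],
                      labs: Optional[pd.DataFrame],
                      weights: Optional[pd.DataFrame]) -> PatientRecord:
    pid = row["patient_id"]
    medications = []
    if meds is not None:
        for _, m in meds.iterrows():
            medications.append(Medication(
                name=m["name"],
                class_tags=set(_split(_opt(m, "class_tags"))),
                dose=_opt(m, "dose"),
                prednisolone_equivalent_mg_per_day=_opt(m, "prednisolone_equivalent_mg_per_day"),
                duration_days=_opt(m, "duration_days"),
                start_date=_opt(m, "start_date"),
            ))
    panel: dict = {}
    if labs is not None:
        for _, entry in labs.iterrows():
            analyte = entry["analyte"]
            if analyte in _STATUS_ANALYTES:
                panel[analyte] = entry["value"]
            elif analyte in CANONICAL_LAB_UNITS:
                panel[analyte] = LabEntry(
                    value=float(entry["value"]),
                    unit=str(entry["unit"]),
                    date=_opt(entry, "date"),
                )
            else:
                raise DatasetError(f"labs.csv: patient {pid}: unknown analyte {analyte!r}")
    bp = None
    if _opt(row, "clinic_systolic") is not None:
        bp = BloodPressure(
            clinic_systolic=row["clinic_systolic"],
            clinic_diastolic=row["clinic_diastolic"],
            abpm_daytime_systolic=_opt(row, "abpm_daytime_systolic"),
            abpm_daytime_diastolic=_opt(row, "abpm_daytime_diastolic"),
            hypertension_comorbidity_flags=set(_split(_opt(row, "hypertension_comorbidity_flags"))),
        )
    weight_history = []
    if weights is not None:
        for _, w in weights.iterrows():
            weight_history.append(WeightEntry(date=w["date"], kg=w["kg"]))
    return PatientRecord(
        patient_id=pid,
        age=int(row["age"]),
        sex=row["sex"],
        diagnoses=set(_split(_opt(row, "diagnoses"))),
        medications=medications,
        labs=LabPanel.model_validate(panel),
        blood_pressure=bp,
        lifestyle=LifestyleProfile(
            smoking_status=_opt(row, "smoking_status") or "undocumented",
            cigarettes_per_day=_opt(row, "cigarettes_per_day"),
            minutes_to_first_cigarette=_opt(row, "minutes_to_first_cigarette"),
            ready_to_quit=_opt_bool(row, "ready_to_quit"),
            alcohol_units_per_week=_opt(row, "alcohol_units_per_week"),
            light_exposure_risk=_opt_bool(row, "light_exposure_risk"),
        ),
        bmi=_opt(row, "bmi"),
        weight_history=weight_history,
        treatment_start_date=_opt(row, "treatment_start_date"),
        cv_risk_10yr=_opt(row, "cv_risk_10yr"),
        cv_risk_source=_opt(row, "cv_risk_source"),
        fracture_risk_assessed=_opt_bool(row, "fracture_risk_assessed"),
        vte_risk_assessed=_opt_bool(row, "vte_risk_assessed"),
        vte_prophylaxis_indicated=_opt_bool(row, "vte_prophylaxis_indicated"),
        pregnancy_status=_opt(row, "pregnancy_status") or "not_applicable",
        setting=_opt(row, "setting") or "outpatient",
        mobility_reduced=_opt_bool(row, "mobility_reduced"),
        record_date=_opt(row, "record_date"),
    )


def record_to_json_dict(record: PatientRecord) -> dict:
    """A JSON-safe dict with unset optionals omitted and sets sorted."""
    doc = record.model_dump(mode="json", exclude_none=True)
    doc["diagnoses"] = sorted(doc.get("diagnoses", []))
    for med in doc.get("medications", []):
        med["class_tags"] = sorted(med["class_tags"])
    bp = doc.get("blood_pressure")
    if bp is not None:
        bp["hypertension_comorbidity_flags"] = sorted(
            bp.get("hypertension_comorbidity_flags", []))
    return doc


def write_patient_json(records: list[PatientRecord], target: str | Path,
                       per_patient: bool = False) -> None:
    """Write records as JSON: one list document, or one file per patient."""
    target = Path(target)
    if per_patient:
        target.mkdir(parents=True, exist_ok=True)
        for record in records:
            doc = record_to_json_dict(record)
            (target / f"{record.patient_id}.json").write_text(
                json.dumps(doc, indent=2, sort_keys=True) + "\n")
    else:
        docs = [record_to_json_dict(r) for r in records]
        target.parent.mkdir(parents=True, exist_ok=True)
        target.write_text(json.dumps(docs, indent=2, sort_keys=True) + "\n")


def write_patient_csv(records: list[PatientRecord], directory: str | Path) -> None:
    """Write the linked-table CSV dialect (inverse of the CSV parser)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    patient_rows, med_rows, lab_rows, weight_rows = [], [], [], []
    for r in records:
        row: dict = {
            "patient_id": r.patient_id, "age": r.age, "sex": r.sex,
            "diagnoses": ";".join(sorted(r.diagnoses)),
            "smoking_status": r.lifestyle.smoking_status,
            "cigarettes_per_day": r.lifestyle.cigarettes_per_day,
            "minutes_to_first_cigarette": r.lifestyle.minutes_to_first_cigarette,
            "ready_to_quit": r.lifestyle.ready_to_quit,
            "alcohol_units_per_week": r.lifestyle.alcohol_units_per_week,
            "light_exposure_risk": r.lifestyle.light_exposure_risk,
            "bmi": r.bmi, "cv_risk_10yr": r.cv_risk_10yr,
            "cv_risk_source": r.cv_risk_source,
            "fracture_risk_assessed": r.fracture_risk_assessed,
            "vte_risk_assessed": r.vte_risk_assessed,
            "vte_prophylaxis_indicated": r.vte_prophylaxis_indicated,
            "pregnancy_status": r.pregnancy_status, "setting": r.setting,
            "mobility_reduced": r.mobility_reduced,
            "record_date": r.record_date,
            "treatment_start_date": r.treatment_start_date,
        }
        if r.blood_pressure is not None:
            row.update({
                "clinic_systolic": r.blood_pressure.clinic_systolic,
                "clinic_diastolic": r.blood_pressure.clinic_diastolic,
                "abpm_daytime_systolic": r.blood_pressure.abpm_daytime_systolic,
                "abpm_daytime_diastolic": r.blood_pressure.abpm_daytime_diastolic,
                "hypertension_comorbidity_flags": ";".join(
                    sorted(r.blood_pressure.hypertension_comorbidity_flags)),
            })
        patient_rows.append(row)
        for m in r.medications:
            med_rows.append({
                "patient_id": r.patient_id, "name": m.name,
                "class_tags": ";".join(sorted(m.class_tags)), "dose": m.dose,
                "prednisolone_equivalent_mg_per_day": m.prednisolone_equivalent_mg_per_day,
                "duration_days": m.duration_days, "start_date": m.start_date,
            })
        for analyte in _NUMERIC_ANALYTES:
            entry = r.labs.entry(analyte)
            if entry is not None:
                lab_rows.append({"patient_id": r.patient_id, "analyte": analyte,
                                 "value": entry.value, "unit": entry.unit,
                                 "date": entry.date})
        for analyte in _STATUS_ANALYTES:
            status = getattr(r.labs, analyte)
            if status is not None:
                lab_rows.append({"patient_id": r.patient_id, "analyte": analyte,
                                 "value": status, "unit": None, "date": None})
        for w in r.weight_history:
            weight_rows.append({"patient_id": r.patient_id, "date": w.date, "kg": w.kg})
    pd.DataFrame(patient_rows).to_csv(directory / "patients.csv", index=False)
    pd.DataFrame(med_rows, columns=["patient_id", "name", "class_tags", "dose",
                                    "prednisolone_equivalent_mg_per_day",
                                    "duration_days", "start_date"]
                 ).to_csv(directory / "medications.csv", index=False)
    pd.DataFrame(lab_rows, columns=["patient_id", "analyte", "value", "unit", "date"]
                 ).to_csv(directory / "labs.csv", index=False)
    pd.DataFrame(weight_rows, columns=["patient_id", "date", "kg"]
                 ).to_csv(directory / "weights.csv", index=False)
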