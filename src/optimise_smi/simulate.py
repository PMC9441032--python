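"""Seeded synthetic data generators for every pipeline stage.

No patient-level data from interrater-reliability (IRR) studies of
screening tools is publicly depositable, so the package ships generators
that emulate the *statistical shape* of a 20-patient inpatient IRR cohort:
sex split 14 male / 6 female, ages ~ Normal(48.3, 13.0) clipped to
[18, 90], physical-comorbidity counts with median 1 (IQR 0-3, 44 in
total), regular-medication counts with median 4.5 (IQR 3-7.5, 116 in
total), plus planted screening features — three records missing an annual
HbA1c, two records on a prolactin-raising antipsychotic without a
prolactin level, four statin-eligible-untreated records (10-year CV risk
>= 10% with no statin), one inpatient presenting with catatonia and
reduced mobility, and one 27-year-old male smoking 20 cigarettes/day on
clozapine (the demonstration case).

Count distributions are matched *by construction*: fixed count multisets
whose median and IQR equal the configured targets exactly are dealt to
patients in seeded random order.  Real-world co-prescription correlations
and longitudinal structure are deliberately not modelled.

Rater decision matrices are simulated by independently flipping a
standard's cells (false-apply rate for cells the standard left blank,
false-omit rate for cells it applied), and Delphi panels by per-item
categorical draws on the 1-5 agreement scale.  Each generator consumes
its own RNG stream spawned from the top-level seed, so adding a generator
never perturbs existing fixtures.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .agreement import DecisionMatrix
from .delphi import RatingMatrix
from .patient import (BloodPressure, LabEntry, LabPanel, LifestyleProfile,
                      Medication, PatientRecord)

__all__ = [
    "DEFAULT_SEED", "CohortConfig", "RaterErrorModel", "generate_cohort",
    "cohort_summary", "simulate_raters", "simulate_panel", "panel_design_83",
]

#: Packaged seed for the default fixture cohort.
DEFAULT_SEED = 20

# Count multisets matched by construction (see module docstring):
# medications: median 4.5, IQR (3, 7.5), total 116 over 20 patients
_MEDICATION_COUNTS = (1, 2, 2, 3, 3, 3, 3, 4, 4, 4, 5, 5, 6, 6, 7, 9, 9, 13, 13, 14)
# physical comorbidities: median 1, IQR (0, 3), total 44 over 20 patients
_COMORBIDITY_COUNTS = (0, 0, 0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 2, 2, 3, 3, 5, 7, 8, 9)


@dataclass
class CohortConfig:
    n_patients: int = 20
    n_male: int = 14
    age_mean: float = 48.3
    age_sd: float = 13.0
    medication_counts: Sequence[int] = _MEDICATION_COUNTS
    comorbidity_counts: Sequence[int] = _COMORBIDITY_COUNTS
    n_missing_hba1c: int = 3
    n_missing_prolactin: int = 2
    n_statin_eligible_untreated: int = 4
    include_catatonia_case: bool = True
    include_smoker_on_clozapine_case: bool = True
    record_date: dt.date = dt.date(2019, 6, 1)
    seed: int = DEFAULT_SEED

    def validate(self) -> None:
        planted = (self.n_missing_hba1c + self.n_missing_prolactin
                   + self.n_statin_eligible_untreated
                   + int(self.include_catatonia_case)
                   + int(self.include_smoker_on_clozapine_case))
        if self.n_male > self.n_patients:
            raise ValueError("n_male exceeds n_patients")
        if planted > self.n_patients:
            raise ValueError(
                f"planted features need {planted} distinct patients but the "
                f"cohort has only {self.n_patients}")
        if len(self.medication_counts) != self.n_patients:
            raise ValueError("medication_counts must have one entry per patient")
        if len(self.comorbidity_counts) != self.n_patients:
            raise ValueError("comorbidity_counts must have one entry per patient")
        if self.include_smoker_on_clozapine_case and self.n_male == 0:
            raise ValueError("the demonstration case is male; n_male must be >= 1")


@dataclass
class RaterErrorModel:
    """Independent cellwise flip model for simulated raters."""

    false_apply_rate: float = 0.0   # standard blank -> rater applies
    false_omit_rate: float = 0.0    # standard applies -> rater omits

    def __post_init__(self) -> None:
        for rate in (self.false_apply_rate, self.false_omit_rate):
            if not 0 <= rate <= 1:
                raise ValueError("flip rates must lie in [0, 1]")


# formulary: name -> class tags.  Drugs that interact with planted
# features (statins, clozapine, prolactin-raising antipsychotics) are kept
# out of the general pool and assigned by role.
_ANTIPSYCHOTICS = {
    "olanzapine": {"antipsychotic", "olanzapine"},
    "quetiapine": {"antipsychotic"},
    "aripiprazole": {"antipsychotic"},
    "risperidone": {"antipsychotic", "prolactin_raising_antipsychotic"},
    "amisulpride": {"antipsychotic", "prolactin_raising_antipsychotic"},
    "paliperidone": {"antipsychotic", "prolactin_raising_antipsychotic"},
}
_GENERAL_POOL = {
    "sertraline": {"ssri"},
    "venlafaxine": {"snri"},
    "mirtazapine": {"mirtazapine"},
    "diazepam": {"benzodiazepine"},
    "sodium valproate": {"antiepileptic", "valproate"},
    "lamotrigine": {"antiepileptic", "lamotrigine"},
    "procyclidine": {"high_acb"},
    "metformin": {"metformin"},
    "amlodipine": {"antihypertensive"},
    "ramipril": {"antihypertensive"},
    "omeprazole": {"ppi"},
    "levothyroxine": {"levothyroxine"},
    "colecalciferol": {"vitamin_d"},
    "calcium carbonate": {"calcium"},
    "ibuprofen": {"nsaid"},
    "aspirin": {"aspirin"},
}
_STATIN = ("atorvastatin", {"statin"})
_PHYSICAL_COMORBIDITIES = (
    "hypertension", "diabetes", "copd", "asthma", "ckd", "cv_disease",
    "cerebrovascular_disease", "dementia", "vertebral_fracture_history",
    "history_of_falls", "hypothyroidism", "osteoarthritis", "epilepsy",
    "hyperlipidaemia", "gord",
)
_SMI_SUBTYPES = ("schizophrenia", "bipolar_disorder",
                 "schizoaffective_disorder", "severe_depression")


def generate_cohort(config: CohortConfig | None = None) -> list[PatientRecord]:
    """Generate a validated synthetic cohort; deterministic for a fixed
    config and seed, with exactly the configured sex split and planted
    feature counts."""
    cfg = config or CohortConfig()
    cfg.validate()
    streams = np.random.SeedSequence(cfg.seed).spawn(4)
    rng_demo = np.random.default_rng(streams[0])     # demographics + roles
    rng_diag = np.random.default_rng(streams[1])
    rng_meds = np.random.default_rng(streams[2])
    rng_labs = np.random.default_rng(streams[3])

    n = cfg.n_patients
    sexes = np.array(["male"] * cfg.n_male + ["female"] * (n - cfg.n_male))
    rng_demo.shuffle(sexes)
    ages = np.clip(np.rint(rng_demo.normal(cfg.age_mean, cfg.age_sd, size=n)),
                   18, 90).astype(int)
    med_counts = np.array(cfg.medication_counts)
    rng_demo.shuffle(med_counts)
    comorbidity_counts = np.array(cfg.comorbidity_counts)
    rng_demo.shuffle(comorbidity_counts)

    # disjoint role assignment
    order = list(rng_demo.permutation(n))
    roles: dict[str, list[int]] = {}

    def take(role: str, count: int, predicate=None) -> None:
        chosen: list[int] = []
        remaining = []
        for idx in order:
            if len(chosen) < count and (predicate is None or predicate(idx)):
                chosen.append(idx)
            else:
                remaining.append(idx)
        if len(chosen) < count:
            raise ValueError(f"cannot place role {role!r}")
        roles[role] = chosen
        order[:] = remaining

    if cfg.include_smoker_on_clozapine_case:
        take("demo", 1, predicate=lambda i: sexes[i] == "male")
        # the young demonstration case carries the fewest comorbidities
        demo_idx = roles["demo"][0]
        low_idx = int(np.argmin(comorbidity_counts))
        comorbidity_counts[[demo_idx, low_idx]] = comorbidity_counts[[low_idx, demo_idx]]
    if cfg.include_catatonia_case:
        take("catatonia", 1)
    take("missing_hba1c", cfg.n_missing_hba1c)
    take("missing_prolactin", cfg.n_missing_prolactin)
    take("statin_eligible", cfg.n_statin_eligible_untreated)

    def has_role(role: str, idx: int) -> bool:
        return idx in roles.get(role, [])

    records = []
    for i in range(n):
        pid = f"P{i + 1:02d}"
        sex = str(sexes[i])
        age = 27 if has_role("demo", i) else int(ages[i])
        diagnoses = {str(rng_diag.choice(_SMI_SUBTYPES))}
        n_comorbid = int(comorbidity_counts[i])
        picks = rng_diag.choice(len(_PHYSICAL_COMORBIDITIES),
                                size=min(n_comorbid, len(_PHYSICAL_COMORBIDITIES)),
                                replace=False)
        diagnoses |= {_PHYSICAL_COMORBIDITIES[p] for p in sorted(picks)}

        # medications: one antipsychotic first, then fill from the pool
        n_meds = int(med_counts[i])
        meds: list[Medication] = []
        if has_role("demo", i):
            meds.append(Medication(name="clozapine",
                                   class_tags={"antipsychotic", "clozapine"}))
        elif has_role("missing_prolactin", i):
            name = str(rng_meds.choice(["risperidone", "amisulpride", "paliperidone"]))
            meds.append(Medication(name=name, class_tags=set(_ANTIPSYCHOTICS[name])))
        else:
            name = str(rng_meds.choice(sorted(_ANTIPSYCHOTICS)))
            meds.append(Medication(name=name, class_tags=set(_ANTIPSYCHOTICS[name])))
        pool = dict(_GENERAL_POOL)
        # statins only for patients allowed to have one
        if not has_role("statin_eligible", i) and rng_meds.random() < 0.25:
            pool[_STATIN[0]] = _STATIN[1]
        extra_names = rng_meds.choice(sorted(pool), replace=False,
                                      size=min(n_meds - 1, len(pool)))
        meds.extend(Medication(name=str(m), class_tags=set(pool[str(m)]))
                    for m in extra_names)

        # cardiovascular risk: only the planted four are >= 10% untreated
        on_statin = any("statin" in m.class_tags for m in meds)
        if has_role("statin_eligible", i):
            cv_risk: Optional[float] = float(np.round(rng_labs.uniform(11, 24), 1))
        elif age >= 40:
            cv_risk = float(np.round(rng_labs.uniform(3, 9.4), 1))
        else:
            cv_risk = None
        if on_statin and cv_risk is not None:
            cv_risk = float(np.round(rng_labs.uniform(3, 9.4), 1))

        labs: dict = {}
        if not has_role("missing_hba1c", i):
            labs["hba1c"] = LabEntry(
                value=float(np.round(rng_labs.normal(38, 5), 0)),
                unit="mmol/mol",
                date=cfg.record_date - dt.timedelta(days=int(rng_labs.integers(7, 180))))
        on_prap = any("prolactin_raising_antipsychotic" in m.class_tags for m in meds)
        if on_prap and not has_role("missing_prolactin", i):
            labs["prolactin"] = LabEntry(
                value=float(np.round(rng_labs.uniform(120, 650), 0)),
                unit="mIU/L",
                date=cfg.record_date - dt.timedelta(days=int(rng_labs.integers(7, 120))))
        labs["total_cholesterol"] = LabEntry(
            value=float(np.round(rng_labs.normal(5.1, 0.9), 1)), unit="mmol/L",
            date=cfg.record_date - dt.timedelta(days=int(rng_labs.integers(7, 180))))

        if has_role("demo", i):
            lifestyle = LifestyleProfile(smoking_status="current",
                                         cigarettes_per_day=20,
                                         minutes_to_first_cigarette=15,
                                         ready_to_quit=True,
                                         alcohol_units_per_week=float(
                                             np.round(rng_labs.uniform(0, 20), 1)))
        else:
            status = str(rng_labs.choice(["current", "ex", "never"], p=[0.5, 0.2, 0.3]))
            lifestyle = LifestyleProfile(
                smoking_status=status,
                cigarettes_per_day=(float(rng_labs.integers(5, 30))
                                    if status == "current" else None),
                alcohol_units_per_week=float(np.round(rng_labs.uniform(0, 30), 1)))

        systolic = float(np.round(rng_labs.normal(128, 12), 0))
        diastolic = min(float(np.round(rng_labs.normal(78, 8), 0)), systolic - 10)
        record = PatientRecord(
            patient_id=pid, age=age, sex=sex, diagnoses=diagnoses,
            medications=meds, labs=LabPanel.model_validate(labs),
            blood_pressure=BloodPressure(
                clinic_systolic=systolic, clinic_diastolic=diastolic),
            lifestyle=lifestyle,
            bmi=float(np.round(rng_labs.normal(28, 4.5), 1)),
            cv_risk_10yr=cv_risk,
            cv_risk_source="QRISK3" if cv_risk is not None else None,
            setting="inpatient",
            record_date=cfg.record_date,
        )
        if has_role("catatonia", i):
            record.diagnoses.add("catatonia")
            record.mobility_reduced = True
            record.vte_prophylaxis_indicated = True
        records.append(record)
    return records


def cohort_summary(records: list[PatientRecord]) -> dict:
    """Descriptive summary: the check surface for :func:`generate_cohort`."""
    if not records:
        raise ValueError("empty cohort")
    ages = np.array([r.age for r in records], dtype=float)
    med_counts = np.array([len(r.medications) for r in records], dtype=float)
    physical = np.array(
        [len(r.diagnoses & set(_PHYSICAL_COMORBIDITIES)) for r in records],
        dtype=float)

    def med_iqr(values):
        q25, q75 = np.percentile(values, [25, 75])
        return float(np.median(values)), (float(q25), float(q75))

    med_median, med_quartiles = med_iqr(med_counts)
    com_median, com_quartiles = med_iqr(physical)
    return {
        "n": len(records),
        "n_male": sum(r.sex == "male" for r in records),
        "n_female": sum(r.sex == "female" for r in records),
        "age_mean": float(ages.mean()),
        "age_sd": float(ages.std(ddof=1)) if len(records) > 1 else 0.0,
        "medications_total": int(med_counts.sum()),
        "medications_median": med_median,
        "medications_iqr": med_quartiles,
        "comorbidities_total": int(physical.sum()),
        "comorbidities_median": com_median,
        "comorbidities_iqr": com_quartiles,
    }


def simulate_raters(standard: DecisionMatrix, model: RaterErrorModel,
                    n_raters: int, seed: int) -> list[DecisionMatrix]:
    """Simulate raters as independent cellwise corruptions of a standard."""
    rng = np.random.default_rng(seed)
    grid = standard.decisions.to_numpy()
    raters = []
    for k in range(n_raters):
        flips = np.where(grid,
                         rng.random(grid.shape) < model.false_omit_rate,
                         rng.random(grid.shape) < model.false_apply_rate)
        decisions = pd.DataFrame(np.where(flips, ~grid, grid),
                                 index=standard.decisions.index,
                                 columns=standard.decisions.columns)
        raters.append(DecisionMatrix(rater_id=f"sim-rater-{k + 1}",
                                     decisions=decisions))
    return raters


@dataclass(frozen=True)
class PanelItemDesign:
    """Categorical rating distribution for one candidate indicator."""

    item_id: str
    probs: tuple[float, float, float, float, float]

    def __post_init__(self) -> None:
        if len(self.probs) != 5 or abs(sum(self.probs) - 1) > 1e-9:
            raise ValueError(f"{self.item_id}: probs must sum to 1 over 1..5")


def simulate_panel(design: Sequence[PanelItemDesign], n_panellists: int,
                   seed: int, round_id: str = "round-1") -> RatingMatrix:
    """Draw a panellist x item Likert matrix from per-item distributions."""
    rng = np.random.default_rng(seed)
    columns = {}
    for item in design:
        columns[item.item_id] = rng.choice(
            [1, 2, 3, 4, 5], size=n_panellists, p=list(item.probs))
    frame = pd.DataFrame(columns,
                         index=[f"panellist-{i + 1:02d}" for i in range(n_panellists)])
    return RatingMatrix(round_id=round_id, ratings=frame)


def panel_design_83(p_agree_accept: float = 0.95, p_agree_reject: float = 0.08,
                    p_agree_borderline: float = 0.62) -> list[PanelItemDesign]:
    """An 83-item first-round design: 53 strong-accept items, 16 reject
    items and 14 borderline items, parameterised by each archetype's
    probability that a panellist rates 1 or 2."""

    def split(p_low: float) -> tuple[float, ...]:
        # low mass split 60/40 over {1,2}; remainder 60/30/10 over {3,4,5}
        hi = 1 - p_low
        return (0.6 * p_low, 0.4 * p_low, 0.6 * hi, 0.3 * hi, 0.1 * hi)

    design = []
    for k in range(53):
        design.append(PanelItemDesign(f"accept-{k + 1:02d}", split(p_agree_accept)))
    for k in range(16):
        design.append(PanelItemDesign(f"reject-{k + 1:02d}", split(p_agree_reject)))
    for k in range(14):
        design.append(PanelItemDesign(f"border-{k + 1:02d}", split(p_agree_borderline)))
    return design
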