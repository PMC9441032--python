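# Methods notes

This note records the modelling conventions, numerical choices and known
limitations behind `optimise-smi`.  It documents *how* the package
computes; every empirical number it mentions is produced by the test
suite or by `scripts/acceptance.py`.

## The screening model

Each OPTIMISE indicator is a condition–action pair: a machine-evaluable
predicate over a patient record plus a recommended action (initiate,
consider, refer, monitor, counsel, avoid, adjust dose).  The 62 shipped
indicators live in `src/optimise_smi/kb/optimise_kb.yaml` as data, not
code, so clinicians can diff the encoded conditions against the tool's
published wording.  Ids are `R<round>-<item>`: 53 indicators accepted in
the first consensus round, 9 in the second, each carrying the expert
panel's recorded median and 75th-centile Likert rating.  The loader
rejects duplicate ids, predicates referencing non-existent record fields,
and any indicator whose recorded summary fails the acceptance rule — an
indicator that the panel did not accept cannot ship.

### Three-valued evaluation

Clinical records are incomplete by nature, and for a screening tool the
difference between "the rule does not apply" and "we cannot tell" is the
clinically interesting signal.  Atoms over absent data therefore
evaluate *unknown*, and composites combine under strong Kleene
semantics (unknown AND false = false; unknown OR true = true; unknown
propagates otherwise).  An indicator whose condition evaluates unknown
reports `insufficient_data`, listing the missing fields.  For trees of
independent atom occurrences, Kleene evaluation coincides with
brute-force enumeration of all completions of the unknown atoms (unknown
exactly when completions disagree); the test suite proves this
exhaustively on small trees and property-based on random ones.  Two
deliberate exceptions are *presence* atoms (`field_absent`,
`lab_absent`), which are two-valued because absence itself is the
condition being screened (e.g. "monitor baseline prolactin" applies
precisely when no prolactin level exists).

### Encoding conventions

* **Boundaries** follow the printed comparators exactly (≥ vs >); ages
  phrased as "over N years" are encoded as age ≥ N, the inclusive
  convention of screening programmes.
* **Units** are fixed per analyte (mmol/L, mmol/mol, mIU/L, mL/min,
  mmHg, kg/m²).  A small synonym table (mU/L ≡ mIU/L, eGFR variants) is
  accepted; any other unit is rejected rather than converted, because a
  silent mg/dL-to-mmol/L confusion is the worst failure mode a lab-value
  pipeline can have.  Unmeasured analytes are absent, never zero.
* **Early weight gain** is ≥ 5% over the baseline weight (the latest
  weight on or before treatment start) within 31 calendar days; no
  baseline or no in-window follow-up yields insufficient data, not
  false.
* **"Older adult"** for the relaxed HbA1c ceiling (58 mmol/mol) is fixed
  at age ≥ 65; the tool text does not define it and 65 is the
  conventional geriatric threshold.
* **Hypertension staging** requires both clinic and ambulatory (ABPM)
  readings exactly as printed; without ABPM the outcome is
  insufficient data rather than a clinic-only guess.
* **Advisory indicators** that defer to external guidance (COPD/asthma
  optimisation, VTE protocols, fracture-risk calculators) trigger on
  their context diagnosis or flag: the engine prompts, it does not
  re-implement QRISK/SCORE/FRAX/QFracture or national guidelines — risk
  scores are record inputs.
* **Decision units.** Reference IRR arithmetic implies 65 decisions per
  dataset against 62 indicators.  The published material does not
  explain the difference, so the package reconstructs it by splitting
  three multi-action indicators (R1-34, R1-41, R1-42) into two
  separately recordable units each, sharing the parent's provenance.
  This expansion is configurable (`decision_unit_ids(expand_sub_units=
  False)` returns the 62-unit surface) and is flagged as a
  reconstruction: which specific rows the original raters scored
  separately is unknowable from the published tables, and no statistic
  computed here depends on the choice — agreement tables are either
  supplied directly as counts or computed on whichever surface the user
  selects.

### Monitoring gaps

Separately from rule outcomes, the engine flags indicated-but-absent
measurements: HbA1c (annual screen for every adult with SMI; a dated
value older than 365 days relative to the record's reference date counts
as absent), prolactin under a prolactin-raising antipsychotic, a CV risk
estimate from age 40, smoking status always, and a VTE risk assessment
for inpatients with reduced mobility.

## Delphi consensus

Ratings are 1–5 Likert agreement scores; missing ratings are dropped per
item (panels shrink between rounds and individual panellists skip
items).  Quantiles use linear interpolation between closest order
statistics (numpy default, R type 7).  The reference analysis does not
name its quantile algorithm, so exact 75th-centile reproduction from raw
ratings is convention-dependent — but the *classification* of every
shipped indicator is robust to the choice, and interpolated values such
as 1.25 and 1.75 from 16–17 raters require an interpolating convention
of this family.  The rule — accept iff median ≤ 2 and p75 ≤ 2, reject
iff median > 2, else revise — is monotone: worsening ratings can never
promote an item to acceptance (property-tested).  "Drop" exists only at
the configured final round, modelling the decision that a further round
would not reach consensus.

## Agreement statistics

Cohen's kappa is computed from the 2×2 rater-vs-standard table with
p_o = (A+D)/n and p_e = ((A+C)(A+B)+(B+D)(C+D))/n²; its standard error
is the Fleiss–Cohen–Everitt asymptotic form and the 95% CI is
κ ± 1.96·SE clipped to [−1, 1].  The implementation is independent and
is cross-checked in the tests against `statsmodels`' kappa (point
estimate and SE agree to machine precision on random tables).
Degenerate cases are explicit: an empty table is an error, both raters
constant (p_e = 1) raises an undefined-kappa signal, one rater constant
yields a kappa with SE/CI flagged as unavailable.  Specific agreement
uses p_pos = 2A/(2A+B+C) and p_neg = 2D/(2D+B+C) with zero denominators
reported as undefined rather than raised.

Two pooling methods are provided and always labelled in the output:
cellwise concatenation (kappa of the summed table) and an n-weighted
mean of per-table kappas.  Neither is asserted to reproduce externally
reported pooled or multi-rater kappas, whose computation method is
typically a statistics-package internal (e.g. a multi-rater routine) and
is not derivable from printed 2×2 marginals; likewise one published
per-rater kappa (rater 2, 0.848) differs in the third decimal from
direct recomputation from its own printed cells (0.853), so the package
reports recomputed values and documents the discrepancy instead of
forcing agreement.  Decisions are strictly binary; an optional recorded
reason code on not-applied decisions is collapsed to not-applied for all
statistics.

## Synthetic data

The cohort generator emulates the statistical shape of a 20-patient
inpatient IRR exercise; its defaults are the study conditions, not
tuning knobs: 14 male / 6 female by construction; ages drawn from
N(48.3, 13.0) clipped to [18, 90]; physical-comorbidity counts with
median 1, IQR 0–3, total 44; regular-medication counts with median 4.5,
IQR 3–7.5, total 116.  Because only summaries (not raw data) of such
cohorts are publishable, the count distributions are matched **by
construction**: fixed multisets whose median/IQR/total equal the targets
exactly are dealt to patients in seeded random order.  Planted features
are placed in disjoint patients and are exactly recoverable by
screening: 3 records missing HbA1c, 2 records on a prolactin-raising
antipsychotic without a prolactin level, 4 statin-eligible-untreated
records (CV risk ≥ 10%, no statin; all other records are constructed to
stay below 10% or be treated), one catatonia inpatient with reduced
mobility and no VTE assessment, and the demonstration case — a
27-year-old man smoking 20 cigarettes/day on clozapine.  Each generator
component consumes its own RNG stream spawned from the top-level seed
(packaged fixture seed: 20), so adding a generator never perturbs
existing fixtures, and a fixed seed regenerates the serialised cohort
byte-identically.

What the generator does **not** model: co-prescription and
diagnosis–drug correlations beyond the planted roles, longitudinal
trajectories, realistic lab covariance, or any mimicry of actual study
patients.  Passing tests on synthetic cohorts therefore demonstrate the
*mechanics* (rule evaluation, gap detection, agreement arithmetic,
determinism), not clinical performance on real records.

Simulated raters corrupt a standard decision grid by independent
cellwise flips (a false-apply rate on blank cells, a false-omit rate on
applied cells); at zero error kappa is exactly 1 and mean kappa
decreases monotonically in the error rate (1000-replicate seeded check
in the tests).  Simulated Delphi panels draw per-item categorical
ratings; with 17 panellists and no missingness an item's classification
depends only on how many panellists rate 1–2 (accept iff ≥ 13, reject
iff ≤ 8), which gives closed-form binomial expectations for flow counts
— the packaged 83-item design (53 strong-accept, 16 reject, 14
borderline archetypes) is calibrated against these expectations and
verified by simulation.

## Problem sizes and determinism

All computations are desk-scale: the full suite (including the
1000-replicate rater-recovery check, exhaustive quantile-oracle
enumeration over all 1286 Likert samples of size ≤ 8, and exhaustive
small-tree Kleene enumeration) runs in a few seconds on one CPU.
Screening is deterministic for a fixed record and knowledge base; all
simulation is seeded; property-based tests run derandomised under
pytest.

## Known limitations

* The knowledge base encodes the machine-checkable core of each
  indicator; free-text nuances ("unless contraindicated", "discuss with
  a specialist") remain in the recommendation text for the clinician.
* No drug-name→class inference or ICD/SNOMED/ATC mapping: records must
  arrive with controlled class tags, and unknown tags are load errors.
* Kleene insufficiency is conservative: a record with sparse labs will
  report many `insufficient_data` outcomes — by design, since these are
  the monitoring prompts the tool exists to surface.
* The asymptotic kappa CI is unreliable for very sparse tables; no
  bootstrap or hierarchical CI is provided.
* Five candidate indicators that failed to reach consensus at the final
  round are not represented: their texts were never published.
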