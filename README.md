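# optimise-smi

People with severe mental illness (SMI — schizophrenia, schizoaffective
disorder, bipolar illness, severe affective disorder) die up to 30 years
earlier than the general population, largely from under-treated physical
illness: statins, antihypertensives, monitoring bloods and lifestyle
interventions that would be routine elsewhere are frequently omitted.
`optimise-smi` implements the **OPTIMISE** medicines-optimisation
instrument — a 62-indicator screening tool for potential prescribing
omissions (PPOs) and monitoring gaps in adults with SMI — as an executable
rule engine, together with the two statistical engines used to build and
validate screening tools of this kind:

* **Screening engine** — the 62 indicators (e.g. *consider statin therapy
  at ≥ 10% 10-year cardiovascular risk*, *refer to endocrinology when
  prolactin > 3000 mIU/L*, *reduce clozapine by up to 50% on abrupt
  smoking cessation*) live in a declarative YAML knowledge base and are
  evaluated against patient records under three-valued Kleene logic:
  every outcome is `triggered`, `not_triggered` or `insufficient_data`,
  so missing laboratory data is surfaced, never silently treated as
  normal.  Monitoring gaps (a missing annual HbA1c, a missing prolactin
  on a prolactin-raising antipsychotic, an absent CV risk score over 40,
  undocumented smoking status, no VTE risk assessment for an immobile
  inpatient) are flagged alongside.
* **Delphi consensus** — expert panels rate candidate indicators on a
  5-point Likert scale (1 = strongly agree … 5 = strongly disagree).  Per
  item the engine computes the median, IQR and 75th centile and applies
  the acceptance rule: accept iff median ≤ 2 **and** p75 ≤ 2; reject iff
  median > 2; otherwise revise (or drop at the final round).
* **Interrater reliability** — rater-vs-standard decisions form a 2×2
  table (A both applied, B rater over-applied, C rater under-applied,
  D both abstained) from which the package computes Cohen's
  κ = (p_o − p_e)/(1 − p_e) with the Fleiss–Cohen–Everitt asymptotic
  standard error and 95% CI, the Cicchetti–Feinstein specific-agreement
  proportions p_pos = 2A/(2A+B+C) and p_neg = 2D/(2D+B+C), band
  interpretation (poor ≤ 0.20 < fair ≤ 0.40 < moderate ≤ 0.60 <
  substantial ≤ 0.80 < good ≤ 1.0), and labelled pooling methods.
* **Synthetic cohorts** — seeded generators emulate a 20-patient
  inpatient IRR cohort (14 male / 6 female, ages ~N(48.3, 13), median 4.5
  regular medicines, planted monitoring gaps and a 27-year-old smoker on
  clozapine as a demonstration case), plus simulated raters and Delphi
  panels, so every pipeline stage is testable without patient data.

It is aimed at clinical-pharmacy and psychiatry informatics researchers
who want to run, audit or extend prescribing-omission screening rules,
and at methodologists reproducing the consensus/agreement arithmetic
behind screening-tool validation.

## Worked example

Interrater reliability from direct agreement counts (four raters against
a consensus standard over 20 patient datasets × 65 decision units):

```bash
$ cat counts.csv
label,A,B,C,D
standard * rater 1,155,42,91,1012
standard * rater 2,229,33,28,1010
standard * rater 3,202,39,44,1015
standard * rater 4,226,35,20,1019
$ optimise irr --counts counts.csv --pool concatenate
comparison                       A     B     C     D   ppos   pneg  kappa (95% CI)          band
standard * rater 1             155    42    91  1012    0.7   0.94  0.639 (0.583 to 0.695)  substantial
standard * rater 2             229    33    28  1010   0.88   0.97  0.853 (0.817 to 0.889)  good
standard * rater 3             202    39    44  1015   0.83   0.96  0.790 (0.747 to 0.834)  substantial
standard * rater 4             226    35    20  1019   0.89   0.97  0.865 (0.831 to 0.900)  good
pooled (pooled_concatenate)                                         0.791
```

Rater 1, say, agreed with the standard on 155 + 1012 of 1300 decisions
(p_o = 0.90), but after correcting for the agreement expected by chance
(p_e = 0.72, dominated by the many jointly not-applied cells) κ falls to
0.639 — substantial agreement.  The specific-agreement proportions show
that disagreement is concentrated on *applying* indicators (p_pos 0.70)
rather than abstaining (p_neg 0.94).

Screening a patient from Python:

```python
from optimise_smi import generate_cohort, load_knowledge_base, screen_patient

kb = load_knowledge_base()            # 62 indicators, 7 body systems
cohort = generate_cohort()            # packaged synthetic 20-patient cohort
demo = next(r for r in cohort if r.has_medication_tag("clozapine"))
report = screen_patient(kb, demo)
print(report.counts)
print(report.by_status("triggered"))
```

prints

```
{'triggered': 13, 'not_triggered': 35, 'insufficient_data': 14}
['R1-09', 'R1-10', 'R1-11', 'R1-25', 'R1-32', 'R1-38', 'R1-39', 'R1-40',
 'R1-41', 'R1-42', 'R1-51', 'R1-52', 'R1-53']
```

— for this 27-year-old smoking 20 cigarettes/day on clozapine the tool
fires the full smoking-cessation bundle: document smoking status
(`R1-38`), offer cessation advice (`R1-39`, `R1-11`, `R1-53`), offer
NRT/varenicline/bupropion since he smokes more than 10/day (`R1-40`), and
warn that clozapine needs a dose reduction of up to 50% with an assay 3–5
days after abrupt cessation (`R1-42`).

Other subcommands: `optimise screen --kb kb.yaml --patients dir/ --out
report.json`, `optimise delphi --ratings round1.csv --ratings round2.csv`,
`optimise simulate cohort --seed 1 --n 20 --out cohort.json`.

## Layout

```
src/optimise_smi/
  kb/optimise_kb.yaml   the 62-indicator knowledge base (data, not code)
  patient.py            unit-aware patient records, JSON/CSV datasets
  logic.py              three-valued predicate expressions
  engine.py             indicator evaluation, screening, monitoring gaps
  delphi.py             Likert summarisation + consensus classification
  agreement.py          kappa, specific agreement, pooling
  simulate.py           seeded cohort / rater / panel generators
  cli.py                the `optimise` command
docs/methods.md         modelling notes, conventions, limitations
```
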