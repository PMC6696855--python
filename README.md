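# sbdh-screen

Screening electronic health records (EHRs) for **social and behavioral
determinants of health (SBDH)** — housing issues, social
connection/isolation, and income/financial resource strain — across both
structured fields and free-text clinical notes.

Health systems that want to target social-needs interventions rarely have
SBDH in clean structured fields: diagnosis Z-codes (e.g. Z59.0
*homelessness*) are used for well under 1% of patients, while clinical notes
mention the same problems severalfold more often. This package is for
clinical informaticians and population-health analysts who need to measure
that availability gap in their own EHR and prescreen patients from notes:

* **Structured screening** — field completeness rates
  (n patients with a value / denominator, as *n (%)*), ICD-10/ICD-9
  diagnosis cohorts per domain with subtype codes, questionnaire completion.
* **Rule-based note mining** — word-boundary literal phrase matching from a
  replaceable YAML lexicon, with deterministic context classification:
  SmartPhrase question/answer handling (`"Is Patient Homeless?" → No` is
  documented absence, not a case), a NegEx-style 40-character pre-span
  negation window, and same-sentence other-referent cues. A note flags a
  domain iff it has ≥1 affirmative mention; a patient counts iff they have
  ≥1 flagged note.
* **Chart-review validation** — tallies of TP-only / FP-only / TN-only /
  conflicting notes and span-level confusion of the classifier against gold
  mention labels.
* **Synthetic EHR generator** — deterministic tables, notes and gold labels
  reproducing the statistical structure of a large reference extract
  (completeness rates, diagnosis prevalences 0.58%/0.19%/0.07%, note
  prevalences 2.60%/3.00%/1.00%, mention-context mixture), so the whole
  pipeline is testable without any patient data.

See `docs/methods.md` for the model, parameters, and limitations.

## Worked example

Run the full pipeline — simulate, screen structured data, mine notes,
evaluate, report — on a 10,000-patient synthetic population:

```bash
sbdh-screen all --n 10000 --seed 1 --out demo
```

```
simulate: 10000 patients, 3111 diagnoses, 75843 notes -> demo/data
screen-structured: 10000 patients, 3111 diagnosis rows -> demo/reports
mine-notes: 75843 notes, 1028 mentions, 1009 flagged notes -> demo/reports
evaluate: 100 fixture notes, 130 occurrences -> demo/reports
report: combined table -> demo/reports/combined_report.csv
```

`demo/reports/completeness_report.csv` — each field's unique-patient
numerator and completeness percentage; the estimates sit at the configured
generator rates (address/zip 95%, race 90%, …, alcohol 9.08%, smoking
32.01%):

```
field,numerator,denominator,rate_pct
address_or_zip,9481,10000,94.81
ethnicity,5015,10000,50.15
race,9002,10000,90.02
preferred_language,4971,10000,49.71
alcohol_drinks_per_week,914,10000,9.14
smoking_status,3218,10000,32.18
```

`demo/reports/prevalence_report.csv` — unique patients with at least one
affirmative-mention note per domain, over all 10,000 noted patients
(configured rates 2.60% / 3.00% / 1.00%):

```
domain,patients_flagged,denominator,pct
social_connection,253,10000,2.53
housing,306,10000,3.06
financial_strain,97,10000,0.97
```

`demo/reports/tally_report.json` — the chart-review validation on the
bundled deterministic 100-note homelessness fixture: the token *homeless*
occurs 130 times; 64 notes carry only true-positive mentions, 14 only
false-positives, 20 only SmartPhrase true negatives ("Is Patient Homeless?
No"), and 2 notes conflict (a true-positive and a false-positive mention in
the same note). Mention-level precision over the fixture's 86 TP and 16 FP
mentions is 86/102 ≈ 0.843:

```json
{"occurrence_total": 130, "notes_tp_only": 64, "notes_fp_only": 14,
 "notes_tn_only": 20, "notes_conflicting": 2,
 "mention_precision": 0.8431372549019608}
```

The same stages are importable as a library (`sbdh_screen.generate_ehr`,
`completeness_report`, `diagnosis_cohort`, `mine_notes`,
`patient_prevalence`, `tally`, …), and `sbdh-screen` exposes each stage as
its own subcommand (`simulate`, `screen-structured`, `mine-notes`,
`evaluate`, `report`).

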