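# Methods

## Problem and scope

Social and behavioral determinants of health (SBDH) — housing issues, social
connection/isolation, income/financial resource strain, and related factors —
are documented inconsistently in electronic health records: partly in
structured fields (demographics, social history, ICD-10 Z-code diagnoses),
partly in free-text clinical notes. This package implements a screening
pipeline over both kinds of data:

1. **Structured screening** — per-field completeness rates, diagnosis-based
   patient cohorts per SBDH domain (with subtype codes), and questionnaire
   completion rates.
2. **Unstructured screening** — rule-based mining of clinical notes for
   domain phrase occurrences, with context classification (affirmative,
   negated, other-referent, SmartPhrase question/answer), aggregated to
   note-level and patient-level flags and stratified by provider role and
   note type.
3. **Validation** — a chart-review style tally (TP-only / FP-only / TN-only /
   conflicting notes) computed against gold mention labels, plus a span-level
   confusion of the rule-based classifier against gold.

Because real multi-million-patient EHR extracts cannot be redistributed, the
package ships a deterministic synthetic-EHR generator that reproduces the
statistical structure of the reference extract the pipeline was designed
around, including gold labels for every planted signal.

## The matcher

Phrase matching is word-boundary, case-insensitive (by default), literal
matching: a boundary is any transition between alphanumeric and
non-alphanumeric characters, or text start/end. `"homeless"` therefore never
matches inside `"homelessness"`; underscores and hyphens are boundaries. This
differs from regex `\b` (which treats `_` as a word character) and is chosen
for determinism and language-independence. Multi-word phrases are stored with
single internal spaces and matched against whitespace-normalized text; the
normalizer keeps an offset map so every reported span indexes the raw note
text exactly (`matched_text == text[start:end]` is an invariant). Overlapping
occurrences of *different* patterns are all reported; a per-pattern scan (not
a single alternation) guarantees this.

## Context classification

Classification is deliberately minimal, deterministic machinery — no trained
model — with a fixed precedence:

1. **SmartPhrase windows.** SmartPhrases are EHR boilerplate questions (e.g.
   `"Is Patient Homeless?"`) followed by a provider-chosen Yes/No token. The
   detector finds each question occurrence (case-insensitive) and the
   earliest answer token starting within `max_answer_distance` characters
   after it (default 15 — answers immediately follow the question in
   templated text). A phrase occurrence inside the question or its answer
   window is `smartphrase_negative` if the answer is "No" *or absent*, and
   `smartphrase_affirmative` if "Yes". Documented absence is not evidence:
   only affirmative classes set note flags.
2. **Negation.** A NegEx-style heuristic: a negation cue (`denies`, `no
   evidence of`, `not`, …; the list lives in the lexicon file) ending within
   the 40 characters before the span, inside the same sentence, yields
   `negated`. Sentences are delimited by `.?!` followed by whitespace, or by
   a raw newline (tracked through normalization).
3. **Other referent.** A same-sentence cue (`brother`, `neighbor`, `works
   at`, …) indicates the phrase describes someone other than the patient.
   Cue occurrences lying entirely inside the matched span itself are ignored
   so phrases cannot self-trigger.
4. Otherwise `affirmative`.

Aggregation uses "at least one" semantics throughout: a note flags a domain
iff it has ≥1 affirmative-context mention (a *raw* mode flags any
occurrence instead, since a site may prefer occurrence screening plus manual
review); a patient counts iff they have ≥1 flagged note; the prevalence
denominator is every unique patient with any note. Subdomains are not
distinguished in text mining — only structured queries report subtype codes.

## Structured metrics

* **Missingness**: absent, empty, or whitespace-only values are missing; the
  literal category `"Unknown"` is a valid EHR value and counts as present
  (it is how preferred language is recorded when unknown).
* **Rounding**: every "n (%)" figure uses half-up rounding at two decimals
  (`percent()`); one documented rule applied everywhere.
* **Cohort queries** count unique patients with ≥1 matching code in a closed
  date window from any source (problem list, billing, encounter). ICD-9
  equivalents are included through a small explicit map
  (V60.0→Z59.0, V60.1→Z59.1, V60.2→Z59.6, V60.8/V60.9→Z59.8, V62.4→Z60.4,
  V61.0→Z63.0/Z63.5), deliberately data not a terminology lookup, and marked
  approximate.
* **Shared codes**: ICD-10-CM Z59.8 belongs to both the housing ("other
  housing problems") and financial ("other economic circumstances problems")
  code sets. Entries carry a `shared_code` flag and cohort queries for such
  entries additionally match the recorded diagnosis description (`label`
  column), mirroring how an EHR reporting tool distinguishes the two usages
  of one code. The synthetic generator writes the domain-appropriate label.
* **Domain totals** are set unions of subtype cohorts; the generator plants
  at most one subtype per domain per patient, so synthetic subtype counts
  reconcile exactly to domain totals, while the union handles real-data
  overlap correctly.

## The synthetic generator

Defaults are the study conditions of the reference extract:

| parameter | default | source |
|---|---|---|
| completeness: address/zip, race, ethnicity, language | 0.95, 0.90, 0.50, 0.50 | reported completeness rates |
| completeness: alcohol use, smoking status | 0.0908, 0.3201 | reported completeness rates |
| ICD prevalence: social / housing / financial | 0.0058 / 0.0019 / 0.0007 | diagnosis-query patient counts over 5,401,324 |
| note prevalence: social / housing / financial | 0.0260 / 0.0300 / 0.0100 | note-based patient counts over 1,188,202 |
| notes per patient | mean 7.6, as 1 + Poisson(6.6) | 9,066,508 encounters / 1,188,202 patients |
| context mixture | affirmative .64, SmartPhrase-negative .20, negated .07, other-referent .07, mixed .02 | 100-note chart-review composition (the 14 false-positive notes are split evenly between negated and other-referent contexts, which the source does not characterise) |
| provider roles / note types | physician-dominant (.60) / progress-note-dominant (.50) | qualitative only |
| smoking-status categories | normalized reported breakdown | social-history status counts |
| structured / unstructured windows | 2003-01-01..2018-06-26 / 2016-07-01..2018-05-31 | collection windows |

Mechanics worth knowing:

* Every stage draws from its own seeded substream
  (`default_rng([seed, stage])`), so stages are reproducible independently
  of call order; identical config+seed gives byte-identical output.
* Every patient receives ≥1 note, so the unstructured denominator equals the
  population.
* A patient is gold-flagged per domain with exactly the configured note
  prevalence. Flagged patients receive one affirmative sentence (and, with
  conditional probability `mixed/(affirmative+mixed)`, an additional
  false-positive-context sentence in the same note — a "mixed" note).
  Non-flagged patients receive confounder notes (SmartPhrase-negative,
  negated, or other-referent sentences) at rate
  `p · (non-affirmative weight)/(affirmative+mixed weight)`, so context
  classes appear in the corpus in the configured proportions without
  touching gold flags. If the mixture gives zero affirmative weight, nobody
  is flagged and the prevalence parameter drives confounders directly.
* Planted sentences come from templates whose wording avoids every cue and
  phrase except the planted one; filler sentences are verified post hoc to
  contain no lexicon phrase. Gold labels are therefore exact, and the miner
  recovers `patient_note_flags` exactly on generated corpora — a tested
  invariant, which also means prevalence estimates inherit the clean
  Binomial(n, p) sampling distribution of the planted flags.
* Questionnaire tables scale the reference administered counts to the
  simulated population (templates that scale to zero administrations are
  omitted) and draw completions binomially at the reference rates.

What the generator does **not** emulate: realistic clinical language (filler
is a small template vocabulary), misspellings and lexical variation,
section structure, temporality ("history of homelessness in 2009"),
cross-field correlation (e.g. between housing codes and housing notes), and
inter-annotator disagreement. Passing tests on synthetic corpora therefore
demonstrate the pipeline's mechanics — matching, offsets, negation scope,
aggregation arithmetic — not real-world recall, which depends on lexicon
coverage that only site-specific curation can provide. The bundled seed
phrase lists (7 phrases per domain, drawn from the domain definitions and
ICD label text) are a documented starting point, not a curated inventory;
the lexicon is a YAML data file precisely so it can be replaced.

## The 100-note annotation fixture

`generate_annotation_fixture` builds the deterministic chart-review corpus
for the homelessness subdomain: 100 notes, each containing the token
`homeless`, composed of 64 notes with only true-positive mentions, 14 with
only false-positive mentions (7 negated, 7 other-referent), 20 with only
SmartPhrase true negatives (`"Is Patient Homeless? No."`), and 2 conflicting
notes with both a true-positive and a false-positive mention. The token
appears 130 times: the 30 occurrences beyond one per note are distributed
deterministically — 20 second affirmative mentions (first 20 TP notes),
8 repeated question/answer lines (first 8 SmartPhrase notes), and the 2
false-positive mentions of the conflicting notes. Composition is fixed by
construction and asserted at build time; the seed varies only surface text
(template choice, filler, note order). Mention-level tallies follow: 86 TP,
16 FP, 28 TN, so the fixture's mention precision is 86/102 ≈ 0.843 — a
diagnostic, since the reference chart review reports no precision figure.

## Numerical and design choices

* Half-up decimal rounding via `decimal.Decimal`, not float `round()`, to
  avoid both binary-representation surprises and banker's rounding.
* Undefined rates (zero denominators) raise `UndefinedRateError` rather than
  returning NaN, so report files never silently carry undefined cells.
* Note classing tie-break: a note mixing true-negative mentions with exactly
  one other class takes that class's "only" label and emits a warning — the
  original four-cell scheme never needed the case, so the completion is
  flagged as such at runtime.
* `evaluate_miner` matches spans by exact offsets; a gold mention whose span
  was found but context-classed differently is a context misclassification,
  not a missed match; recall is reported over gold true-positive mentions.
* Test problem sizes: statistical recovery checks run at 10,000 patients
  across five fixed seeds and assert each estimate inside the central 99%
  binomial interval of the configured parameter; published-arithmetic checks
  are exact.

## Known limitations

* The negation vocabulary is small and window-based; scope errors typical of
  NegEx-style systems (e.g. pseudo-negation, long coordination) will occur
  on real text.
* No false-negative estimation: phrases absent from the lexicon are
  invisible, and the pipeline measures only what it matches.
* The ICD-9 map is approximate and minimal; sites with deep ICD-9 history
  should substitute a curated map.
* Figure-level stratification reproduces only qualitative structure
  (dominant strata), not published magnitudes.
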