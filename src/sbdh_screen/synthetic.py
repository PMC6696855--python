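"""Synthetic EHR generator with planted SBDH ground truth.

Because real EHR extracts cannot be redistributed, every downstream stage of
the pipeline is exercised on synthetic data whose statistical structure
matches the screened health-system extract it emulates: per-field
completeness rates for demographics and social history, per-domain ICD
diagnosis prevalences with subtype codes apportioned by the published
reference tallies, note-level patient prevalences for the three text-mined
domains, and a mention-context mixture (affirmative, negated,
other-referent, SmartPhrase-negative, mixed) mirroring the 100-note
chart-review composition.

The generator is fully deterministic given a config and seed, emits gold
labels (structured domain flags, per-note planted mentions with character
spans, patient-level note flags), and guarantees by construction — verified
post hoc — that filler text contains no lexicon phrase, so gold labels are
exact and the miner can be scored against them without ambiguity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from .annotation import GoldClass, GoldMention
from .lexicon import (
    CompiledMatcher,
    Domain,
    LexiconSet,
    REFERENCE_SUBTYPE_COUNTS,
    TEXT_MINED_DOMAINS,
    default_lexicon,
)
from .notes import ContextClass, NoteDocument
from .structured import ICD9_EQUIVALENTS

# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------

#: Smoking-status collection breakdown (per-status patient counts in the
#: reference extract), normalized into a categorical distribution.
SMOKING_STATUS_COUNTS = {
    "current every day smoker": 114566,
    "current some day smoker": 28547,
    "former smoker": 297099,
    "heavy tobacco smoker": 3111,
    "light tobacco smoker": 12857,
    "never assessed": 302631,
    "never smoker": 952636,
    "passive smoke exposure/never smoker": 4274,
    "ever smoked/current status unknown": 1133,
    "unknown if ever smoked": 11915,
}

#: Preferred-language breakdown among patients with a captured language
#: (``"Unknown"`` is a real EHR value, distinct from a missing record).
LANGUAGE_COUNTS = {
    "English": 2626379,
    "Spanish": 53446,
    "Arabic": 7317,
    "Chinese/Mandarin": 4036,
    "Korean": 3168,
    "Unknown": 5936,
    "Other": 18134,
}

#: Of patients with any alcohol-use value, the fraction reporting >=1
#: drink/week (178,789 of 490,348 in the reference extract).
ALCOHOL_NONZERO_FRACTION = 178789 / 490348

#: Questionnaire templates: (template, domain, administered, completed) in
#: the reference extract; the generator scales administered counts to the
#: simulated population and draws completions binomially at the same rate.
QUESTIONNAIRE_REFERENCE: list[tuple[str, str, int, int]] = [
    ("nursing_assessment", "social_connection", 1026988, 944829),
    ("ed_head_to_toe", "social_connection", 237143, 92486),
    ("ed_nursing_1", "social_connection", 217954, 204877),
    ("ed_nursing_2", "social_connection", 278084, 169631),
    ("ed_pediatrics", "social_connection", 131134, 93105),
    ("ed_social_work_suicide_homicide", "social_connection", 15101, 14648),
    ("ed_social_work", "social_connection", 14481, 12743),
    ("or_pacu_flowsheet", "social_connection", 147694, 82709),
    ("inpatient_ot_home_setup", "social_connection", 131948, 47501),
    ("inpatient_ob_postpartum", "social_connection", 135587, 120672),
    ("inpatient_spiritual_care", "social_connection", 116719, 68864),
    ("pediatrics_screening", "social_connection", 144659, 85349),
    ("social_history_sbirt", "social_connection", 2015, 1995),
    ("housing_utility_voucher", "housing", 217, 97),
    ("abuse_neglect_screen", "housing", 12058, 11575),
    ("social_history_questionnaire", "housing", 1900, 1824),
    ("ed_triage_abuse_resource", "housing", 713702, 39254),
    ("chemical_dependence_admission", "housing", 15056, 2258),
    ("ambulatory_priority_access", "housing", 1116, 78),
    ("adult_admission_intake", "housing", 77230, 27030),
    ("pediatric_newborn_intake", "housing", 1067, 587),
    ("psychiatry_social_work", "housing", 4913, 4422),
]

_REFERENCE_STRUCTURED_DENOMINATOR = 5_401_324


def _normalized(counts: dict[str, int]) -> dict[str, float]:
    total = sum(counts.values())
    return {k: v / total for k, v in counts.items()}


class SimulationConfig(BaseModel):
    """Study-condition parameters for the synthetic EHR.

    Defaults are the reference extract's reported values: completeness rates
    per structured field, ICD diagnosis prevalence per domain (0.58% /
    0.19% / 0.07%), note-level patient prevalence per domain (2.60% / 3.00%
    / 1.00%), a mean of 7.6 notes per patient (9,066,508 encounters over
    1,188,202 patients), and a mention-context mixture read off the 100-note
    chart-review composition. Provider-role and note-type mixtures are
    qualitative (physician- and progress-note-dominant).
    """

    n_patients: int = Field(default=10_000, ge=0)
    structured_window: tuple[date, date] = (date(2003, 1, 1), date(2018, 6, 26))
    unstructured_window: tuple[date, date] = (date(2016, 7, 1), date(2018, 5, 31))
    completeness: dict[str, float] = Field(
        default_factory=lambda: {
            "address_or_zip": 0.95,
            "race": 0.90,
            "ethnicity": 0.50,
            "preferred_language": 0.50,
            "alcohol_use": 0.0908,
            "smoking_status": 0.3201,
        }
    )
    icd_prevalence: dict[Domain, float] = Field(
        default_factory=lambda: {
            Domain.SOCIAL_CONNECTION: 0.0058,
            Domain.HOUSING: 0.0019,
            Domain.FINANCIAL_STRAIN: 0.0007,
        }
    )
    note_prevalence: dict[Domain, float] = Field(
        default_factory=lambda: {
            Domain.SOCIAL_CONNECTION: 0.0260,
            Domain.HOUSING: 0.0300,
            Domain.FINANCIAL_STRAIN: 0.0100,
        }
    )
    notes_per_patient: float = Field(default=7.6, gt=0)
    context_mixture: dict[str, float] = Field(
        default_factory=lambda: {
            "affirmative": 0.64,
            "smartphrase_negative": 0.20,
            "negated": 0.07,
            "other_referent": 0.07,
            "mixed": 0.02,
        }
    )
    provider_role_mixture: dict[str, float] = Field(
        default_factory=lambda: {
            "physician": 0.60,
            "nurse": 0.20,
            "social_worker": 0.10,
            "case_manager": 0.05,
            "other": 0.05,
        }
    )
    note_type_mixture: dict[str, float] = Field(
        default_factory=lambda: {
            "progress_note": 0.50,
            "telephone": 0.15,
            "discharge_summary": 0.10,
            "ED_note": 0.10,
            "other": 0.15,
        }
    )
    smoking_status_distribution: dict[str, float] = Field(
        default_factory=lambda: _normalized(SMOKING_STATUS_COUNTS)
    )
    icd9_fraction: float = Field(default=0.10, ge=0.0, le=1.0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        for name, probs in (
            ("completeness", self.completeness),
            ("icd_prevalence", self.icd_prevalence),
            ("note_prevalence", self.note_prevalence),
        ):
            for key, p in probs.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"{name}[{key}] = {p} outside [0, 1]")
        for name, mixture in (
            ("context_mixture", self.context_mixture),
            ("provider_role_mixture", self.provider_role_mixture),
            ("note_type_mixture", self.note_type_mixture),
            ("smoking_status_distribution", self.smoking_status_distribution),
        ):
            if not mixture:
                raise ValueError(f"{name} must be non-empty")
            total = sum(mixture.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} weights sum to {total}, expected 1")
        return self


# --------------------------------------------------------------------------
# Ground truth
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedMention:
    """A phrase deliberately planted in a synthetic note."""

    domain: Domain
    phrase: str
    start: int
    end: int
    context_class: ContextClass


@dataclass
class GroundTruth:
    """Gold labels emitted alongside the synthetic EHR."""

    structured_positive: dict[Domain, set[str]] = field(default_factory=dict)
    note_mentions: dict[str, list[PlantedMention]] = field(default_factory=dict)
    patient_note_flags: dict[Domain, set[str]] = field(default_factory=dict)


# --------------------------------------------------------------------------
# RNG substreams — each stage draws from its own stream so stages are
# individually reproducible regardless of call order.
# --------------------------------------------------------------------------

_STREAMS = {"population": 0, "social_history": 1, "diagnoses": 2, "notes": 3, "questionnaires": 4}


def _rng(config: SimulationConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng([config.seed, _STREAMS[stage]])


def _iso_dates(rng: np.random.Generator, window: tuple[date, date], n: int) -> list[str]:
    span = (window[1] - window[0]).days
    offsets = rng.integers(0, span + 1, size=n)
    return [(window[0] + timedelta(days=int(o))).isoformat() for o in offsets]


# --------------------------------------------------------------------------
# Population
# --------------------------------------------------------------------------

_RACES = [
    "White",
    "Black or African American",
    "Asian",
    "American Indian or Alaska Native",
    "Native Hawaiian or Other Pacific Islander",
    "Other",
]
_STREETS = ["Main", "Park", "Charles", "Monument", "Pratt", "Calvert", "Eutaw", "Greene"]


def generate_population(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Patients and encounters with per-field missingness at 1 − completeness.

    Addresses and zips are syntactically valid when present; race allows
    multiple self-identified values (semicolon-joined); preferred language
    includes the explicit ``"Unknown"`` value, which is present, not missing.
    """
    if config.n_patients < 0:
        raise ValueError("n_patients must be non-negative")
    rng = _rng(config, "population")
    n = config.n_patients
    c = config.completeness
    patient_ids = [f"P{i:07d}" for i in range(n)]

    has_addr = rng.random(n) < c.get("address_or_zip", 0.0)
    street_pick = rng.integers(0, len(_STREETS), size=n)
    house_num = rng.integers(1, 9999, size=n)
    zip_codes = rng.integers(20600, 21999, size=n)
    addr_also = rng.random(n) < 0.85  # zip always present when the composite is

    has_race = rng.random(n) < c.get("race", 0.0)
    race_pick = rng.integers(0, len(_RACES), size=n)
    race_second = rng.integers(0, len(_RACES), size=n)
    race_multi = rng.random(n) < 0.10

    has_eth = rng.random(n) < c.get("ethnicity", 0.0)
    hispanic = rng.random(n) < 0.20

    has_lang = rng.random(n) < c.get("preferred_language", 0.0)
    lang_names = list(LANGUAGE_COUNTS)
    lang_pick = rng.choice(len(lang_names), size=n, p=list(_normalized(LANGUAGE_COUNTS).values()))

    rows = []
    for i in range(n):
        address = ""
        zip_code = ""
        if has_addr[i]:
            zip_code = str(zip_codes[i])
            if addr_also[i]:
                address = f"{house_num[i]} {_STREETS[street_pick[i]]} St"
        race = ""
        if has_race[i]:
            race = _RACES[race_pick[i]]
            if race_multi[i] and race_second[i] != race_pick[i]:
                race = race + ";" + _RACES[race_second[i]]
        rows.append(
            {
                "patient_id": patient_ids[i],
                "address": address,
                "zip": zip_code,
                "race": race,
                "ethnicity": ("Hispanic" if hispanic[i] else "Non-Hispanic") if has_eth[i] else "",
                "preferred_language": lang_names[lang_pick[i]] if has_lang[i] else "",
            }
        )
    patients = pd.DataFrame(
        rows, columns=["patient_id", "address", "zip", "race", "ethnicity", "preferred_language"]
    )

    enc_counts = 1 + rng.poisson(2.0, size=n) if n else np.array([], dtype=int)
    enc_rows = []
    eid = 0
    for i in range(n):
        dates = _iso_dates(rng, config.structured_window, int(enc_counts[i]))
        for d in dates:
            enc_rows.append({"encounter_id": f"E{eid:08d}", "patient_id": patient_ids[i], "date": d})
            eid += 1
    encounters = pd.DataFrame(enc_rows, columns=["encounter_id", "patient_id", "date"])
    return patients, encounters


def generate_social_history(config: SimulationConfig, patients: pd.DataFrame) -> pd.DataFrame:
    """Social-history rows: alcohol drinks/week and smoking status.

    Any recorded value counts as present — including 0 drinks per week —
    matching how the social-history section stores these fields.
    """
    rng = _rng(config, "social_history")
    n = len(patients)
    c = config.completeness
    has_alc = rng.random(n) < c.get("alcohol_use", 0.0)
    nonzero = rng.random(n) < ALCOHOL_NONZERO_FRACTION
    drinks = 1 + rng.poisson(3.0, size=n)
    has_smoke = rng.random(n) < c.get("smoking_status", 0.0)
    statuses = list(config.smoking_status_distribution)
    status_pick = rng.choice(
        len(statuses), size=n, p=list(config.smoking_status_distribution.values())
    )
    quit_dates = _iso_dates(rng, config.structured_window, n)
    has_quit = rng.random(n) < 0.5
    rows = []
    for i in range(n):
        alcohol = ""
        if has_alc[i]:
            alcohol = str(int(drinks[i])) if nonzero[i] else "0"
        status = statuses[status_pick[i]] if has_smoke[i] else ""
        quit = quit_dates[i] if (status == "former smoker" and has_quit[i]) else ""
        rows.append(
            {
                "patient_id": patients["patient_id"].iat[i],
                "alcohol_drinks_per_week": alcohol,
                "smoking_status": status,
                "smoking_quit_date": quit,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["patient_id", "alcohol_drinks_per_week", "smoking_status", "smoking_quit_date"],
    )


# --------------------------------------------------------------------------
# Diagnoses
# --------------------------------------------------------------------------

_BACKGROUND_CODES = [
    ("I10", "Essential hypertension"),
    ("E11.9", "Type 2 diabetes mellitus without complications"),
    ("J06.9", "Acute upper respiratory infection"),
    ("M54.5", "Low back pain"),
    ("K21.9", "Gastro-esophageal reflux disease"),
]

_SOURCES = ["problem_list", "billing", "encounter"]


def generate_diagnoses(
    config: SimulationConfig,
    patients: pd.DataFrame,
    lexicon_set: LexiconSet,
) -> tuple[pd.DataFrame, dict[Domain, set[str]]]:
    """Diagnosis records with planted SBDH positives.

    A patient is positive for a domain with the configured prevalence and
    receives exactly one subtype code, apportioned by the reference subtype
    tallies so subtype counts reconcile to domain totals; a configurable
    fraction of codes is written as the ICD-9 equivalent. Background
    (non-SBDH) codes and occasional duplicate records exercise query
    filtering and per-patient deduplication.
    """
    rng = _rng(config, "diagnoses")
    n = len(patients)
    patient_ids = list(patients["patient_id"])
    rows: list[dict] = []
    structured_positive: dict[Domain, set[str]] = {}
    for domain in TEXT_MINED_DOMAINS:
        if domain not in lexicon_set or not lexicon_set[domain].codes:
            raise ValueError(f"lexicon has no diagnosis codes for domain {domain.value}")
        prevalence = config.icd_prevalence.get(domain, 0.0)
        entries = {e.code: e for e in lexicon_set[domain].codes}
        weights = REFERENCE_SUBTYPE_COUNTS[domain]
        codes = list(weights)
        probs = np.array([weights[c] for c in codes], dtype=float)
        probs /= probs.sum()
        positive = rng.random(n) < prevalence
        subtype_pick = rng.choice(len(codes), size=n, p=probs)
        use_icd9 = rng.random(n) < config.icd9_fraction
        duplicate = rng.random(n) < 0.2
        source_pick = rng.integers(0, len(_SOURCES), size=n)
        dates = _iso_dates(rng, config.structured_window, n)
        dup_dates = _iso_dates(rng, config.structured_window, n)
        flagged: set[str] = set()
        for i in range(n):
            if not positive[i]:
                continue
            flagged.add(patient_ids[i])
            entry = entries[codes[subtype_pick[i]]]
            system, code = entry.system, entry.code
            if use_icd9[i] and entry.code in ICD9_EQUIVALENTS:
                system, code = "ICD-9-CM", ICD9_EQUIVALENTS[entry.code][0]
            base = {
                "patient_id": patient_ids[i],
                "encounter_id": f"DXE{len(rows):07d}",
                "system": system,
                "code": code,
                "label": entry.label,
                "source": _SOURCES[source_pick[i]],
            }
            rows.append({**base, "date": dates[i]})
            if duplicate[i]:
                rows.append({**base, "encounter_id": f"DXE{len(rows):07d}", "date": dup_dates[i]})
        structured_positive[domain] = flagged
    # background, non-SBDH codes
    bg = rng.random(n) < 0.3
    bg_pick = rng.integers(0, len(_BACKGROUND_CODES), size=n)
    bg_dates = _iso_dates(rng, config.structured_window, n)
    bg_sources = rng.integers(0, len(_SOURCES), size=n)
    for i in range(n):
        if bg[i]:
            code, label = _BACKGROUND_CODES[bg_pick[i]]
            rows.append(
                {
                    "patient_id": patient_ids[i],
                    "encounter_id": f"DXE{len(rows):07d}",
                    "system": "ICD-10-CM",
                    "code": code,
                    "label": label,
                    "source": _SOURCES[bg_sources[i]],
                    "date": bg_dates[i],
                }
            )
    diagnoses = pd.DataFrame(
        rows,
        columns=["patient_id", "encounter_id", "system", "code", "label", "source", "date"],
    )
    return diagnoses, structured_positive


# --------------------------------------------------------------------------
# Notes
# --------------------------------------------------------------------------

_FILLER_SENTENCES = [
    "Patient seen in clinic for routine follow up.",
    "Vital signs reviewed and stable.",
    "Medications reconciled at this visit.",
    "Discussed plan of care with patient.",
    "Laboratory results reviewed.",
    "Patient verbalized understanding of instructions.",
    "Follow up scheduled in two weeks.",
    "Review of systems otherwise unremarkable.",
    "Patient ambulating independently.",
    "Dietary counseling provided.",
]

# Planted-sentence templates; "{P}" marks the phrase slot. Affirmative
# templates contain no negation or other-referent cue; negated and
# other-referent templates place their cue in the same sentence as the span.
_AFFIRMATIVE_TEMPLATES = [
    "Patient reports {P} at this time.",
    "Assessment today documents {P} for this patient.",
    "Patient describes ongoing {P} during the visit.",
    "Social work consult placed given current {P}.",
]
_NEGATED_TEMPLATES = [
    "Patient denies {P} at this time.",
    "Patient denied {P} during screening.",
    "There is no evidence of {P} today.",
    "Patient is not experiencing {P} currently.",
]
_OTHER_REFERENT_TEMPLATES = [
    "Patient mentions a brother dealing with {P} recently.",
    "Patient is worried about a sister facing {P}.",
    "Patient describes a neighbor with {P}.",
]


def _fill(template: str, phrase: str) -> tuple[str, int, int]:
    start = template.index("{P}")
    sentence = template.replace("{P}", phrase)
    return sentence, start, start + len(phrase)


def _smartphrase_sentence(lexicon_set: LexiconSet, domain: Domain) -> tuple[str, int, int, str]:
    """The domain's SmartPhrase question answered "No", with the span of the
    phrase occurrence inside the question."""
    lex = lexicon_set[domain]
    if not lex.smartphrase_templates:
        raise ValueError(f"domain {domain.value} has no SmartPhrase template")
    tpl = lex.smartphrase_templates[0]
    question = tpl.question_text
    lowered = question.lower()
    for pat in lex.patterns:
        pos = lowered.find(pat.phrase.lower())
        if pos != -1:
            surface = question[pos : pos + len(pat.phrase)]
            sentence = f"{question} {tpl.answer_vocabulary[1]}."
            return sentence, pos, pos + len(pat.phrase), surface
    raise ValueError(
        f"no lexicon phrase of domain {domain.value} occurs in SmartPhrase question "
        f"{question!r}"
    )


def _verify_filler(matcher: CompiledMatcher) -> None:
    hits = matcher.scan(" ".join(_FILLER_SENTENCES))
    if hits:
        raise ValueError(
            "filler vocabulary contains lexicon phrases; regenerate with a "
            f"disjoint lexicon (first hit: {hits[0]})"
        )


@dataclass
class _NoteBuilder:
    sentences: list[str] = field(default_factory=list)
    planted: list[tuple[Domain, str, int, int, ContextClass]] = field(default_factory=list)
    #: per-sentence separator drawn at render time; planted offsets are
    #: computed against the rendered text

    def add_filler(self, sentence: str) -> None:
        self.sentences.append(sentence)

    def add_planted(
        self, sentence: str, rel_start: int, rel_end: int, domain: Domain, phrase: str, ctx: ContextClass
    ) -> None:
        self.planted.append((domain, phrase, len(self.sentences), rel_start, rel_end, ctx))  # type: ignore[arg-type]
        self.sentences.append(sentence)

    def render(self, rng: np.random.Generator) -> tuple[str, list[PlantedMention]]:
        seps = [" " if rng.random() >= 0.15 else "\n" for _ in range(max(len(self.sentences) - 1, 0))]
        offsets = []
        pos = 0
        for i, s in enumerate(self.sentences):
            offsets.append(pos)
            pos += len(s)
            if i < len(seps):
                pos += len(seps[i])
        parts: list[str] = []
        for i, s in enumerate(self.sentences):
            parts.append(s)
            if i < len(seps):
                parts.append(seps[i])
        text = "".join(parts)
        mentions = [
            PlantedMention(
                domain=domain,
                phrase=phrase,
                start=offsets[idx] + rs,
                end=offsets[idx] + re_,
                context_class=ctx,
            )
            for domain, phrase, idx, rs, re_, ctx in self.planted  # type: ignore[misc]
        ]
        for m in mentions:
            assert text[m.start : m.end] == m.phrase
        return text, mentions


def generate_notes(
    config: SimulationConfig,
    patients: pd.DataFrame,
    lexicon_set: LexiconSet,
) -> tuple[list[NoteDocument], GroundTruth]:
    """Clinical notes with planted mentions and exact gold labels.

    Every patient receives at least one note (so the unstructured
    denominator equals the population); a patient is gold-flagged for a
    domain with the configured note prevalence, receiving one
    affirmative-mention note (sometimes with an additional false-positive
    mention in the same note — a "mixed" note). Non-flagged patients may
    receive confounder notes carrying SmartPhrase-negative, negated, or
    other-referent mentions at rates derived from the context mixture, so
    that context classes appear in the corpus in the configured proportions
    without affecting gold flags.
    """
    if not config.note_type_mixture or not config.provider_role_mixture:
        raise ValueError("note_type_mixture and provider_role_mixture must be non-empty")
    rng = _rng(config, "notes")
    matcher = CompiledMatcher(lexicon_set)
    _verify_filler(matcher)

    n = len(patients)
    patient_ids = list(patients["patient_id"])
    roles = list(config.provider_role_mixture)
    role_p = list(config.provider_role_mixture.values())
    types = list(config.note_type_mixture)
    type_p = list(config.note_type_mixture.values())

    mix = config.context_mixture
    w_aff = mix.get("affirmative", 0.0)
    w_mixed = mix.get("mixed", 0.0)
    w_sn = mix.get("smartphrase_negative", 0.0)
    w_neg = mix.get("negated", 0.0)
    w_or = mix.get("other_referent", 0.0)
    # With zero affirmative weight nobody is gold-flagged and the prevalence
    # parameter drives confounder notes directly.
    w_am = w_aff + w_mixed

    truth = GroundTruth(patient_note_flags={d: set() for d in TEXT_MINED_DOMAINS})
    notes: list[NoteDocument] = []
    note_counts = 1 + rng.poisson(max(config.notes_per_patient - 1.0, 0.0), size=n) if n else []
    nid = 0
    for i in range(n):
        k = int(note_counts[i])
        builders = []
        for _ in range(k):
            b = _NoteBuilder()
            for _ in range(int(rng.integers(2, 5))):
                b.add_filler(_FILLER_SENTENCES[int(rng.integers(0, len(_FILLER_SENTENCES)))])
            builders.append(b)
        for domain in TEXT_MINED_DOMAINS:
            p = config.note_prevalence.get(domain, 0.0)
            if w_am > 0:
                p_flag = p
                q = p * (w_sn + w_neg + w_or) / w_am
            else:
                p_flag = 0.0
                q = p
            u = rng.random()
            lex = lexicon_set[domain]
            phrases = [pat.phrase for pat in lex.patterns]
            target = builders[int(rng.integers(0, k))]
            if u < p_flag:
                phrase = phrases[int(rng.integers(0, len(phrases)))]
                tpl = _AFFIRMATIVE_TEMPLATES[int(rng.integers(0, len(_AFFIRMATIVE_TEMPLATES)))]
                sentence, rs, re_ = _fill(tpl, phrase)
                target.add_planted(sentence, rs, re_, domain, phrase, ContextClass.AFFIRMATIVE)
                truth.patient_note_flags[domain].add(patient_ids[i])
                if w_mixed and rng.random() < w_mixed / w_am:
                    self_cls, tpls = (
                        (ContextClass.NEGATED, _NEGATED_TEMPLATES)
                        if rng.random() < 0.5
                        else (ContextClass.OTHER_REFERENT, _OTHER_REFERENT_TEMPLATES)
                    )
                    phrase2 = phrases[int(rng.integers(0, len(phrases)))]
                    s2, rs2, re2 = _fill(tpls[int(rng.integers(0, len(tpls)))], phrase2)
                    target.add_planted(s2, rs2, re2, domain, phrase2, self_cls)
            elif u < p_flag + q:
                w_conf = np.array([w_sn, w_neg, w_or])
                cls_idx = int(rng.choice(3, p=w_conf / w_conf.sum()))
                if cls_idx == 0:
                    sentence, rs, re_, surface = _smartphrase_sentence(lexicon_set, domain)
                    target.add_planted(
                        sentence, rs, re_, domain, surface, ContextClass.SMARTPHRASE_NEGATIVE
                    )
                else:
                    ctx, tpls = (
                        (ContextClass.NEGATED, _NEGATED_TEMPLATES)
                        if cls_idx == 1
                        else (ContextClass.OTHER_REFERENT, _OTHER_REFERENT_TEMPLATES)
                    )
                    phrase = phrases[int(rng.integers(0, len(phrases)))]
                    sentence, rs, re_ = _fill(tpls[int(rng.integers(0, len(tpls)))], phrase)
                    target.add_planted(sentence, rs, re_, domain, phrase, ctx)
        dates = _iso_dates(rng, config.unstructured_window, k)
        role_pick = rng.choice(len(roles), size=k, p=role_p)
        type_pick = rng.choice(len(types), size=k, p=type_p)
        for j, b in enumerate(builders):
            text, mentions = b.render(rng)
            note_id = f"N{nid:08d}"
            nid += 1
            notes.append(
                NoteDocument(
                    note_id=note_id,
                    patient_id=patient_ids[i],
                    encounter_id=f"NE{nid:08d}",
                    note_type=types[type_pick[j]],
                    provider_role=roles[role_pick[j]],
                    date=dates[j],
                    text=text,
                )
            )
            if mentions:
                truth.note_mentions[note_id] = mentions
    return notes, truth


def note_table(notes: Sequence[NoteDocument]) -> pd.DataFrame:
    """Metadata table (no text) for a note collection."""
    return pd.DataFrame(
        [
            {
                "note_id": n.note_id,
                "patient_id": n.patient_id,
                "encounter_id": n.encounter_id,
                "note_type": n.note_type,
                "provider_role": n.provider_role,
                "date": n.date,
            }
            for n in notes
        ],
        columns=["note_id", "patient_id", "encounter_id", "note_type", "provider_role", "date"],
    )


# --------------------------------------------------------------------------
# Questionnaires
# --------------------------------------------------------------------------


def generate_questionnaires(config: SimulationConfig) -> pd.DataFrame:
    """Per-template administered/completed counts, scaled to the population.

    Administered counts scale by n_patients relative to the reference
    denominator; completions are drawn binomially at each template's
    reference completion rate.
    """
    rng = _rng(config, "questionnaires")
    scale = config.n_patients / _REFERENCE_STRUCTURED_DENOMINATOR
    rows = []
    for template, domain, administered_ref, completed_ref in QUESTIONNAIRE_REFERENCE:
        administered = int(round(administered_ref * scale))
        if administered == 0:
            # template too rare to appear at this population size
            continue
        rate = completed_ref / administered_ref
        completed = int(rng.binomial(administered, rate))
        rows.append(
            {
                "template": template,
                "domain": domain,
                "administered": administered,
                "completed": completed,
            }
        )
    return pd.DataFrame(rows, columns=["template", "domain", "administered", "completed"])


# --------------------------------------------------------------------------
# Bundle + I/O
# --------------------------------------------------------------------------


@dataclass
class SyntheticEHR:
    """Everything one simulation run produces."""

    config: SimulationConfig
    patients: pd.DataFrame
    encounters: pd.DataFrame
    social_history: pd.DataFrame
    diagnoses: pd.DataFrame
    questionnaires: pd.DataFrame
    notes: list[NoteDocument]
    ground_truth: GroundTruth


def generate_ehr(config: SimulationConfig, lexicon_set: Optional[LexiconSet] = None) -> SyntheticEHR:
    """Run every generator stage under one config and merge the gold labels."""
    if lexicon_set is None:
        lexicon_set = default_lexicon()
    patients, encounters = generate_population(config)
    social_history = generate_social_history(config, patients)
    diagnoses, structured_positive = generate_diagnoses(config, patients, lexicon_set)
    notes, truth = generate_notes(config, patients, lexicon_set)
    truth.structured_positive = structured_positive
    questionnaires = generate_questionnaires(config)
    return SyntheticEHR(
        config=config,
        patients=patients,
        encounters=encounters,
        social_history=social_history,
        diagnoses=diagnoses,
        questionnaires=questionnaires,
        notes=notes,
        ground_truth=truth,
    )


def write_ehr(ehr: SyntheticEHR, outdir: str | Path) -> None:
    """Write the bundle: CSV tables, notes.jsonl, ground_truth.jsonl, config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ehr.patients.to_csv(outdir / "patients.csv", index=False)
    ehr.encounters.to_csv(outdir / "encounters.csv", index=False)
    ehr.social_history.to_csv(outdir / "social_history.csv", index=False)
    ehr.diagnoses.to_csv(outdir / "diagnoses.csv", index=False)
    ehr.questionnaires.to_csv(outdir / "questionnaires.csv", index=False)
    with open(outdir / "notes.jsonl", "w") as fh:
        for n in ehr.notes:
            fh.write(json.dumps(n.__dict__) + "\n")
    truth = ehr.ground_truth
    with open(outdir / "ground_truth.jsonl", "w") as fh:
        fh.write(
            json.dumps(
                {
                    "record": "structured_positive",
                    "data": {d.value: sorted(s) for d, s in truth.structured_positive.items()},
                }
            )
            + "\n"
        )
        fh.write(
            json.dumps(
                {
                    "record": "patient_note_flags",
                    "data": {d.value: sorted(s) for d, s in truth.patient_note_flags.items()},
                }
            )
            + "\n"
        )
        for note_id, mentions in truth.note_mentions.items():
            fh.write(
                json.dumps(
                    {
                        "record": "note_mentions",
                        "note_id": note_id,
                        "mentions": [
                            {
                                "domain": m.domain.value,
                                "phrase": m.phrase,
                                "start": m.start,
                                "end": m.end,
                                "context_class": m.context_class.value,
                            }
                            for m in mentions
                        ],
                    }
                )
                + "\n"
            )
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(json.loads(ehr.config.model_dump_json()), fh, sort_keys=False)


def read_notes_jsonl(path: str | Path) -> list[NoteDocument]:
    """Load a notes.jsonl file back into note documents."""
    notes = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                notes.append(NoteDocument(**json.loads(line)))
    return notes


# --------------------------------------------------------------------------
# Annotation fixture
# --------------------------------------------------------------------------

_FIXTURE_TOKEN = "homeless"

_FIXTURE_AFFIRMATIVE = [
    "Patient is homeless and currently staying under the overpass.",
    "Patient reports being homeless since last spring.",
    "Patient has been homeless for several months.",
    "Patient is homeless and sleeping in his car.",
    "Currently homeless and seeking housing placement assistance.",
]
_FIXTURE_NEGATED = [
    "Patient denies being homeless at this time.",
    "Patient is not homeless and lives with family.",
    "There is no evidence of the patient being homeless today.",
]
_FIXTURE_OTHER_REFERENT = [
    "Patient reports that a brother is homeless and stays with him intermittently.",
    "Patient is worried about her sister who is homeless.",
    "Patient volunteers at a local program serving homeless residents.",
]
_FIXTURE_SMARTPHRASE = "Is Patient Homeless? No."

_FIXTURE_ROLES = ["physician", "nurse", "social_worker"]
_FIXTURE_TYPES = ["progress_note", "ED_note", "discharge_summary"]


def _fixture_sentence(rng: np.random.Generator, variants: list[str]) -> tuple[str, int, int]:
    s = variants[int(rng.integers(0, len(variants)))]
    pos = s.lower().index(_FIXTURE_TOKEN)
    return s, pos, pos + len(_FIXTURE_TOKEN)


def generate_annotation_fixture(
    seed: int = 0,
) -> tuple[list[NoteDocument], list[GoldMention]]:
    """The deterministic 100-note chart-review fixture.

    Composition is fixed by construction and independent of the seed (the
    seed varies only surface text and note order): 64 notes with only
    true-positive mentions, 14 with only false-positive mentions (7 negated,
    7 other-referent), 20 with only SmartPhrase true negatives
    ("Is Patient Homeless? No"), and 2 conflicting notes carrying both a
    true-positive and a false-positive mention. The target token appears 130
    times in total; the 30 occurrences beyond one-per-note are distributed
    deterministically — 20 second affirmative mentions in the first 20
    true-positive notes, 8 repeated question/answer lines in the first 8
    SmartPhrase notes, and 2 false-positive mentions in the conflicting
    notes.
    """
    rng = np.random.default_rng([seed, 99])
    specs: list[tuple[str, bool]] = (
        [("tp", True)] * 20
        + [("tp", False)] * 44
        + [("fp_neg", False)] * 7
        + [("fp_ref", False)] * 7
        + [("tn", True)] * 8
        + [("tn", False)] * 12
        + [("mixed_neg", False), ("mixed_ref", False)]
    )
    order = rng.permutation(len(specs))
    notes: list[NoteDocument] = []
    gold: list[GoldMention] = []
    token_count = 0
    for idx, spec_idx in enumerate(order):
        kind, extra = specs[int(spec_idx)]
        note_id = f"ANN{idx:03d}"
        builder: list[tuple[str, list[tuple[int, int, GoldClass]]]] = []

        def planted(sentence: str, rs: int, re_: int, cls: GoldClass) -> None:
            builder.append((sentence, [(rs, re_, cls)]))

        def filler() -> None:
            builder.append(
                (_FILLER_SENTENCES[int(rng.integers(0, len(_FILLER_SENTENCES)))], [])
            )

        filler()
        if kind == "tp":
            s, rs, re_ = _fixture_sentence(rng, _FIXTURE_AFFIRMATIVE)
            planted(s, rs, re_, GoldClass.TRUE_POSITIVE)
            if extra:
                filler()
                s, rs, re_ = _fixture_sentence(rng, _FIXTURE_AFFIRMATIVE)
                planted(s, rs, re_, GoldClass.TRUE_POSITIVE)
        elif kind == "fp_neg":
            s, rs, re_ = _fixture_sentence(rng, _FIXTURE_NEGATED)
            planted(s, rs, re_, GoldClass.FALSE_POSITIVE)
        elif kind == "fp_ref":
            s, rs, re_ = _fixture_sentence(rng, _FIXTURE_OTHER_REFERENT)
            planted(s, rs, re_, GoldClass.FALSE_POSITIVE)
        elif kind == "tn":
            s = _FIXTURE_SMARTPHRASE
            pos = s.lower().index(_FIXTURE_TOKEN)
            planted(s, pos, pos + len(_FIXTURE_TOKEN), GoldClass.TRUE_NEGATIVE)
            if extra:
                filler()
                planted(s, pos, pos + len(_FIXTURE_TOKEN), GoldClass.TRUE_NEGATIVE)
        else:  # mixed: one affirmative + one false-positive mention
            s, rs, re_ = _fixture_sentence(rng, _FIXTURE_AFFIRMATIVE)
            planted(s, rs, re_, GoldClass.TRUE_POSITIVE)
            filler()
            variants = _FIXTURE_NEGATED if kind == "mixed_neg" else _FIXTURE_OTHER_REFERENT
            s, rs, re_ = _fixture_sentence(rng, variants)
            planted(s, rs, re_, GoldClass.FALSE_POSITIVE)
        filler()

        pos = 0
        parts: list[str] = []
        for si, (sentence, spans) in enumerate(builder):
            for rs, re_, cls in spans:
                gold.append(GoldMention(note_id, pos + rs, pos + re_, cls))
                token_count += 1
            parts.append(sentence)
            pos += len(sentence)
            if si < len(builder) - 1:
                parts.append(" ")
                pos += 1
        text = "".join(parts)
        notes.append(
            NoteDocument(
                note_id=note_id,
                patient_id=f"AP{idx:03d}",
                encounter_id=f"AE{idx:03d}",
                note_type=_FIXTURE_TYPES[int(rng.integers(0, len(_FIXTURE_TYPES)))],
                provider_role=_FIXTURE_ROLES[int(rng.integers(0, len(_FIXTURE_ROLES)))],
                date="2017-06-15",
                text=text,
            )
        )
    assert len(notes) == 100
    assert token_count == 130
    for g in gold:
        note = next(n for n in notes if n.note_id == g.note_id)
        assert note.text[g.start : g.end].lower() == _FIXTURE_TOKEN
    return notes, gold
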