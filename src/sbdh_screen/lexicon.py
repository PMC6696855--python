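"""Domain lexicons for social and behavioral determinants of health (SBDH).

A :class:`DomainLexicon` bundles everything needed to screen one SBDH domain
in an EHR: the ICD diagnosis code set used for structured cohort queries, the
literal phrase patterns used for free-text mining, negation and other-referent
cue vocabularies, and SmartPhrase templates (EHR boilerplate questions such as
``"Is Patient Homeless?"`` with a Yes/No answer).

Three domains are text-mined — social connection/isolation, housing issues,
and income/financial resource strain — while demographics, language, alcohol
use and smoking status are structured-only fields screened by completeness
alone.

The compiled matcher performs word-boundary, case-insensitive literal phrase
matching: a boundary is any transition between alphanumeric and
non-alphanumeric characters (or text start/end), so ``"homeless"`` never
matches inside ``"homelessness"``. Multi-word phrases are written with single
spaces and matched against whitespace-normalized text.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from enum import Enum
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator


class Domain(str, Enum):
    """SBDH domain identifiers."""

    SOCIAL_CONNECTION = "social_connection"
    HOUSING = "housing"
    FINANCIAL_STRAIN = "financial_strain"
    # structured-only fields
    ADDRESS = "address"
    ETHNICITY = "ethnicity"
    RACE = "race"
    PREFERRED_LANGUAGE = "preferred_language"
    ALCOHOL_USE = "alcohol_use"
    SMOKING_STATUS = "smoking_status"


#: The three domains screened in free text (all others are structured-only).
TEXT_MINED_DOMAINS: tuple[Domain, ...] = (
    Domain.SOCIAL_CONNECTION,
    Domain.HOUSING,
    Domain.FINANCIAL_STRAIN,
)

CODE_SYSTEMS = ("ICD-10-CM", "ICD-9-CM")

_CODE_SYNTAX = {
    "ICD-10-CM": re.compile(r"^[A-TV-Z][0-9][0-9A-Z](\.[0-9A-Z]{1,4})?$"),
    "ICD-9-CM": re.compile(r"^(V[0-9]{2}|E[0-9]{3}|[0-9]{3})(\.[0-9]{1,2})?$"),
}


class CodeEntry(BaseModel):
    """One diagnosis code in a domain's code set.

    ``shared_code`` marks a code that appears in more than one domain's code
    set (ICD-10-CM Z59.8 covers both "other housing problems" and "other
    economic circumstances problems"); cohort queries disambiguate shared
    codes by the recorded diagnosis description (``label``).
    """

    system: str
    code: str
    label: str = ""
    subdomain: str = ""
    shared_code: bool = False

    @model_validator(mode="after")
    def _check_code(self) -> "CodeEntry":
        if self.system not in CODE_SYSTEMS:
            raise ValueError(
                f"unknown code system {self.system!r}; expected one of {CODE_SYSTEMS}"
            )
        if not _CODE_SYNTAX[self.system].match(self.code):
            raise ValueError(f"code {self.code!r} is not valid {self.system} syntax")
        return self


class PatternSpec(BaseModel):
    """A literal phrase pattern matched under word-boundary semantics."""

    pattern_id: str
    phrase: str
    match_mode: str = "word_boundary_literal"
    case_sensitive: bool = False

    @field_validator("phrase")
    @classmethod
    def _phrase_nonempty(cls, v: str) -> str:
        if not v or v != v.strip():
            raise ValueError(f"phrase {v!r} must be non-empty with no leading/trailing whitespace")
        return v

    @field_validator("match_mode")
    @classmethod
    def _mode(cls, v: str) -> str:
        if v != "word_boundary_literal":
            raise ValueError(f"unsupported match_mode {v!r}")
        return v


class SmartPhraseTemplate(BaseModel):
    """An EHR SmartPhrase: a templated question with a Yes/No answer.

    ``max_answer_distance`` is the number of characters after the question in
    which the provider's answer token is searched for; answers immediately
    follow the question in templated text.
    """

    question_text: str
    answer_vocabulary: tuple[str, str] = ("Yes", "No")
    max_answer_distance: int = 15

    @field_validator("question_text")
    @classmethod
    def _question_nonempty(cls, v: str) -> str:
        if not v.strip():
            raise ValueError("question_text must be non-empty")
        return v

    @model_validator(mode="after")
    def _answers_distinct(self) -> "SmartPhraseTemplate":
        yes, no = self.answer_vocabulary
        if yes == no:
            raise ValueError("affirmative and negative answer tokens must be distinct")
        return self


class DomainLexicon(BaseModel):
    """Code set, phrase patterns, and context cues for one SBDH domain."""

    domain: Domain
    codes: list[CodeEntry] = Field(default_factory=list)
    patterns: list[PatternSpec] = Field(default_factory=list)
    negation_cues: list[str] = Field(default_factory=list)
    other_referent_cues: list[str] = Field(default_factory=list)
    smartphrase_templates: list[SmartPhraseTemplate] = Field(default_factory=list)

    @model_validator(mode="after")
    def _unique_codes(self) -> "DomainLexicon":
        seen: set[tuple[str, str]] = set()
        for entry in self.codes:
            key = (entry.system, entry.code)
            if key in seen:
                raise ValueError(f"duplicate code {key} within domain {self.domain.value}")
            seen.add(key)
        return self


class LexiconSet(BaseModel):
    """A collection of domain lexicons, keyed by domain identifier."""

    domains: dict[Domain, DomainLexicon]

    @model_validator(mode="after")
    def _validate(self) -> "LexiconSet":
        seen_ids: set[str] = set()
        for domain, lex in self.domains.items():
            if lex.domain != domain:
                raise ValueError(
                    f"lexicon under key {domain.value!r} declares domain {lex.domain.value!r}"
                )
            for pat in lex.patterns:
                if pat.pattern_id in seen_ids:
                    raise ValueError(f"duplicate pattern_id {pat.pattern_id!r} in lexicon set")
                seen_ids.add(pat.pattern_id)
            if domain in TEXT_MINED_DOMAINS and not lex.patterns:
                raise ValueError(
                    f"text-mined domain {domain.value!r} must declare at least one pattern"
                )
        return self

    def __getitem__(self, domain: Domain) -> DomainLexicon:
        return self.domains[domain]

    def __contains__(self, domain: Domain) -> bool:
        return domain in self.domains

    def __iter__(self) -> Iterator[DomainLexicon]:  # type: ignore[override]
        return iter(self.domains.values())


# --------------------------------------------------------------------------
# Reference ICD-10-CM inventory for the three text-mined domains.
# Subtype patient counts are the published reference tallies used by the
# synthetic generator to apportion subtype codes within a domain; they sum to
# 31,628 / 10,433 / 3,543 patients respectively.
# --------------------------------------------------------------------------

_SOCIAL_CODES = [
    ("Z60.2", "Problems related to living alone", "living_alone", 1222),
    ("Z60.4", "Social exclusion and rejection", "social_exclusion", 223),
    ("Z63.0", "Relationship problems with spouse or partner", "relationship_problems", 852),
    ("Z63.5", "Family disruption by separation and divorce", "family_disruption", 548),
    ("Z63.8", "Other primary support group problems", "support_group_problems", 2230),
    ("Z63.9", "Unspecified primary support group problem", "support_group_problems", 3247),
    ("Z65.9", "Unspecified psychosocial circumstances", "psychosocial_circumstances", 938),
    ("Z73.4", "Inadequate social skills", "social_skills", 81),
    ("Z91.89", "Other specified personal risk factors", "personal_risk_factors", 18947),
    ("R45.8", "Other emotional state symptoms and signs", "emotional_state", 3340),
]

_HOUSING_CODES = [
    ("Z59.0", "Homelessness", "homelessness", 7022),
    ("Z59.1", "Inadequate housing", "inadequate_housing", 120),
    ("Z59.8", "Other housing problems", "housing_characteristics", 3291),
]

_FINANCIAL_CODES = [
    ("Z59.5", "Extreme poverty", "poverty", 68),
    ("Z59.6", "Low income", "low_income", 72),
    ("Z59.7", "Insufficient social insurance and welfare", "insufficient_welfare", 46),
    ("Z59.8", "Other economic circumstances problems", "economic_circumstances", 3357),
]

#: Reference per-subtype unique-patient counts used as apportionment weights
#: when the synthetic generator assigns a subtype code to a domain-positive
#: patient.
REFERENCE_SUBTYPE_COUNTS: dict[Domain, dict[str, int]] = {
    Domain.SOCIAL_CONNECTION: {code: n for code, _, _, n in _SOCIAL_CODES},
    Domain.HOUSING: {code: n for code, _, _, n in _HOUSING_CODES},
    Domain.FINANCIAL_STRAIN: {code: n for code, _, _, n in _FINANCIAL_CODES},
}

_SEED_PHRASES: dict[Domain, list[str]] = {
    Domain.HOUSING: [
        "homeless",
        "homelessness",
        "housing instability",
        "housing insecurity",
        "eviction",
        "shelter",
        "inadequate housing",
    ],
    Domain.SOCIAL_CONNECTION: [
        "social isolation",
        "socially isolated",
        "lives alone",
        "no social support",
        "lack of social support",
        "estranged",
        "no family support",
    ],
    Domain.FINANCIAL_STRAIN: [
        "financial strain",
        "financial hardship",
        "cannot afford",
        "unable to afford",
        "poverty",
        "low income",
        "food stamps",
    ],
}

#: Pre-span cues that negate a phrase occurrence (NegEx-style window).
DEFAULT_NEGATION_CUES = [
    "denies",
    "denied",
    "no evidence of",
    "no history of",
    "not",
    "never",
    "without",
    "no longer",
    "ruled out",
]

#: Same-sentence cues indicating the phrase describes someone other than the
#: patient (a relative, an employer, a population).
DEFAULT_OTHER_REFERENT_CUES = [
    "mother",
    "father",
    "brother",
    "sister",
    "son",
    "daughter",
    "cousin",
    "neighbor",
    "friend",
    "works at",
    "works with",
    "volunteers at",
    "population",
]

_SMARTPHRASES: dict[Domain, list[SmartPhraseTemplate]] = {
    Domain.HOUSING: [SmartPhraseTemplate(question_text="Is Patient Homeless?")],
    Domain.SOCIAL_CONNECTION: [
        SmartPhraseTemplate(question_text="Is Patient Socially Isolated?")
    ],
    Domain.FINANCIAL_STRAIN: [
        SmartPhraseTemplate(question_text="Does Patient Report Financial Hardship?")
    ],
}


def _slug(phrase: str) -> str:
    return re.sub(r"[^a-z0-9]+", "_", phrase.lower()).strip("_")


def default_lexicon() -> LexiconSet:
    """Build the bundled seed lexicon for the three text-mined domains.

    The ICD-10-CM code lists are the published reference inventories; the
    phrase lists are a documented seed vocabulary drawn from the domain
    definitions and ICD label text (the lexicon is a data file precisely so
    that sites can replace it with their own curated inventories).
    """
    domains: dict[Domain, DomainLexicon] = {}
    code_rows = {
        Domain.SOCIAL_CONNECTION: _SOCIAL_CODES,
        Domain.HOUSING: _HOUSING_CODES,
        Domain.FINANCIAL_STRAIN: _FINANCIAL_CODES,
    }
    for domain, rows in code_rows.items():
        codes = [
            CodeEntry(
                system="ICD-10-CM",
                code=code,
                label=label,
                subdomain=subdomain,
                shared_code=(code == "Z59.8"),
            )
            for code, label, subdomain, _ in rows
        ]
        patterns = [
            PatternSpec(pattern_id=f"{domain.value}:{_slug(p)}", phrase=p)
            for p in _SEED_PHRASES[domain]
        ]
        domains[domain] = DomainLexicon(
            domain=domain,
            codes=codes,
            patterns=patterns,
            negation_cues=list(DEFAULT_NEGATION_CUES),
            other_referent_cues=list(DEFAULT_OTHER_REFERENT_CUES),
            smartphrase_templates=list(_SMARTPHRASES[domain]),
        )
    return LexiconSet(domains=domains)


# --------------------------------------------------------------------------
# Serialization
# --------------------------------------------------------------------------


def save_lexicon(lexicon_set: LexiconSet, path: str | Path) -> None:
    """Write a lexicon set to YAML (or JSON if the suffix is ``.json``).

    The file has one top-level key per domain; fields mirror
    :class:`DomainLexicon`, with ICD codes stored under explicit system tags.
    """
    path = Path(path)
    payload = {
        domain.value: lex.model_dump(mode="json", exclude={"domain"})
        for domain, lex in lexicon_set.domains.items()
    }
    if path.suffix == ".json":
        path.write_text(json.dumps(payload, indent=2))
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))


def load_lexicon(path: str | Path) -> LexiconSet:
    """Load and validate a lexicon set written by :func:`save_lexicon`.

    Raises a validation error for duplicate pattern ids, unknown code
    systems, empty phrases, or any other type-invariant violation.
    """
    path = Path(path)
    text = path.read_text()
    payload = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(payload, dict):
        raise ValueError(f"lexicon file {path} must contain a mapping of domains")
    domains = {
        Domain(name): DomainLexicon(domain=Domain(name), **(body or {}))
        for name, body in payload.items()
    }
    return LexiconSet(domains=domains)


# --------------------------------------------------------------------------
# Compiled matcher
# --------------------------------------------------------------------------

_ALNUM = r"0-9A-Za-z"


@lru_cache(maxsize=4096)
def _boundary_regex(phrase: str, case_sensitive: bool) -> re.Pattern[str]:
    # A word boundary is any transition between alphanumeric and
    # non-alphanumeric (or text start/end); unlike \b this treats "_" as a
    # boundary character.
    pattern = rf"(?<![{_ALNUM}]){re.escape(phrase)}(?![{_ALNUM}])"
    flags = 0 if case_sensitive else re.IGNORECASE
    return re.compile(pattern, flags)


@dataclass(frozen=True)
class RawMatch:
    """A phrase occurrence located by the compiled matcher.

    Offsets are 0-based, half-open character positions into the scanned text.
    """

    domain: Domain
    pattern_id: str
    start: int
    end: int


class CompiledMatcher:
    """Word-boundary literal matcher over every pattern in a lexicon set.

    Scans report every occurrence of every phrase, including overlapping
    occurrences from different patterns. The matcher operates on the text it
    is given; callers that need whitespace-robust matching normalize first
    (see :func:`sbdh_screen.notes.normalize_text`).
    """

    def __init__(self, lexicon_set: LexiconSet) -> None:
        self._compiled: list[tuple[Domain, str, re.Pattern[str]]] = []
        for lex in lexicon_set:
            for pat in lex.patterns:
                self._compiled.append(
                    (lex.domain, pat.pattern_id, _boundary_regex(pat.phrase, pat.case_sensitive))
                )

    def scan(self, text: str) -> list[RawMatch]:
        """Return every phrase occurrence in ``text``, sorted by position."""
        out: list[RawMatch] = []
        for domain, pattern_id, rx in self._compiled:
            for m in rx.finditer(text):
                out.append(RawMatch(domain, pattern_id, m.start(), m.end()))
        out.sort(key=lambda s: (s.start, s.end, s.pattern_id))
        return out


def compile_matcher(lexicon_set: LexiconSet) -> CompiledMatcher:
    """Compile a lexicon set into a reusable phrase matcher."""
    return CompiledMatcher(lexicon_set)
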