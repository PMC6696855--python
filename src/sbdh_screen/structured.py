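"""Structured-EHR screening metrics.

Three families of metrics over discrete EHR fields:

* **Field completeness** — the fraction of unique patients with at least one
  non-missing value for a field (demographics, preferred language, alcohol
  use, smoking status). Missing means empty, whitespace-only, or absent; the
  literal category ``"Unknown"`` is a valid EHR value and counts as present.
* **Diagnosis cohorts** — unique patients carrying at least one ICD-10-CM
  (optionally ICD-9-CM equivalent) code from a domain's code set within a
  date window, from any source (problem list, billing, or encounter), each
  patient counted once.
* **Questionnaire completion** — completed / administered per questionnaire
  template.

All "n (%)" arithmetic goes through :func:`percent` (half-up, two decimals).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .lexicon import CodeEntry, Domain


class UndefinedRateError(ValueError):
    """Raised when a rate is requested over an empty denominator."""


def percent(numerator: int | float, denominator: int | float, decimals: int = 2) -> float:
    """Percentage ``100 * numerator / denominator``, rounded half-up.

    Half-up rounding at two decimals is the package-wide convention for every
    "n (%)" figure.
    """
    if denominator <= 0:
        raise ValueError(f"denominator must be positive, got {denominator}")
    if numerator < 0:
        raise ValueError(f"numerator must be non-negative, got {numerator}")
    quantum = Decimal(1).scaleb(-decimals)
    value = Decimal(numerator) * 100 / Decimal(denominator)
    return float(value.quantize(quantum, rounding=ROUND_HALF_UP))


# --------------------------------------------------------------------------
# Completeness
# --------------------------------------------------------------------------


@dataclass
class CompletenessEntry:
    """One field's completeness line: numerator, denominator, and rate (%)."""

    field: str
    numerator: int
    denominator: int
    rate: float
    date_range: str = ""
    collection_methods: list[str] = field(default_factory=list)


def _present(series: pd.Series) -> pd.Series:
    """Boolean mask of non-missing, non-empty values.

    The explicit category ``"Unknown"`` is a real EHR value, distinct from an
    empty record, and therefore present.
    """
    notna = series.notna()
    stripped = series.astype("string").str.strip()
    return notna & (stripped != "")


def completeness_rate(
    table: pd.DataFrame,
    field_spec: str,
    denominator: int,
    *,
    id_column: str = "patient_id",
) -> CompletenessEntry:
    """Completeness of one field (or the ``address_or_zip`` composite).

    The numerator counts unique patients with at least one non-missing value
    in any of their rows, so the rate is invariant to duplicated encounters.
    """
    if denominator == 0:
        raise UndefinedRateError(f"completeness of {field_spec!r} undefined over 0 patients")
    if denominator < 0:
        raise ValueError("denominator must be non-negative")
    if field_spec == "address_or_zip":
        for col in ("address", "zip"):
            if col not in table.columns:
                raise KeyError(f"composite field address_or_zip requires column {col!r}")
        mask = _present(table["address"]) | _present(table["zip"])
    else:
        if field_spec not in table.columns:
            raise KeyError(f"unknown field {field_spec!r}")
        mask = _present(table[field_spec])
    numerator = int(table.loc[mask, id_column].nunique())
    return CompletenessEntry(
        field=field_spec,
        numerator=numerator,
        denominator=denominator,
        rate=percent(numerator, denominator),
    )


def completeness_report(
    patients: pd.DataFrame,
    social_history: pd.DataFrame,
    denominator: Optional[int] = None,
) -> pd.DataFrame:
    """Completeness of the standard screened fields, one row per field."""
    if denominator is None:
        denominator = int(patients["patient_id"].nunique())
    entries = [
        completeness_rate(patients, "address_or_zip", denominator),
        completeness_rate(patients, "ethnicity", denominator),
        completeness_rate(patients, "race", denominator),
        completeness_rate(patients, "preferred_language", denominator),
        completeness_rate(social_history, "alcohol_drinks_per_week", denominator),
        completeness_rate(social_history, "smoking_status", denominator),
    ]
    return pd.DataFrame(
        [
            {
                "field": e.field,
                "numerator": e.numerator,
                "denominator": e.denominator,
                "rate_pct": e.rate,
            }
            for e in entries
        ]
    )


# --------------------------------------------------------------------------
# Diagnosis cohorts
# --------------------------------------------------------------------------

#: Approximate ICD-9-CM equivalents for the ICD-10-CM SBDH codes. The source
#: inventories print only ICD-10 codes; this minimal map is deliberately
#: explicit data rather than a terminology-server lookup.
ICD9_EQUIVALENTS: dict[str, list[str]] = {
    "Z59.0": ["V60.0"],
    "Z59.1": ["V60.1"],
    "Z59.6": ["V60.2"],
    "Z59.8": ["V60.8", "V60.9"],
    "Z60.4": ["V62.4"],
    "Z63.0": ["V61.0"],
    "Z63.5": ["V61.0"],
}


def diagnosis_cohort(
    diagnoses: pd.DataFrame,
    code_entries: Sequence[CodeEntry],
    window: tuple[str, str] | None = None,
    include_icd9: bool = True,
) -> set[str]:
    """Unique patients with at least one matching diagnosis code.

    A patient qualifies with one matching record from any source (problem
    list, billing, or encounter) dated inside the closed ``window``; encounter
    multiplicity does not matter. For entries flagged ``shared_code`` the
    recorded diagnosis description must also match the entry label, which is
    how a single ICD code shared between two domains is kept per-domain.
    """
    if len(code_entries) == 0:
        raise ValueError("empty code list")
    df = diagnoses
    if window is not None:
        dates = pd.to_datetime(df["date"])
        start, end = pd.to_datetime(window[0]), pd.to_datetime(window[1])
        df = df[(dates >= start) & (dates <= end)]
    patients: set[str] = set()
    has_label = "label" in df.columns
    for entry in code_entries:
        targets = [(entry.system, entry.code)]
        if include_icd9 and entry.system == "ICD-10-CM":
            for icd9 in ICD9_EQUIVALENTS.get(entry.code, []):
                targets.append(("ICD-9-CM", icd9))
        mask = pd.Series(False, index=df.index)
        for system, code in targets:
            mask |= (df["system"] == system) & (df["code"] == code)
        if entry.shared_code and has_label and entry.label:
            mask &= df["label"] == entry.label
        patients.update(df.loc[mask, "patient_id"].astype(str))
    return patients


@dataclass
class CohortResult:
    """Per-subtype unique-patient counts and their union for one domain."""

    domain: Domain
    subtype_counts: dict[str, int]
    domain_total: int
    pct: float


def domain_summary(
    subtype_cohorts: Mapping[str, set[str]],
    domain: Domain,
    denominator: int,
) -> CohortResult:
    """Aggregate per-subtype cohorts into a domain total (set union)."""
    if not subtype_cohorts:
        raise ValueError(f"no subtype cohorts supplied for domain {domain.value}")
    union: set[str] = set()
    counts: dict[str, int] = {}
    for code, cohort in subtype_cohorts.items():
        counts[code] = len(cohort)
        union |= set(cohort)
    return CohortResult(
        domain=domain,
        subtype_counts=counts,
        domain_total=len(union),
        pct=percent(len(union), denominator),
    )


def cohort_report(
    diagnoses: pd.DataFrame,
    lexicon_set,
    denominator: int,
    window: tuple[str, str] | None = None,
    include_icd9: bool = True,
) -> pd.DataFrame:
    """Diagnosis-based cohort table: one domain row plus one row per subtype."""
    from .lexicon import TEXT_MINED_DOMAINS

    rows: list[dict] = []
    for domain in TEXT_MINED_DOMAINS:
        if domain not in lexicon_set:
            continue
        lex = lexicon_set[domain]
        if not lex.codes:
            raise ValueError(f"lexicon for {domain.value} has no diagnosis codes")
        subtype_cohorts = {
            entry.code: diagnosis_cohort(diagnoses, [entry], window, include_icd9)
            for entry in lex.codes
        }
        summary = domain_summary(subtype_cohorts, domain, denominator)
        rows.append(
            {
                "domain": domain.value,
                "code": "",
                "n_patients": summary.domain_total,
                "pct": summary.pct,
            }
        )
        for entry in lex.codes:
            rows.append(
                {
                    "domain": domain.value,
                    "code": entry.code,
                    "n_patients": summary.subtype_counts[entry.code],
                    "pct": None,
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Questionnaires
# --------------------------------------------------------------------------


def questionnaire_completion(records: pd.DataFrame) -> pd.DataFrame:
    """Per-template completion rate: percent(completed, administered).

    ``records`` carries one row per questionnaire template with ``template``,
    ``administered`` and ``completed`` columns.
    """
    out_rows = []
    for row in records.itertuples(index=False):
        administered = int(row.administered)
        completed = int(row.completed)
        if administered == 0:
            raise UndefinedRateError(
                f"template {row.template!r}: completion rate undefined, 0 administered"
            )
        if completed > administered:
            raise ValueError(
                f"template {row.template!r}: completed ({completed}) exceeds "
                f"administered ({administered})"
            )
        out_rows.append(
            {
                "template": row.template,
                "administered": administered,
                "completed": completed,
                "rate_pct": percent(completed, administered),
            }
        )
    return pd.DataFrame(out_rows)
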