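"""Rule-based mining of SBDH mentions in free-text clinical notes.

The pipeline is deliberately deterministic and model-free:

1. whitespace-normalize the note text (keeping an offset map back to the raw
   text),
2. locate every lexicon phrase occurrence with the compiled word-boundary
   matcher,
3. classify each occurrence's context — SmartPhrase question/answer handling
   first, then a NegEx-style pre-span negation window, then same-sentence
   other-referent cues, defaulting to affirmative,
4. aggregate to note-level flags ("at least one affirmative mention") and
   patient-level prevalence ("at least one flagged note"), and
5. stratify flagged notes by provider role or note type.

SmartPhrases are EHR boilerplate questions (e.g. ``"Is Patient Homeless?"``)
followed by a provider-chosen Yes/No answer; a phrase occurrence inside the
question with the answer "No" is documented absence, not evidence.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .lexicon import (
    CompiledMatcher,
    Domain,
    DomainLexicon,
    LexiconSet,
    SmartPhraseTemplate,
    _boundary_regex,
)
from .structured import UndefinedRateError, percent

#: Characters before a span within which a negation cue negates it.
NEGATION_WINDOW = 40


class ContextClass(str, Enum):
    AFFIRMATIVE = "affirmative"
    SMARTPHRASE_NEGATIVE = "smartphrase_negative"
    SMARTPHRASE_AFFIRMATIVE = "smartphrase_affirmative"
    NEGATED = "negated"
    OTHER_REFERENT = "other_referent"


#: Context classes that constitute positive evidence for a domain.
AFFIRMATIVE_CLASSES = frozenset(
    {ContextClass.AFFIRMATIVE, ContextClass.SMARTPHRASE_AFFIRMATIVE}
)


@dataclass(frozen=True)
class NoteDocument:
    """A free-text clinical note with provenance metadata."""

    note_id: str
    patient_id: str
    encounter_id: str
    note_type: str
    provider_role: str
    date: str
    text: str


@dataclass(frozen=True)
class MentionSpan:
    """A located phrase occurrence; offsets are 0-based half-open into the
    raw note text, so ``matched_text == text[start:end]`` always holds."""

    note_id: str
    domain: Domain
    pattern_id: str
    start: int
    end: int
    matched_text: str
    context_class: Optional[ContextClass] = None


@dataclass(frozen=True)
class SmartPhraseHit:
    """A detected SmartPhrase question and its (possibly absent) answer."""

    question_start: int
    question_end: int
    answer: Optional[str]
    answer_start: Optional[int]
    answer_end: Optional[int]
    max_answer_distance: int


# --------------------------------------------------------------------------
# Normalization
# --------------------------------------------------------------------------


def normalize_text(text: str) -> tuple[str, list[int]]:
    """Collapse whitespace runs to single spaces; return the offset map.

    ``offset_map[i]`` is the raw-text index of normalized character ``i`` (a
    collapsed space maps to the first whitespace character of its run), which
    makes normalized spans invertible back to raw spans. Leading and trailing
    whitespace is dropped. Lowercasing is handled inside matching, not here.
    """
    norm, offset_map, _ = _normalize(text)
    return norm, offset_map


def _normalize(text: str) -> tuple[str, list[int], set[int]]:
    """As :func:`normalize_text`, also reporting which collapsed-space
    positions came from runs containing a newline (sentence boundaries)."""
    chars: list[str] = []
    offset_map: list[int] = []
    newline_spaces: set[int] = set()
    pending_ws: Optional[int] = None  # raw index of first ws char in run
    pending_nl = False
    for i, ch in enumerate(text):
        if ch.isspace():
            if pending_ws is None:
                pending_ws = i
            if ch == "\n":
                pending_nl = True
        else:
            if pending_ws is not None and chars:
                if pending_nl:
                    newline_spaces.add(len(chars))
                chars.append(" ")
                offset_map.append(pending_ws)
            pending_ws = None
            pending_nl = False
            chars.append(ch)
            offset_map.append(i)
    return "".join(chars), offset_map, newline_spaces


def _sentence_bounds(norm: str, newline_spaces: set[int]) -> list[tuple[int, int]]:
    """Sentence spans over normalized text.

    A boundary is a collapsed space that followed a raw newline, or any space
    preceded by sentence-final punctuation (. ? !).
    """
    cuts = [
        i
        for i in range(len(norm))
        if norm[i] == " " and (i in newline_spaces or (i > 0 and norm[i - 1] in ".?!"))
    ]
    bounds = []
    start = 0
    for cut in cuts:
        if cut > start:
            bounds.append((start, cut))
        start = cut + 1
    if len(norm) > start:
        bounds.append((start, len(norm)))
    return bounds


def _raw_span(offset_map: Sequence[int], start: int, end: int) -> tuple[int, int]:
    return offset_map[start], offset_map[end - 1] + 1


def _norm_offset(offset_map: Sequence[int], raw: int) -> int:
    idx = bisect_left(offset_map, raw)
    if idx == len(offset_map) or offset_map[idx] != raw:
        raise ValueError(f"raw offset {raw} has no normalized counterpart")
    return idx


# --------------------------------------------------------------------------
# Matching
# --------------------------------------------------------------------------


def match_mentions(note: NoteDocument, matcher: CompiledMatcher) -> list[MentionSpan]:
    """Every lexicon phrase occurrence in the note, context unclassified.

    The note is whitespace-normalized before scanning and spans are mapped
    back to raw-text offsets; overlapping occurrences from different patterns
    are all reported, each exactly once.
    """
    norm, offset_map = normalize_text(note.text)
    spans: list[MentionSpan] = []
    for m in matcher.scan(norm):
        rs, re_ = _raw_span(offset_map, m.start, m.end)
        spans.append(
            MentionSpan(
                note_id=note.note_id,
                domain=m.domain,
                pattern_id=m.pattern_id,
                start=rs,
                end=re_,
                matched_text=note.text[rs:re_],
            )
        )
    return spans


# --------------------------------------------------------------------------
# SmartPhrase detection
# --------------------------------------------------------------------------


def _detect_smartphrase_norm(
    norm: str, templates: Sequence[SmartPhraseTemplate]
) -> list[SmartPhraseHit]:
    hits: list[SmartPhraseHit] = []
    for tpl in templates:
        q_norm, _ = normalize_text(tpl.question_text)
        q_rx = _boundary_regex(q_norm, case_sensitive=False)
        answer_rx = {tok: _boundary_regex(tok, case_sensitive=False) for tok in tpl.answer_vocabulary}
        for qm in q_rx.finditer(norm):
            window = norm[qm.end() : qm.end() + tpl.max_answer_distance]
            best: Optional[tuple[int, int, str]] = None
            for token, rx in answer_rx.items():
                am = rx.search(window)
                if am and (best is None or am.start() < best[0]):
                    best = (am.start(), am.end(), token)
            if best is None:
                hits.append(
                    SmartPhraseHit(qm.start(), qm.end(), None, None, None, tpl.max_answer_distance)
                )
            else:
                off = qm.end()
                hits.append(
                    SmartPhraseHit(
                        qm.start(),
                        qm.end(),
                        best[2],
                        off + best[0],
                        off + best[1],
                        tpl.max_answer_distance,
                    )
                )
    hits.sort(key=lambda h: h.question_start)
    return hits


def detect_smartphrase(
    note: NoteDocument, templates: Sequence[SmartPhraseTemplate]
) -> list[SmartPhraseHit]:
    """Find SmartPhrase questions and their nearest trailing Yes/No answer.

    The answer is the earliest answer-vocabulary token starting within
    ``max_answer_distance`` characters after the question; if none is found
    the answer is reported absent. Offsets are raw-text offsets.
    """
    if not templates:
        raise ValueError("templates must be non-empty")
    norm, offset_map, _ = _normalize(note.text)
    out = []
    for h in _detect_smartphrase_norm(norm, templates):
        qs, qe = _raw_span(offset_map, h.question_start, h.question_end)
        if h.answer_start is not None:
            as_, ae = _raw_span(offset_map, h.answer_start, h.answer_end)
        else:
            as_ = ae = None
        out.append(SmartPhraseHit(qs, qe, h.answer, as_, ae, h.max_answer_distance))
    return out


# --------------------------------------------------------------------------
# Context classification
# --------------------------------------------------------------------------


def _classify_norm(
    start: int,
    end: int,
    norm: str,
    sentences: list[tuple[int, int]],
    lexicon: DomainLexicon,
    sp_hits: Sequence[SmartPhraseHit],
) -> ContextClass:
    # 1. SmartPhrase question/answer window has top precedence.
    for hit in sp_hits:
        window_end = hit.answer_end if hit.answer_end is not None else hit.question_end + hit.max_answer_distance
        if start >= hit.question_start and end <= max(hit.question_end, window_end):
            if hit.answer is None:
                return ContextClass.SMARTPHRASE_NEGATIVE
            yes, _no = ("Yes", "No")
            if hit.answer.lower() == "yes":
                return ContextClass.SMARTPHRASE_AFFIRMATIVE
            return ContextClass.SMARTPHRASE_NEGATIVE
    sentence = next(((ss, se) for ss, se in sentences if ss <= start < se), (0, len(norm)))
    ss, se = sentence
    # 2. Negation cue ending within the window immediately before the span.
    for cue in lexicon.negation_cues:
        rx = _boundary_regex(cue, case_sensitive=False)
        for m in rx.finditer(norm, ss, se):
            if m.end() <= start and m.end() >= start - NEGATION_WINDOW:
                return ContextClass.NEGATED
    # 3. Other-referent cue anywhere in the same sentence.
    for cue in lexicon.other_referent_cues:
        rx = _boundary_regex(cue, case_sensitive=False)
        m = rx.search(norm, ss, se)
        if m and not (m.start() >= start and m.end() <= end):
            return ContextClass.OTHER_REFERENT
    return ContextClass.AFFIRMATIVE


def classify_context(
    span: MentionSpan,
    note: NoteDocument,
    lexicon: DomainLexicon,
    smartphrase_hits: Optional[Sequence[SmartPhraseHit]] = None,
) -> ContextClass:
    """Classify one located mention's context.

    Precedence: SmartPhrase question/answer window (negative if answered
    "No" or unanswered, affirmative if "Yes"); then a negation cue ending in
    the 40 characters before the span within the same sentence; then an
    other-referent cue in the same sentence; otherwise affirmative.
    ``smartphrase_hits`` carry raw-text offsets, as returned by
    :func:`detect_smartphrase`; if omitted they are detected here.
    """
    if span.start < 0 or span.end > len(note.text) or span.start >= span.end:
        raise ValueError(f"span [{span.start},{span.end}) outside note bounds")
    norm, offset_map, newline_spaces = _normalize(note.text)
    sentences = _sentence_bounds(norm, newline_spaces)
    if smartphrase_hits is None:
        if lexicon.smartphrase_templates:
            sp_hits = _detect_smartphrase_norm(norm, lexicon.smartphrase_templates)
        else:
            sp_hits = []
    else:
        sp_hits = [
            SmartPhraseHit(
                _norm_offset(offset_map, h.question_start),
                _norm_offset(offset_map, h.question_end - 1) + 1,
                h.answer,
                None if h.answer_start is None else _norm_offset(offset_map, h.answer_start),
                None if h.answer_end is None else _norm_offset(offset_map, h.answer_end - 1) + 1,
                h.max_answer_distance,
            )
            for h in smartphrase_hits
        ]
    ns = _norm_offset(offset_map, span.start)
    ne = _norm_offset(offset_map, span.end - 1) + 1
    return _classify_norm(ns, ne, norm, sentences, lexicon, sp_hits)


def mine_note(note: NoteDocument, matcher: CompiledMatcher, lexicon_set: LexiconSet) -> list[MentionSpan]:
    """Match and classify every mention in one note (single normalization)."""
    norm, offset_map, newline_spaces = _normalize(note.text)
    raw_matches = matcher.scan(norm)
    if not raw_matches:
        return []
    sentences = _sentence_bounds(norm, newline_spaces)
    sp_by_domain: dict[Domain, list[SmartPhraseHit]] = {}
    spans: list[MentionSpan] = []
    for m in raw_matches:
        lex = lexicon_set[m.domain]
        if m.domain not in sp_by_domain:
            sp_by_domain[m.domain] = (
                _detect_smartphrase_norm(norm, lex.smartphrase_templates)
                if lex.smartphrase_templates
                else []
            )
        ctx = _classify_norm(m.start, m.end, norm, sentences, lex, sp_by_domain[m.domain])
        rs, re_ = _raw_span(offset_map, m.start, m.end)
        spans.append(
            MentionSpan(
                note_id=note.note_id,
                domain=m.domain,
                pattern_id=m.pattern_id,
                start=rs,
                end=re_,
                matched_text=note.text[rs:re_],
                context_class=ctx,
            )
        )
    return spans


# --------------------------------------------------------------------------
# Aggregation
# --------------------------------------------------------------------------


def note_flag(spans_for_note: Iterable[MentionSpan], mode: str = "filtered") -> dict[Domain, bool]:
    """Per-domain note flags from classified spans.

    In ``filtered`` mode a domain flags true iff the note has at least one
    affirmative-context mention (mixed notes therefore flag true); notes
    with only SmartPhrase-negative, negated, or other-referent mentions do
    not. ``raw`` mode flags on any occurrence regardless of context.
    """
    if mode not in ("filtered", "raw"):
        raise ValueError(f"mode must be 'filtered' or 'raw', got {mode!r}")
    flags: dict[Domain, bool] = {}
    for span in spans_for_note:
        positive = mode == "raw" or span.context_class in AFFIRMATIVE_CLASSES
        flags[span.domain] = flags.get(span.domain, False) or positive
    return flags


def mine_notes(
    notes: Iterable[NoteDocument],
    lexicon_set: LexiconSet,
    mode: str = "filtered",
) -> tuple[list[MentionSpan], dict[str, dict[Domain, bool]]]:
    """Mine a note stream; returns all classified spans and per-note flags."""
    matcher = CompiledMatcher(lexicon_set)
    all_spans: list[MentionSpan] = []
    flags: dict[str, dict[Domain, bool]] = {}
    for note in notes:
        spans = mine_note(note, matcher, lexicon_set)
        if spans:
            all_spans.extend(spans)
            flags[note.note_id] = note_flag(spans, mode=mode)
    return all_spans, flags


@dataclass
class PrevalenceReport:
    """Patient-level prevalence per text-mined domain."""

    rows: pd.DataFrame  # columns: domain, patients_flagged, denominator, pct


def patient_prevalence(
    note_flags: Mapping[str, Mapping[Domain, bool]],
    note_table: pd.DataFrame,
    domains: Optional[Sequence[Domain]] = None,
) -> PrevalenceReport:
    """Unique patients with ≥1 flagged note, over all patients with notes.

    The denominator is every unique patient in the note table (whether or
    not any of their notes matched anything); "at least one" semantics make
    the counts idempotent under duplicate flagged notes.
    """
    if len(note_table) == 0:
        raise UndefinedRateError("prevalence undefined over an empty note table")
    if domains is None:
        from .lexicon import TEXT_MINED_DOMAINS

        domains = TEXT_MINED_DOMAINS
    denominator = int(note_table["patient_id"].nunique())
    patient_of = dict(zip(note_table["note_id"], note_table["patient_id"]))
    flagged: dict[Domain, set[str]] = {d: set() for d in domains}
    for note_id, per_domain in note_flags.items():
        for domain, flag in per_domain.items():
            if flag and domain in flagged:
                flagged[domain].add(patient_of[note_id])
    rows = pd.DataFrame(
        [
            {
                "domain": d.value,
                "patients_flagged": len(flagged[d]),
                "denominator": denominator,
                "pct": percent(len(flagged[d]), denominator),
            }
            for d in domains
        ]
    )
    return PrevalenceReport(rows=rows)


def stratify(
    note_flags: Mapping[str, Mapping[Domain, bool]],
    note_table: pd.DataFrame,
    by: str,
) -> pd.DataFrame:
    """Counts of flagged notes per stratum per domain.

    ``by`` is ``provider_role`` or ``note_type``; notes with missing
    metadata fall in an ``"unknown"`` stratum. Strata counts sum to the
    total flagged-note count for each domain.
    """
    if by not in ("provider_role", "note_type"):
        raise ValueError(f"stratify by must be 'provider_role' or 'note_type', got {by!r}")
    meta = note_table.set_index("note_id")[by]
    counts: dict[tuple[str, str], int] = {}
    for note_id, per_domain in note_flags.items():
        stratum = meta.get(note_id)
        if stratum is None or (isinstance(stratum, float) and pd.isna(stratum)) or str(stratum).strip() == "":
            stratum = "unknown"
        for domain, flag in per_domain.items():
            if flag:
                key = (domain.value, str(stratum))
                counts[key] = counts.get(key, 0) + 1
    rows = [
        {"domain": d, "stratum": s, "n_notes": n}
        for (d, s), n in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["domain", "stratum", "n_notes"])
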