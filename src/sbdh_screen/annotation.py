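"""Manual-annotation style validation of the note miner.

The validation scheme follows chart-review practice for rule-based clinical
NLP: every phrase occurrence in an annotated note carries a gold label —
*true positive* (the patient has the condition), *false positive* (the
phrase occurs but refers to someone else or is denied), or *true negative*
(a SmartPhrase question answered "No") — and notes are classed as TP-only,
FP-only, TN-only, or *conflicting* (both TP and FP mentions in one note).

Note classing conflates mention- and note-level views; the partition used
here is a documented completion of that scheme: a note mixing true-negative
mentions with exactly one other class resolves to that class's "only" label,
with a warning, since chart-review tallies do not define that cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

from .notes import AFFIRMATIVE_CLASSES, ContextClass, MentionSpan, NoteDocument


class GoldClass(str, Enum):
    TRUE_POSITIVE = "true_positive"
    FALSE_POSITIVE = "false_positive"
    TRUE_NEGATIVE = "true_negative"


class NoteClass(str, Enum):
    TP_ONLY = "tp_only"
    FP_ONLY = "fp_only"
    TN_ONLY = "tn_only"
    CONFLICTING = "conflicting"


@dataclass(frozen=True)
class GoldMention:
    """A gold-labelled phrase occurrence in an annotated note."""

    note_id: str
    start: int
    end: int
    gold_class: GoldClass


@dataclass
class TallyReport:
    """Note-class tallies and mention-level precision over an annotated set."""

    occurrence_total: int
    notes_tp_only: int
    notes_fp_only: int
    notes_tn_only: int
    notes_conflicting: int
    mention_precision: Optional[float]

    def as_dict(self) -> dict:
        return {
            "occurrence_total": self.occurrence_total,
            "notes_tp_only": self.notes_tp_only,
            "notes_fp_only": self.notes_fp_only,
            "notes_tn_only": self.notes_tn_only,
            "notes_conflicting": self.notes_conflicting,
            "mention_precision": self.mention_precision,
        }


def classify_note(gold_mentions_for_note: Sequence[GoldMention]) -> NoteClass:
    """Class a note from its gold mention labels.

    Conflicting means the note carries both a true-positive and a
    false-positive mention (true negatives do not block it). A note mixing
    true negatives with exactly one other class takes that class's "only"
    label and emits a warning, since that cell is undefined in the original
    scheme.
    """
    if not gold_mentions_for_note:
        raise ValueError("a note must have at least one gold mention to be classed")
    classes = {m.gold_class for m in gold_mentions_for_note}
    has_tp = GoldClass.TRUE_POSITIVE in classes
    has_fp = GoldClass.FALSE_POSITIVE in classes
    has_tn = GoldClass.TRUE_NEGATIVE in classes
    if has_tp and has_fp:
        return NoteClass.CONFLICTING
    if has_tn and (has_tp or has_fp):
        other = NoteClass.TP_ONLY if has_tp else NoteClass.FP_ONLY
        warnings.warn(
            f"note {gold_mentions_for_note[0].note_id}: true-negative mentions mixed "
            f"with {'true' if has_tp else 'false'}-positive ones; resolved to "
            f"{other.value} (tie-break not defined by the annotation scheme)",
            stacklevel=2,
        )
        return other
    if has_tp:
        return NoteClass.TP_ONLY
    if has_fp:
        return NoteClass.FP_ONLY
    return NoteClass.TN_ONLY


def tally(
    gold: Sequence[GoldMention],
    notes: Sequence[NoteDocument] | Sequence[str],
) -> TallyReport:
    """Tally note classes, total occurrences, and mention-level precision.

    ``notes`` is the annotated note set (documents or ids); every note must
    have gold mentions. The result is invariant to note and mention order.
    """
    note_ids = [n.note_id if isinstance(n, NoteDocument) else str(n) for n in notes]
    by_note: dict[str, list[GoldMention]] = {}
    for m in gold:
        by_note.setdefault(m.note_id, []).append(m)
    missing = [nid for nid in note_ids if nid not in by_note]
    if missing:
        raise ValueError(f"notes without gold annotations: {missing[:5]}")
    counts = {cls: 0 for cls in NoteClass}
    for nid in note_ids:
        counts[classify_note(by_note[nid])] += 1
    n_tp = sum(1 for m in gold if m.gold_class is GoldClass.TRUE_POSITIVE)
    n_fp = sum(1 for m in gold if m.gold_class is GoldClass.FALSE_POSITIVE)
    precision = n_tp / (n_tp + n_fp) if (n_tp + n_fp) else None
    return TallyReport(
        occurrence_total=len(gold),
        notes_tp_only=counts[NoteClass.TP_ONLY],
        notes_fp_only=counts[NoteClass.FP_ONLY],
        notes_tn_only=counts[NoteClass.TN_ONLY],
        notes_conflicting=counts[NoteClass.CONFLICTING],
        mention_precision=precision,
    )


_PREDICTED_LABEL = {
    ContextClass.AFFIRMATIVE: GoldClass.TRUE_POSITIVE.value,
    ContextClass.SMARTPHRASE_AFFIRMATIVE: GoldClass.TRUE_POSITIVE.value,
    ContextClass.NEGATED: GoldClass.FALSE_POSITIVE.value,
    ContextClass.OTHER_REFERENT: GoldClass.FALSE_POSITIVE.value,
    ContextClass.SMARTPHRASE_NEGATIVE: GoldClass.TRUE_NEGATIVE.value,
}


@dataclass
class MinerEvaluation:
    """Span-level confusion of predicted contexts against gold labels.

    ``confusion`` maps gold class -> predicted label -> count, where the
    predicted label collapses miner context classes onto the gold vocabulary
    (affirmative -> true_positive, negated/other-referent -> false_positive,
    SmartPhrase-negative -> true_negative) with ``absent`` for gold mentions
    that have no predicted span at their offsets. A gold mention whose span
    was located but context-classed differently is a context
    misclassification, not a missed match.
    """

    confusion: dict[str, dict[str, int]]
    recall: float
    precision: Optional[float]


def evaluate_miner(
    predicted_spans: Sequence[MentionSpan],
    gold: Sequence[GoldMention],
) -> MinerEvaluation:
    """Compare predicted mention contexts with gold labels by exact offsets.

    Recall is over gold true-positive mentions (fraction predicted present
    and affirmative); precision is over predicted affirmative spans
    (fraction whose gold label is true positive).
    """
    seen: set[tuple[str, int, int]] = set()
    pred_at: dict[tuple[str, int, int], MentionSpan] = {}
    for span in predicted_spans:
        key = (span.note_id, span.start, span.end)
        if key in seen:
            raise ValueError(f"duplicate predicted span {key}")
        seen.add(key)
        pred_at[key] = span
    confusion: dict[str, dict[str, int]] = {c.value: {} for c in GoldClass}
    tp_total = tp_hit = 0
    gold_keys = set()
    for g in gold:
        key = (g.note_id, g.start, g.end)
        gold_keys.add(key)
        span = pred_at.get(key)
        if span is None or span.context_class is None:
            label = "absent"
        else:
            label = _PREDICTED_LABEL[span.context_class]
        row = confusion[g.gold_class.value]
        row[label] = row.get(label, 0) + 1
        if g.gold_class is GoldClass.TRUE_POSITIVE:
            tp_total += 1
            if label == GoldClass.TRUE_POSITIVE.value:
                tp_hit += 1
    recall = tp_hit / tp_total if tp_total else 0.0
    affirmative_preds = [
        s
        for s in predicted_spans
        if s.context_class in AFFIRMATIVE_CLASSES
    ]
    if affirmative_preds:
        gold_tp_keys = {
            (g.note_id, g.start, g.end)
            for g in gold
            if g.gold_class is GoldClass.TRUE_POSITIVE
        }
        hits = sum(
            1 for s in affirmative_preds if (s.note_id, s.start, s.end) in gold_tp_keys
        )
        precision: Optional[float] = hits / len(affirmative_preds)
    else:
        precision = None
    return MinerEvaluation(confusion=confusion, recall=recall, precision=precision)
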