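"""Text normalization, mention matching, context classification, aggregation."""

import pandas as pd
import pytest

from sbdh_screen.lexicon import Domain, compile_matcher, default_lexicon
from sbdh_screen.notes import (
    ContextClass,
    MentionSpan,
    NoteDocument,
    classify_context,
    detect_smartphrase,
    match_mentions,
    mine_note,
    mine_notes,
    normalize_text,
    note_flag,
    patient_prevalence,
    stratify,
)
from sbdh_screen.structured import UndefinedRateError


def _note(text, note_id="N1", patient_id="P1", **kw):
    meta = dict(encounter_id="E1", note_type="progress_note",
                provider_role="physician", date="2017-01-01")
    meta.update(kw)
    return NoteDocument(note_id=note_id, patient_id=patient_id, text=text, **meta)


class TestNormalize:
    def test_collapses_whitespace_with_invertible_offsets(self):
        norm, offsets = normalize_text("homeless\n\n  man")
        assert norm == "homeless man"
        # every normalized char maps back to the raw char it came from
        raw = "homeless\n\n  man"
        assert all(norm[i] == " " or raw[offsets[i]] == norm[i] for i in range(len(norm)))
        assert offsets[norm.index("man")] == raw.index("man")

    def test_empty_text(self):
        assert normalize_text("") == ("", [])

    def test_idempotent(self):
        text = "a  b\tc\n\nd "
        once, _ = normalize_text(text)
        twice, _ = normalize_text(once)
        assert once == twice


class TestMatchMentions:
    def test_span_offsets_point_into_raw_text(self, matcher):
        note = _note("He has been   homeless\nsince June.")
        spans = match_mentions(note, matcher)
        assert len(spans) == 1
        s = spans[0]
        assert note.text[s.start:s.end] == s.matched_text == "homeless"
        assert s.domain is Domain.HOUSING

    def test_phrase_split_across_newline_still_matches(self, matcher):
        note = _note("Patient reports housing\ninstability lately.")
        spans = match_mentions(note, matcher)
        assert len(spans) == 1
        assert spans[0].matched_text == "housing\ninstability"

    def test_note_without_phrases_yields_nothing(self, matcher):
        assert match_mentions(_note("Vitals stable, plan unchanged."), matcher) == []


class TestSmartPhrase:
    @pytest.fixture
    def templates(self, lexicon_set):
        return lexicon_set[Domain.HOUSING].smartphrase_templates

    @pytest.mark.parametrize("answer", ["No", "Yes"])
    def test_answer_detected(self, templates, answer):
        hits = detect_smartphrase(_note(f"Is Patient Homeless? {answer}"), templates)
        assert len(hits) == 1
        assert hits[0].answer == answer

    def test_unanswered_question_reports_absent_answer(self, templates):
        hits = detect_smartphrase(_note("Is Patient Homeless?"), templates)
        assert hits[0].answer is None

    def test_answer_beyond_distance_not_picked_up(self, templates):
        filler = "x" * 30
        hits = detect_smartphrase(_note(f"Is Patient Homeless? {filler} No"), templates)
        assert hits[0].answer is None

    def test_empty_templates_error(self):
        with pytest.raises(ValueError):
            detect_smartphrase(_note("anything"), [])


class TestClassifyContext:
    def _span(self, note, token="homeless"):
        i = note.text.lower().index(token)
        return MentionSpan(note.note_id, Domain.HOUSING, "p", i, i + len(token),
                           note.text[i:i + len(token)])

    @pytest.mark.parametrize(
        "text,expected",
        [
            ("Is Patient Homeless? No", ContextClass.SMARTPHRASE_NEGATIVE),
            ("Is Patient Homeless? Yes", ContextClass.SMARTPHRASE_AFFIRMATIVE),
            ("Is Patient Homeless?", ContextClass.SMARTPHRASE_NEGATIVE),
            ("Patient denies being homeless.", ContextClass.NEGATED),
            ("Patient reports being homeless.", ContextClass.AFFIRMATIVE),
            ("Patient's brother is homeless.", ContextClass.OTHER_REFERENT),
        ],
    )
    def test_precedence_rules(self, lexicon_set, text, expected):
        note = _note(text)
        lex = lexicon_set[Domain.HOUSING]
        assert classify_context(self._span(note), note, lex) is expected

    def test_negation_cue_outside_sentence_does_not_negate(self, lexicon_set):
        note = _note("Patient denies chest pain. Patient is homeless.")
        lex = lexicon_set[Domain.HOUSING]
        assert classify_context(self._span(note), note, lex) is ContextClass.AFFIRMATIVE

    def test_negation_before_window_does_not_fire(self, lexicon_set):
        pad = "the visit was long and " * 3
        note = _note(f"Patient is not aware that {pad}he is homeless")
        lex = lexicon_set[Domain.HOUSING]
        assert classify_context(self._span(note), note, lex) is ContextClass.AFFIRMATIVE

    def test_span_outside_bounds_errors(self, lexicon_set):
        note = _note("short")
        span = MentionSpan("N1", Domain.HOUSING, "p", 0, 99, "x")
        with pytest.raises(ValueError):
            classify_context(span, note, lexicon_set[Domain.HOUSING])


class TestNoteFlag:
    def _span(self, ctx, domain=Domain.HOUSING):
        return MentionSpan("N1", domain, "p", 0, 8, "homeless", ctx)

    def test_affirmative_flags_domain(self):
        assert note_flag([self._span(ContextClass.AFFIRMATIVE)])[Domain.HOUSING] is True

    def test_only_smartphrase_negative_does_not_flag(self):
        flags = note_flag([self._span(ContextClass.SMARTPHRASE_NEGATIVE)])
        assert flags[Domain.HOUSING] is False

    def test_mixed_note_flags_true(self):
        spans = [self._span(ContextClass.OTHER_REFERENT), self._span(ContextClass.AFFIRMATIVE)]
        assert note_flag(spans)[Domain.HOUSING] is True

    def test_raw_mode_flags_any_occurrence(self):
        flags = note_flag([self._span(ContextClass.SMARTPHRASE_NEGATIVE)], mode="raw")
        assert flags[Domain.HOUSING] is True


def _table(rows):
    return pd.DataFrame(rows, columns=["note_id", "patient_id", "encounter_id",
                                       "note_type", "provider_role", "date"])


class TestPrevalence:
    def test_one_of_three_patients(self):
        table = _table([(f"N{i}", f"P{i}", f"E{i}", "progress_note", "physician", "2017-01-01")
                        for i in range(3)])
        flags = {"N0": {Domain.HOUSING: True}}
        report = patient_prevalence(flags, table)
        row = report.rows.set_index("domain").loc["housing"]
        assert (row["patients_flagged"], row["denominator"], row["pct"]) == (1, 3, 33.33)

    def test_additional_flagged_note_for_same_patient_changes_nothing(self):
        table = _table([("N0", "P0", "E0", "progress_note", "physician", "2017-01-01"),
                        ("N1", "P0", "E1", "progress_note", "physician", "2017-01-02")])
        one = patient_prevalence({"N0": {Domain.HOUSING: True}}, table)
        two = patient_prevalence({"N0": {Domain.HOUSING: True},
                                  "N1": {Domain.HOUSING: True}}, table)
        assert one.rows.equals(two.rows)

    def test_denominator_counts_all_noted_patients(self):
        table = _table([("N0", "P0", "E0", "progress_note", "physician", "2017-01-01")])
        report = patient_prevalence({}, table)
        assert (report.rows["denominator"] == 1).all()
        assert (report.rows["patients_flagged"] == 0).all()

    def test_empty_note_table_signals_undefined(self):
        with pytest.raises(UndefinedRateError):
            patient_prevalence({}, _table([]))


class TestStratify:
    def test_counts_sum_to_total_flagged_notes(self):
        table = _table([(f"N{i}", f"P{i}", f"E{i}", "progress_note",
                         "physician" if i % 2 else "nurse", "2017-01-01") for i in range(6)])
        flags = {f"N{i}": {Domain.HOUSING: True} for i in range(5)}
        out = stratify(flags, table, "provider_role")
        assert out["n_notes"].sum() == 5

    def test_missing_metadata_grouped_under_unknown(self):
        table = _table([("N0", "P0", "E0", "progress_note", "", "2017-01-01")])
        out = stratify({"N0": {Domain.HOUSING: True}}, table, "provider_role")
        assert list(out["stratum"]) == ["unknown"]

    def test_invalid_by_errors(self):
        with pytest.raises(ValueError):
            stratify({}, _table([]), "facility")


class TestEndToEnd:
    def test_mine_note_matches_classify_pipeline(self, lexicon_set, matcher):
        note = _note("Patient reports being homeless. Is Patient Homeless? No")
        spans = mine_note(note, matcher, lexicon_set)
        classes = sorted(s.context_class.value for s in spans)
        assert classes == ["affirmative", "smartphrase_negative"]

    def test_matched_text_always_equals_raw_substring(self, small_ehr, lexicon_set):
        spans, _ = mine_notes(small_ehr.notes[:500], lexicon_set)
        by_id = {n.note_id: n for n in small_ehr.notes[:500]}
        for s in spans:
            assert by_id[s.note_id].text[s.start:s.end] == s.matched_text

    def test_adding_a_note_never_decreases_flag_counts(self, lexicon_set):
        base = [_note("Patient reports being homeless.", note_id="N0", patient_id="P0")]
        extra = base + [_note("Patient reports social isolation.", note_id="N1", patient_id="P1")]
        _, f1 = mine_notes(base, lexicon_set)
        _, f2 = mine_notes(extra, lexicon_set)
        t1 = _table([("N0", "P0", "E0", "progress_note", "physician", "2017-01-01")])
        t2 = _table([("N0", "P0", "E0", "progress_note", "physician", "2017-01-01"),
                     ("N1", "P1", "E1", "progress_note", "physician", "2017-01-01")])
        r1 = patient_prevalence(f1, t1).rows.set_index("domain")["patients_flagged"]
        r2 = patient_prevalence(f2, t2).rows.set_index("domain")["patients_flagged"]
        assert (r2 >= r1).all()
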