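"""Synthetic EHR generator: determinism, schemas, planted ground truth."""

import numpy as np
import pandas as pd
import pytest
from pydantic import ValidationError
from scipy import stats

from sbdh_screen.lexicon import Domain, TEXT_MINED_DOMAINS, compile_matcher, default_lexicon
from sbdh_screen.notes import ContextClass, mine_notes
from sbdh_screen.synthetic import (
    SimulationConfig,
    generate_annotation_fixture,
    generate_diagnoses,
    generate_ehr,
    generate_notes,
    generate_population,
    generate_questionnaires,
    generate_social_history,
    note_table,
    read_notes_jsonl,
    write_ehr,
)


def binom99(n: int, p: float) -> tuple[int, int]:
    """Central 99% interval on a Binomial(n, p) count."""
    return int(stats.binom.ppf(0.005, n, p)), int(stats.binom.ppf(0.995, n, p))


class TestConfig:
    def test_defaults_are_valid(self):
        cfg = SimulationConfig()
        assert cfg.note_prevalence[Domain.HOUSING] == 0.0300

    def test_probability_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            SimulationConfig(completeness={"race": 1.2})

    def test_mixture_not_summing_to_one_rejected(self):
        with pytest.raises(ValidationError):
            SimulationConfig(note_type_mixture={"progress_note": 0.7})

    def test_negative_population_rejected(self):
        with pytest.raises(ValidationError):
            SimulationConfig(n_patients=-1)


class TestPopulation:
    def test_zero_patients_yields_empty_tables_with_schema(self):
        patients, encounters = generate_population(SimulationConfig(n_patients=0))
        assert list(patients.columns) == [
            "patient_id", "address", "zip", "race", "ethnicity", "preferred_language",
        ]
        assert len(patients) == 0 and len(encounters) == 0

    def test_race_completeness_within_binomial_interval(self):
        cfg = SimulationConfig(n_patients=10_000, seed=5)
        patients, _ = generate_population(cfg)
        observed = int((patients["race"] != "").sum())
        lo, hi = binom99(10_000, 0.90)
        assert lo <= observed <= hi

    def test_zip_is_five_digits_when_present(self):
        patients, _ = generate_population(SimulationConfig(n_patients=500, seed=2))
        present = patients.loc[patients["zip"] != "", "zip"]
        assert present.str.fullmatch(r"\d{5}").all()

    def test_multiple_races_possible(self):
        patients, _ = generate_population(SimulationConfig(n_patients=5_000, seed=3))
        assert patients["race"].str.contains(";").any()

    def test_unknown_language_is_generated_as_a_value(self):
        patients, _ = generate_population(SimulationConfig(n_patients=20_000, seed=4))
        assert (patients["preferred_language"] == "Unknown").any()

    def test_same_seed_identical_tables(self):
        cfg = SimulationConfig(n_patients=300, seed=9)
        a = generate_population(cfg)
        b = generate_population(cfg)
        assert a[0].equals(b[0]) and a[1].equals(b[1])


class TestDiagnoses:
    def test_housing_prevalence_within_binomial_interval(self, lexicon_set):
        cfg = SimulationConfig(n_patients=100_000, seed=6)
        patients = pd.DataFrame({"patient_id": [f"P{i}" for i in range(100_000)]})
        _, flags = generate_diagnoses(cfg, patients, lexicon_set)
        lo, hi = binom99(100_000, 0.0019)
        assert lo <= len(flags[Domain.HOUSING]) <= hi

    def test_zero_prevalence_plants_no_sbdh_codes(self, lexicon_set):
        cfg = SimulationConfig(
            n_patients=2_000,
            seed=6,
            icd_prevalence={d: 0.0 for d in TEXT_MINED_DOMAINS},
        )
        patients, _ = generate_population(cfg)
        diagnoses, flags = generate_diagnoses(cfg, patients, lexicon_set)
        sbdh_codes = {e.code for lex in lexicon_set for e in lex.codes}
        assert not set(diagnoses["code"]) & sbdh_codes
        assert all(not v for v in flags.values())

    def test_every_flagged_patient_has_a_domain_code(self, small_ehr, lexicon_set):
        diagnoses = small_ehr.diagnoses
        for domain in TEXT_MINED_DOMAINS:
            codes = {e.code for e in lexicon_set[domain].codes}
            icd9 = {"V60.0", "V60.1", "V60.2", "V60.8", "V60.9", "V62.4", "V61.0"}
            for pid in small_ehr.ground_truth.structured_positive[domain]:
                rows = diagnoses[diagnoses["patient_id"] == pid]
                assert set(rows["code"]) & (codes | icd9)


class TestNotes:
    def test_every_patient_has_at_least_one_note(self, small_ehr):
        table = note_table(small_ehr.notes)
        assert table["patient_id"].nunique() == len(small_ehr.patients)

    def test_gold_flag_prevalence_within_binomial_interval(self, lexicon_set):
        cfg = SimulationConfig(n_patients=10_000, seed=8)
        patients, _ = generate_population(cfg)
        _, truth = generate_notes(cfg, patients, lexicon_set)
        lo, hi = binom99(10_000, 0.0300)
        assert lo <= len(truth.patient_note_flags[Domain.HOUSING]) <= hi

    def test_planted_span_text_equals_phrase(self, small_ehr):
        by_id = {n.note_id: n for n in small_ehr.notes}
        for note_id, mentions in small_ehr.ground_truth.note_mentions.items():
            for m in mentions:
                assert by_id[note_id].text[m.start:m.end] == m.phrase

    def test_filler_contains_no_lexicon_phrase(self, small_ehr, matcher):
        """Outside planted spans, generated notes match nothing."""
        truth = small_ehr.ground_truth
        for note in small_ehr.notes[:1000]:
            planted = {(m.start, m.end) for m in truth.note_mentions.get(note.note_id, [])}
            from sbdh_screen.notes import match_mentions

            for span in match_mentions(note, matcher):
                assert (span.start, span.end) in planted

    def test_all_smartphrase_mixture_flags_nobody_but_matches_phrases(self, lexicon_set):
        cfg = SimulationConfig(
            n_patients=300,
            seed=8,
            note_prevalence={d: 0.5 for d in TEXT_MINED_DOMAINS},
            context_mixture={
                "affirmative": 0.0,
                "smartphrase_negative": 1.0,
                "negated": 0.0,
                "other_referent": 0.0,
                "mixed": 0.0,
            },
        )
        patients, _ = generate_population(cfg)
        notes, truth = generate_notes(cfg, patients, lexicon_set)
        assert all(not flagged for flagged in truth.patient_note_flags.values())
        matcher = compile_matcher(lexicon_set)
        n_hits = sum(len(matcher.scan(n.text)) for n in notes)
        assert n_hits > 0
        spans, _flags = mine_notes(notes, lexicon_set)
        assert all(s.context_class is ContextClass.SMARTPHRASE_NEGATIVE for s in spans)

    def test_same_seed_byte_identical_notes(self, lexicon_set):
        cfg = SimulationConfig(n_patients=200, seed=13)
        patients, _ = generate_population(cfg)
        a, _ = generate_notes(cfg, patients, lexicon_set)
        b, _ = generate_notes(cfg, patients, lexicon_set)
        assert [n.text for n in a] == [n.text for n in b]

    def test_miner_reproduces_gold_flags_exactly(self, small_ehr, lexicon_set):
        spans, flags = mine_notes(small_ehr.notes, lexicon_set)
        table = note_table(small_ehr.notes)
        patient_of = dict(zip(table["note_id"], table["patient_id"]))
        for domain in TEXT_MINED_DOMAINS:
            mined = {
                patient_of[nid]
                for nid, per_domain in flags.items()
                if per_domain.get(domain)
            }
            assert mined == small_ehr.ground_truth.patient_note_flags[domain]


class TestQuestionnairesGen:
    def test_scaled_counts_and_rates(self):
        df = generate_questionnaires(SimulationConfig(n_patients=100_000, seed=1))
        assert (df["completed"] <= df["administered"]).all()
        nursing = df.set_index("template").loc["nursing_assessment"]
        # administered scales as 1,026,988 * n / 5,401,324
        assert nursing["administered"] == round(1_026_988 * 100_000 / 5_401_324)


class TestRoundTrip:
    def test_write_then_read_notes(self, tmp_path, small_ehr):
        write_ehr(small_ehr, tmp_path)
        notes = read_notes_jsonl(tmp_path / "notes.jsonl")
        assert notes == small_ehr.notes
        for name in ("patients.csv", "encounters.csv", "social_history.csv",
                     "diagnoses.csv", "questionnaires.csv", "ground_truth.jsonl",
                     "config.yaml"):
            assert (tmp_path / name).exists()


class TestAnnotationFixture:
    @pytest.mark.parametrize("seed", [0, 1, 42])
    def test_composition_is_seed_independent(self, seed):
        notes, gold = generate_annotation_fixture(seed)
        assert len(notes) == 100
        token_total = sum(n.text.lower().count("homeless") for n in notes)
        assert token_total == 130
        assert all("homeless" in n.text.lower() for n in notes)

    def test_surface_text_varies_with_seed(self):
        a, _ = generate_annotation_fixture(0)
        b, _ = generate_annotation_fixture(1)
        assert [n.text for n in a] != [n.text for n in b]

    def test_gold_partition_is_64_14_20_2(self, annotation_fixture):
        from sbdh_screen.annotation import classify_note, NoteClass

        notes, gold = annotation_fixture
        by_note = {}
        for m in gold:
            by_note.setdefault(m.note_id, []).append(m)
        counts = {cls: 0 for cls in NoteClass}
        for n in notes:
            counts[classify_note(by_note[n.note_id])] += 1
        assert counts[NoteClass.TP_ONLY] == 64
        assert counts[NoteClass.FP_ONLY] == 14
        assert counts[NoteClass.TN_ONLY] == 20
        assert counts[NoteClass.CONFLICTING] == 2
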