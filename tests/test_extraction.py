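"""EF parsing, medication lexicon matching, context assertion, RNM rules."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_note
from hfquality.extraction import (
    assert_context,
    assert_context_all,
    default_lexicon,
    extract_ef_mentions,
    extract_med_mentions,
    extract_rnm_mentions,
    parse_ef_value,
)
from hfquality.simulate import render_ef
from hfquality.types import (
    Concept,
    ConceptMention,
    DrugClass,
    EFValue,
    QualitativeEF,
    RNMCategory,
    SectionLabel,
)


class TestParseEFValue:
    @pytest.mark.parametrize(
        "snippet,expected",
        [
            ("LVEF 35%", EFValue.point(35.0)),
            ("EF 30-35%", EFValue.range(30.0, 35.0)),
            ("EF is 55%", EFValue.point(55.0)),
            ("Ejection fraction of 40%", EFValue.point(40.0)),
            ("EF 30 to 35%", EFValue.range(30.0, 35.0)),
            ("EF > 55%", EFValue.point(55.0, direction="gt")),
            ("EF < 20%", EFValue.point(20.0, direction="lt")),
            ("LVEF >= 40%", EFValue.point(40.0, direction="ge")),
            (
                "left ventricular systolic function is severely reduced",
                EFValue.qualitative(QualitativeEF.SEVERELY_REDUCED),
            ),
            (
                "severely reduced systolic function",
                EFValue.qualitative(QualitativeEF.SEVERELY_REDUCED),
            ),
            ("LVEF is normal", EFValue.qualitative(QualitativeEF.NORMAL_OR_PRESERVED)),
            (
                "preserved ejection fraction",
                EFValue.qualitative(QualitativeEF.NORMAL_OR_PRESERVED),
            ),
        ],
    )
    def test_parse(self, snippet, expected):
        assert parse_ef_value(snippet) == expected

    def test_range_representative_is_midpoint(self):
        assert parse_ef_value("EF 30-35%").representative == 32.5

    def test_trigger_without_value_gives_none(self):
        assert parse_ef_value("EF was not documented this admission") is None

    def test_value_outside_0_100_rejected(self):
        assert parse_ef_value("EF 350%") is None

    def test_comparative_direction_blocks_threshold(self):
        assert parse_ef_value("EF > 55%").is_below(40) is False
        assert parse_ef_value("EF < 20%").is_below(40) is True
        # a bound straddling the threshold settles nothing
        assert parse_ef_value("EF > 30%").is_below(40) is None

    def test_ef_40_strictness(self):
        v = parse_ef_value("LVEF 40%")
        assert v.is_below(40, strict=True) is False
        assert v.is_below(40, strict=False) is True

    @given(st.integers(5, 75), st.integers(0, 4))
    @settings(max_examples=60, deadline=None)
    def test_point_render_parse_round_trip(self, value, template_id):
        v = EFValue.point(float(value))
        assert parse_ef_value(render_ef(v, template_id)) == v

    @given(st.integers(10, 60), st.integers(1, 20), st.integers(0, 2))
    @settings(max_examples=60, deadline=None)
    def test_range_render_parse_round_trip(self, lo, width, template_id):
        v = EFValue.range(float(lo), float(lo + width))
        assert parse_ef_value(render_ef(v, template_id)) == v


class TestExtractEFMentions:
    def test_echo_conclusions_mention(self):
        note = make_note(
            "n1",
            "CONCLUSIONS:\nEF 25%. Normal right ventricle.\n",
            title="ECHOCARDIOGRAM REPORT",
        )
        mentions = extract_ef_mentions(note)
        assert len(mentions) == 1
        m = mentions[0]
        assert m.section is SectionLabel.ECHO_NARRATIVE_SUMMARY
        assert m.value == EFValue.point(25.0)
        assert note.text[m.start : m.end] == "EF 25%"

    def test_two_statements_in_document_order(self):
        note = make_note("n1", "EF 30% on admission. Repeat LVEF 45% at discharge.")
        mentions = extract_ef_mentions(note)
        assert [m.value.representative for m in mentions] == [30.0, 45.0]
        assert mentions[0].start < mentions[1].start

    def test_no_trigger_no_mentions(self):
        note = make_note("n1", "Patient resting comfortably, no complaints.")
        assert extract_ef_mentions(note) == []

    def test_trigger_without_value_still_counts_as_mention(self):
        note = make_note("n1", "Ejection fraction not documented previously.")
        mentions = extract_ef_mentions(note)
        assert len(mentions) == 1 and mentions[0].value is None

    def test_spans_never_overlap(self):
        note = make_note("n1", "LVEF (EF) 35% noted. EF 35% again.")
        mentions = extract_ef_mentions(note)
        for a, b in zip(mentions, mentions[1:]):
            assert a.end <= b.start


class TestMedLexicon:
    def test_every_surface_maps_to_unique_generic(self):
        lexicon = default_lexicon()
        for entry in lexicon.entries:
            for surface in (entry.generic, *entry.variants):
                match = lexicon.lookup(surface)
                assert match.generic == entry.generic
                assert match.drug_class is entry.drug_class

    def test_simple_acei_mention(self):
        note = make_note("n1", "Continue lisinopril 10 mg daily")
        mentions = extract_med_mentions(note)
        assert len(mentions) == 1
        assert mentions[0].value.generic == "lisinopril"
        assert mentions[0].value.drug_class is DrugClass.ACEI

    def test_brand_and_generic_normalize_to_same_entry(self):
        note = make_note("n1", "Started losartan; previously on Cozaar.")
        mentions = extract_med_mentions(note)
        assert len(mentions) == 2
        assert {m.value.generic for m in mentions} == {"losartan"}
        assert {m.value.drug_class for m in mentions} == {DrugClass.ARB}

    def test_class_level_mention(self):
        note = make_note("n1", "no ACE inhibitor started")
        mentions = extract_med_mentions(note)
        assert len(mentions) == 1
        assert mentions[0].value.generic is None
        assert mentions[0].value.drug_class is DrugClass.ACEI

    def test_word_boundaries_prevent_substring_hits(self):
        note = make_note("n1", "lisinoprility is not a word; neither is xcozaarx")
        assert extract_med_mentions(note) == []


class TestAssertContext:
    @pytest.mark.parametrize(
        "sentence,negated,discontinued",
        [
            ("not on lisinopril", True, False),
            ("lisinopril held due to hyperkalemia", False, True),
            ("Continue lisinopril", False, False),
            ("denies taking lisinopril", True, False),
            ("lisinopril discontinued today", False, True),
            ("allergic to lisinopril", False, True),
            ("patient refused lisinopril", False, True),
        ],
    )
    def test_trigger_rules(self, sentence, negated, discontinued):
        start = sentence.lower().index("lisinopril")
        mention = ConceptMention(
            Concept.ACEI_ARB, "n1", start, start + len("lisinopril")
        )
        assert_context(mention, sentence)
        assert mention.negated is negated
        assert mention.discontinued is discontinued

    def test_scope_ends_at_clause_break(self):
        sentence = "was not taking aspirin before; lisinopril continued"
        start = sentence.index("lisinopril")
        mention = ConceptMention(Concept.ACEI_ARB, "n1", start, start + 10)
        assert_context(mention, sentence)
        assert mention.negated is False

    def test_context_within_full_note(self):
        note = make_note("n1", "Stable overnight. Not on lisinopril. Plan diuresis.")
        mentions = extract_med_mentions(note)
        assert_context_all(mentions, note.text)
        assert mentions[0].negated is True


class TestExtractRNM:
    def test_contraindication_with_category(self):
        note = make_note("n1", "ACEI contraindicated due to hyperkalemia.")
        mentions = extract_rnm_mentions(note)
        assert len(mentions) == 1
        assert mentions[0].value is RNMCategory.HYPERKALEMIA

    def test_lab_value_mapping_rule(self):
        note = make_note("n1", "lisinopril stopped, K 5.9")
        mentions = extract_rnm_mentions(note)
        assert [m.value for m in mentions] == [RNMCategory.HYPERKALEMIA]

    def test_normal_potassium_is_not_a_reason(self):
        note = make_note("n1", "potassium normal")
        assert extract_rnm_mentions(note) == []

    def test_reason_without_med_or_stop_trigger_not_emitted(self):
        note = make_note("n1", "History of seasonal allergies.")
        assert extract_rnm_mentions(note) == []

    def test_specific_category_beats_generic_contraindication(self):
        note = make_note("n1", "ARB contraindicated given angioedema history.")
        mentions = extract_rnm_mentions(note)
        assert [m.value for m in mentions] == [RNMCategory.ANGIOEDEMA]

    @pytest.mark.parametrize(
        "sentence,category",
        [
            ("Lisinopril held due to worsening renal function.", RNMCategory.RENAL_DYSFUNCTION),
            ("ACE inhibitor held due to hypotension.", RNMCategory.HYPOTENSION),
            ("Patient refused ACEI therapy.", RNMCategory.PATIENT_REFUSAL),
            ("ACEI held; patient transitioned to comfort care.", RNMCategory.COMFORT_CARE),
            ("Allergy to lisinopril documented.", RNMCategory.ALLERGY_INTOLERANCE),
            ("ARB stopped due to angioedema.", RNMCategory.ANGIOEDEMA),
        ],
    )
    def test_category_assignment(self, sentence, category):
        note = make_note("n1", sentence)
        mentions = extract_rnm_mentions(note)
        assert category in {m.value for m in mentions}


class TestDeterminismAndIdempotence:
    def test_extraction_is_deterministic(self):
        note = make_note(
            "n1",
            "ASSESSMENT:\nEF 30-35%. Continue lisinopril. "
            "ACEI contraindicated due to hyperkalemia.\n",
        )
        runs = []
        for _ in range(2):
            ms = (
                extract_ef_mentions(note)
                + extract_med_mentions(note)
                + extract_rnm_mentions(note)
            )
            runs.append([m.to_dict() for m in ms])
        assert runs[0] == runs[1]
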