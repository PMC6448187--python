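"""Rule cascade: blank-fill, precedence, offset fidelity, NOTE_NLP export."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenotext.rules import (
    DiseaseRules,
    blank_fill,
    classify_disease,
    export_matches,
    run_cascade,
)
from phenotext.types import (
    ABSENT,
    NO_DECISION,
    PRESENT,
    QUESTIONABLE,
    UNMENTIONED,
)

CAD = "coronary artery disease"


class TestBlankFill:
    def test_replaces_span_with_spaces_same_length(self):
        out = blank_fill("possible CAD", (0, 8))
        assert out == "         CAD"[:len(out)] and len(out) == 12
        assert out[8:] == " CAD" and out[:8] == " " * 8

    def test_full_span(self):
        assert blank_fill("ABC", (0, 3)) == "   "

    def test_out_of_bounds(self):
        with pytest.raises(ValueError):
            blank_fill("abc", (1, 5))

    @given(
        text=st.text(min_size=2, max_size=40),
        data=st.data(),
    )
    @settings(max_examples=100, derandomize=True)
    def test_length_invariance_and_disjoint_commutativity(self, text, data):
        n = len(text)
        s1 = data.draw(st.integers(0, n - 1))
        e1 = data.draw(st.integers(s1, n))
        out = blank_fill(text, (s1, e1))
        assert len(out) == n
        assert out[:s1] == text[:s1] and out[e1:] == text[e1:]
        assert out[s1:e1] == " " * (e1 - s1)
        # commutativity on disjoint spans
        s2 = data.draw(st.integers(e1, n))
        e2 = data.draw(st.integers(s2, n))
        assert blank_fill(blank_fill(text, (s1, e1)), (s2, e2)) == blank_fill(
            blank_fill(text, (s2, e2)), (s1, e1)
        )


class TestCascade:
    def test_worked_negation_example(self, cad_rules):
        text = f"no evidence of {CAD}"
        judgment, tables = classify_disease(text, cad_rules)
        assert judgment == ABSENT
        (m,) = tables.absent
        assert m.sentence == text and m.sen_pos == (0, len(text))
        assert text[m.dis_pos[0]:m.dis_pos[1]] == CAD

    def test_questionable_beats_absent(self, cad_rules):
        text = f"possible {CAD} but no evidence of {CAD}"
        judgment, tables = classify_disease(text, cad_rules)
        assert judgment == QUESTIONABLE
        assert len(tables.questionable) == 1 and len(tables.absent) == 1
        # both recorded against the original, untouched text
        for m in tables.questionable + tables.absent:
            assert text[m.dis_pos[0]:m.dis_pos[1]] == m.dis_alias
            assert text[m.sen_pos[0]:m.sen_pos[1]] == m.sentence

    def test_absent_beats_present(self, cad_rules):
        text = f"no evidence of {CAD}. The patient has {CAD}."
        judgment, tables = classify_disease(text, cad_rules)
        assert judgment == ABSENT
        assert len(tables.present) == 1

    def test_no_alias_is_unmentioned_or_no_decision(self, cad_rules):
        text = "patient history unremarkable"
        judgment, tables = classify_disease(text, cad_rules, task="textual")
        assert judgment == UNMENTIONED and tables.all_matches() == []
        judgment, _ = classify_disease(text, cad_rules, task="intuitive")
        assert judgment == NO_DECISION

    def test_postposed_negation_trigger(self, cad_rules):
        judgment, tables = classify_disease(f"{CAD} was ruled out", cad_rules)
        assert judgment == ABSENT
        assert tables.absent[0].sentence == f"{CAD} was ruled out"

    def test_question_mark_trigger(self, cad_rules):
        judgment, _ = classify_disease(f"{CAD}?", cad_rules)
        assert judgment == QUESTIONABLE

    def test_plain_mention_is_present(self, cad_rules):
        judgment, tables = classify_disease(f"The patient has {CAD}.", cad_rules)
        assert judgment == PRESENT
        (m,) = tables.present
        assert m.sentence is None and m.sen_pos is None

    def test_purity_and_working_length(self, cad_rules):
        text = f"possible {CAD}; no evidence of {CAD}; has {CAD} today"
        copy = str(text)
        tables, working = run_cascade(text, cad_rules)
        assert text == copy
        assert len(working) == len(text)
        assert len(tables.all_matches()) == 3

    def test_alias_word_boundary(self):
        rules = DiseaseRules("gout", ["gout"])
        judgment, _ = classify_disease("gouty arthropathy noted", rules)
        assert judgment == UNMENTIONED


def random_document_and_rules(rng: random.Random):
    """A random document plus a random rule set over random aliases."""
    vocab = ["fever", "cough", "note", "stable", "exam", "today", "renal", "mild"]
    alias_words = ["zetagrex", "quorvane", "bleximab", "dorvantis"]
    aliases = rng.sample(alias_words, k=rng.randint(1, 2))
    q_triggers = rng.sample(["possible", "probable", "rule out", "suspected"], k=2)
    a_triggers = rng.sample(["no evidence of", "denies", "negative for", "free of"], k=2)
    rules = DiseaseRules(
        "synthetic disease",
        aliases=aliases,
        questionable_contexts=q_triggers,
        absent_contexts=a_triggers,
    )
    sentences = []
    for _ in range(rng.randint(1, 8)):
        kind = rng.random()
        alias = rng.choice(aliases)
        if kind < 0.25:
            sentences.append(f"{rng.choice(q_triggers)} {alias}")
        elif kind < 0.5:
            sentences.append(f"{rng.choice(a_triggers)} {alias}")
        elif kind < 0.7:
            sentences.append(f"{rng.choice(vocab)} {alias} {rng.choice(vocab)}")
        else:
            sentences.append(" ".join(rng.choices(vocab, k=rng.randint(2, 6))))
    return ". ".join(sentences) + ".", rules


def test_offset_fidelity_on_random_documents():
    """Every recorded span slices the original document to the recorded text."""
    rng = random.Random(20240917)
    for _ in range(1000):
        text, rules = random_document_and_rules(rng)
        tables, working = run_cascade(text, rules)
        assert len(working) == len(text)
        for m in tables.all_matches():
            assert text[m.dis_pos[0]:m.dis_pos[1]] == m.dis_alias
            if m.sen_pos is not None:
                assert text[m.sen_pos[0]:m.sen_pos[1]] == m.sentence
                assert m.sen_pos[0] <= m.dis_pos[0] <= m.dis_pos[1] <= m.sen_pos[1]


class TestExportMatches:
    def test_absent_snippet_is_sentence(self, cad_rules):
        text = f"no evidence of {CAD}"
        _, tables = classify_disease(text, cad_rules)
        (row,) = export_matches(tables, note_id=1, note_text=text)
        assert row.snippet == text
        assert row.offset == f"{text.index(CAD)}:{len(text)}"
        assert row.lexical_variant == CAD
        assert row.nlp_system == "rule_engine"
        assert row.note_nlp_concept_id == f"{cad_rules.name}:Absent"

    def test_empty_tables(self, cad_rules):
        _, tables = classify_disease("nothing here", cad_rules)
        assert export_matches(tables, 1, "nothing here") == []

    def test_present_snippet_is_clipped_window(self, cad_rules):
        text = "x" * 100 + f" {CAD} " + "y" * 100
        _, tables = classify_disease(text, cad_rules)
        (row,) = export_matches(tables, 1, text, window=10)
        start, end = row.span()
        assert row.snippet == text[start - 10:end + 10]

    def test_integrity_error_on_corrupted_span(self, cad_rules):
        text = f"has {CAD}"
        _, tables = classify_disease(text, cad_rules)
        with pytest.raises(ValueError, match="integrity"):
            export_matches(tables, 1, "a completely different text of same-ish size")


def test_rules_require_alias_and_compilable_patterns():
    with pytest.raises(ValueError):
        DiseaseRules("d", aliases=[])
    with pytest.raises(Exception):
        DiseaseRules("d", aliases=["("])
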