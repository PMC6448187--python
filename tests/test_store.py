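"""NOTE_NLP persistence: schema lifecycle, round trips, filtered counts."""

import pytest

from phenotext.prep import detect_sections
from phenotext.rules import classify_disease, DiseaseRules
from phenotext.store import CdmStore
from phenotext.types import ConceptAnnotation, Note, NoteNlpRow, Section


def make_store(tmp_path, name="store.db"):
    return CdmStore.init_schema(tmp_path / name)


class TestInitSchema:
    def test_fresh_store_is_empty(self, tmp_path):
        store = make_store(tmp_path)
        assert store.fetch_rows() == []
        assert store.note_ids() == []

    def test_reinit_without_force_refused(self, tmp_path):
        make_store(tmp_path).close()
        with pytest.raises(FileExistsError):
            CdmStore.init_schema(tmp_path / "store.db")

    def test_reinit_with_force_empties(self, tmp_path):
        store = make_store(tmp_path)
        store.insert_notes([Note(1, "x", "x")])
        store.close()
        store = CdmStore.init_schema(tmp_path / "store.db", force=True)
        assert store.note_ids() == []

    def test_mysql_ddl_dialect(self):
        ddl = CdmStore.ddl("mysql")
        assert "AUTO_INCREMENT" in ddl and "`offset`" in ddl
        with pytest.raises(ValueError):
            CdmStore.ddl("postgres")


SECTIONS = [Section(0, "", 0, 40), Section(7, "FAMILY HISTORY", 40, 120)]


def annotation(note_id=1, cui="C0010054", start=5, end=10, semtype="T047"):
    return ConceptAnnotation(
        note_id=note_id, cui=cui, semantic_type=semtype,
        start=start, end=end, lexical_variant="xxxxx",
    )


class TestInsertAnnotations:
    def test_section_assignment_by_offset(self, tmp_path):
        store = make_store(tmp_path)
        store.insert_notes([Note(1, "a" * 120, "a" * 120)])
        store.insert_annotations(
            [annotation(start=45, end=50)], {1: SECTIONS}
        )
        (row,) = store.fetch_rows()
        assert row.section_concept_id == 7

    def test_empty_list_inserts_nothing(self, tmp_path):
        store = make_store(tmp_path)
        assert store.insert_annotations([], {}) == 0

    def test_ids_strictly_increasing(self, tmp_path):
        store = make_store(tmp_path)
        store.insert_notes([Note(1, "a" * 120, "a" * 120)])
        store.insert_annotations(
            [annotation(start=1, end=3), annotation(start=50, end=52)],
            {1: SECTIONS},
        )
        ids = [r.note_nlp_id for r in store.fetch_rows()]
        assert ids == sorted(ids) and len(set(ids)) == 2

    def test_unknown_note_rejected(self, tmp_path):
        store = make_store(tmp_path)
        with pytest.raises(KeyError):
            store.insert_annotations([annotation(note_id=99)], {99: SECTIONS})

    def test_snippet_window_clipped(self, tmp_path):
        text = "0123456789" * 12
        store = make_store(tmp_path)
        store.insert_notes([Note(1, text, text)])
        store.insert_annotations(
            [annotation(start=2, end=4)], {1: SECTIONS}, snippet_window=5
        )
        (row,) = store.fetch_rows()
        assert row.snippet == text[0:9]


class TestRoundTrip:
    def test_concept_rows_field_identical(self, populated):
        store, notes, sections_by_note, annotations = populated
        rows = store.fetch_rows(nlp_system="gazetteer")
        assert len(rows) == len(annotations)
        for ann, row in zip(annotations, rows):
            assert row.note_id == ann.note_id
            assert row.span() == (ann.start, ann.end)
            assert row.lexical_variant == ann.lexical_variant
            assert row.note_nlp_concept_id == ann.cui
            # stored section agrees with a linear interval scan
            expected = next(
                s.section_id
                for s in sections_by_note[ann.note_id]
                if s.start <= ann.start < s.end
            )
            assert row.section_concept_id == expected
            assert store.semantic_type_of(ann.cui) == ann.semantic_type

    def test_rule_rows_roundtrip(self, tmp_path):
        text = "no evidence of coronary artery disease.\nhas asthma."
        note = Note(1, text, text)
        rules = DiseaseRules("coronary artery disease", ["coronary artery disease"])
        _, tables = classify_disease(text, rules)
        store = make_store(tmp_path)
        store.insert_notes([note])
        sections = [Section(0, "", 0, len(text))]
        assert store.insert_rule_matches(note, sections, tables) == 1
        (row,) = store.fetch_rows(nlp_system="rule_engine")
        start, end = row.span()
        assert text[start:end] == row.lexical_variant


def recount(rows, *, exclude_sections=(), allowed_types=None, semtype_of=None):
    """Independent in-memory recount of per-note concept frequencies."""
    counts = {}
    for r in rows:
        if r.nlp_system == "rule_engine":
            continue
        if r.section_concept_id in exclude_sections:
            continue
        if allowed_types is not None:
            st = semtype_of(r.note_nlp_concept_id)
            if st is None or st not in allowed_types:
                continue
        key = (r.note_id, r.note_nlp_concept_id)
        counts[key] = counts.get(key, 0) + 1
    return counts


class TestCuiCounts:
    def test_duplicate_cui_counted(self, tmp_path):
        store = make_store(tmp_path)
        store.insert_notes([Note(1, "b" * 120, "b" * 120)])
        store.insert_annotations(
            [annotation(start=1, end=3), annotation(start=5, end=7)], {1: SECTIONS}
        )
        assert store.query_cui_counts() == {(1, "C0010054"): 2}

    def test_family_history_exclusion(self, tmp_path):
        store = make_store(tmp_path)
        store.insert_notes([Note(1, "b" * 120, "b" * 120)])
        store.insert_annotations(
            [annotation(start=1, end=3), annotation(start=60, end=62)], {1: SECTIONS}
        )
        assert store.query_cui_counts(exclude_section_ids=[7]) == {(1, "C0010054"): 1}

    def test_semantic_type_exclusion(self, tmp_path):
        store = make_store(tmp_path)
        store.insert_notes([Note(1, "b" * 120, "b" * 120)])
        store.insert_annotations(
            [
                annotation(start=1, end=3, cui="C0000001", semtype="T999"),
                annotation(start=5, end=7, cui="C0000002", semtype="T047"),
            ],
            {1: SECTIONS},
        )
        counts = store.query_cui_counts(allowed_semantic_types={"T047"})
        assert counts == {(1, "C0000002"): 1}

    def test_counts_match_brute_force_recount(self, populated):
        store, *_ = populated
        rows = store.fetch_rows()
        configs = [
            {},
            {"exclude_section_ids": [4]},
            {"allowed_semantic_types": {"T047", "T121"}},
            {"exclude_section_ids": [4], "allowed_semantic_types": {"T047", "T121"}},
        ]
        for cfg in configs:
            expected = recount(
                rows,
                exclude_sections=tuple(cfg.get("exclude_section_ids", ())),
                allowed_types=cfg.get("allowed_semantic_types"),
                semtype_of=store.semantic_type_of,
            )
            assert store.query_cui_counts(**cfg) == expected


def test_insert_rows_validates_offsets(tmp_path):
    store = make_store(tmp_path)
    store.insert_notes([Note(1, "abc", "abc")])
    bad = NoteNlpRow(
        note_id=1, section_concept_id=0, snippet="", offset="5:2",
        lexical_variant="x", note_nlp_concept_id="C1", nlp_system="t", nlp_date_time="",
    )
    with pytest.raises(ValueError):
        store.insert_rows([bad])


def test_export_csv(tmp_path, populated):
    import csv

    store, *_ = populated
    n = store.export_note_nlp_csv(tmp_path / "out.csv")
    with open(tmp_path / "out.csv", newline="") as fh:
        records = list(csv.reader(fh))
    assert len(records) == n + 1  # snippets may contain newlines; csv handles it
    assert records[0][:3] == ["note_nlp_id", "note_id", "section_concept_id"]
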