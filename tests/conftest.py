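import logging

import pytest

from phenotext import prep, synth
from phenotext.concepts import tag_gazetteer
from phenotext.rules import DiseaseRules
from phenotext.store import CdmStore

logging.disable(logging.WARNING)


@pytest.fixture
def cad_rules() -> DiseaseRules:
    return DiseaseRules(
        name="coronary artery disease",
        aliases=["coronary artery disease"],
    )


@pytest.fixture(scope="session")
def small_corpus() -> synth.SynthCorpus:
    """40 notes over 6 diseases; shared by store/feature tests (read-only)."""
    config = synth.CorpusConfig(
        n_notes=40, seed=5, diseases=list(synth.DEFAULT_PROFILES)[:6]
    )
    return synth.generate_corpus(config)


def load_corpus_into_store(corpus: synth.SynthCorpus, store_path: str = ":memory:"):
    """Wire prep -> sections -> tagging -> store for a generated corpus."""
    notes = prep.prepare_notes(
        prep.split_records(corpus.master_text, corpus.config.end_tag),
        corpus.abbreviations,
    )
    sections_by_note = {
        n.note_id: prep.detect_sections(n.prepared_text, corpus.section_dictionary)
        for n in notes
    }
    store = CdmStore.init_schema(store_path, force=True)
    store.insert_notes(notes)
    annotations = [a for n in notes for a in tag_gazetteer(n, corpus.gazetteer)]
    store.insert_annotations(annotations, sections_by_note)
    return store, notes, sections_by_note, annotations


@pytest.fixture
def populated(small_corpus):
    store, notes, sections_by_note, annotations = load_corpus_into_store(small_corpus)
    yield store, notes, sections_by_note, annotations
    store.close()
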