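"""End-to-end orchestration: prep -> tag -> load -> rules -> train -> evaluate.

The pipeline wires the six components together: record splitting and
deabbreviation, section detection, concept tagging, NOTE_NLP persistence,
the rule cascade, bag-of-CUIs model training and the hybrid combiner,
finishing with pooled micro/macro evaluation per task on a held-out split.

Two classification modes mirror the portability/accuracy trade-off:

* ``ml_all`` — one model per disease over *all* task classes (most portable,
  no rules at prediction time);
* ``hybrid`` — models trained on major classes only, minor classes decided
  by the rule cascade (the accuracy/portability middle ground).

The six-iteration tuning protocol is the cross product of those two modes
with three feature-filter configurations (all CUIs, family history dropped,
family history dropped + fifteen clinical semantic types); see
:func:`iteration_configs`.
"""

from __future__ import annotations

import hashlib
import json
import logging
import random
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional

import numpy as np

from . import features as feat
from . import metrics, prep, rules as rules_mod
from .concepts import Gazetteer, read_gazetteer, tag_gazetteer
from .metrics import EvalReport
from .rules import RuleSet, read_ruleset, run_cascade
from .store import CdmStore
from .synth import CorpusConfig, SynthCorpus, generate_corpus, read_gold
from .types import (
    ABSENT,
    GoldLabel,
    MAJOR_CLASSES,
    NO_DECISION,
    Note,
    PRESENT,
    QUESTIONABLE,
    SectionDictionary,
    TASK_INTUITIVE,
    TASK_TEXTUAL,
    UNMENTIONED,
)

logger = logging.getLogger(__name__)

TASKS = (TASK_TEXTUAL, TASK_INTUITIVE)


@dataclass
class PipelineConfig:
    """File-based configuration for a full run."""

    corpus_path: str
    gazetteer_path: str
    ruleset_path: str
    sections_path: str
    abbreviations_path: str
    gold_path: str
    store_path: str = ":memory:"
    out_dir: Optional[str] = None
    tasks: tuple[str, ...] = TASKS
    classifier: str = "DT"
    mode: str = "hybrid"  # "hybrid" or "ml_all"
    drop_family_history: bool = False
    semantic_filter: bool = False
    rule_overrides_majors: bool = False
    train_frac: float = 0.6
    seed: int = 0

    def validate_paths(self) -> None:
        missing = [
            p
            for p in (
                self.corpus_path,
                self.gazetteer_path,
                self.ruleset_path,
                self.sections_path,
                self.abbreviations_path,
                self.gold_path,
            )
            if not Path(p).exists()
        ]
        if missing:
            raise FileNotFoundError(f"missing pipeline inputs: {missing}")


@dataclass
class PipelineResult:
    reports: dict[str, EvalReport]
    predictions: dict[tuple[int, str, str], str]
    rule_judgments: dict[tuple[int, str, str], str]
    chosen_params: dict[str, dict[str, dict]]
    test_note_ids: list[int]
    manifest: dict
    store: Optional[CdmStore] = None


def iteration_configs() -> list[dict]:
    """The six tuning iterations: {all-classes, majors-hybrid} x 3 filters."""
    filters = [
        {"drop_family_history": False, "semantic_filter": False},
        {"drop_family_history": True, "semantic_filter": False},
        {"drop_family_history": True, "semantic_filter": True},
    ]
    return [
        {"mode": mode, **f} for mode in ("ml_all", "hybrid") for f in filters
    ]


def split_train_test(
    note_ids: list[int], train_frac: float, seed: int
) -> tuple[list[int], list[int]]:
    """Seeded shuffled split; both halves returned sorted for determinism."""
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    shuffled = list(note_ids)
    random.Random(seed).shuffle(shuffled)
    cut = int(round(train_frac * len(shuffled)))
    return sorted(shuffled[:cut]), sorted(shuffled[cut:])


def run_pipeline(
    *,
    master_text: str,
    abbreviations: dict[str, str],
    section_dictionary: SectionDictionary,
    gazetteer: Gazetteer,
    ruleset: RuleSet,
    gold: list[GoldLabel],
    tasks: tuple[str, ...] = TASKS,
    classifier: str = "DT",
    mode: str = "hybrid",
    drop_family_history: bool = False,
    semantic_filter: bool = False,
    rule_overrides_majors: bool = False,
    train_frac: float = 0.6,
    seed: int = 0,
    store_path: str = ":memory:",
    out_dir: Optional[str | Path] = None,
    end_tag: str = prep.DEFAULT_END_TAG,
) -> PipelineResult:
    """Run every stage on in-memory artifacts and return the evaluation."""
    if mode not in ("hybrid", "ml_all"):
        raise ValueError(f"unknown mode {mode!r}")

    # a) prepare: split the master file, deabbreviate each record
    notes = prep.prepare_notes(prep.split_records(master_text, end_tag), abbreviations)
    if not notes:
        raise ValueError("master file yielded no records")
    logger.info("prepared %d notes", len(notes))

    # b) section boundaries
    sections_by_note = {
        n.note_id: prep.detect_sections(n.prepared_text, section_dictionary)
        for n in notes
    }

    # c) concept annotation + NOTE_NLP persistence
    store = CdmStore.init_schema(store_path, force=True)
    store.insert_notes(notes)
    annotations = [a for n in notes for a in tag_gazetteer(n, gazetteer)]
    store.insert_annotations(annotations, sections_by_note)
    logger.info("stored %d concept annotations", len(annotations))

    # d) rule cascade per (note, disease); matches persisted as NOTE_NLP rows
    rule_judgments: dict[tuple[int, str, str], str] = {}
    for note in notes:
        for disease, drules in ruleset.diseases.items():
            tables, _ = run_cascade(note.prepared_text, drules)
            textual, intuitive = _judgments_from_tables(tables)
            rule_judgments[(note.note_id, disease, TASK_TEXTUAL)] = textual
            rule_judgments[(note.note_id, disease, TASK_INTUITIVE)] = intuitive
            store.insert_rule_matches(note, sections_by_note[note.note_id], tables)

    # e) features + models, f) tuned per-disease training, then evaluation
    fh_id = section_dictionary.family_history_id
    matrix = feat.build_feature_matrix(
        store,
        drop_family_history=drop_family_history,
        family_history_section_id=fh_id,
        semantic_filter=feat.CLINICAL_SEMANTIC_TYPES if semantic_filter else None,
    )
    train_ids, test_ids = split_train_test([n.note_id for n in notes], train_frac, seed)

    gold_by_key = {g.key: g.judgment for g in gold}
    diseases = sorted(ruleset.diseases)
    predictions: dict[tuple[int, str, str], str] = {}
    chosen_params: dict[str, dict[str, dict]] = {t: {} for t in tasks}

    for task in tasks:
        for disease in diseases:
            preds, params = _classify_one_disease(
                task=task,
                disease=disease,
                matrix=matrix,
                gold_by_key=gold_by_key,
                rule_judgments=rule_judgments,
                train_ids=train_ids,
                test_ids=test_ids,
                classifier=classifier,
                mode=mode,
                rule_overrides_majors=rule_overrides_majors,
                seed=seed,
            )
            predictions.update(preds)
            chosen_params[task][disease] = params

    reports = {}
    for task in tasks:
        test_gold = [
            g for g in gold if g.task == task and g.note_id in set(test_ids)
        ]
        reports[task] = metrics.evaluate(test_gold, predictions, task)

    manifest = _manifest(
        classifier=classifier,
        mode=mode,
        drop_family_history=drop_family_history,
        semantic_filter=semantic_filter,
        rule_overrides_majors=rule_overrides_majors,
        train_frac=train_frac,
        seed=seed,
        n_notes=len(notes),
        diseases=diseases,
        tasks=list(tasks),
    )
    result = PipelineResult(
        reports=reports,
        predictions=predictions,
        rule_judgments=rule_judgments,
        chosen_params=chosen_params,
        test_note_ids=test_ids,
        manifest=manifest,
        store=store,
    )
    if out_dir is not None:
        _write_outputs(result, matrix, Path(out_dir))
    return result


def _judgments_from_tables(tables) -> tuple[str, str]:
    if tables.questionable:
        return QUESTIONABLE, QUESTIONABLE
    if tables.absent:
        return ABSENT, ABSENT
    if tables.present:
        return PRESENT, PRESENT
    return UNMENTIONED, NO_DECISION


def _classify_one_disease(
    *,
    task: str,
    disease: str,
    matrix: feat.FeatureMatrix,
    gold_by_key: dict,
    rule_judgments: dict,
    train_ids: list[int],
    test_ids: list[int],
    classifier: str,
    mode: str,
    rule_overrides_majors: bool,
    seed: int,
) -> tuple[dict[tuple[int, str, str], str], dict]:
    """Train one disease's model and predict every test note."""
    majors = MAJOR_CLASSES[task]
    if mode == "hybrid":
        fit_ids = [
            nid for nid in train_ids if gold_by_key.get((nid, disease, task)) in majors
        ]
    else:
        fit_ids = [nid for nid in train_ids if (nid, disease, task) in gold_by_key]
    y_fit = [gold_by_key[(nid, disease, task)] for nid in fit_ids]

    model, params = None, {}
    fallback: Optional[str] = None
    if len(set(y_fit)) >= 2:
        try:
            model, params = feat.train_eval(
                matrix.rows_for(fit_ids), y_fit, classifier, seed=seed
            )
        except ValueError as exc:  # a class too thin for 3-fold CV
            logger.warning("%s/%s: %s; falling back to majority class", task, disease, exc)
    if model is None:
        # degenerate training data: predict the most frequent training label
        # (ties broken lexicographically for determinism)
        if y_fit:
            counts = {label: y_fit.count(label) for label in sorted(set(y_fit))}
            fallback = max(counts, key=lambda l: (counts[l], l))
        else:
            fallback = majors[0] if mode == "hybrid" else PRESENT

    if model is not None:
        model_preds = dict(zip(test_ids, model.predict(matrix.rows_for(test_ids))))
    else:
        model_preds = {nid: fallback for nid in test_ids}

    preds = {}
    for nid in test_ids:
        key = (nid, disease, task)
        if mode == "ml_all":
            preds[key] = str(model_preds[nid])
        else:
            preds[key] = feat.predict_hybrid(
                rule_judgments[key],
                str(model_preds[nid]),
                task,
                rule_overrides_majors=rule_overrides_majors,
            )
    return preds, params


def _manifest(**kw) -> dict:
    blob = json.dumps(kw, sort_keys=True)
    return {"config": kw, "config_hash": hashlib.sha256(blob.encode()).hexdigest()}


def _write_outputs(result: PipelineResult, matrix: feat.FeatureMatrix, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    (out / "manifest.json").write_text(
        json.dumps(result.manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    report_doc = {task: r.to_dict() for task, r in result.reports.items()}
    (out / "report.json").write_text(
        json.dumps(report_doc, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    (out / "chosen_params.json").write_text(
        json.dumps(result.chosen_params, indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    matrix.export_mtx(out / "features")
    if result.store is not None:
        result.store.export_note_nlp_csv(out / "note_nlp.csv")


def run_all(config: PipelineConfig) -> PipelineResult:
    """File-based entry point: load artifacts, run everything."""
    config.validate_paths()
    return run_pipeline(
        master_text=Path(config.corpus_path).read_text(encoding="utf-8"),
        abbreviations=prep.read_abbreviations(config.abbreviations_path),
        section_dictionary=prep.read_section_dictionary(config.sections_path),
        gazetteer=read_gazetteer(config.gazetteer_path),
        ruleset=read_ruleset(config.ruleset_path),
        gold=read_gold(config.gold_path),
        tasks=config.tasks,
        classifier=config.classifier,
        mode=config.mode,
        drop_family_history=config.drop_family_history,
        semantic_filter=config.semantic_filter,
        rule_overrides_majors=config.rule_overrides_majors,
        train_frac=config.train_frac,
        seed=config.seed,
        store_path=config.store_path,
        out_dir=config.out_dir,
    )


def run_synthetic(
    corpus_config: CorpusConfig, **pipeline_kwargs
) -> tuple[SynthCorpus, PipelineResult]:
    """Generate a synthetic corpus and run the full pipeline on it."""
    corpus = generate_corpus(corpus_config)
    result = run_pipeline(
        master_text=corpus.master_text,
        abbreviations=corpus.abbreviations,
        section_dictionary=corpus.section_dictionary,
        gazetteer=corpus.gazetteer,
        ruleset=corpus.ruleset,
        gold=corpus.gold,
        end_tag=corpus_config.end_tag,
        **pipeline_kwargs,
    )
    return corpus, result
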