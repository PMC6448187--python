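"""Bag-of-CUIs features, grid-searched classifiers, and the hybrid combiner.

Each note is represented by the occurrence count of every concept (CUI) the
tagger found in it.  Two feature filters mirror common clinical practice:
dropping concepts found in the family-history section (mentions of a
relative's disease mislead patient-level phenotyping) and restricting
features to fifteen clinically relevant semantic types.

Classes with too few examples cannot support a statistical model, so the
hybrid strategy trains each model on the task's *major* classes only
(intuitive: Present/Absent; textual: Present/Unmentioned) and delegates the
*minor* classes (intuitive: Questionable; textual: Questionable/Absent) to
the rule cascade.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .store import CdmStore
from .types import MAJOR_CLASSES, MINOR_CLASSES, NO_DECISION

#: Fifteen semantic types considered most relevant to clinical phenotyping
#: (anatomy, disorders, findings, lab/diagnostic/therapeutic procedures,
#: drugs and signs/symptoms).
CLINICAL_SEMANTIC_TYPES = frozenset(
    {
        "T017", "T022", "T023", "T033", "T034",
        "T047", "T048", "T049", "T059", "T060",
        "T061", "T121", "T122", "T123", "T184",
    }
)

#: Grid-search spaces per classifier.
PARAM_GRIDS: dict[str, dict[str, list]] = {
    "LR": {"C": [0.01, 0.1, 1, 10, 100]},
    "SVM": {"C": [0.01, 0.1, 1, 10, 100], "kernel": ["linear", "rbf"]},
    "DT": {"criterion": ["gini", "entropy"]},
    "RF": {"n_estimators": [5, 10, 30, 50, 80, 100], "criterion": ["gini", "entropy"]},
}

CLASSIFIER_NAMES = tuple(PARAM_GRIDS)


@dataclass
class FeatureMatrix:
    """Per-note CUI counts: rows follow ``note_ids``, columns ``cuis`` (sorted)."""

    note_ids: list[int]
    cuis: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.note_ids), len(self.cuis)):
            raise ValueError("counts shape inconsistent with indices")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if list(self.cuis) != sorted(self.cuis):
            raise ValueError("CUI columns must be sorted")

    def rows_for(self, note_ids: Sequence[int]) -> np.ndarray:
        index = {nid: i for i, nid in enumerate(self.note_ids)}
        return self.counts[[index[nid] for nid in note_ids]]

    def export_mtx(self, prefix: str | Path) -> None:
        """Write counts as MatrixMarket plus row/column index TSVs."""
        from scipy import io as spio
        from scipy import sparse

        prefix = Path(prefix)
        spio.mmwrite(str(prefix.with_suffix(".mtx")), sparse.csr_matrix(self.counts))
        prefix.with_name(prefix.name + "_notes.tsv").write_text(
            "\n".join(str(n) for n in self.note_ids) + "\n", encoding="utf-8"
        )
        prefix.with_name(prefix.name + "_cuis.tsv").write_text(
            "\n".join(self.cuis) + "\n", encoding="utf-8"
        )


def build_feature_matrix(
    store: CdmStore,
    *,
    drop_family_history: bool = False,
    family_history_section_id: Optional[int] = None,
    semantic_filter: Optional[frozenset[str] | set[str]] = None,
) -> FeatureMatrix:
    """CUI-count matrix over every note in the store.

    The row set is all notes (a note whose annotations are all filtered away
    keeps an all-zero row), so train/test splits stay aligned regardless of
    filter configuration.
    """
    if drop_family_history and family_history_section_id is None:
        raise ValueError("drop_family_history requires family_history_section_id")
    exclude = [family_history_section_id] if drop_family_history else None
    counts = store.query_cui_counts(
        exclude_section_ids=exclude,
        allowed_semantic_types=semantic_filter,
    )
    note_ids = store.note_ids()
    cuis = sorted({cui for (_, cui) in counts})
    matrix = np.zeros((len(note_ids), len(cuis)), dtype=int)
    row_of = {nid: i for i, nid in enumerate(note_ids)}
    col_of = {cui: j for j, cui in enumerate(cuis)}
    for (nid, cui), n in counts.items():
        matrix[row_of[nid], col_of[cui]] = n
    return FeatureMatrix(note_ids=note_ids, cuis=cuis, counts=matrix)


def _make_estimator(classifier: str, seed: int):
    if classifier == "LR":
        return LogisticRegression(max_iter=2000, random_state=seed)
    if classifier == "SVM":
        return SVC(random_state=seed)
    if classifier == "DT":
        return DecisionTreeClassifier(random_state=seed)
    if classifier == "RF":
        return RandomForestClassifier(random_state=seed)
    raise ValueError(f"unknown classifier {classifier!r}; pick from {CLASSIFIER_NAMES}")


def train_eval(
    X: np.ndarray,
    y: Sequence[str],
    classifier: str,
    *,
    grid: Optional[dict[str, list]] = None,
    seed: int = 0,
    return_search: bool = False,
) -> tuple:
    """3-fold cross-validated grid search, refit on all training data.

    Scoring is micro-averaged F (the headline metric); folds are stratified,
    shuffled once under the seed, so repeated runs with the same seed choose
    identical parameters.  A class with fewer than 3 samples cannot be
    stratified into 3 folds: that is what the hybrid rule path is for, and
    the error says so.
    """
    y = np.asarray(y)
    labels, counts = np.unique(y, return_counts=True)
    thin = [f"{l} ({c})" for l, c in zip(labels, counts) if c < 3]
    if thin:
        raise ValueError(
            "classes too small for 3-fold CV: " + ", ".join(thin)
            + "; route minor classes through the rule cascade (hybrid path)"
        )
    if grid is None:
        if classifier not in PARAM_GRIDS:
            raise ValueError(
                f"unknown classifier {classifier!r}; pick from {CLASSIFIER_NAMES}"
            )
        grid = PARAM_GRIDS[classifier]
    cv = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
    search = GridSearchCV(
        _make_estimator(classifier, seed),
        param_grid=grid,
        scoring="f1_micro",
        cv=cv,
        refit=True,
    )
    search.fit(np.asarray(X), y)
    if return_search:
        # the fitted search exposes cv_results_, i.e. every configuration tried
        return search.best_estimator_, dict(search.best_params_), search
    return search.best_estimator_, dict(search.best_params_)


def grid_size(classifier: str, grid: Optional[dict[str, list]] = None) -> int:
    grid = PARAM_GRIDS[classifier] if grid is None else grid
    n = 1
    for values in grid.values():
        n *= len(values)
    return n


def predict_hybrid(
    rule_judgment: str,
    model_judgment: Optional[str],
    task: str,
    *,
    rule_overrides_majors: bool = False,
) -> str:
    """Combine the rule cascade and the major-class model into one judgment.

    Minor-class rule decisions always win (they are the only source of those
    labels).  For major classes the model decides by default; with
    ``rule_overrides_majors`` a major-class rule judgment wins instead.  The
    rule cascade's no-decision marker (intuitive task, nothing matched)
    always defers to the model.
    """
    minors = MINOR_CLASSES[task]
    majors = MAJOR_CLASSES[task]
    if rule_judgment in minors:
        return rule_judgment
    if rule_overrides_majors and rule_judgment in majors:
        return rule_judgment
    if model_judgment is None:
        if rule_judgment == NO_DECISION:
            raise ValueError("no rule decision and no model available")
        return rule_judgment
    if model_judgment not in majors:
        raise ValueError(
            f"model predicted {model_judgment!r}, not a major class of {task}"
        )
    return model_judgment


def save_model_sidecar(path: str | Path, classifier: str, params: dict, seed: int) -> None:
    """Record chosen hyperparameters next to a serialized model."""
    Path(path).write_text(
        json.dumps(
            {"classifier": classifier, "best_params": params, "seed": seed},
            indent=2,
            sort_keys=True,
        )
        + "\n",
        encoding="utf-8",
    )
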