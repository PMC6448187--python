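"""Micro- and macro-averaged precision, recall and F-measure.

Decisions are pooled over all (note, disease) pairs of a task into one
contingency table.  Micro averaging pools true positives, false positives
and false negatives over classes before computing P/R/F; macro averaging
computes per-class P/R/F and takes their unweighted mean over classes with
nonzero gold support (classes never appearing in gold are excluded by
default, configurable).  In the single-label multiclass setting micro-P,
micro-R and micro-F coincide.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .types import GoldLabel


@dataclass
class EvalReport:
    task: str
    p_micro: float
    r_micro: float
    f_micro: float
    p_macro: float
    r_macro: float
    f_macro: float
    per_class: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "p_micro": self.p_micro,
            "r_micro": self.r_micro,
            "f_micro": self.f_micro,
            "p_macro": self.p_macro,
            "r_macro": self.r_macro,
            "f_macro": self.f_macro,
            "per_class": self.per_class,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text

    def to_table(self) -> str:
        """Aligned text table: P-Micro P-Macro R-Micro R-Macro F-Micro F-Macro."""
        header = f"{'task':<12}{'P-Micro':>9}{'P-Macro':>9}{'R-Micro':>9}{'R-Macro':>9}{'F-Micro':>9}{'F-Macro':>9}"
        row = (
            f"{self.task:<12}{self.p_micro:>9.4f}{self.p_macro:>9.4f}"
            f"{self.r_micro:>9.4f}{self.r_macro:>9.4f}"
            f"{self.f_micro:>9.4f}{self.f_macro:>9.4f}"
        )
        return header + "\n" + row


def confusion(
    gold: list[GoldLabel], pred: dict[tuple[int, str, str], str]
) -> pd.DataFrame:
    """Contingency table over the task's label set: rows gold, columns predicted.

    ``pred`` maps (note_id, disease, task) keys to predicted judgments; a
    missing prediction for any gold key is an error listing the keys.
    """
    if not gold:
        raise ValueError("empty gold label list")
    missing = [g.key for g in gold if g.key not in pred]
    if missing:
        raise KeyError(f"missing predictions for {len(missing)} gold keys: {missing[:5]}")
    labels = sorted({g.judgment for g in gold} | {pred[g.key] for g in gold})
    table = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for g in gold:
        table.loc[g.judgment, pred[g.key]] += 1
    table.index.name = "gold"
    table.columns.name = "predicted"
    return table


def _prf(tp: float, fp: float, fn: float) -> tuple[float, float, float]:
    p = tp / (tp + fp) if tp + fp > 0 else 0.0
    r = tp / (tp + fn) if tp + fn > 0 else 0.0
    f = 2 * p * r / (p + r) if p + r > 0 else 0.0
    return p, r, f


def micro_macro(
    table: pd.DataFrame, task: str = "", *, macro_over_supported_only: bool = True
) -> EvalReport:
    """Compute the six headline metrics from a contingency table."""
    if table.empty:
        raise ValueError("empty confusion table")
    classes = list(table.index)
    tp = {c: int(table.loc[c, c]) for c in classes}
    fp = {c: int(table[c].sum()) - tp[c] for c in classes}
    fn = {c: int(table.loc[c].sum()) - tp[c] for c in classes}

    p_micro, r_micro, f_micro = _prf(
        sum(tp.values()), sum(fp.values()), sum(fn.values())
    )

    per_class = {}
    for c in classes:
        p, r, f = _prf(tp[c], fp[c], fn[c])
        per_class[c] = {
            "precision": p,
            "recall": r,
            "f_measure": f,
            "support": int(table.loc[c].sum()),
        }

    macro_classes = [
        c for c in classes
        if not macro_over_supported_only or per_class[c]["support"] > 0
    ]
    if not macro_classes:
        raise ValueError("no class has gold support")
    n = len(macro_classes)
    p_macro = sum(per_class[c]["precision"] for c in macro_classes) / n
    r_macro = sum(per_class[c]["recall"] for c in macro_classes) / n
    f_macro = sum(per_class[c]["f_measure"] for c in macro_classes) / n

    return EvalReport(
        task=task,
        p_micro=p_micro,
        r_micro=r_micro,
        f_micro=f_micro,
        p_macro=p_macro,
        r_macro=r_macro,
        f_macro=f_macro,
        per_class=per_class,
    )


def evaluate(
    gold: list[GoldLabel], pred: dict[tuple[int, str, str], str], task: str
) -> EvalReport:
    """Pool decisions across diseases for one task and compute all metrics."""
    task_gold = [g for g in gold if g.task == task]
    return micro_macro(confusion(task_gold, pred), task=task)
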