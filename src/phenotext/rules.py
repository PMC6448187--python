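"""Disease rule cascade with original-document offset preservation.

Per disease, a cascade of three stages runs over a *working copy* of the
note text: Questionable (uncertainty contexts) first, then Absent (negation
contexts), then Present (bare alias mentions).  Each stage records matches,
then *blank-fills* the matched span — replaces it with spaces of the same
length — before the next stage runs.  Because the working text never changes
length, every recorded span is simultaneously valid in the original
document: slicing the untouched original at a recorded position always
yields the recorded surface text.  This is what lets rule matches be
persisted as stand-off NOTE_NLP annotations.

The final judgment follows strict precedence Questionable > Absent >
Present; a disease with no match at all is Unmentioned on the textual task
and a no-decision marker on the intuitive task (where Unmentioned is not a
legal class and the statistical model must decide).

Context patterns are configuration: uncertainty/negation trigger inventories
vary by site and ship here as editable YAML defaults, not as fixed truth.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .types import (
    ABSENT,
    MatchTables,
    NO_DECISION,
    NoteNlpRow,
    PRESENT,
    QUESTIONABLE,
    RuleMatch,
    TASK_INTUITIVE,
    TASK_TEXTUAL,
    UNMENTIONED,
)

RULE_SYSTEM_NAME = "rule_engine"

#: Default uncertainty triggers (regex fragments).
DEFAULT_QUESTIONABLE_CONTEXTS = [
    "possible",
    "probable",
    "question of",
    "rule out",
    "r/o",
    r"\?",
]
#: Default negation triggers (regex fragments).
DEFAULT_ABSENT_CONTEXTS = [
    "no evidence of",
    "denies",
    "negative for",
    "ruled out",
    "without",
]

#: A context phrase may not cross a clause boundary.
_GAP = r"[^.;:\n?]{0,60}?"


@dataclass
class DiseaseRules:
    """Alias and context patterns for one disease."""

    name: str
    aliases: list[str]
    questionable_contexts: list[str] = field(
        default_factory=lambda: list(DEFAULT_QUESTIONABLE_CONTEXTS)
    )
    absent_contexts: list[str] = field(
        default_factory=lambda: list(DEFAULT_ABSENT_CONTEXTS)
    )

    def __post_init__(self) -> None:
        if not self.aliases:
            raise ValueError(f"disease {self.name!r} needs at least one alias")
        for pattern in [*self.aliases, *self.questionable_contexts, *self.absent_contexts]:
            re.compile(pattern)  # fail fast on uncompilable configuration


@dataclass
class RuleSet:
    """Rules for every phenotype under study."""

    diseases: dict[str, DiseaseRules]

    def __getitem__(self, name: str) -> DiseaseRules:
        return self.diseases[name]


def blank_fill(text: str, span: tuple[int, int]) -> str:
    """Replace ``text[span]`` with spaces, preserving length.

    The same-length replacement is the whole trick: later cascade stages
    search the blanked text yet report offsets valid in the original.
    """
    start, end = span
    if not (0 <= start <= end <= len(text)):
        raise ValueError(f"span [{start}, {end}) out of bounds for length {len(text)}")
    return text[:start] + " " * (end - start) + text[end:]


def _anchored(pattern: str) -> str:
    # Word-boundary anchors only where the fragment starts/ends with a word
    # character, so punctuation triggers like "\?" still match after a word.
    prefix = r"(?<!\w)" if pattern[:1].isalnum() else ""
    suffix = r"(?!\w)" if pattern[-1:].isalnum() else ""
    return f"{prefix}(?:{pattern}){suffix}"


def _alias_group(aliases: list[str]) -> str:
    ordered = sorted(aliases, key=len, reverse=True)  # longest alternative first
    return "(?P<alias>" + "|".join(_anchored(a) for a in ordered) + ")"


def _context_patterns(triggers: list[str], aliases: list[str]) -> list[re.Pattern]:
    """Compile directed trigger/alias context patterns for one stage.

    For each trigger both orders are generated — trigger before alias
    ("no evidence of CAD") and alias before trigger ("CAD was ruled out") —
    with a lazy same-clause gap in between.  The full pattern match is the
    context phrase; the named group ``alias`` is the disease mention.
    """
    alias = _alias_group(aliases)
    patterns = []
    for trigger in triggers:
        t = _anchored(trigger)
        patterns.append(re.compile(t + _GAP + alias, re.IGNORECASE))
        patterns.append(re.compile(alias + _GAP + t, re.IGNORECASE))
    return patterns


def _context_stage(
    working: str,
    original: str,
    disease: str,
    category: str,
    patterns: list[re.Pattern],
) -> tuple[list[RuleMatch], str]:
    """Run one Q or A stage: record context matches, blank-fill each."""
    matches = []
    for pattern in patterns:
        while True:
            m = pattern.search(working)
            if m is None:
                break
            sen_span, dis_span = m.span(), m.span("alias")
            matches.append(
                RuleMatch(
                    disease=disease,
                    dis_alias=original[dis_span[0]:dis_span[1]],
                    dis_pos=dis_span,
                    category=category,
                    sentence=original[sen_span[0]:sen_span[1]],
                    sen_pos=sen_span,
                )
            )
            working = blank_fill(working, sen_span)
    return matches, working


def run_cascade(text: str, rules: DiseaseRules) -> tuple[MatchTables, str]:
    """Run the full Q -> A -> P cascade for one disease over one document.

    Returns the three match tables (offsets valid in ``text``, which is
    never modified) and the final working text, whose length always equals
    ``len(text)``.
    """
    tables = MatchTables()
    working = text

    tables.questionable, working = _context_stage(
        working, text, rules.name, QUESTIONABLE,
        _context_patterns(rules.questionable_contexts, rules.aliases),
    )
    tables.absent, working = _context_stage(
        working, text, rules.name, ABSENT,
        _context_patterns(rules.absent_contexts, rules.aliases),
    )

    alias_pattern = re.compile(_alias_group(rules.aliases), re.IGNORECASE)
    present_spans = [m.span() for m in alias_pattern.finditer(working)]
    for span in present_spans:
        tables.present.append(
            RuleMatch(
                disease=rules.name,
                dis_alias=text[span[0]:span[1]],
                dis_pos=span,
                category=PRESENT,
            )
        )
        working = blank_fill(working, span)
    return tables, working


def classify_disease(
    note_text: str, rules: DiseaseRules, task: str = TASK_TEXTUAL
) -> tuple[str, MatchTables]:
    """Cascade judgment for one disease with strict Q > A > P precedence."""
    if task not in (TASK_TEXTUAL, TASK_INTUITIVE):
        raise ValueError(f"unknown task: {task!r}")
    tables, _ = run_cascade(note_text, rules)
    if tables.questionable:
        return QUESTIONABLE, tables
    if tables.absent:
        return ABSENT, tables
    if tables.present:
        return PRESENT, tables
    return (UNMENTIONED if task == TASK_TEXTUAL else NO_DECISION), tables


def export_matches(
    tables: MatchTables,
    note_id: int,
    note_text: str,
    *,
    window: int = 50,
    nlp_date_time: str = "",
    section_for: "callable | None" = None,
) -> list[NoteNlpRow]:
    """Convert match tables to NOTE_NLP rows.

    ``offset`` comes from ``dis_pos`` and ``lexical_variant`` from
    ``dis_alias``; the snippet is the context sentence for Questionable and
    Absent matches and a clipped +/-``window`` character window around the
    alias for Present matches.  ``section_for`` maps a start offset to a
    section concept id (the store supplies it); without it, rows carry
    section id 0.  Span invariants are re-verified against the original
    text before export.
    """
    rows = []
    for match in tables.all_matches():
        s, e = match.dis_pos
        if note_text[s:e] != match.dis_alias:
            raise ValueError(
                f"span integrity violated: text[{s}:{e}] != alias {match.dis_alias!r}"
            )
        if match.category in (QUESTIONABLE, ABSENT):
            ss, se = match.sen_pos
            if note_text[ss:se] != match.sentence:
                raise ValueError(
                    f"span integrity violated: text[{ss}:{se}] != recorded sentence"
                )
            snippet = match.sentence
        else:
            snippet = note_text[max(0, s - window):min(len(note_text), e + window)]
        rows.append(
            NoteNlpRow(
                note_id=note_id,
                section_concept_id=section_for(s) if section_for else 0,
                snippet=snippet,
                offset=f"{s}:{e}",
                lexical_variant=match.dis_alias,
                note_nlp_concept_id=f"{match.disease}:{match.category}",
                nlp_system=RULE_SYSTEM_NAME,
                nlp_date_time=nlp_date_time,
            )
        )
    return rows


# Configuration I/O -----------------------------------------------------------

def default_ruleset(diseases: dict[str, list[str]]) -> RuleSet:
    """Build a ruleset from disease -> aliases with the default contexts."""
    return RuleSet(
        diseases={
            name: DiseaseRules(name=name, aliases=aliases)
            for name, aliases in diseases.items()
        }
    )


def read_ruleset(path: str | Path) -> RuleSet:
    """Read a ruleset from YAML.

    Layout: optional ``defaults`` mapping with ``questionable_contexts`` /
    ``absent_contexts``, and a ``diseases`` list of mappings with ``name``,
    ``aliases`` and optional per-disease context overrides.
    """
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    defaults = raw.get("defaults", {})
    q_default = defaults.get("questionable_contexts", DEFAULT_QUESTIONABLE_CONTEXTS)
    a_default = defaults.get("absent_contexts", DEFAULT_ABSENT_CONTEXTS)
    diseases = {}
    for item in raw["diseases"]:
        diseases[item["name"]] = DiseaseRules(
            name=item["name"],
            aliases=list(item["aliases"]),
            questionable_contexts=list(item.get("questionable_contexts", q_default)),
            absent_contexts=list(item.get("absent_contexts", a_default)),
        )
    return RuleSet(diseases=diseases)


def write_ruleset(ruleset: RuleSet, path: str | Path) -> None:
    doc = {
        "defaults": {
            "questionable_contexts": DEFAULT_QUESTIONABLE_CONTEXTS,
            "absent_contexts": DEFAULT_ABSENT_CONTEXTS,
        },
        "diseases": [
            {
                "name": d.name,
                "aliases": d.aliases,
                "questionable_contexts": d.questionable_contexts,
                "absent_contexts": d.absent_contexts,
            }
            for d in ruleset.diseases.values()
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")


def write_match_tables_csv(tables: MatchTables, out_dir: str | Path, note_id: int) -> None:
    """Dump the three match tables as CSVs (one per category) for one note."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, matches in (
        ("questionable", tables.questionable),
        ("absent", tables.absent),
        ("present", tables.present),
    ):
        with open(out / f"{note_id}_{name}.csv", "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["disease", "dis_alias", "dis_pos", "sentence", "sen_pos"])
            for m in matches:
                writer.writerow(
                    [
                        m.disease,
                        m.dis_alias,
                        f"{m.dis_pos[0]}:{m.dis_pos[1]}",
                        m.sentence or "",
                        f"{m.sen_pos[0]}:{m.sen_pos[1]}" if m.sen_pos else "",
                    ]
                )
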