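"""Core domain objects shared across the pipeline.

All character offsets in this package are 0-based, half-open ``[start, end)``
into the *prepared* (deabbreviated) note text unless a field explicitly says
otherwise.  Annotations are stand-off: the source text is never mutated, and
every annotation references it by offsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

# Judgment labels -----------------------------------------------------------

PRESENT = "Present"
ABSENT = "Absent"
QUESTIONABLE = "Questionable"
UNMENTIONED = "Unmentioned"

#: Marker emitted by the rule cascade on the intuitive task when no rule
#: fires; "Unmentioned" is not a legal intuitive class, so the hybrid
#: combiner must consult the statistical model instead.
NO_DECISION = "NoDecision"

TASK_TEXTUAL = "textual"
TASK_INTUITIVE = "intuitive"

#: Legal gold/prediction labels per task.
TASK_LABELS = {
    TASK_TEXTUAL: (PRESENT, ABSENT, QUESTIONABLE, UNMENTIONED),
    TASK_INTUITIVE: (PRESENT, ABSENT, QUESTIONABLE),
}

#: Major (model-decided) and minor (rule-decided) classes per task.  Minor
#: classes have too few examples for a statistical model, so their labels
#: come from the rule cascade; the model is trained on majors only.
MAJOR_CLASSES = {
    TASK_INTUITIVE: (PRESENT, ABSENT),
    TASK_TEXTUAL: (PRESENT, UNMENTIONED),
}
MINOR_CLASSES = {
    TASK_INTUITIVE: (QUESTIONABLE,),
    TASK_TEXTUAL: (QUESTIONABLE, ABSENT),
}


@dataclass(frozen=True)
class Note:
    """One patient record.

    ``raw_text`` is the record as found in the master file and is immutable;
    ``prepared_text`` is the deabbreviated text that all downstream offsets
    refer to.
    """

    note_id: int
    raw_text: str
    prepared_text: str


@dataclass(frozen=True)
class Section:
    """A detected section heading with its half-open character span."""

    section_id: int
    heading: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start <= self.end):
            raise ValueError(f"invalid section span [{self.start}, {self.end})")

    def contains(self, offset: int) -> bool:
        return self.start <= offset < self.end


@dataclass
class SectionDictionary:
    """Heading strings mapped to section concept ids.

    ``entries`` maps heading -> section_concept_id.  At most one heading may
    be flagged as the family-history section; its id is used by the
    family-history feature filter.
    """

    entries: dict[str, int]
    family_history_id: Optional[int] = None

    def __post_init__(self) -> None:
        if any(not h for h in self.entries):
            raise ValueError("section headings must be non-empty")
        if len(set(self.entries.values())) != len(self.entries):
            raise ValueError("section concept ids must be unique")
        if 0 in self.entries.values():
            raise ValueError("section id 0 is reserved for the preamble")
        if (
            self.family_history_id is not None
            and self.family_history_id not in self.entries.values()
        ):
            raise ValueError("family_history_id not among section ids")


@dataclass(frozen=True)
class ConceptAnnotation:
    """A concept mention: CUI + semantic type + span + surface text."""

    note_id: int
    cui: str
    semantic_type: str
    start: int
    end: int
    lexical_variant: str
    source_system: str = "gazetteer"

    def __post_init__(self) -> None:
        if not (self.cui.startswith("C") and self.cui[1:].isdigit()):
            raise ValueError(f"malformed CUI: {self.cui!r}")
        if not (
            self.semantic_type.startswith("T")
            and self.semantic_type[1:].isdigit()
            and len(self.semantic_type) == 4
        ):
            raise ValueError(f"malformed semantic type: {self.semantic_type!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")


@dataclass(frozen=True)
class RuleMatch:
    """One cascade match, with offsets into the ORIGINAL document.

    ``dis_pos`` is the span of the matched disease alias; for Questionable
    and Absent matches ``sen_pos``/``sentence`` carry the containing context
    phrase, and ``dis_pos`` is nested within ``sen_pos``.
    """

    disease: str
    dis_alias: str
    dis_pos: tuple[int, int]
    category: str
    sentence: Optional[str] = None
    sen_pos: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.category not in (QUESTIONABLE, ABSENT, PRESENT):
            raise ValueError(f"bad category: {self.category!r}")
        if self.category in (QUESTIONABLE, ABSENT):
            if self.sentence is None or self.sen_pos is None:
                raise ValueError(f"{self.category} match requires sentence context")
            if not (self.sen_pos[0] <= self.dis_pos[0] and self.dis_pos[1] <= self.sen_pos[1]):
                raise ValueError("dis_pos must be nested within sen_pos")


@dataclass
class MatchTables:
    """The three per-document match tables, one per cascade category."""

    questionable: list[RuleMatch] = field(default_factory=list)
    absent: list[RuleMatch] = field(default_factory=list)
    present: list[RuleMatch] = field(default_factory=list)

    def all_matches(self) -> list[RuleMatch]:
        return [*self.questionable, *self.absent, *self.present]


@dataclass(frozen=True)
class NoteNlpRow:
    """One OMOP CDM NOTE_NLP record.

    ``offset`` serializes the span as ``"start:end"`` (0-based half-open);
    ``note_nlp_concept_id`` holds the CUI for concept annotations or a
    ``disease:category`` code for rule matches.
    """

    note_id: int
    section_concept_id: int
    snippet: str
    offset: str
    lexical_variant: str
    note_nlp_concept_id: str
    nlp_system: str
    nlp_date_time: str
    note_nlp_id: Optional[int] = None

    def span(self) -> tuple[int, int]:
        start_s, end_s = self.offset.split(":")
        start, end = int(start_s), int(end_s)
        if not (0 <= start < end):
            raise ValueError(f"bad offset {self.offset!r}")
        return start, end


@dataclass(frozen=True)
class GoldLabel:
    """Gold judgment for one (note, disease, task) triple."""

    note_id: int
    disease: str
    task: str
    judgment: str

    def __post_init__(self) -> None:
        if self.task not in TASK_LABELS:
            raise ValueError(f"unknown task: {self.task!r}")
        if self.judgment not in TASK_LABELS[self.task]:
            raise ValueError(
                f"judgment {self.judgment!r} illegal for {self.task} task"
            )

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.note_id, self.disease, self.task)
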