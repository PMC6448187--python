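"""Concept annotation: gazetteer tagging and MetaMap fielded-output parsing.

Two routes produce :class:`ConceptAnnotation` lists per record:

* :func:`tag_gazetteer` — a desk-scale dictionary tagger (longest match
  first, case-insensitive, word-boundary anchored) standing in for a full
  UMLS concept extractor.
* :func:`parse_mmi` — a reader for MetaMap's pipe-delimited MMI output, for
  sites that run the real parser.

Neither route does negation or uncertainty handling; that is exclusively the
rule engine's job.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

from .types import ConceptAnnotation, Note

logger = logging.getLogger(__name__)

#: MetaMap semantic-type abbreviation -> UMLS T-code.  Covers the fifteen
#: clinically relevant types used by the semantic feature filter plus common
#: extras seen in MMI output.
SEMTYPE_ABBREV_TO_TCODE = {
    "anst": "T017",  # Anatomical Structure
    "bdsy": "T022",  # Body System
    "bpoc": "T023",  # Body Part, Organ, or Organ Component
    "fndg": "T033",  # Finding
    "lbtr": "T034",  # Laboratory or Test Result
    "dsyn": "T047",  # Disease or Syndrome
    "mobd": "T048",  # Mental or Behavioral Dysfunction
    "comd": "T049",  # Cell or Molecular Dysfunction
    "lbpr": "T059",  # Laboratory Procedure
    "diap": "T060",  # Diagnostic Procedure
    "topp": "T061",  # Therapeutic or Preventive Procedure
    "phsu": "T121",  # Pharmacologic Substance
    "bodm": "T122",  # Biomedical or Dental Material
    "bacs": "T123",  # Biologically Active Substance
    "sosy": "T184",  # Sign or Symptom
    # extras commonly emitted by MetaMap
    "aapp": "T116",
    "orch": "T109",
    "neop": "T191",
    "medd": "T074",
    "inpr": "T170",
    "qlco": "T080",
    "tmco": "T079",
}
TCODE_TO_ABBREV = {v: k for k, v in SEMTYPE_ABBREV_TO_TCODE.items()}

Gazetteer = dict[str, tuple[str, str]]  # term -> (cui, semantic_type)


def tag_gazetteer(note: Note, gazetteer: Gazetteer) -> list[ConceptAnnotation]:
    """Tag every gazetteer term occurrence in the note's prepared text.

    Matching is case-insensitive, word-boundary anchored and longest-match
    first: where two terms start at the same offset the longer one wins and
    overlapping shorter matches are suppressed.  Deterministic and
    idempotent; returns annotations sorted by start offset.
    """
    if not gazetteer:
        return []
    if any(not t for t in gazetteer):
        raise ValueError("gazetteer terms must be non-empty")
    # One alternation sorted longest-first: finditer is leftmost and tries
    # alternatives in order, giving longest-match-first with non-overlap.
    terms = sorted(gazetteer, key=len, reverse=True)
    pattern = re.compile(
        r"(?<![\w])(?:" + "|".join(re.escape(t) for t in terms) + r")(?![\w])",
        re.IGNORECASE,
    )
    lowered = {t.lower(): t for t in gazetteer}
    annotations = []
    for m in pattern.finditer(note.prepared_text):
        term = lowered[m.group(0).lower()]
        cui, semtype = gazetteer[term]
        annotations.append(
            ConceptAnnotation(
                note_id=note.note_id,
                cui=cui,
                semantic_type=semtype,
                start=m.start(),
                end=m.end(),
                lexical_variant=m.group(0),
                source_system="gazetteer",
            )
        )
    return annotations


# MetaMap MMI fielded output -------------------------------------------------
#
# Field order handled (pipe-delimited):
#   id | MMI | score | preferred_name | cui | semtypes | trigger | location |
#   positional_info | ...
# where semtypes is a bracketed comma list of abbreviations ("[dsyn,fndg]")
# and positional_info is "start/length" spans joined by ";".

_MMI_MIN_FIELDS = 9
_POS_FIELD = 8


def parse_mmi(
    lines: list[str] | str,
    note_id: int,
    *,
    one_based: bool = False,
    strict: bool = False,
) -> list[ConceptAnnotation]:
    """Parse MetaMap MMI fielded-output lines into annotations.

    Positional info is interpreted as 0-based start/length by default; pass
    ``one_based=True`` for MetaMap dialects that count from 1.  Malformed
    lines are skipped with a warning unless ``strict`` is set.
    """
    if isinstance(lines, str):
        lines = lines.splitlines()
    annotations = []
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        try:
            annotations.extend(_parse_mmi_line(line, note_id, one_based))
        except ValueError as exc:
            if strict:
                raise ValueError(f"MMI line {lineno}: {exc}") from exc
            logger.warning("skipping malformed MMI line %d: %s", lineno, exc)
    return annotations


def _parse_mmi_line(line: str, note_id: int, one_based: bool) -> list[ConceptAnnotation]:
    fields = line.split("|")
    if len(fields) < _MMI_MIN_FIELDS:
        raise ValueError(f"expected >= {_MMI_MIN_FIELDS} fields, got {len(fields)}")
    if fields[1] != "MMI":
        raise ValueError(f"not an MMI record: {fields[1]!r}")
    preferred_name, cui = fields[3], fields[4]
    semtypes = [s for s in fields[5].strip("[]").split(",") if s]
    if not semtypes:
        raise ValueError("empty semantic-type list")
    tcode = SEMTYPE_ABBREV_TO_TCODE.get(semtypes[0])
    if tcode is None:
        raise ValueError(f"unknown semantic-type abbreviation {semtypes[0]!r}")

    annotations = []
    for span_text in fields[_POS_FIELD].split(";"):
        span_text = span_text.strip()
        if not span_text:
            continue
        try:
            start_s, length_s = span_text.split("/")
            start, length = int(start_s), int(length_s)
        except ValueError as exc:
            raise ValueError(f"bad positional info {span_text!r}") from exc
        if one_based:
            start -= 1
        if start < 0 or length <= 0:
            raise ValueError(f"bad span {span_text!r}")
        annotations.append(
            ConceptAnnotation(
                note_id=note_id,
                cui=cui,
                semantic_type=tcode,
                start=start,
                end=start + length,
                lexical_variant=preferred_name,
                source_system="metamap",
            )
        )
    return annotations


def to_mmi_line(annotations: list[ConceptAnnotation], score: float = 5.0) -> str:
    """Serialize same-CUI annotations to one MMI line (testing round-trips)."""
    if not annotations:
        raise ValueError("need at least one annotation")
    first = annotations[0]
    if any(a.cui != first.cui for a in annotations):
        raise ValueError("one MMI line carries a single CUI")
    abbrev = TCODE_TO_ABBREV[first.semantic_type]
    pos = ";".join(f"{a.start}/{a.end - a.start}" for a in annotations)
    return (
        f"{first.note_id}|MMI|{score:.2f}|{first.lexical_variant}|{first.cui}"
        f"|[{abbrev}]|{first.lexical_variant}|TX|{pos}"
    )


def read_mmi_file(path: str | Path, *, one_based: bool = False, strict: bool = False) -> list[ConceptAnnotation]:
    """Read one ``<note_id>.out`` MMI file; the note id comes from the stem."""
    p = Path(path)
    note_id = int(p.stem)
    return parse_mmi(
        p.read_text(encoding="utf-8"), note_id, one_based=one_based, strict=strict
    )


def read_gazetteer(path: str | Path) -> Gazetteer:
    """Read a gazetteer TSV (term, cui, semantic_type)."""
    gazetteer: Gazetteer = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        term, cui, semtype = line.split("\t")
        gazetteer[term] = (cui, semtype)
    return gazetteer


def write_gazetteer(gazetteer: Gazetteer, path: str | Path) -> None:
    lines = [f"{term}\t{cui}\t{semtype}" for term, (cui, semtype) in gazetteer.items()]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_annotations_tsv(annotations: list[ConceptAnnotation], path: str | Path) -> None:
    """Dump annotations as TSV for inspection."""
    header = "note_id\tcui\tsemantic_type\tstart\tend\tlexical_variant\tsource_system"
    rows = [
        f"{a.note_id}\t{a.cui}\t{a.semantic_type}\t{a.start}\t{a.end}"
        f"\t{a.lexical_variant}\t{a.source_system}"
        for a in annotations
    ]
    Path(path).write_text("\n".join([header, *rows]) + "\n", encoding="utf-8")
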