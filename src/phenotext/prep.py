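"""Corpus preparation: deabbreviation, record splitting, section detection.

A master file concatenates patient discharge summaries separated by a
literal end-of-record tag.  Each record is split out, deabbreviated with a
table-driven whole-token expander, and segmented into sections by matching a
heading dictionary at line starts.  Section spans partition the whole text:
each section runs from its heading to the start of the next heading (text
before the first heading is an implicit preamble with section id 0).
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import yaml

from .types import Note, Section, SectionDictionary

logger = logging.getLogger(__name__)

DEFAULT_END_TAG = "[record_end]"

#: Id of the implicit preamble pseudo-section (text before the first heading).
PREAMBLE_SECTION_ID = 0


def deabbreviate(text: str, table: dict[str, str]) -> str:
    """Expand whole-token abbreviations.

    Replacement is case-sensitive and anchored on word boundaries, so "CAD"
    inside "BROADCAST" is left alone.  Longer abbreviations win when one is a
    prefix of another.  Runs before any offset-bearing annotation, so the
    length change is harmless.
    """
    if not table:
        return text
    if any(not k for k in table):
        raise ValueError("abbreviation table keys must be non-empty")
    keys = sorted(table, key=len, reverse=True)
    pattern = re.compile(
        r"(?<![\w])(?:" + "|".join(re.escape(k) for k in keys) + r")(?![\w])"
    )
    return pattern.sub(lambda m: table[m.group(0)], text)


def split_records(master_text: str, end_tag: str = DEFAULT_END_TAG) -> list[Note]:
    """Split a master file into one :class:`Note` per record.

    One note per non-empty segment preceding each ``end_tag``, note ids
    assigned sequentially from 1.  Trailing text after the last tag is
    ignored when whitespace-only, otherwise it becomes a final note with a
    logged warning.  A master with no tag at all yields a single note.
    ``prepared_text`` is initialised to the raw text; callers deabbreviate
    afterwards (per record, streaming-friendly).
    """
    if not end_tag:
        raise ValueError("end_tag must be non-empty")
    if master_text == "":
        return []
    if end_tag not in master_text:
        logger.warning("no end-of-record tag found; treating master as one record")
        return [Note(note_id=1, raw_text=master_text, prepared_text=master_text)]

    segments = master_text.split(end_tag)
    trailing = segments.pop()
    if trailing.strip():
        logger.warning("text after the last end-of-record tag kept as a final record")
        segments.append(trailing)

    notes: list[Note] = []
    for segment in segments:
        if segment.strip() == "":
            continue
        notes.append(
            Note(note_id=len(notes) + 1, raw_text=segment, prepared_text=segment)
        )
    return notes


def prepare_notes(notes: list[Note], table: dict[str, str]) -> list[Note]:
    """Deabbreviate each note's text into ``prepared_text``."""
    return [
        Note(n.note_id, n.raw_text, deabbreviate(n.raw_text, table)) for n in notes
    ]


def detect_sections(text: str, sdict: SectionDictionary) -> list[Section]:
    """Locate section headings and derive half-open section spans.

    Headings match case-insensitively at the start of a line; ties at the
    same offset go to the longest heading.  Each section ends where the next
    begins (the last ends at ``len(text)``); text before the first heading
    forms a preamble section with id 0.  Empty text yields an empty list.
    """
    if text == "":
        return []

    # (offset, heading) of every line-start heading occurrence.
    hits: list[tuple[int, str]] = []
    lower = text.lower()
    for heading in sdict.entries:
        needle = heading.lower()
        pos = lower.find(needle)
        while pos != -1:
            if pos == 0 or text[pos - 1] == "\n":
                hits.append((pos, heading))
            pos = lower.find(needle, pos + 1)

    # Longest heading wins at equal offsets; drop shorter ones nested at the
    # same start.
    hits.sort(key=lambda h: (h[0], -len(h[1])))
    starts: list[tuple[int, str]] = []
    for pos, heading in hits:
        if starts and starts[-1][0] == pos:
            continue
        starts.append((pos, heading))

    sections: list[Section] = []
    if not starts or starts[0][0] > 0:
        first_end = starts[0][0] if starts else len(text)
        sections.append(
            Section(PREAMBLE_SECTION_ID, "", start=0, end=first_end)
        )
    for i, (pos, heading) in enumerate(starts):
        end = starts[i + 1][0] if i + 1 < len(starts) else len(text)
        sections.append(
            Section(sdict.entries[heading], heading, start=pos, end=end)
        )
    return sections


def section_for_offset(sections: list[Section], offset: int) -> Section:
    """Return the unique section whose span contains ``offset``."""
    for section in sections:
        if section.contains(offset):
            return section
    raise ValueError(f"offset {offset} outside every section span")


# I/O helpers ----------------------------------------------------------------

def read_abbreviations(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (abbreviation, expansion)."""
    table: dict[str, str] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        abbrev, expansion = line.split("\t", 1)
        table[abbrev] = expansion
    return table


def read_section_dictionary(path: str | Path) -> SectionDictionary:
    """Read a section dictionary from YAML.

    Expected layout: a list of mappings with keys ``heading``,
    ``section_concept_id`` and an optional boolean ``family_history``.
    """
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    entries: dict[str, int] = {}
    fh_id = None
    for item in raw:
        entries[item["heading"]] = int(item["section_concept_id"])
        if item.get("family_history"):
            if fh_id is not None:
                raise ValueError("multiple family_history flags in section dictionary")
            fh_id = int(item["section_concept_id"])
    return SectionDictionary(entries=entries, family_history_id=fh_id)


def write_section_dictionary(sdict: SectionDictionary, path: str | Path) -> None:
    items = [
        {
            "heading": heading,
            "section_concept_id": sid,
            **({"family_history": True} if sid == sdict.family_history_id else {}),
        }
        for heading, sid in sdict.entries.items()
    ]
    Path(path).write_text(yaml.safe_dump(items, sort_keys=False), encoding="utf-8")


def write_record_files(notes: list[Note], out_dir: str | Path) -> list[Path]:
    """Write one ``<note_id>.txt`` per record (prepared text)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for note in notes:
        p = out / f"{note.note_id}.txt"
        p.write_text(note.prepared_text, encoding="utf-8")
        paths.append(p)
    return paths
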