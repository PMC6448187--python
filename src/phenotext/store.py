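"""OMOP CDM NOTE_NLP persistence in an embedded relational store.

All annotations — concept mentions from the tagger and rule-cascade matches
— live in one NOTE_NLP table with the standard columns, so downstream
consumers see a single, portable stand-off annotation format.  The backend
is a single-file SQLite database (zero-install, testable); :meth:`CdmStore.ddl`
can emit MySQL-flavoured DDL for server deployments, since the portable part
is the schema, not the engine.

Semantic types are not a NOTE_NLP column; they live in a small side table
keyed by concept id so the semantic-type feature filter can join against it
without extending the standard table.
"""

from __future__ import annotations

import csv
import sqlite3
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .rules import RULE_SYSTEM_NAME, export_matches
from .types import ConceptAnnotation, MatchTables, Note, NoteNlpRow, Section

_DDL_SQLITE = """\
CREATE TABLE NOTE (
    note_id        INTEGER PRIMARY KEY,
    note_text      TEXT NOT NULL
);
CREATE TABLE NOTE_NLP (
    note_nlp_id         INTEGER PRIMARY KEY AUTOINCREMENT,
    note_id             INTEGER NOT NULL REFERENCES NOTE(note_id),
    section_concept_id  INTEGER NOT NULL,
    snippet             TEXT,
    "offset"            TEXT NOT NULL,
    lexical_variant     TEXT NOT NULL,
    note_nlp_concept_id TEXT NOT NULL,
    nlp_system          TEXT NOT NULL,
    nlp_date_time       TEXT NOT NULL
);
CREATE TABLE CONCEPT_SEMANTIC_TYPE (
    concept_id     TEXT PRIMARY KEY,
    semantic_type  TEXT NOT NULL
);
"""

_DDL_MYSQL = _DDL_SQLITE.replace(
    "INTEGER PRIMARY KEY AUTOINCREMENT", "INT PRIMARY KEY AUTO_INCREMENT"
).replace('"offset"', "`offset`")

_ROW_COLUMNS = (
    "note_id, section_concept_id, snippet, \"offset\", lexical_variant, "
    "note_nlp_concept_id, nlp_system, nlp_date_time"
)


class CdmStore:
    """A NOTE + NOTE_NLP store backed by a single SQLite file."""

    def __init__(self, conn: sqlite3.Connection, path: str):
        self.conn = conn
        self.path = path

    # Lifecycle ---------------------------------------------------------------

    @classmethod
    def init_schema(cls, store_path: str | Path, force: bool = False) -> "CdmStore":
        """Create an empty store; refuse to clobber an existing one unless forced."""
        path = str(store_path)
        conn = sqlite3.connect(path)
        existing = conn.execute(
            "SELECT name FROM sqlite_master WHERE type='table' AND name IN "
            "('NOTE', 'NOTE_NLP', 'CONCEPT_SEMANTIC_TYPE')"
        ).fetchall()
        if existing:
            if not force:
                conn.close()
                raise FileExistsError(
                    f"store at {path} already initialized; pass force=True to recreate"
                )
            conn.executescript(
                "DROP TABLE IF EXISTS NOTE_NLP;"
                "DROP TABLE IF EXISTS NOTE;"
                "DROP TABLE IF EXISTS CONCEPT_SEMANTIC_TYPE;"
            )
        conn.executescript(_DDL_SQLITE)
        conn.commit()
        return cls(conn, path)

    @classmethod
    def open(cls, store_path: str | Path) -> "CdmStore":
        path = str(store_path)
        if not Path(path).exists():
            raise FileNotFoundError(path)
        return cls(sqlite3.connect(path), path)

    def close(self) -> None:
        self.conn.close()

    @staticmethod
    def ddl(dialect: str = "sqlite") -> str:
        """Return the schema DDL for the given dialect ("sqlite" or "mysql")."""
        if dialect == "sqlite":
            return _DDL_SQLITE
        if dialect == "mysql":
            return _DDL_MYSQL
        raise ValueError(f"unknown dialect {dialect!r}")

    # Inserts -----------------------------------------------------------------

    def insert_notes(self, notes: Iterable[Note]) -> int:
        rows = [(n.note_id, n.prepared_text) for n in notes]
        self.conn.executemany("INSERT INTO NOTE (note_id, note_text) VALUES (?, ?)", rows)
        self.conn.commit()
        return len(rows)

    def note_text(self, note_id: int) -> str:
        row = self.conn.execute(
            "SELECT note_text FROM NOTE WHERE note_id = ?", (note_id,)
        ).fetchone()
        if row is None:
            raise KeyError(f"note {note_id} not in store")
        return row[0]

    def note_ids(self) -> list[int]:
        return [r[0] for r in self.conn.execute("SELECT note_id FROM NOTE ORDER BY note_id")]

    def insert_rows(self, rows: Sequence[NoteNlpRow]) -> int:
        """Low-level insert of pre-built NOTE_NLP rows (auto-assigned ids)."""
        known = set(self.note_ids())
        for row in rows:
            if row.note_id not in known:
                raise KeyError(f"NOTE_NLP row references unknown note {row.note_id}")
            row.span()  # validates the offset serialization
        self.conn.executemany(
            f"INSERT INTO NOTE_NLP ({_ROW_COLUMNS}) VALUES (?, ?, ?, ?, ?, ?, ?, ?)",
            [
                (
                    r.note_id,
                    r.section_concept_id,
                    r.snippet,
                    r.offset,
                    r.lexical_variant,
                    r.note_nlp_concept_id,
                    r.nlp_system,
                    r.nlp_date_time,
                )
                for r in rows
            ],
        )
        self.conn.commit()
        return len(rows)

    def insert_annotations(
        self,
        annotations: Sequence[ConceptAnnotation],
        sections_by_note: dict[int, list[Section]],
        *,
        snippet_window: int = 50,
        nlp_date_time: str = "",
    ) -> int:
        """Insert concept annotations, assigning each to its section by offset.

        The section is the unique one whose span contains the annotation's
        start offset; the snippet is a +/-``snippet_window`` character window
        clipped to the note bounds.  Semantic types are recorded in the side
        table for later filtering.
        """
        rows = []
        semtypes = []
        for a in annotations:
            text = self.note_text(a.note_id)
            section = _assign_section(sections_by_note.get(a.note_id, []), a.start)
            snippet = text[max(0, a.start - snippet_window):min(len(text), a.end + snippet_window)]
            rows.append(
                NoteNlpRow(
                    note_id=a.note_id,
                    section_concept_id=section,
                    snippet=snippet,
                    offset=f"{a.start}:{a.end}",
                    lexical_variant=a.lexical_variant,
                    note_nlp_concept_id=a.cui,
                    nlp_system=a.source_system,
                    nlp_date_time=nlp_date_time,
                )
            )
            semtypes.append((a.cui, a.semantic_type))
        count = self.insert_rows(rows)
        self.conn.executemany(
            "INSERT OR REPLACE INTO CONCEPT_SEMANTIC_TYPE (concept_id, semantic_type) "
            "VALUES (?, ?)",
            semtypes,
        )
        self.conn.commit()
        return count

    def insert_rule_matches(
        self,
        note: Note,
        sections: list[Section],
        tables: MatchTables,
        *,
        snippet_window: int = 50,
        nlp_date_time: str = "",
    ) -> int:
        """Insert one note's cascade match tables as NOTE_NLP rows."""
        rows = export_matches(
            tables,
            note.note_id,
            note.prepared_text,
            window=snippet_window,
            nlp_date_time=nlp_date_time,
            section_for=lambda start: _assign_section(sections, start),
        )
        return self.insert_rows(rows)

    # Queries -----------------------------------------------------------------

    def fetch_rows(
        self,
        note_id: Optional[int] = None,
        nlp_system: Optional[str] = None,
    ) -> list[NoteNlpRow]:
        sql = f"SELECT note_nlp_id, {_ROW_COLUMNS} FROM NOTE_NLP"
        clauses, params = [], []
        if note_id is not None:
            clauses.append("note_id = ?")
            params.append(note_id)
        if nlp_system is not None:
            clauses.append("nlp_system = ?")
            params.append(nlp_system)
        if clauses:
            sql += " WHERE " + " AND ".join(clauses)
        sql += " ORDER BY note_nlp_id"
        return [
            NoteNlpRow(
                note_nlp_id=r[0],
                note_id=r[1],
                section_concept_id=r[2],
                snippet=r[3],
                offset=r[4],
                lexical_variant=r[5],
                note_nlp_concept_id=r[6],
                nlp_system=r[7],
                nlp_date_time=r[8],
            )
            for r in self.conn.execute(sql, params)
        ]

    def query_cui_counts(
        self,
        *,
        exclude_section_ids: Optional[Iterable[int]] = None,
        allowed_semantic_types: Optional[Iterable[str]] = None,
        include_rule_rows: bool = False,
    ) -> dict[tuple[int, str], int]:
        """Per-note CUI occurrence counts with optional section/type filters.

        Rows in excluded sections vanish from the counts; when an allowed
        semantic-type set is given, concepts outside it (or with no recorded
        type) are dropped.  Rule-cascade rows carry category codes rather
        than CUIs and are excluded unless asked for.  Ordering is
        deterministic by (note_id, concept_id).
        """
        sql = (
            "SELECT n.note_id, n.note_nlp_concept_id, COUNT(*) FROM NOTE_NLP n "
        )
        clauses, params = [], []
        if allowed_semantic_types is not None:
            allowed = sorted(set(allowed_semantic_types))
            sql += (
                "JOIN CONCEPT_SEMANTIC_TYPE s ON s.concept_id = n.note_nlp_concept_id "
            )
            clauses.append(
                f"s.semantic_type IN ({','.join('?' * len(allowed))})"
            )
            params.extend(allowed)
        if not include_rule_rows:
            clauses.append("n.nlp_system != ?")
            params.append(RULE_SYSTEM_NAME)
        if exclude_section_ids is not None:
            excluded = sorted(set(exclude_section_ids))
            if excluded:
                clauses.append(
                    f"n.section_concept_id NOT IN ({','.join('?' * len(excluded))})"
                )
                params.extend(excluded)
        if clauses:
            sql += "WHERE " + " AND ".join(clauses) + " "
        sql += "GROUP BY n.note_id, n.note_nlp_concept_id ORDER BY n.note_id, n.note_nlp_concept_id"
        return {
            (note_id, concept_id): count
            for note_id, concept_id, count in self.conn.execute(sql, params)
        }

    def semantic_type_of(self, concept_id: str) -> Optional[str]:
        row = self.conn.execute(
            "SELECT semantic_type FROM CONCEPT_SEMANTIC_TYPE WHERE concept_id = ?",
            (concept_id,),
        ).fetchone()
        return None if row is None else row[0]

    # Export ------------------------------------------------------------------

    def export_note_nlp_csv(self, path: str | Path) -> int:
        """Dump NOTE_NLP to CSV for interoperability; returns the row count."""
        rows = self.fetch_rows()
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(
                [
                    "note_nlp_id",
                    "note_id",
                    "section_concept_id",
                    "snippet",
                    "offset",
                    "lexical_variant",
                    "note_nlp_concept_id",
                    "nlp_system",
                    "nlp_date_time",
                ]
            )
            for r in rows:
                writer.writerow(
                    [
                        r.note_nlp_id,
                        r.note_id,
                        r.section_concept_id,
                        r.snippet,
                        r.offset,
                        r.lexical_variant,
                        r.note_nlp_concept_id,
                        r.nlp_system,
                        r.nlp_date_time,
                    ]
                )
        return len(rows)


def _assign_section(sections: list[Section], offset: int) -> int:
    if not sections:
        return 0
    for section in sections:
        if section.contains(offset):
            return section.section_id
    raise ValueError(f"offset {offset} outside every section span")
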