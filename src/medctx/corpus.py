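"""Reading, validation and tokenization of clinical-note corpora.

The unit record is a :class:`NoteRecord`: one clinical note's non-textual
metadata (author department and staff type, note type, patient demographics,
coded events near the note's timestamp) plus its sectioned free text. Notes
are exchanged as JSON Lines, reviewer highlights as TSV, candidate terms as
plain text, and baseline embeddings in word2vec text format.

Tokenization implements the corpus preprocessing rule used throughout the
package: case-fold, split on non-alphanumeric runs, drop stop words and
single-character tokens. Numeric tokens are kept (configurable corpora may
carry dosages, lab values etc. as meaningful terms).
"""

from __future__ import annotations

import json
import re
from collections import Counter
from datetime import datetime
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from ._stopwords import DEFAULT_STOPWORDS

__all__ = [
    "EventSystem",
    "Gender",
    "EventRecord",
    "SectionRecord",
    "NoteRecord",
    "HighlightSet",
    "EmbeddingTable",
    "CorpusFormatError",
    "read_notes",
    "write_notes",
    "tokenize",
    "read_highlights",
    "read_candidates",
    "read_embeddings",
    "DEFAULT_STOPWORDS",
]


class CorpusFormatError(ValueError):
    """A corpus input file violates its schema or format contract."""


class EventSystem(str, Enum):
    ICD = "ICD"
    CPT = "CPT"
    CHIEF_COMPLAINT = "chief_complaint"


class Gender(str, Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class EventRecord(BaseModel):
    """One coded medical event (diagnosis, procedure or chief complaint)."""

    model_config = ConfigDict(frozen=True)

    system: EventSystem
    code: str = Field(min_length=1)
    timestamp: datetime


class SectionRecord(BaseModel):
    """A named subdivision of a note's free text."""

    model_config = ConfigDict(frozen=True)

    section_name: str
    text: str

    @field_validator("section_name")
    @classmethod
    def _nonempty_after_casefold(cls, v: str) -> str:
        if not v.casefold().strip():
            raise ValueError("section_name empty after case-folding")
        return v


class NoteRecord(BaseModel):
    """One clinical note: metadata context plus sectioned text."""

    model_config = ConfigDict(frozen=True)

    note_id: str = Field(min_length=1)
    patient_id: str
    timestamp: datetime
    department: str
    staff_type: str
    note_type: str
    patient_age_years: int = Field(ge=0)
    patient_gender: Gender
    events: tuple[EventRecord, ...] = ()
    sections: tuple[SectionRecord, ...]

    @field_validator("sections")
    @classmethod
    def _nonempty_sections(cls, v: tuple[SectionRecord, ...]):
        if len(v) == 0:
            raise ValueError("sections must be non-empty; wrap bare text as one 'body' section")
        return v


_TOKEN_SPLIT = re.compile(r"[^a-z0-9]+")


def tokenize(text: str, stopwords: Iterable[str] | None = None) -> list[str]:
    """Case-fold ``text``, split on non-alphanumeric runs, drop stop words
    and single-character tokens. Order and duplicates are preserved.
    """
    sw = DEFAULT_STOPWORDS if stopwords is None else stopwords
    if not isinstance(sw, (set, frozenset)):
        sw = set(sw)
    return [t for t in _TOKEN_SPLIT.split(text.lower()) if len(t) > 1 and t not in sw]


def read_notes(path: str | Path) -> list[NoteRecord]:
    """Read a JSON Lines note file into validated :class:`NoteRecord` objects.

    Raises :class:`CorpusFormatError` naming the line number and offending
    field on any invalid record; duplicate ``note_id`` values are rejected.
    """
    path = Path(path)
    notes: list[NoteRecord] = []
    seen: set[str] = set()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as e:
                raise CorpusFormatError(f"{path}:{lineno}: invalid JSON: {e}") from e
            try:
                note = NoteRecord.model_validate(obj)
            except ValidationError as e:
                first = e.errors()[0]
                loc = ".".join(str(p) for p in first["loc"]) or "<record>"
                raise CorpusFormatError(
                    f"{path}:{lineno}: field '{loc}': {first['msg']}"
                ) from e
            if note.note_id in seen:
                raise CorpusFormatError(f"{path}:{lineno}: duplicate note_id '{note.note_id}'")
            seen.add(note.note_id)
            notes.append(note)
    return notes


def write_notes(notes: Iterable[NoteRecord], path: str | Path) -> None:
    """Write notes as JSON Lines (inverse of :func:`read_notes`)."""
    path = Path(path)
    with path.open("w") as fh:
        for note in notes:
            fh.write(note.model_dump_json() + "\n")


class HighlightSet(BaseModel):
    """Per-(note, term) reviewer highlight counts, terms in canonical form."""

    model_config = ConfigDict(frozen=True)

    entries: Mapping[tuple[str, str], int]

    @field_validator("entries")
    @classmethod
    def _nonnegative(cls, v):
        for key, count in v.items():
            if count < 0:
                raise ValueError(f"negative highlight count for {key}")
        return dict(v)

    def total(self) -> int:
        return sum(self.entries.values())


def read_highlights(
    path: str | Path, stopwords: Iterable[str] | None = None
) -> HighlightSet:
    """Read a highlights TSV (columns ``note_id``, ``term``, ``count``).

    Terms are canonicalized via :func:`tokenize`; a multi-token highlight
    contributes each of its surviving tokens with the row's count, and rows
    mapping to the same ``(note_id, token)`` are summed.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"note_id": str, "term": str})
    missing = {"note_id", "term", "count"} - set(df.columns)
    if missing:
        raise CorpusFormatError(f"{path}: missing column(s) {sorted(missing)}")
    if (df["count"] < 0).any():
        bad = df.index[df["count"] < 0][0]
        raise ValueError(f"{path}: negative count at row {bad + 2}")
    entries: Counter[tuple[str, str]] = Counter()
    for note_id, term, count in df[["note_id", "term", "count"]].itertuples(index=False):
        for token in tokenize(str(term), stopwords):
            entries[(str(note_id), token)] += int(count)
    return HighlightSet(entries=dict(entries))


def read_candidates(path: str | Path, stopwords: Iterable[str] | None = None) -> list[str]:
    """Read a candidate-term list (one term per line), canonicalized.

    Multi-token lines decompose into their tokens; duplicates are removed
    preserving first-seen order.
    """
    out: list[str] = []
    seen: set[str] = set()
    for line in Path(path).read_text().splitlines():
        for token in tokenize(line, stopwords):
            if token not in seen:
                seen.add(token)
                out.append(token)
    return out


class EmbeddingTable(BaseModel):
    """A dense term-embedding lookup (baseline feature space)."""

    model_config = ConfigDict(frozen=True, arbitrary_types_allowed=True)

    dimension: int = Field(gt=0)
    vectors: Mapping[str, tuple[float, ...]]

    @field_validator("vectors")
    @classmethod
    def _consistent_dimension(cls, v, info):
        dim = info.data.get("dimension")
        for term, vec in v.items():
            if dim is not None and len(vec) != dim:
                raise ValueError(f"vector for '{term}' has length {len(vec)}, expected {dim}")
        return dict(v)

    def get(self, term: str) -> np.ndarray | None:
        vec = self.vectors.get(term)
        return None if vec is None else np.asarray(vec, dtype=float)


def read_embeddings(path: str | Path) -> EmbeddingTable:
    """Read word2vec text format (optional ``V D`` header line).

    Terms are case-folded; on a case collision the first occurrence wins.
    Inconsistent vector lengths raise :class:`CorpusFormatError` with the
    line number.
    """
    path = Path(path)
    vectors: dict[str, tuple[float, ...]] = {}
    dimension: int | None = None
    with path.open() as fh:
        lines = fh.readlines()
    start = 0
    if lines:
        head = lines[0].split()
        if len(head) == 2:
            try:
                int(head[0]), int(head[1])
                dimension = int(head[1])
                start = 1
            except ValueError:
                pass
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        parts = line.split()
        term, values = parts[0].lower(), parts[1:]
        try:
            vec = tuple(float(v) for v in values)
        except ValueError as e:
            raise CorpusFormatError(f"{path}:{lineno}: non-numeric value: {e}") from e
        if dimension is None:
            dimension = len(vec)
        if len(vec) != dimension:
            raise CorpusFormatError(
                f"{path}:{lineno}: vector length {len(vec)} != dimension {dimension}"
            )
        vectors.setdefault(term, vec)
    if dimension is None or not vectors:
        raise CorpusFormatError(f"{path}: no embedding vectors found")
    return EmbeddingTable(dimension=dimension, vectors=vectors)
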