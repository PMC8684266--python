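"""The medical-context vector space.

Each clinical term is represented, per medical context, by the normalized
frequencies with which it occurs under that context's attribute values. Ten
contexts are tracked by default, in four groups:

* hospital organizational structure — author department, author staff type;
* medical events — ICD codes, CPT codes and chief complaints documented
  within a time window (default 48 h) of the note's timestamp;
* demographics — patient age (ten-year bins) and gender;
* note structure — note type, note section, and "top" note sections (a
  designated subset of sections that carry the most important content).

Building the space is a three-step pass over a corpus: initialize every
term's per-context count vector at zero, accumulate occurrence counts per
attribute value, then L1-normalize each term's per-context counts into
proportions in [0, 1]. Vectors are stored sparsely, keyed by attribute
label; per-context dimension catalogs define the shared index space.
"""

from __future__ import annotations

import json
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .corpus import NoteRecord, tokenize

__all__ = [
    "ContextType",
    "ContextScope",
    "ContextDef",
    "ContextRegistry",
    "TermContextCounts",
    "MedicalContextVectorSet",
    "default_registry",
    "active_attributes",
    "accumulate",
    "normalize",
    "build_space",
    "dimension_summary",
    "top_dimensions",
]

DEFAULT_KEY_SECTIONS = frozenset(
    {"assessment", "findings", "family medical history", "medications", "problem list"}
)
DEFAULT_AGE_BIN_EDGES = (0, 10, 20, 30, 40, 50, 60, 70, 80, 90)


class ContextType(str, Enum):
    ORGANIZATIONAL = "organizational"
    MEDICAL_EVENT = "medical_event"
    DEMOGRAPHICS = "demographics"
    NOTE_STRUCTURE = "note_structure"


class ContextScope(str, Enum):
    NOTE_LEVEL = "note_level"
    SECTION_LEVEL = "section_level"
    EVENT_LEVEL = "event_level"


@dataclass(frozen=True)
class ContextDef:
    context_id: str
    context_type: ContextType
    scope: ContextScope


_DEFAULT_CONTEXTS: tuple[ContextDef, ...] = (
    ContextDef("department", ContextType.ORGANIZATIONAL, ContextScope.NOTE_LEVEL),
    ContextDef("staff", ContextType.ORGANIZATIONAL, ContextScope.NOTE_LEVEL),
    ContextDef("icd_event", ContextType.MEDICAL_EVENT, ContextScope.EVENT_LEVEL),
    ContextDef("cpt_event", ContextType.MEDICAL_EVENT, ContextScope.EVENT_LEVEL),
    ContextDef("chief_complaint", ContextType.MEDICAL_EVENT, ContextScope.EVENT_LEVEL),
    ContextDef("age", ContextType.DEMOGRAPHICS, ContextScope.NOTE_LEVEL),
    ContextDef("gender", ContextType.DEMOGRAPHICS, ContextScope.NOTE_LEVEL),
    ContextDef("note_type", ContextType.NOTE_STRUCTURE, ContextScope.NOTE_LEVEL),
    ContextDef("note_section", ContextType.NOTE_STRUCTURE, ContextScope.SECTION_LEVEL),
    ContextDef("top_note_section", ContextType.NOTE_STRUCTURE, ContextScope.SECTION_LEVEL),
)

_EVENT_SYSTEM_FOR_CONTEXT = {
    "icd_event": "ICD",
    "cpt_event": "CPT",
    "chief_complaint": "chief_complaint",
}


@dataclass(frozen=True)
class ContextRegistry:
    """The ordered set of contexts plus the corpus-level accumulation knobs."""

    contexts: tuple[ContextDef, ...] = _DEFAULT_CONTEXTS
    event_window_hours: float = 48.0
    key_sections: frozenset[str] = DEFAULT_KEY_SECTIONS
    age_bin_edges: tuple[int, ...] = DEFAULT_AGE_BIN_EDGES

    def __post_init__(self) -> None:
        ids = [c.context_id for c in self.contexts]
        if len(set(ids)) != len(ids):
            raise ValueError("context ids must be unique")
        if self.event_window_hours <= 0:
            raise ValueError("event_window_hours must be positive")
        edges = list(self.age_bin_edges)
        if edges != sorted(edges) or len(set(edges)) != len(edges):
            raise ValueError("age_bin_edges must be strictly ascending")

    @property
    def context_ids(self) -> list[str]:
        return [c.context_id for c in self.contexts]

    def age_bin_label(self, age: int) -> str:
        """Ten-year bin label for an age, e.g. 26 -> '20-29'; last bin open."""
        if age < 0:
            raise ValueError(f"age must be non-negative, got {age}")
        edges = self.age_bin_edges
        for lo, hi in zip(edges, edges[1:]):
            if lo <= age < hi:
                return f"{lo}-{hi - 1}"
        return f"{edges[-1]}+"

    def to_dict(self) -> dict:
        return {
            "contexts": [
                {"context_id": c.context_id, "context_type": c.context_type.value,
                 "scope": c.scope.value}
                for c in self.contexts
            ],
            "event_window_hours": self.event_window_hours,
            "key_sections": sorted(self.key_sections),
            "age_bin_edges": list(self.age_bin_edges),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ContextRegistry":
        return cls(
            contexts=tuple(
                ContextDef(c["context_id"], ContextType(c["context_type"]),
                           ContextScope(c["scope"]))
                for c in d["contexts"]
            ),
            event_window_hours=float(d["event_window_hours"]),
            key_sections=frozenset(d["key_sections"]),
            age_bin_edges=tuple(d["age_bin_edges"]),
        )


def default_registry(
    event_window_hours: float = 48.0,
    key_sections: Iterable[str] | None = None,
    age_bin_edges: Sequence[int] | None = None,
) -> ContextRegistry:
    """The ten-context registry with optional knob overrides."""
    return ContextRegistry(
        event_window_hours=event_window_hours,
        key_sections=frozenset(s.lower() for s in key_sections)
        if key_sections is not None
        else DEFAULT_KEY_SECTIONS,
        age_bin_edges=tuple(age_bin_edges) if age_bin_edges is not None else DEFAULT_AGE_BIN_EDGES,
    )


def active_attributes(
    note: NoteRecord, registry: ContextRegistry
) -> dict[str, set[str]]:
    """The attribute labels a note activates per note-level / event-level
    context (section-level contexts are resolved during accumulation).

    Event contexts activate the codes of their system whose timestamp lies
    within ``event_window_hours`` of the note's timestamp.
    """
    out: dict[str, set[str]] = {}
    window_s = registry.event_window_hours * 3600.0
    for cdef in registry.contexts:
        cid = cdef.context_id
        if cdef.scope is ContextScope.SECTION_LEVEL:
            continue
        if cdef.scope is ContextScope.EVENT_LEVEL:
            system = _EVENT_SYSTEM_FOR_CONTEXT.get(cid)
            codes = {
                ev.code
                for ev in note.events
                if ev.system.value == system
                and abs((ev.timestamp - note.timestamp).total_seconds()) <= window_s
            }
            out[cid] = codes
        elif cid == "department":
            out[cid] = {note.department}
        elif cid == "staff":
            out[cid] = {note.staff_type}
        elif cid == "note_type":
            out[cid] = {note.note_type}
        elif cid == "gender":
            out[cid] = {note.patient_gender.value}
        elif cid == "age":
            out[cid] = {registry.age_bin_label(note.patient_age_years)}
        else:  # custom note-level context: no default binding
            out[cid] = set()
    return out


@dataclass
class TermContextCounts:
    """Raw per-term, per-context occurrence counts (pre-normalization)."""

    counts: dict[str, dict[str, Counter]] = field(default_factory=dict)
    dimension_catalogs: dict[str, set[str]] = field(default_factory=dict)
    registry: ContextRegistry = field(default_factory=ContextRegistry)

    def _bump(self, term: str, context_id: str, label: str, by: int) -> None:
        self.counts.setdefault(term, {}).setdefault(context_id, Counter())[label] += by
        self.dimension_catalogs.setdefault(context_id, set()).add(label)


def accumulate(
    notes: Iterable[NoteRecord],
    registry: ContextRegistry | None = None,
    stopwords: Iterable[str] | None = None,
) -> TermContextCounts:
    """Accumulate token occurrence counts over a corpus.

    For note-level and event-level contexts every token occurrence anywhere
    in the note adds 1 to each of that context's active attributes; for the
    note-section context each occurrence adds 1 to the dimension of the
    section it occurs in, and for the top-note-section context only when
    that section is one of the registry's key sections.
    """
    registry = registry or ContextRegistry()
    tcc = TermContextCounts(registry=registry)
    for cid in registry.context_ids:
        tcc.dimension_catalogs.setdefault(cid, set())
    note_level_ids = [
        c.context_id for c in registry.contexts if c.scope is not ContextScope.SECTION_LEVEL
    ]
    has_section = any(c.context_id == "note_section" for c in registry.contexts)
    has_top = any(c.context_id == "top_note_section" for c in registry.contexts)
    for note in notes:
        attrs = active_attributes(note, registry)
        note_counts: Counter[str] = Counter()
        for section in note.sections:
            sec_name = section.section_name.lower()
            sec_counts = Counter(tokenize(section.text, stopwords))
            is_key = sec_name in registry.key_sections
            for term, n in sec_counts.items():
                if has_section:
                    tcc._bump(term, "note_section", sec_name, n)
                if has_top and is_key:
                    tcc._bump(term, "top_note_section", sec_name, n)
            note_counts.update(sec_counts)
        for term, n in note_counts.items():
            for cid in note_level_ids:
                for label in attrs.get(cid, ()):
                    tcc._bump(term, cid, label, n)
    return tcc


@dataclass
class MedicalContextVectorSet:
    """The normalized medical-context vector space.

    ``vectors[term][context_id]`` is a sparse mapping from attribute label to
    the term's usage proportion under that attribute; each non-empty context
    vector sums to 1. ``dimension_catalogs`` holds every label observed per
    context so that vectors of different terms share an index space.
    """

    vectors: dict[str, dict[str, dict[str, float]]]
    registry: ContextRegistry
    dimension_catalogs: dict[str, set[str]]

    @property
    def terms(self) -> list[str]:
        return sorted(self.vectors)

    def __contains__(self, term: str) -> bool:
        return term in self.vectors

    def context_vector(self, term: str, context_id: str) -> dict[str, float]:
        if term not in self.vectors:
            raise KeyError(f"term '{term}' not in vector space")
        return self.vectors[term].get(context_id, {})

    # -- serialization: one JSON archive, stable ordering, bit-reproducible --

    def save(self, path: str | Path) -> None:
        payload = {
            "registry": self.registry.to_dict(),
            "contexts": {
                cid: sorted(self.dimension_catalogs.get(cid, ()))
                for cid in self.registry.context_ids
            },
            "vectors": {
                term: {
                    cid: [[label, self.vectors[term][cid][label]]
                          for label in sorted(self.vectors[term][cid])]
                    for cid in sorted(self.vectors[term])
                }
                for term in sorted(self.vectors)
            },
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True, separators=(",", ":")))

    @classmethod
    def load(cls, path: str | Path) -> "MedicalContextVectorSet":
        payload = json.loads(Path(path).read_text())
        return cls(
            vectors={
                term: {cid: {label: float(v) for label, v in pairs}
                       for cid, pairs in by_ctx.items()}
                for term, by_ctx in payload["vectors"].items()
            },
            registry=ContextRegistry.from_dict(payload["registry"]),
            dimension_catalogs={cid: set(labels) for cid, labels in payload["contexts"].items()},
        )


def normalize(counts: TermContextCounts) -> MedicalContextVectorSet:
    """L1-normalize each term's per-context counts into proportions.

    All-zero (empty) context vectors stay empty; dimension catalogs carry
    over unchanged.
    """
    vectors: dict[str, dict[str, dict[str, float]]] = {}
    for term, by_ctx in counts.counts.items():
        vectors[term] = {}
        for cid, ctr in by_ctx.items():
            total = sum(ctr.values())
            if total > 0:
                vectors[term][cid] = {label: n / total for label, n in ctr.items() if n > 0}
            else:
                vectors[term][cid] = {}
    return MedicalContextVectorSet(
        vectors=vectors,
        registry=counts.registry,
        dimension_catalogs={cid: set(s) for cid, s in counts.dimension_catalogs.items()},
    )


def build_space(
    notes: Iterable[NoteRecord],
    registry: ContextRegistry | None = None,
    stopwords: Iterable[str] | None = None,
) -> MedicalContextVectorSet:
    """Accumulate and normalize in one call."""
    return normalize(accumulate(notes, registry, stopwords))


def dimension_summary(space: MedicalContextVectorSet) -> dict[str, int]:
    """Number of distinct observed dimension labels per context."""
    return {
        cid: len(space.dimension_catalogs.get(cid, ()))
        for cid in space.registry.context_ids
    }


def top_dimensions(
    space: MedicalContextVectorSet, term: str, context_id: str, k: int
) -> list[tuple[str, float]]:
    """The ``k`` largest-proportion dimensions of a term in one context,
    descending, ties broken by ascending label."""
    vec = space.context_vector(term, context_id)
    ranked = sorted(vec.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:k]
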