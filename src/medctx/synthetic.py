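"""Synthetic EMR corpus generator with planted context structure.

Real chart-review corpora are access-restricted, so every protocol in this
package is exercised against a generator that emulates their statistical
shape end to end:

* each vocabulary term carries a latent per-context usage profile (a
  Dirichlet-sampled categorical over that context's attribute values);
* notes sample their context attributes (department, staff type, note type,
  demographics, nearby coded events, section names) and then fill sections
  with terms whose profiles are compatible with those attributes, so the
  corpus-level vector space estimates the planted profiles;
* a designated set of "related" terms copies the topic word's profile in a
  chosen subset of contexts, creating genuinely similar terms;
* a simulated reviewer highlights occurrences of term w with probability
  driven by a linear-logit in the per-context similarities S_c(topic, w)
  with known weights, so supervised recovery of those weights is well-posed.

All stages are deterministic given the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta
from pathlib import Path
from typing import Mapping, Sequence

import json

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .contexts import (
    ContextRegistry,
    MedicalContextVectorSet,
    build_space,
    default_registry,
)
from .corpus import (
    EventRecord,
    Gender,
    HighlightSet,
    NoteRecord,
    SectionRecord,
    tokenize,
    write_notes,
)
from .similarity import context_cosine

__all__ = [
    "SyntheticSpec",
    "SyntheticBundle",
    "sample_term_profiles",
    "generate_notes",
    "generate_highlights",
    "make_bundle",
    "write_bundle",
]

# Contexts whose latent profiles are sampled directly; the top-note-section
# profile is the note-section profile restricted to the key sections.
_SAMPLED_CONTEXTS = (
    "department",
    "staff",
    "icd_event",
    "cpt_event",
    "chief_complaint",
    "age",
    "gender",
    "note_type",
    "note_section",
)

_KEY_SECTION_NAMES = (
    "assessment",
    "findings",
    "family medical history",
    "medications",
    "problem list",
)
_EXTRA_SECTION_NAMES = ("history", "plan", "exam", "labs", "imaging")


class SyntheticSpec(BaseModel):
    """Study conditions for one synthetic chart-review task.

    Defaults give a desk-scale corpus: 1000 candidate terms (the scale of a
    real candidate semantic set), 800 notes, and a reviewer whose context
    weights span a clear ordering so that weight recovery is informative.
    """

    model_config = ConfigDict(frozen=True)

    seed: int = 0
    n_notes: int = Field(default=800, ge=0)
    vocab_size: int = Field(default=1001, gt=1)
    topic_word: str = "epilepsy"
    context_cardinalities: dict[str, int] = Field(
        default_factory=lambda: {
            "department": 8,
            "staff": 6,
            "icd_event": 25,
            "cpt_event": 25,
            "chief_complaint": 15,
            "note_type": 6,
            "note_section": 10,
        }
    )
    concentration: float = Field(default=0.4, gt=0)
    n_related_terms: int = Field(default=60, ge=0)
    related_contexts: frozenset[str] = frozenset({"chief_complaint", "icd_event", "note_type"})
    # Registry order: department, staff, icd_event, cpt_event, chief_complaint,
    # age, gender, note_type, note_section, top_note_section.
    reviewer_weights: tuple[float, ...] = (1.0, 0.5, 4.0, 1.5, 8.0, 2.0, 3.0, 6.0, 2.5, 5.0)
    reviewer_intercept: float = -14.0
    tokens_per_section: int = Field(default=40, gt=0)
    sections_per_note: int = Field(default=5, gt=0)
    highlight_rate: float = Field(default=0.05, gt=0)

    @model_validator(mode="after")
    def _check(self) -> "SyntheticSpec":
        if self.n_related_terms >= self.vocab_size:
            raise ValueError("n_related_terms must be smaller than vocab_size")
        if len(self.reviewer_weights) != 10:
            raise ValueError("reviewer_weights must have one entry per context (10)")
        for cid, card in self.context_cardinalities.items():
            if card < 1:
                raise ValueError(f"cardinality for {cid} must be >= 1")
        return self

    @property
    def vocabulary(self) -> list[str]:
        return [self.topic_word] + [f"term{i:04d}" for i in range(self.vocab_size - 1)]

    @property
    def related_terms(self) -> list[str]:
        return [f"term{i:04d}" for i in range(self.n_related_terms)]


def _dimension_labels(spec: SyntheticSpec, registry: ContextRegistry) -> dict[str, list[str]]:
    card = spec.context_cardinalities
    labels: dict[str, list[str]] = {
        "department": [f"dept{i:02d}" for i in range(card.get("department", 8))],
        "staff": [f"staff{i:02d}" for i in range(card.get("staff", 6))],
        "icd_event": [f"icd{i:03d}" for i in range(card.get("icd_event", 25))],
        "cpt_event": [f"cpt{i:03d}" for i in range(card.get("cpt_event", 25))],
        "chief_complaint": [f"cc{i:03d}" for i in range(card.get("chief_complaint", 15))],
        "note_type": [f"type{i:02d}" for i in range(card.get("note_type", 6))],
        "age": [registry.age_bin_label(edge) for edge in registry.age_bin_edges],
        "gender": [g.value for g in Gender],
    }
    n_sections = card.get("note_section", 10)
    sec = list(_KEY_SECTION_NAMES) + list(_EXTRA_SECTION_NAMES)
    while len(sec) < n_sections:
        sec.append(f"section{len(sec):02d}")
    labels["note_section"] = sec[:max(n_sections, len(_KEY_SECTION_NAMES))]
    return labels


def sample_term_profiles(
    spec: SyntheticSpec, registry: ContextRegistry | None = None
) -> dict[str, dict[str, np.ndarray]]:
    """Latent per-term per-context categorical profiles.

    Each profile is Dirichlet(concentration) over the context's dimensions;
    related terms copy the topic word's profile exactly in the related
    contexts and sample independently elsewhere.
    """
    registry = registry or default_registry()
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
    labels = _dimension_labels(spec, registry)
    vocab = spec.vocabulary
    related = set(spec.related_terms)
    profiles: dict[str, dict[str, np.ndarray]] = {}
    for term in vocab:
        profiles[term] = {}
        for cid in _SAMPLED_CONTEXTS:
            dims = len(labels[cid])
            profiles[term][cid] = rng.dirichlet(np.full(dims, spec.concentration))
    topic = spec.topic_word
    for term in related:
        for cid in spec.related_contexts:
            profiles[term][cid] = profiles[topic][cid].copy()
    return profiles


def _event_factor(profile_mat: np.ndarray, code_idx: list[int]) -> np.ndarray:
    """Mean profile mass on a note's in-window codes (1.0 if none)."""
    if not code_idx:
        return np.ones(profile_mat.shape[0])
    return profile_mat[:, code_idx].mean(axis=1)


def generate_notes(
    spec: SyntheticSpec,
    profiles: Mapping[str, Mapping[str, np.ndarray]],
    registry: ContextRegistry | None = None,
) -> list[NoteRecord]:
    """Sample a note corpus whose term usage follows the latent profiles.

    Note attributes are uniform over their cardinalities; each system draws
    0-3 events with timestamps spread inside and outside the 48 h window;
    sections are filled by sampling terms with probability proportional to
    the product of each term's profile mass on the note's attributes.
    """
    registry = registry or default_registry()
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    labels = _dimension_labels(spec, registry)
    vocab = spec.vocabulary
    v = len(vocab)
    vocab_arr = np.array(vocab)
    # per-context profile matrices, shape (V, dims)
    mats = {cid: np.stack([profiles[t][cid] for t in vocab]) for cid in _SAMPLED_CONTEXTS}
    age_labels = labels["age"]
    gender_labels = labels["gender"]
    base_ts = datetime(2016, 1, 1)
    event_systems = (
        ("icd_event", "ICD", labels["icd_event"]),
        ("cpt_event", "CPT", labels["cpt_event"]),
        ("chief_complaint", "chief_complaint", labels["chief_complaint"]),
    )
    window_h = registry.event_window_hours
    notes: list[NoteRecord] = []
    for i in range(spec.n_notes):
        ts = base_ts + timedelta(minutes=int(rng.integers(0, 365 * 24 * 60)))
        dept_i = int(rng.integers(len(labels["department"])))
        staff_i = int(rng.integers(len(labels["staff"])))
        type_i = int(rng.integers(len(labels["note_type"])))
        age = int(rng.integers(0, 90))
        age_i = age_labels.index(registry.age_bin_label(age))
        gender_i = int(rng.integers(len(gender_labels)))

        weight = (
            mats["department"][:, dept_i]
            * mats["staff"][:, staff_i]
            * mats["note_type"][:, type_i]
            * mats["age"][:, age_i]
            * mats["gender"][:, gender_i]
        )
        events: list[EventRecord] = []
        for cid, system, codes in event_systems:
            n_ev = int(rng.integers(0, 4))
            in_window_idx: list[int] = []
            for _ in range(n_ev):
                code_i = int(rng.integers(len(codes)))
                offset_h = float(rng.uniform(-2 * window_h, 2 * window_h))
                events.append(
                    EventRecord(
                        system=system,
                        code=codes[code_i],
                        timestamp=ts + timedelta(hours=offset_h),
                    )
                )
                if abs(offset_h) <= window_h:
                    in_window_idx.append(code_i)
            weight = weight * _event_factor(mats[cid], in_window_idx)

        sec_labels = labels["note_section"]
        n_sec = min(spec.sections_per_note, len(sec_labels))
        sec_idx = rng.choice(len(sec_labels), size=n_sec, replace=False)
        sections: list[SectionRecord] = []
        for si in sec_idx:
            w = weight * mats["note_section"][:, si]
            total = w.sum()
            p = w / total if total > 0 else np.full(v, 1.0 / v)
            toks = vocab_arr[rng.choice(v, size=spec.tokens_per_section, p=p)]
            sections.append(
                SectionRecord(section_name=sec_labels[si], text=" ".join(toks))
            )
        notes.append(
            NoteRecord(
                note_id=f"note{i:05d}",
                patient_id=f"pt{int(rng.integers(0, max(1, spec.n_notes // 3))):05d}",
                timestamp=ts,
                department=labels["department"][dept_i],
                staff_type=labels["staff"][staff_i],
                note_type=labels["note_type"][type_i],
                patient_age_years=age,
                patient_gender=Gender(gender_labels[gender_i]),
                events=tuple(events),
                sections=tuple(sections),
            )
        )
    return notes


def planted_preference_probability(
    spec: SyntheticSpec, space: MedicalContextVectorSet, term: str
) -> float:
    """The reviewer's highlight propensity sigmoid(b0 + sum_c w*_c S_c(K, w))."""
    logit = spec.reviewer_intercept
    for w_c, cid in zip(spec.reviewer_weights, space.registry.context_ids):
        logit += w_c * context_cosine(space, spec.topic_word, term, cid)
    return float(1.0 / (1.0 + np.exp(-logit)))


def generate_highlights(
    spec: SyntheticSpec,
    notes: Sequence[NoteRecord],
    space: MedicalContextVectorSet,
) -> HighlightSet:
    """Simulate the reviewer: each occurrence of term w in a note is
    highlighted independently with probability p(w) * highlight_rate, where
    p(w) is the planted linear-logit preference probability."""
    if spec.topic_word not in space:
        raise ValueError(f"topic word '{spec.topic_word}' absent from vector space")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    probs: dict[str, float] = {}
    for term in space.vectors:
        p = planted_preference_probability(spec, space, term) * spec.highlight_rate
        probs[term] = min(1.0, max(0.0, p))
    entries: dict[tuple[str, str], int] = {}
    for note in notes:
        occ: dict[str, int] = {}
        for section in note.sections:
            for tok in tokenize(section.text):
                occ[tok] = occ.get(tok, 0) + 1
        for term in sorted(occ):
            p = probs.get(term)
            if not p:
                continue
            h = int(rng.binomial(occ[term], p))
            if h > 0:
                entries[(note.note_id, term)] = h
    return HighlightSet(entries=entries)


@dataclass
class SyntheticBundle:
    """A complete synthetic chart-review task plus its ground truth."""

    spec: SyntheticSpec
    notes: list[NoteRecord]
    highlights: HighlightSet
    candidates: list[str]
    space: MedicalContextVectorSet
    truth: dict


def make_bundle(spec: SyntheticSpec | None = None) -> SyntheticBundle:
    """Profiles -> notes -> vector space -> highlights, with truth recorded.

    Candidates are the full vocabulary minus the topic word.
    """
    spec = spec or SyntheticSpec()
    registry = default_registry()
    profiles = sample_term_profiles(spec, registry)
    notes = generate_notes(spec, profiles, registry)
    space = build_space(notes, registry)
    highlights = generate_highlights(spec, notes, space)
    candidates = [t for t in spec.vocabulary if t != spec.topic_word]
    truth = {
        "reviewer_weights": list(spec.reviewer_weights),
        "reviewer_intercept": spec.reviewer_intercept,
        "related_terms": spec.related_terms,
        "profiles": {
            term: {cid: prof.tolist() for cid, prof in by_ctx.items()}
            for term, by_ctx in profiles.items()
        },
    }
    return SyntheticBundle(
        spec=spec,
        notes=notes,
        highlights=highlights,
        candidates=candidates,
        space=space,
        truth=truth,
    )


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> dict[str, Path]:
    """Write notes JSONL, highlights TSV, candidates TXT and truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "notes": outdir / "notes.jsonl",
        "highlights": outdir / "highlights.tsv",
        "candidates": outdir / "candidates.txt",
        "truth": outdir / "truth.json",
    }
    write_notes(bundle.notes, paths["notes"])
    with paths["highlights"].open("w") as fh:
        fh.write("note_id\tterm\tcount\n")
        for (note_id, term), count in sorted(bundle.highlights.entries.items()):
            fh.write(f"{note_id}\t{term}\t{count}\n")
    paths["candidates"].write_text("\n".join(bundle.candidates) + "\n")
    paths["truth"].write_text(json.dumps(bundle.truth, sort_keys=True))
    return paths
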