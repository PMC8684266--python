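"""Accumulation and normalization of the medical-context vector space."""

from collections import Counter
from datetime import datetime, timedelta

import pytest

from medctx import (
    EventRecord,
    Gender,
    NoteRecord,
    SectionRecord,
    accumulate,
    active_attributes,
    build_space,
    default_registry,
    dimension_summary,
    normalize,
    tokenize,
    top_dimensions,
)
from medctx.contexts import ContextScope, MedicalContextVectorSet

TS = datetime(2016, 3, 1, 10, 0)


def make_note(note_id="n1", department="Neuro-Epilepsy", age=26, gender="male",
              events=(), sections=(("body", "eeg eeg eeg eeg"),), **kw):
    return NoteRecord(
        note_id=note_id,
        patient_id="p1",
        timestamp=TS,
        department=department,
        staff_type=kw.get("staff_type", "physician"),
        note_type=kw.get("note_type", "progress"),
        patient_age_years=age,
        patient_gender=Gender(gender),
        events=tuple(events),
        sections=tuple(SectionRecord(section_name=n, text=t) for n, t in sections),
    )


class TestActiveAttributes:
    def test_department_singleton(self):
        attrs = active_attributes(make_note(), default_registry())
        assert attrs["department"] == {"Neuro-Epilepsy"}

    def test_age_bin(self):
        attrs = active_attributes(make_note(age=26), default_registry())
        assert attrs["age"] == {"20-29"}

    def test_age_open_top_bin(self):
        attrs = active_attributes(make_note(age=97), default_registry())
        assert attrs["age"] == {"90+"}

    @pytest.mark.parametrize("hours,expect", [(49, set()), (47, {"345.90"}), (-47, {"345.90"})])
    def test_event_window(self, hours, expect):
        ev = EventRecord(system="ICD", code="345.90", timestamp=TS + timedelta(hours=hours))
        attrs = active_attributes(make_note(events=[ev]), default_registry())
        assert attrs["icd_event"] == expect

    def test_section_contexts_not_note_level(self):
        attrs = active_attributes(make_note(), default_registry())
        assert "note_section" not in attrs and "top_note_section" not in attrs


class TestAccumulate:
    def test_department_counts_per_occurrence(self):
        tcc = accumulate([make_note()], default_registry(), stopwords=set())
        assert tcc.counts["eeg"]["department"]["Neuro-Epilepsy"] == 4

    def test_empty_corpus(self):
        tcc = accumulate([], default_registry())
        assert tcc.counts == {}

    def test_event_level_each_code_incremented(self):
        events = [
            EventRecord(system="ICD", code="250.00", timestamp=TS),
            EventRecord(system="ICD", code="401.9", timestamp=TS + timedelta(hours=1)),
            EventRecord(system="ICD", code="345.90", timestamp=TS + timedelta(hours=60)),
        ]
        note = make_note(events=events, sections=(("body", "pain"),))
        tcc = accumulate([note], default_registry(), stopwords=set())
        assert tcc.counts["pain"]["icd_event"] == Counter({"250.00": 1, "401.9": 1})

    def test_section_vs_top_section(self):
        note = make_note(sections=(("medications", "keppra keppra"), ("plan", "keppra")))
        tcc = accumulate([note], default_registry(), stopwords=set())
        assert tcc.counts["keppra"]["note_section"] == Counter({"medications": 2, "plan": 1})
        # only the key section flows into the top-note-section context
        assert tcc.counts["keppra"]["top_note_section"] == Counter({"medications": 2})
        # note-level contexts see all 3 occurrences regardless of section
        assert tcc.counts["keppra"]["department"]["Neuro-Epilepsy"] == 3

    def test_conservation_against_brute_force(self, tiny_bundle):
        """Per (term, context) totals match an independent single pass."""
        registry = default_registry()
        notes = tiny_bundle.notes[:40]
        tcc = accumulate(notes, registry)
        window = timedelta(hours=registry.event_window_hours)
        system_for = {"icd_event": "ICD", "cpt_event": "CPT",
                      "chief_complaint": "chief_complaint"}
        oracle: Counter = Counter()
        for note in notes:
            sec_tokens = [(s.section_name.lower(), tokenize(s.text)) for s in note.sections]
            note_occ = Counter(t for _, toks in sec_tokens for t in toks)
            multiplicity = {
                "department": 1, "staff": 1, "note_type": 1, "gender": 1, "age": 1}
            for cid, system in system_for.items():
                codes = {e.code for e in note.events
                         if e.system.value == system and abs(e.timestamp - note.timestamp) <= window}
                multiplicity[cid] = len(codes)
            for term, n in note_occ.items():
                for cid, m in multiplicity.items():
                    oracle[(term, cid)] += n * m
            for sec_name, toks in sec_tokens:
                for term, n in Counter(toks).items():
                    oracle[(term, "note_section")] += n
                    if sec_name in registry.key_sections:
                        oracle[(term, "top_note_section")] += n
        for term, by_ctx in tcc.counts.items():
            for cid, ctr in by_ctx.items():
                assert sum(ctr.values()) == oracle[(term, cid)], (term, cid)

    def test_additivity(self, tiny_bundle):
        notes = tiny_bundle.notes[:20]
        a, b = notes[:11], notes[11:]
        whole = accumulate(notes).counts
        pa, pb = accumulate(a).counts, accumulate(b).counts
        for term in set(pa) | set(pb):
            for cid in set(pa.get(term, {})) | set(pb.get(term, {})):
                expected = Counter(pa.get(term, {}).get(cid, Counter()))
                expected.update(pb.get(term, {}).get(cid, Counter()))
                assert whole[term][cid] == expected

    def test_order_invariance(self, tiny_bundle):
        notes = tiny_bundle.notes[:20]
        assert accumulate(notes).counts == accumulate(list(reversed(notes))).counts


class TestNormalize:
    def test_proportions(self):
        tcc = accumulate(
            [make_note(sections=(("body", "eeg eeg eeg seizure"),))],
            default_registry(), stopwords=set())
        space = normalize(tcc)
        vec = space.context_vector("eeg", "department")
        assert vec == {"Neuro-Epilepsy": 1.0}
        sec = space.context_vector("eeg", "note_section")
        assert sec["body"] == 1.0

    def test_l1_split(self):
        notes = [
            make_note(note_id="n1", department="A", sections=(("body", "eeg eeg eeg"),)),
            make_note(note_id="n2", department="B", sections=(("body", "eeg"),)),
        ]
        space = normalize(accumulate(notes, default_registry(), stopwords=set()))
        assert space.context_vector("eeg", "department") == {"A": 0.75, "B": 0.25}

    def test_every_nonzero_vector_sums_to_one(self, tiny_bundle):
        for term, by_ctx in tiny_bundle.space.vectors.items():
            for cid, vec in by_ctx.items():
                if vec:
                    assert abs(sum(vec.values()) - 1.0) < 1e-9
                    assert all(0.0 <= v <= 1.0 for v in vec.values())


def test_dimension_summary(tiny_bundle):
    summary = dimension_summary(tiny_bundle.space)
    depts = {n.department for n in tiny_bundle.notes}
    genders = {n.patient_gender.value for n in tiny_bundle.notes}
    assert summary["department"] == len(depts)
    assert summary["gender"] == len(genders)
    assert summary["top_note_section"] <= 5


def test_dimension_summary_empty():
    space = normalize(accumulate([], default_registry()))
    assert all(v == 0 for v in dimension_summary(space).values())


class TestTopDimensions:
    def _space(self, text_by_dept):
        notes = [
            make_note(note_id=f"n{i}", department=d, sections=(("body", t),))
            for i, (d, t) in enumerate(text_by_dept)
        ]
        return normalize(accumulate(notes, default_registry(), stopwords=set()))

    def test_descending(self):
        space = self._space([("A", "eeg " * 5), ("B", "eeg " * 3), ("C", "eeg " * 2)])
        assert top_dimensions(space, "eeg", "department", 2) == [("A", 0.5), ("B", 0.3)]

    def test_tie_break_by_label(self):
        space = self._space([("B", "eeg eeg"), ("A", "eeg eeg"), ("C", "eeg")])
        assert top_dimensions(space, "eeg", "department", 1) == [("A", 0.4)]

    def test_fewer_than_k(self):
        space = self._space([("A", "eeg")])
        assert top_dimensions(space, "eeg", "cpt_event", 3) == []

    def test_unknown_term(self):
        space = self._space([("A", "eeg")])
        with pytest.raises(KeyError):
            top_dimensions(space, "absent", "department", 1)


def test_archive_round_trip_and_determinism(tiny_bundle, tmp_path):
    p1, p2 = tmp_path / "s1.json", tmp_path / "s2.json"
    tiny_bundle.space.save(p1)
    tiny_bundle.space.save(p2)
    assert p1.read_bytes() == p2.read_bytes()
    loaded = MedicalContextVectorSet.load(p1)
    assert loaded.vectors == tiny_bundle.space.vectors
    assert loaded.registry == tiny_bundle.space.registry
    assert loaded.dimension_catalogs == tiny_bundle.space.dimension_catalogs
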