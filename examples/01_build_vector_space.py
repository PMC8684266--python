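"""Build a medical-context vector space from a (synthetic) note corpus.

Generates a small corpus, accumulates per-term usage counts across the ten
medical contexts, normalizes them into proportions, and inspects where the
topic word is used.
"""

from medctx import SyntheticSpec, build_space, dimension_summary, generate_notes, \
    sample_term_profiles, top_dimensions

spec = SyntheticSpec(seed=1, n_notes=300, vocab_size=200, n_related_terms=20)
notes = generate_notes(spec, sample_term_profiles(spec))
space = build_space(notes)

print("observed dimensions per context:")
for cid, n in dimension_summary(space).items():
    print(f"  {cid:18s} {n}")

print(f"\ntop dimensions for '{spec.topic_word}':")
for cid in ("department", "note_section", "chief_complaint"):
    top = top_dimensions(space, spec.topic_word, cid, 3)
    pretty = ", ".join(f"{label} ({p:.2f})" for label, p in top)
    print(f"  {cid:18s} {pretty}")

# Each proportion is the share of the term's occurrences that fall under
# that attribute value, so each context row sums to 1 where the term occurs.
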