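"""Learn a reviewer's semantic preference from highlight counts.

Labels come from total highlight counts (important iff H > cutoff); a
logistic model on the per-context similarity features then ranks unlabeled
candidates and exposes interpretable context weights.
"""

from medctx import (
    SyntheticSpec, aggregate_highlight_counts, build_labels, featurize,
    interpret, make_bundle, predict_scores, rank, train,
)

bundle = make_bundle(SyntheticSpec(seed=2))
spec = bundle.spec
H = aggregate_highlight_counts(bundle.highlights)
labels = build_labels(bundle.candidates, H, cutoff=1)
features = featurize(bundle.space, spec.topic_word, bundle.candidates)
model = train(features, labels, "logistic_regression", seed=0)

print(f"{labels.positives} of {len(bundle.candidates)} candidates labeled important (I=1)\n")
print("top 5 recommended terms:")
for term, score in rank(predict_scores(model, features)).entries[:5]:
    print(f"  {term}\t{score:.3f}")

print("\nfitted context weights vs the planted reviewer weights:")
table = interpret(model)
for (_, row), true_w in zip(table.iloc[1:].iterrows(), spec.reviewer_weights):
    star = "*" if row.p_value < 0.05 else ""
    print(f"  {row.context:18s} fitted {row.coefficient:+6.2f}{star}  planted {true_w:+5.1f}")
# The fitted coefficients order the contexts the same way as the planted
# weights: the model has learned which contexts this reviewer cares about.
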