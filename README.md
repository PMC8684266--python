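# medctx — medical-context vector space for chart-review query expansion

Chart review — a clinician reading a patient's notes to answer a specific
question — usually starts from a keyword and relies on highlighting similar
terms. Which terms count as "similar" depends on the task: a reviewer
studying seizures cares about terms that co-occur with the same chief
complaints and ICD codes, not terms that merely look alike in running text.
`medctx` represents each clinical term by *how it is used*, not what it says:
its normalized usage frequencies across ten non-textual **medical contexts**
of the notes it appears in —

| group | contexts |
|---|---|
| hospital organizational structure | author department, author staff type |
| medical events (within 48 h of the note) | ICD codes, CPT codes, chief complaints |
| demographics | patient age (ten-year bins), gender |
| note structure | note type, note section, top note sections |

For a term *w*, the context-*c* vector *u_c(w)* holds the proportion of
*w*'s occurrences under each attribute value of *c* (each non-empty vector
sums to 1). The similarity of two terms in context *c* is the cosine

    S_c(w_i, w_j) = u_c(w_i) · u_c(w_j) / (‖u_c(w_i)‖ ‖u_c(w_j)‖)

and the **medical-context similarity vector** S(w_i, w_j) stacks the ten
per-context cosines. Given a topic word *K*, a candidate set, and reviewer
highlight counts H(w) (a candidate is *important* when H(w) > cutoff *I*),
a classifier on S(K, w) learns the reviewer's **semantic preference** and
ranks unlabeled candidates. With logistic regression the fitted weights are
directly interpretable:

    ln( P(preferred) / P(non-preferred) ) = intercept + Σ_c W_c · S_c(w, K)

The package includes the full evaluation machinery (importance-cutoff sweep,
seeded stratified ten-fold cross-validation with AUROC, one-sided
Mann–Whitney comparison of feature spaces, 1%–90% learning curves) and a
synthetic EMR generator with planted ground truth, so every protocol runs
end to end without access to restricted clinical data.

## Worked example

```python
from medctx import (SyntheticSpec, aggregate_highlight_counts, build_labels,
                    featurize, interpret, make_bundle, train)

bundle = make_bundle(SyntheticSpec(seed=2))          # 800 notes, 1000 candidates
H = aggregate_highlight_counts(bundle.highlights)
labels = build_labels(bundle.candidates, H, cutoff=1)
features = featurize(bundle.space, bundle.spec.topic_word, bundle.candidates)
model = train(features, labels, "logistic_regression", seed=0)
print(interpret(model))
```

prints (excerpt; full script in `examples/03_preference_model.py`):

```
  department         fitted  +1.16*  planted  +1.0
  staff              fitted  +0.61*  planted  +0.5
  icd_event          fitted  +1.99*  planted  +4.0
  cpt_event          fitted  +1.17*  planted  +1.5
  chief_complaint    fitted  +5.42*  planted  +8.0
  ...
```

Each row is one medical context: the fitted logistic weight (starred when
the one-tailed Wald p < 0.05) next to the weight the synthetic reviewer was
generated with. The fitted weights recover the planted ordering — the model
has learned *which contexts this reviewer's notion of similarity lives in*
(here chief complaint and note type dominate) from a single cutoff's labels.

`examples/` contains one short script per capability: building the space,
per-context similarity rankings, preference learning, and both evaluation
protocols. The `medctx` CLI exposes the same pipeline as subcommands
(`simulate`, `build-space`, `similar`, `featurize`, `train`, `recommend`,
`evaluate`, `learning-curve`, `interpret`); every run writes a manifest with
the resolved parameters, seed and input checksums.

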