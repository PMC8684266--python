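# Methods

## The medical-context vector space

Each clinical term is represented per context by the empirical distribution
of its occurrences over that context's attribute values. Building the space
is a single corpus pass: initialize every term's per-context counts at zero;
for each note, tokenize each section (case-fold, split on non-alphanumeric
runs, drop stop words and single-character tokens) and

* for **note-level contexts** (department, staff type, note type, age bin,
  gender) add every token occurrence anywhere in the note to the note's
  single attribute value;
* for **event-level contexts** (ICD, CPT, chief complaint) add every token
  occurrence to *each distinct code* of that system documented within the
  event window (default 48 h, configurable) of the note's timestamp — no
  division among co-occurring codes, so a token near two in-window ICD codes
  contributes one count to each;
* for the **note-section context** add each occurrence to the section it
  occurs in, and for the **top-note-section context** only when that section
  is one of the designated key sections (default: assessment, findings,
  family medical history, medications, problem list).

Counts are then L1-normalized per term per context into proportions; an
all-zero context vector stays all-zero. L1 (rather than L2) normalization is
used because the vectors are interpreted as usage-frequency distributions;
the cosine similarity consumed downstream is scale-invariant, so the choice
does not affect similarity values.

Age is binned into ten-year bins `0-9 … 80-89` with an open-ended `90+` bin
(edges configurable). Vectors are stored sparsely by attribute label;
per-context catalogs of observed labels define the shared index space, so no
fixed dimensionality needs declaring up front. The archive format is a
single JSON file with sorted keys, making rebuilds bit-reproducible.

Tokenization keeps numeric tokens (dosages and lab values can be meaningful
query terms); the bundled stop-word list is a compact set of English
function words and can be replaced by a user file. Both choices are
configurable because real deployments differ on them.

## Similarity and preference learning

Per-context similarity is the cosine of the two sparse context vectors,
defined as 0.0 when either vector is all-zero (no usage evidence ⇒ no
similarity), and clamped to [0, 1] (non-negative inputs admit no negative
cosine; clamping only absorbs rounding). The sparse dot product iterates the
sorted key intersection so the value is exactly symmetric in its arguments.

The feature vector of a candidate w for topic K is S(K, w), the ten
per-context cosines in registry order. Three classifiers are provided with
fixed, recorded hyperparameters: L2-penalized logistic regression (C = 1),
a 100-tree random forest, and an RBF SVM with Platt-style probability
calibration; all are seeded and deterministic. Similarity features are used
unstandardized (they already live in [0, 1]); raw-embedding baseline
features are standardized per feature before fitting to avoid scale
pathologies (a recorded flag on the model).

Labels are strict-threshold: important iff H(w) > I, with terms absent from
the highlight record counted as H = 0. Multi-token highlight rows decompose
into their tokens, each credited with the row's count, because H is defined
per term rather than per span.

`interpret` reports the logistic coefficient table with one-tailed Wald
p-values computed from the curvature (observed information) of the penalized
log-likelihood at the fit, with the intercept unpenalized to match the
estimator. Wald was chosen because the fit is penalized (a likelihood-ratio
test against the penalized deviance is not asymptotically χ²); with C = 1
and hundreds of candidates the penalty's effect on the standard errors is
small.

## Evaluation protocols

**Cutoff sweep + cross-validation.** Starting at I = 1, build labels and run
stratified ten-fold cross-validation, reporting per-fold AUROC; increment I
until fewer than 10 candidates are important (10 positives guarantee every
test fold at least one positive under stratification; at least 10 negatives
are required for the same reason). AUROC uses the Mann–Whitney formulation
(ties credited 1/2). Feature spaces are compared at matched cutoff and model
by a one-sided Mann–Whitney U test on the two sets of fold AUROCs: exact
null distribution when both sides have ≤ 10 tie-free values, otherwise the
normal approximation with tie correction and continuity; two identical fold
multisets are reported as p = 0.5 (no directional evidence).

**Learning curve.** For each fraction x in 1%…90% (step 1%), draw a
stratified training set of max(2, round(x·n)) candidates with at least one
instance of each class on both sides of the split, train, and compute AUROC
on the complement; 100 independent seeded repetitions per fraction, with the
test set refreshed every draw (it is the draw's complement). Degenerate
draws are redrawn and counted.

## The synthetic generator

The generator emulates the statistical shape of a chart-review task, not
clinical language. Its moving parts:

* **Latent profiles.** Each term gets, per context, a Dirichlet(0.4)
  categorical over that context's attribute values. Low concentration gives
  the spiky, specialized usage patterns real clinical terms show. The
  top-note-section profile is derived from the note-section profile
  restricted to the key sections, since that is how the accumulation rule
  relates the two contexts.
* **Related terms.** 60 of the 1000 candidates copy the topic word's profile
  exactly in three contexts (chief complaint, ICD events, note type) and
  sample independently elsewhere — terms genuinely similar to the topic in
  some usages, not others.
* **Notes.** 800 notes sample attributes uniformly (8 departments, 6 staff
  types, 6 note types, 3 genders, ages 0–89, 0–3 events per coding system
  with timestamps spread inside and outside the 48 h window); each of 5
  sections per note is filled with 40 tokens drawn with probability
  proportional to the product of the term's profile mass on the note's
  attributes. The corpus-level vector space therefore estimates the planted
  profiles. Because a note's term weights are renormalized against the whole
  vocabulary and occurrences cluster within notes, the empirical usage
  distribution of a term converges to its profile with an effective sample
  size of *notes carrying the term*, not raw occurrences — tests of this
  convergence use mild dispersion (concentration 5) so the check is
  well-powered.
* **Reviewer.** Highlighting follows the same linear-logit form the
  preference model fits: each occurrence of w is highlighted with
  probability sigmoid(−14 + Σ_c w*_c · S_c(topic, w)) × 0.05, with planted
  weights (1.0, 0.5, 4.0, 1.5, 8.0, 2.0, 3.0, 6.0, 2.5, 5.0) in registry
  order — all distinct, spanning an unambiguous ordering so rank recovery is
  informative, with chief complaint dominant. The intercept centers the
  unrelated candidates' logits a few units below zero (their summed
  similarity contribution is roughly +10), giving a broad spread of
  highlight propensities; the 0.05 per-occurrence rate converts ~200
  occurrences per term into single-digit highlight counts, so the cutoff
  sweep at I = 1 comfortably exceeds the 10-positive protocol floor and
  continues for roughly a dozen cutoffs.

Matching the reviewer's functional form to the fitted model makes weight
recovery well-posed by design; the generator does not model reviewer
disagreement, annotation fatigue, or non-linear preference, so passing
results say the pipeline recovers a linear-logit reviewer from realistic
count noise — not that real reviewers are linear.

All stages derive their randomness from the spec's single seed through
separate seed sequences, so every artifact (notes JSONL, highlights TSV,
vector-space archive, fitted models, reports) reproduces byte-for-byte.

## Problem sizes and numerical choices

Default study conditions — 1000 candidates, 800 notes, 5×40 tokens per note
— were chosen as the scale of one real chart-review task (candidate sets of
roughly a thousand terms) while keeping the full pipeline (space build,
cutoff sweep with ten-fold CV, and two 90-fraction × 100-rep learning
curves) at about two minutes on one CPU. Normalization uses a 1e-9 tolerance
on vector sums; the sparse-cosine oracle agreement is checked to 1e-12;
all-zero feature rows (candidates absent from the space) are admitted with a
warning by default and a hard error under `strict=True`. Ranking ties break
lexicographically everywhere for determinism.

## Known limitations

* Sections are taken as given in the input records; no section tagger is
  bundled (a note without sections must be wrapped as a single `body`
  section upstream).
* Candidate semantic sets are an input; the package does not generate
  candidates from a corpus beyond the unsupervised mean-cosine ranking.
* No ICD-9↔ICD-10 mapping or code-hierarchy rollup: codes are opaque labels.
* Event accumulation gives every in-window code a full count; a
  co-occurrence-weighted alternative would change event-context vectors for
  densely coded patients.
* `top_k_similar`'s unweighted mean over contexts is a convenience for
  exploration; the supervised preference model is the task-aware ranking.
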