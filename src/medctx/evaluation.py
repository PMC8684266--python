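"""Evaluation protocols for semantic-preference prediction.

Two protocols are provided, each usable with any feature space:

* **Cutoff sweep + cross-validation.** Starting at importance cutoff I = 1,
  build a label set, run seeded stratified ten-fold cross-validation and
  record per-fold AUROC; increment I until fewer than ten candidates are
  labeled important (ten positives are required so every test fold contains
  at least one positive). Feature spaces are compared at matched cutoffs by
  a one-sided Mann-Whitney U test on the ten fold AUROCs.

* **Learning curve.** For each training fraction x on a 1%-90% grid, draw a
  stratified x-fraction training set, train, and measure AUROC on the
  complement; repeat (default 100 times) and record every repetition.

AUROC follows the Mann-Whitney formulation: the probability that a random
positive outscores a random negative, ties credited 1/2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .preference import LabelSet, _make_estimator, build_labels
from .similarity import FeatureMatrix

__all__ = [
    "CVResult",
    "ComparisonResult",
    "LearningCurveResult",
    "auroc",
    "cutoff_sweep",
    "cross_validate",
    "compare_feature_spaces",
    "learning_curve",
    "MIN_POSITIVES",
]

logger = logging.getLogger(__name__)

# Minimum positive labels for ten-fold CV: with stratification this puts at
# least one positive in every test fold.
MIN_POSITIVES = 10
N_FOLDS = 10
DEFAULT_FRACTIONS: tuple[float, ...] = tuple(round(0.01 * i, 2) for i in range(1, 91))


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve (Mann-Whitney form, ties counted 1/2)."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("AUROC undefined: labels contain a single class")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def cutoff_sweep(
    candidates: list[str],
    H: Mapping[str, int],
    min_positives: int = MIN_POSITIVES,
) -> list[tuple[int, LabelSet]]:
    """Label sets for I = 1, 2, ... while at least ``min_positives``
    candidates remain labeled important; the first cutoff below that is
    excluded. May be empty."""
    out: list[tuple[int, LabelSet]] = []
    if not candidates:
        return out
    cutoff = 1
    while True:
        labels = build_labels(candidates, H, cutoff)
        if labels.positives < min_positives:
            break
        out.append((cutoff, labels))
        cutoff += 1
    return out


@dataclass(frozen=True)
class CVResult:
    cutoff: int
    model_kind: str
    feature_space_name: str
    fold_aurocs: tuple[float, ...]
    mean_auroc: float


def cross_validate(
    features: FeatureMatrix,
    labels: LabelSet,
    model_kind: str = "logistic_regression",
    seed: int = 0,
    feature_space_name: str = "medical_context",
    standardize: bool = False,
) -> CVResult:
    """Seeded stratified ten-fold cross-validation; per-fold AUROC."""
    terms = [t for t in features.terms if t in labels.labels]
    sub = features.subset(terms)
    y = labels.aligned(terms)
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos < MIN_POSITIVES:
        raise ValueError(
            f"ten-fold cross-validation requires >= {MIN_POSITIVES} positive labels "
            f"(got {n_pos}); stop the cutoff sweep earlier"
        )
    if n_neg < N_FOLDS:
        raise ValueError(
            f"ten-fold cross-validation requires >= {N_FOLDS} negative labels (got {n_neg})"
        )
    skf = StratifiedKFold(n_splits=N_FOLDS, shuffle=True, random_state=seed)
    fold_aurocs: list[float] = []
    for train_idx, test_idx in skf.split(sub.features, y):
        est = _make_estimator(model_kind, seed, standardize)
        est.fit(sub.features[train_idx], y[train_idx])
        classes = est.classes_ if hasattr(est, "classes_") else est.named_steps["clf"].classes_
        pos_col = int(np.where(classes == 1)[0][0])
        scores = est.predict_proba(sub.features[test_idx])[:, pos_col]
        fold_aurocs.append(auroc(scores, y[test_idx]))
    return CVResult(
        cutoff=labels.cutoff,
        model_kind=model_kind,
        feature_space_name=feature_space_name,
        fold_aurocs=tuple(fold_aurocs),
        mean_auroc=float(np.mean(fold_aurocs)),
    )


@dataclass(frozen=True)
class ComparisonResult:
    cutoff: int
    model_kind: str
    auroc_a: float
    auroc_b: float
    p_value: float


def compare_feature_spaces(cv_a: CVResult, cv_b: CVResult) -> ComparisonResult:
    """One-sided Mann-Whitney U test that feature space A's fold AUROCs are
    stochastically greater than B's.

    Exact null distribution for tie-free samples of at most ten per side;
    normal approximation with tie correction and continuity otherwise.
    """
    if cv_a.cutoff != cv_b.cutoff:
        raise ValueError(f"cutoff mismatch: {cv_a.cutoff} vs {cv_b.cutoff}")
    if cv_a.model_kind != cv_b.model_kind:
        raise ValueError(f"model mismatch: {cv_a.model_kind} vs {cv_b.model_kind}")
    a = np.asarray(cv_a.fold_aurocs)
    b = np.asarray(cv_b.fold_aurocs)
    if len(a) == len(b) and np.array_equal(np.sort(a), np.sort(b)):
        p_value = 0.5  # identical fold AUROCs carry no directional evidence
    else:
        has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
        method = "exact" if (not has_ties and len(a) <= 10 and len(b) <= 10) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="greater", method=method, use_continuity=True)
        p_value = float(res.pvalue)
    return ComparisonResult(
        cutoff=cv_a.cutoff,
        model_kind=cv_a.model_kind,
        auroc_a=cv_a.mean_auroc,
        auroc_b=cv_b.mean_auroc,
        p_value=p_value,
    )


@dataclass
class LearningCurveResult:
    cutoff: int
    feature_space_name: str
    points: dict[float, list[float]]
    reps: int
    redraws: int = 0

    def mean_curve(self) -> dict[float, float]:
        return {x: float(np.mean(v)) for x, v in self.points.items()}

    def to_frame(self):
        import pandas as pd

        rows = [
            {"fraction": x, "rep": i, "auroc": v}
            for x, vals in sorted(self.points.items())
            for i, v in enumerate(vals)
        ]
        return pd.DataFrame(rows)


def _stratified_draw(
    rng: np.random.Generator, y: np.ndarray, size: int
) -> tuple[np.ndarray, np.ndarray]:
    """Indices of a stratified training draw of ``size`` and its complement,
    with at least one instance of each class on both sides."""
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    n = len(y)
    n_pos = int(round(size * len(pos) / n))
    n_pos = min(max(n_pos, 1), len(pos) - 1)
    n_neg = size - n_pos
    n_neg = min(max(n_neg, 1), len(neg) - 1)
    train = np.concatenate(
        [rng.choice(pos, size=n_pos, replace=False), rng.choice(neg, size=n_neg, replace=False)]
    )
    mask = np.ones(n, dtype=bool)
    mask[train] = False
    return train, np.flatnonzero(mask)


def learning_curve(
    features: FeatureMatrix,
    labels: LabelSet,
    model_kind: str = "logistic_regression",
    reps: int = 100,
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    seed: int = 0,
    feature_space_name: str = "medical_context",
    standardize: bool = False,
) -> LearningCurveResult:
    """Repeated stratified-subsample learning curve.

    For each fraction x the training set has max(2, round(x*n)) candidates,
    stratified with at least one of each class, and the complement is the
    test set; ``reps`` independent seeded draws per fraction.
    """
    terms = [t for t in features.terms if t in labels.labels]
    sub = features.subset(terms)
    y = labels.aligned(terms)
    if int(y.sum()) < 2 or int((1 - y).sum()) < 2:
        raise ValueError("learning curve requires at least two candidates per class")
    rng = np.random.default_rng(seed)
    points: dict[float, list[float]] = {}
    redraws = 0
    for x in fractions:
        size = max(2, int(round(x * len(y))))
        vals: list[float] = []
        for _ in range(reps):
            train_idx, test_idx = _stratified_draw(rng, y, size)
            if len(np.unique(y[test_idx])) < 2:  # complement lost a class
                redraws += 1
                train_idx, test_idx = _stratified_draw(rng, y, size)
            est = _make_estimator(model_kind, seed, standardize)
            est.fit(sub.features[train_idx], y[train_idx])
            classes = (
                est.classes_ if hasattr(est, "classes_") else est.named_steps["clf"].classes_
            )
            pos_col = int(np.where(classes == 1)[0][0])
            scores = est.predict_proba(sub.features[test_idx])[:, pos_col]
            vals.append(auroc(scores, y[test_idx]))
        points[float(x)] = vals
    if redraws:
        logger.info("learning_curve: %d degenerate draws redrawn", redraws)
    return LearningCurveResult(
        cutoff=labels.cutoff,
        feature_space_name=feature_space_name,
        points=points,
        reps=reps,
        redraws=redraws,
    )


def plot_learning_curves(results: Sequence[LearningCurveResult], path):
    """Render mean AUROC vs training fraction for one or more curves."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for res in results:
        curve = res.mean_curve()
        xs = sorted(curve)
        ax.plot([100 * x for x in xs], [curve[x] for x in xs], label=res.feature_space_name)
    ax.set_xlabel("training set size (% of label set)")
    ax.set_ylabel("mean AUROC")
    ax.set_ylim(0.0, 1.05)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
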