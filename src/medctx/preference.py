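"""Learning a reviewer's semantic preference from highlight counts.

A chart-review task has a topic word and a candidate set of possibly-similar
terms. The reviewer's highlights over the task's documents give each
candidate a total highlight count H(w); candidates with H(w) strictly
greater than an importance cutoff I are labeled important (1), the rest 0.
A classifier trained on medical-context similarity vectors then predicts
which unlabeled candidates the reviewer would highlight; with logistic
regression, the per-context coefficients W_c are directly interpretable as
the weight the reviewer places on similarity within each context:

    ln(P(preferred) / P(non-preferred)) = intercept + sum_c W_c * S_c(w, K)
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping

import joblib
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.calibration import CalibratedClassifierCV
from sklearn.linear_model import LogisticRegression
from sklearn.ensemble import RandomForestClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .corpus import HighlightSet
from .similarity import FeatureMatrix

__all__ = [
    "ModelKind",
    "LabelSet",
    "PreferenceModel",
    "RankedRecommendation",
    "aggregate_highlight_counts",
    "build_labels",
    "train",
    "predict_scores",
    "rank",
    "interpret",
]

ModelKind = Literal["logistic_regression", "random_forest", "svm"]
MODEL_KINDS: tuple[str, ...] = ("logistic_regression", "random_forest", "svm")

# Fixed, recorded hyperparameters: L2 logistic at unit strength, 100-tree
# forest, RBF SVM with Platt probability calibration.
LOGISTIC_C = 1.0


def aggregate_highlight_counts(
    highlights: HighlightSet, doc_ids: Iterable[str] | None = None
) -> dict[str, int]:
    """Total highlight count H(w) per term over the given documents
    (all documents when ``doc_ids`` is None)."""
    docs = set(doc_ids) if doc_ids is not None else None
    out: dict[str, int] = {}
    for (note_id, term), count in highlights.entries.items():
        if docs is None or note_id in docs:
            out[term] = out.get(term, 0) + count
    return out


@dataclass(frozen=True)
class LabelSet:
    """Importance labels for a candidate set at one cutoff I."""

    labels: dict[str, int]
    cutoff: int
    positives: int

    def aligned(self, terms: Iterable[str]) -> np.ndarray:
        return np.array([self.labels[t] for t in terms], dtype=int)


def build_labels(candidates: list[str], H: Mapping[str, int], cutoff: int) -> LabelSet:
    """Label each candidate 1 iff H(term) > cutoff (strict), else 0.

    Candidates absent from ``H`` count as never highlighted.
    """
    if not candidates:
        raise ValueError("candidate list is empty")
    if cutoff < 1:
        raise ValueError(f"importance cutoff must be >= 1, got {cutoff}")
    labels = {term: int(H.get(term, 0) > cutoff) for term in candidates}
    return LabelSet(labels=labels, cutoff=cutoff, positives=sum(labels.values()))


def _make_estimator(model_kind: str, seed: int, standardize: bool):
    if model_kind == "logistic_regression":
        est = LogisticRegression(C=LOGISTIC_C, solver="lbfgs", max_iter=2000)
    elif model_kind == "random_forest":
        est = RandomForestClassifier(n_estimators=100, random_state=seed)
    elif model_kind == "svm":
        # RBF SVM with Platt-style probability calibration
        est = CalibratedClassifierCV(SVC(kernel="rbf", random_state=seed), ensemble=False)
    else:
        raise ValueError(f"unknown model kind '{model_kind}'; expected one of {MODEL_KINDS}")
    if standardize:
        return Pipeline([("scale", StandardScaler()), ("clf", est)])
    return est


@dataclass
class PreferenceModel:
    """A fitted semantic-preference classifier plus its provenance."""

    model_kind: str
    feature_names: tuple[str, ...]
    estimator: object
    seed: int
    standardize: bool
    context_weights: tuple[float, ...] | None = None
    intercept: float | None = None
    training_X: np.ndarray | None = None
    training_y: np.ndarray | None = None

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path: str | Path) -> "PreferenceModel":
        model = joblib.load(path)
        if not isinstance(model, cls):
            raise TypeError(f"{path} does not contain a PreferenceModel")
        return model


def train(
    features: FeatureMatrix,
    labels: LabelSet,
    model_kind: str = "logistic_regression",
    seed: int = 0,
    standardize: bool = False,
) -> PreferenceModel:
    """Fit a preference classifier on labeled candidates.

    Similarity features already lie in [0, 1] and are used unstandardized by
    default; set ``standardize=True`` for raw-embedding baselines whose
    feature scales are arbitrary.
    """
    missing = [t for t in labels.labels if t not in features.terms]
    if missing:
        raise ValueError(f"labeled terms missing from feature matrix: {missing[:5]}")
    terms = [t for t in features.terms if t in labels.labels]
    sub = features.subset(terms)
    y = labels.aligned(terms)
    if len(np.unique(y)) < 2:
        raise ValueError(
            "labels contain a single class; lower the importance cutoff to "
            "obtain both important and non-important terms"
        )
    est = _make_estimator(model_kind, seed, standardize)
    est.fit(sub.features, y)
    weights: tuple[float, ...] | None = None
    intercept: float | None = None
    if model_kind == "logistic_regression":
        clf = est.named_steps["clf"] if standardize else est
        weights = tuple(float(w) for w in clf.coef_[0])
        intercept = float(clf.intercept_[0])
    return PreferenceModel(
        model_kind=model_kind,
        feature_names=features.feature_names,
        estimator=est,
        seed=seed,
        standardize=standardize,
        context_weights=weights,
        intercept=intercept,
        training_X=sub.features.copy(),
        training_y=y.copy(),
    )


def predict_scores(model: PreferenceModel, features: FeatureMatrix) -> dict[str, float]:
    """Probability-like preference score in [0, 1] per candidate term."""
    if features.feature_names != model.feature_names:
        raise ValueError(
            f"feature names {features.feature_names[:3]}... do not match the "
            f"model's {model.feature_names[:3]}..."
        )
    if len(features.terms) == 0:
        return {}
    proba = model.estimator.predict_proba(features.features)
    classes = (
        model.estimator.classes_
        if hasattr(model.estimator, "classes_")
        else model.estimator.named_steps["clf"].classes_
    )
    pos_col = int(np.where(classes == 1)[0][0])
    return {term: float(p) for term, p in zip(features.terms, proba[:, pos_col])}


@dataclass(frozen=True)
class RankedRecommendation:
    """Candidates ranked by preference score, descending; lexicographic ties."""

    entries: tuple[tuple[str, float], ...]
    model_ref: str = ""


def rank(scores: Mapping[str, float], model_ref: str = "") -> RankedRecommendation:
    ordered = tuple(sorted(scores.items(), key=lambda ts: (-ts[1], ts[0])))
    return RankedRecommendation(entries=ordered, model_ref=model_ref)


def interpret(model: PreferenceModel) -> pd.DataFrame:
    """Coefficient table for a logistic preference model.

    Returns one row per context plus an intercept row, with one-tailed Wald
    p-values computed from the curvature of the penalized log-likelihood at
    the fit (the intercept is unpenalized, matching the estimator).
    """
    if model.model_kind != "logistic_regression":
        raise ValueError(
            f"interpretation requires a logistic_regression model, got '{model.model_kind}'"
        )
    if model.training_X is None or model.training_y is None:
        raise ValueError("model lacks stored fit data needed for Wald statistics")
    X = model.training_X
    if model.standardize:
        scaler: StandardScaler = model.estimator.named_steps["scale"]
        X = scaler.transform(X)
    beta = np.concatenate(([model.intercept], model.context_weights))
    Xd = np.column_stack([np.ones(len(X)), X])
    p = 1.0 / (1.0 + np.exp(-(Xd @ beta)))
    W = p * (1.0 - p)
    hess = Xd.T @ (Xd * W[:, None])
    penalty = np.ones(len(beta)) / LOGISTIC_C
    penalty[0] = 0.0  # intercept unpenalized
    hess += np.diag(penalty)
    cov = np.linalg.inv(hess)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = stats.norm.sf(np.abs(z))  # one-tailed, in the direction of the estimate
    names = ["Intercept"] + list(model.feature_names)
    return pd.DataFrame(
        {"context": names, "coefficient": beta, "std_error": se, "z": z, "p_value": pvals}
    )
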