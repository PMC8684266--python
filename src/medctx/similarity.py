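"""Per-context cosine similarity and similarity-vector features.

The similarity of two terms within one medical context is the cosine of
their sparse, L1-normalized usage vectors for that context. The
medical-context similarity vector of a (topic, candidate) pair stacks those
per-context cosines in registry order; it is the feature vector consumed by
the preference classifiers. A baseline feature space substitutes raw word
embeddings for the similarity vector.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .contexts import MedicalContextVectorSet
from .corpus import EmbeddingTable

__all__ = [
    "SimilarityVector",
    "FeatureMatrix",
    "context_cosine",
    "similarity_vector",
    "featurize",
    "embedding_features",
    "top_k_similar",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimilarityVector:
    """Per-context cosine similarities between a topic word and another term."""

    topic: str
    other: str
    values: tuple[float, ...]


@dataclass(frozen=True)
class FeatureMatrix:
    """Per-candidate feature rows (similarity vectors or embeddings)."""

    terms: tuple[str, ...]
    features: np.ndarray  # shape (len(terms), len(feature_names))
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.features.shape != (len(self.terms), len(self.feature_names)):
            raise ValueError(
                f"feature matrix shape {self.features.shape} does not match "
                f"{len(self.terms)} terms x {len(self.feature_names)} features"
            )

    def row(self, term: str) -> np.ndarray:
        return self.features[self.terms.index(term)]

    def subset(self, terms: Sequence[str]) -> "FeatureMatrix":
        idx = [self.terms.index(t) for t in terms]
        return FeatureMatrix(tuple(terms), self.features[idx], self.feature_names)

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.features, columns=list(self.feature_names))
        df.insert(0, "term", list(self.terms))
        df.to_csv(path, sep="\t", index=False)


def _sparse_cosine(u: Mapping[str, float], v: Mapping[str, float]) -> float:
    if not u or not v:
        return 0.0
    # sorted intersection keeps the sum order-independent, so the cosine is
    # exactly symmetric in its arguments
    dot = sum(u[key] * v[key] for key in sorted(u.keys() & v.keys()))
    nu = math.sqrt(sum(val * val for val in u.values()))
    nv = math.sqrt(sum(val * val for val in v.values()))
    if nu == 0.0 or nv == 0.0:
        return 0.0
    return min(1.0, max(0.0, dot / (nu * nv)))


def context_cosine(
    space: MedicalContextVectorSet, term_i: str, term_j: str, context_id: str
) -> float:
    """Cosine similarity of two terms' usage vectors in one context.

    Defined as 0.0 when either vector is all-zero (no usage evidence implies
    no similarity). Always in [0, 1] since usage vectors are non-negative.
    """
    return _sparse_cosine(
        space.context_vector(term_i, context_id),
        space.context_vector(term_j, context_id),
    )


def similarity_vector(
    space: MedicalContextVectorSet, topic: str, other: str
) -> SimilarityVector:
    """The medical-context similarity vector, one cosine per registry context."""
    values = tuple(
        context_cosine(space, topic, other, cid) for cid in space.registry.context_ids
    )
    return SimilarityVector(topic=topic, other=other, values=values)


def featurize(
    space: MedicalContextVectorSet,
    topic: str,
    candidates: Sequence[str],
    strict: bool = False,
) -> FeatureMatrix:
    """Feature matrix of similarity vectors for a candidate set.

    Candidates absent from the space get an all-zero row and a logged
    warning; pass ``strict=True`` to raise instead.
    """
    if topic not in space:
        raise KeyError(f"topic word '{topic}' not in vector space")
    n_ctx = len(space.registry.context_ids)
    rows = np.zeros((len(candidates), n_ctx))
    for i, cand in enumerate(candidates):
        if cand not in space:
            if strict:
                raise KeyError(f"candidate '{cand}' not in vector space")
            logger.warning("candidate '%s' not in vector space; zero feature row", cand)
            continue
        rows[i] = similarity_vector(space, topic, cand).values
    return FeatureMatrix(tuple(candidates), rows, tuple(space.registry.context_ids))


def embedding_features(
    table: EmbeddingTable, candidates: Sequence[str], strict: bool = False
) -> FeatureMatrix:
    """Baseline feature matrix of raw embedding vectors."""
    if not table.vectors:
        raise ValueError("empty embedding table")
    rows = np.zeros((len(candidates), table.dimension))
    for i, cand in enumerate(candidates):
        vec = table.get(cand)
        if vec is None:
            if strict:
                raise KeyError(f"candidate '{cand}' not in embedding table")
            logger.warning("candidate '%s' not in embedding table; zero feature row", cand)
            continue
        rows[i] = vec
    names = tuple(f"dim_{d}" for d in range(table.dimension))
    return FeatureMatrix(tuple(candidates), rows, names)


def top_k_similar(
    space: MedicalContextVectorSet,
    topic: str,
    k: int,
    context_subset: Iterable[str] | None = None,
) -> list[tuple[str, float]]:
    """Unsupervised top-k terms by mean per-context cosine to the topic.

    A simple unweighted aggregate for exploration; the supervised preference
    model is the task-aware ranking. Ties break lexicographically.
    """
    if topic not in space:
        raise KeyError(f"topic word '{topic}' not in vector space")
    cids = list(context_subset) if context_subset is not None else space.registry.context_ids
    unknown = set(cids) - set(space.registry.context_ids)
    if unknown:
        raise KeyError(f"unknown context id(s): {sorted(unknown)}")
    scored = []
    for term in space.vectors:
        if term == topic:
            continue
        score = float(np.mean([context_cosine(space, topic, term, cid) for cid in cids]))
        scored.append((term, score))
    scored.sort(key=lambda ts: (-ts[1], ts[0]))
    return scored[: max(0, k)]
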