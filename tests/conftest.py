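import numpy as np
import pytest

from medctx import (
    EmbeddingTable,
    SyntheticSpec,
    aggregate_highlight_counts,
    cutoff_sweep,
    featurize,
    make_bundle,
)


@pytest.fixture(scope="session")
def tiny_spec():
    return SyntheticSpec(
        seed=7,
        n_notes=60,
        vocab_size=40,
        n_related_terms=8,
        tokens_per_section=15,
        sections_per_note=4,
    )


@pytest.fixture(scope="session")
def tiny_bundle(tiny_spec):
    return make_bundle(tiny_spec)


@pytest.fixture(scope="session")
def default_bundle():
    """The package's default study conditions: 1000 candidates, 800 notes."""
    return make_bundle(SyntheticSpec(seed=0))


@pytest.fixture(scope="session")
def default_H(default_bundle):
    return aggregate_highlight_counts(default_bundle.highlights)


@pytest.fixture(scope="session")
def default_sweep(default_bundle, default_H):
    return cutoff_sweep(default_bundle.candidates, default_H)


@pytest.fixture(scope="session")
def default_features(default_bundle):
    return featurize(default_bundle.space, default_bundle.spec.topic_word,
                     default_bundle.candidates)


@pytest.fixture(scope="session")
def gaussian_embedding(default_bundle):
    """A 100-dimensional random-Gaussian embedding over the candidate set:
    an uninformative baseline feature space."""
    rng = np.random.default_rng(12345)
    vocab = [default_bundle.spec.topic_word] + default_bundle.candidates
    return EmbeddingTable(
        dimension=100,
        vectors={t: tuple(rng.standard_normal(100)) for t in vocab},
    )
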