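"""Label construction, preference classifiers and interpretable weights."""

import numpy as np
import pytest
from scipy.special import expit

from medctx import (
    HighlightSet,
    FeatureMatrix,
    aggregate_highlight_counts,
    build_labels,
    interpret,
    predict_scores,
    rank,
    train,
)
from medctx.evaluation import auroc
from medctx.preference import PreferenceModel


class TestAggregateHighlights:
    def test_sum_over_docs(self):
        hs = HighlightSet(entries={("n1", "eeg"): 2, ("n2", "eeg"): 3})
        assert aggregate_highlight_counts(hs, {"n1", "n2"}) == {"eeg": 5}

    def test_doc_restriction(self):
        hs = HighlightSet(entries={("n1", "eeg"): 2, ("n2", "eeg"): 3})
        assert aggregate_highlight_counts(hs, {"n1"}) == {"eeg": 2}

    def test_empty(self):
        assert aggregate_highlight_counts(HighlightSet(entries={})) == {}


class TestBuildLabels:
    H = {"a": 5, "b": 1, "c": 0}

    @pytest.mark.parametrize(
        "cutoff,expected,positives",
        [
            (1, {"a": 1, "b": 0, "c": 0}, 1),
            (4, {"a": 1, "b": 0, "c": 0}, 1),
            (5, {"a": 0, "b": 0, "c": 0}, 0),  # strict inequality at the boundary
        ],
    )
    def test_strict_threshold(self, cutoff, expected, positives):
        ls = build_labels(["a", "b", "c"], self.H, cutoff)
        assert ls.labels == expected and ls.positives == positives

    def test_absent_term_counts_zero(self):
        ls = build_labels(["a", "zzz"], self.H, 1)
        assert ls.labels["zzz"] == 0

    def test_empty_candidates(self):
        with pytest.raises(ValueError):
            build_labels([], self.H, 1)

    def test_positives_monotone_in_cutoff(self, default_bundle, default_H):
        prev = None
        for cutoff in range(1, 12):
            pos = build_labels(default_bundle.candidates, default_H, cutoff).positives
            if prev is not None:
                assert pos <= prev
            prev = pos


def separable_features(n=40, seed=0):
    """Positives concentrated at high feature values: linearly separable."""
    rng = np.random.default_rng(seed)
    terms = tuple(f"t{i:03d}" for i in range(n))
    y = np.array([1] * (n // 2) + [0] * (n - n // 2))
    X = np.where(y[:, None] == 1, 0.8, 0.2) + rng.uniform(-0.1, 0.1, size=(n, 3))
    fm = FeatureMatrix(terms, X, ("f0", "f1", "f2"))
    labels = build_labels(list(terms), {t: 5 * int(v) for t, v in zip(terms, y)}, 1)
    return fm, labels, y


@pytest.mark.parametrize("model_kind", ["logistic_regression", "random_forest", "svm"])
def test_train_separable_perfect_training_auroc(model_kind):
    fm, labels, y = separable_features()
    model = train(fm, labels, model_kind, seed=0)
    scores = predict_scores(model, fm)
    assert auroc([scores[t] for t in fm.terms], y) == pytest.approx(1.0)


def test_train_single_class_error():
    fm, _, _ = separable_features()
    all_zero = build_labels(list(fm.terms), {}, 1)
    with pytest.raises(ValueError, match="cutoff"):
        train(fm, all_zero, "logistic_regression")


def test_train_unknown_model_kind():
    fm, labels, _ = separable_features()
    with pytest.raises(ValueError, match="unknown model kind"):
        train(fm, labels, "perceptron")


def test_logistic_exposes_weights_and_intercept():
    fm, labels, _ = separable_features()
    model = train(fm, labels, "logistic_regression")
    assert model.context_weights is not None and len(model.context_weights) == 3
    assert model.intercept is not None
    forest = train(fm, labels, "random_forest")
    assert forest.context_weights is None


class TestPredictScores:
    def test_zero_row_is_sigmoid_intercept(self):
        fm, labels, _ = separable_features()
        model = train(fm, labels, "logistic_regression")
        zero = FeatureMatrix(("z",), np.zeros((1, 3)), fm.feature_names)
        scores = predict_scores(model, zero)
        assert scores["z"] == pytest.approx(expit(model.intercept), abs=1e-9)

    def test_training_positive_scores_high(self):
        fm, labels, y = separable_features()
        model = train(fm, labels, "logistic_regression")
        scores = predict_scores(model, fm)
        pos_term = fm.terms[0]
        assert y[0] == 1 and scores[pos_term] > 0.5

    def test_empty_matrix(self):
        fm, labels, _ = separable_features()
        model = train(fm, labels, "logistic_regression")
        empty = FeatureMatrix((), np.zeros((0, 3)), fm.feature_names)
        assert predict_scores(model, empty) == {}

    def test_feature_name_mismatch(self):
        fm, labels, _ = separable_features()
        model = train(fm, labels, "logistic_regression")
        wrong = FeatureMatrix(("a",), np.zeros((1, 3)), ("x", "y", "z"))
        with pytest.raises(ValueError, match="feature names"):
            predict_scores(model, wrong)

    def test_bounds(self, default_bundle, default_features, default_sweep):
        _, labels = default_sweep[0]
        model = train(default_features, labels, "logistic_regression")
        scores = predict_scores(model, default_features)
        vals = np.array(list(scores.values()))
        assert vals.min() >= 0.0 and vals.max() <= 1.0


class TestRank:
    def test_descending(self):
        assert rank({"a": 0.9, "b": 0.1}).entries == (("a", 0.9), ("b", 0.1))

    def test_tie_lexicographic(self):
        assert rank({"b": 0.5, "a": 0.5}).entries == (("a", 0.5), ("b", 0.5))

    def test_empty(self):
        assert rank({}).entries == ()


class TestInterpret:
    def test_coefficients_pass_through(self):
        fm, labels, _ = separable_features()
        model = train(fm, labels, "logistic_regression")
        table = interpret(model)
        assert list(table["context"]) == ["Intercept", "f0", "f1", "f2"]
        assert table["coefficient"].iloc[1:].tolist() == pytest.approx(model.context_weights)
        assert table["coefficient"].iloc[0] == pytest.approx(model.intercept)
        assert ((table["p_value"] > 0) & (table["p_value"] <= 0.5 + 1e-12)).all()

    def test_single_driving_feature_recovered(self):
        """When only one feature carries the signal, it gets the largest
        positive coefficient and the smallest p-value among features."""
        rng = np.random.default_rng(5)
        n = 400
        X = rng.uniform(0, 1, size=(n, 4))
        logit = -3.0 + 6.0 * X[:, 2]
        y = (rng.uniform(size=n) < expit(logit)).astype(int)
        terms = tuple(f"t{i}" for i in range(n))
        fm = FeatureMatrix(terms, X, ("c0", "c1", "c2", "c3"))
        labels = build_labels(list(terms), {t: 5 * int(v) for t, v in zip(terms, y)}, 1)
        table = interpret(train(fm, labels, "logistic_regression"))
        feats = table.iloc[1:].set_index("context")
        assert feats["coefficient"].idxmax() == "c2"
        assert feats["p_value"].idxmin() == "c2"
        assert feats.loc["c2", "coefficient"] > 0

    def test_non_logistic_unsupported(self):
        fm, labels, _ = separable_features()
        model = train(fm, labels, "random_forest")
        with pytest.raises(ValueError, match="logistic"):
            interpret(model)


def test_training_determinism(tmp_path):
    fm, labels, _ = separable_features()
    scores = []
    for name in ("m1", "m2"):
        model = train(fm, labels, "logistic_regression", seed=11)
        model.save(tmp_path / name)
        scores.append(predict_scores(model, fm))
    assert (tmp_path / "m1").read_bytes() == (tmp_path / "m2").read_bytes()
    assert scores[0] == scores[1]
    reloaded = PreferenceModel.load(tmp_path / "m1")
    assert predict_scores(reloaded, fm) == scores[0]
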