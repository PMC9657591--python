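"""The fused CNN classifier: sklearn contract, learning, determinism."""

import numpy as np
import pytest
from scipy.stats import binomtest
from sklearn.base import clone
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split

from mol2mat import FusedCNNClassifier, SyntheticConfig, generate, generate_branches


@pytest.fixture(scope="module")
def fitted(separable_data):
    X, y = separable_data
    clf = FusedCNNClassifier(branch_lengths=(144,), epochs=12, random_state=0)
    return clf.fit(X, y), X, y


def test_sklearn_contract(fitted):
    clf, X, y = fitted
    assert sorted(clf.classes_) == sorted(np.unique(y))
    assert clf.n_features_in_ == 144
    cloned = clone(clf)  # params survive cloning, fitted state does not
    assert cloned.get_params()["epochs"] == 12
    assert not hasattr(cloned, "model_")
    probs = clf.predict_proba(X)
    assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-5)
    assert set(clf.predict(X)) <= set(clf.classes_)


def test_separable_data_is_learned(fitted, separable_data):
    clf, X, y = fitted
    # the generator makes classes linearly separable; confirm with a logistic oracle
    oracle = LogisticRegression(max_iter=2000).fit(X, y)
    assert oracle.score(X, y) >= 0.99
    assert clf.history_["accuracy"].iloc[-1] >= 0.99


def test_noise_free_signatures_reach_perfect_training_accuracy():
    cfg = SyntheticConfig(
        n_classes=3, per_class=20, length=100, signature_size=16,
        p_signature=1.0, p_background=0.0, p_cross=0.0, seed=1,
    )
    X, y = generate(cfg)
    clf = FusedCNNClassifier(branch_lengths=(100,), epochs=20, random_state=1).fit(X, y)
    assert clf.history_["accuracy"].iloc[-1] >= 0.99


def test_training_trace_schema_and_determinism(separable_data):
    X, y = separable_data
    runs = [
        FusedCNNClassifier(branch_lengths=(144,), epochs=4, random_state=7).fit(X, y).history_
        for _ in range(2)
    ]
    assert list(runs[0].columns) == ["epoch", "accuracy", "mse"]
    assert runs[0].equals(runs[1])
    assert runs[0]["accuracy"].between(0, 1).all()
    assert (runs[0]["mse"] >= 0).all()


def test_validation_trace(separable_data):
    X, y = separable_data
    X_tr, X_te, y_tr, y_te = train_test_split(X, y, test_size=0.3, random_state=0, stratify=y)
    clf = FusedCNNClassifier(branch_lengths=(144,), epochs=3, random_state=0)
    clf.fit(X_tr, y_tr, eval_set=(X_te, y_te))
    assert {"val_accuracy", "val_mse"} <= set(clf.history_.columns)


def test_one_class_dataset_rejected(rng):
    X = rng.integers(0, 2, size=(10, 16))
    with pytest.raises(ValueError, match="2 classes"):
        FusedCNNClassifier(branch_lengths=(16,)).fit(X, ["only"] * 10)


def test_class_below_two_examples_rejected(rng):
    X = rng.integers(0, 2, size=(5, 16))
    with pytest.raises(ValueError, match=">= 2 training examples"):
        FusedCNNClassifier(branch_lengths=(16,)).fit(X, ["a", "a", "a", "a", "b"])


def test_branch_length_mismatch_rejected(rng):
    X = rng.integers(0, 2, size=(8, 100))
    with pytest.raises(ValueError, match="branch_lengths"):
        FusedCNNClassifier(branch_lengths=(64, 64)).fit(X, ["a", "b"] * 4)


def test_two_branch_fusion_recovers_classes():
    cfg = SyntheticConfig(
        n_classes=3, per_class=40, length=144, signature_size=16,
        p_signature=0.9, p_background=0.02, p_cross=0.05, seed=7,
    )
    Xs, y = generate_branches(cfg, 2)
    X = np.hstack(Xs)
    X_tr, X_te, y_tr, y_te = train_test_split(X, y, test_size=0.25, random_state=0, stratify=y)
    clf = FusedCNNClassifier(branch_lengths=(144, 144), epochs=10, random_state=0).fit(X_tr, y_tr)
    assert (clf.predict(X_te) == y_te).mean() >= 0.95


def test_accuracy_beats_chance_across_seed_panel():
    # held-out accuracy must beat the 1/k chance level (binomial p < 0.01)
    cfg = SyntheticConfig(
        n_classes=4, per_class=30, length=144, signature_size=16,
        p_signature=0.8, p_background=0.05, p_cross=0.1, seed=0,
    )
    X, y = generate(cfg)
    for seed in (0, 1, 2):
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, test_size=0.3, random_state=seed, stratify=y
        )
        clf = FusedCNNClassifier(branch_lengths=(144,), epochs=8, random_state=seed)
        hits = int((clf.fit(X_tr, y_tr).predict(X_te) == y_te).sum())
        assert binomtest(hits, len(y_te), p=0.25, alternative="greater").pvalue < 0.01
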