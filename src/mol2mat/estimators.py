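"""Scikit-learn style classifier over the fused CNN.

``FusedCNNClassifier`` takes a 2-D feature matrix whose columns are the
concatenated fingerprint vectors of the fused families (split positions given
by ``branch_lengths``), reshapes each block into its square matrix encoding,
and trains the multi-branch network.  It follows the sklearn estimator
contract (get_params/set_params, fitted ``*_`` attributes, classes_), so it
composes with pipelines and model selection.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.preprocessing import LabelBinarizer
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .architecture import DEFAULT_CHANNELS, make_fused_spec
from .encoding import matrix_size
from .nn import FusedCNN

__all__ = ["FusedCNNClassifier", "train"]


class FusedCNNClassifier(BaseEstimator, ClassifierMixin):
    """Multi-branch fused convolutional classifier for fingerprint tables.

    Parameters
    ----------
    branch_lengths : tuple of int, default (1024,)
        Fingerprint length per branch; X columns are split at these
        boundaries, and each block is reshaped to its ceil(sqrt(L)) square
        matrix.  A single entry gives the single-branch model.
    epochs, batch_size, learning_rate : training configuration (minibatch
        Adam on categorical cross-entropy).
    channels : channel counts of the two per-branch convolutions.
    dense : optional (d1, d2) override of the per-k dense-head plan.
    normalise : scale each branch by its training maximum into [0, 1]
        (no-op for binary fingerprints).
    random_state : seed for parameter initialisation and batch shuffling.

    Attributes
    ----------
    classes_ : sorted class labels.
    model_ : the underlying :class:`~mol2mat.nn.FusedCNN`.
    spec_ : the instantiated :class:`~mol2mat.architecture.FusedArchitectureSpec`.
    history_ : per-epoch DataFrame with columns epoch, accuracy, mse
        (plus val_* when an eval_set is supplied to ``fit``).
    scales_ : per-branch count-normalisation divisors fitted on the training data.
    """

    def __init__(
        self,
        branch_lengths: tuple = (1024,),
        epochs: int = 20,
        batch_size: int = 32,
        learning_rate: float = 1e-3,
        channels: tuple = DEFAULT_CHANNELS,
        dense: tuple | None = None,
        normalise: bool = True,
        random_state: int = 0,
    ):
        self.branch_lengths = branch_lengths
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.channels = channels
        self.dense = dense
        self.normalise = normalise
        self.random_state = random_state

    # -- helpers -------------------------------------------------------------

    def _split_branches(self, X: np.ndarray) -> list[np.ndarray]:
        bounds = np.cumsum(self.branch_lengths)
        if X.shape[1] != bounds[-1]:
            raise ValueError(
                f"X has {X.shape[1]} columns but branch_lengths sum to {bounds[-1]}"
            )
        return np.split(X, bounds[:-1], axis=1)

    def _encode(self, blocks: list[np.ndarray], scales) -> list[np.ndarray]:
        stacks = []
        for block, scale, length in zip(blocks, scales, self.branch_lengths):
            n = matrix_size(length)
            flat = np.clip(block / scale, 0.0, 1.0)
            padded = np.zeros((block.shape[0], n * n), dtype=np.float32)
            padded[:, :length] = flat
            stacks.append(padded.reshape(-1, n, n))
        return stacks

    # -- estimator API -------------------------------------------------------

    def fit(self, X, y, eval_set: tuple | None = None):
        """Fit on (X, y); ``eval_set=(X_val, y_val)`` adds per-epoch
        validation accuracy/MSE to ``history_``."""
        X, y = check_X_y(X, y, dtype=np.float64)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("training data must contain at least 2 classes")
        if counts.min() < 2:
            small = classes[counts < 2]
            raise ValueError(f"every class needs >= 2 training examples; too small: {list(small)}")

        self._binarizer = LabelBinarizer().fit(y)
        self.classes_ = self._binarizer.classes_
        onehot = self._to_onehot(y)

        blocks = self._split_branches(X)
        self.scales_ = [
            float(max(b.max(), 1.0)) if self.normalise else 1.0 for b in blocks
        ]
        stacks = self._encode(blocks, self.scales_)

        self.spec_ = make_fused_spec(
            [int(l) for l in self.branch_lengths],
            n_classes=len(self.classes_),
            channels=tuple(self.channels),
            dense=self.dense,
        )
        self.model_ = FusedCNN(self.spec_, seed=self.random_state)

        validation = None
        if eval_set is not None:
            X_val, y_val = eval_set
            X_val = check_array(X_val, dtype=np.float64)
            validation = (
                self._encode(self._split_branches(X_val), self.scales_),
                self._to_onehot(np.asarray(y_val)),
            )

        history = self.model_.fit(
            stacks,
            onehot,
            epochs=self.epochs,
            batch_size=self.batch_size,
            lr=self.learning_rate,
            seed=self.random_state,
            validation=validation,
        )
        self.history_ = pd.DataFrame(history)
        self.n_features_in_ = X.shape[1]
        return self

    def _to_onehot(self, y) -> np.ndarray:
        onehot = self._binarizer.transform(y)
        if onehot.shape[1] == 1:  # LabelBinarizer collapses the 2-class case
            onehot = np.hstack([1 - onehot, onehot])
        return onehot.astype(np.float32)

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        X = check_array(X, dtype=np.float64)
        stacks = self._encode(self._split_branches(X), self.scales_)
        return self.model_.predict_proba(stacks).astype(np.float64)

    def predict(self, X) -> np.ndarray:
        # argmax breaks ties toward the lowest class index
        return self.classes_[self.predict_proba(X).argmax(axis=1)]


def train(model: FusedCNN, stacks, onehot, config: dict | None = None, seed: int = 0):
    """Functional wrapper: train an instantiated FusedCNN on Mol2mat stacks.

    ``config`` keys: epochs, batch_size, learning_rate.  Returns the fitted
    model and its per-epoch trace (list of dicts with accuracy and mse).
    """
    config = config or {}
    labels = onehot.argmax(axis=1)
    counts = np.bincount(labels, minlength=onehot.shape[1])
    if (counts < 2).any():
        raise ValueError("every class needs >= 2 training examples")
    trace = model.fit(
        stacks,
        onehot,
        epochs=config.get("epochs", 20),
        batch_size=config.get("batch_size", 32),
        lr=config.get("learning_rate", 1e-3),
        seed=seed,
    )
    return model, trace
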