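"""Fingerprint-to-matrix (Mol2mat) encoding.

A length-L fingerprint vector is reshaped into the smallest square matrix
holding it, in row-major order with trailing zero padding: n = ceil(sqrt(L)),
entry (r, c) holds the value at flattened index r*n + c for indices < L, and 0
beyond.  Binary vectors pass through unchanged; count vectors (ECFC4, ALOGP)
are first scaled to [0, 1] by the maximum count observed in the training
split, so that every matrix entry lies in [0, 1] regardless of family.
"""

from __future__ import annotations

import json
import math

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .fingerprints import FingerprintSpec, get_spec

__all__ = ["matrix_size", "to_mol2mat", "from_mol2mat", "CountScaler", "Mol2MatTransformer"]


def matrix_size(length: int) -> int:
    """Side length of the smallest square matrix with at least ``length`` cells.

    >>> [matrix_size(n) for n in (120, 166, 881, 1024)]
    [11, 13, 30, 32]
    """
    if length < 1:
        raise ValueError(f"fingerprint length must be >= 1, got {length}")
    return math.isqrt(length - 1) + 1


def to_mol2mat(vector: np.ndarray, scale: float | None = None) -> np.ndarray:
    """Reshape one fingerprint vector into its square Mol2mat matrix.

    ``scale`` divides count vectors into [0, 1] (values are clipped); omit it
    for binary vectors, which pass through unchanged.  Padding cells are 0.
    """
    vector = np.asarray(vector, dtype=np.float64)
    if vector.ndim != 1:
        raise ValueError(f"expected a 1-D vector, got shape {vector.shape}")
    length = vector.shape[0]
    n = matrix_size(length)
    if scale is not None:
        if scale <= 0:
            raise ValueError(f"scale must be positive, got {scale}")
        vector = np.clip(vector / scale, 0.0, 1.0)
    if vector.min() < 0 or vector.max() > 1:
        raise ValueError("matrix entries must lie in [0, 1]; pass a scale for count vectors")
    padded = np.zeros(n * n, dtype=np.float64)
    padded[:length] = vector
    return padded.reshape(n, n)


def from_mol2mat(matrix: np.ndarray, spec: FingerprintSpec | str | int) -> np.ndarray:
    """Row-major flattening truncated to the fingerprint length (round-trip
    inverse of :func:`to_mol2mat` for unscaled vectors)."""
    length = spec if isinstance(spec, int) else get_spec(spec).length
    matrix = np.asarray(matrix)
    n = matrix_size(length)
    if matrix.shape != (n, n):
        raise ValueError(f"expected a {n}x{n} matrix for length {length}, got {matrix.shape}")
    return matrix.reshape(-1)[:length].copy()


class CountScaler(BaseEstimator, TransformerMixin):
    """Scale count fingerprints to [0, 1] by the training-split maximum.

    Binary data is a fixed point (max 1), so the transformer is safe to apply
    uniformly.  Values exceeding the training maximum at transform time are
    clipped to 1.
    """

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=1)
        self.max_ = float(max(X.max(), 1.0))
        return self

    def transform(self, X):
        check_is_fitted(self, "max_")
        X = check_array(X)
        return np.clip(X / self.max_, 0.0, 1.0)


class Mol2MatTransformer(BaseEstimator, TransformerMixin):
    """Transform a fingerprint table (N, L) into a Mol2mat stack (N, n, n).

    Parameters
    ----------
    normalise : bool, default True
        Fit a :class:`CountScaler` on the training data (no-op for binary
        fingerprints, whose maximum is 1).

    Attributes
    ----------
    n_ : matrix side length, ``ceil(sqrt(n_features_in_))``.
    scale_ : the fitted count normaliser (the training-split maximum).
    """

    def __init__(self, normalise: bool = True):
        self.normalise = normalise

    def fit(self, X, y=None):
        X = check_array(X)
        self.n_features_in_ = X.shape[1]
        self.n_ = matrix_size(X.shape[1])
        self.scale_ = float(max(X.max(), 1.0)) if self.normalise else 1.0
        return self

    def transform(self, X):
        check_is_fitted(self, "n_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        X = np.clip(X / self.scale_, 0.0, 1.0)
        n = self.n_
        out = np.zeros((X.shape[0], n * n), dtype=np.float64)
        out[:, : X.shape[1]] = X
        return out.reshape(-1, n, n)

    def inverse_transform(self, M):
        check_is_fitted(self, "n_")
        M = np.asarray(M)
        return M.reshape(M.shape[0], -1)[:, : self.n_features_in_] * self.scale_

    def export(self, path_prefix: str, M: np.ndarray, spec_name: str = "") -> None:
        """Write a Mol2mat stack as a dense .npy plus a JSON sidecar recording
        the fingerprint name, side length and normaliser."""
        np.save(f"{path_prefix}.npy", M)
        with open(f"{path_prefix}.json", "w") as fh:
            json.dump({"spec_name": spec_name, "n": self.n_, "scale": self.scale_}, fh)
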