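"""Dataset-diversity analysis via mean pairwise Tanimoto similarity (MPS).

The structural homogeneity of an activity class is summarised by the mean
Tanimoto similarity over all unordered within-class molecule pairs.  Classes
are split at a cut-off (default 0.200, the mean pairwise similarity of a large
random compound sample): MPS >= cut-off means a structurally homogeneous
(low-diversity) class, below it a heterogeneous (high-diversity) class.
Boundary values are assigned to the homogeneous group.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = ["tanimoto", "class_mps", "diversity_split", "DEFAULT_CUTOFF"]

DEFAULT_CUTOFF = 0.200


def tanimoto(a, b) -> float:
    """Tanimoto coefficient c/(alpha+beta-c) of two equal-length binary vectors.

    Defined as 0 when both vectors are all-zero.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    a = a != 0
    b = b != 0
    c = int((a & b).sum())
    denom = int(a.sum()) + int(b.sum()) - c
    return c / denom if denom else 0.0


def _pairwise_mean(X: np.ndarray) -> float:
    """Mean Tanimoto over all unordered row pairs, via bit-count algebra."""
    X = (np.asarray(X) != 0).astype(np.float64)
    m = X.shape[0]
    inter = X @ X.T  # c for every pair
    ones = X.sum(axis=1)
    union = ones[:, None] + ones[None, :] - inter
    iu = np.triu_indices(m, k=1)
    num, den = inter[iu], union[iu]
    sims = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return float(sims.mean())


def class_mps(vectors, max_exact: int = 10_000, seed: int = 0) -> float:
    """Mean pairwise similarity of one class (NaN below 2 molecules).

    Exact over all m(m-1)/2 pairs; classes larger than ``max_exact`` are
    subsampled to that size with a seeded generator.
    """
    X = np.asarray(vectors)
    if X.ndim != 2:
        raise ValueError(f"expected a 2-D (molecules x bits) array, got shape {X.shape}")
    if X.shape[0] < 2:
        return math.nan
    if X.shape[0] > max_exact:
        rng = np.random.default_rng(seed)
        X = X[rng.choice(X.shape[0], size=max_exact, replace=False)]
    return _pairwise_mean(X)


def diversity_split(X, y, cutoff: float = DEFAULT_CUTOFF, max_exact: int = 10_000, seed: int = 0) -> pd.DataFrame:
    """Per-class MPS report with the high/low-diversity split.

    Returns a DataFrame with one row per activity class: molecule count, mps,
    and ``diversity_group`` (``low_diversity`` iff mps >= cutoff — homogeneous
    classes have *high* within-class similarity).
    """
    if not 0.0 < cutoff < 1.0:
        raise ValueError(f"cutoff must lie in (0, 1), got {cutoff}")
    X = np.asarray(X)
    y = np.asarray(y)
    rows = []
    for cls in pd.unique(y):
        mps = class_mps(X[y == cls], max_exact=max_exact, seed=seed)
        group = (
            "unknown" if math.isnan(mps)
            else "low_diversity" if mps >= cutoff
            else "high_diversity"
        )
        rows.append(
            {"class": cls, "n_molecules": int((y == cls).sum()), "mps": mps, "diversity_group": group}
        )
    return pd.DataFrame(rows).set_index("class")
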