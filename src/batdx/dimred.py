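"""PCA of subject-level feature vectors.

Features typically combined: specific IgE to Pru p 3 (log10-transformed by
the pipeline before entry — serum IgE is heavily right-skewed), percent
CD63+ and CD203c-high reactivity at a discriminating concentration, SPT
wheal area, curve AUC and CD-sens. Rows with undefined entries (e.g.
CD-sens in a nonresponder) are dropped and counted.

Deterministic SVD on the centered (and, by default, unit-variance scaled)
matrix; component signs are fixed by making each component's
largest-magnitude loading positive.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = ["PCAResult", "run_pca"]


@dataclass
class PCAResult:
    feature_names: list
    standardization: str            # "unit-variance" | "none"
    loadings: np.ndarray            # features × components
    scores: np.ndarray              # subjects × components
    explained_variance_pct: np.ndarray
    index: list                     # row labels of the retained subjects
    n_dropped: int                  # rows removed for undefined entries

    def reconstruct(self) -> np.ndarray:
        """Centered/scaled data matrix rebuilt from all components."""
        return self.scores @ self.loadings.T


def run_pca(feature_table: pd.DataFrame, standardize: str = "unit-variance") -> PCAResult:
    """Principal component analysis of a subjects × features table.

    ``standardize='unit-variance'`` (default) centers and scales each
    feature to unit standard deviation before the eigendecomposition;
    ``'none'`` only centers. A feature that is constant across retained
    subjects cannot be unit-variance scaled and raises an error naming it.
    """
    if standardize not in ("unit-variance", "none"):
        raise InputError(f"unknown standardization {standardize!r}")
    df = feature_table.apply(pd.to_numeric)
    if df.shape[1] < 2:
        raise InputError("need >= 2 features")
    complete = df.dropna()
    n_dropped = len(df) - len(complete)
    if complete.shape[0] < 2:
        raise InputError("need >= 2 subjects with complete features")

    X = complete.to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    if standardize == "unit-variance":
        sd = X.std(axis=0, ddof=1)
        zero = np.nonzero(sd == 0)[0]
        if len(zero):
            raise InputError(
                f"constant feature under unit-variance scaling: "
                f"{complete.columns[zero[0]]!r}")
        X = X / sd

    # Economy SVD: loadings = right singular vectors, scores = U @ diag(S).
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    loadings = Vt.T
    scores = U * S
    # Sign convention: largest-|loading| entry of each component positive.
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0
    var = S ** 2 / (X.shape[0] - 1)
    total = X.var(axis=0, ddof=1).sum()
    explained = 100.0 * var / total
    return PCAResult(
        feature_names=list(complete.columns),
        standardization=standardize,
        loadings=loadings, scores=scores,
        explained_variance_pct=explained,
        index=list(complete.index), n_dropped=n_dropped)
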