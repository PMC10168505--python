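"""PCA fit/reconstruct baseline for the reconstruction-error comparison."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class PCABasis:
    """Top-k principal subspace of a training matrix.

    ``components`` rows are orthonormal (within 1e-8) directions of the
    centered training data, ordered by explained variance.
    """

    mean: np.ndarray
    components: np.ndarray  # (k, d)
    k: int


def fit_pca(train: np.ndarray, k: int) -> PCABasis:
    """Top-k principal directions of the centered training matrix via SVD."""
    X = np.asarray(train, dtype=float)
    if X.ndim != 2:
        raise ValueError("training data must be a 2-D matrix")
    n, d = X.shape
    if not (1 <= k <= min(n, d)):
        raise ValueError(f"k must be in [1, min(n, d)] = [1, {min(n, d)}]")
    mean = X.mean(axis=0)
    _, _, vt = np.linalg.svd(X - mean, full_matrices=False)
    return PCABasis(mean=mean, components=vt[:k].copy(), k=k)


def pca_transform(basis: PCABasis, X: np.ndarray) -> np.ndarray:
    return (np.asarray(X, dtype=float) - basis.mean) @ basis.components.T


def pca_reconstruct(basis: PCABasis, scores: np.ndarray) -> np.ndarray:
    return np.asarray(scores, dtype=float) @ basis.components + basis.mean


def pca_reconstruction_mse(basis: PCABasis, validation: np.ndarray) -> float:
    """Project-then-reconstruct MSE, averaged across dimensions then samples."""
    X = np.asarray(validation, dtype=float)
    if X.shape[1] != basis.components.shape[1]:
        raise ValueError("dimension mismatch with basis")
    recon = pca_reconstruct(basis, pca_transform(basis, X))
    return float(((X - recon) ** 2).mean(axis=1).mean())
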