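"""PCA reduction of the GA-selected feature subset.

Eigendecomposition of the sample covariance of mean-centered columns,
eigenpairs sorted by descending eigenvalue. Deterministic up to
eigenvector sign, which is fixed by making each eigenvector's
largest-magnitude entry positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class PCAModel:
    means: np.ndarray
    eigenvalues: np.ndarray  # descending, non-negative
    eigenvectors: np.ndarray  # orthonormal columns, one per eigenvalue

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        if total <= 0:
            return np.zeros_like(self.eigenvalues)
        return self.eigenvalues / total

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


def fit_pca(data: np.ndarray) -> PCAModel:
    """Fit PCA on rows of ``data`` (n_samples x n_features).

    Uses the unbiased (1/(n-1)) sample covariance; eigenvalues are
    clipped at zero to absorb numerical round-off.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("PCA needs a 2-D matrix with at least 2 rows")
    means = X.mean(axis=0)
    cov = np.cov(X - means, rowvar=False, ddof=1).reshape(X.shape[1], X.shape[1])
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    # sign convention: largest-magnitude entry of each component positive
    for j in range(eigvecs.shape[1]):
        k = np.argmax(np.abs(eigvecs[:, j]))
        if eigvecs[k, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    return PCAModel(means=means, eigenvalues=eigvals, eigenvectors=eigvecs)


def project(model: PCAModel, data: np.ndarray, k: int) -> np.ndarray:
    """Project rows onto the top-k principal components."""
    if not (1 <= k <= model.n_components):
        raise ValueError(f"k={k} outside 1..{model.n_components}")
    X = np.asarray(data, dtype=float)
    if X.shape[1] != len(model.means):
        raise ValueError("data width does not match the fitted model")
    return (X - model.means) @ model.eigenvectors[:, :k]


def reconstruct(model: PCAModel, scores: np.ndarray) -> np.ndarray:
    """Back-project component scores into the original feature space."""
    k = scores.shape[1]
    return scores @ model.eigenvectors[:, :k].T + model.means


def choose_k(model: PCAModel, variance_threshold: float = 0.95) -> int:
    """Smallest k whose cumulative explained-variance ratio reaches the
    threshold (full rank at threshold 1.0)."""
    if not (0.0 < variance_threshold <= 1.0):
        raise ValueError("variance_threshold must lie in (0, 1]")
    cum = np.cumsum(model.explained_variance_ratio)
    idx = np.searchsorted(cum, variance_threshold - 1e-12)
    return int(min(idx + 1, model.n_components))
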