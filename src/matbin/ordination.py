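"""Ordination: PCA of feature matrices, PCoA of dissimilarity matrices."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["OrdinationResult", "pca", "pcoa"]


@dataclass
class OrdinationResult:
    """Scores, loadings and eigenvalues of one ordination.

    ``variance_explained`` entries are fractions of total (positive)
    variance, non-increasing. ``method`` is ``"PCA"`` or ``"PCoA"``.
    For PCoA, ``negative_variance`` records the summed magnitude of any
    dropped negative eigenvalues (fraction of total absolute eigenvalue
    mass).
    """

    sample_ids: list
    scores: np.ndarray  # samples x axes
    eigenvalues: np.ndarray
    variance_explained: np.ndarray
    method: str
    loadings: np.ndarray | None = None  # features x axes (PCA only)
    feature_ids: list | None = None
    negative_variance: float = 0.0

    @property
    def n_axes(self) -> int:
        return self.scores.shape[1]


def _as_array(matrix, ids_attr="index"):
    if isinstance(matrix, pd.DataFrame):
        return matrix.to_numpy(dtype=float), list(matrix.index), list(matrix.columns)
    X = np.asarray(matrix, dtype=float)
    return X, list(range(X.shape[0])), list(range(X.shape[1]))


def _fix_signs(scores: np.ndarray, loadings: np.ndarray | None) -> None:
    """Deterministic sign convention: per axis, the largest-magnitude
    loading (or score, for PCoA) is made positive. In place."""
    ref = loadings if loadings is not None else scores
    for j in range(scores.shape[1]):
        col = ref[:, j]
        i = int(np.argmax(np.abs(col)))
        if col[i] < 0:
            scores[:, j] *= -1
            if loadings is not None:
                loadings[:, j] *= -1


def pca(matrix, n_axes: int | None = None, scale: bool = False) -> OrdinationResult:
    """Principal components via SVD of the column-centered matrix.

    ``scale=True`` additionally divides columns by their SD (correlation
    PCA) — useful when feature scales differ, e.g. functional-category
    matrices. Axes are ordered by eigenvalue; requesting more axes than
    the rank truncates with a warning.
    """
    X, sample_ids, feature_ids = _as_array(matrix)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 rows")
    if not np.all(np.isfinite(X)):
        raise ValueError("PCA input contains non-finite values")
    Xc = X - X.mean(axis=0)
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        keep = sd > 0
        Xc = Xc[:, keep] / sd[keep]
        feature_ids = [f for f, k in zip(feature_ids, keep) if k]
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    n = X.shape[0]
    eigvals = s**2 / (n - 1)
    tol = max(X.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int(np.sum(s > tol))
    if n_axes is None:
        n_axes = rank
    if n_axes > rank:
        warnings.warn(
            f"requested {n_axes} axes but rank is {rank}; truncating", stacklevel=2
        )
        n_axes = rank
    scores = U[:, :n_axes] * s[:n_axes]
    loadings = Vt[:n_axes].T.copy()
    _fix_signs(scores, loadings)
    total = eigvals.sum()
    ve = eigvals[:n_axes] / total if total > 0 else np.zeros(n_axes)
    return OrdinationResult(
        sample_ids=sample_ids,
        scores=scores,
        eigenvalues=eigvals[:n_axes],
        variance_explained=ve,
        method="PCA",
        loadings=loadings,
        feature_ids=feature_ids,
    )


def pcoa(distance_matrix, n_axes: int | None = None) -> OrdinationResult:
    """Principal coordinates: double-centered eigen-decomposition.

    Requires a symmetric, zero-diagonal, nonnegative matrix. Negative
    eigenvalues (non-Euclidean input such as Gower with missing data)
    are dropped; their share of total absolute eigenvalue mass is noted
    in ``negative_variance``.
    """
    if isinstance(distance_matrix, pd.DataFrame):
        D = distance_matrix.to_numpy(dtype=float)
        sample_ids = list(distance_matrix.index)
    else:
        D = np.asarray(distance_matrix, dtype=float)
        sample_ids = list(range(D.shape[0]))
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if np.any(D < -1e-12):
        raise ValueError("distance matrix must be nonnegative")
    if np.any(np.abs(np.diag(D)) > 1e-12):
        raise ValueError("distance matrix must have zero diagonal")
    n = D.shape[0]
    A = -0.5 * D**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = J @ A @ J
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(abs(eigvals[0]), 1.0) * n * np.finfo(float).eps if n else 0.0
    pos = eigvals > tol
    neg_mass = float(np.abs(eigvals[eigvals < -tol]).sum())
    total_abs = float(np.abs(eigvals).sum())
    eigvals_pos = eigvals[pos]
    scores_full = eigvecs[:, pos] * np.sqrt(eigvals_pos)
    rank = scores_full.shape[1]
    if n_axes is None:
        n_axes = rank
    if n_axes > rank:
        warnings.warn(
            f"requested {n_axes} axes but only {rank} positive eigenvalues; truncating",
            stacklevel=2,
        )
        n_axes = rank
    scores = scores_full[:, :n_axes].copy()
    _fix_signs(scores, None)
    total_pos = eigvals_pos.sum()
    ve = eigvals_pos[:n_axes] / total_pos if total_pos > 0 else np.zeros(n_axes)
    return OrdinationResult(
        sample_ids=sample_ids,
        scores=scores,
        eigenvalues=eigvals_pos[:n_axes],
        variance_explained=ve,
        method="PCoA",
        negative_variance=neg_mass / total_abs if total_abs > 0 else 0.0,
    )
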