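"""Principal component analysis of Procrustes shape coordinates.

PCA is computed on the vectorized aligned coordinates about their sample
mean.  Because Procrustes alignment removes 7 similarity degrees of
freedom (and one more for the mean), at most ``min(n - 1, 3k)`` components
carry variance; percentages of variance are reported over the retained
non-null dimensions and sum to 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .procrustes import AlignedSample

__all__ = ["ShapeSpace", "ShapePCA", "pca_shape", "select_pcs"]


@dataclass
class ShapeSpace:
    """PC scores, eigenvalues and loadings of a shape sample."""

    scores: np.ndarray  # (n, p)
    eigenvalues: np.ndarray  # (p,)
    pct_variance: np.ndarray  # (p,), sums to 100
    loadings: np.ndarray  # (3k, p), orthonormal columns
    mean_shape: np.ndarray  # (k, 3)

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def reconstruct(self, scores: np.ndarray | None = None) -> np.ndarray:
        """Back-project scores to (n, k, 3) landmark coordinates."""
        s = self.scores if scores is None else np.atleast_2d(scores)
        flat = self.mean_shape.reshape(1, -1) + s @ self.loadings.T
        return flat.reshape(s.shape[0], *self.mean_shape.shape)

    def shape_at(self, axis: int, score: float) -> np.ndarray:
        """Model shape at a given score along one axis (others at zero)."""
        s = np.zeros(self.n_components)
        s[axis] = score
        return self.reconstruct(s)[0]


class ShapePCA(BaseEstimator, TransformerMixin):
    """PCA of vectorized Procrustes coordinates (covariance eigendecomposition)."""

    def __init__(self, eps: float = 1e-12):
        self.eps = eps

    @staticmethod
    def _flatten(X) -> np.ndarray:
        if isinstance(X, AlignedSample):
            return X.flattened()
        X = np.asarray(X, dtype=float)
        if X.ndim == 3:
            return X.reshape(X.shape[0], -1)
        return X

    def fit(self, X, y=None) -> "ShapePCA":
        flat = self._flatten(X)
        n = flat.shape[0]
        if n < 3:
            raise ValueError("shape PCA needs at least 3 specimens")
        self.mean_ = flat.mean(axis=0)
        centred = flat - self.mean_
        _, svals, vt = np.linalg.svd(centred, full_matrices=False)
        eigenvalues = svals**2 / (n - 1)
        keep = eigenvalues > self.eps * max(eigenvalues[0], 1.0)
        self.eigenvalues_ = eigenvalues[keep]
        self.components_ = vt[keep]
        self.pct_variance_ = 100.0 * self.eigenvalues_ / self.eigenvalues_.sum()
        return self

    def transform(self, X) -> np.ndarray:
        flat = self._flatten(X)
        return (flat - self.mean_) @ self.components_.T

    def to_shape_space(self, X) -> ShapeSpace:
        k3 = self.mean_.shape[0]
        return ShapeSpace(
            scores=self.transform(X),
            eigenvalues=self.eigenvalues_,
            pct_variance=self.pct_variance_,
            loadings=self.components_.T,
            mean_shape=self.mean_.reshape(k3 // 3, 3),
        )


def pca_shape(aligned: AlignedSample) -> ShapeSpace:
    """Shape-space PCA of an aligned sample (thin wrapper over :class:`ShapePCA`)."""
    return ShapePCA().fit(aligned).to_shape_space(aligned)


def select_pcs(
    space: ShapeSpace | np.ndarray,
    group_sizes,
    max_cum_pct: float = 95.0,
) -> int:
    """Number of PCs to carry into group statistics, guarding against overfit.

    Returns the largest count whose cumulative percentage of variance does
    not exceed ``max_cum_pct``, additionally capped at the smallest group
    size; always at least 1.
    """
    pct = space.pct_variance if isinstance(space, ShapeSpace) else np.asarray(space, float)
    group_sizes = list(group_sizes)
    if not group_sizes:
        raise ValueError("at least one group is required")
    cum = np.cumsum(pct)
    n_cum = int(np.searchsorted(cum, max_cum_pct + 1e-9, side="right"))
    n = min(max(n_cum, 1), min(group_sizes), len(pct))
    return max(n, 1)
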