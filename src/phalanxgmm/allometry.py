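"""Allometry: multivariate regression of shape on log centroid size.

Each Procrustes shape coordinate is regressed on log centroid size by
least squares.  The size-related fraction of shape variation is the model
sum of squares over the total sum of squares (summed across coordinates),
and its significance is assessed by permuting log sizes across specimens.
Regression scores — the projection of each (centred) shape on the fitted
allometric direction — give a univariate axis for shape-vs-size plots.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .procrustes import AlignedSample

__all__ = ["AllometricRegression", "AllometryResult", "allometry_regression"]


class AllometricRegression(BaseEstimator, RegressorMixin):
    """OLS fit of vectorized shape on log centroid size, with permutation test.

    Parameters
    ----------
    n_permutations : int, default 999
        Size of the permutation null for the %-variance statistic.
    random_state : int, default 0
        Seed for the permutation draw.

    Attributes (after fit)
    ----------------------
    pct_variance_size_ : percentage of total shape variance explained by size
    p_permutation_ : permutation p-value of that percentage
    slope_ : (3k,) shape change per unit log centroid size
    intercept_ : (3k,) shape at log size zero
    regression_scores_ : (n,) projections on the fitted direction
    """

    def __init__(self, n_permutations: int = 999, random_state: int = 0):
        self.n_permutations = n_permutations
        self.random_state = random_state

    def fit(self, X, y) -> "AllometricRegression":
        Y = np.asarray(X, dtype=float)  # shapes are the responses
        if Y.ndim == 3:
            Y = Y.reshape(Y.shape[0], -1)
        x = np.asarray(y, dtype=float)  # log centroid sizes
        n = Y.shape[0]
        if n < 4:
            raise ValueError("allometric regression needs at least 4 specimens")
        if np.ptp(x) == 0:
            raise ValueError("log centroid size is constant: degenerate predictor")
        xc = x - x.mean()
        Yc = Y - Y.mean(axis=0)
        sxx = float(xc @ xc)
        beta = (Yc.T @ xc) / sxx  # (3k,)
        ss_total = float((Yc**2).sum())
        ss_model = float(beta @ beta) * sxx
        self.slope_ = beta
        self.intercept_ = Y.mean(axis=0) - beta * x.mean()
        self.pct_variance_size_ = 100.0 * ss_model / ss_total
        direction = beta / np.linalg.norm(beta)
        self.regression_scores_ = Yc @ direction

        rng = np.random.default_rng(self.random_state)
        exceed = 0
        for _ in range(self.n_permutations):
            xp = rng.permutation(xc)
            ss_perm = float((Yc.T @ xp) @ (Yc.T @ xp)) / sxx
            if ss_perm >= ss_model:
                exceed += 1
        self.p_permutation_ = (exceed + 1) / (self.n_permutations + 1)
        return self

    def predict(self, y) -> np.ndarray:
        x = np.atleast_1d(np.asarray(y, dtype=float))
        return self.intercept_[None, :] + x[:, None] * self.slope_[None, :]


@dataclass
class AllometryResult:
    pct_variance_size: float
    p_permutation: float
    regression_scores: np.ndarray
    predicted_shapes: Callable[[np.ndarray], np.ndarray]

    def as_row(self) -> dict:
        return {
            "% variance (size)": self.pct_variance_size,
            "p (permutation)": self.p_permutation,
        }


def allometry_regression(
    aligned: AlignedSample, n_permutations: int = 999, seed: int = 0
) -> AllometryResult:
    """Allometric regression of an aligned sample on its log centroid sizes."""
    k = aligned.n_points
    model = AllometricRegression(n_permutations=n_permutations, random_state=seed)
    model.fit(aligned.flattened(), aligned.log_centroid_sizes)

    def predicted_shapes(log_cs) -> np.ndarray:
        flat = model.predict(log_cs)
        return flat.reshape(-1, k, 3)

    return AllometryResult(
        pct_variance_size=model.pct_variance_size_,
        p_permutation=model.p_permutation_,
        regression_scores=model.regression_scores_,
        predicted_shapes=predicted_shapes,
    )
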