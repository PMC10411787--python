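"""Canonical variate analysis with cross-validated classification.

CVA finds the linear axes maximizing between-group relative to pooled
within-group variation of the PC scores (a generalized symmetric
eigenproblem).  Specimens are classified to the nearest group mean in
canonical space — equivalent to a Mahalanobis-distance rule with equal
priors, appropriate when group sizes are sampling artifacts.  Assignment
accuracy is assessed by leave-one-out cross-validation with the axes and
means refitted in every fold, and summarized as the correct cross-
validated classification percentage and Cohen's kappa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg as sla
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = [
    "CanonicalVariateClassifier",
    "CvaReport",
    "cva_crossvalidated",
    "cohen_kappa",
]


class CanonicalVariateClassifier(BaseEstimator, ClassifierMixin):
    """Nearest-group-mean classifier in canonical variate space (equal priors).

    Attributes (after fit):
    ``classes_`` — sorted group labels; ``axes_`` — (p, r) canonical axes
    with r = min(g - 1, p), scaled so the pooled within-group covariance is
    whitened; ``means_`` — (g, r) group means in canonical space.
    """

    def fit(self, X, y) -> "CanonicalVariateClassifier":
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y)
        self.classes_ = np.array(sorted(pd.unique(y).tolist()))
        g = len(self.classes_)
        n, p = X.shape
        if g < 2:
            raise ValueError("CVA needs at least 2 groups")
        counts = np.array([np.sum(y == c) for c in self.classes_])
        if np.any(counts < 2):
            small = self.classes_[counts < 2]
            raise ValueError(f"every group needs >= 2 members; too small: {small}")
        grand = X.mean(axis=0)
        B = np.zeros((p, p))
        W = np.zeros((p, p))
        means = np.empty((g, p))
        for j, c in enumerate(self.classes_):
            block = X[y == c]
            means[j] = block.mean(axis=0)
            d = (means[j] - grand)[:, None]
            B += block.shape[0] * (d @ d.T)
            r = block - means[j]
            W += r.T @ r
        W /= n - g  # pooled within-group covariance
        try:
            evals, evecs = sla.eigh(B, W)
        except (np.linalg.LinAlgError, sla.LinAlgError) as exc:
            raise np.linalg.LinAlgError(
                "singular pooled within-group covariance; use fewer PCs"
            ) from exc
        order = np.argsort(evals)[::-1][: min(g - 1, p)]
        self.axes_ = evecs[:, order]  # v' W v = 1 normalization from eigh
        self.eigenvalues_ = evals[order]
        self.means_ = means @ self.axes_
        self.grand_mean_ = grand
        return self

    def canonical_scores(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return X @ self.axes_

    def predict(self, X) -> np.ndarray:
        scores = self.canonical_scores(X)
        d2 = ((scores[:, None, :] - self.means_[None, :, :]) ** 2).sum(axis=2)
        return self.classes_[np.argmin(d2, axis=1)]


@dataclass
class CvaReport:
    n_pcs_used: int
    canonical_axes: np.ndarray  # (p, g-1) from the full fit
    confusion: pd.DataFrame  # rows: true group, cols: predicted (LOO)
    ccv_pct: float
    kappa: float

    def as_row(self) -> dict:
        return {"PCs": self.n_pcs_used, "CCV (%)": self.ccv_pct, "Kappa": self.kappa}


def cohen_kappa(confusion) -> float:
    """Chance-corrected agreement of a g x g confusion matrix.

    kappa = (p_o - p_e) / (1 - p_e) with p_o the observed agreement rate and
    p_e the agreement expected from the row/column margins.
    """
    c = np.asarray(
        confusion.to_numpy() if isinstance(confusion, pd.DataFrame) else confusion,
        dtype=float,
    )
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("confusion matrix must be square")
    if np.any(c < 0):
        raise ValueError("confusion matrix counts must be non-negative")
    n = c.sum()
    if n < 1:
        raise ValueError("confusion matrix must contain at least one count")
    p_o = np.trace(c) / n
    p_e = float((c.sum(axis=1) * c.sum(axis=0)).sum()) / n**2
    if p_e >= 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def cva_crossvalidated(scores, factor, n_pcs: int | None = None) -> CvaReport:
    """Leave-one-out cross-validated CVA classification on the first PCs.

    Axes and group means are refitted in every fold.  Folds are taken in
    the given specimen order; sort inputs by specimen id beforehand for a
    canonical bookkeeping order (predictions themselves are order-free).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    y = np.asarray(factor)
    n, p = scores.shape
    if n_pcs is None:
        n_pcs = p
    if n_pcs > p:
        raise ValueError(f"n_pcs = {n_pcs} exceeds available scores ({p})")
    X = scores[:, :n_pcs]
    classes = np.array(sorted(pd.unique(y).tolist()))
    predictions = np.empty(n, dtype=y.dtype)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        clf = CanonicalVariateClassifier().fit(X[mask], y[mask])
        predictions[i] = clf.predict(X[i : i + 1])[0]
        mask[i] = True
    confusion = pd.DataFrame(0, index=classes, columns=classes)
    for t, pr in zip(y, predictions):
        confusion.loc[t, pr] += 1
    full = CanonicalVariateClassifier().fit(X, y)
    ccv = 100.0 * np.trace(confusion.to_numpy()) / n
    return CvaReport(
        n_pcs_used=n_pcs,
        canonical_axes=full.axes_,
        confusion=confusion,
        ccv_pct=float(ccv),
        kappa=cohen_kappa(confusion),
    )
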