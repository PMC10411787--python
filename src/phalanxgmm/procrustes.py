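"""Centroid size and Generalized Procrustes Analysis (GPA).

GPA iteratively removes position, orientation and (optionally) size from a
sample of landmark configurations: each configuration is centred, scaled to
unit centroid size and rotated onto the running consensus by orthogonal
Procrustes fitting (proper rotations only — reflections are handled at
I/O), and the consensus is re-estimated until it stabilizes.  The output
consensus is put into a canonical orientation (principal axes on the
coordinate axes, signs fixed by the first landmark's octant) so that
repeated runs and permuted inputs yield identical coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .io import Dataset, LandmarkConfiguration

__all__ = [
    "centroid_size",
    "AlignedSample",
    "GeneralizedProcrustesAnalysis",
    "gpa_align",
]


def centroid_size(config) -> float:
    """Centroid size: root summed squared deviation of landmarks from their centroid."""
    coords = config.coords if isinstance(config, LandmarkConfiguration) else config
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 2:
        raise ValueError("centroid size needs a (k>=2) x d coordinate matrix")
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates")
    cs = float(np.sqrt(((coords - coords.mean(axis=0)) ** 2).sum()))
    if cs == 0.0:
        raise ValueError("degenerate configuration: all landmarks coincide")
    return cs


@dataclass
class AlignedSample:
    """Procrustes-aligned coordinates with consensus and centroid sizes."""

    aligned: np.ndarray  # (n, k, 3), centred, unit centroid size
    mean_shape: np.ndarray  # (k, 3)
    centroid_sizes: np.ndarray  # (n,), mm
    specimen_ids: list[str] = field(default_factory=list)

    @property
    def log_centroid_sizes(self) -> np.ndarray:
        return np.log(self.centroid_sizes)

    @property
    def n_specimens(self) -> int:
        return self.aligned.shape[0]

    @property
    def n_points(self) -> int:
        return self.aligned.shape[1]

    def flattened(self) -> np.ndarray:
        """(n, 3k) view of the aligned coordinates (x1,y1,z1,x2,...)."""
        return self.aligned.reshape(self.n_specimens, -1)


def _optimal_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper rotation R minimizing ||a @ R - b||; reflections disallowed."""
    u, _, vt = np.linalg.svd(a.T @ b)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, 1.0, d]) @ vt


def _canonical_rotation(consensus: np.ndarray) -> np.ndarray:
    """Rotation putting a consensus into canonical principal-axes orientation."""
    cov = consensus.T @ consensus
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    R = evecs[:, order]
    probe = consensus[0] @ R  # first landmark fixes the axis signs
    signs = np.where(probe < 0, -1.0, 1.0)
    R = R * signs
    if np.linalg.det(R) < 0:  # restore a proper rotation via the weakest axis
        R[:, 2] *= -1.0
    return R


class GeneralizedProcrustesAnalysis(BaseEstimator, TransformerMixin):
    """Iterative Procrustes superimposition of a landmark sample.

    Parameters
    ----------
    scale : bool, default True
        Scale configurations to unit centroid size (full GPA).  With
        ``scale=False`` a partial Procrustes fit is performed: centred
        configurations keep their size and only rotation is optimized.
    tol : float
        Convergence threshold on the consensus change between iterations.
    max_iter : int
        Iteration cap for the consensus update loop.

    Attributes
    ----------
    mean_shape_ : (k, 3) consensus in canonical orientation
    aligned_ : (n, k, 3) aligned coordinates of the fitted sample
    centroid_sizes_ : (n,) original centroid sizes in mm
    n_iter_ : iterations run
    """

    def __init__(self, scale: bool = True, tol: float = 1e-10, max_iter: int = 100):
        self.scale = scale
        self.tol = tol
        self.max_iter = max_iter

    def _coerce(self, X) -> tuple[np.ndarray, list[str]]:
        if isinstance(X, Dataset):
            return X.coords_array(), X.specimen_ids
        if isinstance(X, (list, tuple)) and X and isinstance(X[0], LandmarkConfiguration):
            return np.stack([c.coords for c in X]), [c.specimen_id for c in X]
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise ValueError(f"expected (n, k, 3) coordinates, got {arr.shape}")
        return arr, [str(i) for i in range(arr.shape[0])]

    def fit(self, X, y=None) -> "GeneralizedProcrustesAnalysis":
        coords, ids = self._coerce(X)
        n = coords.shape[0]
        if n < 2:
            raise ValueError("GPA needs at least 2 configurations")
        sizes = np.empty(n)
        centred = np.empty_like(coords)
        for i in range(n):
            c = coords[i] - coords[i].mean(axis=0)
            try:
                sizes[i] = centroid_size(coords[i])
            except ValueError as exc:
                raise ValueError(f"specimen {ids[i]!r}: {exc}") from exc
            centred[i] = c / sizes[i] if self.scale else c

        mean = centred[0] / np.linalg.norm(centred[0])
        aligned = centred.copy()
        for it in range(1, self.max_iter + 1):
            for i in range(n):
                aligned[i] = centred[i] @ _optimal_rotation(centred[i], mean)
            new_mean = aligned.mean(axis=0)
            new_mean -= new_mean.mean(axis=0)
            new_mean /= np.linalg.norm(new_mean)
            if np.linalg.norm(new_mean - mean) < self.tol:
                mean = new_mean
                break
            mean = new_mean
        self.n_iter_ = it

        R = _canonical_rotation(mean)
        mean = mean @ R
        for i in range(n):
            a = aligned[i] @ R
            aligned[i] = a @ _optimal_rotation(a, mean)

        self.mean_shape_ = mean
        self.aligned_ = aligned
        self.centroid_sizes_ = sizes
        self.specimen_ids_ = ids
        return self

    def transform(self, X) -> np.ndarray:
        """Align configurations to the fitted consensus (centre, scale, rotate)."""
        coords, ids = self._coerce(X)
        out = np.empty_like(coords)
        for i in range(coords.shape[0]):
            c = coords[i] - coords[i].mean(axis=0)
            if self.scale:
                c = c / centroid_size(coords[i])
            out[i] = c @ _optimal_rotation(c, self.mean_shape_)
        return out

    def to_aligned_sample(self) -> AlignedSample:
        return AlignedSample(
            aligned=self.aligned_,
            mean_shape=self.mean_shape_,
            centroid_sizes=self.centroid_sizes_,
            specimen_ids=list(self.specimen_ids_),
        )


def gpa_align(configs, scale: bool = True) -> AlignedSample:
    """Generalized Procrustes superimposition of a list of configurations.

    Thin wrapper over :class:`GeneralizedProcrustesAnalysis`.
    """
    return GeneralizedProcrustesAnalysis(scale=scale).fit(configs).to_aligned_sample()
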