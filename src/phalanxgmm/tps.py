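"""Thin-plate-spline interpolation and bending energy in three dimensions.

The 3D spline kernel is U(r) = -r, the fundamental-solution kernel whose
sign is chosen so that the bending-energy quadratic form is positive
semi-definite (the interpolating map itself is identical under either
sign).  For source points :math:`x_1..x_k` the interpolation system is

.. math::  L \\begin{pmatrix} W \\\\ A \\end{pmatrix}
           = \\begin{pmatrix} Y \\\\ 0 \\end{pmatrix},
   \\qquad
   L = \\begin{pmatrix} K & P \\\\ P^T & 0 \\end{pmatrix}

with ``K[i,j] = U(|x_i - x_j|)`` and ``P = [1 | X]``.  The bending-energy
matrix is the upper-left k x k block of ``L^{-1}``; the bending energy of a
target configuration ``Y`` is ``tr(Y' BE Y)``, zero exactly when ``Y`` is
an affine image of the source.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator

__all__ = [
    "ThinPlateSpline",
    "fit_tps",
    "bending_energy_matrix",
    "bending_energy",
]

#: minimum inter-point distance below which the TPS system is declared singular
_MIN_SEPARATION = 1e-9


def _kernel(r: np.ndarray) -> np.ndarray:
    return -r


def _check_source(source: np.ndarray) -> np.ndarray:
    source = np.asarray(source, dtype=float)
    if source.ndim != 2 or source.shape[1] != 3:
        raise ValueError(f"source points must be k x 3, got {source.shape}")
    if source.shape[0] < 5:
        raise ValueError("3D TPS needs at least 5 source points")
    d = cdist(source, source)
    np.fill_diagonal(d, np.inf)
    if d.min() < _MIN_SEPARATION:
        i, j = np.unravel_index(np.argmin(d), d.shape)
        raise np.linalg.LinAlgError(
            f"TPS system is singular: source points {i} and {j} coincide"
        )
    return source


def _tps_lhs(source: np.ndarray) -> np.ndarray:
    k = source.shape[0]
    K = _kernel(cdist(source, source))
    P = np.hstack([np.ones((k, 1)), source])
    L = np.zeros((k + 4, k + 4))
    L[:k, :k] = K
    L[:k, k:] = P
    L[k:, :k] = P.T
    return L


def bending_energy_matrix(source: np.ndarray) -> np.ndarray:
    """k x k bending-energy quadratic form of a source configuration.

    Positive semi-definite, with every affine function of the source
    coordinates (in particular the coordinates themselves) in its null
    space.
    """
    source = _check_source(source)
    k = source.shape[0]
    L_inv = np.linalg.inv(_tps_lhs(source))
    be = L_inv[:k, :k]
    return 0.5 * (be + be.T)


class ThinPlateSpline(BaseEstimator):
    """Exact TPS interpolant from a source to a target landmark configuration.

    After :meth:`fit`, :meth:`transform` warps arbitrary 3D points by the
    fitted deformation; ``bending_energy_`` holds the non-affine roughness
    of the map.
    """

    def fit(self, source: np.ndarray, target: np.ndarray) -> "ThinPlateSpline":
        source = _check_source(source)
        target = np.asarray(target, dtype=float)
        if target.shape != source.shape:
            raise ValueError(
                f"target shape {target.shape} does not match source {source.shape}"
            )
        k = source.shape[0]
        L = _tps_lhs(source)
        rhs = np.vstack([target, np.zeros((4, 3))])
        try:
            sol = np.linalg.solve(L, rhs)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "TPS system is singular (coincident or degenerate source points)"
            ) from exc
        self.source_points_ = source
        self.warp_coefficients_ = sol[:k]  # k x 3
        self.affine_part_ = sol[k:].T  # 3 x 4, columns: constant, x, y, z
        self.bending_energy_matrix_ = bending_energy_matrix(source)
        self.bending_energy_ = float(
            np.einsum("id,ij,jd->", target, self.bending_energy_matrix_, target)
        )
        return self

    def transform(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        U = _kernel(cdist(points, self.source_points_))
        affine = self.affine_part_[:, 0] + points @ self.affine_part_[:, 1:].T
        return affine + U @ self.warp_coefficients_


def fit_tps(source: np.ndarray, target: np.ndarray) -> ThinPlateSpline:
    """Fit the exact TPS interpolant mapping ``source`` onto ``target``."""
    return ThinPlateSpline().fit(source, target)


def bending_energy(reference: np.ndarray, config: np.ndarray) -> float:
    """Bending energy of the TPS deformation from ``reference`` to ``config``.

    Zero iff ``config`` is an affine image of ``reference``.
    """
    reference = _check_source(reference)
    config = np.asarray(config, dtype=float)
    if config.shape != reference.shape:
        raise ValueError("reference and config must have the same shape")
    be = bending_energy_matrix(reference)
    return float(np.einsum("id,ij,jd->", config, be, config))
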