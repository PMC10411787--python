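"""Sliding semilandmarks by bending-energy minimization.

Curve semilandmarks are allowed to displace along their estimated tangent
line, and surface semilandmarks within their estimated tangent plane, so
as to minimize the thin-plate-spline bending energy of each configuration
relative to a reference shape.  Because the allowed displacement is linear
in the sliding parameters and the bending energy is a quadratic form, each
sliding step is an exact quadratic minimization (solved as a linear
system), so the energy against the current reference never increases.

The reference is either the sample Procrustes consensus (default, updated
between outer iterations of slide -> re-superimpose) or a fixed template
configuration.  Tangent directions are estimated from the data: central
differences along the stored curve order for curve points (anchors close
the ends), and the two leading principal directions of the 6 nearest
within-patch neighbours for surface points.  Slid points are not
re-projected onto an underlying mesh.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .io import Dataset, LandmarkConfiguration
from .procrustes import GeneralizedProcrustesAnalysis, centroid_size
from .templates import LandmarkTemplate, PointRole
from .tps import bending_energy_matrix

__all__ = ["SemilandmarkSlider", "slide_semilandmarks", "tangent_directions"]


def tangent_directions(
    template: LandmarkTemplate, coords: np.ndarray
) -> list[tuple[int, np.ndarray]]:
    """Sliding bases for one configuration: (point index, directions) pairs.

    Curve points get one unit tangent (3,) from central differences along
    the curve (the run's anchor landmarks serve as end neighbours); surface
    points get a (2, 3) orthonormal tangent-plane basis from a local PCA of
    their 6 nearest neighbours within the same patch.
    """
    bases: list[tuple[int, np.ndarray]] = []
    for run in template.curves:
        if len(run) < 3:
            raise ValueError(
                f"curve run {run.start}:{run.stop} has fewer than 3 semilandmarks; "
                "tangent estimation needs at least 3"
            )
        chain = np.concatenate(
            [[run.anchors[0] - 1], run.indices, [run.anchors[1] - 1]]
        )
        pts = coords[chain]
        for pos, idx in enumerate(run.indices, start=1):
            t = pts[pos + 1] - pts[pos - 1]
            norm = np.linalg.norm(t)
            if norm == 0:  # degenerate: one-sided difference
                t = pts[pos + 1] - pts[pos]
                norm = np.linalg.norm(t)
            bases.append((int(idx), (t / norm)[None, :]))
    for patch in template.surface_patch_indices():
        pts = coords[patch]
        for local, idx in enumerate(patch):
            d2 = ((pts - pts[local]) ** 2).sum(axis=1)
            neigh = np.argsort(d2)[: min(7, len(patch))]  # self + 6 nearest
            local_pts = pts[neigh] - pts[neigh].mean(axis=0)
            _, _, vt = np.linalg.svd(local_pts, full_matrices=False)
            bases.append((int(idx), vt[:2]))
    return bases


def _slide_one(
    coords: np.ndarray, be: np.ndarray, bases: list[tuple[int, np.ndarray]]
) -> np.ndarray:
    """Minimize tr(X' BE X) over tangential semilandmark displacements."""
    cols: list[np.ndarray] = []  # owning point of each sliding parameter
    dirs: list[np.ndarray] = []
    for idx, u in bases:
        for a in range(u.shape[0]):
            cols.append(idx)
            dirs.append(u[a])
    pidx = np.asarray(cols)
    U = np.asarray(dirs)  # (m, 3)
    G = be @ coords  # (k, 3)
    g = 2.0 * np.einsum("md,md->m", U, G[pidx])
    H = 2.0 * be[np.ix_(pidx, pidx)] * (U @ U.T)
    t, *_ = np.linalg.lstsq(H, -g, rcond=None)
    out = coords.copy()
    np.add.at(out, pidx, t[:, None] * U)
    return out


@dataclass
class SlidingHistory:
    """Per-iteration total bending energy before and after the sliding step."""

    energy_before: list[float] = field(default_factory=list)
    energy_after: list[float] = field(default_factory=list)
    displacement: list[float] = field(default_factory=list)


class SemilandmarkSlider(BaseEstimator):
    """Slide semilandmarks of a sample to minimize bending energy.

    Parameters
    ----------
    n_iter : int, default 3
        Outer iterations of (slide -> re-superimpose).
    tol : float, default 1e-6
        Stop when the total slid displacement falls below this.
    reference : {"consensus", "template"}
        Slide against the recomputed Procrustes consensus (default) or
        against a fixed template configuration.
    """

    def __init__(
        self, n_iter: int = 3, tol: float = 1e-6, reference: str = "consensus"
    ):
        self.n_iter = n_iter
        self.tol = tol
        self.reference = reference

    def fit_transform_dataset(
        self, dataset: Dataset, template_config: LandmarkConfiguration | None = None
    ) -> Dataset:
        if self.reference not in ("consensus", "template"):
            raise ValueError("reference must be 'consensus' or 'template'")
        template = dataset.template
        coords = dataset.coords_array()
        n = coords.shape[0]

        if template_config is not None:
            ref_fixed = template.validate_coords(
                template_config.coords, template_config.specimen_id
            )
            ref_fixed = ref_fixed - ref_fixed.mean(axis=0)
            ref_fixed = ref_fixed / centroid_size(ref_fixed)
        elif self.reference == "template":
            raise ValueError("reference='template' requires a template_config")
        else:
            ref_fixed = None

        history = SlidingHistory()
        gpa = GeneralizedProcrustesAnalysis()
        current = coords.copy()  # kept in each specimen's original frame
        for _ in range(self.n_iter):
            centroids = current.mean(axis=1)
            sizes = np.array([centroid_size(c) for c in current])
            gpa.fit(current)
            aligned = gpa.aligned_
            if self.reference == "consensus":
                reference = gpa.mean_shape_
            else:
                reference = ref_fixed @ _best_rotation(ref_fixed, gpa.mean_shape_)
            be = bending_energy_matrix(reference)
            e_before = e_after = disp = 0.0
            for i in range(n):
                bases = tangent_directions(template, aligned[i])
                e_before += float(np.einsum("id,ij,jd->", aligned[i], be, aligned[i]))
                slid = _slide_one(aligned[i], be, bases)
                e_after += float(np.einsum("id,ij,jd->", slid, be, slid))
                disp += float(np.abs(slid - aligned[i]).sum())
                # map back through the specimen's own similarity transform so
                # that fixed landmarks keep their original coordinates exactly
                norm = (current[i] - centroids[i]) / sizes[i]
                rot = _best_rotation(norm, aligned[i])
                current[i] = centroids[i] + sizes[i] * (slid @ rot.T)
            history.energy_before.append(e_before)
            history.energy_after.append(e_after)
            history.displacement.append(disp)
            if disp < self.tol:
                break

        self.history_ = history
        self.n_iter_run_ = len(history.displacement)
        return dataset.with_coords(current)


def _best_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    u, _, vt = np.linalg.svd(a.T @ b)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, 1.0, d]) @ vt


def slide_semilandmarks(
    dataset: Dataset,
    template_config: LandmarkConfiguration | None = None,
    n_iter: int = 3,
    tol: float = 1e-6,
    reference: str = "consensus",
) -> Dataset:
    """Slide a dataset's semilandmarks; returns a new Dataset (original sizes kept)."""
    slider = SemilandmarkSlider(n_iter=n_iter, tol=tol, reference=reference)
    out = slider.fit_transform_dataset(dataset, template_config)
    slide_semilandmarks.last_history = slider.history_  # diagnostic hook
    return out
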