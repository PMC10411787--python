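"""Landmark templates for the proximal phalanx epiphysis.

A template fixes the number and the role of every digitized point on one
limb's proximal first phalanx: a handful of true anatomical landmarks at
well-defined positions (crest intersections, cavity extrema), ordered runs
of curve semilandmarks along the articular crests, and patches of surface
semilandmarks covering the two articular facets.  Semilandmarks lack exact
point-wise homology and are later allowed to slide (see
:mod:`phalanxgmm.sliding`).

Point indices are 1-based in template definitions (matching how such
configurations are tabulated) and converted to 0-based arrays internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "Limb",
    "PointRole",
    "CurveRun",
    "LandmarkTemplate",
    "forelimb_template",
    "hindlimb_template",
    "template_for_limb",
]


class Limb(str, Enum):
    FORE = "fore"
    HIND = "hind"


class PointRole(str, Enum):
    FIXED = "fixed"
    CURVE = "curve"
    SURFACE = "surface"


@dataclass(frozen=True)
class CurveRun:
    """An ordered run of curve semilandmarks with its two anchor landmarks.

    ``start``/``stop`` are 1-based inclusive point indices of the
    semilandmarks; ``anchors`` are the 1-based indices of the fixed (or
    previously defined) points the crest runs between.
    """

    start: int
    stop: int
    anchors: tuple[int, int]

    @property
    def indices(self) -> np.ndarray:
        """0-based indices of the semilandmarks in this run, in curve order."""
        return np.arange(self.start - 1, self.stop)

    def __len__(self) -> int:
        return self.stop - self.start + 1


@dataclass(frozen=True)
class LandmarkTemplate:
    """Roles and curve/surface structure of one limb's landmark configuration."""

    limb: Limb
    n_points: int
    n_fixed: int
    curves: tuple[CurveRun, ...]
    surface_patches: tuple[tuple[int, int], ...]  # 1-based inclusive ranges
    _roles: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        roles = np.full(self.n_points, "", dtype="U7")
        roles[: self.n_fixed] = PointRole.FIXED.value
        for run in self.curves:
            if np.any(roles[run.indices] != ""):
                raise ValueError("curve runs overlap fixed points or each other")
            roles[run.indices] = PointRole.CURVE.value
        for lo, hi in self.surface_patches:
            idx = np.arange(lo - 1, hi)
            if np.any(roles[idx] != ""):
                raise ValueError("surface patches overlap other roles")
            roles[idx] = PointRole.SURFACE.value
        if np.any(roles == ""):
            raise ValueError("template leaves points without a role")
        object.__setattr__(self, "_roles", roles)

    @property
    def roles(self) -> np.ndarray:
        """Per-point role values (``"fixed"``, ``"curve"``, ``"surface"``)."""
        return self._roles

    def indices_of(self, role: PointRole | str) -> np.ndarray:
        return np.flatnonzero(self._roles == PointRole(role).value)

    @property
    def n_curve(self) -> int:
        return int(sum(len(r) for r in self.curves))

    @property
    def n_surface(self) -> int:
        return int(sum(hi - lo + 1 for lo, hi in self.surface_patches))

    def surface_patch_indices(self) -> list[np.ndarray]:
        return [np.arange(lo - 1, hi) for lo, hi in self.surface_patches]

    def validate_coords(self, coords: np.ndarray, specimen_id: str = "?") -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_points, 3):
            raise ValueError(
                f"specimen {specimen_id!r}: expected {self.n_points}x3 coordinates "
                f"for the {self.limb.value} template, got {coords.shape}"
            )
        if not np.all(np.isfinite(coords)):
            raise ValueError(f"specimen {specimen_id!r}: non-finite coordinates")
        return coords


def forelimb_template() -> LandmarkTemplate:
    """Forelimb proximal phalanx: 4 landmarks, 43 curve and 25 surface semilandmarks."""
    return LandmarkTemplate(
        limb=Limb.FORE,
        n_points=72,
        n_fixed=4,
        curves=(
            CurveRun(5, 16, (1, 2)),
            CurveRun(17, 30, (2, 3)),
            CurveRun(31, 38, (3, 2)),
            CurveRun(39, 47, (4, 18)),  # LM 4 to curve semilandmark 14 (point 18)
        ),
        surface_patches=((48, 57), (58, 72)),
    )


def hindlimb_template() -> LandmarkTemplate:
    """Hindlimb proximal phalanx: 4 landmarks, 45 curve and 25 surface semilandmarks."""
    return LandmarkTemplate(
        limb=Limb.HIND,
        n_points=74,
        n_fixed=4,
        curves=(
            CurveRun(5, 18, (1, 2)),
            CurveRun(19, 32, (2, 3)),
            CurveRun(33, 40, (3, 2)),
            CurveRun(41, 49, (4, 20)),  # LM 4 to curve semilandmark 16 (point 20)
        ),
        surface_patches=((50, 58), (59, 74)),
    )


def template_for_limb(limb: Limb | str) -> LandmarkTemplate:
    limb = Limb(limb)
    return forelimb_template() if limb is Limb.FORE else hindlimb_template()
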