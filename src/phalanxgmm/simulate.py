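"""Synthetic landmark populations with the statistical structure of the study.

The generator emulates a two-limb sampling design of wild caribou proximal
phalanges: 7 subspecies+habitat+mobility groups with fixed sample sizes,
group mean-shape offsets, a within-group allometric shape component driven
by log centroid size, sexual size dimorphism with overlap, and isotropic
digitization noise.  Every specimen is finally moved by a random similarity
transform so that superimposition has real work to do.

Planted effect directions (group offsets, the allometric vector) are drawn
once per specification from seeded Gaussians and projected orthogonal to
the similarity-transform tangent directions at the base shape, so planted
effects live purely in shape space.  Default effect magnitudes are
calibrated so that a default forelimb run lands in the regime the analyses
expect (first two PCs near half the shape variance, a size-related share
of roughly 6%); the constants live in :data:`DEFAULT_CALIBRATION`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .io import (
    Dataset,
    Habitat,
    LandmarkConfiguration,
    Mobility,
    Sex,
    SpecimenRecord,
    Subspecies,
    load_study_metadata,
)
from .procrustes import centroid_size
from .templates import LandmarkTemplate, Limb, template_for_limb

__all__ = [
    "DEFAULT_CALIBRATION",
    "ALLOMETRY_TARGET_PCT",
    "GroupSpec",
    "SyntheticSpec",
    "make_template_shape",
    "generate_population",
    "study_spec",
    "planted_size_pct",
    "amplitude_for_planted_pct",
    "orthogonal_offsets",
]

#: Calibration constants of the default synthetic study conditions.
#: Units: shape offsets and noise are in Procrustes shape units (the base
#: shape has unit centroid size); log sizes are natural logs of mm.
DEFAULT_CALIBRATION: dict[str, float] = {
    "noise_sd": 0.01,  # digitization + individual noise, per coordinate
    "group_offset_scale": 0.16,  # norm of each group's mean-shape offset
    "allometric_amplitude": 0.84,  # |shape change| per unit log centroid size
    "sd_log_cs": 0.06,  # within-group spread of log centroid size
    "sex_size_shift": 0.04,  # +male / -female shift of mean log size
    # group offsets are drawn mostly within a shared 2-D "ecological" plane
    # (habitat/mobility axes); this is the relative weight of the
    # idiosyncratic out-of-plane component of each group's offset
    "offset_plane_mix": 0.4,
}

#: Planted percentage of shape variance attributable to size in the default
#: study conditions, per limb (forelimb allometry is markedly stronger).
ALLOMETRY_TARGET_PCT: dict[Limb, float] = {Limb.FORE: 5.90, Limb.HIND: 2.34}

#: Per-limb norm of the default group mean-shape offsets, calibrated so the
#: leading two PCs of a default run (sliding included) carry roughly half
#: the shape variance.
OFFSET_SCALE: dict[Limb, float] = {Limb.FORE: 0.28, Limb.HIND: 0.30}

#: Default mean log centroid sizes (mm scale) by subspecies; the two
#: high-arctic subspecies are distinctly smaller-bodied.
MEAN_LOG_CS: dict[Subspecies, float] = {
    Subspecies.CARIBOU: 4.00,
    Subspecies.GRANTI: 3.98,
    Subspecies.GROENLANDICUS: 3.90,
    Subspecies.PEARYI: 3.83,
}


@dataclass
class GroupSpec:
    """One sampled group: its labels, size, sexes and planted effects."""

    subspecies: Subspecies
    habitat: Habitat
    mobility: Mobility
    n: int
    sexes: tuple[Sex, ...] = ()
    shape_offset: np.ndarray | None = None  # (3k,), drawn if None
    mean_log_cs: float | None = None
    sd_log_cs: float | None = None

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("group size must be non-negative")
        if self.sexes and len(self.sexes) != self.n:
            raise ValueError("sexes must have one entry per specimen")
        if not self.sexes:
            self.sexes = tuple([Sex.UNKNOWN] * self.n)


@dataclass
class SyntheticSpec:
    """Full specification of a synthetic landmark population."""

    template: LandmarkTemplate
    groups: list[GroupSpec]
    base_shape: np.ndarray | None = None  # (k, 3), built from seed if None
    allometric_vector: np.ndarray | None = None  # (3k,), drawn if None
    allometry_strength: float = 1.0  # scales the allometric amplitude, in [0, 1]
    noise_sd: float = DEFAULT_CALIBRATION["noise_sd"]
    group_offset_scale: float = DEFAULT_CALIBRATION["group_offset_scale"]
    allometric_amplitude: float = DEFAULT_CALIBRATION["allometric_amplitude"]
    sex_size_shift: float = DEFAULT_CALIBRATION["sex_size_shift"]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not self.groups:
            raise ValueError("a synthetic spec needs at least one group")


def _smooth_field(points: np.ndarray, rng: np.random.Generator, amp: float) -> np.ndarray:
    """Low-frequency sinusoidal displacement field (smooth, seeded)."""
    disp = np.zeros_like(points)
    for _ in range(3):
        freq = rng.uniform(0.5, 2.0, size=3)
        phase = rng.uniform(0, 2 * np.pi)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        disp += amp * np.sin(points @ freq + phase)[:, None] * direction
    return disp


def make_template_shape(template: LandmarkTemplate, seed: int = 0) -> np.ndarray:
    """Deterministic stylized proximal-epiphysis point cloud at unit centroid size.

    Two articular-surface patches (lateral and medial cups) separated by a
    sagittal groove, crest semilandmarks running along elliptical arcs
    between the anchor landmarks, in the stored curve order.
    """
    rng = np.random.default_rng(seed)
    k = template.n_points
    pts = np.zeros((k, 3))

    # anatomical landmarks: abaxial crest point, anterior and posterior
    # junctions of the glenoid cavities, posterior end of the sagittal groove
    pts[0] = (-1.10, 0.25, 0.30)
    pts[1] = (0.00, 0.85, 0.25)
    pts[2] = (0.00, -0.85, 0.25)
    pts[3] = (0.05, -0.45, -0.10)

    # crest arcs between their anchors; each run bulges out of the chord in
    # its own direction, so each projected polyline is a simple arc
    bulges = [
        np.array([-0.45, 0.0, 0.35]),  # lateral crest, outward + up
        np.array([0.95, 0.0, 0.25]),  # medial rim, toward the medial side
        np.array([0.35, 0.0, -0.30]),  # groove-side return arc, lower
        np.array([-0.55, -0.35, 0.10]),  # posterior crest from LM 4
    ]
    for run, bulge in zip(template.curves, bulges):
        a = pts[run.anchors[0] - 1]
        b = pts[run.anchors[1] - 1]
        t = np.linspace(0.0, 1.0, len(run) + 2)[1:-1]
        arc = (1 - t)[:, None] * a + t[:, None] * b
        arc += np.sin(np.pi * t)[:, None] * bulge
        pts[run.indices] = arc

    # articular facets: sunflower layouts on two elliptical paraboloid cups
    centres = [(-0.45, 0.0), (0.50, 0.0)]
    semi_axes = [(0.45, 0.55), (0.42, 0.60)]
    golden = np.pi * (3.0 - np.sqrt(5.0))
    for patch, (cx, cy), (ax, ay) in zip(
        template.surface_patch_indices(), centres, semi_axes
    ):
        m = len(patch)
        i = np.arange(m)
        r = np.sqrt((i + 0.5) / m)
        th = golden * i
        x = cx + ax * r * np.cos(th)
        y = cy + ay * r * np.sin(th)
        z = -0.35 * (1.0 - ((x - cx) / ax) ** 2 - ((y - cy) / ay) ** 2)
        pts[patch] = np.column_stack([x, y, z])

    pts = pts + _smooth_field(pts, rng, amp=0.02)
    pts -= pts.mean(axis=0)
    return pts / centroid_size(pts)


def _similarity_tangent_basis(base: np.ndarray) -> np.ndarray:
    """Orthonormal (3k, 7) basis of translation/rotation/scale directions."""
    k = base.shape[0]
    cols = []
    for d in range(3):
        t = np.zeros((k, 3))
        t[:, d] = 1.0
        cols.append(t.ravel())
    cols.append(base.ravel())  # scaling direction
    generators = [
        np.array([[0, -1, 0], [1, 0, 0], [0, 0, 0]], float),
        np.array([[0, 0, -1], [0, 0, 0], [1, 0, 0]], float),
        np.array([[0, 0, 0], [0, 0, -1], [0, 1, 0]], float),
    ]
    for gmat in generators:
        cols.append((base @ gmat.T).ravel())
    q, _ = np.linalg.qr(np.column_stack(cols))
    return q


def _draw_shape_direction(
    rng: np.random.Generator, basis: np.ndarray, dim: int
) -> np.ndarray:
    """Unit vector in shape space, orthogonal to the similarity directions."""
    v = rng.normal(size=dim)
    v -= basis @ (basis.T @ v)
    return v / np.linalg.norm(v)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, [0, 1]] = q[:, [1, 0]]
    return q


def orthogonal_offsets(
    template: LandmarkTemplate, n: int, scale: float, seed: int = 0,
    base_shape: np.ndarray | None = None,
) -> list[np.ndarray]:
    """``n`` mutually orthogonal shape-space offsets of norm ``scale``.

    Useful for planting group separations of a known, exactly realized
    Mahalanobis size: with isotropic noise of standard deviation ``sd``,
    offsets of norm ``delta * sd`` put every group mean at Mahalanobis
    distance ``delta`` from the base shape and ``delta * sqrt(2)`` from one
    another.
    """
    rng = np.random.default_rng(seed)
    base = make_template_shape(template, seed=seed) if base_shape is None else base_shape
    basis = _similarity_tangent_basis(base)
    dim = 3 * template.n_points
    units: list[np.ndarray] = []
    while len(units) < n:
        v = _draw_shape_direction(rng, basis, dim)
        for u in units:
            v = v - (u @ v) * u
        norm = np.linalg.norm(v)
        if norm > 1e-8:
            units.append(v / norm)
    return [scale * u for u in units]


def generate_population(spec: SyntheticSpec) -> Dataset:
    """Draw a full synthetic dataset (configurations + metadata) from a spec."""
    rng = np.random.default_rng(spec.seed)
    template = spec.template
    k = template.n_points
    base = (
        make_template_shape(template, seed=spec.seed)
        if spec.base_shape is None
        else np.asarray(spec.base_shape, dtype=float)
    )
    basis = _similarity_tangent_basis(base)

    allom = spec.allometric_vector
    if allom is None:
        allom = spec.allometric_amplitude * _draw_shape_direction(rng, basis, 3 * k)
    else:
        allom = np.asarray(allom, dtype=float)

    # default offsets: mostly within a shared 2-D plane of "ecological"
    # shape axes, plus a smaller idiosyncratic component per group, so the
    # between-group variance concentrates on leading PCs as in real samples
    eps = DEFAULT_CALIBRATION["offset_plane_mix"]
    d1 = _draw_shape_direction(rng, basis, 3 * k)
    d2 = _draw_shape_direction(rng, basis, 3 * k)
    offsets = []
    for grp in spec.groups:
        if grp.shape_offset is None:
            c1, c2 = rng.normal(size=2)
            v = c1 * d1 + c2 * d2 + eps * np.linalg.norm([c1, c2]) * (
                _draw_shape_direction(rng, basis, 3 * k)
            )
            offsets.append(spec.group_offset_scale * v / np.linalg.norm(v))
        else:
            offsets.append(np.asarray(grp.shape_offset, dtype=float))

    sex_shift = {Sex.MALE: spec.sex_size_shift, Sex.FEMALE: -spec.sex_size_shift}
    configs: list[LandmarkConfiguration] = []
    records: list[SpecimenRecord] = []
    counter = 0
    for grp, offset in zip(spec.groups, offsets):
        mean_lcs = (
            grp.mean_log_cs
            if grp.mean_log_cs is not None
            else MEAN_LOG_CS[grp.subspecies]
        )
        sd_lcs = (
            grp.sd_log_cs
            if grp.sd_log_cs is not None
            else DEFAULT_CALIBRATION["sd_log_cs"]
        )
        for sex in grp.sexes:
            counter += 1
            sid = f"SYN {counter}"
            log_cs = rng.normal(mean_lcs + sex_shift.get(sex, 0.0), sd_lcs)
            shape = (
                base.ravel()
                + offset
                + spec.allometry_strength * (log_cs - mean_lcs) * allom
                + rng.normal(scale=spec.noise_sd, size=3 * k)
            ).reshape(k, 3)
            # random similarity transform; scale set so the recorded centroid
            # size is exactly exp(log_cs)
            shape = shape - shape.mean(axis=0)
            shape = shape / centroid_size(shape) * np.exp(log_cs)
            coords = shape @ _random_rotation(rng).T + rng.normal(scale=50.0, size=3)
            configs.append(LandmarkConfiguration(sid, template.limb, coords))
            records.append(
                SpecimenRecord(
                    specimen_id=sid,
                    subspecies=grp.subspecies,
                    habitat=grp.habitat,
                    mobility=grp.mobility,
                    sex=sex,
                    limb=template.limb,
                )
            )
    return Dataset(template, configs, records)


def study_spec(limb: Limb | str = Limb.FORE, seed: int = 0, **overrides) -> SyntheticSpec:
    """Synthetic spec reproducing the study's sampling design for one limb.

    Group sizes and the per-group sex composition are taken from the
    packaged study metadata (34 forelimb / 44 hindlimb specimens in 7
    subspecies+habitat+mobility groups).  Keyword overrides are applied to
    the resulting :class:`SyntheticSpec`.
    """
    limb = Limb(limb)
    template = template_for_limb(limb)
    records = load_study_metadata(limb)
    keys: list[tuple] = []
    grouped: dict[tuple, list[SpecimenRecord]] = {}
    for rec in records:
        key = (rec.subspecies, rec.habitat, rec.mobility)
        if key not in grouped:
            grouped[key] = []
            keys.append(key)
        grouped[key].append(rec)
    groups = [
        GroupSpec(
            subspecies=ssp,
            habitat=hab,
            mobility=mob,
            n=len(members),
            sexes=tuple(m.sex for m in members),
        )
        for (ssp, hab, mob), members in grouped.items()
    ]
    spec = SyntheticSpec(template=template, groups=groups, seed=seed)
    spec = replace(
        spec,
        group_offset_scale=OFFSET_SCALE[limb],
        allometric_amplitude=amplitude_for_planted_pct(
            replace(spec, group_offset_scale=OFFSET_SCALE[limb]),
            ALLOMETRY_TARGET_PCT[limb],
        ),
    )
    return replace(spec, **overrides) if overrides else spec


def _variance_components(spec: SyntheticSpec) -> tuple[float, float, float]:
    """(size-variance of log CS, between-group shape var, noise var) of a spec.

    The first component is the weighted within-group variance of log
    centroid size (sex shifts widen it); multiplied by the squared
    allometric amplitude it gives the planted size-related shape variance.
    """
    n = sum(g.n for g in spec.groups)
    if n == 0:
        raise ValueError("empty spec")
    w = np.array([g.n for g in spec.groups], float) / n
    vl = 0.0
    for g, wg in zip(spec.groups, w):
        sd = g.sd_log_cs if g.sd_log_cs is not None else DEFAULT_CALIBRATION["sd_log_cs"]
        shifts = np.array(
            [
                spec.sex_size_shift
                if s is Sex.MALE
                else -spec.sex_size_shift
                if s is Sex.FEMALE
                else 0.0
                for s in g.sexes
            ]
        )
        vl += wg * (sd**2 + (np.var(shifts) if len(shifts) else 0.0))
    norms = np.array(
        [
            spec.group_offset_scale
            if g.shape_offset is None
            else float(np.linalg.norm(g.shape_offset))
            for g in spec.groups
        ]
    )
    # independent offset directions: E||o_g - o_bar||^2 summed with weights
    b_var = float(np.sum(w * norms**2) * (1.0 - np.sum(w**2)))
    n_var = 3 * spec.template.n_points * spec.noise_sd**2
    return vl, b_var, n_var


def planted_size_pct(spec: SyntheticSpec) -> float:
    """Analytic percentage of shape variance planted by the size effect.

    Computed from the spec's variance components: allometric variance
    (within-group log-size spread times the squared allometric amplitude),
    between-group offset variance, and total isotropic noise variance.
    """
    vl, b_var, n_var = _variance_components(spec)
    amp = spec.allometry_strength * (
        spec.allometric_amplitude
        if spec.allometric_vector is None
        else float(np.linalg.norm(spec.allometric_vector))
    )
    a_var = amp**2 * vl
    return 100.0 * a_var / (a_var + b_var + n_var)


def amplitude_for_planted_pct(spec: SyntheticSpec, target_pct: float) -> float:
    """Allometric amplitude planting exactly ``target_pct`` % size variance."""
    if not 0 <= target_pct < 100:
        raise ValueError("target percentage must be in [0, 100)")
    if target_pct == 0:
        return 0.0
    vl, b_var, n_var = _variance_components(spec)
    t = target_pct / 100.0
    return float(np.sqrt(t * (b_var + n_var) / ((1.0 - t) * vl)))
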