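"""Centroid size and Generalized Procrustes superimposition."""

import itertools

import numpy as np
import pytest

from phalanxgmm.procrustes import (
    GeneralizedProcrustesAnalysis,
    centroid_size,
    gpa_align,
)


def _random_rotation(rng):
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, [0, 1]] = q[:, [1, 0]]
    return q


def test_centroid_size_symmetric_cross():
    pts = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0]], float)
    assert centroid_size(pts) == pytest.approx(2.0)


def test_centroid_size_homogeneous(rng):
    pts = rng.normal(size=(7, 3))
    c = 3.7
    assert centroid_size(c * pts) == pytest.approx(c * centroid_size(pts), rel=1e-12)


def test_centroid_size_brute_force_oracle(rng):
    pts = rng.normal(size=(10, 3)) * 25
    centroid = pts.sum(axis=0) / 10
    total = 0.0
    for p in pts:  # direct summation oracle
        for d in range(3):
            total += (p[d] - centroid[d]) ** 2
    assert centroid_size(pts) == pytest.approx(np.sqrt(total), rel=1e-12)


def test_centroid_size_degenerate():
    with pytest.raises(ValueError, match="coincide"):
        centroid_size(np.ones((5, 3)))


def test_gpa_identical_configs(rng):
    base = rng.normal(size=(6, 3))
    sample = gpa_align([base.copy() for _ in range(3)])
    d = np.linalg.norm(sample.aligned[0] - sample.aligned[1])
    assert d == pytest.approx(0.0, abs=1e-12)
    np.testing.assert_allclose(sample.aligned[0], sample.mean_shape, atol=1e-9)


def test_gpa_similarity_invariance(rng):
    """A config that is a scaled/rotated/translated copy of another aligns
    onto it exactly, and sizes are recorded in the original units."""
    a = rng.normal(size=(8, 3))
    R = _random_rotation(rng)
    b = 2.0 * a @ R.T + rng.normal(size=3)
    sample = gpa_align([a, b])
    np.testing.assert_allclose(sample.aligned[0], sample.aligned[1], atol=1e-9)
    assert sample.centroid_sizes[1] == pytest.approx(2 * sample.centroid_sizes[0])


def test_gpa_sample_transform_invariance(rng):
    """Applying one random similarity to every input leaves the aligned
    coordinates unchanged (canonical orientation pins the output frame)."""
    configs = rng.normal(size=(5, 9, 3))
    R = _random_rotation(rng)
    t = rng.normal(size=3)
    moved = 0.5 * configs @ R.T + t
    s1 = gpa_align(list(configs))
    s2 = gpa_align(list(moved))
    np.testing.assert_allclose(s1.aligned, s2.aligned, atol=1e-8)
    np.testing.assert_allclose(s1.mean_shape, s2.mean_shape, atol=1e-8)


def test_gpa_unit_size_and_centred(rng):
    configs = [rng.normal(size=(7, 3)) * 12 for _ in range(6)]
    sample = gpa_align(configs)
    for a in sample.aligned:
        np.testing.assert_allclose(a.mean(axis=0), 0.0, atol=1e-10)
        assert np.sqrt((a**2).sum()) == pytest.approx(1.0, abs=1e-10)
    assert np.sqrt((sample.mean_shape**2).sum()) == pytest.approx(1.0, abs=1e-10)


def test_gpa_residual_matches_rotation_grid_search(rng):
    """Converged residual sum of squares per configuration agrees with a
    brute-force search over rotation space (refined Euler-angle grid)."""
    configs = [rng.normal(size=(4, 3)) for _ in range(3)]
    sample = gpa_align(configs)
    mean = sample.mean_shape

    def euler(a, b, c):
        ca, sa = np.cos(a), np.sin(a)
        cb, sb = np.cos(b), np.sin(b)
        cc, sc = np.cos(c), np.sin(c)
        rz1 = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1]])
        ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
        rz2 = np.array([[cc, -sc, 0], [sc, cc, 0], [0, 0, 1]])
        return rz1 @ ry @ rz2

    for cfg, aligned in zip(configs, sample.aligned):
        x = cfg - cfg.mean(axis=0)
        x /= np.sqrt((x**2).sum())
        ours = ((aligned - mean) ** 2).sum()
        centre = np.zeros(3)
        width = np.pi
        best = np.inf
        for _ in range(4):  # coarse-to-fine grid refinement
            axes = [np.linspace(c - width, c + width, 11) for c in centre]
            for abc in itertools.product(*axes):
                rss = ((x @ euler(*abc) - mean) ** 2).sum()
                if rss < best:
                    best = rss
                    arg = abc
            centre = np.array(arg)
            width /= 5.0
        assert ours == pytest.approx(best, abs=1e-4)


def test_gpa_degenerate_config_named(rng):
    from phalanxgmm.io import LandmarkConfiguration

    good = LandmarkConfiguration("DPpha 1", "fore", rng.normal(size=(5, 3)))
    bad = LandmarkConfiguration("DPpha 2", "fore", np.ones((5, 3)))
    with pytest.raises(ValueError, match="DPpha 2"):
        gpa_align([good, bad])


def test_partial_procrustes_keeps_size(rng):
    configs = [rng.normal(size=(6, 3)) * s for s in (1.0, 3.0)]
    gpa = GeneralizedProcrustesAnalysis(scale=False).fit(configs)
    sizes = [np.sqrt((a**2).sum()) for a in gpa.aligned_]
    assert sizes[1] / sizes[0] == pytest.approx(
        centroid_size(configs[1]) / centroid_size(configs[0]), rel=1e-9
    )
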