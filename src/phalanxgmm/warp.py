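"""TPS warping of the consensus shape for visualizing shape variation.

Shape differences along principal axes are visualized by deforming the
consensus (or a surface sampled on it) toward a target shape, with the
displacement optionally magnified — small magnifications (e.g. 0.1) make
subtle articular-surface differences visible.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .tps import fit_tps

__all__ = ["tps_warp_mean", "write_ply_points", "read_ply_points"]


def tps_warp_mean(
    mean_shape: np.ndarray,
    target_shape: np.ndarray,
    surface_points: np.ndarray,
    magnification: float = 0.1,
) -> np.ndarray:
    """Warp ``surface_points`` by the TPS from the mean toward a target shape.

    The deformation maps ``mean_shape`` onto
    ``mean_shape + magnification * (target_shape - mean_shape)``; with
    ``magnification=0`` the map is the identity, with 1 it interpolates the
    full difference.
    """
    mean_shape = np.asarray(mean_shape, dtype=float)
    target_shape = np.asarray(target_shape, dtype=float)
    if target_shape.shape != mean_shape.shape:
        raise ValueError("mean and target shapes must have identical dimensions")
    if magnification < 0:
        raise ValueError("magnification must be non-negative")
    target = mean_shape + magnification * (target_shape - mean_shape)
    return fit_tps(mean_shape, target).transform(surface_points)


def write_ply_points(points: np.ndarray, path: str | Path) -> None:
    """Write a point set as an ASCII PLY file."""
    points = np.asarray(points, dtype=float)
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {points.shape[0]}\n")
        fh.write("property double x\nproperty double y\nproperty double z\n")
        fh.write("end_header\n")
        for x, y, z in points:
            fh.write(f"{x:.12g} {y:.12g} {z:.12g}\n")


def read_ply_points(path: str | Path) -> np.ndarray:
    """Read vertices back from an ASCII PLY point file."""
    lines = Path(path).read_text().splitlines()
    try:
        start = lines.index("end_header") + 1
    except ValueError as exc:
        raise ValueError(f"{path}: not an ASCII PLY file") from exc
    return np.array([[float(v) for v in ln.split()] for ln in lines[start:] if ln])
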