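"""Scalar implant-migration summaries and surface-distance maps.

MTPM (maximum total point motion) is the standard RSA migration measure:
the displacement in mm of the implant point that moves the most under the
relative transform. mTRE (mean target registration error) is the mean
per-point displacement. Both mix object geometry and motion into one
scalar — MTPM grows linearly with object size under a pure rotation —
which is why they are reported alongside the decomposed parameters.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .imaging import SurfaceMesh
from .registration import RigidTransform

__all__ = ["mtpm", "mtre", "point_displacements", "surface_distance"]


def point_displacements(points: np.ndarray, transform: RigidTransform) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(points, float))
    if pts.size == 0:
        raise ValueError("empty point set")
    return np.linalg.norm(transform.apply(pts) - pts, axis=1)


def mtpm(points: np.ndarray, transform: RigidTransform) -> float:
    """Maximum total point motion: max over points of |M p - p| in mm."""
    return float(point_displacements(points, transform).max())


def mtre(points: np.ndarray, transform: RigidTransform) -> float:
    """Mean target registration error: mean over points of |M p - p| in mm."""
    return float(point_displacements(points, transform).mean())


def surface_distance(mesh_a: SurfaceMesh, mesh_b: SurfaceMesh) -> np.ndarray:
    """Per-vertex nearest-neighbour distance from mesh_a to mesh_b vertices.

    The heatmap substrate: after aligning two tibia segmentations on one
    segment, these distances visualise where the bone deformed.
    """
    if len(mesh_a.vertices) == 0 or len(mesh_b.vertices) == 0:
        raise ValueError("surface_distance requires non-empty meshes")
    tree = cKDTree(mesh_b.vertices)
    d, _ = tree.query(mesh_a.vertices, k=1)
    return np.asarray(d, dtype=float)


def save_surface_distance_ply(mesh_a: SurfaceMesh, distances: np.ndarray, path: str) -> None:
    """Write mesh_a as PLY with the distance as a per-vertex quality/color scalar."""
    tm = mesh_a.to_trimesh()
    d = np.asarray(distances, float)
    rng = np.ptp(d)
    u = (d - d.min()) / rng if rng > 0 else np.zeros_like(d)
    colors = np.zeros((len(d), 4), dtype=np.uint8)
    colors[:, 0] = np.round(255 * u)
    colors[:, 2] = np.round(255 * (1 - u))
    colors[:, 3] = 255
    tm.visual.vertex_colors = colors
    tm.export(path)
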