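"""Relative-displacement algebra and the implant-anchored local frame.

Given the absolute displacements ``Mi`` and ``Mj`` of two objects between
the valgus and varus scans (each obtained by registration), the relative
displacement of object i with respect to object j in the global (CT)
coordinate system is ``M(i,j) = Mj^-1 @ Mi``. Because any extra rigid
motion applied to the whole specimen multiplies both absolute displacements
on the same side, M(i,j) is invariant to specimen repositioning — the
property that makes load-CT displacement measurement possible without
fixing the leg.

Displacements are reported in a local coordinate system anchored to the
implant: origin at the centroid of the implant plateau surface, z pointing
distoproximally (the plateau normal), x to the lateral side (the long
medial-lateral plateau axis) and y posterior-anterior. The frame is built
automatically from the implant mesh by projecting an axial grid of rays
onto the plateau and taking principal axes of the hit points' inertia
tensor, which removes the observer variability of manual landmarking.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .imaging import SurfaceMesh
from .registration import RigidTransform, matrix_to_params

__all__ = [
    "LocalCS",
    "DisplacementResult",
    "relative_displacement",
    "build_local_cs",
    "to_local",
    "decompose",
    "plateau_points",
]


@dataclass(frozen=True)
class LocalCS:
    """Implant local coordinate system.

    ``m_cs`` maps local coordinates into the global frame (its columns are
    the x, y, z axes and its translation the plateau centroid), so a global
    relative displacement M is expressed locally as ``m_cs^-1 @ M @ m_cs``.
    """

    m_cs: RigidTransform
    origin: np.ndarray
    axes: np.ndarray  # columns x, y, z

    def transformed(self, T: RigidTransform) -> "LocalCS":
        """The same anatomical frame after rigidly moving the implant by T."""
        m = T @ self.m_cs
        return LocalCS(m_cs=m, origin=m.translation_vector, axes=m.rotation)


@dataclass
class DisplacementResult:
    """Decomposed local-frame displacement for one object pair."""

    dx: float
    dy: float
    dz: float
    dphi_x: float
    dphi_y: float
    dphi_z: float
    translation_magnitude: float
    rotation_magnitude: float
    mtre: float | None = None
    mtpm: float | None = None
    object_pair: str = ""
    gimbal_flag: bool = False

    def parameters(self) -> np.ndarray:
        return np.array([self.dx, self.dy, self.dz, self.dphi_x, self.dphi_y, self.dphi_z])

    def to_dict(self) -> dict:
        d = {
            "object_pair": self.object_pair,
            "dx_mm": self.dx,
            "dy_mm": self.dy,
            "dz_mm": self.dz,
            "dphi_x_deg": self.dphi_x,
            "dphi_y_deg": self.dphi_y,
            "dphi_z_deg": self.dphi_z,
            "translation_magnitude_mm": self.translation_magnitude,
            "rotation_magnitude_deg": self.rotation_magnitude,
        }
        if self.mtre is not None:
            d["mtre_mm"] = self.mtre
        if self.mtpm is not None:
            d["mtpm_mm"] = self.mtpm
        return d


def relative_displacement(mi: RigidTransform, mj: RigidTransform) -> RigidTransform:
    """Relative displacement of object i w.r.t. object j: ``Mj^-1 @ Mi``."""
    if not isinstance(mi, RigidTransform) or not isinstance(mj, RigidTransform):
        raise TypeError("relative_displacement expects RigidTransform inputs")
    return mj.inverse() @ mi


def to_local(m: RigidTransform, cs: LocalCS) -> RigidTransform:
    """Express a global relative displacement in the local CS (conjugation)."""
    return cs.m_cs.inverse() @ m @ cs.m_cs


def plateau_points(
    mesh: SurfaceMesh,
    grid_spacing: float,
) -> np.ndarray:
    """First intersections of a downward axial ray grid with the mesh.

    A regular grid of rays parallel to -z is cast from above the mesh over
    its xy bounding box; for each grid cell the highest-z triangle
    intersection is kept (a z-buffer over mesh triangles, exact for axial
    rays). The surviving points sample the upward-facing implant plateau.
    """
    v = mesh.vertices
    f = mesh.faces
    xmin, ymin = v[:, 0].min(), v[:, 1].min()
    xmax, ymax = v[:, 0].max(), v[:, 1].max()
    nx = max(2, int(np.floor((xmax - xmin) / grid_spacing)) + 1)
    ny = max(2, int(np.floor((ymax - ymin) / grid_spacing)) + 1)
    zbuf = np.full((nx, ny), -np.inf)

    tri = v[f]  # (m, 3, 3)
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    # candidate grid nodes per triangle from its xy bounding box
    ix0 = np.clip(np.ceil((np.minimum.reduce([a[:, 0], b[:, 0], c[:, 0]]) - xmin) / grid_spacing), 0, nx - 1).astype(int)
    ix1 = np.clip(np.floor((np.maximum.reduce([a[:, 0], b[:, 0], c[:, 0]]) - xmin) / grid_spacing), 0, nx - 1).astype(int)
    iy0 = np.clip(np.ceil((np.minimum.reduce([a[:, 1], b[:, 1], c[:, 1]]) - ymin) / grid_spacing), 0, ny - 1).astype(int)
    iy1 = np.clip(np.floor((np.maximum.reduce([a[:, 1], b[:, 1], c[:, 1]]) - ymin) / grid_spacing), 0, ny - 1).astype(int)
    counts = np.maximum(ix1 - ix0 + 1, 0) * np.maximum(iy1 - iy0 + 1, 0)
    tri_idx = np.repeat(np.arange(len(f)), counts)
    if len(tri_idx) == 0:
        raise ValueError("mesh projects onto no grid nodes; grid too coarse")
    # enumerate (ix, iy) pairs per triangle
    local = np.arange(len(tri_idx)) - np.repeat(np.cumsum(counts) - counts, counts)
    width = np.maximum(iy1 - iy0 + 1, 1)[tri_idx]
    ix = ix0[tri_idx] + local // width
    iy = iy0[tri_idx] + local % width
    px = xmin + ix * grid_spacing
    py = ymin + iy * grid_spacing

    a2, b2, c2 = a[tri_idx], b[tri_idx], c[tri_idx]
    # barycentric point-in-triangle in the xy plane
    v0 = (b2 - a2)[:, :2]
    v1 = (c2 - a2)[:, :2]
    vp = np.stack([px - a2[:, 0], py - a2[:, 1]], axis=1)
    den = v0[:, 0] * v1[:, 1] - v0[:, 1] * v1[:, 0]
    ok = np.abs(den) > 1e-12
    den = np.where(ok, den, 1.0)
    s = (vp[:, 0] * v1[:, 1] - vp[:, 1] * v1[:, 0]) / den
    t = (v0[:, 0] * vp[:, 1] - v0[:, 1] * vp[:, 0]) / den
    inside = ok & (s >= -1e-9) & (t >= -1e-9) & (s + t <= 1 + 1e-9)
    z = a2[:, 2] + s * (b2[:, 2] - a2[:, 2]) + t * (c2[:, 2] - a2[:, 2])
    np.maximum.at(zbuf, (ix[inside], iy[inside]), z[inside])

    hit = np.isfinite(zbuf)
    gx, gy = np.nonzero(hit)
    return np.column_stack([xmin + gx * grid_spacing, ymin + gy * grid_spacing, zbuf[hit]])


def build_local_cs(
    implant_mesh: SurfaceMesh,
    side: Literal["left", "right"],
    grid_spacing: float = 0.9,
) -> LocalCS:
    """Automatic implant coordinate system from the plateau inertia axes.

    The plateau point set (axial ray grid, first hits from above) is reduced
    to its centroid (the frame origin and centre of rotation) and the
    eigenvectors of its inertia tensor. For a near-planar plateau the
    largest-eigenvalue eigenvector is the plane normal (z, oriented
    proximally, i.e. away from the bone); the smallest is the long
    medial-lateral in-plane axis (x, signed toward the lateral side as given
    by ``side``); y = z x x completes a right-handed frame
    (posterior-anterior).

    ``side`` resolves the lateral sign: scans are assumed in the standard
    patient orientation, so lateral is world +x for a right leg and world -x
    for a left leg.
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    pts = plateau_points(implant_mesh, grid_spacing)
    if len(pts) < 50:
        raise ValueError(f"only {len(pts)} plateau ray hits; need at least 50")
    origin = pts.mean(axis=0)
    q = pts - origin
    # inertia tensor of unit point masses about the centroid
    r2 = np.sum(q * q, axis=1).sum()
    inertia = r2 * np.eye(3) - q.T @ q
    w, v = np.linalg.eigh(inertia)  # ascending
    if w[1] > 0 and w[0] / w[1] > 0.95:
        raise ValueError("in-plane inertia eigenvalues nearly degenerate; axes ambiguous")
    z_axis = v[:, 2]
    if np.dot(z_axis, origin - implant_mesh.centroid) < 0:
        z_axis = -z_axis
    x_axis = v[:, 0]
    x_axis = x_axis - np.dot(x_axis, z_axis) * z_axis
    x_axis /= np.linalg.norm(x_axis)
    lateral_sign = 1.0 if side == "right" else -1.0
    if lateral_sign * x_axis[0] < 0:
        x_axis = -x_axis
    y_axis = np.cross(z_axis, x_axis)
    axes = np.column_stack([x_axis, y_axis, z_axis])
    m_cs = RigidTransform.from_rotation_translation(axes, origin)
    return LocalCS(m_cs=m_cs, origin=origin, axes=axes)


def decompose(m_local: RigidTransform, object_pair: str = "") -> DisplacementResult:
    """Decompose a local-frame displacement into parameters and magnitudes.

    Translations along and rotations about the local x, y, z axes follow the
    y, x, z Euler sequence; the magnitudes are the root-sum-squares
    ``sqrt(dx^2+dy^2+dz^2)`` and ``sqrt(dphi_x^2+dphi_y^2+dphi_z^2)``.
    """
    p = matrix_to_params(m_local)
    gimbal = bool(abs(abs(p[3]) - 90.0) < 1e-6)
    return DisplacementResult(
        dx=p[0],
        dy=p[1],
        dz=p[2],
        dphi_x=p[3],
        dphi_y=p[4],
        dphi_z=p[5],
        translation_magnitude=float(np.linalg.norm(p[:3])),
        rotation_magnitude=float(np.linalg.norm(p[3:])),
        object_pair=object_pair,
        gimbal_flag=gimbal,
    )
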