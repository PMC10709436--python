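"""Volume and surface-mesh data model, file I/O and trilinear sampling.

The world frame is right-handed with the axial (distoproximal) direction
along +z. A :class:`Volume` couples a scalar intensity grid to an affine
index-to-world map (``world = origin + spacing * index``); every downstream
stage (segmentation, double-contour sampling, registration) works in world
millimetres so that volumes with different origins or shapes interoperate.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
import trimesh
from scipy import ndimage

__all__ = [
    "Volume",
    "SurfaceMesh",
    "read_volume",
    "write_volume",
    "trilinear_sample",
]


@dataclass
class Volume:
    """A 3D scalar intensity grid with physical spacing and origin.

    ``data`` is indexed ``[i, j, k]`` along the world x, y, z axes, so that
    voxel ``(i, j, k)`` is centred at ``origin + spacing * (i, j, k)`` mm.
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("Volume data must be a 3D array")
        self.spacing = np.broadcast_to(np.asarray(self.spacing, dtype=float), (3,)).copy()
        self.origin = np.asarray(self.origin, dtype=float).reshape(3).copy()
        if not np.all(self.spacing > 0):
            raise ValueError("voxel spacing must be strictly positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def is_isotropic(self) -> bool:
        return bool(np.allclose(self.spacing, self.spacing[0]))

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Map world-mm points (n, 3) to continuous voxel indices."""
        return (np.atleast_2d(points) - self.origin) / self.spacing

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        return np.atleast_2d(indices) * self.spacing + self.origin

    def voxel_centers_world(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis world coordinates of voxel centres."""
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a]) for a in range(3)
        )

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.spacing.copy(), self.origin.copy())


def trilinear_sample(volume: Volume, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sample a volume at world-mm points by trilinear interpolation.

    Points outside the grid (beyond the outermost voxel centres) are flagged
    invalid and receive value 0; they are never extrapolated or clamped, so a
    caller can exclude them (the correlation metric does).

    Returns
    -------
    values, valid : (n,) float array and (n,) bool array
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    idx = volume.world_to_index(pts)
    upper = np.asarray(volume.shape, dtype=float) - 1.0
    eps = 1e-9  # voxel-index rounding slack at the outermost centres
    valid = np.all((idx >= -eps) & (idx <= upper + eps), axis=1)
    idx = np.clip(idx, 0.0, upper)
    values = ndimage.map_coordinates(
        volume.data.astype(float, copy=False), idx.T, order=1, mode="constant", cval=0.0,
        prefilter=False,
    )
    values[~valid] = 0.0
    return values, valid


@dataclass
class SurfaceMesh:
    """Triangulated object surface with per-vertex outward normals, in mm."""

    vertices: np.ndarray
    faces: np.ndarray
    normals: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        self.normals = np.asarray(self.normals, dtype=float).reshape(-1, 3)
        if len(self.normals) != len(self.vertices):
            raise ValueError("one normal per vertex required")
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ValueError("faces index invalid vertices")

    @classmethod
    def from_arrays(cls, vertices: np.ndarray, faces: np.ndarray) -> "SurfaceMesh":
        """Build a mesh computing area-weighted per-vertex normals via trimesh."""
        tm = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
        normals = np.asarray(tm.vertex_normals, dtype=float)
        return cls(vertices=np.asarray(vertices, float), faces=np.asarray(faces), normals=normals)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    @property
    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    def transformed(self, matrix: np.ndarray) -> "SurfaceMesh":
        """Apply a rigid 4x4 transform to vertices and normals."""
        R = np.asarray(matrix)[:3, :3]
        t = np.asarray(matrix)[:3, 3]
        return SurfaceMesh(self.vertices @ R.T + t, self.faces.copy(), self.normals @ R.T)

    def submesh(self, vertex_mask: np.ndarray) -> "SurfaceMesh":
        """Restrict to faces whose three vertices all satisfy the mask."""
        vertex_mask = np.asarray(vertex_mask, dtype=bool)
        keep = np.flatnonzero(vertex_mask)
        remap = -np.ones(len(self.vertices), dtype=np.int64)
        remap[keep] = np.arange(len(keep))
        face_keep = vertex_mask[self.faces].all(axis=1)
        return SurfaceMesh(self.vertices[keep], remap[self.faces[face_keep]], self.normals[keep])

    def save(self, path: str) -> None:
        """Write PLY or STL, inferred from the extension."""
        self.to_trimesh().export(path)


def read_volume(path: str) -> Volume:
    """Read a NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd) volume.

    World coordinates are preserved: spacing and origin are taken from the
    header. Oblique direction matrices are not supported (knee CT protocols
    produce axis-aligned grids); anisotropic spacing triggers a warning since
    the study design assumes isotropic voxels.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        img = sitk.ReadImage(path)
    except RuntimeError as exc:  # pragma: no cover - format detail
        raise ValueError(f"could not read volume {path!r}: {exc}") from exc
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-6):
        raise ValueError("volumes with non-identity direction matrices are not supported")
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    data = np.ascontiguousarray(arr.transpose(2, 1, 0))
    spacing = np.asarray(img.GetSpacing(), dtype=float)  # (x, y, z)
    origin = np.asarray(img.GetOrigin(), dtype=float)
    vol = Volume(data, spacing, origin)
    if not vol.is_isotropic:
        warnings.warn(f"volume {path!r} has anisotropic spacing {spacing}", stacklevel=2)
    return vol


def write_volume(volume: Volume, path: str) -> None:
    """Write NIfTI or MetaImage; the format follows the file extension."""
    img = sitk.GetImageFromArray(np.ascontiguousarray(volume.data.transpose(2, 1, 0)))
    img.SetSpacing(tuple(volume.spacing))
    img.SetOrigin(tuple(volume.origin))
    sitk.WriteImage(img, path)
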