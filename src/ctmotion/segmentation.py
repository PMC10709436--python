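"""Object extraction from the valgus scan and the double-contour feature.

The implant and the tibial cortex are segmented by threshold-connected
region growing (approx. 1600 intensity units for cortex, 3500 for the
implant), refined with a Laplacian level-set evolution that pulls the
boundary onto intensity edges, and meshed with marching cubes. The mesh
vertices, offset by +/-0.3 mm along the surface normals and tagged with
the gray values interpolated from the segmentation image, form the
double contour that drives registration. The tibia mesh is clipped into
proximal and distal end segments at a fraction (default 20%) of the bone
length measured along its principal axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk
from scipy import ndimage
from skimage import measure

from .imaging import SurfaceMesh, Volume, trilinear_sample

__all__ = [
    "DoubleContour",
    "region_grow",
    "levelset_refine",
    "extract_mesh",
    "build_double_contour",
    "clip_segments",
    "find_seed",
    "dice",
]

CONTOUR_OFFSET_MM = 0.3

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    return 1.0 if denom == 0 else 2.0 * np.logical_and(a, b).sum() / denom


def find_seed(volume: Volume, threshold: float) -> tuple[int, int, int]:
    """Index of the brightest voxel at or above ``threshold``."""
    idx = np.unravel_index(int(np.argmax(volume.data)), volume.shape)
    if volume.data[idx] < threshold:
        raise ValueError("no voxel reaches the requested threshold")
    return tuple(int(i) for i in idx)


def region_grow(
    volume: Volume,
    seed_index: tuple[int, int, int],
    threshold: float,
    exclude: np.ndarray | None = None,
) -> np.ndarray:
    """Threshold-connected region growing.

    Returns the 26-connected component of voxels with intensity >=
    ``threshold`` that contains ``seed_index``. ``exclude`` removes voxels
    (e.g. an already-segmented implant) before connectivity is evaluated,
    which separates the cortex from the implant where they touch.
    """
    seed_index = tuple(int(i) for i in seed_index)
    if volume.data[seed_index] < threshold:
        raise ValueError(
            f"seed intensity {volume.data[seed_index]:.1f} is below the threshold {threshold:.1f}"
        )
    mask = volume.data >= threshold
    if exclude is not None:
        mask &= ~np.asarray(exclude, bool)
        if not mask[seed_index]:
            raise ValueError("seed voxel is excluded")
    labels, _ = ndimage.label(mask, structure=_STRUCT26)
    return labels == labels[seed_index]


def levelset_refine(
    volume: Volume,
    mask: np.ndarray,
    iterations: int = 50,
    curvature_weight: float = 0.2,
    min_dice: float = 0.8,
) -> np.ndarray:
    """Laplacian level-set refinement of a binary mask.

    The mask boundary, initialised as a signed distance map, evolves toward
    zero-crossings of the image Laplacian (intensity edges) under curvature
    regularisation. The output must overlap the input (Dice > ``min_dice``)
    — a refinement should move the boundary by voxels, not re-segment.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("input mask is empty")
    if iterations == 0:
        return mask.copy()

    def to_sitk(arr, dtype):
        img = sitk.GetImageFromArray(np.ascontiguousarray(arr.transpose(2, 1, 0)).astype(dtype))
        img.SetSpacing(tuple(volume.spacing))
        return img

    init = sitk.SignedMaurerDistanceMap(
        to_sitk(mask, np.uint8),
        insideIsPositive=False,
        squaredDistance=False,
        useImageSpacing=True,
    )
    feature = to_sitk(volume.data, np.float32)
    ls = sitk.LaplacianSegmentationLevelSetImageFilter()
    ls.SetNumberOfIterations(int(iterations))
    ls.SetCurvatureScaling(float(curvature_weight))
    ls.SetPropagationScaling(1.0)
    # with an inside-negative initial distance map, ITK's default expansion
    # direction shrinks the front; reverse it so the front seeks the edge
    ls.SetReverseExpansionDirection(True)
    ls.SetMaximumRMSError(1e-4)
    out = ls.Execute(init, feature)
    refined = sitk.GetArrayFromImage(out).transpose(2, 1, 0) <= 0.0
    if not refined.any():
        raise ValueError("level-set refinement collapsed to the empty set")
    d = dice(refined, mask)
    if d < min_dice:
        raise ValueError(f"refined mask departs too far from the input (Dice {d:.3f} < {min_dice})")
    return refined


def extract_mesh(
    mask: np.ndarray,
    spacing: np.ndarray,
    origin: np.ndarray | None = None,
    smoothing_sigma: float = 0.8,
    volume: Volume | None = None,
) -> SurfaceMesh:
    """Marching-cubes surface of a binary mask, in world mm.

    The mask is Gaussian-smoothed (``smoothing_sigma`` in voxels) before
    meshing so the iso-surface and its normals are sub-voxel smooth rather
    than staircase; tiny masks (< 27 voxels) are meshed unsmoothed. Vertex
    normals are area-weighted face normals, oriented outward (checked by
    probing the mask along the normals and flipping if inverted).
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("cannot mesh an empty mask")
    spacing = np.broadcast_to(np.asarray(spacing, float), (3,))
    field = mask.astype(np.float32)
    if smoothing_sigma > 0 and mask.sum() >= 27:
        field = ndimage.gaussian_filter(field, smoothing_sigma)
        # keep the 0.5 level inside the smoothed support
        level = min(0.5, float(field.max()) / 2.0)
    else:
        level = 0.5
    field = np.pad(field, 1, mode="constant")
    verts, faces, _, _ = measure.marching_cubes(field, level=level, spacing=tuple(spacing))
    verts = verts - spacing  # undo padding shift
    if origin is not None:
        verts = verts + np.asarray(origin, float)
    mesh = SurfaceMesh.from_arrays(verts, faces)
    # orient outward: probing outward along the normal must leave the mask
    probe_in = (mesh.vertices - 0.75 * spacing * mesh.normals)
    probe_out = (mesh.vertices + 0.75 * spacing * mesh.normals)
    ref = Volume(mask.astype(np.float32), spacing, origin if origin is not None else np.zeros(3))
    vin, _ = trilinear_sample(ref, probe_in)
    vout, _ = trilinear_sample(ref, probe_out)
    if vout.mean() > vin.mean():
        mesh = SurfaceMesh(mesh.vertices, mesh.faces[:, ::-1], -mesh.normals)
    return mesh


@dataclass
class DoubleContour:
    """Paired offset point sets with reference gray values.

    ``outer_points`` and ``inner_points`` sit at +/-0.3 mm from the mesh
    vertices along the outward normals; ``reference_grays`` holds the
    segmentation-image intensities at [outer; inner] (the registration
    feature), so the sample count is twice the vertex count.
    """

    base_points: np.ndarray
    outer_points: np.ndarray
    inner_points: np.ndarray
    reference_grays: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.base_points)
        if not (len(self.outer_points) == len(self.inner_points) == n):
            raise ValueError("contour point sets must have equal length")
        if len(self.reference_grays) != 2 * n:
            raise ValueError("reference_grays must hold outer then inner values (2n)")
        if not np.all(np.isfinite(self.reference_grays)):
            raise ValueError("reference grays must be finite")

    @property
    def sample_points(self) -> np.ndarray:
        return np.concatenate([self.outer_points, self.inner_points])

    @property
    def centroid(self) -> np.ndarray:
        return self.base_points.mean(axis=0)


def build_double_contour(
    volume: Volume,
    mesh: SurfaceMesh,
    offset: float = CONTOUR_OFFSET_MM,
    max_points: int | None = None,
    max_invalid_fraction: float = 0.05,
) -> DoubleContour:
    """Sample the segmentation image at +/-``offset`` mm along the normals.

    ``max_points`` subsamples the mesh vertices with a deterministic stride
    (registration cost scales with the point count; the correlation metric
    needs thousands, not hundreds of thousands, of samples). More than
    ``max_invalid_fraction`` of points outside the volume is an error: the
    mesh does not belong to this image.
    """
    verts, normals = mesh.vertices, mesh.normals
    if max_points is not None and len(verts) > max_points:
        stride = int(np.ceil(len(verts) / max_points))
        verts, normals = verts[::stride], normals[::stride]
    outer = verts + offset * normals
    inner = verts - offset * normals
    grays, valid = trilinear_sample(volume, np.concatenate([outer, inner]))
    bad = 1.0 - valid.mean()
    if bad > max_invalid_fraction:
        raise ValueError(
            f"{bad:.1%} of double-contour points fall outside the volume "
            f"(allowed {max_invalid_fraction:.1%})"
        )
    grays = grays.copy()
    if (~valid).any():  # rare boundary points: neutral fill, excluded later by the metric
        grays[~valid] = grays[valid].mean()
    return DoubleContour(verts.copy(), outer, inner, grays)


def clip_segments(
    mesh: SurfaceMesh,
    fraction: float = 0.20,
    proximal_reference: np.ndarray | None = None,
    implant_mesh: SurfaceMesh | None = None,
) -> tuple[SurfaceMesh, SurfaceMesh, SurfaceMesh]:
    """Clip the tibia mesh into (proximal, distal, whole) pieces.

    The long axis is the principal axis of the vertex cloud, oriented
    proximally (toward the implant if one is given, else toward world +z).
    Length runs from the implant-plateau level (``proximal_reference``, or
    the most proximal vertex) to the most distal vertex; the proximal and
    distal segments are the end portions of ``fraction`` of that length,
    cut by planes perpendicular to the axis. ``whole`` is everything below
    the plateau level.
    """
    if not (0.0 < fraction <= 0.5):
        raise ValueError("fraction must be in (0, 0.5]")
    v = mesh.vertices
    c = v.mean(axis=0)
    cov = (v - c).T @ (v - c) / len(v)
    w, vec = np.linalg.eigh(cov)
    if w[2] < 4.0 * w[1]:
        raise ValueError("mesh is not elongated; cannot identify a long axis")
    axis = vec[:, 2]
    if implant_mesh is not None:
        orient = implant_mesh.centroid - c
    else:
        orient = np.array([0.0, 0.0, 1.0])
    if np.dot(axis, orient) < 0:
        axis = -axis
    s = v @ axis
    s_min = s.min()
    if proximal_reference is not None:
        s_top = float(np.asarray(proximal_reference, float) @ axis)
    else:
        s_top = s.max()
    length = s_top - s_min
    if length <= 0:
        raise ValueError("degenerate clip: proximal reference below the distal end")
    prox = mesh.submesh((s >= s_top - fraction * length) & (s <= s_top))
    dist = mesh.submesh(s <= s_min + fraction * length)
    whole = mesh.submesh(s <= s_top)
    for name, seg in (("proximal", prox), ("distal", dist)):
        if len(seg.vertices) == 0:
            raise ValueError(f"{name} segment is empty")
    return prox, dist, whole
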