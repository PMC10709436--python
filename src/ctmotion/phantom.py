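"""Synthetic tibia + implant CT phantom with exactly known ground truth.

The phantom emulates the imaging situation of load-CT implant-migration
measurement: a long tubular bone with a bright cortical shell and darker
trabecular interior, a very bright tibial implant (elliptical plateau, ML
wider than AP, plus an intramedullary stem), an optional cement mantle,
coronal-plane bending of the bone between the valgus and varus load
states, optional rigid implant micro-motion relative to the proximal bone
(a loose implant), additive Gaussian noise, and arbitrary whole-specimen
repositioning between scans.

Geometry is analytic (implicit solids), so every generated volume comes
with exact surface meshes and exact ground-truth relative displacement
matrices. The bend is a rotation-field warp about a y-parallel (coronal)
axis: the rotation angle ramps linearly with axial position between the
distal and proximal 20% of the bone and saturates over both end segments,
so the two end segments move exactly rigidly while the shaft deforms.
The cortical cross-section carries a mild three-fold (triangular) radial
modulation like a real tibial shaft, the shaft centreline bows laterally,
and the implant stem is offset from the plateau centre — the asymmetries
of real anatomy that make each object's pose (including roll about the
long axis) uniquely observable by intensity registration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .imaging import SurfaceMesh, Volume
from .registration import RigidTransform, params_to_matrix

__all__ = [
    "PhantomSpec",
    "PhantomGeometry",
    "LoadPairGroundTruth",
    "build_geometry",
    "apply_bending",
    "voxelize",
    "generate_load_pair",
    "generate_repeat_scans",
    "sample_pose",
]

# voxel class labels
BACKGROUND, TRABECULAR, CORTEX, CEMENT, IMPLANT = 0, 1, 2, 3, 4

MAX_BEND_DEG = 10.0  # small-deformation regime guard


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensity and sampling parameters of the digital phantom.

    Intensities are in scanner units chosen so that the segmentation
    thresholds of the real pipeline (approx. 1600 for cortex, 3500 for the
    implant) apply unchanged. The default 0.45 mm isotropic spacing matches
    the scan protocol the method targets; desk-scale runs use 0.9 mm.
    """

    bone_length: float = 260.0  # mm, scanned tibia extent
    shaft_radius: float = 12.0  # mm, mid-shaft outer radius
    proximal_radius: float = 34.0  # mm, metaphyseal flare outer radius
    flare_start_fraction: float = 0.75  # of bone length, where the flare begins
    distal_radius: float = 17.0  # mm, distal (ankle-ward) flare outer radius
    distal_flare_fraction: float = 0.12  # of bone length, distal flare extent
    shaft_bow: float = 4.0  # mm lateral bow of the shaft centreline (mid-length)
    stem_offset: tuple[float, float] = (2.0, 3.0)  # mm, stem centre w.r.t. plateau centre
    triangularity: float = 0.07  # 3-fold radial modulation of the cortex
    cortical_thickness: float = 4.5  # mm
    intensity_background: float = 200.0
    intensity_trabecular: float = 600.0
    intensity_cortex: float = 1900.0
    intensity_cement: float = 2400.0
    intensity_implant: float = 3800.0
    plateau_halfwidth_ml: float = 33.0  # mm, x (medial-lateral, the long axis)
    plateau_halfwidth_ap: float = 22.0  # mm, y (anterior-posterior)
    plateau_thickness: float = 4.0  # mm
    stem_length: float = 40.0  # mm
    stem_radius: float = 6.5  # mm
    cement_thickness: float = 0.0  # mm; 0 disables the cement mantle
    voxel_spacing: float = 0.45  # mm, isotropic
    psf_sigma_mm: float = 0.45  # scanner point-spread function (Gaussian sigma)
    noise_sd: float = 100.0  # additive Gaussian noise, intensity units
    supersample: int = 3  # per-axis anti-aliasing factor at class boundaries
    fov_margin: float = 12.0  # mm of background around the posed specimen
    max_voxels: int = 60_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (
            self.intensity_implant
            > self.intensity_cortex
            > self.intensity_trabecular
            > self.intensity_background
        ):
            raise ValueError("intensities must satisfy implant > cortex > trabecular > background")
        if self.cement_thickness and not (
            self.intensity_cortex < self.intensity_cement < self.intensity_implant
        ):
            raise ValueError("cement intensity must lie between cortex and implant")
        if self.voxel_spacing <= 0:
            raise ValueError("voxel_spacing must be positive")
        for name in (
            "bone_length",
            "shaft_radius",
            "proximal_radius",
            "cortical_thickness",
            "plateau_halfwidth_ml",
            "plateau_halfwidth_ap",
            "plateau_thickness",
            "stem_length",
            "stem_radius",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.plateau_halfwidth_ml <= self.plateau_halfwidth_ap:
            raise ValueError("plateau ML halfwidth must exceed AP halfwidth")
        if self.cortical_thickness >= self.shaft_radius:
            raise ValueError("cortical_thickness must be smaller than the shaft radius")

    @property
    def plateau_center(self) -> np.ndarray:
        """Centroid of the implant plateau top surface in canonical coordinates."""
        return np.array([0.0, 0.0, self.bone_length + self.plateau_thickness])

    @property
    def intensity_lut(self) -> np.ndarray:
        return np.array(
            [
                self.intensity_background,
                self.intensity_trabecular,
                self.intensity_cortex,
                self.intensity_cement,
                self.intensity_implant,
            ]
        )


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


@dataclass(frozen=True)
class PhantomGeometry:
    """Analytic phantom in the specimen frame (bent, implant posed).

    The canonical frame has the bone axis along z from 0 (distal end) to
    ``bone_length`` (tibial cut), the implant plateau on top, lateral = +x
    (a right leg). ``bend_angle`` is the saturated rotation reached over the
    proximal end segment; ``implant_motion`` is a rigid transform of the
    implant relative to the proximal bone (identity = fixed implant).
    """

    spec: PhantomSpec
    bend_angle: float = 0.0  # degrees, about a y-parallel axis
    bend_axis_origin: np.ndarray = field(default=None)  # type: ignore[assignment]
    implant_motion: RigidTransform = field(default_factory=RigidTransform.identity)
    ramp_fractions: tuple[float, float] = (0.20, 0.80)

    def __post_init__(self) -> None:
        if abs(self.bend_angle) > MAX_BEND_DEG:
            raise ValueError(f"|bend_angle| > {MAX_BEND_DEG} deg is outside the small-deformation regime")
        origin = self.bend_axis_origin
        if origin is None:
            origin = np.array([0.0, 0.0, self.ramp_fractions[0] * self.spec.bone_length])
        object.__setattr__(self, "bend_axis_origin", np.asarray(origin, float).reshape(3))

    # ----- canonical implicit solids ---------------------------------
    def _outer_radius(self, z: np.ndarray, phi: np.ndarray) -> np.ndarray:
        s = self.spec
        zf = s.flare_start_fraction * s.bone_length
        zd = s.distal_flare_fraction * s.bone_length
        base = (
            s.shaft_radius
            + (s.proximal_radius - s.shaft_radius) * _smoothstep((z - zf) / (s.bone_length - zf))
            + (s.distal_radius - s.shaft_radius) * _smoothstep((zd - z) / zd)
        )
        return base * (1.0 + s.triangularity * np.cos(3.0 * phi))

    def _bow(self, z: np.ndarray) -> np.ndarray:
        """Lateral (x) offset of the bowed shaft centreline; zero at both ends."""
        s = self.spec
        return s.shaft_bow * np.sin(np.pi * np.clip(z, 0.0, s.bone_length) / s.bone_length)

    def _bone_class(self, pts: np.ndarray) -> np.ndarray:
        """Canonical-frame bone classification (no implant)."""
        s = self.spec
        x, y, z = pts[:, 0] - self._bow(pts[:, 2]), pts[:, 1], pts[:, 2]
        lab = np.zeros(len(pts), dtype=np.uint8)
        inside_z = (z >= 0.0) & (z <= s.bone_length)
        r = np.hypot(x, y)
        phi = np.arctan2(y, x)
        r_out = self._outer_radius(z, phi)
        cortex = inside_z & (r <= r_out) & (r > r_out - s.cortical_thickness)
        trab = inside_z & (r <= r_out - s.cortical_thickness)
        lab[trab] = TRABECULAR
        lab[cortex] = CORTEX
        return lab

    def _in_implant(self, pts: np.ndarray) -> np.ndarray:
        """Canonical-frame implant solid (plateau slab + stem cylinder)."""
        s = self.spec
        x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
        in_plateau = (
            (z >= s.bone_length)
            & (z <= s.bone_length + s.plateau_thickness)
            & ((x / s.plateau_halfwidth_ml) ** 2 + (y / s.plateau_halfwidth_ap) ** 2 <= 1.0)
        )
        ox, oy = s.stem_offset
        in_stem = (
            (z >= s.bone_length - s.stem_length)
            & (z < s.bone_length)
            & (np.hypot(x - ox, y - oy) <= s.stem_radius)
        )
        return in_plateau | in_stem

    def _in_cement(self, pts: np.ndarray) -> np.ndarray:
        s = self.spec
        if s.cement_thickness <= 0:
            return np.zeros(len(pts), dtype=bool)
        x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
        ox, oy = s.stem_offset
        sheath = (
            (z >= s.bone_length - s.stem_length)
            & (z < s.bone_length)
            & (np.hypot(x - ox, y - oy) <= s.stem_radius + s.cement_thickness)
        )
        return sheath & ~self._in_implant(pts)

    # ----- bend warp -------------------------------------------------
    def _ramp_angle(self, z: np.ndarray) -> np.ndarray:
        """Per-point bend angle (degrees) as a function of canonical z."""
        z0 = self.ramp_fractions[0] * self.spec.bone_length
        z1 = self.ramp_fractions[1] * self.spec.bone_length
        return self.bend_angle * np.clip((np.asarray(z, float) - z0) / (z1 - z0), 0.0, 1.0)

    def _rotate_y_about(self, pts: np.ndarray, ang_deg: np.ndarray) -> np.ndarray:
        c = self.bend_axis_origin
        a = np.deg2rad(ang_deg)
        ca, sa = np.cos(a), np.sin(a)
        dx, dz = pts[:, 0] - c[0], pts[:, 2] - c[2]
        out = pts.copy()
        out[:, 0] = c[0] + ca * dx + sa * dz
        out[:, 2] = c[2] - sa * dx + ca * dz
        return out

    def bend_points(self, pts: np.ndarray) -> np.ndarray:
        """Forward warp: canonical -> bent specimen frame."""
        pts = np.atleast_2d(np.asarray(pts, float))
        if self.bend_angle == 0.0:
            return pts.copy()
        return self._rotate_y_about(pts, self._ramp_angle(pts[:, 2]))

    def unbend_points(self, pts: np.ndarray, iterations: int = 8) -> np.ndarray:
        """Inverse warp by fixed-point iteration on the canonical z."""
        pts = np.atleast_2d(np.asarray(pts, float))
        if self.bend_angle == 0.0:
            return pts.copy()
        z = pts[:, 2].copy()
        q = pts
        for _ in range(iterations):
            q = self._rotate_y_about(pts, -self._ramp_angle(z))
            z = q[:, 2]
        return q

    @property
    def saturated_rotation(self) -> RigidTransform:
        """Rigid motion of the proximal end segment (and a fixed implant)."""
        return RigidTransform.rotation_about([0.0, 1.0, 0.0], self.bend_angle, self.bend_axis_origin)

    @property
    def implant_pose(self) -> RigidTransform:
        """Canonical -> specimen-frame pose of the implant."""
        return self.saturated_rotation @ self.implant_motion

    # ----- classification --------------------------------------------
    def classify(self, pts: np.ndarray) -> np.ndarray:
        """Class label for specimen-frame points.

        Overlaps resolve by priority implant > cement > cortex > trabecular;
        the cavity left behind by a displaced (loose) implant is background.
        """
        pts = np.atleast_2d(np.asarray(pts, float))
        u = self.implant_pose.inverse().apply(pts)
        implant = self._in_implant(u)
        q0 = self.unbend_points(pts)
        lab = self._bone_class(q0)
        cavity = self._in_implant(q0)
        lab[cavity] = BACKGROUND
        cement = self._in_cement(self.saturated_rotation.inverse().apply(pts))
        lab[cement] = CEMENT
        lab[implant] = IMPLANT
        return lab

    def intensities(self, pts: np.ndarray) -> np.ndarray:
        return self.spec.intensity_lut[self.classify(pts)]

    # ----- analytic meshes -------------------------------------------
    def _canonical_bone_mesh(self, n_phi: int = 96, dz: float = 1.0):
        """Structured cortex-shell mesh: outer + inner walls and end rings.

        Returns the mesh and the canonical z of every vertex (used for
        segment masks).
        """
        s = self.spec
        nz = max(3, int(np.ceil(s.bone_length / dz)) + 1)
        z = np.linspace(0.0, s.bone_length, nz)
        phi = np.linspace(0.0, 2 * np.pi, n_phi, endpoint=False)
        P, Z = np.meshgrid(phi, z, indexing="ij")  # (n_phi, nz)
        r_out = self._outer_radius(Z, P)
        r_in = r_out - s.cortical_thickness

        def wall(r):
            return np.stack(
                [r * np.cos(P) + self._bow(Z), r * np.sin(P), Z], axis=-1
            ).reshape(-1, 3)

        def wall_faces(offset):
            faces = []
            for i in range(n_phi):
                i2 = (i + 1) % n_phi
                for j in range(nz - 1):
                    a = offset + i * nz + j
                    b = offset + i2 * nz + j
                    faces.append([a, b, a + 1])
                    faces.append([b, b + 1, a + 1])
            return faces

        verts = [wall(r_out), wall(r_in)]
        faces = wall_faces(0) + wall_faces(n_phi * nz)
        n_wall = n_phi * nz
        # end rings joining outer and inner walls at z = 0 and z = L
        for j in (0, nz - 1):
            for i in range(n_phi):
                i2 = (i + 1) % n_phi
                a_out, b_out = i * nz + j, i2 * nz + j
                a_in, b_in = n_wall + i * nz + j, n_wall + i2 * nz + j
                faces.append([a_out, b_out, a_in])
                faces.append([b_out, b_in, a_in])
        vertices = np.concatenate(verts, axis=0)
        zcanon = np.concatenate([Z.reshape(-1), Z.reshape(-1)])
        return vertices, np.asarray(faces, dtype=np.int64), zcanon

    def _canonical_implant_mesh(self, n_phi: int = 96, n_rad: int = 12):
        s = self.spec
        a, b = s.plateau_halfwidth_ml, s.plateau_halfwidth_ap
        zb, zt = s.bone_length, s.bone_length + s.plateau_thickness
        phi = np.linspace(0.0, 2 * np.pi, n_phi, endpoint=False)
        ex, ey = a * np.cos(phi), b * np.sin(phi)
        verts: list[np.ndarray] = []
        faces: list[list[int]] = []

        def add_disk(cx, cy, z, rx, ry, flip):
            """Elliptical disk sampled on concentric rings (dense interior)."""
            start = sum(len(v) for v in verts)
            rings = []
            for k in range(n_rad, 0, -1):
                f_k = k / n_rad
                rings.append(
                    np.stack(
                        [cx + f_k * rx * np.cos(phi), cy + f_k * ry * np.sin(phi), np.full(n_phi, z)],
                        axis=1,
                    )
                )
            center = np.array([[cx, cy, z]])
            verts.append(np.concatenate(rings + [center]))
            for k in range(n_rad - 1):
                o0, o1 = start + k * n_phi, start + (k + 1) * n_phi
                for i in range(n_phi):
                    i2 = (i + 1) % n_phi
                    for tri in ([o0 + i, o0 + i2, o1 + i], [o0 + i2, o1 + i2, o1 + i]):
                        faces.append(tri[::-1] if flip else tri)
            o_last = start + (n_rad - 1) * n_phi
            c_idx = start + n_rad * n_phi
            for i in range(n_phi):
                tri = [o_last + i, o_last + (i + 1) % n_phi, c_idx]
                faces.append(tri[::-1] if flip else tri)

        def add_tube(xy_ring, z0, z1):
            start = sum(len(v) for v in verts)
            n_z = max(2, int(np.ceil(z1 - z0)) + 1)
            levels = np.linspace(z0, z1, n_z)
            verts.append(
                np.concatenate(
                    [np.column_stack([xy_ring[0], xy_ring[1], np.full(n_phi, z)]) for z in levels]
                )
            )
            for j in range(n_z - 1):
                o0, o1 = start + j * n_phi, start + (j + 1) * n_phi
                for i in range(n_phi):
                    i2 = (i + 1) % n_phi
                    faces.append([o0 + i, o0 + i2, o1 + i])
                    faces.append([o0 + i2, o1 + i2, o1 + i])

        add_tube((ex, ey), zb, zt)  # plateau side wall
        add_disk(0, 0, zt, a, b, flip=False)  # plateau top
        add_disk(0, 0, zb, a, b, flip=True)  # plateau underside
        r = s.stem_radius
        ox, oy = s.stem_offset
        add_tube((ox + r * np.cos(phi), oy + r * np.sin(phi)), zb - s.stem_length, zb)  # stem wall
        add_disk(ox, oy, zb - s.stem_length, r, r, flip=True)  # stem tip
        return np.concatenate(verts), np.asarray(faces, dtype=np.int64)

    def analytic_meshes(self, clip_fraction: float = 0.20) -> dict[str, SurfaceMesh]:
        """Exact surface meshes in the specimen frame.

        Keys: ``implant``, ``bone`` (whole cortex shell), ``bone_proximal``
        and ``bone_distal`` (end segments of ``clip_fraction`` of the bone
        length).
        """
        s = self.spec
        bv, bf, zc = self._canonical_bone_mesh()
        bone_bent = self.bend_points(bv)
        bone = SurfaceMesh.from_arrays(bone_bent, bf)
        prox = bone.submesh(zc >= (1.0 - clip_fraction) * s.bone_length)
        dist = bone.submesh(zc <= clip_fraction * s.bone_length)
        iv, if_ = self._canonical_implant_mesh()
        implant = SurfaceMesh.from_arrays(self.implant_pose.apply(iv), if_)
        return {"implant": implant, "bone": bone, "bone_proximal": prox, "bone_distal": dist}


def build_geometry(spec: PhantomSpec) -> PhantomGeometry:
    """Undeformed phantom with a fixed implant."""
    return PhantomGeometry(spec=spec)


def apply_bending(
    geometry: PhantomGeometry,
    bend_angle: float,
    bend_axis_origin: Sequence[float] | None = None,
) -> PhantomGeometry:
    """Bend the bone by ``bend_angle`` degrees about a y-parallel coronal axis.

    The implant rides rigidly with the proximal bone segment; any loose
    motion is supplied separately via ``implant_motion``.
    """
    return replace(
        geometry,
        bend_angle=float(bend_angle),
        bend_axis_origin=None if bend_axis_origin is None else np.asarray(bend_axis_origin, float),
    )


def _boundary_mask(labels: np.ndarray) -> np.ndarray:
    """Voxels with a 6-neighbour of a different class."""
    b = np.zeros(labels.shape, dtype=bool)
    for ax in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[ax] = slice(0, -1)
        sl_b[ax] = slice(1, None)
        diff = labels[tuple(sl_a)] != labels[tuple(sl_b)]
        b[tuple(sl_a)] |= diff
        b[tuple(sl_b)] |= diff
    return b


def voxelize(
    geometry: PhantomGeometry,
    spec: PhantomSpec | None = None,
    pose: RigidTransform | None = None,
    noise_seed: int | None = None,
    chunk: int = 1_000_000,
) -> Volume:
    """Render the phantom into a CT-like volume.

    The grid auto-fits the posed specimen (analytic mesh bounds plus
    ``fov_margin``), with the origin snapped to the spacing so repeated
    renderings of identical geometry/pose are bit-identical. Voxels at class
    boundaries are supersampled ``supersample``^3 times for partial-volume
    realism; the scanner point-spread function is emulated by a Gaussian
    blur of ``psf_sigma_mm``; Gaussian noise of ``noise_sd`` is added with
    ``noise_seed`` (default: the spec seed).
    """
    spec = spec or geometry.spec
    pose = pose or RigidTransform.identity()
    h = spec.voxel_spacing

    meshes = geometry.analytic_meshes()
    all_v = np.concatenate([meshes["bone"].vertices, meshes["implant"].vertices])
    all_v = pose.apply(all_v)
    lo = np.floor((all_v.min(axis=0) - spec.fov_margin) / h) * h
    hi = all_v.max(axis=0) + spec.fov_margin
    shape = np.ceil((hi - lo) / h).astype(int) + 1
    n_vox = int(np.prod(shape))
    if n_vox > spec.max_voxels:
        raise ValueError(f"volume of {n_vox} voxels exceeds the budget of {spec.max_voxels}")

    inv = pose.inverse()
    labels = np.empty(shape, dtype=np.uint8)
    flat = labels.reshape(-1)
    for start in range(0, n_vox, chunk):
        stop = min(start + chunk, n_vox)
        ii, jj, kk = np.unravel_index(np.arange(start, stop), shape)
        pts = np.column_stack([ii, jj, kk]) * h + lo
        flat[start:stop] = geometry.classify(inv.apply(pts))

    data = spec.intensity_lut[labels].astype(np.float32)

    ss = max(1, int(spec.supersample))
    if ss > 1:
        border = _boundary_mask(labels)
        bidx = np.argwhere(border)
        if len(bidx):
            offs = (np.arange(ss) + 0.5) / ss - 0.5
            ox, oy, oz = np.meshgrid(offs, offs, offs, indexing="ij")
            offsets = np.column_stack([ox.ravel(), oy.ravel(), oz.ravel()]) * h
            centers = bidx * h + lo
            acc = np.zeros(len(bidx), dtype=np.float64)
            for off in offsets:
                acc += geometry.intensities(inv.apply(centers + off))
            data[border] = (acc / len(offsets)).astype(np.float32)

    if spec.psf_sigma_mm > 0:
        data = ndimage.gaussian_filter(data, spec.psf_sigma_mm / h)

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed if noise_seed is None else noise_seed)
        data = data + rng.normal(0.0, spec.noise_sd, size=data.shape).astype(np.float32)

    return Volume(data, spacing=np.full(3, h), origin=lo)


def sample_pose(
    rng: np.random.Generator,
    center: np.ndarray,
    max_translation: float = 20.0,
    max_rotation: float = 10.0,
) -> RigidTransform:
    """Random specimen repositioning: U(-t, t) mm translations and
    U(-r, r) deg rotations about each axis, rotating about ``center``."""
    p = np.concatenate(
        [
            rng.uniform(-max_translation, max_translation, 3),
            rng.uniform(-max_rotation, max_rotation, 3),
        ]
    )
    base = params_to_matrix(p)
    center = np.asarray(center, float)
    R = base.rotation
    return RigidTransform.from_rotation_translation(R, base.translation_vector + center - R @ center)


@dataclass
class LoadPairGroundTruth:
    """Exact ground truth for one valgus/varus pair.

    ``true_M_prox_distal`` and ``true_M_implant_prox`` are the relative
    displacement matrices the pipeline's Eq.-style algebra should recover,
    expressed in the valgus (segmentation) image frame; the ``*_local``
    variants are the same displacements in the canonical implant coordinate
    system and therefore depend only on the bend and the implant motion,
    never on the specimen poses. ``true_M_implant_whole`` exists only when
    the bone does not deform (bend = 0), since a deforming reference has no
    rigid ground truth — that is the measurement artefact the method is
    designed to expose.
    """

    global_pose_valgus: RigidTransform
    global_pose_varus: RigidTransform
    bend_angle: float  # per-state, degrees; net relative bend = 2 * bend_angle
    bend_axis_origin: np.ndarray
    implant_motion: RigidTransform
    true_M_prox_distal: RigidTransform
    true_M_implant_prox: RigidTransform
    true_M_implant_whole: RigidTransform | None
    true_M_prox_distal_local: RigidTransform
    true_M_implant_prox_local: RigidTransform
    canonical_cs: RigidTransform

    def to_json(self) -> str:
        def enc(v):
            if isinstance(v, RigidTransform):
                return v.to_dict()
            if isinstance(v, np.ndarray):
                return v.tolist()
            return v

        return json.dumps({k: enc(v) for k, v in self.__dict__.items()}, indent=2)

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())


def generate_load_pair(
    spec: PhantomSpec,
    bend_angle: float,
    implant_motion: RigidTransform | None = None,
    global_poses: tuple[RigidTransform, RigidTransform] | None = None,
    pose_jitter: tuple[float, float] = (20.0, 10.0),
) -> tuple[Volume, Volume, LoadPairGroundTruth]:
    """Render a valgus/varus volume pair with exact ground truth.

    The valgus state bends by ``+bend_angle`` and the varus state by
    ``-bend_angle`` (net relative bend ``2 * bend_angle`` degrees); the
    implant rides with the proximal bone, with ``implant_motion`` applied
    additionally in the varus state relative to the proximal bone (identity
    = fixed implant). Each state is posed by its global transform (drawn
    from ``pose_jitter`` if not supplied) and rendered with independent
    noise.
    """
    implant_motion = implant_motion or RigidTransform.identity()
    rng = np.random.default_rng(spec.seed)
    noise_seeds = rng.integers(0, 2**31 - 1, size=2)
    geom_valgus = PhantomGeometry(spec=spec, bend_angle=+bend_angle)
    geom_varus = PhantomGeometry(spec=spec, bend_angle=-bend_angle, implant_motion=implant_motion)
    if global_poses is None:
        center = np.array([0.0, 0.0, spec.bone_length / 2.0])
        global_poses = (
            sample_pose(rng, center, *pose_jitter),
            sample_pose(rng, center, *pose_jitter),
        )
    gv, gw = global_poses
    vol_valgus = voxelize(geom_valgus, spec, pose=gv, noise_seed=int(noise_seeds[0]))
    vol_varus = voxelize(geom_varus, spec, pose=gw, noise_seed=int(noise_seeds[1]))

    r_v = geom_valgus.saturated_rotation
    r_net = RigidTransform.rotation_about(
        [0.0, 1.0, 0.0], -2.0 * bend_angle, geom_valgus.bend_axis_origin
    )
    cs0 = RigidTransform.from_rotation_translation(np.eye(3), spec.plateau_center)
    m_prox_distal = gv @ r_net @ gv.inverse()
    m_implant_prox = gv @ (r_v @ implant_motion @ r_v.inverse()) @ gv.inverse()
    truth = LoadPairGroundTruth(
        global_pose_valgus=gv,
        global_pose_varus=gw,
        bend_angle=float(bend_angle),
        bend_axis_origin=geom_valgus.bend_axis_origin,
        implant_motion=implant_motion,
        true_M_prox_distal=m_prox_distal,
        true_M_implant_prox=m_implant_prox,
        true_M_implant_whole=(m_implant_prox if bend_angle == 0.0 else None),
        true_M_prox_distal_local=cs0.inverse() @ r_net @ cs0,
        true_M_implant_prox_local=cs0.inverse() @ implant_motion @ cs0,
        canonical_cs=cs0,
    )
    return vol_valgus, vol_varus, truth


def generate_repeat_scans(
    spec: PhantomSpec,
    n: int,
    pose_jitter: tuple[float, float] = (20.0, 10.0),
    seed: int | None = None,
) -> tuple[list[Volume], list[RigidTransform]]:
    """Render ``n`` repeat scans of the identical undeformed phantom.

    Nothing moves internally between scans (no bend, fixed implant), so the
    true relative displacement between any two scans is the identity for
    every object pair; only the global pose and the noise differ.
    """
    if n < 2:
        raise ValueError("need at least 2 repeat scans")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    geom = build_geometry(spec)
    center = np.array([0.0, 0.0, spec.bone_length / 2.0])
    volumes, poses = [], []
    for _ in range(n):
        pose = (
            sample_pose(rng, center, *pose_jitter)
            if (pose_jitter[0] or pose_jitter[1])
            else RigidTransform.identity()
        )
        noise_seed = int(rng.integers(0, 2**31 - 1))
        volumes.append(voxelize(geom, spec, pose=pose, noise_seed=noise_seed))
        poses.append(pose)
    return volumes, poses
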