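"""Rigid transforms and intensity-based rigid registration.

The registration feature is a double contour: mesh points offset by
+/-0.3 mm along the surface normals, carrying the gray values sampled from
the segmentation (valgus) image. An object's displacement into the target
(varus) image is found by maximising the Pearson correlation between those
stored reference grays and the target grays sampled at the transformed
points, over a six-parameter rigid search space
``(tx, ty, tz, phi_x, phi_y, phi_z)`` with rotation sequence y, x, z.
The optimiser is Nelder-Mead downhill simplex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .imaging import Volume, trilinear_sample

__all__ = [
    "RigidTransform",
    "RegistrationResult",
    "RegistrationSettings",
    "params_to_matrix",
    "matrix_to_params",
    "correlation_metric",
    "register",
    "prealign_principal_axes",
    "MetricUndefinedError",
]

_GIMBAL_EPS = 1e-8


class MetricUndefinedError(ValueError):
    """Raised when the correlation metric cannot be evaluated."""


def _rot_x(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _rot_y(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rot_z(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


@dataclass(frozen=True)
class RigidTransform:
    """A rigid body transform as a 4x4 homogeneous matrix.

    The parameter form is ``(tx, ty, tz, phi_x, phi_y, phi_z)`` with
    translations in mm and rotations in degrees, composed about the fixed
    axes in the sequence y, x, z: ``R = Rz(phi_z) @ Rx(phi_x) @ Ry(phi_y)``.
    """

    matrix: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float).reshape(4, 4).copy()
        R = m[:3, :3]
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-6) or np.linalg.det(R) < 0:
            raise ValueError("matrix is not a proper rigid transform")
        if not np.allclose(m[3], [0, 0, 0, 1], atol=1e-9):
            raise ValueError("last homogeneous row must be [0, 0, 0, 1]")
        # tidy numerical drift from compositions, never beyond 1e-12-scale
        u, _, vt = np.linalg.svd(R)
        m[:3, :3] = u @ vt
        m[3] = [0.0, 0.0, 0.0, 1.0]
        m.flags.writeable = False
        object.__setattr__(self, "matrix", m)

    # -- constructors -------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))

    @classmethod
    def from_params(cls, params: np.ndarray) -> "RigidTransform":
        return params_to_matrix(params)

    @classmethod
    def from_rotation_translation(cls, R: np.ndarray, t: np.ndarray) -> "RigidTransform":
        m = np.eye(4)
        m[:3, :3] = R
        m[:3, 3] = np.asarray(t, float).reshape(3)
        return cls(m)

    @classmethod
    def translation(cls, t) -> "RigidTransform":
        return cls.from_rotation_translation(np.eye(3), t)

    @classmethod
    def rotation_about(cls, axis: np.ndarray, angle_deg: float, center: np.ndarray) -> "RigidTransform":
        """Rotation by ``angle_deg`` about a line through ``center`` along ``axis``."""
        axis = np.asarray(axis, float)
        axis = axis / np.linalg.norm(axis)
        a = np.deg2rad(angle_deg)
        K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
        R = np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)
        center = np.asarray(center, float).reshape(3)
        return cls.from_rotation_translation(R, center - R @ center)

    # -- algebra ------------------------------------------------------
    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation_vector(self) -> np.ndarray:
        return self.matrix[:3, 3]

    def params(self) -> np.ndarray:
        return matrix_to_params(self)

    def inverse(self) -> "RigidTransform":
        R = self.rotation
        return RigidTransform.from_rotation_translation(R.T, -R.T @ self.translation_vector)

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return RigidTransform(self.matrix @ other.matrix)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        return pts @ self.rotation.T + self.translation_vector

    def rotation_angle_deg(self) -> float:
        """Screw rotation angle, i.e. the geodesic distance from identity."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))

    def to_dict(self) -> dict:
        return {
            "matrix_row_major": self.matrix.ravel().tolist(),
            "params_tx_ty_tz_mm_phix_phiy_phiz_deg": self.params().tolist(),
            "convention": "R = Rz @ Rx @ Ry (sequence y, x, z, fixed axes)",
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(np.asarray(d["matrix_row_major"], float).reshape(4, 4))


def params_to_matrix(params: np.ndarray) -> RigidTransform:
    """Six parameters (tx,ty,tz mm, phi_x,phi_y,phi_z deg) -> rigid matrix.

    Rotations are composed about the fixed frame axes in the sequence
    y, x, z: ``R = Rz @ Rx @ Ry``.
    """
    p = np.asarray(params, dtype=float).reshape(6)
    ax, ay, az = np.deg2rad(p[3:6])
    R = _rot_z(az) @ _rot_x(ax) @ _rot_y(ay)
    return RigidTransform.from_rotation_translation(R, p[:3])


def matrix_to_params(transform: RigidTransform) -> np.ndarray:
    """Inverse Euler decomposition for the y, x, z sequence.

    Angles are returned in degrees in (-180, 180]. At gimbal lock
    (|cos phi_x| ~ 0) the y-rotation is absorbed into the z-rotation and
    phi_y is reported as 0.
    """
    R = transform.rotation
    sx = np.clip(R[2, 1], -1.0, 1.0)
    ax = np.arcsin(sx)
    if abs(np.cos(ax)) < _GIMBAL_EPS:
        ay = 0.0
        az = np.arctan2(R[1, 0], R[0, 0])
    else:
        ay = np.arctan2(-R[2, 0], R[2, 2])
        az = np.arctan2(-R[0, 1], R[1, 1])
    t = transform.translation_vector
    return np.array([t[0], t[1], t[2], np.degrees(ax), np.degrees(ay), np.degrees(az)])


@dataclass
class RegistrationSettings:
    """Nelder-Mead registration knobs.

    Translation steps are in mm and rotation steps in degrees, so the simplex
    explores both at a comparable physical scale. ``coarse_step`` runs an
    initial wide simplex pass before the 1 mm / 1 deg refinement, which lets
    the optimiser recover poses several mm / deg from the initialisation.
    """

    initial_step: float = 1.0
    coarse_step: float = 4.0
    tol: float = 1e-4
    max_evaluations: int = 2000
    restarts: int = 3
    restart_scale: float = 0.5
    seed: int = 0
    min_valid_fraction: float = 0.5


@dataclass
class RegistrationResult:
    transform: RigidTransform
    metric_value: float
    iterations: int
    converged: bool
    fraction_valid_samples: float


def correlation_metric(contour, target: Volume, transform: RigidTransform) -> float:
    """Pearson correlation between stored contour grays and the target image.

    The double-contour points (outer and inner shells) are mapped into the
    target by ``transform``; target grays are sampled trilinearly; points
    falling outside the target grid are excluded. At least 10 valid points
    and nonzero variance on both sides are required.
    """
    pts = transform.apply(contour.sample_points)
    values, valid = trilinear_sample(target, pts)
    n_valid = int(valid.sum())
    if n_valid < 10:
        raise MetricUndefinedError(f"only {n_valid} contour points fall inside the target")
    ref = contour.reference_grays[valid]
    tgt = values[valid]
    if np.ptp(ref) == 0 or np.ptp(tgt) == 0:
        raise MetricUndefinedError("zero gray-value variance; correlation undefined")
    return float(np.corrcoef(ref, tgt)[0, 1])


def _centered_transform(params: np.ndarray, center: np.ndarray) -> RigidTransform:
    """Interpret the 6 parameters with the rotation taken about ``center``.

    Rotating about the contour centroid decouples translations from rotations
    in the search space; the returned matrix is an ordinary world-frame
    transform (centre-independent representation).
    """
    base = params_to_matrix(params)
    R = base.rotation
    t = base.translation_vector + center - R @ center
    return RigidTransform.from_rotation_translation(R, t)


def register(
    contour,
    target: Volume,
    init: RigidTransform | None = None,
    settings: RegistrationSettings | None = None,
) -> RegistrationResult:
    """Find the rigid transform carrying a double contour into ``target``.

    Maximises :func:`correlation_metric` with Nelder-Mead over the
    six-parameter space. The rotation is parameterised about the contour
    centroid; random seeded restarts perturb the best parameters and keep
    the best optimum. Non-convergence is flagged, never silent.
    """
    settings = settings or RegistrationSettings()
    init = init or RigidTransform.identity()
    center = init.apply(contour.sample_points).mean(axis=0)

    def objective(p: np.ndarray) -> float:
        T = _centered_transform(p, center) @ init
        try:
            return -correlation_metric(contour, target, T)
        except MetricUndefinedError:
            return 2.0  # worse than any correlation; pushes the simplex back

    def run(x0: np.ndarray, step: float, maxfev: int):
        simplex = np.vstack([x0, x0 + np.eye(6) * step])
        return optimize.minimize(
            objective,
            x0,
            method="Nelder-Mead",
            options={
                "initial_simplex": simplex,
                "xatol": settings.tol,
                "fatol": settings.tol,
                "maxfev": maxfev,
                "adaptive": False,
            },
        )

    rng = np.random.default_rng(settings.seed)
    budget = settings.max_evaluations
    # two independent routes — a fine pass from the init and a coarse-then-
    # fine pass — guard each other: the wide simplex can escape to a distant
    # basin on a near-converged problem, and the narrow one can stall when
    # the init is several steps off. Keep whichever scores best.
    best = run(np.zeros(6), settings.initial_step, budget)
    if settings.coarse_step:
        coarse = run(np.zeros(6), settings.coarse_step, budget // 2)
        refined = run(coarse.x, settings.initial_step, budget)
        if refined.fun < best.fun:
            best = refined
    for _ in range(max(0, settings.restarts - 1)):
        jitter = rng.uniform(-settings.restart_scale, settings.restart_scale, 6)
        res = run(best.x + jitter, settings.initial_step, budget)
        if res.fun < best.fun:
            best = res
    T = _centered_transform(best.x, center) @ init
    pts = T.apply(contour.sample_points)
    _, valid = trilinear_sample(target, pts)
    return RegistrationResult(
        transform=T,
        metric_value=-float(best.fun),
        iterations=int(best.nfev),
        converged=bool(best.success),
        fraction_valid_samples=float(valid.mean()),
    )


def _long_axis(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and dominant principal axis of a point cloud, with the axis
    sign fixed by the third central moment along it (a tibia cloud is
    strongly skewed toward its flared ends)."""
    c = points.mean(axis=0)
    q = points - c
    cov = q.T @ q / len(q)
    w, v = np.linalg.eigh(cov)
    axis = v[:, np.argmax(w)]
    if np.mean((q @ axis) ** 3) < 0:
        axis = -axis
    return c, axis


def _align_vectors(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation carrying unit vector a onto unit vector b."""
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else -np.eye(3) + 2 * np.outer(a, a)
    K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + K + K @ K / (1.0 + c)


def prealign_principal_axes(
    contour,
    source: Volume,
    target: Volume,
    threshold: float,
    sample_stride: int = 3,
    roll_step_deg: float = 15.0,
) -> RigidTransform:
    """Coarse initial pose from supra-threshold voxel clouds.

    The whole-specimen repositioning between scans can be tens of mm and
    ~10 deg — far outside the simplex basin. The centroids and dominant
    principal axes of the voxel clouds above ``threshold`` fix four of the
    six degrees of freedom; the roll about the long axis (ill-determined by
    moments for a near-tubular bone) and the axis sign are resolved by
    scanning the correlation metric over candidate roll angles and keeping
    the best pose, which lands within half a roll step of the optimum.
    """

    def cloud(vol: Volume) -> np.ndarray:
        sub = vol.data[::sample_stride, ::sample_stride, ::sample_stride]
        idx = np.argwhere(sub >= threshold) * sample_stride
        if len(idx) < 100:
            raise ValueError("too few supra-threshold voxels for pre-alignment")
        return vol.index_to_world(idx)

    c_src, u_src = _long_axis(cloud(source))
    c_tgt, u_tgt = _long_axis(cloud(target))
    best: tuple[float, RigidTransform] | None = None
    for axis_sign in (1.0, -1.0):
        R0 = _align_vectors(u_src, axis_sign * u_tgt)
        for roll in np.arange(0.0, 360.0, roll_step_deg):
            R = (
                RigidTransform.rotation_about(axis_sign * u_tgt, roll, np.zeros(3)).rotation
                @ R0
            )
            T = RigidTransform.from_rotation_translation(R, c_tgt - R @ c_src)
            try:
                m = correlation_metric(contour, target, T)
            except MetricUndefinedError:
                continue
            if best is None or m > best[0]:
                best = (m, T)
    if best is None:
        raise ValueError("pre-alignment failed: no candidate pose sampled the target")
    return best[1]
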