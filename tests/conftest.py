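"""Shared fixtures: small phantoms and their segmentations.

The "small" phantom is a 120 mm bone at 0.9 mm spacing (fast but with the
full geometry: flares, bow, triangular cortex, offset stem); the "tiny"
phantom is a 70 mm bone at 1.5 mm spacing for brute-force oracles. Both
are noise-free so that geometric assertions are deterministic.
"""

import numpy as np
import pytest

from ctmotion.experiments import ExperimentConfig, segment_scan
from ctmotion.phantom import PhantomSpec, build_geometry, voxelize
from ctmotion.registration import RigidTransform

KNOWN_POSE_PARAMS = np.array([2.0, -1.5, 1.0, 1.0, -2.0, 1.5])


@pytest.fixture(scope="session")
def small_spec():
    return PhantomSpec(
        bone_length=120.0,
        proximal_radius=26.0,
        distal_radius=16.0,
        plateau_halfwidth_ml=25.0,
        plateau_halfwidth_ap=17.0,
        stem_length=25.0,
        voxel_spacing=0.9,
        noise_sd=0.0,
        seed=1,
    )


@pytest.fixture(scope="session")
def small_geometry(small_spec):
    return build_geometry(small_spec)


@pytest.fixture(scope="session")
def small_volume(small_geometry):
    return voxelize(small_geometry)


@pytest.fixture(scope="session")
def known_pose():
    return RigidTransform.from_params(KNOWN_POSE_PARAMS)


@pytest.fixture(scope="session")
def reposed_volume(small_geometry, known_pose):
    return voxelize(small_geometry, pose=known_pose)


@pytest.fixture(scope="session")
def small_objects(small_volume):
    return segment_scan(small_volume, ExperimentConfig())


@pytest.fixture(scope="session")
def small_labels(small_geometry, small_volume):
    """Ground-truth class label of every voxel of the small phantom volume."""
    vol = small_volume
    ii, jj, kk = np.meshgrid(*[np.arange(s) for s in vol.shape], indexing="ij")
    pts = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()]) * vol.spacing + vol.origin
    return small_geometry.classify(pts).reshape(vol.shape)


@pytest.fixture(scope="session")
def tiny_spec():
    return PhantomSpec(
        bone_length=70.0,
        shaft_radius=9.0,
        proximal_radius=17.0,
        distal_radius=12.0,
        cortical_thickness=3.5,
        plateau_halfwidth_ml=16.0,
        plateau_halfwidth_ap=11.0,
        plateau_thickness=3.0,
        stem_length=15.0,
        stem_radius=4.0,
        stem_offset=(1.5, 2.0),
        shaft_bow=2.5,
        voxel_spacing=1.5,
        noise_sd=0.0,
        supersample=2,
        seed=2,
    )


@pytest.fixture(scope="session")
def tiny_geometry(tiny_spec):
    return build_geometry(tiny_spec)


@pytest.fixture(scope="session")
def tiny_volume(tiny_geometry):
    return voxelize(tiny_geometry)
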