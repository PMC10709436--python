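"""Phantom generator: geometry, bending, voxelization, ground truth."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.spatial import cKDTree

from ctmotion.kinematics import decompose
from ctmotion.phantom import (
    BACKGROUND,
    CORTEX,
    IMPLANT,
    TRABECULAR,
    PhantomGeometry,
    PhantomSpec,
    apply_bending,
    build_geometry,
    generate_load_pair,
    generate_repeat_scans,
    voxelize,
)
from ctmotion.registration import RigidTransform
from ctmotion.segmentation import extract_mesh


class TestSpecValidation:
    def test_intensity_ordering_enforced(self):
        with pytest.raises(ValueError, match="implant > cortex"):
            PhantomSpec(intensity_cortex=4000.0)

    def test_plateau_ml_must_exceed_ap(self):
        with pytest.raises(ValueError, match="ML halfwidth"):
            PhantomSpec(plateau_halfwidth_ml=20.0, plateau_halfwidth_ap=22.0)

    def test_positive_dimensions(self):
        with pytest.raises(ValueError):
            PhantomSpec(stem_radius=-1.0)
        with pytest.raises(ValueError):
            PhantomSpec(voxel_spacing=0.0)


class TestClassification:
    def test_point_classes_by_construction(self, small_geometry):
        s = small_geometry.spec
        mid_z = s.bone_length / 2
        bow = float(small_geometry._bow(np.array([mid_z]))[0])
        on_axis = [bow, 0.0, mid_z]
        r_out = s.shaft_radius  # phi = 0 direction has +triangularity modulation
        r_out *= 1 + s.triangularity
        cortex_pt = [bow + r_out - s.cortical_thickness / 2, 0.0, mid_z]
        stem_pt = [s.stem_offset[0], s.stem_offset[1], s.bone_length - 2.0]
        plateau_pt = [0.0, 0.0, s.bone_length + s.plateau_thickness / 2]
        outside = [0.0, 0.0, -20.0]
        labels = small_geometry.classify([on_axis, cortex_pt, stem_pt, plateau_pt, outside])
        assert list(labels) == [TRABECULAR, CORTEX, IMPLANT, IMPLANT, BACKGROUND]


class TestBending:
    def test_zero_bend_is_identity(self, small_geometry):
        pts = np.array([[3.0, -2.0, 10.0], [0.0, 0.0, 100.0]])
        np.testing.assert_allclose(small_geometry.bend_points(pts), pts, atol=1e-15)

    @pytest.mark.parametrize("theta", [1.5, -1.5])
    def test_proximal_end_offset_matches_closed_form(self, small_spec, theta):
        """The proximal end rotates rigidly by theta about the bend axis, so
        its lateral offset is the circular formula (L - z0) sin(theta)."""
        geom = apply_bending(build_geometry(small_spec), theta)
        L = small_spec.bone_length
        z0 = geom.bend_axis_origin[2]
        tip = geom.bend_points([[0.0, 0.0, L]])[0]
        a = np.deg2rad(theta)
        np.testing.assert_allclose(tip[0], (L - z0) * np.sin(a), atol=1e-12)
        np.testing.assert_allclose(tip[2], z0 + (L - z0) * np.cos(a), atol=1e-12)

    def test_sign_flip_mirrors_offset(self, small_spec):
        g_pos = apply_bending(build_geometry(small_spec), 2.0)
        g_neg = apply_bending(build_geometry(small_spec), -2.0)
        p = [0.0, 0.0, small_spec.bone_length]
        assert g_pos.bend_points([p])[0][0] == pytest.approx(-g_neg.bend_points([p])[0][0])

    def test_distal_segment_unchanged(self, small_spec):
        geom = apply_bending(build_geometry(small_spec), 3.0)
        pts = np.array([[5.0, 1.0, 2.0], [0.0, -4.0, 0.2 * small_spec.bone_length]])
        np.testing.assert_allclose(geom.bend_points(pts), pts, atol=1e-12)

    def test_unbend_inverts_bend(self, small_spec):
        geom = apply_bending(build_geometry(small_spec), 4.0)
        rng = np.random.default_rng(0)
        pts = rng.uniform([-20, -20, 0], [20, 20, small_spec.bone_length], (200, 3))
        np.testing.assert_allclose(geom.unbend_points(geom.bend_points(pts)), pts, atol=1e-9)

    def test_large_bend_rejected(self, small_spec):
        with pytest.raises(ValueError, match="small-deformation"):
            apply_bending(build_geometry(small_spec), 11.0)


class TestVoxelize:
    def test_deep_cortex_voxel_has_cortex_intensity(self, small_volume, small_labels, small_spec):
        # voxels well inside the cortex (eroded) keep the pure class value
        from scipy import ndimage

        deep = ndimage.binary_erosion(small_labels == CORTEX, iterations=3)
        assert deep.any()
        vals = small_volume.data[deep]
        assert np.abs(vals - small_spec.intensity_cortex).max() < 5.0

    def test_background_block_mean_follows_noise_statistics(self, small_geometry):
        spec = replace(small_geometry.spec, noise_sd=100.0)
        vol = voxelize(small_geometry, spec=spec, noise_seed=123)
        block = vol.data[:10, :10, :10]  # far corner: pure background
        tol = 3 * spec.noise_sd / np.sqrt(block.size)
        assert abs(block.mean() - spec.intensity_background) < tol

    def test_same_seed_bit_identical(self, small_geometry):
        spec = replace(small_geometry.spec, noise_sd=80.0)
        v1 = voxelize(small_geometry, spec=spec, noise_seed=5)
        v2 = voxelize(small_geometry, spec=spec, noise_seed=5)
        assert np.array_equal(v1.data, v2.data)
        np.testing.assert_array_equal(v1.origin, v2.origin)

    def test_voxel_budget_guard(self, small_geometry):
        spec = replace(small_geometry.spec, max_voxels=1000)
        with pytest.raises(ValueError, match="budget"):
            voxelize(small_geometry, spec=spec)

    def test_marching_cubes_within_one_voxel_of_analytic_surface(self, tiny_geometry, tiny_volume):
        """Voxelization and analytic geometry agree: the marching-cubes
        surface of the noise-free implant lies within one voxel of the
        densely sampled analytic implant surface (directed Hausdorff)."""
        vol = tiny_volume
        ii, jj, kk = np.meshgrid(*[np.arange(s) for s in vol.shape], indexing="ij")
        pts = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()]) * vol.spacing + vol.origin
        labels = tiny_geometry.classify(pts).reshape(vol.shape)
        mesh = extract_mesh(labels == IMPLANT, vol.spacing, vol.origin)
        fine_v, _ = tiny_geometry._canonical_implant_mesh(n_phi=256, n_rad=40)
        d, _ = cKDTree(fine_v).query(mesh.vertices)
        assert d.max() < vol.spacing[0]


class TestLoadPair:
    def test_null_pair_has_identity_ground_truth(self, tiny_spec):
        _, _, truth = generate_load_pair(tiny_spec, bend_angle=0.0)
        for M in (
            truth.true_M_prox_distal,
            truth.true_M_implant_prox,
            truth.true_M_implant_whole,
            truth.true_M_prox_distal_local,
            truth.true_M_implant_prox_local,
        ):
            np.testing.assert_allclose(M.matrix, np.eye(4), atol=1e-9)

    def test_loose_implant_translation_magnitude_preserved(self, tiny_spec):
        motion = RigidTransform.translation([0.5, 0.0, 0.0])
        _, _, truth = generate_load_pair(tiny_spec, bend_angle=0.0, implant_motion=motion)
        assert np.linalg.norm(truth.true_M_implant_prox.translation_vector) == pytest.approx(0.5, abs=1e-9)
        local = decompose(truth.true_M_implant_prox_local)
        assert local.translation_magnitude == pytest.approx(0.5, abs=1e-9)

    def test_net_bend_equals_prox_distal_rotation_magnitude(self, tiny_spec):
        _, _, truth = generate_load_pair(tiny_spec, bend_angle=0.32)
        rec = decompose(truth.true_M_prox_distal_local)
        assert rec.rotation_magnitude == pytest.approx(0.64, abs=1e-9)

    def test_local_ground_truth_invariant_to_global_poses(self, tiny_spec):
        """The core rigid-motion invariance: specimen repositioning cannot
        change the relative displacements expressed in the implant frame."""
        motion = RigidTransform.from_params([0.3, -0.2, 0.1, 0.2, 0.4, -0.1])
        truths = []
        for seed in (11, 99):
            spec = replace(tiny_spec, seed=seed)
            _, _, truth = generate_load_pair(spec, 0.4, implant_motion=motion)
            truths.append(truth)
        t0, t1 = truths
        assert not np.allclose(t0.global_pose_valgus.matrix, t1.global_pose_valgus.matrix)
        np.testing.assert_allclose(
            t0.true_M_prox_distal_local.matrix, t1.true_M_prox_distal_local.matrix, atol=1e-9
        )
        np.testing.assert_allclose(
            t0.true_M_implant_prox_local.matrix, t1.true_M_implant_prox_local.matrix, atol=1e-9
        )


class TestRepeatScans:
    def test_requires_at_least_two(self, tiny_spec):
        with pytest.raises(ValueError):
            generate_repeat_scans(tiny_spec, 1)

    def test_no_jitter_no_noise_identical_volumes(self, tiny_spec):
        vols, poses = generate_repeat_scans(tiny_spec, 2, pose_jitter=(0.0, 0.0))
        assert np.array_equal(vols[0].data, vols[1].data)
        for p in poses:
            np.testing.assert_allclose(p.matrix, np.eye(4), atol=1e-15)

    def test_n_scans_and_poses_recorded(self, tiny_spec):
        vols, poses = generate_repeat_scans(tiny_spec, 10, pose_jitter=(5.0, 3.0))
        assert len(vols) == 10 and len(poses) == 10
        # distinct random poses
        assert not np.allclose(poses[0].matrix, poses[1].matrix)
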