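"""Segmentation: region growing, level-set refinement, meshing, contours, clipping."""

import numpy as np
import pytest

from ctmotion.imaging import SurfaceMesh, Volume, trilinear_sample
from ctmotion.phantom import CORTEX, IMPLANT
from ctmotion.registration import RigidTransform
from ctmotion.segmentation import (
    build_double_contour,
    clip_segments,
    dice,
    extract_mesh,
    find_seed,
    levelset_refine,
    region_grow,
)


def _two_blob_volume():
    data = np.zeros((30, 20, 20), dtype=float)
    data[3:8, 8:13, 8:13] = 2000.0
    data[20:25, 8:13, 8:13] = 2000.0
    return Volume(data, spacing=1.0)


class TestRegionGrow:
    def test_grows_only_connected_component(self):
        vol = _two_blob_volume()
        mask = region_grow(vol, (5, 10, 10), 1500.0)
        assert mask[5, 10, 10] and not mask[22, 10, 10]
        assert mask.sum() == 5 * 5 * 5

    def test_seed_below_threshold_raises(self):
        with pytest.raises(ValueError, match="below the threshold"):
            region_grow(_two_blob_volume(), (0, 0, 0), 1500.0)

    def test_exclusion_separates_touching_objects(self):
        vol = _two_blob_volume()
        vol.data[8:20, 10, 10] = 2000.0  # bridge the blobs
        exclude = np.zeros(vol.shape, bool)
        exclude[13:15, :, :] = True  # cut the bridge
        mask = region_grow(vol, (5, 10, 10), 1500.0, exclude=exclude)
        assert not mask[22, 10, 10]

    def test_phantom_implant_mask_equals_class_voxels(self, small_objects, small_labels):
        """Pipeline implant/cortex masks recover the ground-truth classes."""
        assert dice(small_objects.implant_mask, small_labels == IMPLANT) > 0.95
        assert dice(small_objects.cortex_mask, small_labels == CORTEX) > 0.95


class TestLevelSetRefine:
    def test_zero_iterations_is_identity(self, small_volume, small_objects):
        out = levelset_refine(small_volume, small_objects.implant_mask, iterations=0)
        assert np.array_equal(out, small_objects.implant_mask)

    def test_empty_mask_raises(self, small_volume):
        with pytest.raises(ValueError, match="empty"):
            levelset_refine(small_volume, np.zeros(small_volume.shape, bool), 10)

    def test_refinement_improves_undergrown_mask(self, small_volume, small_labels):
        """A mask grown at too high a threshold recovers the true boundary."""
        under = region_grow(small_volume, find_seed(small_volume, 3500.0), 3600.0)
        refined = levelset_refine(small_volume, under, iterations=40, min_dice=0.5)
        truth = small_labels == IMPLANT
        assert dice(refined, truth) > dice(under, truth)

    def test_edge_aligned_mask_is_fixed_point(self, small_volume, small_labels):
        aligned = levelset_refine(small_volume, small_labels == IMPLANT, iterations=10)
        assert dice(aligned, small_labels == IMPLANT) > 0.97


class TestExtractMesh:
    def test_sphere_radius_recovered(self):
        spacing = 0.5
        idx = np.indices((50, 50, 50)).astype(float) * spacing
        center = np.array([12.0, 12.0, 12.0])
        r = np.linalg.norm(idx - center[:, None, None, None], axis=0)
        mesh = extract_mesh(r <= 10.0, [spacing] * 3)
        radii = np.linalg.norm(mesh.vertices - center, axis=1)
        assert np.abs(radii - 10.0).max() < 0.5 * spacing + 1e-6

    def test_normals_point_outward_and_unit(self):
        mask = np.zeros((12, 12, 12), bool)
        mask[3:9, 3:9, 3:9] = True
        mesh = extract_mesh(mask, [1.0] * 3)
        np.testing.assert_allclose(np.linalg.norm(mesh.normals, axis=1), 1.0, atol=1e-6)
        center = mesh.vertices.mean(axis=0)
        outward = np.einsum("ij,ij->i", mesh.normals, mesh.vertices - center)
        assert (outward > 0).mean() > 0.95

    def test_single_voxel_gives_closed_surface(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 2, 2] = True
        tm = extract_mesh(mask, [1.0] * 3).to_trimesh()
        assert tm.euler_number == 2 and tm.is_watertight

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            extract_mesh(np.zeros((4, 4, 4), bool), [1.0] * 3)


class TestDoubleContour:
    def test_offset_distances_exact(self, small_objects):
        c = small_objects.contours["implant"]
        np.testing.assert_allclose(np.linalg.norm(c.outer_points - c.base_points, axis=1), 0.3, atol=1e-6)
        np.testing.assert_allclose(np.linalg.norm(c.inner_points - c.base_points, axis=1), 0.3, atol=1e-6)
        assert len(c.reference_grays) == 2 * len(c.base_points)

    def test_monotone_radial_field_orders_shells(self):
        idx = np.indices((40, 40, 40)).astype(float)
        center = np.array([19.5, 19.5, 19.5])
        r = np.linalg.norm(idx - center[:, None, None, None], axis=0)
        vol = Volume(r * 100.0, spacing=1.0)
        sphere = extract_mesh(r <= 12.0, [1.0] * 3)
        c = build_double_contour(vol, sphere)
        n = len(c.base_points)
        assert (c.reference_grays[:n] > c.reference_grays[n:]).all()

    def test_base_gray_is_mean_of_shells_in_linear_field(self, small_objects):
        idx = np.indices((30, 30, 30)).astype(float)
        vol = Volume(3.0 * idx[0] - 2.0 * idx[1] + idx[2], spacing=1.0)
        mask = np.zeros((30, 30, 30), bool)
        mask[10:20, 10:20, 10:20] = True
        mesh = extract_mesh(mask, [1.0] * 3)
        c = build_double_contour(vol, mesh)
        base_vals, _ = trilinear_sample(vol, c.base_points)
        n = len(c.base_points)
        shell_mean = (c.reference_grays[:n] + c.reference_grays[n:]) / 2
        np.testing.assert_allclose(base_vals, shell_mean, atol=1e-9)

    def test_out_of_volume_mesh_rejected(self, small_volume, small_objects):
        shifted = small_objects.implant_mesh.transformed(
            RigidTransform.translation([500.0, 0.0, 0.0]).matrix
        )
        with pytest.raises(ValueError, match="outside the volume"):
            build_double_contour(small_volume, shifted)

    def test_reproducible_bit_exact(self, small_volume, small_objects):
        c1 = build_double_contour(small_volume, small_objects.implant_mesh, max_points=800)
        c2 = build_double_contour(small_volume, small_objects.implant_mesh, max_points=800)
        assert np.array_equal(c1.reference_grays, c2.reference_grays)


def _tube_mesh(length=300.0, radius=10.0, n_phi=24, n_z=151):
    phi = np.linspace(0, 2 * np.pi, n_phi, endpoint=False)
    z = np.linspace(0, length, n_z)
    P, Z = np.meshgrid(phi, z, indexing="ij")
    verts = np.stack([radius * np.cos(P), radius * np.sin(P), Z], axis=-1).reshape(-1, 3)
    faces = []
    for i in range(n_phi):
        i2 = (i + 1) % n_phi
        for j in range(n_z - 1):
            a, b = i * n_z + j, i2 * n_z + j
            faces.append([a, b, a + 1])
            faces.append([b, b + 1, a + 1])
    return SurfaceMesh.from_arrays(verts, np.array(faces))


class TestClipSegments:
    def test_tube_segment_extents(self):
        prox, dist, whole = clip_segments(_tube_mesh(), fraction=0.2)
        assert prox.vertices[:, 2].max() == pytest.approx(300.0, abs=2.1)
        assert prox.vertices[:, 2].min() == pytest.approx(240.0, abs=2.1)
        assert dist.vertices[:, 2].max() == pytest.approx(60.0, abs=2.1)

    def test_fraction_half_partitions_mesh(self):
        mesh = _tube_mesh()
        prox, dist, _ = clip_segments(mesh, fraction=0.5)
        assert len(prox.vertices) + len(dist.vertices) >= len(mesh.vertices)

    def test_invalid_fraction_rejected(self):
        mesh = _tube_mesh()
        for f in (0.0, 0.6, -0.1):
            with pytest.raises(ValueError):
                clip_segments(mesh, fraction=f)

    def test_rigid_motion_equivariance(self):
        # fraction chosen so the cut planes fall between vertex rings, where
        # inclusion cannot flip on numerical jitter
        mesh = _tube_mesh()
        T = RigidTransform.from_params([5.0, -3.0, 10.0, 4.0, -6.0, 3.0])
        prox, dist, whole = clip_segments(mesh, fraction=0.23)
        prox_t, dist_t, _ = clip_segments(mesh.transformed(T.matrix), fraction=0.23)
        np.testing.assert_allclose(prox_t.vertices, T.apply(prox.vertices), atol=1e-9)
        np.testing.assert_allclose(dist_t.vertices, T.apply(dist.vertices), atol=1e-9)

    def test_non_elongated_mesh_rejected(self):
        with pytest.raises(ValueError, match="elongated"):
            clip_segments(_tube_mesh(length=25.0, radius=10.0, n_z=13))

    def test_phantom_clip_matches_analytic_segments(self, small_objects, small_spec):
        """Clip planes match the analytic geometry: length runs from the
        plateau level to the distal end, and each end segment spans 20% of
        it, within a voxel band at the cut plane."""
        top = small_spec.bone_length + small_spec.plateau_thickness  # plateau level
        tol = 2 * small_spec.voxel_spacing
        zmin = small_objects.prox_mesh.vertices[:, 2].min()
        assert abs(zmin - 0.8 * top) < tol
        zmax_dist = small_objects.distal_mesh.vertices[:, 2].max()
        assert abs(zmax_dist - 0.2 * top) < tol
        # whole tibia = everything below the plateau
        assert small_objects.whole_mesh.vertices[:, 2].max() <= top + tol
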