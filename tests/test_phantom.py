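"""Synthetic radius generation, CT-like rendering, placement simulation."""

from dataclasses import replace

import numpy as np
import pytest
import trimesh

from guidefit.phantom import (
    DESIGNS,
    LOCATIONS,
    BonePhantomParams,
    CTSimParams,
    PlacementErrorModel,
    compose_scene,
    default_phantom_set,
    make_synthetic_radius,
    simulate_experiment,
    voxelize,
)

CLEAN_BINARY = CTSimParams(psf_sigma=0.0, noise_sd=0.0, supersample=1)


class TestMakeSyntheticRadius:
    def test_degenerate_params_give_capped_cylinder(self):
        params = BonePhantomParams(
            total_length=60, shaft_radius=8, distal_width_factor=1.0,
            styloid_length=0.0, n_anchor_bumps=0, bump_amplitude=0.0,
        )
        mesh, _ = make_synthetic_radius(params)
        assert mesh.is_watertight and mesh.is_winding_consistent
        radii = np.linalg.norm(mesh.vertices[:, :2], axis=1)
        np.testing.assert_allclose(radii, 8.0, atol=1e-9)
        assert mesh.bounds[1, 2] - mesh.bounds[0, 2] == pytest.approx(60.0)

    def test_same_seed_is_bit_identical(self, desk_params):
        m1, lm1 = make_synthetic_radius(desk_params)
        m2, lm2 = make_synthetic_radius(desk_params)
        assert np.array_equal(m1.vertices, m2.vertices)
        assert np.array_equal(lm1["styloid_tip"], lm2["styloid_tip"])
        m3, _ = make_synthetic_radius(replace(desk_params, seed=desk_params.seed + 1))
        assert not np.array_equal(m1.vertices, m3.vertices)

    def test_styloid_tip_is_a_distal_surface_vertex(self, desk_bone):
        mesh, landmarks = desk_bone
        tip = landmarks["styloid_tip"]
        assert np.any(np.all(np.isclose(mesh.vertices, tip), axis=1))
        length = mesh.bounds[1, 2] - mesh.bounds[0, 2]
        assert tip[2] > mesh.bounds[0, 2] + 2 * length / 3  # distal third
        assert tip[0] > 0  # protrudes toward +x

    def test_mesh_volume_matches_voxel_count(self, desk_bone):
        mesh, _ = desk_bone
        vol = voxelize(mesh, CLEAN_BINARY)
        voxel_volume = (vol.data == CLEAN_BINARY.bone_intensity).sum() * 0.33**3
        assert voxel_volume == pytest.approx(mesh.volume, rel=0.02)

    def test_voxelized_volume_converges_with_voxel_size(self, desk_bone, rng):
        """Expected voxel-count volume error shrinks as the grid refines.

        The error at a single fixed orientation is an oscillatory boundary
        term, so the comparison averages over random orientations.
        """
        from guidefit.transforms import random_rigid

        mesh, _ = desk_bone
        rotations = [random_rigid(rng, np.zeros(3), 0, 180) for _ in range(3)]
        means = []
        for vs in (1.32, 0.33):
            sim = replace(CLEAN_BINARY, voxel_size=vs)
            errs = []
            for M in rotations:
                m = mesh.copy()
                m.apply_transform(M)
                vol = voxelize(m, sim)
                v = (vol.data == sim.bone_intensity).sum() * vs**3
                errs.append(abs(v - mesh.volume) / mesh.volume)
            means.append(np.mean(errs))
        assert means[1] < means[0]

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            make_synthetic_radius(BonePhantomParams(total_length=0.0))
        with pytest.raises(ValueError):
            make_synthetic_radius(BonePhantomParams(shaft_radius=-1.0))
        with pytest.raises(ValueError):
            make_synthetic_radius(BonePhantomParams(distal_width_factor=0.5))


class TestVoxelize:
    def test_unit_cube_interior_count(self):
        cube = trimesh.creation.box(extents=[1, 1, 1])
        cube.apply_translation([0.5, 0.5, 0.5])
        sim = replace(CLEAN_BINARY, voxel_size=0.5)
        vol = voxelize(cube, sim)
        assert (vol.data == sim.bone_intensity).sum() == 8

    def test_noise_free_renders_are_seed_independent(self, desk_bone):
        mesh, _ = desk_bone
        a = voxelize(mesh, replace(CLEAN_BINARY, seed=1))
        b = voxelize(mesh, replace(CLEAN_BINARY, seed=99))
        assert np.array_equal(a.data, b.data)

    def test_noisy_renders_are_seeded(self, desk_bone):
        mesh, _ = desk_bone
        sim = CTSimParams(seed=5)
        a = voxelize(mesh, sim)
        b = voxelize(mesh, sim)
        c = voxelize(mesh, replace(sim, seed=6))
        assert np.array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)

    def test_psf_conserves_total_intensity(self, desk_bone):
        mesh, _ = desk_bone
        sharp = voxelize(mesh, CLEAN_BINARY)
        blurred = voxelize(mesh, replace(CLEAN_BINARY, psf_sigma=0.5))
        assert blurred.data.sum() == pytest.approx(sharp.data.sum(), rel=1e-3)

    def test_partial_volume_supersampling_refines_boundary(self, desk_bone):
        mesh, _ = desk_bone
        pv = voxelize(mesh, replace(CLEAN_BINARY, supersample=2))
        fractional = (pv.data > 0) & (pv.data < CLEAN_BINARY.bone_intensity)
        assert fractional.any()
        assert pv.data.sum() * 0.33**3 / CLEAN_BINARY.bone_intensity == pytest.approx(
            mesh.volume, rel=0.01
        )

    def test_open_mesh_rejected(self):
        tri = trimesh.Trimesh(
            vertices=[[0, 0, 0], [1, 0, 0], [0, 1, 0]], faces=[[0, 1, 2]]
        )
        with pytest.raises(ValueError):
            voxelize(tri, CLEAN_BINARY)


class TestComposeScene:
    def test_empty_scene_equals_voxelize(self, desk_bone):
        mesh, _ = desk_bone
        a = compose_scene(mesh, [], [], CLEAN_BINARY)
        b = voxelize(mesh, CLEAN_BINARY)
        assert np.array_equal(a.data, b.data)
        np.testing.assert_allclose(a.origin, b.origin)

    def test_guide_blob_centroid_shifts_with_pose(self):
        bone = trimesh.creation.box(extents=[4, 4, 4])
        guide = trimesh.creation.box(extents=[6, 5, 4])
        guide.apply_translation([20.0, 0, 0])
        sim = CLEAN_BINARY
        shift = np.eye(4)
        shift[0, 3] = 5 * sim.voxel_size
        bounds = np.array([[-5.0, -6, -5], [30.0, 6, 5]])
        ref = compose_scene(bone, [guide], [np.eye(4)], sim, bounds=bounds)
        posed = compose_scene(bone, [guide], [shift], sim, bounds=bounds)

        def blob_centroid(vol):
            w = vol.data.copy()
            idx = np.argwhere(w > 0)
            ww = w[w > 0]
            com = (idx * ww[:, None]).sum(axis=0) / ww.sum()
            return com * vol.spacing + vol.origin

        # isolate the guide blob by subtracting the static bone rendering
        bone_only = compose_scene(bone, [], [], sim, bounds=bounds)
        g_ref = ref.copy()
        g_ref.data = ref.data - bone_only.data
        g_posed = posed.copy()
        g_posed.data = posed.data - bone_only.data
        delta = blob_centroid(g_posed) - blob_centroid(g_ref)
        np.testing.assert_allclose(
            delta, [5 * sim.voxel_size, 0, 0], atol=0.1 * sim.voxel_size
        )

    def test_non_rigid_pose_rejected(self, desk_bone):
        mesh, _ = desk_bone
        guide = trimesh.creation.box(extents=[5, 5, 5])
        with pytest.raises(ValueError):
            compose_scene(mesh, [guide], [np.diag([2.0, 1, 1, 1])], CLEAN_BINARY)


class TestSimulateExperiment:
    def test_default_factorial_has_144_complete_records(self):
        records = simulate_experiment(
            default_phantom_set(0), PlacementErrorModel.default(), 4, seed=1
        )
        assert len(records) == 144
        combos = {(r.operator, r.geometry, r.location, r.design) for r in records}
        assert len(combos) == 144
        assert {r.location for r in records} == set(LOCATIONS)
        assert {r.design for r in records} == set(DESIGNS)

    def test_zero_error_model_gives_identity_transforms(self):
        records = simulate_experiment(
            default_phantom_set(0, n=2), PlacementErrorModel.zero(), 2, seed=0
        )
        for rec in records:
            np.testing.assert_allclose(
                rec.true_error(np.array([5.0, 3.0, 1.0])), np.eye(4), atol=1e-12
            )

    def test_records_are_seed_reproducible(self):
        a = simulate_experiment(default_phantom_set(0), PlacementErrorModel.default(), 4, seed=7)
        b = simulate_experiment(default_phantom_set(0), PlacementErrorModel.default(), 4, seed=7)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.true_params, rb.true_params)

    def test_empirical_sd_matches_model(self, rng):
        model = PlacementErrorModel.default()
        draws = np.array(
            [model.sample_params("mid-shaft", "standard", rng) for _ in range(10_000)]
        )
        cell = model.cells[("mid-shaft", "standard")]
        np.testing.assert_allclose(
            draws[:, :3].std(axis=0), cell.translation_sd, rtol=0.05
        )
        np.testing.assert_allclose(
            draws[:, 3:].std(axis=0), cell.rotation_sd, rtol=0.05
        )

    def test_missing_cell_rejected(self):
        model = PlacementErrorModel(cells={})
        with pytest.raises(ValueError):
            simulate_experiment(default_phantom_set(0), model, 4, seed=0)
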