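"""Guide CAD pipeline: box fitting, projection, morphology, footprint, extrusion."""

import numpy as np
import pytest
import trimesh

from guidefit.guide_design import (
    GuideSpec,
    ProjectionImage,
    VirtualBox,
    build_guide,
    cleanup_extended,
    cleanup_standard,
    extrude_guide,
    fit_virtual_box,
    make_footprint,
    project_grid,
)
from guidefit.meshutil import point_mesh_distance
from guidefit.phantom import BonePhantomParams, make_synthetic_radius
from guidefit.pose_error import AnatomicFrame, anatomic_frame


def world_frame():
    return AnatomicFrame(
        origin=np.zeros(3),
        x_axis=np.array([1.0, 0, 0]),
        y_axis=np.array([0, 1.0, 0]),
        z_axis=np.array([0, 0, 1.0]),
    )


@pytest.fixture(scope="module")
def cylinder_bone():
    """Degenerate 240 mm cylindrical phantom with a lateral frame marker."""
    params = BonePhantomParams(
        total_length=240, shaft_radius=10, distal_width_factor=1.0,
        styloid_length=0.0, n_anchor_bumps=0, bump_amplitude=0.0,
    )
    mesh, _ = make_synthetic_radius(params)
    frame = anatomic_frame(mesh, np.array([10.0, 0.0, 230.0]))
    return mesh, frame


def make_image(mask, spacing=1.0, hit_y=None, box=None):
    H, W = mask.shape
    if hit_y is None:
        hit_y = np.where(mask, 0.0, np.nan)
    if box is None:
        box = VirtualBox(
            center=np.zeros(3),
            half_extents=np.array([W * spacing, 10.0, H * spacing]),
            frame=world_frame(),
        )
    return ProjectionImage(
        mask=mask.astype(bool),
        hit_y=hit_y,
        lateral=np.zeros_like(mask, dtype=bool),
        grid_spacing=spacing,
        u0=0.0,
        v0=0.0,
        box=box,
    )


def brute_force_disk_op(mask, radius, op):
    """Shift-based erosion/dilation oracle with a Euclidean disk."""
    H, W = mask.shape
    shifts = [
        (di, dj)
        for di in range(-radius, radius + 1)
        for dj in range(-radius, radius + 1)
        if di * di + dj * dj <= radius * radius
    ]
    padded = np.pad(mask, radius, constant_values=(op == "erode"))
    out = np.full_like(mask, op == "erode")
    for di, dj in shifts:
        window = padded[radius + di : radius + di + H, radius + dj : radius + dj + W]
        out = (out & window) if op == "erode" else (out | window)
    return out


class TestFitVirtualBox:
    def test_box_length_is_twenty_percent_of_bone(self, cylinder_bone):
        mesh, frame = cylinder_bone
        box = fit_virtual_box(mesh, GuideSpec("mid-shaft", "standard"), frame)
        assert 2 * box.half_extents[2] == pytest.approx(48.0, rel=1e-6)

    def test_distal_box_center_in_distal_third(self, desk_bone, desk_frame):
        mesh, _ = desk_bone
        box = fit_virtual_box(mesh, GuideSpec("distal", "standard"), desk_frame)
        # frame z runs distally; the box center must sit in the top third
        z_f = (mesh.vertices - desk_frame.origin) @ desk_frame.z_axis
        lo, hi = z_f.min(), z_f.max()
        assert hi - (hi - lo) / 3 <= box.center[2] <= hi

    def test_extended_box_splits_volume_in_half(self, cylinder_bone):
        mesh, frame = cylinder_bone
        box = fit_virtual_box(mesh, GuideSpec("mid-shaft", "extended"), frame)
        # voxel-count the boxed slab on each side of the opposite face plane
        pitch = 0.25
        z0, z1 = box.center[2] - box.half_extents[2], box.center[2] + box.half_extents[2]
        xs = np.arange(-12, 12, pitch)
        ys = np.arange(-12, 12, pitch)
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        inside = gx**2 + gy**2 <= 10.0**2  # cylinder cross-section
        above = inside & (gy > box.y_opposite)
        frac = above.sum() / inside.sum()
        assert frac == pytest.approx(0.5, abs=0.02)


class TestProjectGrid:
    def test_sphere_silhouette_area(self):
        sphere = trimesh.creation.icosphere(subdivisions=4, radius=10.0)
        box = VirtualBox(
            center=np.zeros(3),
            half_extents=np.array([14.0, 14.0, 12.0]),
            frame=world_frame(),
        )
        img = project_grid(box, sphere, grid_spacing=0.5)
        area = img.n_set * 0.5**2
        assert area == pytest.approx(np.pi * 100.0, rel=0.03)

    def test_halving_spacing_quadruples_count(self):
        sphere = trimesh.creation.icosphere(subdivisions=3, radius=10.0)
        box = VirtualBox(
            center=np.zeros(3),
            half_extents=np.array([14.0, 14.0, 12.0]),
            frame=world_frame(),
        )
        coarse = project_grid(box, sphere, grid_spacing=1.0)
        fine = project_grid(box, sphere, grid_spacing=0.5)
        assert fine.n_set == pytest.approx(4 * coarse.n_set, rel=0.05)

    def test_bone_outside_box_rejected(self):
        sphere = trimesh.creation.icosphere(subdivisions=2, radius=5.0)
        box = VirtualBox(
            center=np.array([100.0, 0, 0]),
            half_extents=np.array([10.0, 10.0, 10.0]),
            frame=world_frame(),
        )
        with pytest.raises(ValueError):
            project_grid(box, sphere, grid_spacing=1.0)


class TestCleanup:
    def test_erosion_of_square_matches_brute_force(self):
        mask = np.zeros((14, 14), dtype=bool)
        mask[2:12, 2:12] = True  # 10x10 filled square
        out = cleanup_standard(make_image(mask), erosion_radius_px=1)
        oracle = brute_force_disk_op(
            brute_force_disk_op(mask, 1, "erode"), 1, "erode"
        )
        oracle = brute_force_disk_op(oracle, 1, "dilate")  # opening after erosion
        np.testing.assert_array_equal(out.mask, oracle)
        # the erosion itself takes the 10x10 square to an 8x8 square
        eroded = brute_force_disk_op(mask, 1, "erode")
        assert eroded.sum() == 64
        assert eroded[3:11, 3:11].all()

    def test_cleanup_is_anti_extensive(self, rng):
        mask = np.zeros((30, 30), dtype=bool)
        for _ in range(6):  # union of random rectangles, survives erosion
            i, j = rng.integers(0, 18, 2)
            h, w = rng.integers(6, 12, 2)
            mask[i : i + h, j : j + w] = True
        out = cleanup_standard(make_image(mask), erosion_radius_px=2)
        assert not (out.mask & ~mask).any()
        assert out.mask.sum() <= mask.sum()

    def test_opening_idempotent_on_filled_rectangle(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[4:16, 3:17] = True
        out = cleanup_standard(make_image(mask), erosion_radius_px=0)
        out2 = cleanup_standard(out, erosion_radius_px=0)
        np.testing.assert_array_equal(out.mask, out2.mask)

    def test_vanishing_footprint_rejected(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[5, 5] = True
        with pytest.raises(ValueError):
            cleanup_standard(make_image(mask), erosion_radius_px=2)

    def test_dilation_matches_brute_force_and_flags_lateral(self):
        mask = np.zeros((14, 14), dtype=bool)
        mask[3:11, 3:11] = True  # 8x8 square
        out = cleanup_extended(make_image(mask), dilation_radius_px=1)
        oracle = brute_force_disk_op(mask, 1, "dilate")
        np.testing.assert_array_equal(out.mask, oracle)
        np.testing.assert_array_equal(out.lateral, oracle & ~mask)
        assert out.lateral.sum() == out.mask.sum() - mask.sum()

    def test_dilation_radius_zero_is_identity(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[2:6, 2:6] = True
        out = cleanup_extended(make_image(mask), dilation_radius_px=0)
        np.testing.assert_array_equal(out.mask, mask)
        assert not out.lateral.any()

    def test_dilation_to_lateral_border_rejected(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[2:8, 1:9] = True  # one px from the lateral borders
        with pytest.raises(ValueError):
            cleanup_extended(make_image(mask), dilation_radius_px=2)


class TestFootprint:
    def test_cylinder_footprint_lies_on_surface_at_radius(self, cylinder_bone):
        mesh, frame = cylinder_bone
        box = fit_virtual_box(mesh, GuideSpec("mid-shaft", "standard"), frame)
        img = cleanup_standard(project_grid(box, mesh, 0.5), 2)
        footprint, lateral = make_footprint(img, mesh, box)
        assert not lateral.any()
        radii = np.linalg.norm(footprint.vertices[:, :2], axis=1)
        np.testing.assert_allclose(radii, 10.0, atol=0.05)  # tessellation chord
        d = point_mesh_distance(footprint.vertices, mesh)
        assert d.max() < 1e-6

    def test_flat_slab_gives_planar_footprint(self):
        slab = trimesh.creation.box(extents=[30, 10, 30])
        box = VirtualBox(
            center=np.zeros(3),
            half_extents=np.array([12.0, 10.0, 12.0]),
            frame=world_frame(),
        )
        img = cleanup_standard(project_grid(box, slab, 1.0), 1)
        footprint, _ = make_footprint(img, slab, box)
        assert np.ptp(footprint.vertices[:, 1]) < 1e-9
        np.testing.assert_allclose(footprint.vertices[:, 1], 5.0, atol=1e-9)


class TestExtrude:
    @pytest.fixture(scope="class")
    def slab_footprint(self):
        slab = trimesh.creation.box(extents=[30, 10, 30])
        box = VirtualBox(
            center=np.zeros(3),
            half_extents=np.array([12.0, 10.0, 12.0]),
            frame=world_frame(),
        )
        img = cleanup_standard(project_grid(box, slab, 1.0), 1)
        footprint, _ = make_footprint(img, slab, box)
        return footprint, box

    def test_prism_volume(self, slab_footprint):
        footprint, box = slab_footprint
        guide = extrude_guide(footprint, box, depth=20.0)
        assert guide.volume == pytest.approx(footprint.area * 20.0, rel=1e-9)

    def test_watertight_with_two_faces_per_edge(self, slab_footprint):
        footprint, box = slab_footprint
        guide = extrude_guide(footprint, box, depth=20.0)
        assert guide.is_watertight
        _, counts = np.unique(guide.edges_sorted, axis=0, return_counts=True)
        assert set(counts) == {2}


class TestFullPipeline:
    def test_design_is_deterministic(self, desk_bone, desk_frame):
        mesh, _ = desk_bone
        a = build_guide(mesh, desk_frame, GuideSpec("proximal", "extended"))
        b = build_guide(mesh, desk_frame, GuideSpec("proximal", "extended"))
        assert np.array_equal(a["guide"].vertices, b["guide"].vertices)
        assert np.array_equal(a["guide"].faces, b["guide"].faces)

    def test_extended_contact_superset_of_standard(self, desk_bone, desk_frame):
        """The extended silhouette keeps every raw bone pixel the standard keeps."""
        mesh, _ = desk_bone
        for loc in ("distal", "mid-shaft", "proximal"):
            std = build_guide(mesh, desk_frame, GuideSpec(loc, "standard"))
            ext = build_guide(mesh, desk_frame, GuideSpec(loc, "extended"))
            n_contact_std = (~std["lateral"]).sum()
            n_contact_ext = (~ext["lateral"]).sum()
            assert n_contact_ext > n_contact_std
            assert ext["lateral"].sum() > 0

    def test_extended_lateral_wall_reaches_split_plane(self, desk_bone, desk_frame):
        mesh, _ = desk_bone
        ext = build_guide(mesh, desk_frame, GuideSpec("mid-shaft", "extended"))
        fp_frame = ext["footprint"].copy()
        fp_frame.apply_transform(desk_frame.from_world())
        lateral_y = fp_frame.vertices[ext["lateral"], 1]
        np.testing.assert_allclose(lateral_y, ext["box"].y_opposite, atol=1e-8)
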