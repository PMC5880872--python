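"""Segmentation, surface extraction and double-contour point sets.

The measurement chain starts from the reference volume (bone plus guides in
their planned pose, one connected plastic object in the image): the object
is segmented by threshold-connected region growing with hole filling and a
short curvature-regularized boundary refinement, an iso-surface is
extracted, and the surface is decimated into a *double-contour* point set —
paired points just inside and just outside the surface carrying the gray
values sampled from the reference image.  Clipping then splits this set
into the five registration groups: distal and proximal bone (the parts not
covered by guides) and one group per guide (excluding points close to the
bone surface, where guide and bone merge without contrast).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import trimesh
from scipy import ndimage
from skimage.measure import marching_cubes

from .meshutil import point_mesh_distance, sample_surface
from .pose_error import AnatomicFrame
from .volume import VoxelVolume

__all__ = [
    "SegmentationMask",
    "DoubleContourPointSet",
    "segment",
    "extract_surface",
    "build_double_contour",
    "clip_groups",
]


@dataclass
class SegmentationMask:
    """Binary object mask sharing its grid with the source volume."""

    mask: np.ndarray
    spacing: float
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.origin = np.asarray(self.origin, dtype=float)

    def save(self, path) -> None:
        """Write the mask as a uint8 volume (NIfTI/MetaImage by extension)."""
        VoxelVolume(self.mask.astype(np.uint8), self.spacing, self.origin).save(path)


def segment(
    volume: VoxelVolume,
    seed_point: np.ndarray,
    low_thr: float,
    high_thr: float,
    refine_iterations: int = 10,
    curvature_weight: float = 0.2,
) -> SegmentationMask:
    """Threshold-connected region growing, hole filling, boundary refinement.

    Region growing keeps the face-connected component of the threshold band
    containing the seed; holes are filled; then a fixed number of
    curvature-regularized refinement iterations trade a graded data term
    (how far a voxel's value is outside the band) against a local smoothness
    term.  On clean two-intensity data the refinement is an exact no-op, so
    the result equals the voxelized truth.
    """
    band = (volume.data >= low_thr) & (volume.data <= high_thr)
    seed_idx = tuple(np.round(volume.world_to_index(seed_point)[0]).astype(int))
    if any(i < 0 or i >= s for i, s in zip(seed_idx, volume.shape)):
        raise ValueError("seed point outside the volume")
    if not band[seed_idx]:
        raise ValueError("seed point is not inside the threshold band")

    def grow(m: np.ndarray) -> np.ndarray:
        labels, _ = ndimage.label(m)
        lab = labels[seed_idx]
        if lab == 0:
            raise ValueError("seed lost during refinement")
        return ndimage.binary_fill_holes(labels == lab)

    mask = grow(band)
    if refine_iterations > 0 and curvature_weight > 0:
        bandwidth = high_thr - low_thr
        gap = np.maximum(low_thr - volume.data, volume.data - high_thr)
        data_term = np.where(
            band, 1.0, -np.minimum(gap / (0.1 * bandwidth), 1.0)
        )
        w = curvature_weight
        for _ in range(refine_iterations):
            smooth = ndimage.uniform_filter(mask.astype(float), size=3)
            score = (1.0 - w) * data_term + w * (2.0 * smooth - 1.0)
            new_mask = score > 0
            if np.array_equal(new_mask, mask):
                break
            mask = new_mask
        mask = grow(mask)
    return SegmentationMask(mask, volume.spacing, volume.origin)


def extract_surface(
    mask: SegmentationMask, smooth_sigma: float = 0.7
) -> trimesh.Trimesh:
    """Marching-cubes iso-surface of the mask at the 0.5 level, in world mm.

    The binary mask is lightly Gaussian-smoothed (sigma in voxels) before
    extraction; this removes the staircase bias of a binary iso-surface at
    negligible shrinkage for the curvatures present here.
    """
    if not mask.mask.any():
        raise ValueError("cannot extract a surface from an empty mask")
    pad = 2
    field = np.pad(mask.mask.astype(float), pad)
    if smooth_sigma > 0:
        field = ndimage.gaussian_filter(field, smooth_sigma)
    verts, faces, _, _ = marching_cubes(field, level=0.5)
    verts = (verts - pad) * mask.spacing + mask.origin
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if mesh.is_watertight and mesh.volume < 0:
        mesh.invert()
    return mesh


@dataclass
class DoubleContourPointSet:
    """Paired inner/outer contour points with reference gray values.

    Each surface point ``p`` with outward unit normal ``n`` spawns an inner
    point ``p − offset·n`` and an outer point ``p + offset·n``; the gray
    values of the source image at those positions are the registration
    template.  ``group`` names the clipped subset this set represents.
    """

    surface_points: np.ndarray  # (n, 3) mm
    normals: np.ndarray  # (n, 3) unit outward
    offset: float  # mm
    inner_gray: np.ndarray  # (n,)
    outer_gray: np.ndarray  # (n,)
    group: str = "all"

    def __len__(self) -> int:
        return len(self.surface_points)

    @property
    def inner_points(self) -> np.ndarray:
        return self.surface_points - self.offset * self.normals

    @property
    def outer_points(self) -> np.ndarray:
        return self.surface_points + self.offset * self.normals

    @property
    def all_points(self) -> np.ndarray:
        """Inner then outer points, the moving point set for registration."""
        return np.vstack([self.inner_points, self.outer_points])

    @property
    def template_gray(self) -> np.ndarray:
        return np.concatenate([self.inner_gray, self.outer_gray])

    @property
    def centroid(self) -> np.ndarray:
        return self.surface_points.mean(axis=0)

    def subset(self, idx: np.ndarray, group: str | None = None) -> "DoubleContourPointSet":
        return DoubleContourPointSet(
            surface_points=self.surface_points[idx],
            normals=self.normals[idx],
            offset=self.offset,
            inner_gray=self.inner_gray[idx],
            outer_gray=self.outer_gray[idx],
            group=group if group is not None else self.group,
        )

    @staticmethod
    def merge(sets: list["DoubleContourPointSet"], group: str) -> "DoubleContourPointSet":
        offsets = {s.offset for s in sets}
        if len(offsets) != 1:
            raise ValueError("cannot merge sets with different offsets")
        return DoubleContourPointSet(
            surface_points=np.vstack([s.surface_points for s in sets]),
            normals=np.vstack([s.normals for s in sets]),
            offset=offsets.pop(),
            inner_gray=np.concatenate([s.inner_gray for s in sets]),
            outer_gray=np.concatenate([s.outer_gray for s in sets]),
            group=group,
        )


def _trilinear(volume: VoxelVolume, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    idx = volume.world_to_index(points)
    inside = np.all((idx >= 0) & (idx <= np.array(volume.shape) - 1), axis=1)
    vals = ndimage.map_coordinates(
        volume.data, idx.T, order=1, mode="nearest"
    )
    return vals, inside


def build_double_contour(
    mesh: trimesh.Trimesh,
    source: VoxelVolume,
    offset: float = 0.33,
    sampling_step: float = 1.0,
    seed: int = 0,
) -> DoubleContourPointSet:
    """Decimate a surface to ~``sampling_step`` spacing and sample gray pairs.

    The default offset of one voxel each side maximizes the gray contrast
    between the inner and outer contour at minimal blur overlap.  Points
    whose inner or outer partner falls outside the source volume are
    dropped with a warning.
    """
    points, normals = sample_surface(mesh, sampling_step, seed=seed)
    inner = points - offset * normals
    outer = points + offset * normals
    in_vals, in_ok = _trilinear(source, inner)
    out_vals, out_ok = _trilinear(source, outer)
    keep = in_ok & out_ok
    if not keep.any():
        raise ValueError("all double-contour points fall outside the volume")
    if not keep.all():
        warnings.warn(
            f"dropped {int((~keep).sum())} double-contour points outside the volume",
            stacklevel=2,
        )
    return DoubleContourPointSet(
        surface_points=points[keep],
        normals=normals[keep],
        offset=offset,
        inner_gray=in_vals[keep],
        outer_gray=out_vals[keep],
    )


def clip_groups(
    reference_set: DoubleContourPointSet,
    bone: trimesh.Trimesh,
    guides: dict[str, trimesh.Trimesh],
    frame: AnatomicFrame,
    surface_tol: float = 0.7,
    bone_clearance: float = 3.0,
    exclusion_distance: float = 2.0,
) -> dict[str, DoubleContourPointSet]:
    """Split the assembly contour into bone and guide registration groups.

    Bone points within ``bone_clearance`` of any guide are discarded (near
    the guide rim the image carries no bone/guide contrast); the remaining
    bone points are split into distal and proximal groups at the anatomic
    mid-plane (frame-z of the bone centroid).  Guide points closer than
    ``exclusion_distance`` to the bone surface are discarded for the same
    reason.  ``surface_tol`` decides which planned surface a contour point
    belongs to.
    """
    pts = reference_set.surface_points
    cutoff = max(surface_tol, bone_clearance, exclusion_distance) + 0.5
    d_bone = point_mesh_distance(pts, bone, max_distance=cutoff)
    d_guides = {
        loc: point_mesh_distance(pts, g, max_distance=cutoff)
        for loc, g in guides.items()
    }

    groups: dict[str, DoubleContourPointSet] = {}
    on_bone = d_bone < surface_tol
    clear = np.ones(len(pts), dtype=bool)
    for d in d_guides.values():
        clear &= d > bone_clearance
    bone_pts = on_bone & clear
    z_f = (pts - frame.origin) @ frame.z_axis
    z_mid = float((np.asarray(bone.center_mass) - frame.origin) @ frame.z_axis)
    for name, sel in [
        ("bone_distal", bone_pts & (z_f > z_mid)),
        ("bone_proximal", bone_pts & (z_f <= z_mid)),
    ]:
        if not sel.any():
            raise ValueError(f"clipping produced an empty group: {name}")
        groups[name] = reference_set.subset(sel, group=name)

    for loc, d_g in d_guides.items():
        sel = (d_g < surface_tol) & (d_bone >= exclusion_distance)
        name = f"guide_{loc}"
        if not sel.any():
            raise ValueError(f"clipping produced an empty group: {name}")
        groups[name] = reference_set.subset(sel, group=name)
    return groups
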