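"""Patient-specific guide CAD: box, silhouette projection, footprint, extrusion.

A guide is a printed mold whose inner surface is the negative of a patch of
the bone.  The design pipeline mirrors the interactive CAD workflow used
clinically, automated from the anatomic frame:

1. a virtual box is fitted around the target surface — 20% of the bone
   length, centered on the requested third (distal / mid-shaft / proximal),
   with the projection face on the volar (+y) side;
2. a regular grid of points on the projection face is ray-cast along −y,
   producing a 2D binary silhouette image of the boxed bone;
3. the silhouette is cleaned up — eroded then opened for the standard
   design, or dilated for the extended design, whose extra "lateral" pixels
   will wrap around the side of the bone;
4. set pixels are projected onto the bone surface (first hit from the face)
   to form the footprint; lateral pixels land on the opposite box face,
   which for the extended design sits at the plane splitting the boxed bone
   volume 50/50 in the coronal plane;
5. the footprint is extruded 20 mm along the face normal into a closed,
   watertight guide solid.

All steps are deterministic: the same bone and spec yield an identical mesh.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
import trimesh
from shapely.geometry import LineString
from skimage.morphology import dilation, disk, erosion, opening

from .meshutil import even_odd_contains, slice_polygons
from .pose_error import AnatomicFrame
from .transforms import transform_points

__all__ = [
    "GuideSpec",
    "VirtualBox",
    "ProjectionImage",
    "fit_virtual_box",
    "project_grid",
    "cleanup_standard",
    "cleanup_extended",
    "make_footprint",
    "extrude_guide",
    "build_guide",
]


@dataclass(frozen=True)
class GuideSpec:
    """Which guide to build and its fixed design parameters."""

    location: str  # distal | mid-shaft | proximal
    design: str  # standard | extended
    length_fraction: float = 0.20  # of bone length
    extrusion_depth: float = 20.0  # mm
    coronal_split_fraction: float = 0.5  # extended design only

    def validate(self) -> None:
        from .phantom import DESIGNS, LOCATIONS

        if self.location not in LOCATIONS:
            raise ValueError(f"unknown location {self.location!r}")
        if self.design not in DESIGNS:
            raise ValueError(f"unknown design {self.design!r}")
        if not 0 < self.length_fraction < 1:
            raise ValueError("length_fraction must be in (0, 1)")
        if self.extrusion_depth <= 0:
            raise ValueError("extrusion_depth must be positive")
        if not 0 < self.coronal_split_fraction < 1:
            raise ValueError("coronal_split_fraction must be in (0, 1)")


@dataclass(frozen=True)
class VirtualBox:
    """Axis-aligned box in the anatomic frame enclosing the target surface.

    ``center`` and ``half_extents`` live in frame coordinates; ``frame``
    maps them to the world.  The projection face is the +y (volar) face and
    rays are cast along −y; the extrusion direction is the outward face
    normal (+y in frame coordinates).
    """

    center: np.ndarray  # frame coords
    half_extents: np.ndarray
    frame: AnatomicFrame

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.half_extents) <= 0):
            raise ValueError("half_extents must be positive")

    @property
    def y_face(self) -> float:
        """Frame-y coordinate of the projection face."""
        return float(self.center[1] + self.half_extents[1])

    @property
    def y_opposite(self) -> float:
        return float(self.center[1] - self.half_extents[1])

    @property
    def extrusion_direction(self) -> np.ndarray:
        """World-space unit vector of the +y face normal."""
        return self.frame.y_axis.copy()


def _bone_in_frame(bone: trimesh.Trimesh, frame: AnatomicFrame) -> trimesh.Trimesh:
    bf = bone.copy()
    bf.apply_transform(frame.from_world())
    return bf


def _coronal_split_plane(
    bone_f: trimesh.Trimesh,
    z_lo: float,
    z_hi: float,
    fraction: float,
    pitch: float = 0.5,
) -> float:
    """Frame-y plane below which (dorsally) 1-``fraction`` of the boxed bone
    volume lies, found by voxel counting on the z-slab.  With fraction 0.5
    the +y (volar) side of the plane holds half the boxed bone volume."""
    lo, hi = bone_f.bounds
    zs = np.arange(z_lo + pitch / 2, z_hi, pitch)
    polys = slice_polygons(bone_f, zs)
    ys = np.arange(lo[1] + pitch / 2, hi[1], pitch)
    xs = np.arange(lo[0] + pitch / 2, hi[0], pitch)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    col = np.zeros(len(ys))
    for plist in polys:
        if plist:
            inside = even_odd_contains(plist, gx.ravel(), gy.ravel()).reshape(gx.shape)
            col += inside.sum(axis=0)
    total = col.sum()
    if total == 0:
        raise ValueError("no bone volume inside the box slab")
    cum = np.cumsum(col) / total
    y_edges = ys + pitch / 2  # cum[k] = fraction of volume below this edge
    return float(np.interp(1.0 - fraction, cum, y_edges))


def fit_virtual_box(
    bone: trimesh.Trimesh,
    spec: GuideSpec,
    frame: AnatomicFrame,
    margin: float = 2.0,
) -> VirtualBox:
    """Automated box placement from the anatomic frame.

    The box spans ``length_fraction`` of the bone length along z, centered
    on the requested third (equal one-third division of the bone length,
    distal at high frame-z).  Lateral extents cover the boxed bone cross
    section with a margin.  For the extended design the −y (dorsal) face is
    moved to the coronal plane that splits the boxed bone volume 50/50.
    """
    spec.validate()
    bone_f = _bone_in_frame(bone, frame)
    lo, hi = bone_f.bounds
    length = hi[2] - lo[2]
    thirds = {
        "proximal": (lo[2], lo[2] + length / 3),
        "mid-shaft": (lo[2] + length / 3, lo[2] + 2 * length / 3),
        "distal": (lo[2] + 2 * length / 3, hi[2]),
    }
    t_lo, t_hi = thirds[spec.location]
    z_center = 0.5 * (t_lo + t_hi)
    hz = 0.5 * spec.length_fraction * length
    z0, z1 = z_center - hz, z_center + hz
    if z0 < lo[2] - 1e-6 or z1 > hi[2] + 1e-6:
        raise ValueError("guide span falls outside the bone extent")

    verts = bone_f.vertices
    # lateral extents come from a slightly expanded slab: surface bumps that
    # peak just outside [z0, z1] still widen the silhouette inside the box
    slab = verts[(verts[:, 2] >= z0 - margin) & (verts[:, 2] <= z1 + margin)]
    if len(slab) == 0:
        raise ValueError("no bone surface inside the requested box span")
    x0, x1 = slab[:, 0].min() - margin, slab[:, 0].max() + margin
    y_top = slab[:, 1].max() + margin
    if spec.design == "extended":
        y_bot = _coronal_split_plane(bone_f, z0, z1, spec.coronal_split_fraction)
    else:
        y_bot = slab[:, 1].min() - margin
    center = np.array([0.5 * (x0 + x1), 0.5 * (y_top + y_bot), z_center])
    half = np.array([0.5 * (x1 - x0), 0.5 * (y_top - y_bot), hz])
    return VirtualBox(center=center, half_extents=half, frame=frame)


@dataclass
class ProjectionImage:
    """Binary silhouette of the boxed bone seen from the projection face.

    Row index v maps to frame-z, column index u to frame-x.  ``hit_y``
    stores the frame-y of the first ray-bone intersection from the face
    (NaN where the ray misses); ``lateral`` flags pixels added by the
    extended design's dilation, whose footprint vertices land on the
    opposite box face.
    """

    mask: np.ndarray  # (H, W) bool
    hit_y: np.ndarray  # (H, W) float
    lateral: np.ndarray  # (H, W) bool
    grid_spacing: float
    u0: float  # frame-x of column 0
    v0: float  # frame-z of row 0
    box: VirtualBox

    @property
    def n_set(self) -> int:
        return int(self.mask.sum())

    def pixel_uv(self) -> tuple[np.ndarray, np.ndarray]:
        """Frame-x (u) and frame-z (v) coordinates of all pixels."""
        H, W = self.mask.shape
        u = self.u0 + np.arange(W) * self.grid_spacing
        v = self.v0 + np.arange(H) * self.grid_spacing
        return u, v

    def replace(self, **kw) -> "ProjectionImage":
        data = {
            "mask": self.mask,
            "hit_y": self.hit_y,
            "lateral": self.lateral,
            "grid_spacing": self.grid_spacing,
            "u0": self.u0,
            "v0": self.v0,
            "box": self.box,
        }
        data.update(kw)
        return ProjectionImage(**data)


def project_grid(
    box: VirtualBox, bone: trimesh.Trimesh, grid_spacing: float = 0.5
) -> ProjectionImage:
    """Ray-cast a regular grid from the +y box face along −y onto the bone.

    A pixel is set iff its ray intersects the bone inside the box; the first
    (largest-y) intersection is recorded for the later footprint projection.
    """
    if grid_spacing <= 0:
        raise ValueError("grid_spacing must be positive")
    bone_f = _bone_in_frame(bone, box.frame)
    cx, cy, cz = box.center
    hx, hy, hz = box.half_extents
    W = max(int(np.floor(2 * hx / grid_spacing)) + 1, 2)
    H = max(int(np.floor(2 * hz / grid_spacing)) + 1, 2)
    u = cx - (W - 1) / 2 * grid_spacing + np.arange(W) * grid_spacing
    v = cz - (H - 1) / 2 * grid_spacing + np.arange(H) * grid_spacing
    y_hi, y_lo = box.y_face, box.y_opposite

    mask = np.zeros((H, W), dtype=bool)
    hit_y = np.full((H, W), np.nan)
    slices = slice_polygons(bone_f, v)
    for i, plist in enumerate(slices):
        if not plist:
            continue
        for j, uj in enumerate(u):
            best = -np.inf
            for poly in plist:
                bx0, _, bx1, _ = poly.bounds
                if uj < bx0 or uj > bx1:
                    continue
                seg = poly.intersection(LineString([(uj, y_hi), (uj, y_lo)]))
                if seg.is_empty:
                    continue
                ys = [c[1] for geom in getattr(seg, "geoms", [seg]) for c in geom.coords]
                if ys:
                    best = max(best, max(ys))
            if np.isfinite(best):
                mask[i, j] = True
                hit_y[i, j] = best
    if not mask.any():
        raise ValueError("no ray intersects the bone: box is misplaced")
    return ProjectionImage(
        mask=mask,
        hit_y=hit_y,
        lateral=np.zeros_like(mask),
        grid_spacing=grid_spacing,
        u0=float(u[0]),
        v0=float(v[0]),
        box=box,
    )


def cleanup_standard(img: ProjectionImage, erosion_radius_px: int = 2) -> ProjectionImage:
    """Erode away silhouette-edge pixels, then smooth with a binary opening.

    Pixels that project onto the steep edge of the bone would give the mold
    an unstable, near-vertical contact; erosion removes them and the opening
    smooths the remaining contour.  The result is a subset of the input.
    """
    if not img.mask.any():
        raise ValueError("empty projection image")
    out = img.mask
    if erosion_radius_px > 0:
        out = erosion(out, disk(erosion_radius_px))
    elem = disk(max(erosion_radius_px, 1))
    out = opening(out, elem)
    if not out.any():
        raise ValueError("guide footprint vanished during cleanup")
    return img.replace(mask=out, lateral=np.zeros_like(out))


def cleanup_extended(img: ProjectionImage, dilation_radius_px: int = 2) -> ProjectionImage:
    """Dilate the silhouette; added pixels become the lateral wall.

    The added pixels miss the bone when projected and are flagged
    ``lateral`` — their footprint vertices will drop to the opposite box
    face, wrapping the guide around the side of the bone.
    """
    if not img.mask.any():
        raise ValueError("empty projection image")
    if dilation_radius_px == 0:
        return img.replace(lateral=np.zeros_like(img.mask))
    out = dilation(img.mask, disk(dilation_radius_px))
    # the bone crosses the box in z, so the first/last rows legitimately hold
    # silhouette pixels; only lateral (u) border contact means the box is too
    # narrow for the extension
    if (out[:, 0] | out[:, -1]).any():
        raise ValueError("dilation reached the lateral image border: box too tight")
    lateral = out & ~img.mask
    return img.replace(mask=out, lateral=lateral)


def make_footprint(
    img: ProjectionImage, bone: trimesh.Trimesh, box: VirtualBox
) -> tuple[trimesh.Trimesh, np.ndarray]:
    """Project set pixels into 3D and triangulate them into the footprint.

    Non-lateral pixels land at their first ray-bone intersection; lateral
    pixels land on the opposite box face.  Grid connectivity triangulates
    the height field; triangles are oriented with +y (away from the bone).
    Returns the open footprint mesh in world coordinates and a per-vertex
    lateral flag.
    """
    H, W = img.mask.shape
    u, v = img.pixel_uv()
    idx = -np.ones((H, W), dtype=int)
    verts_f = []
    lateral_flags = []
    for i in range(H):
        for j in range(W):
            if not img.mask[i, j]:
                continue
            if img.lateral[i, j] or not np.isfinite(img.hit_y[i, j]):
                y = box.y_opposite
                lateral_flags.append(True)
            else:
                y = img.hit_y[i, j]
                lateral_flags.append(False)
            idx[i, j] = len(verts_f)
            verts_f.append([u[j], y, v[i]])
    verts_f = np.asarray(verts_f, dtype=float)

    faces = []
    for i in range(H - 1):
        for j in range(W - 1):
            corners = [idx[i, j], idx[i, j + 1], idx[i + 1, j + 1], idx[i + 1, j]]
            present = [c for c in corners if c >= 0]
            if len(present) == 4:
                faces.append([corners[0], corners[1], corners[2]])
                faces.append([corners[0], corners[2], corners[3]])
            elif len(present) == 3:
                faces.append(present)
    if not faces:
        raise ValueError("footprint has no triangles")
    faces = np.asarray(faces, dtype=int)
    # orient every triangle with positive frame-y normal (height field)
    tv = verts_f[faces]
    ny = np.cross(tv[:, 1] - tv[:, 0], tv[:, 2] - tv[:, 0])[:, 1]
    flip = ny < 0
    faces[flip] = faces[flip][:, ::-1]

    verts_w = transform_points(box.frame.to_world(), verts_f)
    mesh = trimesh.Trimesh(vertices=verts_w, faces=faces, process=False)
    edges = mesh.edges_sorted
    _, counts = np.unique(edges, axis=0, return_counts=True)
    if counts.max() > 2:
        raise ValueError("footprint triangulation is non-manifold")
    return mesh, np.asarray(lateral_flags, dtype=bool)


def extrude_guide(
    footprint: trimesh.Trimesh, box: VirtualBox, depth: float = 20.0
) -> trimesh.Trimesh:
    """Extrude the footprint along the face normal into a watertight solid.

    The solid is bounded by the bone-conforming footprint (inner surface),
    its translate by ``depth`` along the extrusion direction, and side walls
    along the footprint boundary.
    """
    if depth <= 0:
        raise ValueError("extrusion depth must be positive")
    d = box.extrusion_direction * depth
    n = len(footprint.vertices)
    verts = np.vstack([footprint.vertices, footprint.vertices + d])
    faces = [footprint.faces[:, ::-1], footprint.faces + n]
    # boundary edges -> side walls
    edges = footprint.edges_sorted
    uniq, inv, counts = np.unique(edges, axis=0, return_counts=True, return_inverse=True)
    boundary = uniq[counts == 1]
    walls = []
    for a, b in boundary:
        walls.append([a, b, b + n])
        walls.append([a, b + n, a + n])
    faces.append(np.asarray(walls, dtype=int))
    mesh = trimesh.Trimesh(vertices=verts, faces=np.vstack(faces), process=False)
    trimesh.repair.fix_normals(mesh)
    if mesh.volume < 0:
        mesh.invert()
    if not mesh.is_watertight:
        raise ValueError("extruded guide is not watertight")
    return mesh


def build_guide(
    bone: trimesh.Trimesh,
    frame: AnatomicFrame,
    spec: GuideSpec,
    grid_spacing: float = 0.5,
    morphology_radius_px: int = 2,
) -> dict:
    """Run the whole design pipeline; returns guide, footprint, flags, box."""
    box = fit_virtual_box(bone, spec, frame)
    img = project_grid(box, bone, grid_spacing)
    if spec.design == "standard":
        img = cleanup_standard(img, morphology_radius_px)
    else:
        img = cleanup_extended(img, morphology_radius_px)
    footprint, lateral = make_footprint(img, bone, box)
    guide = extrude_guide(footprint, box, spec.extrusion_depth)
    return {
        "guide": guide,
        "footprint": footprint,
        "lateral": lateral,
        "box": box,
        "image": img,
    }
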