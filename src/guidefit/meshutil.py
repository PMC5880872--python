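"""Mesh geometry helpers: slicing, exact point-to-surface distance, sampling.

These are the small geometric primitives the rest of the pipeline leans on:

* cross-section polygons of a closed mesh along z (used by the voxelizer and
  the guide-design silhouette projection),
* exact point-to-triangle-mesh distance with KD-tree candidate pruning
  (used for clipping contour points near guide/bone surfaces),
* deterministic uniform surface sampling at a target point spacing.
"""

from __future__ import annotations

import numpy as np
import shapely
import trimesh
from scipy.spatial import cKDTree

__all__ = [
    "slice_polygons",
    "point_mesh_distance",
    "sample_surface",
    "closest_point_triangles",
]


def slice_polygons(mesh: trimesh.Trimesh, z_values: np.ndarray) -> list:
    """Cross-section loops of a mesh at each z (world x-y coordinates).

    Returns a list (one entry per z) of lists of shapely Polygons, one per
    closed boundary loop, with *even-odd* semantics: a point is inside the
    solid iff it falls inside an odd number of loops (holes are loops
    contained in an outer loop).  Empty list where the plane misses the
    mesh.
    """
    z_values = np.asarray(z_values, dtype=float)
    sections = mesh.section_multiplane(
        plane_origin=[0.0, 0.0, 0.0], plane_normal=[0.0, 0.0, 1.0], heights=z_values
    )
    out = []
    for sec in sections:
        if sec is None:
            out.append([])
        else:
            out.append([p for p in sec.polygons_closed if p is not None])
    return out


def even_odd_contains(loops: list, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Even-odd inside test of points against a list of boundary loops."""
    inside = np.zeros(np.shape(xs), dtype=bool)
    for loop in loops:
        inside ^= shapely.contains_xy(loop, xs, ys)
    return inside


def _dot(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.einsum("ij,ij->i", a, b)


def closest_point_triangles(
    points: np.ndarray, tri_a: np.ndarray, tri_b: np.ndarray, tri_c: np.ndarray
) -> np.ndarray:
    """Closest point on triangle (a,b,c) for each (point, triangle) pair.

    Vectorized region classification (vertex / edge / interior) following the
    standard closest-point-on-triangle construction; all inputs are (n, 3).
    """
    p = np.asarray(points, dtype=float)
    a, b, c = (np.asarray(x, dtype=float) for x in (tri_a, tri_b, tri_c))
    ab, ac, ap = b - a, c - a, p - a
    d1, d2 = _dot(ab, ap), _dot(ac, ap)
    bp = p - b
    d3, d4 = _dot(ab, bp), _dot(ac, bp)
    cp = p - c
    d5, d6 = _dot(ab, cp), _dot(ac, cp)
    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2

    with np.errstate(divide="ignore", invalid="ignore"):
        denom = va + vb + vc
        denom = np.where(denom == 0, 1.0, denom)
        v_face = vb / denom
        w_face = vc / denom
        closest = a + ab * v_face[:, None] + ac * w_face[:, None]

        # edge BC
        den_bc = (d4 - d3) + (d5 - d6)
        w_bc = np.where(den_bc == 0, 0.0, (d4 - d3) / np.where(den_bc == 0, 1.0, den_bc))
        m = (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)
        closest[m] = (b + (c - b) * w_bc[:, None])[m]

        # edge AC
        den_ac = d2 - d6
        w_ac = np.where(den_ac == 0, 0.0, d2 / np.where(den_ac == 0, 1.0, den_ac))
        m = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
        closest[m] = (a + ac * w_ac[:, None])[m]

        # vertex C
        m = (d6 >= 0) & (d5 <= d6)
        closest[m] = c[m]

        # edge AB
        den_ab = d1 - d3
        v_ab = np.where(den_ab == 0, 0.0, d1 / np.where(den_ab == 0, 1.0, den_ab))
        m = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
        closest[m] = (a + ab * v_ab[:, None])[m]

        # vertex B
        m = (d3 >= 0) & (d4 <= d3)
        closest[m] = b[m]

        # vertex A
        m = (d1 <= 0) & (d2 <= 0)
        closest[m] = a[m]
    return closest


def point_mesh_distance(
    points: np.ndarray,
    mesh: trimesh.Trimesh,
    max_edge: float = 2.0,
    max_distance: float | None = None,
    chunk: int = 2000,
) -> np.ndarray:
    """Exact unsigned distance from each point to the mesh surface.

    Long triangles are first subdivided to ``max_edge`` (the surface, hence
    every distance, is unchanged); a KD-tree over the subdivided vertices
    gives a tight upper bound per point, and only triangles whose bounding
    sphere can beat that bound are evaluated exactly.  The result equals a
    brute-force scan over all triangles.  When ``max_distance`` is given,
    points provably farther than it get a lower bound (still ``>
    max_distance``) instead of the exact value.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    verts, faces = trimesh.remesh.subdivide_to_size(
        mesh.vertices, mesh.faces, max_edge=max_edge
    )
    tris = verts[faces]  # (m, 3, 3)
    centroids = tris.mean(axis=1)
    radii = np.linalg.norm(tris - centroids[:, None, :], axis=2).max(axis=1)
    rmax = float(radii.max())
    vtree = cKDTree(verts)
    ctree = cKDTree(centroids)
    ub, _ = vtree.query(points)  # a vertex is on the surface: true dist <= ub
    d_cent, _ = ctree.query(points)
    lb = np.maximum(d_cent - rmax, 0.0)

    best = ub.copy()
    if max_distance is not None:
        todo = np.flatnonzero(lb <= max_distance)
        best[lb > max_distance] = lb[lb > max_distance]
    else:
        todo = np.arange(len(points))
    for start in range(0, len(todo), chunk):
        sel = todo[start : start + chunk]
        cand = ctree.query_ball_point(points[sel], ub[sel] + rmax + 1e-12)
        counts = np.array([len(c) for c in cand])
        if counts.sum() == 0:
            continue
        pt_idx = np.repeat(sel, counts)
        tri_idx = np.concatenate([np.asarray(c, dtype=int) for c in cand])
        cp = closest_point_triangles(
            points[pt_idx], tris[tri_idx, 0], tris[tri_idx, 1], tris[tri_idx, 2]
        )
        d = np.linalg.norm(points[pt_idx] - cp, axis=1)
        np.minimum.at(best, pt_idx, d)
    return best


def sample_surface(
    mesh: trimesh.Trimesh, step: float, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform random surface samples at ~``step`` mm spacing with normals.

    The sample count is ``area / step**2`` so the mean inter-point spacing
    matches the requested step; sampling is seeded and deterministic.
    """
    if step <= 0:
        raise ValueError("sampling step must be positive")
    n = max(int(round(mesh.area / step**2)), 16)
    points, face_idx = trimesh.sample.sample_surface(mesh, n, seed=int(seed))
    normals = mesh.face_normals[face_idx]
    return np.asarray(points, dtype=float), np.asarray(normals, dtype=float)
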