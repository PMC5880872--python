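"""Guide positioning error metrics: error matrices, 6-DOF decomposition,
anatomic frame, mTRE and Hausdorff distances.

Given the rigid registration of the bone (``M_R``) and of a guide
(``M_G``) to a pose image, the error matrix

    E = M_R^-1 · M_G

brings the guide from its planned to its actual position relative to the
bone.  E is decomposed about the guide centroid ``c`` as

    E = T(c + Δ) · Rz · Rx · Ry · T(-c)

yielding three translation errors (Δx, Δy, Δz, mm) and three rotation
errors (Δφx, Δφy, Δφz, degrees), summarized as ΔT = ‖Δ‖ and ΔR = ‖Δφ‖.
The mean target registration error (mTRE) is the mean displacement of the
guide's clipped contour points under E.  Errors are reported in a
right-handed anatomic frame: z along the bone's principal axis of inertia
(pointing distally), x toward the styloid process, y completing the triad.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .transforms import decompose_rigid, is_rigid, transform_points

__all__ = [
    "AnatomicFrame",
    "PoseError",
    "anatomic_frame",
    "error_matrix",
    "decompose",
    "to_anatomic",
    "mtre",
    "hausdorff",
]


@dataclass(frozen=True)
class AnatomicFrame:
    """Right-handed orthonormal bone coordinate system (axes in world coords)."""

    origin: np.ndarray
    x_axis: np.ndarray  # toward the styloid process
    y_axis: np.ndarray
    z_axis: np.ndarray  # principal inertia axis, pointing distally

    def __post_init__(self) -> None:
        R = self.rotation
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("frame axes must be orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("frame must be right-handed")

    @property
    def rotation(self) -> np.ndarray:
        """3x3 with columns x, y, z (frame -> world rotation)."""
        return np.column_stack([self.x_axis, self.y_axis, self.z_axis])

    def to_world(self) -> np.ndarray:
        """4x4 mapping frame coordinates to world coordinates."""
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = self.origin
        return M

    def from_world(self) -> np.ndarray:
        M = np.eye(4)
        M[:3, :3] = self.rotation.T
        M[:3, 3] = -self.rotation.T @ self.origin
        return M


@dataclass
class PoseError:
    """Six-DOF positioning error about a centroid, plus derived summaries."""

    dx: float
    dy: float
    dz: float
    dphix: float  # degrees
    dphiy: float
    dphiz: float
    centroid: np.ndarray
    mtre: float | None = None

    @property
    def translation(self) -> np.ndarray:
        return np.array([self.dx, self.dy, self.dz])

    @property
    def rotation(self) -> np.ndarray:
        return np.array([self.dphix, self.dphiy, self.dphiz])

    @property
    def dT(self) -> float:
        return float(np.linalg.norm(self.translation))

    @property
    def dR(self) -> float:
        return float(np.linalg.norm(self.rotation))


def anatomic_frame(
    bone: trimesh.Trimesh, styloid_tip: np.ndarray
) -> AnatomicFrame:
    """Anatomic frame from the bone solid's inertia and the styloid landmark.

    z is the principal axis with the smallest moment of inertia (the long
    axis of the bone, uniform density), with its sign chosen so it points
    toward the styloid (distal) end; x is the component of the
    centroid-to-styloid direction orthogonal to z; y = z × x.
    """
    if not bone.is_watertight:
        raise ValueError("anatomic frame requires a closed bone mesh")
    centroid = np.asarray(bone.center_mass, dtype=float)
    inertia = bone.moment_inertia
    eigval, eigvec = np.linalg.eigh(inertia)
    z = eigvec[:, int(np.argmin(eigval))]
    # deterministic sign before the landmark is consulted
    z = z * np.sign(z[np.argmax(np.abs(z))])
    to_sty = np.asarray(styloid_tip, dtype=float) - centroid
    axial = float(z @ to_sty)
    if abs(axial) > 1e-6 * np.linalg.norm(to_sty):
        z = z * np.sign(axial)
    x = to_sty - (z @ to_sty) * z
    nx = np.linalg.norm(x)
    if nx < 1e-9 * np.linalg.norm(to_sty) or nx == 0:
        raise ValueError("styloid landmark is parallel to the long axis")
    x = x / nx
    y = np.cross(z, x)
    return AnatomicFrame(origin=centroid, x_axis=x, y_axis=y, z_axis=z)


def error_matrix(M_R: np.ndarray, M_G: np.ndarray) -> np.ndarray:
    """Planned-to-actual error transform E = M_R^-1 · M_G."""
    if not (is_rigid(M_R) and is_rigid(M_G)):
        raise ValueError("error_matrix requires rigid inputs")
    return np.linalg.inv(M_R) @ M_G


def decompose(E: np.ndarray, centroid: np.ndarray) -> PoseError:
    """Split an error matrix into 6 DOF about the given centroid."""
    params = decompose_rigid(E, centroid)
    return PoseError(
        dx=float(params[0]),
        dy=float(params[1]),
        dz=float(params[2]),
        dphix=float(params[3]),
        dphiy=float(params[4]),
        dphiz=float(params[5]),
        centroid=np.asarray(centroid, dtype=float),
    )


def to_anatomic(
    E: np.ndarray, centroid: np.ndarray, frame: AnatomicFrame
) -> PoseError:
    """Re-express an error matrix in the anatomic frame and re-decompose.

    The similarity transform F^-1·E·F rotates the error into anatomic axes;
    ΔT and ΔR are invariant under this change of frame.
    """
    F = frame.to_world()
    E_f = frame.from_world() @ np.asarray(E, dtype=float) @ F
    c_f = transform_points(
        frame.from_world(), np.asarray(centroid, float).reshape(1, 3)
    )[0]
    return decompose(E_f, c_f)


def mtre(points: np.ndarray, M_R: np.ndarray, M_G: np.ndarray) -> float:
    """Mean target registration error of a point set.

    mTRE = (1/n) Σ ‖p_i − M_R^-1·M_G·p_i‖ over the clipped guide contour
    points p_i (planned positions in the reference image).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.size == 0:
        raise ValueError("mTRE requires at least one point")
    E = error_matrix(M_R, M_G)
    moved = transform_points(E, points)
    return float(np.mean(np.linalg.norm(points - moved, axis=1)))


def hausdorff(A: np.ndarray, B: np.ndarray) -> dict[str, float]:
    """Directed and symmetric Hausdorff plus mean nearest-neighbor distances.

    h(A,B) is the maximum over a in A of the distance to the nearest b in B;
    H = max(h(A,B), h(B,A)).  ``mean_nn``/``max_nn`` summarize the pooled
    nearest-neighbor distances of both directions.  KD-trees accelerate the
    search; results equal the brute-force double loop.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.size == 0 or B.size == 0:
        raise ValueError("hausdorff requires nonempty point sets")
    d_ab, _ = cKDTree(B).query(A)
    d_ba, _ = cKDTree(A).query(B)
    pooled = np.concatenate([d_ab, d_ba])
    return {
        "h_ab": float(d_ab.max()),
        "h_ba": float(d_ba.max()),
        "H": float(max(d_ab.max(), d_ba.max())),
        "mean_nn": float(pooled.mean()),
        "max_nn": float(pooled.max()),
    }
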