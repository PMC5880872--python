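"""Rigid transforms parameterized as translations plus Rz·Rx·Ry Euler rotations.

Every rigid transform in the pipeline is represented both as a 4x4
homogeneous matrix acting on column vectors and as a six-parameter vector
``(tx, ty, tz, rx, ry, rz)`` — translations in mm, rotations in degrees —
about a stated pivot point ``c``.  The matrix form of the parameter vector
is

    M = T(c + t) · Rz(rz) · Rx(rx) · Ry(ry) · T(-c)

i.e. the object is moved so its pivot sits at the origin, rotated about the
world axes in the fixed order z, x, y (matrix product Rz·Rx·Ry), and moved
back with the pivot displaced by ``t``.  The same convention is used for
sampling placement perturbations, for the registration search space and for
decomposing error matrices, so ground-truth perturbations round-trip
exactly through measurement.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = [
    "rotation_zxy",
    "euler_zxy_from_matrix",
    "compose_rigid",
    "decompose_rigid",
    "is_rigid",
    "transform_points",
    "random_rigid",
    "GimbalLockWarning",
]


class GimbalLockWarning(UserWarning):
    """Raised when the x-rotation sits near ±90° and rz/ry are degenerate."""


def rotation_zxy(rx: float, ry: float, rz: float, degrees: bool = True) -> np.ndarray:
    """3x3 rotation matrix Rz(rz)·Rx(rx)·Ry(ry) for column vectors."""
    if degrees:
        rx, ry, rz = np.deg2rad([rx, ry, rz])
    ca, sa = np.cos(rx), np.sin(rx)
    cb, sb = np.cos(ry), np.sin(ry)
    cg, sg = np.cos(rz), np.sin(rz)
    # Rz @ Rx @ Ry expanded analytically
    return np.array(
        [
            [cg * cb - sg * sa * sb, -sg * ca, cg * sb + sg * sa * cb],
            [sg * cb + cg * sa * sb, cg * ca, sg * sb - cg * sa * cb],
            [-ca * sb, sa, ca * cb],
        ]
    )


def euler_zxy_from_matrix(R: np.ndarray, degrees: bool = True) -> np.ndarray:
    """Extract (rx, ry, rz) with R = Rz(rz)·Rx(rx)·Ry(ry).

    The extraction uses R[2,1] = sin(rx); at rx = ±90° the remaining two
    angles are not separable (gimbal lock) and a :class:`GimbalLockWarning`
    is emitted, resolving the ambiguity by setting ry = 0.
    """
    R = np.asarray(R, dtype=float)
    sa = np.clip(R[2, 1], -1.0, 1.0)
    rx = np.arcsin(sa)
    if abs(abs(rx) - np.pi / 2) < np.deg2rad(0.1):
        warnings.warn(
            "x-rotation within 0.1 deg of +/-90 deg: Rz.Rx.Ry angles are "
            "near-degenerate (gimbal lock); setting ry = 0",
            GimbalLockWarning,
            stacklevel=2,
        )
        ry = 0.0
        # with ry = 0: R[0,0] = cos(rz), R[1,0] = sin(rz)
        rz = np.arctan2(R[1, 0], R[0, 0])
    else:
        ry = np.arctan2(-R[2, 0], R[2, 2])
        rz = np.arctan2(-R[0, 1], R[1, 1])
    out = np.array([rx, ry, rz])
    return np.rad2deg(out) if degrees else out


def compose_rigid(params: np.ndarray, pivot: np.ndarray) -> np.ndarray:
    """4x4 matrix T(c+t)·Rz·Rx·Ry·T(-c) from (tx,ty,tz,rx,ry,rz) about pivot c."""
    params = np.asarray(params, dtype=float)
    if params.shape != (6,):
        raise ValueError("params must be a 6-vector (tx,ty,tz,rx,ry,rz)")
    c = np.asarray(pivot, dtype=float)
    R = rotation_zxy(params[3], params[4], params[5])
    M = np.eye(4)
    M[:3, :3] = R
    M[:3, 3] = c + params[:3] - R @ c
    return M


def decompose_rigid(E: np.ndarray, pivot: np.ndarray) -> np.ndarray:
    """Invert :func:`compose_rigid`: parameter 6-vector of E about the pivot.

    The translation components are the displacement of the pivot itself,
    ``t = E·c − c``, so they measure how far the pivot moved; the angles come
    from the Rz·Rx·Ry factorization of the rotation block.
    """
    E = np.asarray(E, dtype=float)
    if not is_rigid(E):
        raise ValueError("matrix is not a rigid transform")
    c = np.asarray(pivot, dtype=float)
    angles = euler_zxy_from_matrix(E[:3, :3])
    delta = E[:3, :3] @ c + E[:3, 3] - c
    return np.concatenate([delta, angles])


def is_rigid(M: np.ndarray, tol: float = 1e-8) -> bool:
    """True when M is 4x4 homogeneous with an orthonormal, det=+1 rotation."""
    M = np.asarray(M)
    if M.shape != (4, 4):
        return False
    if not np.allclose(M[3], [0, 0, 0, 1], atol=tol):
        return False
    R = M[:3, :3]
    return bool(
        np.allclose(R.T @ R, np.eye(3), atol=tol) and np.linalg.det(R) > 0
    )


def transform_points(M: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Apply a homogeneous 4x4 to an (n,3) point array."""
    points = np.asarray(points, dtype=float)
    return points @ M[:3, :3].T + M[:3, 3]


def random_rigid(
    rng: np.random.Generator,
    pivot: np.ndarray,
    max_translation: float = 5.0,
    max_rotation: float = 10.0,
) -> np.ndarray:
    """Uniformly drawn small rigid transform about a pivot (test/simulation aid)."""
    t = rng.uniform(-max_translation, max_translation, 3)
    r = rng.uniform(-max_rotation, max_rotation, 3)
    return compose_rigid(np.concatenate([t, r]), pivot)
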