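"""Rigid point-set-to-image registration with a Nelder–Mead simplex search.

A clipped double-contour group is registered to a pose volume by maximizing
the Pearson correlation between the template gray values (sampled from the
reference image when the contour was built) and the gray values the pose
volume takes at the transformed point positions.  The search space is the
six rigid parameters (three displacements in mm, three rotations in degrees
about the group centroid, composed Rz·Rx·Ry) and the optimizer is the
Nelder–Mead downhill simplex with deterministic shrinking restarts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .imaging import DoubleContourPointSet
from .transforms import compose_rigid, decompose_rigid, transform_points
from .volume import VoxelVolume

__all__ = [
    "RegistrationSettings",
    "RegistrationResult",
    "sample_gray",
    "correlation_metric",
    "register",
]


@dataclass(frozen=True)
class RegistrationSettings:
    """Optimizer configuration.

    The initial simplex steps (1 mm / 1°) match the scale of manual
    placement error; the simplex must collapse below ``xatol`` in every
    parameter before a run counts as converged.  Each restart re-expands a
    simplex around the best point, shrunk by ``restart_shrink`` per round.
    """

    step_mm: float = 1.0
    step_deg: float = 1.0
    xatol: float = 1e-4
    max_evaluations: int = 2000
    restarts: int = 2
    restart_shrink: float = 0.1
    max_out_of_bounds: float = 0.5


@dataclass
class RegistrationResult:
    transform: np.ndarray  # 4x4, maps reference points into the pose volume
    params: np.ndarray  # (tx,ty,tz,rx,ry,rz) about the pivot
    pivot: np.ndarray
    final_metric: float
    initial_metric: float
    n_evaluations: int
    converged: bool


def sample_gray(
    volume: VoxelVolume, points: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Trilinear gray values at world points plus an in-bounds mask.

    Out-of-bounds points get the nearest-voxel value but are flagged so the
    metric can exclude them.  Raises if every point is outside.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    idx = volume.world_to_index(points)
    inside = np.all((idx >= 0) & (idx <= np.array(volume.shape) - 1), axis=1)
    if not inside.any():
        raise ValueError("all points fall outside the volume")
    vals = ndimage.map_coordinates(volume.data, idx.T, order=1, mode="nearest")
    return vals, inside


def correlation_metric(template: np.ndarray, sampled: np.ndarray) -> float:
    """Pearson correlation of template vs sampled gray values."""
    template = np.asarray(template, dtype=float)
    sampled = np.asarray(sampled, dtype=float)
    if template.shape != sampled.shape or template.ndim != 1:
        raise ValueError("template and sampled must be equal-length vectors")
    if len(template) < 2:
        raise ValueError("correlation needs at least two pairs")
    t = template - template.mean()
    s = sampled - sampled.mean()
    vt, vs = t @ t, s @ s
    if vt == 0 or vs == 0:
        raise ValueError("zero variance: degenerate contrast")
    return float((t @ s) / np.sqrt(vt * vs))


def register(
    group: DoubleContourPointSet,
    pose_volume: VoxelVolume,
    init: np.ndarray | None = None,
    settings: RegistrationSettings = RegistrationSettings(),
) -> RegistrationResult:
    """Maximize gray-value correlation over the six rigid parameters.

    The pivot of the parameterization is the group centroid.  Points that
    leave the volume are dropped from the metric; an evaluation that loses
    more than half the points scores −1.  The optimization is fully
    deterministic.
    """
    points = group.all_points
    template = group.template_gray
    pivot = group.centroid
    x0 = (
        np.zeros(6)
        if init is None
        else decompose_rigid(np.asarray(init, dtype=float), pivot)
    )

    n_eval = 0

    def metric_at(params: np.ndarray) -> float:
        M = compose_rigid(params, pivot)
        moved = transform_points(M, points)
        vals, inside = sample_gray(pose_volume, moved)
        if inside.mean() < 1.0 - settings.max_out_of_bounds:
            return -1.0
        try:
            return correlation_metric(template[inside], vals[inside])
        except ValueError:
            return -1.0

    def objective(params: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        return -metric_at(params)

    initial_metric = metric_at(x0)
    steps = np.array([settings.step_mm] * 3 + [settings.step_deg] * 3)
    best_x, best_f = x0.copy(), -initial_metric
    converged = False
    for round_i in range(settings.restarts + 1):
        scale = settings.restart_shrink**round_i
        simplex = np.vstack([best_x, best_x + np.diag(steps * scale)])
        res = optimize.minimize(
            objective,
            best_x,
            method="Nelder-Mead",
            options={
                "initial_simplex": simplex,
                "xatol": settings.xatol,
                "fatol": 1e-12,
                "maxfev": settings.max_evaluations,
                "disp": False,
            },
        )
        if res.fun <= best_f:
            best_x, best_f = res.x, res.fun
        converged = bool(res.status == 0)
    final_metric = -best_f
    if final_metric < initial_metric:  # monotone acceptance guarantee
        best_x, final_metric = x0, initial_metric
    return RegistrationResult(
        transform=compose_rigid(best_x, pivot),
        params=best_x,
        pivot=pivot,
        final_metric=final_metric,
        initial_metric=initial_metric,
        n_evaluations=n_eval,
        converged=converged,
    )
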