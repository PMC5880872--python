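"""File I/O: meshes, landmarks, double-contour point sets, model traces.

Meshes go through trimesh (STL/PLY by extension), volumes through
:class:`~guidefit.volume.VoxelVolume` (SimpleITK NIfTI/MetaImage), and
double-contour point sets are written as ASCII PLY point clouds with the
custom per-vertex properties (normal, inner/outer gray, group id) that the
registration needs — properties no off-the-shelf point-cloud writer
round-trips, hence the small writer/reader here.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .imaging import DoubleContourPointSet

__all__ = [
    "save_mesh",
    "load_mesh",
    "save_landmarks",
    "load_landmarks",
    "save_pointsets_ply",
    "load_pointsets_ply",
    "glm_trace_to_dict",
    "save_json",
]


def save_mesh(mesh: trimesh.Trimesh, path: str | Path) -> None:
    mesh.export(str(path))


def load_mesh(path: str | Path) -> trimesh.Trimesh:
    mesh = trimesh.load_mesh(str(path))
    if not isinstance(mesh, trimesh.Trimesh):
        raise ValueError(f"{path} did not contain a single triangle mesh")
    return mesh


def save_landmarks(landmarks: dict[str, np.ndarray], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({k: list(map(float, v)) for k, v in landmarks.items()}, fh, indent=1)


def load_landmarks(path: str | Path) -> dict[str, np.ndarray]:
    with open(path) as fh:
        return {k: np.asarray(v, dtype=float) for k, v in json.load(fh).items()}


_PLY_PROPS = ["x", "y", "z", "nx", "ny", "nz", "inner_gray", "outer_gray"]


def save_pointsets_ply(
    groups: dict[str, DoubleContourPointSet], path: str | Path
) -> None:
    """Write clipped double-contour groups as one ASCII PLY point cloud."""
    names = sorted(groups)
    offsets = {g.offset for g in groups.values()}
    if len(offsets) != 1:
        raise ValueError("all groups must share one contour offset")
    n_total = sum(len(g) for g in groups.values())
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"comment double-contour offset_mm {offsets.pop():.9g}\n")
        for i, name in enumerate(names):
            fh.write(f"comment group {i} {name}\n")
        fh.write(f"element vertex {n_total}\n")
        for prop in _PLY_PROPS:
            fh.write(f"property float {prop}\n")
        fh.write("property int group_id\nend_header\n")
        for i, name in enumerate(names):
            g = groups[name]
            block = np.column_stack(
                [g.surface_points, g.normals, g.inner_gray, g.outer_gray]
            )
            for row in block:
                fh.write(" ".join(f"{v:.9g}" for v in row) + f" {i}\n")


def load_pointsets_ply(path: str | Path) -> dict[str, DoubleContourPointSet]:
    names: dict[int, str] = {}
    offset = None
    rows = []
    with open(path) as fh:
        line = fh.readline()
        if line.strip() != "ply":
            raise ValueError("not a PLY file")
        while True:
            line = fh.readline()
            if not line:
                raise ValueError("truncated PLY header")
            tok = line.split()
            if tok[0] == "comment" and tok[1] == "double-contour":
                offset = float(tok[3])
            elif tok[0] == "comment" and tok[1] == "group":
                names[int(tok[2])] = tok[3]
            elif tok[0] == "end_header":
                break
        for line in fh:
            if line.strip():
                rows.append([float(v) for v in line.split()])
    if offset is None:
        raise ValueError("missing double-contour offset in PLY header")
    data = np.asarray(rows, dtype=float)
    out = {}
    for gid, name in names.items():
        sel = data[:, 8].astype(int) == gid
        if not sel.any():
            continue
        out[name] = DoubleContourPointSet(
            surface_points=data[sel, 0:3],
            normals=data[sel, 3:6],
            offset=offset,
            inner_gray=data[sel, 6],
            outer_gray=data[sel, 7],
            group=name,
        )
    return out


def glm_trace_to_dict(trace) -> dict:
    """JSON-serializable stepwise-reduction trace."""
    return {
        "response": trace[0].response,
        "models": [
            {
                "effects": list(m.effects),
                "nobs": m.nobs,
                "scale": m.scale,
                "coefficients": m.coefficients.to_dict(orient="records"),
                "effect_tests": m.effect_tests.to_dict(orient="records"),
            }
            for m in trace
        ],
    }


def _default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    if isinstance(o, pd.DataFrame):
        return o.to_dict(orient="records")
    raise TypeError(f"cannot serialize {type(o)}")


def save_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=_default)
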