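"""End-to-end in-silico replica of the guide-positioning experiment.

``run_experiment`` drives the whole chain from one seeded configuration:
synthetic radiuses → guide designs → reference volumes (guides in planned
pose) → segmentation and clipped double contours → per-trial pose volumes
(guides perturbed by the placement error model) → registration → error
matrices, anatomic 6-DOF decomposition, mTRE/ΔT/ΔR → three stepwise GLMs.
Every trial's measured errors sit next to its ground truth in the output
table, so measurement fidelity is directly checkable.

Two measurement modes exist: ``"registration"`` runs the full imaging
chain; ``"analytic"`` bypasses imaging and reports the exact decomposition
of the ground-truth perturbation — the fast path for statistical
experiments where the imaging chain adds cost but no information.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .experiments import build_reference_scene, desk_phantom_params
from .imaging import DoubleContourPointSet
from .meshutil import point_mesh_distance, sample_surface
from .phantom import (
    DESIGNS,
    LOCATIONS,
    BonePhantomParams,
    CTSimParams,
    PlacementErrorModel,
    TrialRecord,
    default_phantom_set,
    simulate_experiment,
    trial_seed,
)
from .pose_error import anatomic_frame, error_matrix, mtre, to_anatomic
from .registration import RegistrationSettings, register
from .stats import DEFAULT_EFFECTS, RESPONSES, stepwise_reduce

__all__ = ["RunConfig", "RunResult", "run_experiment", "measure_trials"]

log = logging.getLogger("guidefit")


@dataclass
class RunConfig:
    """Fully serializable description of one in-silico experiment."""

    seed: int = 0
    n_geometries: int = 6
    n_operators: int = 4
    phantom_base: BonePhantomParams = field(default_factory=desk_phantom_params)
    sim: CTSimParams = field(default_factory=CTSimParams)
    err_model: PlacementErrorModel = field(default_factory=PlacementErrorModel.default)
    registration: RegistrationSettings = field(default_factory=RegistrationSettings)
    measurement: str = "registration"  # "registration" | "analytic"
    bone_step: float = 1.0
    guide_step: float = 0.7
    exclusion_distance: float = 2.0
    alpha: float = 0.05
    make_figures: bool = True
    out_dir: str | None = None

    def validate(self) -> None:
        if self.measurement not in ("registration", "analytic"):
            raise ValueError("measurement must be 'registration' or 'analytic'")
        if self.n_geometries < 1 or self.n_operators < 1:
            raise ValueError("need at least one geometry and one operator")


@dataclass
class RunResult:
    trials: pd.DataFrame
    glm_traces: dict  # response -> list[GLMResult]
    records: list[TrialRecord]
    config: RunConfig


def _trial_row(
    rec: TrialRecord,
    measured_params: np.ndarray,
    true_params_at_pivot: np.ndarray,
    measured_mtre: float,
    true_mtre: float,
) -> dict:
    row = {
        "operator": rec.operator,
        "geometry": rec.geometry,
        "location": rec.location,
        "design": rec.design,
    }
    for i, name in enumerate(["dx", "dy", "dz", "dphix", "dphiy", "dphiz"]):
        row[name] = measured_params[i]
        row["true_" + name] = true_params_at_pivot[i]
    row["dT"] = float(np.linalg.norm(measured_params[:3]))
    row["dR"] = float(np.linalg.norm(measured_params[3:]))
    row["true_dT"] = float(np.linalg.norm(true_params_at_pivot[:3]))
    row["true_dR"] = float(np.linalg.norm(true_params_at_pivot[3:]))
    row["mTRE"] = measured_mtre
    row["true_mTRE"] = true_mtre
    return row


def measure_trials(
    records: list[TrialRecord],
    phantoms: list[BonePhantomParams],
    config: RunConfig,
) -> pd.DataFrame:
    """Measure every trial record, returning the trials table.

    Trials are grouped by (geometry, design): each such group shares one
    reference model (bone + the three guides of that design in planned
    pose), exactly as the physical experiment shared reference scans.  In
    registration mode one pose volume is rendered per (operator, geometry,
    design) containing the operator's three perturbed guides, and the bone
    plus each guide are registered to it.
    """
    by_scene: dict[tuple[str, str], list[TrialRecord]] = {}
    for rec in records:
        by_scene.setdefault((rec.geometry, rec.design), []).append(rec)

    rows = []
    for (geom, design), recs in sorted(by_scene.items()):
        gi = int(geom[1:]) - 1
        t0 = time.time()
        if config.measurement == "registration":
            scene = build_reference_scene(
                phantom=phantoms[gi],
                sim=config.sim,
                design=design,
                bone_step=config.bone_step,
                guide_step=config.guide_step,
                seed=trial_seed(config.seed, "ref", geom, design),
            )
            frame = scene.frame
            guides = scene.guides
            guide_groups = {
                loc: scene.groups[f"guide_{loc}"] for loc in LOCATIONS
            }
        else:
            scene = None
            from .guide_design import GuideSpec, build_guide
            from .phantom import make_synthetic_radius

            bone, landmarks = make_synthetic_radius(phantoms[gi])
            frame = anatomic_frame(bone, landmarks["styloid_tip"])
            guides = {
                loc: build_guide(bone, frame, GuideSpec(loc, design))["guide"]
                for loc in LOCATIONS
            }
            guide_groups = {}
            for loc, g in guides.items():
                pts, normals = sample_surface(
                    g, config.guide_step, seed=trial_seed(config.seed, "pts", geom, loc)
                )
                far = point_mesh_distance(
                    pts, bone, max_distance=config.exclusion_distance + 0.5
                )
                keep = far >= config.exclusion_distance
                guide_groups[loc] = DoubleContourPointSet(
                    surface_points=pts[keep],
                    normals=normals[keep],
                    offset=config.sim.voxel_size,
                    inner_gray=np.zeros(keep.sum()),
                    outer_gray=np.zeros(keep.sum()),
                    group=f"guide_{loc}",
                )

        by_operator: dict[str, list[TrialRecord]] = {}
        for rec in recs:
            by_operator.setdefault(rec.operator, []).append(rec)

        for op, op_recs in sorted(by_operator.items()):
            true_T = {
                rec.location: rec.true_error(guides[rec.location].center_mass)
                for rec in op_recs
            }
            if config.measurement == "registration":
                pose_vol = scene.render_pose(
                    true_T,
                    noise_seed=trial_seed(config.seed, "pose", op, geom, design),
                )
                M_R = register(
                    scene.bone_group, pose_vol, settings=config.registration
                ).transform
            else:
                M_R = np.eye(4)

            for rec in op_recs:
                grp = guide_groups[rec.location]
                T = true_T[rec.location]
                if config.measurement == "registration":
                    M_G = register(grp, pose_vol, settings=config.registration).transform
                else:
                    M_G = T
                E = error_matrix(M_R, M_G)
                pivot = grp.centroid
                meas = to_anatomic(E, pivot, frame)
                true = to_anatomic(T, pivot, frame)
                measured_params = np.concatenate([meas.translation, meas.rotation])
                true_params = np.concatenate([true.translation, true.rotation])
                row = _trial_row(
                    rec,
                    measured_params,
                    true_params,
                    measured_mtre=mtre(grp.surface_points, M_R, M_G),
                    true_mtre=mtre(grp.surface_points, np.eye(4), T),
                )
                rec.measured = row
                rows.append(row)
        log.info(
            "scene %s/%s: %d trials in %.1fs", geom, design, len(recs), time.time() - t0
        )
    return pd.DataFrame(rows)


def _make_figures(trials: pd.DataFrame, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out.mkdir(parents=True, exist_ok=True)
    for resp, unit in [("mTRE", "mm"), ("dT", "mm"), ("dR", "deg")]:
        fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
        for ax, by in zip(axes, ["location", "design"]):
            order = list(LOCATIONS) if by == "location" else list(DESIGNS)
            data = [trials.loc[trials[by] == lvl, resp] for lvl in order]
            ax.boxplot(data, tick_labels=order)
            ax.set_xlabel(by)
            ax.set_ylabel(f"{resp} [{unit}]")
        fig.suptitle(f"{resp} by fitting location and guide design")
        fig.tight_layout()
        fig.savefig(out / f"{resp}_boxplots.png", dpi=120)
        plt.close(fig)


def run_experiment(config: RunConfig) -> RunResult:
    """Run the full factorial experiment described by ``config``.

    Returns the trials table and the three stepwise GLM traces; when
    ``config.out_dir`` is set, writes ``trials.csv``, ``models/*.json``,
    ``figures/*.png`` and ``provenance.json``.
    """
    config.validate()
    phantoms = default_phantom_set(
        seed=config.seed, n=config.n_geometries, base=config.phantom_base
    )
    records = simulate_experiment(
        phantoms, config.err_model, n_operators=config.n_operators, seed=config.seed
    )
    trials = measure_trials(records, phantoms, config)
    # keep only effects with >= 2 levels (reduced designs drop Operator etc.)
    levels = {
        "Extension": trials["design"],
        "Location": trials["location"],
        "Operator": trials["operator"],
        "Geometry": trials["geometry"],
    }
    effects = tuple(
        e
        for e in DEFAULT_EFFECTS
        if all(levels[p].nunique() > 1 for p in e.split("*"))
    )
    traces = {}
    for resp in RESPONSES:
        try:
            traces[resp] = stepwise_reduce(
                trials, resp, full_effects=effects, alpha=config.alpha
            )
        except (ValueError, np.linalg.LinAlgError) as exc:
            log.warning("GLM for %s skipped: %s", resp, exc)

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        trials.to_csv(out / "trials.csv", index=False, float_format="%.9g")
        models = out / "models"
        models.mkdir(exist_ok=True)
        for resp, trace in traces.items():
            gio.save_json(gio.glm_trace_to_dict(trace), models / f"{resp}.json")
        if config.make_figures:
            _make_figures(trials, out / "figures")
        from . import __version__

        cfg_dict = asdict(config)
        cfg_dict["err_model"]["cells"] = {
            f"{loc}/{des}": cell
            for (loc, des), cell in cfg_dict["err_model"]["cells"].items()
        }
        gio.save_json(
            {"config": cfg_dict, "version": __version__},
            out / "provenance.json",
        )
    return RunResult(trials=trials, glm_traces=traces, records=records, config=config)
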