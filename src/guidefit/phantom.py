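"""Synthetic radius phantoms, CT-like volume rendering and placement trials.

The experimental study this package replays used six printed models of adult
radiuses, CT-scanned at 0.33 mm isotropic voxels, with guides positioned by
four operators at three fitting locations (distal, mid-shaft, proximal) in
two designs (standard, extended) — a 4 x 6 x 3 x 2 full factorial of 144
guide placements.  Nothing here requires printing or scanning: this module
generates radius-like bones (tapered shaft, widened distal end carrying a
styloid-like protrusion, Gaussian surface bumps standing in for anatomical
surface anchors), renders them into blurred/noisy two-intensity volumes, and
draws ground-truth placement perturbations from a configurable per-cell
error model.

The bone is built as a surface of revolution about the z axis with the
distal end at high z; the styloid protrusion points along +x, which also
anchors the anatomic coordinate frame downstream.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import trimesh
from scipy import ndimage

from .meshutil import slice_polygons
from .transforms import compose_rigid, is_rigid
from .volume import VoxelVolume

__all__ = [
    "LOCATIONS",
    "DESIGNS",
    "BonePhantomParams",
    "CTSimParams",
    "PlacementErrorModel",
    "TrialRecord",
    "make_synthetic_radius",
    "voxelize",
    "compose_scene",
    "add_noise",
    "simulate_experiment",
    "default_phantom_set",
]

LOCATIONS = ("distal", "mid-shaft", "proximal")
DESIGNS = ("standard", "extended")


@dataclass(frozen=True)
class BonePhantomParams:
    """Shape parameters of one synthetic radius.

    Defaults approximate a healthy adult radius: ~24 cm long, ~1 cm shaft
    radius, distal end widened by 60% and a styloid-like radial protrusion.
    ``n_anchor_bumps`` Gaussian bumps emulate surface anchors; they are laid
    down densely on the distal third, sparsely mid-shaft and moderately on
    the proximal third, mirroring where real bone offers guides the most
    purchase.
    """

    total_length: float = 240.0  # mm
    shaft_radius: float = 10.0  # mm
    distal_width_factor: float = 1.6
    styloid_length: float = 12.0  # mm, radial protrusion amplitude
    n_anchor_bumps: int = 24
    bump_amplitude: float = 1.2  # mm
    seed: int = 0

    def validate(self) -> None:
        if self.total_length <= 0 or self.shaft_radius <= 0:
            raise ValueError("bone length and shaft radius must be positive")
        if self.distal_width_factor < 1:
            raise ValueError("distal_width_factor must be >= 1")
        if self.styloid_length < 0 or self.bump_amplitude < 0:
            raise ValueError("styloid_length and bump_amplitude must be >= 0")
        if self.n_anchor_bumps < 0:
            raise ValueError("n_anchor_bumps must be >= 0")


@dataclass(frozen=True)
class CTSimParams:
    """CT-like acquisition model: binary voxelization, Gaussian PSF, noise.

    The printed models the study scanned were homogeneous plastic in air, so
    a two-intensity model suffices; ``psf_sigma`` is the in-plane blur of the
    scanner (one voxel by default) and ``noise_sd`` defaults to 1% of the
    plastic-air contrast.
    """

    voxel_size: float = 0.33  # mm, isotropic
    bone_intensity: float = 1000.0
    background_intensity: float = 0.0
    psf_sigma: float = 0.33  # mm
    noise_sd: float = 10.0
    supersample: int = 2  # sub-voxel sampling factor for partial volume
    seed: int = 0

    def validate(self) -> None:
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.bone_intensity == self.background_intensity:
            raise ValueError("bone and background intensity must differ")
        if self.psf_sigma < 0 or self.noise_sd < 0:
            raise ValueError("psf_sigma and noise_sd must be >= 0")
        if self.supersample < 1:
            raise ValueError("supersample must be >= 1")


def make_synthetic_radius(
    params: BonePhantomParams,
) -> tuple[trimesh.Trimesh, dict[str, np.ndarray]]:
    """Closed radius-like mesh plus named landmarks (``styloid_tip``).

    The surface is a seeded, deterministic surface of revolution
    ``r(theta, z)`` about z: constant shaft radius, Gaussian distal/proximal
    widening, a styloid-like Gaussian protrusion at theta=0 near the distal
    end, and ``n_anchor_bumps`` Gaussian surface bumps.  End caps are
    triangulated from rim vertices only, so in the degenerate configuration
    (no widening, no styloid, no bumps) every vertex lies exactly at
    ``shaft_radius`` from the axis.
    """
    params.validate()
    L, s = params.total_length, params.shaft_radius
    rng = np.random.default_rng(params.seed)

    n_theta = 64
    n_z = max(int(round(L / 1.0)) + 1, 32)
    theta = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    z = np.linspace(0.0, L, n_z)

    # base radial profile: distal widening (z = L end) + mild radial-head
    # widening proximally, both vanish as distal_width_factor -> 1
    widen = params.distal_width_factor - 1.0
    r_z = s * (
        1.0
        + widen * np.exp(-(((L - z) / (0.10 * L)) ** 2))
        + 0.4 * widen * np.exp(-((z / (0.06 * L)) ** 2))
    )
    r = np.tile(r_z[:, None], (1, n_theta))

    def wrap(dt: np.ndarray) -> np.ndarray:
        return (dt + np.pi) % (2 * np.pi) - np.pi

    # styloid-like protrusion at theta = 0 (+x), near the distal end
    z_sty = 0.96 * L
    i_sty = int(np.argmin(np.abs(z - z_sty)))
    if params.styloid_length > 0:
        dz = (z[:, None] - z[i_sty]) / (0.04 * L)
        dt = wrap(theta[None, :]) / 0.25
        r = r + params.styloid_length * np.exp(-(dz**2) - dt**2)

    # anchor bumps: dense distal, sparse mid-shaft, moderate proximal
    if params.n_anchor_bumps > 0 and params.bump_amplitude > 0:
        weights = {"distal": 0.50, "mid-shaft": 0.15, "proximal": 0.35}
        spans = {
            "proximal": (0.05 * L, L / 3),
            "mid-shaft": (L / 3, 2 * L / 3),
            "distal": (2 * L / 3, 0.95 * L),
        }
        sigma_z = max(2.0, 0.015 * L)
        counts = {
            k: int(round(w * params.n_anchor_bumps)) for k, w in weights.items()
        }
        for region, n_b in counts.items():
            lo, hi = spans[region]
            for _ in range(n_b):
                zb = rng.uniform(lo, hi)
                tb = rng.uniform(0, 2 * np.pi)
                amp = params.bump_amplitude * rng.uniform(0.6, 1.0)
                dz = (z[:, None] - zb) / sigma_z
                dt = wrap(theta[None, :] - tb) / 0.30
                r = r + amp * np.exp(-(dz**2) - dt**2)

    verts = np.empty((n_z * n_theta, 3))
    verts[:, 0] = (r * np.cos(theta)[None, :]).ravel()
    verts[:, 1] = (r * np.sin(theta)[None, :]).ravel()
    verts[:, 2] = np.repeat(z, n_theta)

    def vid(j: int, k: int) -> int:
        return j * n_theta + (k % n_theta)

    faces = []
    for j in range(n_z - 1):
        for k in range(n_theta):
            a, b = vid(j, k), vid(j, k + 1)
            c, d = vid(j + 1, k + 1), vid(j + 1, k)
            faces.append([a, b, c])
            faces.append([a, c, d])
    # rim-fan caps (no apex vertex)
    for k in range(1, n_theta - 1):
        faces.append([vid(0, 0), vid(0, k + 1), vid(0, k)])  # proximal cap
        faces.append([vid(n_z - 1, 0), vid(n_z - 1, k), vid(n_z - 1, k + 1)])
    mesh = trimesh.Trimesh(vertices=verts, faces=np.array(faces), process=False)
    if mesh.volume < 0:
        mesh.invert()
    if not mesh.is_watertight:
        raise RuntimeError("phantom construction produced a non-watertight mesh")
    landmarks = {"styloid_tip": verts[vid(i_sty, 0)].copy()}
    return mesh, landmarks


def _make_grid(
    bounds: np.ndarray, spacing: float, pad: int = 4
) -> tuple[np.ndarray, tuple[int, int, int]]:
    """Voxel-center grid covering ``bounds`` with a ``pad``-voxel margin.

    The origin is offset by half a voxel so that voxel centers never land
    exactly on an axis-aligned bounding plane of the mesh.
    """
    lo, hi = np.asarray(bounds, dtype=float)
    origin = lo - (pad + 0.5) * spacing
    shape = tuple(np.ceil((hi - lo) / spacing).astype(int) + 2 * pad + 1)
    return origin, shape


def _rasterize_mask(
    mesh: trimesh.Trimesh, spacing: float, origin: np.ndarray, shape: tuple
) -> np.ndarray:
    """Boolean inside-mask on the voxel-center grid via z-slice polygon tests.

    Slice loops carry even-odd semantics (see ``slice_polygons``), so the
    inside test XOR-accumulates over the loops of each slice.
    """
    import shapely

    mask = np.zeros(shape, dtype=bool)
    zmin, zmax = mesh.bounds[0, 2], mesh.bounds[1, 2]
    k_lo = max(int(np.ceil((zmin - origin[2]) / spacing)), 0)
    k_hi = min(int(np.floor((zmax - origin[2]) / spacing)), shape[2] - 1)
    if k_hi < k_lo:
        return mask
    z_values = origin[2] + np.arange(k_lo, k_hi + 1) * spacing
    polys = slice_polygons(mesh, z_values)
    xs = origin[0] + np.arange(shape[0]) * spacing
    ys = origin[1] + np.arange(shape[1]) * spacing
    for k, plist in zip(range(k_lo, k_hi + 1), polys):
        for poly in plist:
            bx0, by0, bx1, by1 = poly.bounds
            i0 = np.searchsorted(xs, bx0)
            i1 = np.searchsorted(xs, bx1, side="right")
            j0 = np.searchsorted(ys, by0)
            j1 = np.searchsorted(ys, by1, side="right")
            if i1 <= i0 or j1 <= j0:
                continue
            gx, gy = np.meshgrid(xs[i0:i1], ys[j0:j1], indexing="ij")
            inside = shapely.contains_xy(poly, gx.ravel(), gy.ravel())
            mask[i0:i1, j0:j1, k] ^= inside.reshape(gx.shape)
    return mask


def _rasterize_occupancy(
    mesh: trimesh.Trimesh,
    spacing: float,
    origin: np.ndarray,
    shape: tuple,
    supersample: int,
) -> np.ndarray:
    """Fractional voxel occupancy via sub-voxel center-inside tests.

    ``supersample=1`` is the plain binary center-inside test; larger values
    average an n³ sub-grid per voxel, emulating the partial-volume effect
    of a real scanner (a boundary voxel's value is proportional to the
    plastic fraction it contains).
    """
    n = int(supersample)
    if n == 1:
        return _rasterize_mask(mesh, spacing, origin, shape)
    fine_spacing = spacing / n
    fine_origin = np.asarray(origin) - spacing / 2 + fine_spacing / 2
    fine_shape = tuple(s * n for s in shape)
    fine = _rasterize_mask(mesh, fine_spacing, fine_origin, fine_shape)
    return fine.reshape(shape[0], n, shape[1], n, shape[2], n).mean(axis=(1, 3, 5))


def _require_closed(mesh: trimesh.Trimesh) -> None:
    if not mesh.is_watertight:
        raise ValueError("mesh must be closed (watertight) for an inside test")


def voxelize(mesh: trimesh.Trimesh, sim: CTSimParams) -> VoxelVolume:
    """Render one closed mesh into a CT-like volume.

    With ``supersample=1`` voxels whose centers fall inside the mesh take
    ``bone_intensity`` and the rest ``background_intensity``; the default
    ``supersample=2`` renders fractional partial-volume intensities at
    boundary voxels instead.  The image is then blurred with a normalized
    Gaussian PSF and seeded Gaussian noise is added.
    """
    sim.validate()
    _require_closed(mesh)
    origin, shape = _make_grid(mesh.bounds, sim.voxel_size)
    occ = _rasterize_occupancy(mesh, sim.voxel_size, origin, shape, sim.supersample)
    return _finalize_volume(occ, origin, sim)


def _finalize_volume(
    occupancy: np.ndarray, origin: np.ndarray, sim: CTSimParams
) -> VoxelVolume:
    data = sim.background_intensity + (
        sim.bone_intensity - sim.background_intensity
    ) * occupancy.astype(np.float64)
    if sim.psf_sigma > 0:
        data = ndimage.gaussian_filter(
            data, sigma=sim.psf_sigma / sim.voxel_size, mode="nearest"
        )
    vol = VoxelVolume(data, sim.voxel_size, origin)
    if sim.noise_sd > 0:
        vol = add_noise(vol, sim.noise_sd, sim.seed)
    return vol


def render_scene_mask(
    bone: trimesh.Trimesh,
    guides: list[trimesh.Trimesh],
    guide_poses: list[np.ndarray],
    sim: CTSimParams,
    bounds: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Union occupancy of bone plus posed guides; returns (occupancy, origin)."""
    sim.validate()
    _require_closed(bone)
    if len(guides) != len(guide_poses):
        raise ValueError("guides and guide_poses must have equal length")
    posed = []
    for g, pose in zip(guides, guide_poses):
        if not is_rigid(pose):
            raise ValueError("guide poses must be rigid transforms")
        _require_closed(g)
        gp = g.copy()
        gp.apply_transform(pose)
        posed.append(gp)
    if bounds is None:
        all_bounds = np.array([m.bounds for m in [bone, *posed]])
        bounds = np.array(
            [all_bounds[:, 0, :].min(axis=0), all_bounds[:, 1, :].max(axis=0)]
        )
    origin, shape = _make_grid(bounds, sim.voxel_size)
    occ = _rasterize_occupancy(bone, sim.voxel_size, origin, shape, sim.supersample)
    for gp in posed:
        occ = np.maximum(
            occ,
            _rasterize_occupancy(gp, sim.voxel_size, origin, shape, sim.supersample),
        )
    return occ, origin


def compose_scene(
    bone: trimesh.Trimesh,
    guides: list[trimesh.Trimesh],
    guide_poses: list[np.ndarray],
    sim: CTSimParams,
    bounds: np.ndarray | None = None,
) -> VoxelVolume:
    """Render bone plus posed guides into one volume.

    Bone and guides are the same printed plastic, so overlapping voxels
    simply take the bone intensity (the guides sit in contact with the bone
    surface and merge into one connected object, exactly as in the scanned
    reference models).  Passing explicit world ``bounds`` lets several
    scenes share one voxel grid.
    """
    mask, origin = render_scene_mask(bone, guides, guide_poses, sim, bounds)
    return _finalize_volume(mask, origin, sim)


def add_noise(volume: VoxelVolume, noise_sd: float, seed: int) -> VoxelVolume:
    """Additive Gaussian noise with its own seed (repeat-scan emulation)."""
    rng = np.random.default_rng(seed)
    data = volume.data + rng.standard_normal(volume.shape) * noise_sd
    return VoxelVolume(data, volume.spacing, volume.origin.copy())


@dataclass(frozen=True)
class ErrorCell:
    """Per-axis perturbation scales for one (location, design) cell."""

    translation_sd: float  # mm, per axis
    rotation_sd: float  # degrees, per axis

    def validate(self) -> None:
        if self.translation_sd < 0 or self.rotation_sd < 0:
            raise ValueError("perturbation sds must be >= 0")


@dataclass(frozen=True)
class PlacementErrorModel:
    """Stochastic stand-in for manual guide placement.

    Each (location, design) cell has its own per-axis translation and
    rotation sd; every operator additionally carries a small systematic
    offset (drawn once per operator) with sd ``operator_offset_sd_mm`` /
    ``operator_offset_sd_deg``.  The default cell scales follow the ordering
    the physical experiment observed: distal placements are the most
    accurate and mid-shaft the worst; the lateral extension improves
    translational accuracy everywhere but degrades rotational accuracy on
    the near-cylindrical mid-shaft.
    """

    cells: dict[tuple[str, str], ErrorCell] = field(default_factory=dict)
    operator_offset_sd_mm: float = 0.15
    operator_offset_sd_deg: float = 0.15

    @classmethod
    def default(cls) -> "PlacementErrorModel":
        cells = {
            ("distal", "extended"): ErrorCell(0.30, 0.50),
            ("distal", "standard"): ErrorCell(0.85, 0.70),
            ("proximal", "extended"): ErrorCell(0.65, 1.10),
            ("proximal", "standard"): ErrorCell(1.20, 1.30),
            ("mid-shaft", "extended"): ErrorCell(1.05, 1.90),
            ("mid-shaft", "standard"): ErrorCell(1.60, 1.60),
        }
        return cls(cells=cells)

    @classmethod
    def zero(cls) -> "PlacementErrorModel":
        cells = {
            (loc, des): ErrorCell(0.0, 0.0) for loc in LOCATIONS for des in DESIGNS
        }
        return cls(cells=cells, operator_offset_sd_mm=0.0, operator_offset_sd_deg=0.0)

    def validate(self) -> None:
        for loc in LOCATIONS:
            for des in DESIGNS:
                if (loc, des) not in self.cells:
                    raise ValueError(f"error model missing cell ({loc}, {des})")
        for cell in self.cells.values():
            cell.validate()
        if self.operator_offset_sd_mm < 0 or self.operator_offset_sd_deg < 0:
            raise ValueError("operator offset sds must be >= 0")

    def sample_params(
        self, location: str, design: str, rng: np.random.Generator
    ) -> np.ndarray:
        """Draw one 6-parameter perturbation (tx,ty,tz in mm; rx,ry,rz in deg)."""
        cell = self.cells[(location, design)]
        t = rng.standard_normal(3) * cell.translation_sd
        r = rng.standard_normal(3) * cell.rotation_sd
        return np.concatenate([t, r])


@dataclass
class TrialRecord:
    """One guide placement of the factorial experiment.

    ``true_params`` is the ground-truth perturbation as the canonical
    six-parameter vector about the guide centroid; :meth:`true_error`
    materializes it as a 4x4 matrix once the centroid is known.
    ``measured`` is filled by the measurement pipeline.
    """

    operator: str
    geometry: str
    location: str
    design: str
    true_params: np.ndarray
    seed: int
    measured: dict | None = None

    def true_error(self, centroid: np.ndarray) -> np.ndarray:
        return compose_rigid(self.true_params, centroid)


def trial_seed(global_seed: int, *keys) -> int:
    """Stable per-trial sub-seed from the global seed and trial identity."""
    tag = "|".join(str(k) for k in keys)
    return (int(global_seed) * 1_000_003 + zlib.crc32(tag.encode())) % (2**31 - 1)


def simulate_experiment(
    phantoms: list[BonePhantomParams],
    err_model: PlacementErrorModel,
    n_operators: int = 4,
    seed: int = 0,
) -> list[TrialRecord]:
    """Draw the full factorial of guide placements with ground-truth errors.

    Every (operator, geometry, location, design) combination appears exactly
    once: ``n_operators x len(phantoms) x 3 x 2`` records (144 at the study
    defaults).  Each record's perturbation is seeded by the trial identity,
    so the list is reproducible independent of iteration order.
    """
    err_model.validate()
    operators = [f"op{i + 1}" for i in range(n_operators)]
    offsets = {}
    for op in operators:
        rng = np.random.default_rng(trial_seed(seed, "operator-offset", op))
        offsets[op] = np.concatenate(
            [
                rng.standard_normal(3) * err_model.operator_offset_sd_mm,
                rng.standard_normal(3) * err_model.operator_offset_sd_deg,
            ]
        )
    records = []
    for op in operators:
        for gi in range(len(phantoms)):
            geom = f"g{gi + 1}"
            for loc in LOCATIONS:
                for des in DESIGNS:
                    ts = trial_seed(seed, op, geom, loc, des)
                    rng = np.random.default_rng(ts)
                    params = err_model.sample_params(loc, des, rng) + offsets[op]
                    records.append(
                        TrialRecord(
                            operator=op,
                            geometry=geom,
                            location=loc,
                            design=des,
                            true_params=params,
                            seed=ts,
                        )
                    )
    return records


def default_phantom_set(
    seed: int = 0, n: int = 6, base: BonePhantomParams | None = None
) -> list[BonePhantomParams]:
    """Radius phantoms with individual shape variation (one per 'patient')."""
    rng = np.random.default_rng(seed)
    base = BonePhantomParams() if base is None else base
    out = []
    for i in range(n):
        out.append(
            replace(
                base,
                total_length=base.total_length * rng.uniform(0.92, 1.08),
                shaft_radius=base.shaft_radius * rng.uniform(0.9, 1.1),
                distal_width_factor=1.0
                + (base.distal_width_factor - 1.0) * rng.uniform(0.85, 1.15),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return out
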