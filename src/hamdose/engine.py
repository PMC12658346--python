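"""Monte Carlo engine: scenes, scoring grids, dose maps, and simulation driver.

The engine transports photons from a :class:`~hamdose.geometry.DwellPlan`
through an analytic applicator/phantom geometry and scores dose to water as
collisional KERMA with a track-length estimator.  Dose maps are always indexed
in the flat ("transformed") frame; for bent applicators the scoring grid is
deformed to follow the applicator so that maps remain voxel-by-voxel
comparable with flat-applicator maps.

Uncertainties are batch-based: histories are split into ``n_batches``
independent batches and every metric's standard error derives from the spread
of batch means.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import _kernels
from .geometry import (ApplicatorSpec, CurvatureSpec, DwellPlan,
                       cable_polylines, deform_scoring_grid)
from .materials import MaterialLibrary, default_library
from .source import SourceGeometry, orthonormal_basis
from .spectrum import GammaSpectrum, ir192_spectrum

__all__ = [
    "TransportSettings", "PhantomSpec", "GridSpec", "DoseMap", "Scene",
    "run_simulation", "characterization_run", "sample_compton",
    "allocate_histories", "derive_seed",
]

MC_E_GRID_N = 256


def derive_seed(seed: int, tag: str) -> int:
    """Deterministic child seed below 2**31 from a base seed and a label."""
    h = hashlib.sha256(f"{seed}:{tag}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31 - 1)


@dataclass(frozen=True)
class TransportSettings:
    """Photon transport configuration.

    ``n_histories`` is the total photon budget over all dwells; the default is
    the desk-scale budget (the full-fidelity budget of the underlying study,
    9.0018e8 histories, is available by configuration).
    """

    n_histories: int = 20_000_000
    seed: int = 20177
    cutoff_keV: float = 10.0
    rayleigh: bool = False
    n_batches: int = 50
    substep_cm: float = 0.05        # deformed-grid scoring substep
    polar_substep_min: float = 0.03  # polar scoring substeps
    polar_substep_frac: float = 0.05

    def __post_init__(self):
        if not (self.n_histories >= self.n_batches >= 2):
            raise ValueError("need n_histories >= n_batches >= 2")
        if self.cutoff_keV < 10.0:
            raise ValueError("cutoff must be >= 10 keV (table range)")


@dataclass(frozen=True)
class PhantomSpec:
    """Infinite water phantom, or semi-infinite with air upstream.

    In semi-infinite mode everything upstream of the surface
    ``boundary_offset`` cm from the (possibly bent) source plane is air.
    """

    mode: str = "infinite"
    world_half: float = 50.0
    boundary_offset: float = 0.3

    def __post_init__(self):
        if self.mode not in ("infinite", "semi_infinite"):
            raise ValueError("mode must be 'infinite' or 'semi_infinite'")


@dataclass(frozen=True)
class GridSpec:
    """Axis-aligned voxel grid in the flat frame (x lateral, y depth, z long)."""

    origin: tuple[float, float, float]   # lower corner (edges), cm
    spacing: tuple[float, float, float]  # cm
    shape: tuple[int, int, int]

    def __post_init__(self):
        if any(n < 1 for n in self.shape) or any(s <= 0 for s in self.spacing):
            raise ValueError("invalid grid")

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def centers(self, axis: int) -> np.ndarray:
        return self.origin[axis] + (np.arange(self.shape[axis]) + 0.5) * self.spacing[axis]

    def center_array(self) -> np.ndarray:
        """(nx, ny, nz, 3) voxel-center coordinates."""
        cx, cy, cz = (self.centers(i) for i in range(3))
        X, Y, Z = np.meshgrid(cx, cy, cz, indexing="ij")
        return np.stack([X, Y, Z], axis=-1)

    def aabb(self) -> np.ndarray:
        lo = np.asarray(self.origin)
        hi = lo + np.asarray(self.spacing) * np.asarray(self.shape)
        return np.concatenate([lo, hi])

    # ---- standard grids of the study
    @staticmethod
    def prescription_column(voxel: float = 0.1) -> "GridSpec":
        """1 cm x 1 cm column of voxels centered on the axis at 1.0 cm depth."""
        n = int(round(1.0 / voxel))
        return GridSpec((-0.5, 1.0 - voxel / 2, -0.5), (voxel, voxel, voxel), (n, 1, n))

    @staticmethod
    def _depth_axis(voxel: float, depth: tuple[float, float]):
        # anchor a voxel-center layer at exactly 1.0 cm depth (prescription)
        c0 = 1.0 - voxel * np.round((1.0 - depth[0]) / voxel)
        ny = int(round((depth[1] - c0) / voxel)) + 1
        return c0 - voxel / 2, ny

    @staticmethod
    def lateral_plane(voxel: float = 0.2, half_lat: float = 5.5,
                      depth: tuple[float, float] = (0.5, 5.0)) -> "GridSpec":
        nx = int(round(2 * half_lat / voxel))
        oy, ny = GridSpec._depth_axis(voxel, depth)
        return GridSpec((-half_lat, oy, -voxel / 2),
                        (voxel, voxel, voxel), (nx, ny, 1))

    @staticmethod
    def longitudinal_plane(voxel: float = 0.2, half_long: float = 7.0,
                           depth: tuple[float, float] = (0.5, 5.0)) -> "GridSpec":
        nz = int(round(2 * half_long / voxel))
        oy, ny = GridSpec._depth_axis(voxel, depth)
        return GridSpec((-voxel / 2, oy, -half_long),
                        (voxel, voxel, voxel), (1, ny, nz))


@dataclass
class DoseMap:
    """Voxelized relative dose (per emitted history) with batch-based errors.

    ``dose`` and ``se`` are (nx, ny, nz); ``batch_doses`` is
    (n_batches, nx, ny, nz) and feeds every downstream uncertainty estimate.
    ``norm`` carries the normalization constant applied downstream (with its
    provenance tag); the stored arrays stay in per-history units.
    """

    grid: GridSpec
    dose: np.ndarray
    se: np.ndarray
    batch_doses: np.ndarray
    n_histories: int
    norm: float = 1.0
    norm_provenance: str = "unnormalized"
    excluded: np.ndarray | None = None

    def __post_init__(self):
        if np.any(self.dose < 0) or np.any(self.se < 0):
            raise ValueError("dose and standard error must be nonnegative")

    def region_mask(self, xlim=None, ylim=None, zlim=None) -> np.ndarray:
        eps = 1e-9
        m = np.ones(self.grid.shape, bool)
        for axis, lim in enumerate((xlim, ylim, zlim)):
            if lim is None:
                continue
            c = self.grid.centers(axis)
            sel = (c >= lim[0] - eps) & (c <= lim[1] + eps)
            shp = [1, 1, 1]
            shp[axis] = -1
            m &= sel.reshape(shp)
        return m

    def region_mean(self, mask: np.ndarray) -> tuple[float, float]:
        """Mean dose over masked voxels and its batch-based standard error."""
        if not np.any(mask):
            raise ValueError("region outside grid")
        vals = self.batch_doses[:, mask].mean(axis=1)
        nb = len(vals)
        return float(vals.mean()), float(vals.std(ddof=1) / np.sqrt(nb))

    def prescription_region_mask(self) -> np.ndarray:
        return self.region_mask(xlim=(-0.5, 0.5), ylim=(0.95, 1.05), zlim=(-0.5, 0.5))


@dataclass(frozen=True)
class Scene:
    """Applicator + phantom + media; resolves any point to a material."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    applicator: ApplicatorSpec | None = field(default_factory=ApplicatorSpec)
    curvature: CurvatureSpec = field(default_factory=CurvatureSpec)
    water_only: bool = False
    library: MaterialLibrary = field(default_factory=default_library)

    def kernel_arrays(self):
        app = self.applicator
        scene_i = np.array([
            1 if self.phantom.mode == "semi_infinite" else 0,
            self.curvature.bend_axis,
            1 if (self.water_only or app is None) else 0,
            0 if app is None else app.n_catheters,
        ], np.int64)
        if app is None:
            scene_f = np.array([self.curvature.a, 0, 0, 0,
                                self.phantom.boundary_offset, 0, 0,
                                self.phantom.world_half])
            cath = np.zeros(1)
        else:
            scene_f = np.array([
                self.curvature.a, app.flap_half_width, app.flap_half_length,
                app.patient_side_offset, self.phantom.boundary_offset,
                app.catheter_outer_radius, app.catheter_lumen_radius,
                self.phantom.world_half,
            ])
            cath = np.asarray(app.catheter_lateral_offsets, float)
        return scene_i, scene_f, cath

    def geometry_hash(self) -> str:
        payload = {
            "phantom": asdict(self.phantom),
            "applicator": None if self.applicator is None else asdict(self.applicator),
            "curvature": asdict(self.curvature),
            "water_only": self.water_only,
            "materials": {m.name: [m.density, sorted(m.composition.items())]
                          for m in self.library.transport_materials()},
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


# ------------------------------------------------------------------ tables

def _energy_tables(library: MaterialLibrary):
    e = np.geomspace(10.0, 1500.0, MC_E_GRID_N)
    logE0 = float(np.log(e[0]))
    invdlog = (MC_E_GRID_N - 1) / (np.log(e[-1]) - np.log(e[0]))
    mats = library.transport_materials()
    mu_t = np.stack([m.mu_linear(e) for m in mats])
    mu_maj = mu_t.max(axis=0)
    mu_en = library.mu_en_water(e)
    ne = np.array([m.electrons_per_gram * m.density for m in mats])
    mu_metal = np.stack([library.iridium.mu_linear(e), library.steel.mu_linear(e)])
    coh = library.coherent_fraction(e)
    return logE0, float(invdlog), mu_t, mu_maj, mu_en, ne, mu_metal, coh


def allocate_histories(times: np.ndarray, n_total: int) -> np.ndarray:
    """Integer history counts proportional to dwell times (largest remainder)."""
    t = np.asarray(times, float)
    if np.any(t < 0) or t.sum() <= 0:
        raise ValueError("dwell times must be nonnegative and not all zero")
    quota = n_total * t / t.sum()
    n = np.floor(quota).astype(np.int64)
    short = n_total - int(n.sum())
    if short > 0:
        order = np.argsort(-(quota - n), kind="stable")
        n[order[:short]] += 1
    return n


def _batch_counts(n_per_dwell: np.ndarray, n_batches: int):
    """Per-batch dwell allocations and history-uid bases (stable across pairs)."""
    base = np.concatenate([[0], np.cumsum(n_per_dwell)[:-1]])
    counts = np.empty((n_batches, len(n_per_dwell)), np.int64)
    uid0 = np.empty((n_batches, len(n_per_dwell)), np.int64)
    for b in range(n_batches):
        q, r = np.divmod(n_per_dwell, n_batches)
        counts[b] = q + (b < r)
        uid0[b] = base + b * q + np.minimum(b, r)
    return counts, uid0


_EMPTY_GRID = (np.zeros(3), np.ones(3), np.zeros(3, np.int64),
               np.zeros((1, 1, 1)), np.zeros(6))


def _grid_args(grid: GridSpec | None):
    if grid is None:
        o, sp, n, acc, aabb = _EMPTY_GRID
        return o, sp, n, np.zeros((1, 1, 1)), aabb
    o = np.asarray(grid.origin, float)
    sp = np.asarray(grid.spacing, float)
    n = np.asarray(grid.shape, np.int64)
    return o, sp, n, np.zeros(grid.shape), grid.aabb()


def _deformed_aabb(grid: GridSpec, curvature: CurvatureSpec, pad: float = 0.3):
    """Bounding box (real space) of the deformed grid region."""
    lo = np.asarray(grid.origin)
    hi = lo + np.asarray(grid.spacing) * np.asarray(grid.shape)
    xs = [np.linspace(lo[i], hi[i], 9) for i in range(3)]
    X, Y, Z = np.meshgrid(*xs, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)
    mapped, _ = deform_scoring_grid(pts, curvature)
    return np.concatenate([mapped.min(axis=0) - pad, mapped.max(axis=0) + pad])


def run_simulation(
    plan: DwellPlan,
    scene: Scene,
    grids: list[GridSpec],
    settings: TransportSettings,
    spectrum: GammaSpectrum | None = None,
    source: SourceGeometry | None = None,
    flat_plan: DwellPlan | None = None,
    primary_only: bool = False,
    include_metal: bool = True,
    pencil: tuple | None = None,
) -> list[DoseMap]:
    """Simulate a dwell plan and score dose maps on 1-2 grids.

    ``plan`` must already be posed in real space (use
    :func:`~hamdose.geometry.bend_plan` first for bent applicators and pass the
    original ``flat_plan`` so cable polylines follow the bent catheters).
    Histories are allocated to dwells proportional to dwell time with
    largest-remainder rounding.
    """
    if not 1 <= len(grids) <= 2:
        raise ValueError("one or two scoring grids")
    spectrum = spectrum or ir192_spectrum()
    source = source or SourceGeometry()
    if np.any(np.abs(plan.positions) > scene.phantom.world_half):
        raise ValueError("dwell pose outside the world volume")

    scene_i, scene_f, cath = scene.kernel_arrays()
    logE0, invdlog, mu_t, mu_maj, mu_en, ne, mu_metal, coh = _energy_tables(scene.library)

    n_per_dwell = allocate_histories(plan.times, settings.n_histories)
    counts, uid0 = _batch_counts(n_per_dwell, settings.n_batches)

    axes = plan.axes
    e1 = np.empty_like(axes)
    e2 = np.empty_like(axes)
    for i in range(plan.n_dwells):
        e1[i], e2[i] = orthonormal_basis(axes[i])

    curv = scene.curvature
    base_plan = flat_plan if flat_plan is not None else plan
    cables = cable_polylines(base_plan, curv, source)

    src_arr = np.array([source.active_radius, source.active_length / 2,
                        source.capsule_outer_radius, source.capsule_length / 2,
                        source.cable_radius])

    deformed = 1 if curv.a > 0 else 0
    g1 = grids[0]
    g2 = grids[1] if len(grids) > 1 else None
    g1o, g1sp, g1n, _, aabb1 = _grid_args(g1)
    g2o, g2sp, g2n, _, aabb2 = _grid_args(g2)
    if deformed:
        aabb1 = _deformed_aabb(g1, curv)
        if g2 is not None:
            aabb2 = _deformed_aabb(g2, curv)

    spec_E = spectrum.energies
    spec_cdf = spectrum.cdf
    pencil_arr = np.zeros(7)
    emission_mode = 0
    if pencil is not None:
        emission_mode = 1
        pencil_arr = np.concatenate([np.asarray(pencil[0], float),
                                     np.asarray(pencil[1], float),
                                     [float(pencil[2])]])

    r_edges = np.array([0.0, 1.0])
    th_edges = np.array([0.0, np.pi])
    accp = np.zeros((1, 1))

    nb = settings.n_batches
    batch1 = np.empty((nb,) + tuple(int(v) for v in (g1n if g1 else [1, 1, 1])))
    batch2 = (np.empty((nb,) + tuple(int(v) for v in g2n)) if g2 is not None else None)

    for b in range(nb):
        acc1 = np.zeros(tuple(int(v) for v in g1n)) if g1 else np.zeros((1, 1, 1))
        acc2 = np.zeros(tuple(int(v) for v in g2n)) if g2 is not None else np.zeros((1, 1, 1))
        _kernels.run_batch(
            np.uint64(settings.seed), uid0[b], counts[b],
            plan.positions, axes, e1, e2, src_arr, cables,
            spec_E, spec_cdf,
            logE0, invdlog, mu_t, mu_maj, mu_en, ne, mu_metal, coh,
            scene_i, scene_f, cath,
            settings.cutoff_keV, 1 if settings.rayleigh else 0,
            1 if primary_only else 0, 1 if include_metal else 0,
            0,
            g1o, g1sp, g1n, acc1, aabb1,
            g2o, g2sp, g2n, acc2, aabb2,
            deformed, settings.substep_cm,
            r_edges, th_edges, accp,
            settings.polar_substep_min, settings.polar_substep_frac,
            emission_mode, pencil_arr,
        )
        nb_hist = counts[b].sum()
        batch1[b] = acc1 / max(nb_hist, 1)
        if batch2 is not None:
            batch2[b] = acc2 / max(nb_hist, 1)

    out = []
    for grid, batches in ((g1, batch1), (g2, batch2)):
        if grid is None or batches is None:
            continue
        batches = batches / grid.voxel_volume
        if deformed:
            centers = grid.center_array().reshape(-1, 3)
            _, excl = deform_scoring_grid(centers, curv)
            excluded = excl.reshape(grid.shape)
        else:
            excluded = None
        dose = batches.mean(axis=0)
        se = batches.std(axis=0, ddof=1) / np.sqrt(nb)
        out.append(DoseMap(grid, dose, se, batches, settings.n_histories,
                           excluded=excluded))
    return out


def characterization_run(
    plan: DwellPlan,
    scene: Scene,
    r_edges: np.ndarray,
    theta_edges_rad: np.ndarray,
    settings: TransportSettings,
    spectrum: GammaSpectrum | None = None,
    source: SourceGeometry | None = None,
    include_metal: bool = True,
):
    """Score a (r, theta) polar dose array about the origin (axis = +z).

    Returns ``(dose (nr, nt), se, batch_doses (nb, nr, nt))`` in per-history
    units (already divided by the exact bin volumes).
    """
    spectrum = spectrum or ir192_spectrum()
    source = source or SourceGeometry()
    scene_i, scene_f, cath = scene.kernel_arrays()
    logE0, invdlog, mu_t, mu_maj, mu_en, ne, mu_metal, coh = _energy_tables(scene.library)

    n_per_dwell = allocate_histories(plan.times, settings.n_histories)
    counts, uid0 = _batch_counts(n_per_dwell, settings.n_batches)
    axes = plan.axes
    e1 = np.empty_like(axes)
    e2 = np.empty_like(axes)
    for i in range(plan.n_dwells):
        e1[i], e2[i] = orthonormal_basis(axes[i])
    cables = cable_polylines(plan, CurvatureSpec(0.0), source)
    src_arr = np.array([source.active_radius, source.active_length / 2,
                        source.capsule_outer_radius, source.capsule_length / 2,
                        source.cable_radius])
    g1o, g1sp, g1n, _, aabb1 = _grid_args(None)
    nr, nt = len(r_edges) - 1, len(theta_edges_rad) - 1
    # exact spherical-sector bin volumes
    ct = np.cos(theta_edges_rad)
    shell = (2 * np.pi / 3) * (np.asarray(r_edges[1:]) ** 3 - np.asarray(r_edges[:-1]) ** 3)
    vol = shell[:, None] * (ct[:-1] - ct[1:])[None, :]

    nb = settings.n_batches
    batches = np.empty((nb, nr, nt))
    for b in range(nb):
        accp = np.zeros((nr, nt))
        _kernels.run_batch(
            np.uint64(settings.seed), uid0[b], counts[b],
            plan.positions, axes, e1, e2, src_arr, cables,
            spectrum.energies, spectrum.cdf,
            logE0, invdlog, mu_t, mu_maj, mu_en, ne, mu_metal, coh,
            scene_i, scene_f, cath,
            settings.cutoff_keV, 1 if settings.rayleigh else 0,
            0, 1 if include_metal else 0,
            1,
            g1o, g1sp, g1n, np.zeros((1, 1, 1)), aabb1,
            g1o, g1sp, g1n, np.zeros((1, 1, 1)), aabb1,
            0, settings.substep_cm,
            np.asarray(r_edges, float), np.asarray(theta_edges_rad, float), accp,
            settings.polar_substep_min, settings.polar_substep_frac,
            0, np.zeros(7),
        )
        batches[b] = accp / max(counts[b].sum(), 1) / vol
    dose = batches.mean(axis=0)
    se = batches.std(axis=0, ddof=1) / np.sqrt(nb)
    return dose, se, batches


def sample_compton(energy_keV: float, n: int, seed: int = 0):
    """Klein-Nishina samples ``(E_out, cos theta)`` at a fixed energy."""
    if energy_keV <= 0:
        raise ValueError("energy must be positive")
    x = np.empty(n)
    ct = np.empty(n)
    _kernels.sample_compton_batch(np.uint64(seed), float(energy_keV), n, x, ct)
    return energy_keV * x, ct
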