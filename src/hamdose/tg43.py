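"""TG-43-style relative dose engine characterized from the in-package MC engine.

The dataset holds the radial dose function g_L(r) and the 2-D anisotropy
function F(r, theta) extracted from a single-source Monte Carlo run in a large
water cube, together with the line-source geometry factor
G_L(r, theta) = beta / (L r sin theta).  Relative dose is

    D(r, theta) = [G_L(r, theta) / G_L(r0, 90 deg)] * g_L(r) * F(r, theta)

normalized to 1 at the reference point (r0 = 1 cm, theta = 90 deg).  The whole
treatment study is expressed in relative dose; absolute calibration
(air-kerma strength, dose-rate constant) is out of scope.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import (GridSpec, PhantomSpec, Scene, TransportSettings,
                     characterization_run)
from .geometry import DwellPlan
from .source import SourceGeometry

__all__ = ["TG43Dataset", "geometry_factor_line", "characterize_tg43",
           "tg43_relative_dose", "tg43_dose_map", "PrecisionError"]

log = logging.getLogger(__name__)


class PrecisionError(RuntimeError):
    """A characterized node's Monte Carlo standard error exceeds tolerance."""


def geometry_factor_line(r, theta_rad, L):
    """Line-source geometry factor G_L(r, theta) = beta/(L r sin theta).

    The sin(theta) = 0 limit is the analytic 1/(r^2 - L^2/4); beta is the
    angle subtended by the active line at the point.
    """
    r = np.asarray(r, float)
    th = np.asarray(theta_rad, float)
    if np.any(r <= 0):
        raise ValueError("r must be positive")
    rho = r * np.sin(th)
    z = r * np.cos(th)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.arctan2(rho, z - L / 2) - np.arctan2(rho, z + L / 2)
        g = beta / (L * rho)
    axial = np.abs(rho) < 1e-9
    g = np.where(axial, 1.0 / np.maximum(z * z - L * L / 4, 1e-12), g)
    return g if g.ndim else float(g)


@dataclass
class TG43Dataset:
    """Characterized source dataset (all dimensionless except lengths in cm)."""

    L: float
    r_nodes: np.ndarray        # cm, geometric spacing
    gL: np.ndarray             # g_L at r_nodes, g_L(r0) = 1
    theta_nodes_deg: np.ndarray
    F: np.ndarray              # (n_r, n_theta), F(r, 90 deg) = 1
    ref_dose_per_history: float  # MC dose (arb.) at (r0, 90 deg) per history
    r0: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self._warned = False
        self.r_nodes = np.asarray(self.r_nodes, float)
        self.gL = np.asarray(self.gL, float)
        self.theta_nodes_deg = np.asarray(self.theta_nodes_deg, float)
        self.F = np.asarray(self.F, float)
        if np.any(self.gL <= 0) or np.any(self.F <= 0):
            raise ValueError("g_L and F must be positive")
        if abs(self._interp_g(np.array([self.r0]))[0] - 1.0) > 1e-6:
            raise ValueError("g_L(r0) must be 1 after normalization")
        j90 = int(np.argmin(np.abs(self.theta_nodes_deg - 90.0)))
        if np.max(np.abs(self.F[:, j90] - 1.0)) > 1e-9:
            raise ValueError("F(r, 90 deg) must be 1 after normalization")

    # ---- interpolation (log-linear in r for g_L, bilinear in (log r, theta) for F)
    def _clip_r(self, r):
        rmin, rmax = self.r_nodes[0], self.r_nodes[-1]
        out = np.clip(r, rmin, rmax)
        if not self._warned and (np.any(r < rmin) or np.any(r > rmax)):
            self._warned = True
            log.warning("TG-43 table queried outside r range [%g, %g] cm; "
                        "nearest-node values used", rmin, rmax)
        return out

    def _interp_g(self, r):
        lr = np.log(self.r_nodes)
        return np.exp(np.interp(np.log(self._clip_r(r)), lr, np.log(self.gL)))

    def _interp_F(self, r, theta_deg):
        lr = np.log(self._clip_r(r))
        lnodes = np.log(self.r_nodes)
        th = np.clip(theta_deg, self.theta_nodes_deg[0], self.theta_nodes_deg[-1])
        i = np.clip(np.searchsorted(lnodes, lr) - 1, 0, len(lnodes) - 2)
        j = np.clip(np.searchsorted(self.theta_nodes_deg, th) - 1, 0,
                    len(self.theta_nodes_deg) - 2)
        wr = (lr - lnodes[i]) / (lnodes[i + 1] - lnodes[i])
        wt = (th - self.theta_nodes_deg[j]) / (
            self.theta_nodes_deg[j + 1] - self.theta_nodes_deg[j])
        F = self.F
        return ((1 - wr) * (1 - wt) * F[i, j] + wr * (1 - wt) * F[i + 1, j]
                + (1 - wr) * wt * F[i, j + 1] + wr * wt * F[i + 1, j + 1])

    def relative_dose(self, r, theta_deg):
        """Relative dose rate at polar points; 1 at (r0, 90 deg)."""
        r = np.asarray(r, float)
        if np.any(r <= 0):
            raise ValueError("r must be positive")
        th = np.deg2rad(np.asarray(theta_deg, float))
        g_ref = geometry_factor_line(self.r0, np.pi / 2, self.L)
        G = geometry_factor_line(r, th, self.L) / g_ref
        return G * self._interp_g(r) * self._interp_F(r, np.asarray(theta_deg, float))

    def dose_from_plan(self, plan: DwellPlan, points: np.ndarray) -> np.ndarray:
        """Superposed relative dose at arbitrary points (times as weights).

        The result is per unit total dwell weight, so doubling all dwell times
        leaves it unchanged.
        """
        pts = np.atleast_2d(np.asarray(points, float))
        total = np.zeros(len(pts))
        tsum = plan.times.sum()
        for i in range(plan.n_dwells):
            if plan.times[i] == 0:
                continue
            v = pts - plan.positions[i]
            r = np.linalg.norm(v, axis=1)
            ct = np.clip(v @ plan.axes[i] / np.maximum(r, 1e-12), -1, 1)
            total += plan.times[i] * self.relative_dose(r, np.degrees(np.arccos(ct)))
        return total / tsum

    # ---- serialization
    def save(self, directory):
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        pd.DataFrame({"r_cm": self.r_nodes, "gL": self.gL}).to_csv(
            d / "gL.csv", index=False)
        rr, tt = np.meshgrid(self.r_nodes, self.theta_nodes_deg, indexing="ij")
        pd.DataFrame({"r_cm": rr.ravel(), "theta_deg": tt.ravel(),
                      "F": self.F.ravel()}).to_csv(d / "F.csv", index=False)
        with open(d / "meta.json", "w") as f:
            json.dump({"L": self.L, "r0": self.r0,
                       "ref_dose_per_history": self.ref_dose_per_history,
                       **self.meta}, f, indent=1)

    @classmethod
    def load(cls, directory) -> "TG43Dataset":
        d = Path(directory)
        g = pd.read_csv(d / "gL.csv")
        Fdf = pd.read_csv(d / "F.csv")
        meta = json.load(open(d / "meta.json"))
        r = g["r_cm"].to_numpy()
        th = np.unique(Fdf["theta_deg"].to_numpy())
        F = Fdf.pivot(index="r_cm", columns="theta_deg", values="F").to_numpy()
        return cls(meta.pop("L"), r, g["gL"].to_numpy(), th, F,
                   meta.pop("ref_dose_per_history"), meta.pop("r0"), meta)


def _theta_edges(step_deg: float) -> np.ndarray:
    half = step_deg / 2
    inner = np.arange(half, 180.0, step_deg)
    return np.deg2rad(np.concatenate([[0.0], inner, [180.0]]))


def characterize_tg43(
    geometry: SourceGeometry,
    settings: TransportSettings,
    scene: Scene | None = None,
    r_edges: np.ndarray | None = None,
    theta_step_deg: float = 5.0,
    se_tolerance: float | None = 0.05,
    include_metal: bool = True,
) -> TG43Dataset:
    """Characterize g_L(r), F(r, theta) from a single centered source in water.

    The source sits at the origin (axis +z) of a 100-cm cubical water volume,
    approximating the infinite-water TG-43 condition; dose is scored on a
    polar (r, theta) grid and converted to g_L and F with the line-source
    geometry factor.  Radial nodes are placed at the 1/r^2-weighted effective
    radius of each shell.
    """
    if r_edges is None:
        r_edges = np.geomspace(0.2, 12.5, 29)
    r_edges = np.asarray(r_edges, float)
    th_edges = _theta_edges(theta_step_deg)
    scene = scene or Scene(phantom=PhantomSpec("infinite"), applicator=None,
                           water_only=True)

    plan = DwellPlan(np.array([0]), np.array([0]), np.zeros((1, 3)),
                     np.array([[0.0, 0.0, 1.0]]), np.array([1.0]),
                     "characterization", None)
    dose, se, _ = characterization_run(plan, scene, r_edges, th_edges, settings,
                                       source=geometry,
                                       include_metal=include_metal)

    r1, r2 = r_edges[:-1], r_edges[1:]
    r_nodes = np.sqrt((r1 * r1 + r1 * r2 + r2 * r2) / 3.0)
    ct_edges = np.cos(th_edges)
    th_nodes = np.degrees(np.arccos((ct_edges[:-1] + ct_edges[1:]) / 2.0))

    if se_tolerance is not None:
        rel = np.where(dose > 0, se / np.maximum(dose, 1e-300), np.inf)
        # treatment region: pole bins carry little solid angle and are only
        # queried for near-axis points, so they are excluded from the gate
        use_r = r_nodes <= 10.0
        use_t = (th_nodes >= 5.0) & (th_nodes <= 175.0)
        sub = rel[np.ix_(use_r, use_t)]
        worst = np.unravel_index(np.argmax(sub), sub.shape)
        if sub.max() > se_tolerance:
            raise PrecisionError(
                f"node (r={r_nodes[use_r][worst[0]]:.2f} cm, "
                f"theta={th_nodes[use_t][worst[1]]:.1f} deg) has relative SE "
                f"{sub.max():.3f} > {se_tolerance}")

    L = geometry.active_length
    j90 = int(np.argmin(np.abs(th_nodes - 90.0)))
    th_rad = np.deg2rad(th_nodes)
    G = geometry_factor_line(np.repeat(r_nodes, len(th_nodes)),
                             np.tile(th_rad, len(r_nodes)), L
                             ).reshape(len(r_nodes), len(th_nodes))
    d90 = dose[:, j90]
    g_raw = d90 / G[:, j90]
    g_at_r0 = np.exp(np.interp(np.log(1.0), np.log(r_nodes), np.log(g_raw)))
    gL = g_raw / g_at_r0

    F = dose * G[:, j90][:, None] / (d90[:, None] * G)
    F[:, j90] = 1.0

    ref = float(np.exp(np.interp(np.log(1.0), np.log(r_nodes), np.log(d90))))
    meta = {"n_histories": settings.n_histories, "seed": settings.seed,
            "theta_step_deg": theta_step_deg}
    return TG43Dataset(L, r_nodes, gL, th_nodes, F, ref, 1.0, meta)


def tg43_relative_dose(dataset: TG43Dataset, points) -> np.ndarray:
    """Relative dose at (r, theta_deg) pairs; thin wrapper over the dataset."""
    pts = np.atleast_2d(np.asarray(points, float))
    return dataset.relative_dose(pts[:, 0], pts[:, 1])


def tg43_dose_map(dataset: TG43Dataset, plan: DwellPlan, grid: GridSpec,
                  subsample: int = 4) -> np.ndarray:
    """Voxel-averaged TG-43 dose of a plan on a grid (flat geometry).

    Each voxel is averaged over ``subsample**3`` midpoint subsamples so the
    result is comparable with the MC track-length voxel mean.
    """
    offs = [(np.arange(subsample) + 0.5) / subsample * grid.spacing[i]
            for i in range(3)]
    centers = [grid.origin[i] + np.arange(grid.shape[i]) * grid.spacing[i]
               for i in range(3)]
    axes_pts = [np.add.outer(centers[i], offs[i]).ravel() for i in range(3)]
    X, Y, Z = np.meshgrid(*axes_pts, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=-1)
    vals = dataset.dose_from_plan(plan, pts)
    shape = (grid.shape[0], subsample, grid.shape[1], subsample,
             grid.shape[2], subsample)
    return vals.reshape(shape).mean(axis=(1, 3, 5))
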