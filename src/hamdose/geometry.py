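"""HAM applicator geometry: plan template, parabolic bending, grid deformation.

Coordinate convention (cm): x is lateral (across catheters), z is longitudinal
(along catheters), y is depth, positive toward the patient.  The source plane is
y = 0; the patient-side flap surface is y = +0.5 and the upstream surface is
y = -0.3 for the default 0.8-cm flap.

Bending follows y = -a*u^2 where u is the in-plane coordinate along the bending
axis: the applicator curls *away* from the patient, and embedded lengths are
inextensible, so flat in-plane coordinates are treated as arc lengths along the
bent mid-source-plane.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .source import SourceGeometry

__all__ = [
    "ApplicatorSpec", "CurvatureSpec", "DwellPlan",
    "build_flat_plan_template", "parabola_arclength", "arclength_to_x",
    "radius_of_curvature", "bend_plan", "deform_scoring_grid",
    "cable_polylines", "project_to_parabola",
]


@dataclass(frozen=True)
class ApplicatorSpec:
    """6-catheter, 8-cm HAM applicator by default (all lengths cm)."""

    n_catheters: int = 6
    catheter_spacing: float = 1.0
    flap_thickness: float = 0.8
    patient_side_offset: float = 0.5   # source plane -> patient-side surface
    upstream_offset: float = 0.3       # source plane -> upstream surface
    catheter_outer_radius: float = 0.10
    catheter_lumen_radius: float = 0.07
    treatment_length: float = 8.0
    dwell_step: float = 0.5
    flap_margin: float = 0.5           # flap extends this far beyond the dwell array

    def __post_init__(self):
        if abs(self.flap_thickness - (self.patient_side_offset + self.upstream_offset)) > 1e-9:
            raise ValueError("flap thickness must equal the sum of the two surface offsets")
        if self.n_catheters >= 2 and self.catheter_spacing <= 2 * self.catheter_outer_radius:
            raise ValueError("catheter spacing must exceed the catheter diameter")
        if self.catheter_lumen_radius >= self.catheter_outer_radius:
            raise ValueError("lumen radius must be smaller than the outer radius")
        n_steps = self.treatment_length / self.dwell_step
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ValueError("treatment length must be an integer multiple of the dwell step")

    @property
    def dwells_per_catheter(self) -> int:
        return int(round(self.treatment_length / self.dwell_step)) + 1

    @property
    def n_dwells(self) -> int:
        return self.n_catheters * self.dwells_per_catheter

    @property
    def catheter_lateral_offsets(self) -> np.ndarray:
        n = self.n_catheters
        return (np.arange(n) - (n - 1) / 2.0) * self.catheter_spacing

    @property
    def flap_half_width(self) -> float:  # lateral
        span = (self.n_catheters - 1) * self.catheter_spacing / 2.0
        return span + self.flap_margin

    @property
    def flap_half_length(self) -> float:  # longitudinal
        return self.treatment_length / 2.0 + self.flap_margin


@dataclass(frozen=True)
class CurvatureSpec:
    """Parabolic bending y = -a*u^2, away from the patient.

    ``a`` in 1/cm; orientation 'lateral' bends across the catheters,
    'longitudinal' along them.  Clinical range per the applicator-conformation
    literature: a in {0.09, 0.25, 0.54}.
    """

    a: float = 0.0
    orientation: str = "lateral"

    def __post_init__(self):
        if self.a < 0:
            raise ValueError("curvature parameter a must be >= 0")
        if self.orientation not in ("lateral", "longitudinal"):
            raise ValueError("orientation must be 'lateral' or 'longitudinal'")

    @property
    def bend_axis(self) -> int:
        """Kernel code: 0 = flat, 1 = lateral (x), 2 = longitudinal (z)."""
        if self.a == 0:
            return 0
        return 1 if self.orientation == "lateral" else 2


@dataclass
class DwellPlan:
    """Dwell positions, source-axis orientations, and relative dwell times."""

    catheter_index: np.ndarray
    step_index: np.ndarray
    positions: np.ndarray      # (n, 3)
    axes: np.ndarray           # (n, 3) unit vectors
    times: np.ndarray          # (n,) relative, >= 0
    provenance: str = "flat-template"
    spec: ApplicatorSpec | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        if np.any(self.times < 0):
            raise ValueError("dwell times must be nonnegative")
        if self.positions.shape != (self.n_dwells, 3):
            raise ValueError("positions shape mismatch")
        norms = np.linalg.norm(self.axes, axis=1)
        if np.any(np.abs(norms - 1) > 1e-9):
            raise ValueError("axes must be unit vectors")

    @property
    def n_dwells(self) -> int:
        return len(self.times)

    def with_times(self, times, provenance=None) -> "DwellPlan":
        return DwellPlan(self.catheter_index, self.step_index, self.positions,
                         self.axes, np.asarray(times, float),
                         provenance or self.provenance, self.spec)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "catheter": self.catheter_index, "step": self.step_index,
            "x_cm": self.positions[:, 0], "y_cm": self.positions[:, 1],
            "z_cm": self.positions[:, 2],
            "ax": self.axes[:, 0], "ay": self.axes[:, 1], "az": self.axes[:, 2],
            "time_rel": self.times,
        })

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, spec=None, provenance="loaded") -> "DwellPlan":
        df = pd.read_csv(path)
        return cls(df["catheter"].to_numpy(int), df["step"].to_numpy(int),
                   df[["x_cm", "y_cm", "z_cm"]].to_numpy(float),
                   df[["ax", "ay", "az"]].to_numpy(float),
                   df["time_rel"].to_numpy(float), provenance, spec)


def build_flat_plan_template(spec: ApplicatorSpec) -> DwellPlan:
    """Unit-time dwell template on the flat source plane.

    Catheters sit at lateral offsets symmetric about x = 0; dwells step along z
    symmetric about z = 0; all source axes point along +z (distal).
    """
    xs = spec.catheter_lateral_offsets
    m = spec.dwells_per_catheter
    zs = (np.arange(m) - (m - 1) / 2.0) * spec.dwell_step
    cat, step = np.meshgrid(np.arange(spec.n_catheters), np.arange(m), indexing="ij")
    cat, step = cat.ravel(), step.ravel()
    pos = np.column_stack([xs[cat], np.zeros(cat.size), zs[step]])
    axes = np.tile([0.0, 0.0, 1.0], (cat.size, 1))
    return DwellPlan(cat, step, pos, axes, np.ones(cat.size), "flat-template", spec)


# ---------------------------------------------------------------- parabola math

def parabola_arclength(a: float, x) -> np.ndarray | float:
    """Arc length of y = a*x^2 from 0 to x (odd in x); closed form."""
    if a < 0:
        raise ValueError("a must be >= 0")
    x = np.asarray(x, float)
    if a == 0:
        s = x.copy()
    else:
        q = 2 * a * x
        s = 0.5 * (x * np.sqrt(1 + q * q) + np.arcsinh(q) / (2 * a))
    return float(s) if s.ndim == 0 else s


def arclength_to_x(a: float, s) -> np.ndarray | float:
    """Inverse of :func:`parabola_arclength`, Newton-iterated below 1e-12 cm."""
    if a < 0:
        raise ValueError("a must be >= 0")
    s_arr = np.atleast_1d(np.asarray(s, float))
    if a == 0:
        out = s_arr.copy()
    else:
        x = s_arr.copy()
        for _ in range(60):
            f = parabola_arclength(a, x) - s_arr
            fp = np.sqrt(1 + (2 * a * x) ** 2)
            dx = f / fp
            x = x - dx
            if np.max(np.abs(dx)) < 1e-13:
                break
        out = x
    return float(out[0]) if np.ndim(s) == 0 else out.reshape(np.shape(s))


def radius_of_curvature(a: float) -> float:
    """Osculating-circle radius at the parabola apex, R = 1/(2a)."""
    if a < 0:
        raise ValueError("a must be >= 0")
    return math.inf if a == 0 else 1.0 / (2.0 * a)


def _cbrt(x: float) -> float:
    return math.copysign(abs(x) ** (1.0 / 3.0), x)


def project_to_parabola_impl(a: float, u: float, w: float) -> float:
    """Parameter t of the point on the curve w_c(t) = -a*t^2 nearest to (u, w).

    The stationarity condition is the cubic 2a^2 t^3 + (1+2aw) t - u = 0,
    solved in closed form; inside the caustic (three real roots) the root with
    the smallest Euclidean distance is returned.  Pure-math implementation so
    the MC kernel can jit-compile the same function.
    """
    if a == 0.0:
        return u
    c2 = 2.0 * a * a
    p = (1.0 + 2.0 * a * w) / c2
    q = -u / c2
    disc = 0.25 * q * q + p * p * p / 27.0
    if disc >= 0.0:
        rt = math.sqrt(disc)
        u1 = -0.5 * q + rt
        u2 = -0.5 * q - rt
        return (math.copysign(abs(u1) ** (1.0 / 3.0), u1)
                + math.copysign(abs(u2) ** (1.0 / 3.0), u2))
    m = 2.0 * math.sqrt(-p / 3.0)
    arg = 3.0 * q / (p * m)
    if arg > 1.0:
        arg = 1.0
    elif arg < -1.0:
        arg = -1.0
    theta = math.acos(arg) / 3.0
    best_t, best_d = 0.0, 1e300
    for k in range(3):
        t = m * math.cos(theta - 2.0943951023931953 * k)
        dw = -a * t * t - w
        d = (t - u) * (t - u) + dw * dw
        if d < best_d:
            best_d, best_t = d, t
    return best_t


def project_to_parabola(a: float, u: float, w: float) -> tuple[float, float, float]:
    """Nearest-point data for (u, w) against the bent surface w = -a*u^2.

    Returns ``(t, s, d)``: curve parameter, arc length at t, and signed normal
    distance (positive toward the patient).
    """
    t = project_to_parabola_impl(a, u, w)
    sn = math.sqrt(1 + (2 * a * t) ** 2)
    d = ((u - t) * 2 * a * t + (w + a * t * t)) / sn
    return t, parabola_arclength(a, t), d


# ------------------------------------------------------------------- operations

def bend_plan(plan: DwellPlan, curvature: CurvatureSpec) -> DwellPlan:
    """Wrap a flat plan onto the bent surface, preserving arc lengths.

    The flat in-plane coordinate along the bending axis becomes inextensible
    arc length s; the dwell moves to (x(s), -a x(s)^2) in the bending plane.
    For longitudinal bending the source axis becomes the local tangent; for
    lateral bending the axes stay longitudinal.  Times are copied unchanged.
    """
    a = curvature.a
    if a == 0:
        return replace_provenance(plan, f"{plan.provenance}")
    pos = plan.positions.copy()
    axes = plan.axes.copy()
    if curvature.orientation == "lateral":
        s = pos[:, 0]
        t = arclength_to_x(a, s)
        pos[:, 0] = t
        pos[:, 1] = pos[:, 1] - a * t**2
    else:
        s = pos[:, 2]
        t = arclength_to_x(a, s)
        pos[:, 2] = t
        pos[:, 1] = pos[:, 1] - a * t**2
        tang = np.column_stack([np.zeros_like(t), -2 * a * t, np.ones_like(t)])
        axes = tang / np.linalg.norm(tang, axis=1, keepdims=True)
    return DwellPlan(plan.catheter_index, plan.step_index, pos, axes, plan.times,
                     f"bent(a={a},{curvature.orientation})", plan.spec)


def replace_provenance(plan: DwellPlan, provenance: str) -> DwellPlan:
    return DwellPlan(plan.catheter_index, plan.step_index, plan.positions.copy(),
                     plan.axes.copy(), plan.times.copy(), provenance, plan.spec)


def deform_scoring_grid(centers_flat: np.ndarray, curvature: CurvatureSpec):
    """Map flat-frame voxel centers onto the bent geometry.

    ``centers_flat`` is (..., 3) in flat coordinates (x, y=depth, z).  Each
    center (u, v, d) maps to P(u) + d*nhat(u) on the bent surface, with the
    transverse coordinate v unchanged, so a dose map indexed by flat
    coordinates is voxel-by-voxel comparable with flat-applicator maps.

    Returns ``(mapped positions, excluded mask)`` where excluded marks
    fold-over voxels (|d| beyond the local radius of curvature on the concave
    side, Jacobian 1 + d*kappa <= 0).
    """
    c = np.asarray(centers_flat, float)
    flat_shape = c.shape
    c = c.reshape(-1, 3)
    a = curvature.a
    mapped = c.copy()
    excluded = np.zeros(len(c), bool)
    if a > 0:
        iu = 0 if curvature.orientation == "lateral" else 2
        s = c[:, iu]
        d = c[:, 1]
        t = arclength_to_x(a, s)
        sn = np.sqrt(1 + (2 * a * t) ** 2)
        nx, nw = 2 * a * t / sn, 1.0 / sn
        mapped[:, iu] = t + d * nx
        mapped[:, 1] = -a * t**2 + d * nw
        kappa = 2 * a / sn**3
        excluded = (1 + d * kappa) <= 0
    return mapped.reshape(flat_shape), excluded.reshape(flat_shape[:-1])


def cable_polylines(flat_plan: DwellPlan, curvature: CurvatureSpec,
                    source: SourceGeometry, seg_step: float = 0.5) -> np.ndarray:
    """Drive-cable polylines, one per dwell, laid proximally along the catheter.

    The cable starts just behind the capsule and runs ``source.cable_length``
    cm toward the proximal (-z) end; for longitudinal bending it follows the
    (extended) parabola, which is how a curved cable comes to intercept the
    radiation field.  Returns (n_dwells, n_pts, 3).
    """
    a = curvature.a
    n = flat_plan.n_dwells
    start = source.capsule_length / 2.0
    arcs = -np.arange(start, start + source.cable_length + seg_step / 2, seg_step)
    npts = arcs.size
    out = np.empty((n, npts, 3))
    bent = bend_plan(flat_plan, curvature) if a > 0 else flat_plan
    if a == 0 or curvature.orientation == "lateral":
        for i in range(n):
            p = bent.positions[i]
            out[i] = p[None, :] + np.outer(arcs, [0.0, 0.0, 1.0])
    else:
        for i in range(n):
            s0 = flat_plan.positions[i, 2]
            s_pts = s0 + arcs
            t = arclength_to_x(a, s_pts)
            out[i, :, 0] = flat_plan.positions[i, 0]
            out[i, :, 1] = -a * t**2
            out[i, :, 2] = t
    return out
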