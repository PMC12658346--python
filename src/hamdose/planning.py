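"""Dwell-time optimization on the flat TG-43 model (the TPS-equivalent step).

The plan aims for uniform relative dose at prescription points placed 1.0 cm
below each dwell position.  The default solver is nonnegative least squares on
the uniform-dose objective sum_j (D_j - 1)^2 — deterministic and reproducible —
with a seeded simulated-annealing refinement available for parity with the
inverse-planning-by-annealing character of commercial optimizers.  Optimized
times are finally rescaled so the central-axis prescription dose equals 1.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .engine import GridSpec
from .geometry import DwellPlan
from .tg43 import TG43Dataset, tg43_dose_map

__all__ = ["PrescriptionPointSet", "place_prescription_points",
           "influence_matrix", "optimize_dwell_times", "prescription_norm"]

PRESCRIPTION_DEPTH = 1.0  # cm below the source plane


@dataclass(frozen=True)
class PrescriptionPointSet:
    """One point per dwell, directly below it at 1.0 cm depth; target dose 1."""

    points: np.ndarray  # (n, 3)
    target: float = 1.0

    def __post_init__(self):
        if np.any(np.abs(self.points[:, 1] - PRESCRIPTION_DEPTH) > 1e-9):
            raise ValueError("prescription points must sit at exactly 1.0 cm depth")


def place_prescription_points(plan: DwellPlan) -> PrescriptionPointSet:
    """Translate each (flat) dwell by +1.0 cm in depth."""
    if np.any(np.abs(plan.positions[:, 1]) > 1e-9):
        raise ValueError("prescription points are defined for a flat plan")
    pts = plan.positions.copy()
    pts[:, 1] += PRESCRIPTION_DEPTH
    return PrescriptionPointSet(pts)


def influence_matrix(plan: DwellPlan, points: PrescriptionPointSet,
                     dataset: TG43Dataset) -> np.ndarray:
    """(n_points, n_dwells) relative dose per unit dwell time."""
    A = np.empty((len(points.points), plan.n_dwells))
    for i in range(plan.n_dwells):
        v = points.points - plan.positions[i]
        r = np.linalg.norm(v, axis=1)
        ct = np.clip(v @ plan.axes[i] / np.maximum(r, 1e-12), -1, 1)
        A[:, i] = dataset.relative_dose(r, np.degrees(np.arccos(ct)))
    return A


def _symmetrize(times: np.ndarray, plan: DwellPlan) -> np.ndarray:
    """Average times over the lateral and longitudinal mirror images.

    The uniform-dose objective is convex and invariant under both mirrors of
    the default template, so the average of optimal images is optimal too.
    """
    spec = plan.spec
    if spec is None:
        return times
    nc, m = spec.n_catheters, spec.dwells_per_catheter
    if times.size != nc * m:
        return times
    t = times.reshape(nc, m)
    t = (t + t[::-1, :] + t[:, ::-1] + t[::-1, ::-1]) / 4.0
    return t.ravel()


def _anneal(A, t0, rng, n_iter=2000, temp0=1e-3):
    """Seeded simulated-annealing polish of the NNLS solution."""
    t = t0.copy()
    resid = A @ t - 1.0
    obj = resid @ resid
    scale = max(t.max(), 1e-12)
    for k in range(n_iter):
        temp = temp0 * (1.0 - k / n_iter) + 1e-9
        i = rng.integers(len(t))
        delta = rng.normal(0.0, 0.05 * scale)
        ti = max(0.0, t[i] + delta)
        new_resid = resid + A[:, i] * (ti - t[i])
        new_obj = new_resid @ new_resid
        if new_obj < obj or rng.random() < np.exp(-(new_obj - obj) / temp):
            t[i], resid, obj = ti, new_resid, new_obj
    return t


def optimize_dwell_times(
    template: DwellPlan,
    points: PrescriptionPointSet,
    dataset: TG43Dataset,
    smoothness: float = 0.0,
    symmetrize: bool = True,
    anneal: bool = False,
    seed: int = 0,
) -> DwellPlan:
    """Nonnegative dwell times minimizing sum_j (D_j - 1)^2.

    ``smoothness`` adds lam * ||Dt||^2 on neighboring-dwell time differences.
    Returned times are rescaled so the mean TG-43 dose over the central
    prescription voxel column (1 cm x 1 cm at 1.0 cm depth) equals 1.
    """
    A = influence_matrix(template, points, dataset)
    if not np.any(A):
        raise ValueError("influence matrix is identically zero")
    b = np.full(len(points.points), points.target)
    if smoothness > 0:
        n = template.n_dwells
        D = (np.eye(n - 1, n, 1) - np.eye(n - 1, n)) * np.sqrt(smoothness)
        A_fit = np.vstack([A, D])
        b_fit = np.concatenate([b, np.zeros(n - 1)])
    else:
        A_fit, b_fit = A, b
    t, _ = nnls(A_fit, b_fit)
    if anneal:
        t = _anneal(A, t, np.random.default_rng(seed))
    if symmetrize:
        t = _symmetrize(t, template)
    # relative-dose maps are invariant under a common rescaling of the times
    # (histories are allocated proportionally), so times are reported with the
    # longest dwell at 1; the prescription normalization is carried by the
    # reference constant computed after optimization.
    return template.with_times(t / t.max(), "flat-optimized")


def prescription_norm(dataset: TG43Dataset, plan: DwellPlan) -> float:
    """TG-43 mean dose over the central prescription voxel column.

    This per-unit-weight constant is the '100%' that every dose map of the
    study is normalized by.
    """
    return float(tg43_dose_map(dataset, plan, GridSpec.prescription_column()).mean())
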