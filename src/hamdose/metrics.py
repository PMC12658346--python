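"""Dose-map metrics: prescription dose, PDD, isodose contours, map comparison.

All metrics operate on normalized dose (fraction of the reference prescription
dose) and are therefore invariant under a common rescaling of map and norm.
Standard errors derive from the per-batch dose arrays carried by every
:class:`~hamdose.engine.DoseMap`.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import measure

from .engine import DoseMap

__all__ = ["prescription_dose", "pdd", "isodose_contours", "compare_maps",
           "MetricsReport"]


def prescription_dose(dose_map: DoseMap, reference_norm: float) -> tuple[float, float]:
    """Prescription-point dose as % of the reference, with standard error.

    The prescription region is the mean over voxels at 1.0 cm depth within
    +-0.5 cm of the central axis in both in-plane coordinates (clipped to the
    voxels the map actually covers, e.g. a single central plane).
    """
    mask = dose_map.prescription_region_mask()
    if not np.any(mask):
        raise ValueError("map does not cover the prescription region")
    mean, se = dose_map.region_mean(mask)
    return 100.0 * mean / reference_norm, 100.0 * se / reference_norm


def pdd(dose_map: DoseMap, reference_norm: float) -> pd.DataFrame:
    """Central-axis percent depth dose: mean over |x|,|z| <= 0.5 cm per depth."""
    mask = dose_map.region_mask(xlim=(-0.5, 0.5), zlim=(-0.5, 0.5))
    depths = dose_map.grid.centers(1)
    rows = []
    for iy, d in enumerate(depths):
        m = np.zeros_like(mask)
        m[:, iy, :] = mask[:, iy, :]
        val, se = dose_map.region_mean(m)
        rows.append((d, 100.0 * val / reference_norm, 100.0 * se / reference_norm))
    return pd.DataFrame(rows, columns=["depth_cm", "dose_pct", "se_pct"])


def _plane_slice(arr: np.ndarray, grid) -> tuple[np.ndarray, int, int]:
    """Squeeze a (nx, ny, nz) plane map to 2-D, returning the two kept axes."""
    thin = int(np.argmin(arr.shape))
    kept = [i for i in range(3) if i != thin]
    sl = [slice(None)] * 3
    sl[thin] = arr.shape[thin] // 2
    return arr[tuple(sl)], kept[0], kept[1]


def isodose_contours(dose_map: DoseMap, reference_norm: float,
                     levels=(0.25, 0.5, 0.75, 1.0, 1.25)) -> dict:
    """Marching-squares isodose polylines on a plane map, in cm coordinates.

    Returns {level: [poly (n, 2) arrays in (first-axis cm, depth-or-second cm)]};
    a level outside the data range yields an empty list.
    """
    arr2d, ax_a, ax_b = _plane_slice(dose_map.dose / reference_norm, dose_map.grid)
    ca = dose_map.grid.centers(ax_a)
    cb = dose_map.grid.centers(ax_b)
    out = {}
    for lev in levels:
        polys = []
        if arr2d.min() < lev < arr2d.max():
            for c in measure.find_contours(arr2d, lev):
                polys.append(np.column_stack([
                    np.interp(c[:, 0], np.arange(len(ca)), ca),
                    np.interp(c[:, 1], np.arange(len(cb)), cb)]))
        out[lev] = polys
    return out


def compare_maps(map_a: DoseMap, ref_vals: np.ndarray, norm_a: float,
                 norm_ref: float, floor: float = 0.05,
                 region_mask: np.ndarray | None = None) -> dict:
    """Maximum relative deviation of map A from a reference map.

    Both maps are first normalized (A by ``norm_a``, the reference array by
    ``norm_ref``); the deviation max |A-ref|/ref runs over voxels whose
    reference dose exceeds ``floor`` (fraction of the reference prescription
    dose, default 5%) to keep noise-dominated voxels out of the statistic.
    The all-voxel maximum is reported alongside.
    """
    if ref_vals.shape != map_a.dose.shape:
        raise ValueError("grid mismatch between compared maps")
    a = map_a.dose / norm_a
    b = np.asarray(ref_vals, float) / norm_ref
    if region_mask is None:
        region_mask = np.ones(a.shape, bool)
    if map_a.excluded is not None:
        region_mask = region_mask & ~map_a.excluded
    with np.errstate(divide="ignore", invalid="ignore"):
        dev = np.abs(a - b) / b
    valid = region_mask & (b > 0)
    floored = valid & (b >= floor)
    if not np.any(floored):
        raise ValueError("no voxels above the noise floor in the region")
    idx = np.unravel_index(np.argmax(np.where(floored, dev, -1.0)), dev.shape)
    # SE of the deviation at the argmax, from A's batch spread
    m = np.zeros(a.shape, bool)
    m[idx] = True
    _, se_a = map_a.region_mean(m)
    return {
        "max_rel_dev_pct": float(100.0 * dev[idx]),
        "se_pct": float(100.0 * se_a / norm_a / b[idx]),
        "argmax_index": tuple(int(i) for i in idx),
        "n_compared": int(floored.sum()),
        "max_rel_dev_all_pct": float(100.0 * np.nanmax(np.where(valid, dev, -1.0))),
    }


@dataclass
class MetricsReport:
    """Bundle of the quantities reported per study configuration."""

    label: str
    prescription_pct: float = np.nan
    prescription_se: float = np.nan
    pdd_table: pd.DataFrame | None = field(default=None, repr=False)
    contours: dict | None = field(default=None, repr=False)
    comparisons: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def to_json(self, path):
        payload = {"label": self.label,
                   "prescription_pct": self.prescription_pct,
                   "prescription_se": self.prescription_se,
                   "comparisons": self.comparisons, "extra": self.extra}
        with open(path, "w") as f:
            json.dump(payload, f, indent=1, default=float)

    def save_tables(self, directory, stem=""):
        from pathlib import Path
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        if self.pdd_table is not None:
            self.pdd_table.to_csv(d / f"{stem}pdd.csv", index=False)
        if self.contours is not None:
            rows = []
            for lev, polys in self.contours.items():
                for k, poly in enumerate(polys):
                    for u, v in poly:
                        rows.append((lev, k, u, v))
            pd.DataFrame(rows, columns=["level", "poly", "u_cm", "v_cm"]).to_csv(
                d / f"{stem}contours.csv", index=False)
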