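"""End-to-end studies: validation, materials, backscatter, and bending.

Every study runs from a single :class:`StudyConfig`: characterize the source
(TG-43 dataset) with the MC engine, optimize dwell times on the flat template,
compute the reference normalization once from the TG-43 prescription dose, and
reuse the same flat-optimized plan, unmodified, for every perturbed simulation
— mirroring clinical practice, where the plan is not corrected for materials,
backscatter, or bending.

Intermediates (TG-43 dataset, optimized plan) are cached under
``out_dir/cache`` keyed by configuration hashes, so studies are restartable.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import (DoseMap, GridSpec, PhantomSpec, Scene, TransportSettings,
                     derive_seed, run_simulation)
from .geometry import (ApplicatorSpec, CurvatureSpec, DwellPlan,
                       bend_plan, build_flat_plan_template)
from .materials import default_library
from .metrics import MetricsReport, compare_maps, isodose_contours, pdd, prescription_dose
from .planning import optimize_dwell_times, place_prescription_points, prescription_norm
from .source import SourceGeometry
from .spectrum import ir192_spectrum
from .tg43 import TG43Dataset, characterize_tg43, tg43_dose_map

__all__ = ["StudyConfig", "StudyContext", "prepare_context", "run_validation",
           "run_material_backscatter_study", "run_bending_study"]

log = logging.getLogger(__name__)

BEND_VALUES = (0.09, 0.25, 0.54)


@dataclass
class StudyConfig:
    """Configuration for the treatment-perturbation studies."""

    seed: int = 20177
    out_dir: str = "hamdose_out"
    applicator: ApplicatorSpec = field(default_factory=ApplicatorSpec)
    source: SourceGeometry = field(default_factory=SourceGeometry)
    n_histories_characterize: int = 15_000_000
    n_histories_validate: int = 20_000_000
    n_histories_flat: int = 20_000_000
    n_histories_bend: int = 6_000_000
    n_batches: int = 50
    voxel_validate: float = 0.2
    scoring: str = "rx"          # 'rx' (prescription region) or 'full' planes
    bend_values: tuple = BEND_VALUES
    use_cache: bool = True
    characterize_se_tolerance: float | None = 0.05

    def settings(self, n_histories: int, tag: str) -> TransportSettings:
        return TransportSettings(n_histories=n_histories,
                                 seed=derive_seed(self.seed, tag),
                                 n_batches=self.n_batches)

    def cache_dir(self) -> Path:
        d = Path(self.out_dir) / "cache"
        d.mkdir(parents=True, exist_ok=True)
        return d


@dataclass
class StudyContext:
    """Shared intermediates: dataset, flat-optimized plan, reference norm."""

    config: StudyConfig
    dataset: TG43Dataset
    plan: DwellPlan
    norm_rx: float          # TG-43 prescription mean per unit dwell weight

    @property
    def reference_norm_map_units(self) -> float:
        """The 100% level in per-history DoseMap units."""
        return self.dataset.ref_dose_per_history * self.norm_rx


def _hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str)
                          .encode()).hexdigest()[:16]


def prepare_context(cfg: StudyConfig) -> StudyContext:
    """Characterize (or load) the TG-43 dataset and build the optimized plan."""
    char_key = _hash({"source": asdict(cfg.source),
                      "n": cfg.n_histories_characterize,
                      "seed": derive_seed(cfg.seed, "characterize"),
                      "nb": cfg.n_batches})
    cache = cfg.cache_dir() / f"tg43_{char_key}"
    if cfg.use_cache and (cache / "meta.json").exists():
        log.info("loading cached TG-43 dataset %s", cache)
        dataset = TG43Dataset.load(cache)
    else:
        log.info("characterizing TG-43 dataset (%d histories)",
                 cfg.n_histories_characterize)
        dataset = characterize_tg43(
            cfg.source, cfg.settings(cfg.n_histories_characterize, "characterize"),
            se_tolerance=cfg.characterize_se_tolerance)
        if cfg.use_cache:
            dataset.save(cache)

    template = build_flat_plan_template(cfg.applicator)
    plan_key = _hash({"app": asdict(cfg.applicator), "char": char_key})
    plan_cache = cfg.cache_dir() / f"plan_{plan_key}.csv"
    if cfg.use_cache and plan_cache.exists():
        plan = DwellPlan.from_csv(plan_cache, cfg.applicator, "flat-optimized")
    else:
        points = place_prescription_points(template)
        plan = optimize_dwell_times(template, points, dataset)
        if cfg.use_cache:
            plan.to_csv(plan_cache)
    norm = prescription_norm(dataset, plan)
    return StudyContext(cfg, dataset, plan, norm)


def _plane_grids(cfg: StudyConfig) -> list[GridSpec]:
    return [GridSpec.lateral_plane(cfg.voxel_validate),
            GridSpec.longitudinal_plane(cfg.voxel_validate)]


def run_validation(ctx: StudyContext) -> MetricsReport:
    """MC vs TG-43 on the flat, water-only, infinite-water treatment.

    Both engines see only the source and its cable in water; each dose map is
    normalized to its own prescription-region mean, and the maximum relative
    deviation (above the 5%-of-reference floor) is reported per central plane.
    """
    cfg = ctx.config
    grids = _plane_grids(cfg)
    scene = Scene(phantom=PhantomSpec("infinite"), applicator=cfg.applicator,
                  water_only=True)
    maps = run_simulation(ctx.plan, scene, grids,
                          cfg.settings(cfg.n_histories_validate, "flat-rx"),
                          source=cfg.source)
    report = MetricsReport("validation")
    worst = None
    for name, grid, mc_map in zip(("lateral", "longitudinal"), grids, maps):
        ref_vals = tg43_dose_map(ctx.dataset, ctx.plan, grid)
        norm_mc, _ = mc_map.region_mean(mc_map.prescription_region_mask())
        norm_ref = float(ref_vals[mc_map.prescription_region_mask()].mean())
        cmp = compare_maps(mc_map, ref_vals, norm_mc, norm_ref, floor=0.05)
        report.comparisons[name] = cmp
        report.extra[f"pdd_{name}"] = pdd(mc_map, norm_mc).to_dict("list")
        if worst is None or cmp["max_rel_dev_pct"] > worst["max_rel_dev_pct"]:
            worst = cmp
        report.extra.setdefault("maps", {})[name] = {
            "max_se_pct": float(100 * np.nanmax(
                np.where(mc_map.dose > 0, mc_map.se / np.maximum(mc_map.dose, 1e-300), 0)
                * (mc_map.dose / norm_mc >= 0.05)))}
    report.comparisons["max_over_planes"] = worst
    report.prescription_pct, report.prescription_se = prescription_dose(
        maps[0], ctx.reference_norm_map_units)
    return report


def _study_grids(cfg: StudyConfig) -> list[GridSpec]:
    """Prescription-region column (fast default) or figure-grade full planes.

    Either choice covers the prescription region, so downstream metrics are
    identical in definition; 'full' additionally resolves the whole maps.
    """
    if cfg.scoring == "full":
        return _plane_grids(cfg)
    return [GridSpec.prescription_column(0.1)]


def _flat_run(ctx: StudyContext, water_only: bool, phantom_mode: str,
              settings: TransportSettings) -> DoseMap:
    scene = Scene(phantom=PhantomSpec(phantom_mode), applicator=ctx.config.applicator,
                  water_only=water_only)
    return run_simulation(ctx.plan, scene, _study_grids(ctx.config), settings,
                          source=ctx.config.source)[0]


def _paired_diff(map_a: DoseMap, map_b: DoseMap, norm: float):
    """Paired (common-random-number) difference of prescription doses, in pp."""
    mask = map_a.prescription_region_mask()
    da = map_a.batch_doses[:, mask].mean(axis=1) / norm * 100
    db = map_b.batch_doses[:, mask].mean(axis=1) / norm * 100
    d = da - db
    return float(d.mean()), float(d.std(ddof=1) / np.sqrt(len(d)))


def run_material_backscatter_study(ctx: StudyContext) -> MetricsReport:
    """The 2x2 grid {all-water, full materials} x {infinite, semi-infinite}.

    All four runs share one seed, so decay samples are common random numbers
    and paired differences (backscatter deficit, material effect) have
    collapsed variance.
    """
    cfg = ctx.config
    settings = cfg.settings(cfg.n_histories_flat, "flat-rx")
    runs = {}
    for water_only in (True, False):
        for mode in ("infinite", "semi_infinite"):
            key = f"{'water' if water_only else 'materials'}_{mode}"
            log.info("flat study run: %s", key)
            runs[key] = _flat_run(ctx, water_only, mode, settings)
    norm = ctx.reference_norm_map_units
    report = MetricsReport("materials_backscatter")
    for key, m in runs.items():
        pct, se = prescription_dose(m, norm)
        report.extra[key] = {"prescription_pct": pct, "se_pct": se}
    d_bs, se_bs = _paired_diff(runs["materials_infinite"],
                               runs["materials_semi_infinite"], norm)
    d_mat_inf, se_mat_inf = _paired_diff(runs["materials_infinite"],
                                         runs["water_infinite"], norm)
    d_mat_semi, se_mat_semi = _paired_diff(runs["materials_semi_infinite"],
                                           runs["water_semi_infinite"], norm)
    report.comparisons = {
        "backscatter_deficit_pp": {"value": d_bs, "se": se_bs},
        "material_effect_infinite_pp": {"value": d_mat_inf, "se": se_mat_inf},
        "material_effect_semi_infinite_pp": {"value": d_mat_semi, "se": se_mat_semi},
    }
    report.prescription_pct = report.extra["materials_infinite"]["prescription_pct"]
    report.prescription_se = report.extra["materials_infinite"]["se_pct"]
    return report


def run_bending_study(ctx: StudyContext,
                      phantoms=("infinite", "semi_infinite"),
                      orientations=("lateral", "longitudinal")) -> pd.DataFrame:
    """Prescription-dose loss across the bent-applicator configuration grid.

    For each curvature a x orientation x phantom (full materials,
    flat-optimized times), the plan and applicator solids are bent, dose is
    scored on the deformed prescription-region grid, and loss =
    100% - prescription dose (%) is tabulated.
    """
    cfg = ctx.config
    norm = ctx.reference_norm_map_units
    rows = []
    for a in cfg.bend_values:
        for orient in orientations:
            curv = CurvatureSpec(a, orient)
            bent = bend_plan(ctx.plan, curv)
            settings = cfg.settings(cfg.n_histories_bend, f"bend-{a}-{orient}")
            for mode in phantoms:
                log.info("bending run: a=%g %s %s", a, orient, mode)
                scene = Scene(phantom=PhantomSpec(mode), applicator=cfg.applicator,
                              curvature=curv, water_only=False)
                m = run_simulation(bent, scene, _study_grids(cfg), settings,
                                   source=cfg.source, flat_plan=ctx.plan)[0]
                if m.excluded is not None and m.excluded.mean() > 0.25:
                    raise RuntimeError(
                        f"fold-over voxel fraction {m.excluded.mean():.2f} "
                        f"too high for a={a} {orient}")
                pct, se = prescription_dose(m, norm)
                rows.append({"a": a, "orientation": orient, "phantom": mode,
                             "prescription_pct": pct, "se_pct": se,
                             "loss_pct": 100.0 - pct})
    return pd.DataFrame(rows)
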