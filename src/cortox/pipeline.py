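"""End-to-end orchestration: generate -> flow -> oxygen -> occlude -> analyse.

The same spatial-statistics functions process simulated hypoxia masks and
experimental-style section stacks, which is what makes the in-silico and
imaging arms directly comparable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import spatial
from .column import (BranchingSpec, DiameterLaw, generate_arteriole_tree,
                     generate_capillary_cube, assemble_column, network_stats)
from .config import RunConfig
from .experiment import (SectionStack, downsample_to_analysis_grid,
                         generate_synthetic_experiment, load_beads)
from .occlusion import run_scenarios, write_manifest
from .spatial import (PointSet, aggregate_column, classify_intensity,
                      hypoxic_intensity, monte_carlo_controls,
                      nearest_point_distances, pixel_gx)

log = logging.getLogger("cortox")


def generate_column_from_config(cfg: RunConfig, seed: int):
    rng = np.random.default_rng(seed)
    cube_seed, art_seed = (int(s) for s in rng.integers(0, 2**31 - 1, size=2))
    cube = generate_capillary_cube(cfg.box_um[0], cfg.cube_density,
                                   cfg.diameter_law, cube_seed)
    art = generate_arteriole_tree(depth=cfg.box_um[2] - 100.0,
                                  branching=cfg.branching, seed=art_seed)
    return assemble_column(art, cube,
                           n_stack=int(round(cfg.box_um[2] / cfg.box_um[0])))


@dataclass
class ColumnResult:
    seed: int
    stats: "object"
    n_scenarios: int
    perfusion_drops: list
    type_counts: dict
    gx: spatial.GxCurve
    intensity: spatial.HypoxicIntensityCurve


def analyze_batch(batch, cfg: RunConfig):
    """Spatial statistics for one column's completed scenario batch."""
    grid = batch.healthy_oxygen.grid
    spacing, origin = grid.spacing, grid.origin
    distances, curves = [], []
    for sc in batch.completed:
        pts = PointSet(sc.bead_xyz.reshape(1, 3))
        distances.append(nearest_point_distances(
            sc.hypoxia, pts, domain=grid.in_domain,
            baseline=batch.baseline_hypoxia, spacing=spacing, origin=origin))
        curves.append(hypoxic_intensity(
            sc.hypoxia, sc.bead_xyz, domain=grid.in_domain,
            spacing=spacing, origin=origin, radii=cfg.intensity_radii))
    return aggregate_column(distances, curves, cfg.gx_bin_um, cfg.gx_max_um)


def run_pipeline(cfg: RunConfig, outdir: str | Path | None = None) -> dict:
    """Full multi-column run; writes per-column artifacts plus a summary.

    Per-column or per-scenario failures are contained and reported in the
    manifest rather than aborting the batch.
    """
    outdir = Path(outdir or cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "resolved_config.yaml")

    results, failures = [], []
    gx_curves, intensity_curves = [], []
    for i, seed in enumerate(cfg.column_seeds()):
        cdir = outdir / f"column_{i:02d}"
        cdir.mkdir(exist_ok=True)
        try:
            column = generate_column_from_config(cfg, seed)
            column.write(cdir, "graph")
            batch = run_scenarios(column, cfg.hemo, cfg.oxy,
                                  cfg.bead_diameter_um)
            write_manifest(batch, cdir / "scenarios.json")
            batch.healthy_oxygen.grid.write(cdir / "healthy_po2.tif")
            agg = analyze_batch(batch, cfg)
            spatial.curves_to_frame(
                {"gx": agg.gx, "intensity": agg.intensity}
            ).assign(column=i).to_csv(cdir / "curves.csv", index=False)
            st = network_stats(column)
            results.append(ColumnResult(
                seed=seed, stats=st, n_scenarios=len(batch.completed),
                perfusion_drops=[s.perfusion_drop for s in batch.completed],
                type_counts=agg.type_counts, gx=agg.gx,
                intensity=agg.intensity))
            gx_curves.append(agg.gx)
            intensity_curves.append(agg.intensity)
            log.info("column %d: %d scenarios", i, len(batch.completed))
        except Exception as exc:  # contained per column
            log.warning("column %d failed: %s", i, exc)
            failures.append({"column": i, "error": str(exc)})

    summary = summarize(results, cfg)
    summary["failures"] = failures
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1))
    if gx_curves:
        mean_gx = np.mean([c.fraction for c in gx_curves], axis=0)
        sd_gx = np.std([c.fraction for c in gx_curves], axis=0)
        mean_in = np.nanmean([c.fraction for c in intensity_curves], axis=0)
        sd_in = np.nanstd([c.fraction for c in intensity_curves], axis=0)
        pd.DataFrame({
            "distance_um": gx_curves[0].distance_um,
            "gx_mean": mean_gx, "gx_sd": sd_gx,
        }).to_csv(outdir / "gx_mean.csv", index=False)
        pd.DataFrame({
            "radius_um": intensity_curves[0].radius_um,
            "intensity_mean": mean_in, "intensity_sd": sd_in,
        }).to_csv(outdir / "intensity_mean.csv", index=False)
    return summary


def summarize(results: list, cfg: RunConfig) -> dict:
    if not results:
        return {"n_columns": 0}
    type_b = sum(r.type_counts.get("B", 0) for r in results)
    type_a = sum(r.type_counts.get("A", 0) for r in results)
    mean_gx = np.mean([r.gx.fraction for r in results], axis=0)
    grid = results[0].gx.distance_um
    ix50 = np.nonzero(mean_gx >= 0.5)[0]
    ix90 = np.nonzero(mean_gx >= 0.9)[0]
    return {
        "n_columns": len(results),
        "vessel_density_mean": float(np.mean(
            [r.stats.vessel_density_per_mm3 for r in results])),
        "volume_fraction_mean": float(np.mean(
            [r.stats.volume_fraction for r in results])),
        "scenarios_per_column": [r.n_scenarios for r in results],
        "total_scenarios": int(sum(r.n_scenarios for r in results)),
        "type_A": int(type_a),
        "type_B": int(type_b),
        "type_B_percent": 100.0 * type_b / max(type_a + type_b, 1),
        "gx50_um": float(grid[ix50[0]]) if len(ix50) else None,
        "gx90_um": float(grid[ix90[0]]) if len(ix90) else None,
        "mean_perfusion_drop": float(np.mean(
            [d for r in results for d in r.perfusion_drops])) if results else None,
    }


def run_experiment_analysis(
    stack: SectionStack,
    beads: PointSet,
    cfg: RunConfig | None = None,
    n_controls: int = 20,
    control_seed: int = 0,
) -> dict:
    """Gx + intensity + type table + Monte-Carlo controls for one data set.

    Uses exactly the same spatial-statistics functions as the simulated
    arm (pixel_gx / hypoxic_intensity / classify_intensity).
    """
    cfg = cfg or RunConfig()
    hyp, dom, spacing, origin = downsample_to_analysis_grid(stack)
    gx = pixel_gx(hyp, beads, domain=dom, spacing=spacing, origin=origin,
                  bin_um=cfg.gx_bin_um, max_um=cfg.gx_max_um)
    curves = [hypoxic_intensity(hyp, b, domain=dom, spacing=spacing,
                                origin=origin, radii=cfg.intensity_radii)
              for b in beads.xyz]
    types = [classify_intensity(c) for c in curves]
    type_table = {}
    for t, sub in types:
        type_table[f"{t}/{sub}"] = type_table.get(f"{t}/{sub}", 0) + 1

    vol_mm3 = float(dom.sum()) * float(np.prod(spacing)) * 1e-9
    density = beads.n / vol_mm3 if vol_mm3 > 0 else 0.0
    control_curves = []
    if beads.n and density > 0:
        for rep in monte_carlo_controls(dom, density, n_controls, control_seed,
                                        spacing, origin):
            reps = [hypoxic_intensity(hyp, c, domain=dom, spacing=spacing,
                                      origin=origin, radii=cfg.intensity_radii)
                    for c in rep.xyz]
            with np.errstate(invalid="ignore"):
                control_curves.append(np.nanmean([r.fraction for r in reps], axis=0))
    with np.errstate(invalid="ignore"):
        mean_intensity = np.nanmean([c.fraction for c in curves], axis=0)
        mean_control = (np.nanmean(control_curves, axis=0)
                        if control_curves else None)
    return {
        "gx": gx,
        "intensity_curves": curves,
        "mean_intensity": mean_intensity,
        "types": types,
        "type_table": type_table,
        "control_mean_intensity": mean_control,
        "bead_density_per_mm3": density,
    }
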