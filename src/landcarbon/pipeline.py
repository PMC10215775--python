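"""End-to-end orchestration of the study workflow.

One :func:`run` call executes the full chain on a configured input —
transfer/Markov analysis, scenario demands, suitability learning, CA
allocation per scenario, carbon bookkeeping, fishnet aggregation and the
spatial-statistics suite — and writes a machine-readable JSON report plus
per-stage CSV/raster outputs.  All randomness flows from one top-level seed
through named per-stage substreams, so replaying a config reproduces every
number byte for byte.
"""

from __future__ import annotations

import json
import logging
import os
import time
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import datasets
from .ca_simulator import CAParams, simulate
from .carbon_accounting import carbon_from_areas, carbon_map, carbon_change, load_density_table
from .grid_core import build_fishnet, class_areas, read_landuse, write_landuse
from .rs_indices import extract_impervious, ndvi, point_accuracy
from .scenario_engine import PRESET_NAMES, apply_constraints, preset
from .spatial_stats import (
    bivariate_moran,
    build_weights,
    getis_ord_gistar,
    global_morans_i,
    pearson,
)
from .suitability import ModelSpec, extract_expansion_samples, factor_contributions, fit_predict_suitability
from .synthetic_data import make_benchmark, synth_reflectance
from .transitions import agreement, crosstab, markov_project, transition_probabilities

log = logging.getLogger("landcarbon.pipeline")


def substream(seed: int, name: str) -> int:
    """Deterministic per-stage seed derived from the top-level seed."""
    return int((seed * 1_000_003 + zlib.crc32(name.encode())) % (2**31 - 1))


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    seed: int
    out_dir: str
    scenarios: tuple[str, ...] = PRESET_NAMES
    benchmark_shape: tuple[int, int] = (256, 256)
    landuse_t1: str | None = None  # raster paths; None = synthetic benchmark
    landuse_t2: str | None = None
    density_csv: str | None = None  # None = embedded study table
    n_steps: int = 1
    fishnet_edge_m: float = 2000.0
    min_valid_fraction: float = 0.5
    per_class_samples: int = 1500
    n_trees: int = 60
    ca: CAParams = field(default_factory=CAParams)
    n_perm: int = 999
    write_rasters: bool = True

    def to_yaml(self, path: str) -> None:
        payload = {
            "seed": self.seed,
            "out_dir": self.out_dir,
            "scenarios": list(self.scenarios),
            "benchmark_shape": list(self.benchmark_shape),
            "landuse_t1": self.landuse_t1,
            "landuse_t2": self.landuse_t2,
            "density_csv": self.density_csv,
            "n_steps": self.n_steps,
            "fishnet_edge_m": self.fishnet_edge_m,
            "min_valid_fraction": self.min_valid_fraction,
            "per_class_samples": self.per_class_samples,
            "n_trees": self.n_trees,
            "ca": {
                "tau0": self.ca.tau0,
                "decay": self.ca.decay,
                "p_seed": self.ca.p_seed,
                "window": self.ca.window,
                "max_iters": self.ca.max_iters,
                "demand_tolerance_cells": self.ca.demand_tolerance_cells,
            },
            "n_perm": self.n_perm,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


def _stage(report: dict, name: str):
    class _Timer:
        def __enter__(self):
            log.info("stage %s ...", name)
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            report.setdefault("timings_s", {})[name] = round(dt, 3)
            if exc_type is not None:
                log.error("stage %s FAILED after %.1fs", name, dt)
                raise RuntimeError(f"pipeline stage {name!r} failed") from exc
            log.info("stage %s done in %.1fs", name, dt)

    return _Timer()


def run(config: RunConfig) -> dict:
    """Execute the full workflow; returns (and writes) the run report."""
    os.makedirs(config.out_dir, exist_ok=True)
    config.to_yaml(os.path.join(config.out_dir, "resolved_config.yaml"))
    report: dict = {"seed": config.seed}

    with _stage(report, "inputs"):
        if config.landuse_t1 and config.landuse_t2:
            grid_t1 = read_landuse(config.landuse_t1)
            grid_t2 = read_landuse(config.landuse_t2)
            bench = None
            from .synthetic_data import synth_drivers

            drivers = synth_drivers(grid_t1, seed=substream(config.seed, "drivers"))
        else:
            bench = make_benchmark(substream(config.seed, "benchmark"), config.benchmark_shape)
            grid_t1, grid_t2 = bench["grid_t1"], bench["grid_t2"]
            drivers = bench["drivers"]
        density = load_density_table(config.density_csv or datasets.carbon_density_table())

    with _stage(report, "transfer"):
        tm = crosstab(grid_t1, grid_t2)
        tm.to_csv(os.path.join(config.out_dir, "transfer_matrix.csv"))
        tp = transition_probabilities(tm)
        report["transfer"] = {
            "total_km2": tm.total(),
            "deltas_km2": tm.deltas().round(4).to_dict(),
        }

    with _stage(report, "suitability"):
        samples = extract_expansion_samples(
            grid_t1, grid_t2, config.per_class_samples, substream(config.seed, "samples")
        )
        suit = fit_predict_suitability(
            samples, drivers, ModelSpec(n_trees=config.n_trees, seed=substream(config.seed, "rf"))
        )
        if suit.models:
            contrib = factor_contributions(suit)
            contrib.to_csv(os.path.join(config.out_dir, "factor_contributions.csv"))
        report["suitability"] = {"no_expansion": list(suit.fallback)}

    areas_t2 = class_areas(grid_t2)
    scenario_reports = {}
    masks = {"water": grid_t2.codes == {v: k for k, v in grid_t2.class_table.items()}["water"]}
    for name in config.scenarios:
        with _stage(report, f"scenario:{name}"):
            cfg = preset(name, masks=masks)
            tp_s = apply_constraints(tp, cfg)
            demand = markov_project(areas_t2, tp_s, config.n_steps)
            Pn = np.linalg.matrix_power(tp_s.P.values, config.n_steps)
            flows = pd.DataFrame(
                Pn * areas_t2.loc[tp_s.classes].values[:, None],
                index=tp_s.classes,
                columns=tp_s.classes,
            )
            ca_run = simulate(
                grid_t2,
                suit.surfaces,
                cfg,
                demand,
                config.ca,
                seed=substream(config.seed, f"ca:{name}"),
                flow_targets_km2=flows,
            )
            ca_run.log.to_csv(os.path.join(config.out_dir, f"ca_log_{name}.csv"), index=False)
            if config.write_rasters:
                write_landuse(os.path.join(config.out_dir, f"landuse_{name}.asc"), ca_run.grid)
            tm_future = crosstab(grid_t2, ca_run.grid)
            _, net_change = carbon_change(tm_future, density)
            future_carbon = carbon_from_areas(class_areas(ca_run.grid), density)
            gaps = (demand - class_areas(ca_run.grid)).abs()
            scenario_reports[name] = {
                "converged": bool(ca_run.converged),
                "iterations": int(ca_run.log["iteration"].max()),
                "demand_km2": demand.round(4).to_dict(),
                "final_areas_km2": class_areas(ca_run.grid).round(4).to_dict(),
                "max_demand_gap_km2": float(gaps.max()),
                "carbon_total_t": future_carbon["total_t"],
                "carbon_net_change_t": net_change,
            }

    with _stage(report, "carbon"):
        c1 = carbon_from_areas(class_areas(grid_t1), density)
        c2 = carbon_from_areas(areas_t2, density)
        _, net = carbon_change(tm, density)
        cmap2 = carbon_map(grid_t2, density)
        report["carbon"] = {
            "total_t1_t": c1["total_t"],
            "total_t2_t": c2["total_t"],
            "net_change_t": net,
            "per_pool_t2_t": c2["per_pool_t"],
        }
        report["scenarios"] = scenario_reports

    with _stage(report, "indices"):
        stack = synth_reflectance(grid_t2, seed=substream(config.seed, "reflectance"))
        isa = extract_impervious(stack)
        code_of = {v: k for k, v in grid_t2.class_table.items()}
        reference = (grid_t2.codes == code_of["construction"]).astype(float)
        reference[~np.isfinite(isa)] = np.nan
        conf = point_accuracy(isa, reference, n_points=700, seed=substream(config.seed, "points"))
        report["impervious"] = {
            "oa": conf.overall_accuracy,
            "kappa": conf.kappa,
        }
        ndvi_map = ndvi(stack)

    with _stage(report, "spatial_stats"):
        fishnet = build_fishnet(
            {
                "carbon": cmap2.carbon_t,
                "impervious": np.nan_to_num(isa, nan=0.0),
                "ndvi": ndvi_map,
            },
            cell_size_m=grid_t2.cell_size,
            cell_edge_m=config.fishnet_edge_m,
            min_valid_fraction=config.min_valid_fraction,
            valid_mask=grid_t2.valid_mask,
        )
        fishnet.to_csv(os.path.join(config.out_dir, "fishnet.csv"))
        W = build_weights(fishnet, "queen", row_standardize=True)
        active = fishnet.active()
        carbon_v = active["carbon_t"].to_numpy()
        isa_v = active["isa_fraction"].to_numpy()
        ndvi_v = active["ndvi_mean"].to_numpy()
        moran = global_morans_i(carbon_v, W, config.n_perm, substream(config.seed, "moran"))
        Wg = build_weights(fishnet, "queen", row_standardize=False, include_self=True)
        gi = getis_ord_gistar(carbon_v, Wg)
        bv_isa = bivariate_moran(
            isa_v, carbon_v, W, config.n_perm, substream(config.seed, "bv_isa")
        )
        bv_ndvi = bivariate_moran(
            ndvi_v, carbon_v, W, config.n_perm, substream(config.seed, "bv_ndvi")
        )
        hot = {cls: int((gi.classes == cls).sum()) for cls in np.unique(gi.classes)}
        report["spatial_stats"] = {
            "n_fishnet_cells": int(fishnet.n_cells),
            "n_active_cells": int(len(active)),
            "moran_i_carbon": moran.I,
            "moran_p_sim": moran.p_sim,
            "gi_star_classes": hot,
            "bivariate_i_isa_carbon": bv_isa.global_i,
            "bivariate_i_ndvi_carbon": bv_ndvi.global_i,
            "pearson": {
                "isa_carbon": pearson(isa_v, carbon_v),
                "ndvi_carbon": pearson(ndvi_v, carbon_v),
            },
        }
        lisa = pd.DataFrame(
            {
                "cell_id": bv_isa.ids,
                "local_i_isa_carbon": bv_isa.local_i,
                "p": bv_isa.p_values,
                "label": bv_isa.labels,
                "gi_z": gi.z_scores,
                "gi_class": gi.classes,
            }
        )
        lisa.to_csv(os.path.join(config.out_dir, "lisa_gistar.csv"), index=False)

    report_path = os.path.join(config.out_dir, "report.json")
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    report["report_path"] = report_path
    return report
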