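"""Benchmark experiments: Markov recovery and the simulate-then-validate check.

These are the package's reproducible substitutes for the study's
real-raster validation (hindcast the later map from the earlier one and
score agreement): they generate a synthetic landscape with known ground
truth, run the estimation/simulation chain, and measure recovery.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ca_simulator import CAParams, simulate
from .grid_core import class_areas
from .scenario_engine import ScenarioConfig, preset
from .suitability import ModelSpec, extract_expansion_samples, fit_predict_suitability
from .synthetic_data import benchmark_spec, make_validation_benchmark, synth_landscape, synth_transition
from .transitions import agreement, crosstab, transition_probabilities


def markov_recovery(seed: int, shape: tuple[int, int] = (512, 512)) -> dict:
    """Estimate P̂ from a synthetic transition with known P* (zero adjacency).

    Returns the elementwise recovery error and the area-conservation error
    of projecting one step with the estimated matrix.
    """
    spec = benchmark_spec(seed, shape)
    grid_t1 = synth_landscape(spec)
    grid_t2, _ = synth_transition(grid_t1, spec.P_star, 0.0, seed=seed + 1)
    tm = crosstab(grid_t1, grid_t2)
    P_hat = transition_probabilities(tm).P
    P_star = spec.P_star.loc[P_hat.index, P_hat.columns]
    areas = class_areas(grid_t1)
    from .transitions import markov_project

    demand = markov_project(areas, transition_probabilities(tm))
    return {
        "max_abs_error": float(np.abs(P_hat.values - P_star.values).max()),
        "area_conservation_error_km2": float(abs(demand.sum() - areas.sum())),
        "P_hat": P_hat,
        "P_star": P_star,
    }


def neutral_scenario() -> ScenarioConfig:
    """Calibration scenario: every transition allowed, trend weights."""
    s1 = preset("s1-trend")
    return ScenarioConfig(
        name="calibration",
        allowed=s1.allowed.copy() | True,
        neighborhood_weights=s1.neighborhood_weights,
        multipliers=s1.multipliers * 0 + 1.0,
    )


def validate_simulation(
    seed: int,
    shape: tuple[int, int] = (256, 256),
    per_class_n: int = 1500,
    n_trees: int = 60,
    params: CAParams | None = None,
) -> dict:
    """Hindcast t2 from t1 on the expansion benchmark and score agreement.

    Learns suitability from the t1→t2 expansion (as the workflow's
    expansion-analysis stage does), allocates the calibrated gross flows
    with the CA, and compares Cohen's kappa of the simulated map against
    the null persistence model (t1 itself).
    """
    bench = make_validation_benchmark(seed, shape)
    g1, g2 = bench["grid_t1"], bench["grid_t2"]
    samples = extract_expansion_samples(g1, g2, per_class_n, seed=seed + 10)
    suit = fit_predict_suitability(samples, bench["drivers"], ModelSpec(n_trees=n_trees, seed=seed + 20))
    flows = crosstab(g1, g2).areas
    run = simulate(
        g1,
        suit.surfaces,
        neutral_scenario(),
        params=params or CAParams(max_iters=100),
        seed=seed + 30,
        flow_targets_km2=flows,
    )
    conf_sim = agreement(g2, run.grid)
    conf_null = agreement(g2, g1)
    gaps = (run.demand_cells - run.grid.counts().loc[run.demand_cells.index]).abs()
    return {
        "kappa_simulated": conf_sim.kappa,
        "kappa_persistence": conf_null.kappa,
        "oa_simulated": conf_sim.overall_accuracy,
        "oa_persistence": conf_null.overall_accuracy,
        "converged": run.converged,
        "max_gap_cells": int(gaps.max()),
        "run": run,
        "bench": bench,
        "suitability": suit,
    }
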