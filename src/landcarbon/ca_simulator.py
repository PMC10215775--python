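"""Patch-growing cellular automaton for scenario-constrained land allocation.

The automaton evolves a categorical land-use raster toward a per-class area
demand (from the Markov projection) under a scenario's constraints.  Demand
is allocated at the level of the calibrated transition flows: the expected
flow matrix F = diag(areas)·P says how many cells each source class owes
each destination, the column sums reproduce the Markov demand, and each
pair-flow stops when its target is met — so gross conversions (including
compensating chains such as cultivated→construction backfilled by
grassland→cultivated) are represented, not just net shifts.

Each iteration, a candidate cell's score for destination class k combines

* the learned development probability ``P_{c,k}`` (suitability),
* the neighborhood effect ``Ω_{c,k}``: the class-k fraction of the cell's
  Moore window scaled by the scenario's per-class neighborhood weight,
* an adaptive inertia coefficient ``D_k`` steered by the demand-gap history,

with stochastic patch nucleation: cells with no class-k neighbours draw a
uniform seed factor with probability ``p_seed``, so new patches can start
away from existing ones.  Scores must exceed a monotonically decaying
threshold τ; the destination is drawn by roulette wheel over the passing
scores; acceptances are capped by the remaining flow targets.  Restricted
cells never enter the candidate pool and forbidden transitions score zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid_core import LandUseGrid
from .scenario_engine import ScenarioConfig
from .transitions import TransitionProbabilities


@dataclass
class CAParams:
    """Automaton knobs: all have benchmark-scale defaults."""

    tau0: float = 0.8  # initial score threshold
    decay: float = 0.9  # τ multiplier per iteration
    p_seed: float = 0.01  # patch-nucleation probability where Ω = 0
    window: int = 3  # Moore neighborhood edge (odd, ≥ 3)
    max_iters: int = 200
    demand_tolerance_cells: float = 10.0
    argmax: bool = False  # debugging alternative to roulette selection

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and ≥ 3")
        if not 0 < self.tau0 <= 1:
            raise ValueError("tau0 must lie in (0, 1]")


def neighborhood_effect(
    grid: LandUseGrid, class_code: int, window: int = 3, weight: float = 1.0
) -> np.ndarray:
    """Ω surface for one class: neighbour fraction × class weight.

    The fraction is the count of class members in the (window × window)
    neighborhood, centre excluded, over the number of in-grid neighbours —
    (window²−1) at interior cells, fewer at edges (shrunken windows).
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and ≥ 3")
    if not 0 <= weight <= 1:
        raise ValueError("weight must lie in [0, 1]")
    onehot = (grid.codes == class_code).astype(float)
    kernel = np.ones((window, window))
    total = ndimage.convolve(onehot, kernel, mode="constant", cval=0.0)
    avail = ndimage.convolve(np.ones_like(onehot), kernel, mode="constant", cval=0.0)
    counts = total - onehot
    denom = avail - 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(denom > 0, counts / denom, 0.0)
    return frac * weight


@dataclass
class CAState:
    """Mutable simulation state."""

    grid: LandUseGrid
    inertia: pd.Series
    tau: float
    rng: np.random.Generator
    flow_need: pd.DataFrame  # remaining cells owed per (source, destination)
    iteration: int = 0
    prev_gaps: pd.Series | None = None


@dataclass
class CARun:
    """Simulation output: final grid, per-iteration log, convergence flag."""

    grid: LandUseGrid
    log: pd.DataFrame
    converged: bool
    demand_cells: pd.Series


def _round_preserving_total(values: np.ndarray, target: int) -> np.ndarray:
    floor = np.floor(values).astype(np.int64)
    short = int(target - floor.sum())
    if short > 0:
        order = np.argsort(-(values - floor))
        floor[order[:short]] += 1
    elif short < 0:
        order = np.argsort(values - floor)
        floor[order[: -short]] = np.maximum(floor[order[: -short]] - 1, 0)
    return floor


def flow_targets_from_probabilities(
    areas_km2: pd.Series, tp: TransitionProbabilities
) -> pd.DataFrame:
    """Expected transition flows F = diag(areas)·P (km²)."""
    P = tp.P.loc[areas_km2.index, areas_km2.index]
    return P.mul(areas_km2, axis=0)


def _flows_to_cells(flows_km2: pd.DataFrame, cell_area_km2: float) -> pd.DataFrame:
    classes = list(flows_km2.index)
    out = pd.DataFrame(0, index=classes, columns=classes, dtype=np.int64)
    for i in classes:
        row = flows_km2.loc[i].values / cell_area_km2
        out.loc[i] = _round_preserving_total(row, int(round(row.sum())))
    return out


def step(
    state: CAState,
    suitability: dict[str, np.ndarray],
    scenario: ScenarioConfig,
    params: CAParams,
) -> CAState:
    """One contested-allocation iteration (mutates and returns ``state``)."""
    grid = state.grid
    classes = scenario.classes
    name_to_code = {v: k for k, v in grid.class_table.items()}

    need = state.flow_need
    off = need.values.copy()
    np.fill_diagonal(off, 0)
    sources = [c for i, c in enumerate(classes) if off[i].sum() > 0]
    dests = [c for j, c in enumerate(classes) if off[:, j].sum() > 0]
    if sources and dests:
        mutable = grid.valid_mask.copy()
        if scenario.restricted_mask is not None:
            mutable &= ~scenario.restricted_mask
        src_codes = [name_to_code[c] for c in sources]
        cand = mutable & np.isin(grid.codes, src_codes)
        cand_idx = np.flatnonzero(cand.ravel())
        if cand_idx.size:
            cur = grid.codes.ravel()[cand_idx]
            n_cand = cand_idx.size
            scores = np.zeros((n_cand, len(dests)))
            for j, rec in enumerate(dests):
                k_code = name_to_code[rec]
                omega = neighborhood_effect(
                    grid, k_code, params.window, float(scenario.neighborhood_weights[rec])
                ).ravel()[cand_idx]
                if params.p_seed > 0:
                    zero = omega <= 0
                    if zero.any():
                        seeded = state.rng.random(int(zero.sum())) < params.p_seed
                        factors = np.zeros(int(zero.sum()))
                        factors[seeded] = state.rng.random(int(seeded.sum()))
                        omega[zero] = factors
                p = suitability[rec].ravel()[cand_idx]
                s = p * omega * float(state.inertia[rec])
                # zero where the scenario forbids current→k or no flow is owed
                open_lut = {
                    name_to_code[c]: bool(scenario.allowed.loc[c, rec])
                    and c != rec
                    and need.loc[c, rec] > 0
                    for c in sources
                }
                ok = np.array([open_lut[c] for c in cur])
                scores[:, j] = np.where(ok, s, 0.0)

            passing = scores > state.tau
            scores = np.where(passing, scores, 0.0)
            row_tot = scores.sum(axis=1)
            has = row_tot > 0
            if has.any():
                sub = scores[has]
                if params.argmax:
                    choice = sub.argmax(axis=1)
                    priority = sub.max(axis=1)
                else:
                    cum = np.cumsum(sub, axis=1)
                    r = state.rng.random(sub.shape[0]) * cum[:, -1]
                    choice = (r[:, None] >= cum).sum(axis=1)
                    priority = sub[np.arange(sub.shape[0]), choice]
                prop_cells = cand_idx[has]
                prop_from = cur[has]
                dest_codes = np.array([name_to_code[c] for c in dests])
                prop_to = dest_codes[choice]
                order = np.argsort(-priority, kind="stable")
                remaining = {
                    (name_to_code[i], name_to_code[j]): int(need.loc[i, j])
                    for i in sources
                    for j in dests
                    if i != j and need.loc[i, j] > 0
                }
                code_to_name = dict(grid.class_table)
                flat = grid.codes.ravel()
                for i in order:
                    key = (int(prop_from[i]), int(prop_to[i]))
                    left = remaining.get(key, 0)
                    if left > 0:
                        flat[prop_cells[i]] = key[1]
                        remaining[key] = left - 1
                grid.codes = flat.reshape(grid.shape)
                for (src, dst), left in remaining.items():
                    state.flow_need.loc[code_to_name[src], code_to_name[dst]] = left

    # adaptive inertia from the remaining-flow (net inflow still owed) history
    off_rem = state.flow_need.values.copy()
    np.fill_diagonal(off_rem, 0)
    new_gaps = pd.Series(off_rem.sum(axis=0) - off_rem.sum(axis=1), index=classes)
    if state.prev_gaps is not None:
        for c in classes:
            g0, g1 = float(state.prev_gaps[c]), float(new_gaps[c])
            if abs(g1) <= abs(g0) and g0 * g1 >= 0:
                continue
            if g0 * g1 < 0:  # overshoot: damp
                state.inertia[c] *= float(np.clip(abs(g0) / max(abs(g1), 1e-9), 0.5, 1.0))
            elif abs(g1) > abs(g0):  # gap grew with demand unmet: boost
                state.inertia[c] *= float(min(abs(g1) / max(abs(g0), 1e-9), 2.0))
    state.prev_gaps = new_gaps
    state.tau *= params.decay
    state.iteration += 1
    return state


def simulate(
    grid0: LandUseGrid,
    suitability: dict[str, np.ndarray],
    scenario: ScenarioConfig,
    demand_km2: pd.Series | None = None,
    params: CAParams = CAParams(),
    seed: int = 0,
    flow_targets_km2: pd.DataFrame | None = None,
) -> CARun:
    """Iterate :func:`step` until every demand gap is within tolerance.

    Either ``flow_targets_km2`` (full expected flow matrix, km²) or
    ``demand_km2`` (per-class totals) must be given; totals-only demand is
    decomposed into flows by proportionally assigning each net-surplus
    class's excess to the net-deficit classes.  Deterministic under
    ``seed``.  On non-convergence the final state is returned with
    ``converged=False``.
    """
    classes = scenario.classes
    areas0 = grid0.counts().loc[classes] * grid0.cell_area_km2
    if flow_targets_km2 is None:
        if demand_km2 is None:
            raise ValueError("provide demand_km2 or flow_targets_km2")
        demand = demand_km2.loc[classes]
        mapped0 = float(grid0.valid_mask.sum()) * grid0.cell_area_km2
        if abs(float(demand.sum()) - mapped0) > max(1e-6, 2 * grid0.cell_area_km2 * len(classes)):
            raise ValueError(
                f"demand total {float(demand.sum()):.6f} km² does not match mapped area {mapped0:.6f} km²"
            )
        net = demand - areas0
        give = (-net).clip(lower=0.0)
        take = net.clip(lower=0.0)
        flow = pd.DataFrame(0.0, index=classes, columns=classes)
        total_take = float(take.sum())
        for i in classes:
            stay = areas0[i] - give[i]
            flow.loc[i, i] = stay
            if give[i] > 0 and total_take > 0:
                for j in classes:
                    flow.loc[i, j] += give[i] * take[j] / total_take
        flow_targets_km2 = flow
    else:
        flow_targets_km2 = flow_targets_km2.loc[classes, classes]
        row_mismatch = (flow_targets_km2.sum(axis=1) - areas0).abs().max()
        if row_mismatch > max(1e-6, 2 * grid0.cell_area_km2 * len(classes)):
            raise ValueError("flow-target row sums do not match current class areas")

    demand_vec = flow_targets_km2.sum(axis=0)
    mapped = float(grid0.valid_mask.sum()) * grid0.cell_area_km2
    if abs(float(demand_vec.sum()) - mapped) > max(1e-6, 2 * grid0.cell_area_km2 * len(classes)):
        raise ValueError(
            f"demand total {float(demand_vec.sum()):.6f} km² does not match mapped area {mapped:.6f} km²"
        )
    flow_cells = _flows_to_cells(flow_targets_km2, grid0.cell_area_km2)
    demand_cells = flow_cells.sum(axis=0)

    state = CAState(
        grid=grid0.copy(),
        inertia=pd.Series(1.0, index=classes),
        tau=params.tau0,
        rng=np.random.default_rng(seed),
        flow_need=flow_cells.copy(),
    )
    records = []
    converged = False
    for _ in range(params.max_iters + 1):
        counts = state.grid.counts().loc[classes]
        gaps = demand_cells - counts
        rec = {"iteration": state.iteration, "tau": state.tau}
        rec.update({f"area_{c}": counts[c] * grid0.cell_area_km2 for c in classes})
        rec.update({f"D_{c}": float(state.inertia[c]) for c in classes})
        rec.update({f"gap_cells_{c}": int(gaps[c]) for c in classes})
        records.append(rec)
        if (gaps.abs() <= params.demand_tolerance_cells).all():
            converged = True
            break
        if state.iteration >= params.max_iters:
            break
        state = step(state, suitability, scenario, params)
    log = pd.DataFrame(records)
    if not converged:
        warnings.warn(
            f"CA did not meet demand within {params.max_iters} iterations", stacklevel=2
        )
    return CARun(state.grid, log, converged, demand_cells)
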