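"""Synthetic study-area generators with known ground truth.

Every input the pipeline needs — categorical landscapes with controllable
spatial autocorrelation, Markov transitions with adjacency preference (and
an exact per-transition ledger), class-correlated driver surfaces, and
per-class reflectance spectra — is generated here as a pure function of a
spec plus a seed, so every stage of the workflow is testable offline.

The default benchmark (:func:`benchmark_spec`) is a 256×256 grid of 30 m
cells whose class proportions and transition rates mirror the embedded
2000→2020 study tables, i.e. a desk-scale landscape shaped like the real
study area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from . import datasets
from .grid_core import CLASSES, DEFAULT_CLASS_TABLE, LandUseGrid
from .rs_indices import BANDS, SpectralStack
from .suitability import DriverStack
from .transitions import TransferMatrix, transition_probabilities

#: per-class band means (blue, green, red, nir, swir1, swir2) used by the
#: reflectance generator: built surfaces bright in blue/swir2, vegetation
#: bright in nir, water bright in green relative to swir1.
DEFAULT_SPECTRA: dict[str, tuple[float, ...]] = {
    "cultivated": (0.10, 0.14, 0.18, 0.30, 0.25, 0.20),
    "forest": (0.03, 0.06, 0.04, 0.45, 0.20, 0.10),
    "grassland": (0.05, 0.08, 0.07, 0.40, 0.22, 0.12),
    "water": (0.06, 0.10, 0.05, 0.03, 0.01, 0.01),
    "construction": (0.35, 0.14, 0.18, 0.12, 0.18, 0.55),
    "unused": (0.15, 0.20, 0.25, 0.30, 0.35, 0.30),
}


@dataclass
class SynthSpec:
    """Recipe for one synthetic landscape (seed mandatory)."""

    seed: int
    shape: tuple[int, int] = (256, 256)
    cell_size: float = 30.0
    classes: tuple[str, ...] = CLASSES
    proportions: dict[str, float] | None = None  # None = equal shares
    autocorr_length: float = 8.0  # Gaussian smoothing radius, cells
    P_star: pd.DataFrame | None = None  # true transition matrix
    adjacency_strength: float = 0.0
    noise_sigma: float = 0.01  # reflectance noise

    def __post_init__(self) -> None:
        if min(self.shape) < 16:
            raise ValueError("synthetic grids must be at least 16×16")
        if self.P_star is not None:
            if not np.allclose(self.P_star.values.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("P_star must be row-stochastic")


def _smooth_field(shape, length: float, rng: np.random.Generator) -> np.ndarray:
    f = rng.standard_normal(shape)
    if length > 0:
        f = ndimage.gaussian_filter(f, length, mode="reflect")
    s = f.std()
    return (f - f.mean()) / (s if s > 0 else 1.0)


def synth_landscape(spec: SynthSpec) -> LandUseGrid:
    """Spatially autocorrelated categorical map.

    One smoothed Gaussian field per class plus an additive bias tuned so the
    argmax assignment approximates the target class proportions.  Length 0
    gives an i.i.d. (spatially random) landscape.
    """
    rng = np.random.default_rng(spec.seed)
    k = len(spec.classes)
    fields = np.stack([_smooth_field(spec.shape, spec.autocorr_length, rng) for _ in range(k)])
    targets = np.array(
        [
            (spec.proportions or {}).get(c, 1.0 / k)
            for c in spec.classes
        ]
    )
    targets = targets / targets.sum()
    bias = np.zeros(k)
    n = spec.shape[0] * spec.shape[1]
    for _ in range(80):  # proportional-fitting of the per-class offsets
        assign = np.argmax(fields + bias[:, None, None], axis=0)
        current = np.bincount(assign.ravel(), minlength=k) / n
        if np.abs(current - targets).max() < 0.002:
            break
        bias += 0.4 * np.log((targets + 1e-6) / (current + 1e-6))
    codes = assign.astype(np.int32) + 1
    table = {i + 1: c for i, c in enumerate(spec.classes)}
    return LandUseGrid(codes, table, spec.cell_size)


def synth_transition(
    grid: LandUseGrid,
    P_star: pd.DataFrame,
    adjacency_strength: float = 0.0,
    seed: int = 0,
) -> tuple[LandUseGrid, pd.DataFrame]:
    """Transition every cell by P*, optionally boosted toward neighbours.

    Destination probabilities for a cell of class i are
    P*_{ij} × (1 + strength × f_j) renormalised, with f_j the fraction of
    the 8 neighbours in class j.  Returns the new grid and the exact
    per-transition cell-count ledger (rows = source class).
    """
    classes = list(P_star.index)
    if not np.allclose(P_star.values.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("P_star must be row-stochastic")
    rng = np.random.default_rng(seed)
    name_to_code = {v: c for c, v in grid.class_table.items()}
    codes = np.array([name_to_code[c] for c in classes])
    k = len(classes)
    flat = grid.codes.ravel()
    idx_of = np.full(codes.max() + 1, -1)
    for i, c in enumerate(codes):
        idx_of[c] = i
    cur_idx = idx_of[flat]

    probs = P_star.values[cur_idx]  # n × k
    if adjacency_strength != 0:
        kernel = np.ones((3, 3))
        kernel[1, 1] = 0
        boost = np.empty((flat.size, k))
        avail = ndimage.convolve(np.ones(grid.shape), kernel, mode="constant", cval=0.0)
        for j, c in enumerate(codes):
            cnt = ndimage.convolve(
                (grid.codes == c).astype(float), kernel, mode="constant", cval=0.0
            )
            boost[:, j] = 1.0 + adjacency_strength * (cnt / avail).ravel()
        probs = probs * boost
        probs /= probs.sum(axis=1, keepdims=True)

    cum = np.cumsum(probs, axis=1)
    r = rng.random(flat.size)
    new_idx = (r[:, None] >= cum).sum(axis=1)
    new_codes = codes[new_idx].astype(np.int32).reshape(grid.shape)

    ledger = np.zeros((k, k), dtype=np.int64)
    np.add.at(ledger, (cur_idx, new_idx), 1)
    out = LandUseGrid(new_codes, dict(grid.class_table), grid.cell_size, grid.nodata)
    return out, pd.DataFrame(ledger, index=classes, columns=classes)


def synth_expansion(
    grid: LandUseGrid,
    flows_cells: pd.DataFrame,
    affinity: dict[str, np.ndarray] | None = None,
    adjacency_weight: float = 1.0,
    affinity_weight: float = 0.5,
    noise: float = 0.05,
    seed: int = 0,
) -> tuple[LandUseGrid, pd.DataFrame]:
    """Competitive patch expansion: the best-scoring edge cells convert first.

    ``flows_cells`` gives directed cell counts i→k (off-diagonal); for each
    flow the N highest-scoring class-i cells convert to k, where the score
    is adjacency (fraction of the 8 neighbours already class k, weighted)
    plus a standardised per-class affinity surface plus Gaussian noise.
    This emulates expansion processes (urban growth along development
    gradients, afforestation at forest edges) where change is predictable
    from observables — the regime a patch-growing allocator is built for —
    in contrast to :func:`synth_transition`'s independent per-cell sampling.
    Flows are processed in descending size; a cell converts at most once.
    Returns the new grid and the exact realised ledger (cells).
    """
    rng = np.random.default_rng(seed)
    classes = list(flows_cells.index)
    name_to_code = {v: c for c, v in grid.class_table.items()}
    kernel = np.ones((3, 3))
    kernel[1, 1] = 0
    avail = ndimage.convolve(np.ones(grid.shape), kernel, mode="constant", cval=0.0)
    new_codes = grid.codes.copy()
    converted = np.zeros(grid.shape, dtype=bool)
    ledger = pd.DataFrame(0, index=classes, columns=classes, dtype=np.int64)
    flows = [
        (i, k, int(flows_cells.loc[i, k]))
        for i in classes
        for k in classes
        if i != k and flows_cells.loc[i, k] > 0
    ]
    flows.sort(key=lambda t: -t[2])
    for i, k, n in flows:
        frac = (
            ndimage.convolve(
                (grid.codes == name_to_code[k]).astype(float), kernel, mode="constant", cval=0.0
            )
            / avail
        )
        score = adjacency_weight * frac + noise * rng.standard_normal(grid.shape)
        if affinity and k in affinity:
            a = np.asarray(affinity[k], dtype=float)
            s = a.std()
            score = score + affinity_weight * (a - a.mean()) / (s if s > 0 else 1.0)
        eligible = (grid.codes == name_to_code[i]) & ~converted
        idx = np.flatnonzero(eligible.ravel())
        if idx.size == 0 or n == 0:
            continue
        n = min(n, idx.size)
        top = idx[np.argsort(-score.ravel()[idx], kind="stable")[:n]]
        new_codes.ravel()[top] = name_to_code[k]
        converted.ravel()[top] = True
        ledger.loc[i, k] = n
    for i in classes:
        stayed = int(np.count_nonzero((grid.codes == name_to_code[i]) & (new_codes == grid.codes)))
        ledger.loc[i, i] = stayed
    out = LandUseGrid(new_codes, dict(grid.class_table), grid.cell_size, grid.nodata)
    return out, ledger


def directional_flows(tm_areas: pd.DataFrame) -> pd.DataFrame:
    """Keep only the dominant direction of each class-pair flow.

    For every pair (i, j) the smaller of the two opposing flows is folded
    into persistence, leaving the net expansion processes — the flows the
    land-expansion analysis actually models.
    """
    A = tm_areas.copy().astype(float)
    for i in A.index:
        for j in A.columns:
            if i == j:
                continue
            if A.loc[i, j] <= A.loc[j, i]:
                A.loc[i, i] += A.loc[i, j]
                A.loc[i, j] = 0.0
    return A


#: benchmark driver recipe: per-driver class means in arbitrary field units
DEFAULT_DRIVER_MEANS: dict[str, dict[str, float]] = {
    "dem": {"cultivated": 0.3, "forest": 1.2, "grassland": 0.9, "water": -0.5,
            "construction": 0.0, "unused": 1.6},
    "slope": {"cultivated": 0.2, "forest": 1.0, "grassland": 0.8, "water": -0.6,
              "construction": -0.2, "unused": 1.4},
    "dist_water": {"cultivated": 0.5, "forest": 0.8, "grassland": 0.7, "water": -1.5,
                   "construction": 0.2, "unused": 1.0},
    "gdp": {"cultivated": 0.2, "forest": -0.6, "grassland": -0.4, "water": -0.2,
            "construction": 1.8, "unused": -0.8},
    "popdens": {"cultivated": 0.3, "forest": -0.7, "grassland": -0.4, "water": -0.3,
                "construction": 1.6, "unused": -0.9},
    "rainfall": {"cultivated": 0.2, "forest": 0.5, "grassland": 0.3, "water": 0.1,
                 "construction": -0.1, "unused": -0.3},
}


def synth_drivers(
    grid: LandUseGrid,
    coefficients: dict[str, dict[str, float]] | None = None,
    seed: int = 0,
    smooth_length: float = 8.0,
    noise_sigma: float = 0.3,
    categorical: tuple[str, ...] = (),
) -> DriverStack:
    """Class-correlated continuous driver surfaces.

    Each layer = per-class mean (looked up from the land-use map) + a
    smooth random field + white noise, so class membership is recoverable
    from the drivers with strength set by the coefficient spread.  Zero
    coefficients give class-independent layers.
    """
    coefficients = coefficients if coefficients is not None else DEFAULT_DRIVER_MEANS
    rng = np.random.default_rng(seed)
    name_to_code = {v: c for c, v in grid.class_table.items()}
    layers = {}
    for name, means in coefficients.items():
        mean_by_code = np.zeros(max(grid.class_table) + 1)
        for cls, m in means.items():
            mean_by_code[name_to_code[cls]] = m
        base = mean_by_code[np.where(grid.valid_mask, grid.codes, list(grid.class_table)[0])]
        layer = (
            base
            + _smooth_field(grid.shape, smooth_length, rng)
            + noise_sigma * rng.standard_normal(grid.shape)
        )
        layers[name] = layer
    return DriverStack(layers, categorical=categorical)


def synth_reflectance(
    class_grid: LandUseGrid,
    spectra: dict[str, tuple[float, ...]] | None = None,
    sigma: float = 0.01,
    seed: int = 0,
) -> SpectralStack:
    """Per-class mean spectra + Gaussian noise, clipped to [0, 1]."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    spectra = spectra or DEFAULT_SPECTRA
    rng = np.random.default_rng(seed)
    name_to_code = {v: c for c, v in class_grid.class_table.items()}
    bands = {}
    for bi, band in enumerate(BANDS):
        mean_by_code = np.zeros(max(class_grid.class_table) + 1)
        for cls, spec in spectra.items():
            mean_by_code[name_to_code[cls]] = spec[bi]
        base = mean_by_code[np.where(class_grid.valid_mask, class_grid.codes, 1)]
        arr = base + sigma * rng.standard_normal(class_grid.shape)
        bands[band] = np.clip(arr, 0.0, 1.0)
    return SpectralStack(**bands)


# ---------------------------------------------------------------------------
# the desk-scale benchmark
# ---------------------------------------------------------------------------


def benchmark_spec(seed: int, shape: tuple[int, int] = (256, 256)) -> SynthSpec:
    """Benchmark landscape: study-shaped proportions and transition rates.

    Class shares follow the embedded transfer matrix's earlier-date margins
    and P* is its row-normalisation, so the synthetic landscape has the
    observed mix of a dominant forest matrix, substantial cultivated and
    grassland area, and a small but fast-growing construction class.
    """
    tm = datasets.transfer_matrix_2000_2020()
    shares = (tm.row_totals() / tm.total()).to_dict()
    P = transition_probabilities(tm).P
    return SynthSpec(
        seed=seed,
        shape=shape,
        proportions=shares,
        autocorr_length=6.0,
        P_star=P,
        adjacency_strength=8.0,
    )


def make_benchmark(seed: int, shape: tuple[int, int] = (256, 256)) -> dict:
    """Generate the full benchmark bundle with independent substreams.

    Returns grid_t1, grid_t2 (transitioned with adjacency preference), the
    exact transition ledger, the driver stack and the true P*.
    """
    spec = benchmark_spec(seed, shape)
    grid_t1 = synth_landscape(spec)
    grid_t2, ledger = synth_transition(
        grid_t1, spec.P_star, spec.adjacency_strength, seed=spec.seed + 1
    )
    drivers = synth_drivers(grid_t1, seed=spec.seed + 2)
    return {
        "spec": spec,
        "grid_t1": grid_t1,
        "grid_t2": grid_t2,
        "ledger": ledger,
        "drivers": drivers,
        "P_star": spec.P_star,
    }


def class_affinity(drivers: DriverStack, means: dict[str, dict[str, float]] | None = None) -> dict[str, np.ndarray]:
    """Per-class affinity surfaces: driver layers projected on class profiles.

    affinity_k = Σ_d mean_{d,k} · z(layer_d): high where the local driver
    mix looks like class k's typical environment.
    """
    means = means or DEFAULT_DRIVER_MEANS
    z = {}
    for name, arr in drivers.layers.items():
        a = np.asarray(arr, dtype=float)
        z[name] = (a - a.mean()) / (a.std() if a.std() > 0 else 1.0)
    classes = set()
    for m in means.values():
        classes.update(m)
    return {
        k: sum(means[d][k] * z[d] for d in means if k in means[d]) for k in classes
    }


def make_validation_benchmark(seed: int, shape: tuple[int, int] = (256, 256)) -> dict:
    """Benchmark for the simulate-then-validate pathway.

    The landscape is the study-shaped one, but the t1→t2 change is the
    competitive-expansion process (:func:`synth_expansion`) driven by the
    directional study flows, adjacency, and driver affinity — change that
    is predictable from observables, so a skilful allocator should place
    conversions better than the null persistence model.
    """
    spec = benchmark_spec(seed, shape)
    grid_t1 = synth_landscape(spec)
    drivers = synth_drivers(grid_t1, seed=spec.seed + 2)
    tm = datasets.transfer_matrix_2000_2020()
    P_dir = transition_probabilities(TransferMatrix(directional_flows(tm.areas))).P
    counts = grid_t1.counts()
    flows = pd.DataFrame(0, index=P_dir.index, columns=P_dir.columns, dtype=np.int64)
    for i in P_dir.index:
        for j in P_dir.columns:
            if i != j:
                flows.loc[i, j] = int(round(P_dir.loc[i, j] * counts[i]))
    affinity = class_affinity(drivers)
    grid_t2, ledger = synth_expansion(
        grid_t1, flows, affinity=affinity, seed=spec.seed + 3
    )
    return {
        "spec": spec,
        "grid_t1": grid_t1,
        "grid_t2": grid_t2,
        "ledger": ledger,
        "drivers": drivers,
        "flows_cells": flows,
        "P_dir": P_dir,
    }
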