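"""Spatial autocorrelation statistics on fishnet layers.

Implements the hotspot-analysis toolkit of the workflow: global Moran's I
with permutation inference, Getis-Ord Gi* hot/cold-spot classification,
bivariate global/local Moran (LISA clusters), and Pearson correlation.
Weights are sparse contiguity (queen/rook) or k-nearest structures over the
fishnet cells; the workflow default is row-standardised queen contiguity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .grid_core import FishnetLayer

#: Gi* z-score class boundaries (90/95/99% two-tail)
GI_THRESHOLDS = (1.65, 1.96, 2.58)
GI_CLASSES = ("cold99", "cold95", "cold90", "ns", "hot90", "hot95", "hot99")


@dataclass
class SpatialWeights:
    """Sparse neighbour structure over fishnet cells."""

    W: sparse.csr_matrix
    ids: np.ndarray  # cell ids, aligned with W rows
    scheme: str
    row_standardized: bool
    includes_self: bool = False

    @property
    def n(self) -> int:
        return self.W.shape[0]

    @property
    def s0(self) -> float:
        return float(self.W.sum())

    def islands(self) -> np.ndarray:
        deg = np.asarray(self.W.sum(axis=1)).ravel()
        if self.includes_self:
            deg = deg - self.W.diagonal()
        return self.ids[deg == 0]


def _lattice_pairs(rows: np.ndarray, cols: np.ndarray, scheme: str):
    """Neighbour index pairs for cells at integer (row, col) lattice sites."""
    pos = {(r, c): i for i, (r, c) in enumerate(zip(rows, cols))}
    if scheme == "rook":
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    elif scheme == "queen":
        offsets = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    else:
        raise ValueError(f"unknown contiguity scheme {scheme!r}")
    ii, jj = [], []
    for (r, c), i in pos.items():
        for dr, dc in offsets:
            j = pos.get((r + dr, c + dc))
            if j is not None:
                ii.append(i)
                jj.append(j)
    return np.array(ii, dtype=np.int64), np.array(jj, dtype=np.int64)


def build_weights(
    fishnet: FishnetLayer | pd.DataFrame,
    scheme: str = "queen",
    row_standardize: bool = True,
    include_self: bool = False,
    k: int = 8,
) -> SpatialWeights:
    """Neighbour weights over the active (non-excluded) fishnet cells.

    ``scheme`` is ``queen``/``rook`` contiguity or ``knn`` (k nearest by
    centre distance).  Islands are reported with a warning; an all-island
    layer is an error.  ``include_self`` adds unit self-weights (the Gi*
    variant).
    """
    table = fishnet.active() if isinstance(fishnet, FishnetLayer) else fishnet
    if len(table) < 2:
        raise ValueError("need at least 2 cells to build weights")
    rows = table["row"].to_numpy()
    cols = table["col"].to_numpy()
    ids = table["cell_id"].to_numpy()
    n = len(table)
    if scheme in ("queen", "rook"):
        ii, jj = _lattice_pairs(rows, cols, scheme)
    elif scheme == "knn":
        from scipy.spatial import cKDTree

        pts = np.column_stack([rows, cols]).astype(float)
        tree = cKDTree(pts)
        _, idx = tree.query(pts, k=min(k + 1, n))
        ii = np.repeat(np.arange(n), idx.shape[1] - 1)
        jj = idx[:, 1:].ravel()
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    data = np.ones(ii.size)
    W = sparse.csr_matrix((data, (ii, jj)), shape=(n, n))
    if include_self:
        W = W + sparse.identity(n, format="csr")
    deg = np.asarray(W.sum(axis=1)).ravel()
    n_islands = int(np.count_nonzero(deg == 0))
    if n_islands == n:
        raise ValueError("every cell is an island; no weights can be built")
    if n_islands:
        warnings.warn(f"{n_islands} island cell(s) with no neighbours", stacklevel=2)
    if row_standardize:
        with np.errstate(divide="ignore"):
            inv = np.where(deg > 0, 1.0 / deg, 0.0)
        W = sparse.diags(inv) @ W
    return SpatialWeights(W.tocsr(), ids, scheme, row_standardize, include_self)


# ---------------------------------------------------------------------------
# global Moran's I
# ---------------------------------------------------------------------------


@dataclass
class MoranResult:
    I: float
    expected_i: float
    p_sim: float  # min-tail permutation p (directional)
    p_greater: float  # P(I_perm >= I_obs), exactly uniform under the null
    n_perm: int
    seed: int
    z_sim: float = np.nan


def _moran_stat(z: np.ndarray, W: sparse.csr_matrix, s0: float) -> float:
    n = z.size
    num = float(z @ (W @ z))
    den = float(z @ z)
    return (n / s0) * num / den


def global_morans_i(
    values: np.ndarray, weights: SpatialWeights, n_perm: int = 999, seed: int = 0
) -> MoranResult:
    """Global Moran's I with permutation inference.

    I = (n/S₀) Σᵢⱼ wᵢⱼ zᵢ zⱼ / Σᵢ zᵢ² with z the mean deviations; the null
    distribution comes from random relabelling of the values.
    """
    x = np.asarray(values, dtype=float)
    if x.std() == 0:
        raise ValueError("Moran's I is undefined for a constant surface")
    if x.size != weights.n:
        raise ValueError("values length does not match weights")
    z = x - x.mean()
    s0 = weights.s0
    I_obs = _moran_stat(z, weights.W, s0)
    n = x.size
    expected = -1.0 / (n - 1)
    if n_perm <= 0:
        return MoranResult(I_obs, expected, np.nan, np.nan, 0, seed)
    rng = np.random.default_rng(seed)
    Z = rng.permuted(np.tile(z, (n_perm, 1)), axis=1).T  # n × n_perm
    nums = np.einsum("ij,ij->j", Z, weights.W @ Z)
    I_perm = (n / s0) * nums / float(z @ z)
    ge = int(np.count_nonzero(I_perm >= I_obs))
    le = int(np.count_nonzero(I_perm <= I_obs))
    p_greater = (ge + 1) / (n_perm + 1)
    p_sim = (min(ge, le) + 1) / (n_perm + 1)
    sd = I_perm.std()
    z_sim = (I_obs - I_perm.mean()) / sd if sd > 0 else np.nan
    return MoranResult(I_obs, expected, p_sim, p_greater, n_perm, seed, z_sim)


def morans_i_bruteforce(values: np.ndarray, weights: SpatialWeights) -> float:
    """Literal double-sum Moran's I (independent oracle; O(n²))."""
    x = np.asarray(values, dtype=float)
    z = x - x.mean()
    W = weights.W.toarray()
    n = x.size
    num = sum(W[i, j] * z[i] * z[j] for i in range(n) for j in range(n))
    return (n / weights.s0) * num / float((z**2).sum())


# ---------------------------------------------------------------------------
# Getis-Ord Gi*
# ---------------------------------------------------------------------------


@dataclass
class GiStarResult:
    z_scores: np.ndarray
    classes: np.ndarray  # strings from GI_CLASSES
    ids: np.ndarray


def classify_z(z: np.ndarray) -> np.ndarray:
    """Map z-scores to hot/cold classes at the fixed 90/95/99% thresholds."""
    t90, t95, t99 = GI_THRESHOLDS
    out = np.full(z.shape, "ns", dtype=object)
    out[z >= t90] = "hot90"
    out[z >= t95] = "hot95"
    out[z >= t99] = "hot99"
    out[z <= -t90] = "cold90"
    out[z <= -t95] = "cold95"
    out[z <= -t99] = "cold99"
    return out.astype(str)


def getis_ord_gistar(values: np.ndarray, weights: SpatialWeights) -> GiStarResult:
    """Per-cell Gi* z-scores with hot/cold classification.

    Uses the analytic standardisation of the self-inclusive local sum:
    z_i = (Σⱼ wᵢⱼ xⱼ − x̄ Wᵢ) / (S √[(n Σⱼwᵢⱼ² − Wᵢ²)/(n−1)]).
    ``weights`` must include self-neighbours (binary form is conventional).
    """
    if not weights.includes_self:
        raise ValueError("Gi* requires self-inclusive weights (include_self=True)")
    x = np.asarray(values, dtype=float)
    if x.std() == 0:
        raise ValueError("Gi* is undefined for a constant surface")
    n = x.size
    W = weights.W
    wi = np.asarray(W.sum(axis=1)).ravel()
    wi2 = np.asarray(W.multiply(W).sum(axis=1)).ravel()
    lag = W @ x
    xbar = x.mean()
    S = np.sqrt((x**2).sum() / n - xbar**2)
    denom = S * np.sqrt(np.maximum(n * wi2 - wi**2, 0.0) / (n - 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(denom > 0, (lag - xbar * wi) / denom, 0.0)
    return GiStarResult(z, classify_z(z), weights.ids)


# ---------------------------------------------------------------------------
# bivariate Moran / LISA
# ---------------------------------------------------------------------------


@dataclass
class BivariateLisaResult:
    global_i: float
    local_i: np.ndarray
    p_values: np.ndarray  # conditional-permutation, min-tail
    labels: np.ndarray  # HH/LL/HL/LH/ns
    ids: np.ndarray
    n_perm: int
    seed: int


def _standardize(x: np.ndarray) -> np.ndarray:
    s = x.std()
    if s == 0:
        raise ValueError("cannot standardise a constant input")
    return (x - x.mean()) / s


def bivariate_moran(
    x: np.ndarray,
    y: np.ndarray,
    weights: SpatialWeights,
    n_perm: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
) -> BivariateLisaResult:
    """Bivariate Moran's I of x against the spatial lag of y.

    Global: I_xy = Σᵢ z_{x,i} (Σⱼ wᵢⱼ z_{y,j}) / n (row-standardised W);
    local: I_{xy,i} = z_{x,i} · lag(z_y)ᵢ.  Significance is by conditional
    permutation of y; labels combine the signs of (z_x, lag z_y) where
    p ≤ alpha.
    """
    zx = _standardize(np.asarray(x, dtype=float))
    zy = _standardize(np.asarray(y, dtype=float))
    if zx.size != weights.n or zy.size != weights.n:
        raise ValueError("input length does not match weights")
    n = zx.size
    W = weights.W
    lag = W @ zy
    local = zx * lag
    global_i = float(local.sum()) / n

    rng = np.random.default_rng(seed)
    Y = rng.permuted(np.tile(zy, (n_perm, 1)), axis=1).T  # n × n_perm
    lag_perm = W @ Y
    local_perm = zx[:, None] * lag_perm
    ge = (local_perm >= local[:, None]).sum(axis=1)
    le = (local_perm <= local[:, None]).sum(axis=1)
    p = (np.minimum(ge, le) + 1) / (n_perm + 1)

    labels = np.full(n, "ns", dtype=object)
    sig = p <= alpha
    hh = sig & (zx > 0) & (lag > 0)
    ll = sig & (zx < 0) & (lag < 0)
    hl = sig & (zx > 0) & (lag < 0)
    lh = sig & (zx < 0) & (lag > 0)
    labels[hh], labels[ll], labels[hl], labels[lh] = "HH", "LL", "HL", "LH"
    return BivariateLisaResult(
        global_i, local, p, labels.astype(str), weights.ids, n_perm, seed
    )


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("degenerate variance")
    return float(stats.pearsonr(x, y).statistic)
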