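"""Land-use change cross-tabulation, Markov demand projection and map agreement.

The transfer matrix between two dates is the hinge of the whole workflow:
its row-normalisation gives the Markov transition probabilities, its column
totals give the later date's class areas, and its cells drive the carbon
change decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid_core import CLASSES, LandUseGrid


@dataclass
class TransferMatrix:
    """Cross-tabulated areas (km²) moving between classes across two dates.

    Rows index the earlier date, columns the later; the diagonal is
    persistence.  Row sums reproduce the earlier date's class areas, column
    sums the later date's.
    """

    areas: pd.DataFrame  # classes × classes, km²
    date_from: str = ""
    date_to: str = ""

    def __post_init__(self) -> None:
        if (self.areas.values < -1e-12).any():
            raise ValueError("transfer matrix entries must be non-negative")
        if list(self.areas.index) != list(self.areas.columns):
            raise ValueError("transfer matrix must have matching row/column classes")

    @property
    def classes(self) -> list[str]:
        return list(self.areas.index)

    def row_totals(self) -> pd.Series:
        """Earlier-date class areas (km²)."""
        return self.areas.sum(axis=1)

    def col_totals(self) -> pd.Series:
        """Later-date class areas (km²)."""
        return self.areas.sum(axis=0)

    def total(self) -> float:
        return float(self.areas.values.sum())

    def deltas(self) -> pd.Series:
        """Per-class net area change (later − earlier, km²)."""
        return self.col_totals() - self.row_totals()

    def shares(self, when: str = "to") -> pd.Series:
        """Per-class share (%) of the mapped total at either date."""
        totals = self.col_totals() if when == "to" else self.row_totals()
        return 100.0 * totals / self.total()

    # -- labelled CSV, Total row/col included, as the study table prints it --

    def to_csv(self, path: str) -> None:
        out = self.areas.copy()
        out["Total"] = out.sum(axis=1)
        total_row = out.sum(axis=0)
        out.loc["Total"] = total_row
        out.index.name = "class"
        out.to_csv(path, float_format="%.2f")

    @classmethod
    def from_csv(cls, path, date_from: str = "", date_to: str = "") -> "TransferMatrix":
        df = pd.read_csv(path, index_col=0)
        has_totals = "Total" in df.columns and "Total" in df.index
        if has_totals:
            core = df.drop(index="Total", columns="Total")
            # validate the printed margins against the cells (rounding slack)
            if not np.allclose(core.sum(axis=1), df.loc[core.index, "Total"], atol=0.011):
                raise ValueError(f"{path}: Total column inconsistent with row sums")
            if not np.allclose(core.sum(axis=0), df.loc["Total", core.columns], atol=0.011):
                raise ValueError(f"{path}: Total row inconsistent with column sums")
        else:
            core = df
        return cls(core.astype(float), date_from, date_to)


def crosstab(grid_t1: LandUseGrid, grid_t2: LandUseGrid) -> TransferMatrix:
    """Transfer matrix between two aligned categorical rasters.

    Cells that are nodata in either raster are excluded.
    """
    if grid_t1.shape != grid_t2.shape:
        raise ValueError(f"shape mismatch: {grid_t1.shape} vs {grid_t2.shape}")
    if grid_t1.cell_size != grid_t2.cell_size:
        raise ValueError("cell size mismatch")
    both = grid_t1.valid_mask & grid_t2.valid_mask
    codes = sorted(grid_t1.class_table)
    names = [grid_t1.class_table[c] for c in codes]
    k = len(codes)
    code_to_idx = {c: i for i, c in enumerate(codes)}
    lut = np.full(max(codes) + 2, -1, dtype=np.int64)
    for c, i in code_to_idx.items():
        lut[c] = i
    a = lut[grid_t1.codes[both]]
    b = lut[grid_t2.codes[both]]
    counts = np.bincount(a * k + b, minlength=k * k).reshape(k, k)
    areas = pd.DataFrame(counts * grid_t1.cell_area_km2, index=names, columns=names)
    return TransferMatrix(areas)


@dataclass
class TransitionProbabilities:
    """Row-stochastic Markov transition matrix over one calibration period."""

    P: pd.DataFrame
    period_years: float = 20.0

    def __post_init__(self) -> None:
        v = self.P.values
        if (v < -1e-12).any() or (v > 1 + 1e-12).any():
            raise ValueError("transition probabilities must lie in [0, 1]")
        if not np.allclose(v.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition matrix rows must sum to 1")

    @property
    def classes(self) -> list[str]:
        return list(self.P.index)


def transition_probabilities(tm: TransferMatrix, period_years: float = 20.0) -> TransitionProbabilities:
    """Row-normalise a transfer matrix; empty rows become identity rows.

    A class absent at the earlier date cannot be observed transitioning, so
    its row is the identity by convention (avoids 0/0).
    """
    rows = tm.row_totals()
    P = tm.areas.div(rows.where(rows > 0, 1.0), axis=0)
    for cls in tm.classes:
        if rows[cls] == 0:
            P.loc[cls] = 0.0
            P.loc[cls, cls] = 1.0
    return TransitionProbabilities(P, period_years)


def markov_project(areas_t: pd.Series, tp: TransitionProbabilities, n_steps: int = 1) -> pd.Series:
    """Project per-class area demand: demand = areas_t · Pⁿ.

    One step spans the probabilities' calibration period.  Total area is
    conserved (row-stochasticity), to within 1e-6 km² numerically.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be ≥ 1")
    P = tp.P.loc[areas_t.index, areas_t.index].values
    v = areas_t.values.astype(float)
    out = v @ np.linalg.matrix_power(P, n_steps)
    if abs(out.sum() - v.sum()) > 1e-6:
        raise ValueError("projection failed to conserve total area")
    return pd.Series(out, index=areas_t.index)


@dataclass
class ConfusionMatrix:
    """k×k counts of (reference class, simulated class) with OA and Kappa."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return int(self.counts.values.sum())

    @property
    def overall_accuracy(self) -> float:
        """Fraction of agreeing cells (po)."""
        return float(np.trace(self.counts.values)) / self.n

    @property
    def kappa(self) -> float:
        """Unweighted Cohen's kappa: (po − pe) / (1 − pe)."""
        c = self.counts.values.astype(float)
        n = c.sum()
        po = np.trace(c) / n
        pe = float((c.sum(axis=1) * c.sum(axis=0)).sum()) / n**2
        if pe == 1.0:
            return 1.0
        return (po - pe) / (1 - pe)


def agreement(reference: LandUseGrid, simulated: LandUseGrid) -> ConfusionMatrix:
    """Confusion matrix of two aligned maps; nodata excluded pairwise."""
    if reference.shape != simulated.shape:
        raise ValueError("shape mismatch")
    both = reference.valid_mask & simulated.valid_mask
    if not both.any():
        raise ValueError("no jointly valid cells")
    codes = sorted(reference.class_table)
    names = [reference.class_table[c] for c in codes]
    k = len(codes)
    lut = np.full(max(codes) + 2, -1, dtype=np.int64)
    for i, c in enumerate(codes):
        lut[c] = i
    a = lut[reference.codes[both]]
    b = lut[simulated.codes[both]]
    counts = np.bincount(a * k + b, minlength=k * k).reshape(k, k)
    return ConfusionMatrix(pd.DataFrame(counts, index=names, columns=names))
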