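"""Four-pool ecosystem carbon bookkeeping.

The model is deliberately simple: each land class carries a fixed carbon
density per pool (aboveground, belowground, soil, dead organic matter,
t/ha); total storage is Σ_i density_i × area_i.  Change over a period
decomposes exactly over the transfer matrix:
ΔC_ij = area_ij × (c_total_j − c_total_i) × 100 ha/km².
Inter-annual density dynamics are out of scope by assumption.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid_core import HA_PER_KM2, LandUseGrid, class_areas
from .transitions import TransferMatrix

POOLS = ("c_above", "c_below", "c_soil", "c_dead")


@dataclass
class CarbonDensityTable:
    """Per-class carbon density (t/ha) for the four pools.

    ``densities`` has one row per class and the four pool columns; water and
    construction are expected to be all-zero rows (no stable carbon stock is
    attributed to them in this accounting).
    """

    densities: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [p for p in POOLS if p not in self.densities.columns]
        if missing:
            raise ValueError(f"density table missing pool columns: {missing}")
        if (self.densities[list(POOLS)].values < 0).any():
            raise ValueError("carbon densities must be non-negative")
        if self.densities.index.duplicated().any():
            raise ValueError("duplicate class rows in density table")
        if (self.densities[list(POOLS)].values == 0).all():
            warnings.warn("all carbon densities are zero", stacklevel=2)

    @property
    def classes(self) -> list[str]:
        return list(self.densities.index)

    @property
    def c_total(self) -> pd.Series:
        """Pool-summed density per class (t/ha)."""
        return self.densities[list(POOLS)].sum(axis=1)


def load_density_table(source) -> CarbonDensityTable:
    """Load and validate a density CSV (class, c_above, c_below, c_soil, c_dead)."""
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source, index_col=0)
    return CarbonDensityTable(df.astype(float))


def carbon_from_areas(areas: pd.Series, table: CarbonDensityTable) -> dict:
    """Carbon totals (t) per pool and overall from per-class areas (km²).

    Per pool p: Σ_i density_{i,p} (t/ha) × area_i (km²) × 100 ha/km².
    """
    unknown = [c for c in areas.index if c not in table.classes]
    if unknown:
        raise KeyError(f"classes absent from density table: {unknown}")
    d = table.densities.loc[areas.index]
    per_pool = {p: float((d[p] * areas).sum() * HA_PER_KM2) for p in POOLS}
    per_class = table.c_total.loc[areas.index] * areas * HA_PER_KM2
    return {
        "per_pool_t": per_pool,
        "per_class_t": per_class,
        "total_t": float(sum(per_pool.values())),
    }


@dataclass
class CarbonMap:
    """Per-cell carbon raster (t) with its scalar totals."""

    carbon_t: np.ndarray
    per_pool_t: dict
    total_t: float


def carbon_map(grid: LandUseGrid, table: CarbonDensityTable) -> CarbonMap:
    """Rasterise carbon: each cell carries c_total(class) × cell area (ha).

    The map total equals the area-based total exactly (same arithmetic,
    different order), nodata cells carry 0.
    """
    density_by_code = np.zeros(max(grid.class_table) + 1)
    for code, name in grid.class_table.items():
        if name not in table.classes:
            raise KeyError(f"class {name!r} absent from density table")
        density_by_code[code] = table.c_total[name]
    cell_ha = grid.cell_area_km2 * HA_PER_KM2
    codes = np.where(grid.valid_mask, grid.codes, 0)
    carbon = density_by_code[codes] * cell_ha
    carbon[~grid.valid_mask] = 0.0
    totals = carbon_from_areas(class_areas(grid), table)
    return CarbonMap(carbon, totals["per_pool_t"], totals["total_t"])


def carbon_change(tm: TransferMatrix, table: CarbonDensityTable):
    """Per-transition carbon change matrix (t) and the net change.

    ΔC_ij = area_ij × 100 × (c_total_j − c_total_i); the net sum equals
    C_tot(later) − C_tot(earlier) by algebra.
    """
    ct = table.c_total.loc[tm.classes].values
    diff = ct[np.newaxis, :] - ct[:, np.newaxis]
    delta = pd.DataFrame(
        tm.areas.values * HA_PER_KM2 * diff, index=tm.classes, columns=tm.classes
    )
    return delta, float(delta.values.sum())
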