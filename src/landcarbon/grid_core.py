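"""Raster data model, file I/O, area accounting and fishnet aggregation.

The package works on single-band categorical rasters (land-use class codes)
and continuous rasters (drivers, carbon, indices) that share one grid.  Two
on-disk formats are supported: ESRI ASCII grid (``.asc``/``.txt``), which
carries cell size and nodata in its header, and TIFF via :mod:`tifffile`,
where cell size and nodata travel in a JSON ``ImageDescription`` tag.

Conventions: row-major arrays, origin at the upper-left corner, cell (0, 0)
is the NW corner.  Areas are km² internally; carbon densities are t/ha; the
conversion lives in :data:`HA_PER_KM2`.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import tifffile

#: hectares per square kilometre — the single place the t/ha × km² unit
#: bridge is encoded.
HA_PER_KM2 = 100.0

#: canonical class order used by every table in the package
CLASSES = ("cultivated", "forest", "grassland", "water", "construction", "unused")

#: default code book: 1..6 in canonical order
DEFAULT_CLASS_TABLE = {i + 1: name for i, name in enumerate(CLASSES)}

DEFAULT_NODATA = -9999


class GridFormatError(ValueError):
    """Raised for malformed raster files or inconsistent grid stacks."""


@dataclass
class LandUseGrid:
    """Categorical land-use raster.

    Parameters
    ----------
    codes
        Integer matrix (rows × cols) of class codes.
    class_table
        Mapping code -> class name for every legal code.
    cell_size
        Cell edge length in metres (> 0).
    nodata
        Reserved integer marking unmapped cells.
    crs_tag
        Opaque coordinate-system label, carried through I/O unchanged.
    """

    codes: np.ndarray
    class_table: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_CLASS_TABLE))
    cell_size: float = 30.0
    nodata: int = DEFAULT_NODATA
    crs_tag: str = ""

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if not np.issubdtype(self.codes.dtype, np.integer):
            if not np.all(np.mod(self.codes[np.isfinite(self.codes)], 1) == 0):
                raise GridFormatError("land-use raster must be integer-valued")
            self.codes = self.codes.astype(np.int32)
        if self.codes.ndim != 2 or min(self.codes.shape) < 1:
            raise GridFormatError("raster must be a 2-D matrix of at least 1×1")
        if self.cell_size <= 0:
            raise GridFormatError("cell_size must be positive")
        unknown = self._unknown_codes()
        if unknown.size:
            raise GridFormatError(
                f"codes not in class table: {sorted(int(c) for c in unknown)}"
            )

    def _unknown_codes(self) -> np.ndarray:
        present = np.unique(self.codes)
        legal = set(self.class_table) | {self.nodata}
        return np.array([c for c in present if int(c) not in legal])

    @property
    def shape(self) -> tuple[int, int]:
        return self.codes.shape

    @property
    def valid_mask(self) -> np.ndarray:
        return self.codes != self.nodata

    @property
    def cell_area_km2(self) -> float:
        return self.cell_size**2 / 1e6

    def copy(self) -> "LandUseGrid":
        return replace(self, codes=self.codes.copy(), class_table=dict(self.class_table))

    def counts(self) -> pd.Series:
        """Per-class valid cell counts in class-table order."""
        out = {}
        for code, name in sorted(self.class_table.items()):
            out[name] = int(np.count_nonzero(self.codes == code))
        return pd.Series(out, dtype=np.int64)


def class_areas(grid: LandUseGrid) -> pd.Series:
    """Per-class area in km² (nodata excluded).

    area_k = count(code == k) × cell_size² / 10⁶.
    """
    return grid.counts() * grid.cell_area_km2


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_ASC_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def _read_ascii_grid(path: str) -> tuple[np.ndarray, float, float]:
    """Return (array, cell_size, nodata) from an ESRI ASCII grid."""
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            pos = fh.tell()
            line = fh.readline()
            if not line:
                raise GridFormatError(f"{path}: truncated header")
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in _ASC_HEADER_KEYS + ("nodata_value",):
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        for key in ("ncols", "nrows", "cellsize"):
            if key not in header:
                raise GridFormatError(f"{path}: missing ASCII-grid header field {key}")
        data = np.loadtxt(fh, ndmin=2)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if data.shape != (nrows, ncols):
        raise GridFormatError(
            f"{path}: data block {data.shape} does not match header ({nrows}, {ncols})"
        )
    nodata = header.get("nodata_value", float(DEFAULT_NODATA))
    return data, header["cellsize"], nodata


def _write_ascii_grid(path: str, array: np.ndarray, cell_size: float, nodata) -> None:
    nrows, ncols = array.shape
    with open(path, "w") as fh:
        fh.write(
            f"ncols {ncols}\nnrows {nrows}\nxllcorner 0.0\nyllcorner 0.0\n"
            f"cellsize {cell_size:g}\nNODATA_value {nodata:g}\n"
        )
        fmt = "%d" if np.issubdtype(array.dtype, np.integer) else "%.10g"
        np.savetxt(fh, array, fmt=fmt)


def read_raster(path: str, cell_size: float | None = None, nodata=None):
    """Read a single-band raster (.asc/.txt or .tif/.tiff).

    Returns ``(array, cell_size, nodata)``.  For TIFFs the cell size and
    nodata are taken from the JSON ``ImageDescription`` written by
    :func:`write_raster`, falling back to the arguments.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    ext = os.path.splitext(path)[1].lower()
    if ext in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tif:
            arr = tif.asarray()
            desc = tif.pages[0].description or ""
        meta: dict = {}
        try:
            meta = json.loads(desc)
        except (ValueError, TypeError):
            pass
        cs = float(meta.get("cell_size", cell_size if cell_size else 30.0))
        nd = meta.get("nodata", nodata if nodata is not None else DEFAULT_NODATA)
        return arr, cs, nd
    arr, cs, nd = _read_ascii_grid(path)
    if cell_size is not None:
        cs = cell_size
    if nodata is not None:
        nd = nodata
    return arr, cs, nd


def write_raster(path: str, array: np.ndarray, cell_size: float, nodata, crs_tag: str = "") -> None:
    """Write a single-band raster; format chosen by extension."""
    ext = os.path.splitext(path)[1].lower()
    array = np.asarray(array)
    if ext in (".tif", ".tiff"):
        desc = json.dumps(
            {"cell_size": cell_size, "nodata": None if nodata is None else float(nodata),
             "crs_tag": crs_tag}
        )
        tifffile.imwrite(path, array, description=desc)
    else:
        _write_ascii_grid(path, array, cell_size, DEFAULT_NODATA if nodata is None else nodata)


def read_landuse(
    path: str,
    class_table: dict[int, str] | None = None,
    *,
    strict: bool = True,
    cell_size: float | None = None,
    crs_tag: str = "",
) -> LandUseGrid:
    """Read a categorical land-use raster.

    In strict mode (default) any code outside ``class_table`` raises
    :class:`GridFormatError` naming the offending codes; with
    ``strict=False`` unknown codes are mapped to nodata.
    """
    class_table = dict(class_table or DEFAULT_CLASS_TABLE)
    arr, cs, nd = read_raster(path, cell_size=cell_size)
    if not np.issubdtype(np.asarray(arr).dtype, np.integer):
        frac = np.mod(arr, 1)
        if np.any(frac != 0):
            raise GridFormatError(f"{path}: non-integer band in a land-use raster")
        arr = arr.astype(np.int32)
    arr = arr.astype(np.int32)
    nd = int(nd)
    legal = set(class_table) | {nd}
    unknown = [int(c) for c in np.unique(arr) if int(c) not in legal]
    if unknown:
        if strict:
            raise GridFormatError(f"{path}: unknown class codes {unknown} (strict mode)")
        arr = np.where(np.isin(arr, unknown), nd, arr)
    return LandUseGrid(arr, class_table, cs, nd, crs_tag)


def write_landuse(path: str, grid: LandUseGrid) -> None:
    write_raster(path, grid.codes.astype(np.int32), grid.cell_size, grid.nodata, grid.crs_tag)


# ---------------------------------------------------------------------------
# fishnet
# ---------------------------------------------------------------------------


@dataclass
class FishnetLayer:
    """Square analysis cells tiling a raster extent.

    ``table`` holds one row per fishnet cell (reading order): ``cell_id``,
    ``row``, ``col``, one column per aggregated attribute, ``valid_fraction``
    and an ``excluded`` flag for cells whose valid coverage falls below the
    configured minimum.  Aggregation semantics: ``carbon`` and any ``*_sum``
    attribute are summed, so fishnet totals conserve raster totals exactly;
    ``impervious`` becomes ``isa_fraction`` (mean over valid cells); other
    attributes are means over valid cells.
    """

    table: pd.DataFrame
    cell_edge_m: float
    grid_shape: tuple[int, int]
    shape: tuple[int, int]
    cell_size_m: float

    @property
    def n_cells(self) -> int:
        return len(self.table)

    def active(self) -> pd.DataFrame:
        """Rows not flagged excluded."""
        return self.table.loc[~self.table["excluded"]]

    def polygons(self):
        """Shapely boxes for every fishnet cell (origin at upper-left)."""
        from shapely.geometry import box

        e = self.cell_edge_m
        H = self.shape[0] * e
        return [
            box(c * e, H - (r + 1) * e, (c + 1) * e, H - r * e)
            for r, c in self.table[["row", "col"]].itertuples(index=False)
        ]

    def to_csv(self, path: str) -> None:
        self.table.to_csv(path, index=False)


def build_fishnet(
    rasters: dict[str, np.ndarray],
    cell_size_m: float,
    cell_edge_m: float = 2000.0,
    min_valid_fraction: float = 0.5,
    valid_mask: np.ndarray | None = None,
) -> FishnetLayer:
    """Aggregate aligned rasters onto a square fishnet.

    All rasters must share one shape; ``valid_mask`` (default: all cells
    finite in every raster) defines which raster cells count as valid.
    Partially covered edge fishnet cells are retained with their
    ``valid_fraction`` recorded; cells below ``min_valid_fraction`` are
    flagged ``excluded``.
    """
    if not rasters:
        raise ValueError("at least one raster is required")
    shapes = {np.asarray(a).shape for a in rasters.values()}
    if len(shapes) != 1:
        raise GridFormatError(f"rasters do not share one shape: {sorted(shapes)}")
    shape = shapes.pop()
    factor = cell_edge_m / cell_size_m
    if factor < 1:
        raise ValueError("fishnet edge must be at least one raster cell")

    if valid_mask is None:
        valid_mask = np.ones(shape, dtype=bool)
        for arr in rasters.values():
            valid_mask &= np.isfinite(np.asarray(arr, dtype=float))
    valid_mask = np.asarray(valid_mask, dtype=bool)

    # assign raster cells by centre position; the fishnet need not align
    # with cell boundaries (2 km over 30 m cells does not)
    rows, cols = np.indices(shape)
    frow = ((rows + 0.5) * cell_size_m / cell_edge_m).astype(np.int64)
    fcol = ((cols + 0.5) * cell_size_m / cell_edge_m).astype(np.int64)
    nfr = int(frow.max()) + 1
    nfc = int(fcol.max()) + 1
    block = frow * nfc + fcol
    nblocks = nfr * nfc
    f2 = factor * factor  # nominal raster cells per fishnet cell

    valid_counts = np.bincount(block.ravel(), weights=valid_mask.ravel(), minlength=nblocks)
    out = pd.DataFrame(
        {
            "cell_id": np.arange(nblocks),
            "row": np.arange(nblocks) // nfc,
            "col": np.arange(nblocks) % nfc,
        }
    )
    for name, arr in rasters.items():
        arr = np.asarray(arr, dtype=float)
        vals = np.where(valid_mask, np.nan_to_num(arr, nan=0.0), 0.0)
        sums = np.bincount(block.ravel(), weights=vals.ravel(), minlength=nblocks)
        if name == "carbon" or name.endswith("_sum"):
            out[name if name != "carbon" else "carbon_t"] = sums
        elif name == "impervious":
            with np.errstate(invalid="ignore"):
                out["isa_fraction"] = np.where(valid_counts > 0, sums / valid_counts, np.nan)
        else:
            colname = name if name.endswith("_mean") else f"{name}_mean"
            with np.errstate(invalid="ignore"):
                out[colname] = np.where(valid_counts > 0, sums / valid_counts, np.nan)
    out["valid_fraction"] = np.minimum(valid_counts / f2, 1.0)
    out["excluded"] = out["valid_fraction"] < min_valid_fraction
    return FishnetLayer(out, cell_edge_m, shape, (nfr, nfc), cell_size_m)
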