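"""Raster grids, stacks and occurrence tables.

The data model is deliberately small: a :class:`Grid` is a rectangular 2-D
array of cell values anchored to a geographic transform (west edge, north
edge, square cell size in degrees, WGS84 lon/lat), and a :class:`GridStack`
is a name->Grid mapping whose members are co-registered.  Row 0 is the
northernmost row.  A cell contains its upper-left corner (half-open
convention), so the cell of a point is ``floor((lon - west)/cell)``,
``floor((north - lat)/cell)``.

Rasters are serialised as ESRI ASCII grids (a plain-text header of six
``key value`` lines followed by the rows north to south), which round-trips
losslessly at double precision and needs no binary dependencies.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: geometry comparison tolerance for co-registration checks
GEOM_ATOL = 1e-9

DEFAULT_NODATA = -9999.0


@dataclass(frozen=True)
class GridTransform:
    """Anchors a raster to lon/lat: west edge, north edge, square cell size."""

    west: float
    north: float
    cell_size: float

    def cell_center(self, row, col):
        """Lon/lat of the center of cell (row, col); accepts arrays."""
        lon = self.west + (np.asarray(col) + 0.5) * self.cell_size
        lat = self.north - (np.asarray(row) + 0.5) * self.cell_size
        return lon, lat

    def cell_of(self, lon, lat):
        """Row/col of the cell containing (lon, lat); half-open convention."""
        col = np.floor((np.asarray(lon, dtype=float) - self.west) / self.cell_size)
        row = np.floor((self.north - np.asarray(lat, dtype=float)) / self.cell_size)
        return row.astype(int), col.astype(int)

    def close_to(self, other: "GridTransform", atol: float = GEOM_ATOL) -> bool:
        return (
            abs(self.west - other.west) <= atol
            and abs(self.north - other.north) <= atol
            and abs(self.cell_size - other.cell_size) <= atol
        )


@dataclass
class Grid:
    """A single co-registered raster layer."""

    values: np.ndarray
    transform: GridTransform
    crs_label: str = "WGS84"
    nodata: float = DEFAULT_NODATA

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("Grid values must be 2-D")

    @property
    def shape(self):
        return self.values.shape

    @property
    def n_rows(self):
        return self.values.shape[0]

    @property
    def n_cols(self):
        return self.values.shape[1]

    def valid_mask(self) -> np.ndarray:
        """Boolean mask of cells carrying data."""
        vals = self.values
        mask = vals != self.nodata
        if np.issubdtype(vals.dtype, np.floating):
            mask &= ~np.isnan(vals)
        return mask

    def masked(self) -> np.ndarray:
        """Values as float with NoData replaced by NaN."""
        out = self.values.astype(float).copy()
        out[~self.valid_mask()] = np.nan
        return out

    def contains(self, lon, lat):
        """True where (lon, lat) falls inside the grid extent."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        east = self.transform.west + self.n_cols * self.transform.cell_size
        south = self.transform.north - self.n_rows * self.transform.cell_size
        return (
            (lon >= self.transform.west)
            & (lon < east)
            & (lat <= self.transform.north)
            & (lat > south)
        )

    def like(self, values, nodata=None) -> "Grid":
        """A new grid sharing this grid's geometry."""
        return Grid(
            values=np.asarray(values),
            transform=self.transform,
            crs_label=self.crs_label,
            nodata=self.nodata if nodata is None else nodata,
        )

    def copy(self) -> "Grid":
        return replace(self, values=self.values.copy())


class GridStack:
    """Named co-registered layers sharing shape and transform.

    Layers may differ in their per-layer NoData footprint; the combined
    valid-data mask is the intersection over all layers.
    """

    def __init__(self, layers: dict[str, Grid] | None = None):
        self._layers: dict[str, Grid] = {}
        for name, grid in (layers or {}).items():
            self.add(name, grid)

    def add(self, name: str, grid: Grid):
        if self._layers:
            ref = next(iter(self._layers.values()))
            if grid.shape != ref.shape:
                raise ValueError(
                    f"layer {name!r} shape {grid.shape} != stack shape {ref.shape}"
                )
            if not grid.transform.close_to(ref.transform):
                raise ValueError(f"layer {name!r} transform disagrees with stack")
        self._layers[name] = grid

    def __getitem__(self, name: str) -> Grid:
        return self._layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self._layers

    def __iter__(self):
        return iter(self._layers)

    def __len__(self):
        return len(self._layers)

    @property
    def names(self) -> list[str]:
        return list(self._layers)

    @property
    def transform(self) -> GridTransform:
        return next(iter(self._layers.values())).transform

    @property
    def shape(self):
        return next(iter(self._layers.values())).shape

    def combined_mask(self, names=None) -> np.ndarray:
        """Intersection of the valid masks of the requested layers."""
        names = self.names if names is None else list(names)
        mask = np.ones(self.shape, dtype=bool)
        for name in names:
            mask &= self._layers[name].valid_mask()
        return mask

    def table(self, names=None, mask=None) -> pd.DataFrame:
        """Per-cell variable table over the valid (or given) mask.

        Returns a DataFrame with one row per cell (index = flat cell index
        in row-major order) and one column per layer.
        """
        names = self.names if names is None else list(names)
        if mask is None:
            mask = self.combined_mask(names)
        rows, cols = np.nonzero(mask)
        data = {name: self._layers[name].values[rows, cols] for name in names}
        idx = rows * self.shape[1] + cols
        return pd.DataFrame(data, index=idx)

    def subset(self, names) -> "GridStack":
        return GridStack({n: self._layers[n] for n in names})

    def copy(self) -> "GridStack":
        return GridStack({n: g.copy() for n, g in self._layers.items()})


@dataclass
class OccurrenceSet:
    """Cleaned presence points (lon/lat), optionally with true suitability."""

    lon: np.ndarray
    lat: np.ndarray
    source_tag: str = ""
    true_suitability: np.ndarray | None = None

    def __post_init__(self):
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)

    def __len__(self):
        return len(self.lon)

    def points(self) -> np.ndarray:
        return np.column_stack([self.lon, self.lat])

    def to_frame(self, species: str = "virtual") -> pd.DataFrame:
        return pd.DataFrame({"species": species, "lon": self.lon, "lat": self.lat})


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O

def write_raster(grid: Grid, path) -> None:
    """Write a grid as an ESRI ASCII raster (text, double precision)."""
    t = grid.transform
    yll = t.north - grid.n_rows * t.cell_size
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {t.west!r}\n")
        fh.write(f"yllcorner {yll!r}\n")
        fh.write(f"cellsize {t.cell_size!r}\n")
        fh.write(f"NODATA_value {grid.nodata!r}\n")
        np.savetxt(fh, grid.values, fmt="%.17g")


def read_raster(path, crs_label: str | None = None) -> Grid:
    """Read an ESRI ASCII raster.

    The format carries no CRS; unless a label is supplied the grid is
    tagged ``"unknown"`` with a warning (coordinates in this package are
    treated as WGS84 lon/lat throughout).
    """
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = 0
        for _ in range(6):
            line = fh.readline()
            key, value = line.split()
            header[key.lower()] = float(value)
            pos = fh.tell()
        fh.seek(pos)
        values = np.loadtxt(fh, ndmin=2)
    n_rows = int(header["nrows"])
    n_cols = int(header["ncols"])
    if values.shape != (n_rows, n_cols):
        raise ValueError(f"raster body {values.shape} disagrees with header")
    if "xllcorner" not in header:
        raise ValueError("only corner-registered ASCII grids are supported")
    cell = header["cellsize"]
    transform = GridTransform(
        west=header["xllcorner"],
        north=header["yllcorner"] + n_rows * cell,
        cell_size=cell,
    )
    if crs_label is None:
        warnings.warn("ASCII grid carries no CRS; tagging as 'unknown'")
        crs_label = "unknown"
    return Grid(
        values=values,
        transform=transform,
        crs_label=crs_label,
        nodata=header.get("nodata_value", DEFAULT_NODATA),
    )


# ---------------------------------------------------------------------------
# occurrences

def load_occurrences(path, grid: Grid, source_tag: str = "") -> OccurrenceSet:
    """Load and clean an occurrence CSV (columns ``lon``, ``lat``).

    Cleaning: rows with missing or unparseable coordinates are dropped,
    exact-duplicate coordinate pairs are collapsed, and points outside the
    grid extent are dropped with a logged count.  Raises if nothing
    survives.
    """
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "lon" not in cols or "lat" not in cols:
        raise ValueError("occurrence CSV must have lon and lat columns")
    lon = pd.to_numeric(df[cols["lon"]], errors="coerce")
    lat = pd.to_numeric(df[cols["lat"]], errors="coerce")
    ok = lon.notna() & lat.notna()
    n_incomplete = int((~ok).sum())
    pts = pd.DataFrame({"lon": lon[ok], "lat": lat[ok]})
    n_before = len(pts)
    pts = pts.drop_duplicates()
    n_dup = n_before - len(pts)
    inside = grid.contains(pts["lon"].to_numpy(), pts["lat"].to_numpy())
    n_outside = int((~inside).sum())
    pts = pts[inside]
    if n_incomplete or n_dup or n_outside:
        log.info(
            "occurrence cleaning: dropped %d incomplete, %d duplicate, "
            "%d outside-extent rows", n_incomplete, n_dup, n_outside,
        )
    if len(pts) == 0:
        raise ValueError("no valid occurrence points after cleaning")
    return OccurrenceSet(
        lon=pts["lon"].to_numpy(), lat=pts["lat"].to_numpy(), source_tag=source_tag
    )


def extract_values(stack: GridStack, lon, lat, names=None) -> pd.DataFrame:
    """Variable values at the cells containing the given points.

    Uses the containing-cell (nearest-cell) lookup shared with the
    occurrence-to-cell mapping.  The returned frame carries the point
    coordinates, one column per layer, and a boolean ``on_nodata`` flag
    (True where any requested layer lacks data at that cell).
    """
    names = stack.names if names is None else list(names)
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    ref = stack[names[0]]
    inside = ref.contains(lon, lat)
    if not inside.all():
        raise ValueError(f"{int((~inside).sum())} points fall outside the grid extent")
    rows, cols = stack.transform.cell_of(lon, lat)
    out = pd.DataFrame({"lon": lon, "lat": lat})
    on_nodata = np.zeros(len(lon), dtype=bool)
    for name in names:
        g = stack[name]
        vals = g.values[rows, cols].astype(float)
        bad = ~g.valid_mask()[rows, cols]
        vals[bad] = np.nan
        on_nodata |= bad
        out[name] = vals
    out["on_nodata"] = on_nodata
    return out
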