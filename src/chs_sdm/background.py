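"""Pseudo-absence (background) sampling in a buffered convex hull.

Presence-only data carry no absences, so the presence/absence learners are
trained against pseudo-absences drawn from a background region: the convex
hull of the occurrence points buffered outward by a great-circle distance
(default 200 km), minus the presence cells themselves and any NoData cells.
Replicate sets of a fixed size (default 3 x 500) are drawn uniformly
without replacement at cell granularity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import LineString, MultiPoint, Point

from .grids import Grid, OccurrenceSet

EARTH_RADIUS_KM = 6371.0


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km on a sphere of radius 6371 km."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float))
                              for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


@dataclass
class BackgroundRegion:
    """Eligible background cells with their provenance."""

    rows: np.ndarray
    cols: np.ndarray
    grid: Grid
    buffer_km: float
    hull_wkt: str

    def __len__(self):
        return len(self.rows)

    def cell_set(self) -> set[tuple[int, int]]:
        return set(zip(self.rows.tolist(), self.cols.tolist()))

    def mask(self) -> np.ndarray:
        m = np.zeros(self.grid.shape, dtype=bool)
        m[self.rows, self.cols] = True
        return m


@dataclass
class PseudoAbsenceSet:
    """One replicate of pseudo-absence points (cell centers)."""

    replicate_id: int
    lon: np.ndarray
    lat: np.ndarray

    def __len__(self):
        return len(self.lon)


def _hull_geometry(lon: np.ndarray, lat: np.ndarray):
    """Convex hull of the points; degenerates to a segment or point."""
    return MultiPoint([Point(x, y) for x, y in zip(lon, lat)]).convex_hull


def _densify_boundary(geom, step_deg: float) -> np.ndarray:
    """Sample points along the hull boundary (or the degenerate geometry)."""
    if geom.geom_type == "Point":
        return np.array([[geom.x, geom.y]])
    boundary = geom.exterior if geom.geom_type == "Polygon" else geom
    if isinstance(boundary, LineString) or boundary.geom_type == "LinearRing":
        length = boundary.length
        n = max(int(np.ceil(length / step_deg)), 1) + 1
        pts = [boundary.interpolate(d) for d in np.linspace(0, length, n)]
        return np.array([[p.x, p.y] for p in pts])
    raise ValueError(f"unexpected hull geometry {geom.geom_type}")


def build_background_region(
    occ: OccurrenceSet, grid: Grid, buffer_km: float = 200.0
) -> BackgroundRegion:
    """Cells whose centers lie in or within ``buffer_km`` of the hull.

    The hull is the planar convex hull of the occurrence lon/lat points
    (degenerating gracefully for < 3 or collinear points, where the buffer
    alone defines the region); distance to the hull is zero inside it and
    the great-circle (haversine) distance to the densified hull boundary
    outside.  Presence cells and NoData cells are excluded.
    """
    if len(occ) == 0:
        raise ValueError("no occurrences")
    hull = _hull_geometry(occ.lon, occ.lat)
    step = grid.transform.cell_size / 8.0
    boundary = _densify_boundary(hull, step)

    rows, cols = np.nonzero(grid.valid_mask())
    lon, lat = grid.transform.cell_center(rows, cols)

    inside = np.zeros(len(rows), dtype=bool)
    if hull.geom_type == "Polygon":
        from shapely import contains_xy
        inside = contains_xy(hull, lon, lat)

    # min great-circle distance to the hull boundary, chunked to bound memory
    near = np.zeros(len(rows), dtype=bool)
    todo = ~inside
    idx = np.nonzero(todo)[0]
    for start in range(0, len(idx), 4096):
        sl = idx[start:start + 4096]
        d = haversine_km(
            lon[sl][:, None], lat[sl][:, None],
            boundary[None, :, 0], boundary[None, :, 1],
        ).min(axis=1)
        near[sl] = d <= buffer_km
    eligible = inside | near

    pr, pc = grid.transform.cell_of(occ.lon, occ.lat)
    presence = np.zeros(grid.shape, dtype=bool)
    ok = (pr >= 0) & (pr < grid.n_rows) & (pc >= 0) & (pc < grid.n_cols)
    presence[pr[ok], pc[ok]] = True
    eligible &= ~presence[rows, cols]

    if not eligible.any():
        raise ValueError("background region is empty")
    return BackgroundRegion(
        rows=rows[eligible], cols=cols[eligible], grid=grid,
        buffer_km=buffer_km, hull_wkt=hull.wkt,
    )


def sample_pseudo_absences(
    region: BackgroundRegion, n: int = 500, replicates: int = 3, seed: int = 0
) -> list[PseudoAbsenceSet]:
    """Draw replicate pseudo-absence sets uniformly without replacement.

    Each replicate uses an independent stream derived from ``(seed,
    replicate_id)`` so replicates are distinct but individually
    reproducible.
    """
    if len(region) < n:
        raise ValueError(
            f"background region has {len(region)} cells, fewer than n={n}"
        )
    out = []
    for rep in range(1, replicates + 1):
        rng = np.random.default_rng(np.random.SeedSequence([seed, rep]))
        pick = rng.choice(len(region), size=n, replace=False)
        lon, lat = region.grid.transform.cell_center(
            region.rows[pick], region.cols[pick]
        )
        out.append(PseudoAbsenceSet(replicate_id=rep, lon=lon, lat=lat))
    return out
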