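"""Zonal area accounting, class transitions, response curves, importance.

Areas use spherical cell areas: for a lon/lat grid the area of a cell in a
row spanning latitudes [phi_b, phi_t] is

    A = R^2 * d_lambda * (sin phi_t - sin phi_b),   R = 6371 km,

so areas are exact on the sphere and additive by construction.  Response
curves use the evaluation-strip method (vary one variable over its observed
range, hold the others at their valid-cell medians) and report the
suitable range(s) where the curve exceeds a cutoff.  Variable importance is
the permutation kind: one minus the Pearson correlation between intact and
variable-shuffled predictions, averaged over shuffles and normalized to
sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import Grid, GridStack
from .habitat import CLASS_NAMES, CHS_NODATA

EARTH_RADIUS_KM = 6371.0

#: Published province-level accounting of current habitat classes for the
#: reference species (Notopterygium incisum): percentage of each region's
#: land in each class and the class areas in 10^3 km^2.  The "Other area"
#: row reports areas only.  Used by the internal-consistency checks
#: (additivity of areas, recomputation of percentages).
REFERENCE_AREA_TABLE = pd.DataFrame(
    [
        # region, pct_suit, pct_marg, pct_unsuit, suit, marg, unsuit
        ("Gansu",   4.20, 4.31, 91.49, 19.06, 19.55, 415.09),
        ("Qinghai", 1.93, 1.82, 96.25, 13.86, 13.07, 691.34),
        ("Tibet",   1.01, 2.23, 96.76, 11.69, 25.82, 1120.17),
        ("Sichuan", 8.02, 7.85, 84.13, 38.71, 37.89, 406.12),
        ("Shaanxi", 0.12, 0.90, 98.98,  0.25,  1.89, 207.54),
        ("Other",   np.nan, np.nan, np.nan, 0.19, 4.5, np.nan),
    ],
    columns=["region", "pct_suitable", "pct_marginal", "pct_unsuitable",
             "area_suitable", "area_marginal", "area_unsuitable"],
)

#: published national totals (10^3 km^2): current / 2050s / 2070s suitable,
#: and current marginally suitable
REFERENCE_TOTALS = {
    "suitable_current": 83.76,
    "suitable_2050s": 69.53,
    "suitable_2070s": 60.21,
    "marginal_current": 102.72,
}


def cell_area_grid(ref: Grid) -> Grid:
    """Spherical area (km^2) of every cell of a lon/lat grid."""
    t = ref.transform
    d_lambda = np.radians(t.cell_size)
    rows = np.arange(ref.n_rows)
    lat_top = np.radians(t.north - rows * t.cell_size)
    lat_bot = np.radians(t.north - (rows + 1) * t.cell_size)
    row_area = EARTH_RADIUS_KM**2 * d_lambda * (np.sin(lat_top) - np.sin(lat_bot))
    values = np.repeat(row_area[:, None], ref.n_cols, axis=1)
    return Grid(values=values, transform=t, crs_label=ref.crs_label,
                nodata=ref.nodata)


def zonal_area_table(chs: Grid, zones: Grid, cell_areas: Grid) -> pd.DataFrame:
    """Per-zone, per-class areas (km^2) and percentages of the zone.

    Rows: one per (zone, class) plus a ``total`` zone aggregating all
    zones.  Percentages are of the zone's valid area; rounding happens only
    at serialization, not here.
    """
    for g, name in ((zones, "zones"), (cell_areas, "cell areas")):
        if g.shape != chs.shape or not g.transform.close_to(chs.transform):
            raise ValueError(f"{name} grid is not co-registered")
    valid = chs.valid_mask()
    z = zones.values
    cls = chs.values
    area = cell_areas.values
    rows = []
    zone_ids = sorted(int(v) for v in np.unique(z[valid]))
    classes = sorted(CLASS_NAMES)
    for zid in zone_ids + ["total"]:
        in_zone = valid if zid == "total" else (valid & (z == zid))
        zone_area = float(area[in_zone].sum())
        for c in classes:
            a = float(area[in_zone & (cls == c)].sum())
            rows.append({
                "zone": zid, "class_code": c, "class": CLASS_NAMES[c],
                "area_km2": a,
                "percent_of_zone": 100.0 * a / zone_area if zone_area else np.nan,
            })
    return pd.DataFrame(rows)


def transition_table(
    chs_a: Grid, chs_b: Grid, cell_areas: Grid
) -> pd.DataFrame:
    """3x3 area cross-tabulation class(period A) -> class(period B), km^2."""
    if chs_b.shape != chs_a.shape or not chs_b.transform.close_to(chs_a.transform):
        raise ValueError("period maps are not co-registered")
    valid = chs_a.valid_mask() & chs_b.valid_mask()
    classes = sorted(CLASS_NAMES)
    mat = np.zeros((len(classes), len(classes)))
    for i, ca in enumerate(classes):
        for j, cb in enumerate(classes):
            sel = valid & (chs_a.values == ca) & (chs_b.values == cb)
            mat[i, j] = float(cell_areas.values[sel].sum())
    names = [CLASS_NAMES[c] for c in classes]
    return pd.DataFrame(mat, index=pd.Index(names, name="from"),
                        columns=pd.Index(names, name="to"))


# ---------------------------------------------------------------------------
# ensemble predictor over tables (for curves and importance)

class EnsemblePredictor:
    """Weighted-sum predictor over the retained runs, on variable tables."""

    def __init__(self, retained_runs, weights):
        by_id = {r.run_id: r for r in retained_runs}
        self.runs = [by_id[rid] for rid in weights.run_ids]
        self.weights = weights
        self.variables = list(self.runs[0].model.variables)

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        out = np.zeros(len(table))
        for w, run in zip(self.weights.weights, self.runs):
            out += w * run.model.predict01(table)
        return np.clip(out, 0.0, 1.0)


@dataclass
class ResponseCurve:
    variable: str
    values: np.ndarray
    probability: np.ndarray
    cutoff: float

    @property
    def peak(self) -> float:
        return float(self.values[np.argmax(self.probability)])

    def suitable_ranges(self) -> list[tuple[float, float]]:
        """Maximal intervals of the evaluation strip where p > cutoff."""
        above = self.probability > self.cutoff
        ranges = []
        start = None
        for i, flag in enumerate(above):
            if flag and start is None:
                start = self.values[i]
            if not flag and start is not None:
                ranges.append((float(start), float(self.values[i - 1])))
                start = None
        if start is not None:
            ranges.append((float(start), float(self.values[-1])))
        return ranges

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"value": self.values, "probability": self.probability})


def response_curve(
    predictor: EnsemblePredictor,
    stack: GridStack,
    variable: str,
    n_points: int = 100,
    cutoff: float = 0.3,
) -> ResponseCurve:
    """Evaluation-strip response curve for one variable.

    The target variable sweeps its observed valid-cell range at
    ``n_points``; all other predictor variables are held at their medians
    over valid cells.
    """
    if variable not in stack:
        raise KeyError(f"{variable!r} not in stack")
    mask = stack.combined_mask(predictor.variables)
    table = stack.table(predictor.variables, mask=mask)
    col = table[variable]
    if float(col.max()) == float(col.min()):
        import warnings
        warnings.warn(f"variable {variable!r} is constant; empty curve")
        return ResponseCurve(variable, np.array([]), np.array([]), cutoff)
    grid_vals = np.linspace(col.min(), col.max(), n_points)
    strip = pd.DataFrame(
        {v: np.full(n_points, float(table[v].median()))
         for v in predictor.variables}
    )
    strip[variable] = grid_vals
    prob = predictor.predict(strip)
    return ResponseCurve(variable, grid_vals, prob, cutoff)


def variable_importance(
    predictor: EnsemblePredictor,
    stack: GridStack,
    n_shuffles: int = 3,
    seed: int = 0,
    max_cells: int = 2000,
) -> pd.Series:
    """Permutation importance, normalized to sum to 1.

    Per variable: shuffle its column over a sample of valid cells, predict,
    and take 1 - Pearson r against the intact predictions; average over
    shuffles.  A variable the ensemble ignores scores ~0.
    """
    rng = np.random.default_rng(seed)
    mask = stack.combined_mask(predictor.variables)
    table = stack.table(predictor.variables, mask=mask).reset_index(drop=True)
    if len(table) > max_cells:
        table = table.iloc[
            rng.choice(len(table), size=max_cells, replace=False)
        ].reset_index(drop=True)
    base = predictor.predict(table)
    scores = {}
    for var in predictor.variables:
        vals = []
        for _ in range(n_shuffles):
            shuffled = table.copy()
            shuffled[var] = rng.permutation(shuffled[var].to_numpy())
            pred = predictor.predict(shuffled)
            if np.std(pred) == 0 or np.std(base) == 0:
                r = 0.0
            else:
                r = float(np.corrcoef(base, pred)[0, 1])
            vals.append(1.0 - r)
        scores[var] = float(np.mean(vals))
    s = pd.Series(scores).clip(lower=0.0)
    total = s.sum()
    return s / total if total > 0 else s


# ---------------------------------------------------------------------------
# internal-consistency helpers over the published reference table

def reference_additivity(table: pd.DataFrame = REFERENCE_AREA_TABLE) -> dict:
    """Sum the per-region class areas (10^3 km^2) across all regions."""
    return {
        "suitable": float(table["area_suitable"].sum()),
        "marginal": float(table["area_marginal"].sum()),
    }


def recompute_percentages(table: pd.DataFrame = REFERENCE_AREA_TABLE) -> pd.DataFrame:
    """Re-derive each region's class percentages from its three areas."""
    t = table.dropna(subset=["area_unsuitable"]).copy()
    total = t["area_suitable"] + t["area_marginal"] + t["area_unsuitable"]
    for cls in ("suitable", "marginal", "unsuitable"):
        t[f"recomputed_pct_{cls}"] = 100.0 * t[f"area_{cls}"] / total
    return t
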