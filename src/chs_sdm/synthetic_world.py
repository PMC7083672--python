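"""Synthetic study system: environment, virtual species, scenarios, zones.

The generator emulates the structure of a montane study region: smooth
(spatially autocorrelated) climate surfaces with a latitudinal temperature
gradient and an elevational lapse rate, precipitation-like nonnegative
layers, topography (elevation plus Horn slope/aspect), categorical soil and
vegetation mosaics tied to elevation bands, a virtual species with a known
product-Gaussian climatic niche, occurrence points sampled in proportion to
true suitability, spatially uniform per-scenario climate deltas (several
emission pathways x several climate models, two future periods), and a zone
raster standing in for administrative regions.

Everything is deterministic given the spec seed.  Continuous fields are
Gaussian random fields built by smoothing white noise with a Gaussian
kernel of bandwidth ``autocorr_length`` cells and rescaling to unit
variance, which makes the autocorrelation length directly controllable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy import ndimage

from .grids import Grid, GridStack, GridTransform, OccurrenceSet

EARTH_RADIUS_KM = 6371.0

#: default vegetation classes the virtual species tolerates (mid/upper
#: elevation bands: analogue of alpine forest / shrubland / alpine meadow)
DEFAULT_SUITABLE_VEG = frozenset({4, 5, 6})


@dataclass(frozen=True)
class WorldSpec:
    """Geometry and categorical structure of the synthetic world."""

    n_rows: int = 100
    n_cols: int = 100
    west: float = 95.0
    north: float = 38.0
    cell_size: float = 0.1
    autocorr_length: float = 5.0
    n_soil_classes: int = 10
    n_veg_classes: int = 8
    suitable_veg_classes: frozenset = DEFAULT_SUITABLE_VEG
    seed: int = 0

    def __post_init__(self):
        if self.n_rows < 10 or self.n_cols < 10:
            raise ValueError("grid must be at least 10 cells per side")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_soil_classes < 2 or self.n_veg_classes < 2:
            raise ValueError("need at least 2 soil and 2 vegetation classes")
        sv = frozenset(self.suitable_veg_classes)
        if not 0 < len(sv) < self.n_veg_classes:
            raise ValueError(
                "suitable_veg_classes must be a nonempty proper subset of classes"
            )
        object.__setattr__(self, "suitable_veg_classes", sv)

    @property
    def transform(self) -> GridTransform:
        return GridTransform(self.west, self.north, self.cell_size)

    def to_yaml(self, path) -> None:
        d = {k: v for k, v in self.__dict__.items()}
        d["suitable_veg_classes"] = sorted(self.suitable_veg_classes)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path) -> "WorldSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["suitable_veg_classes"] = frozenset(d["suitable_veg_classes"])
        return cls(**d)


@dataclass(frozen=True)
class VirtualSpeciesSpec:
    """Known product-Gaussian niche of the virtual species.

    The defaults describe a cold-humid alpine herb: the niche is driven by
    the temperature variables (narrow widths relative to their landscape
    spread) with only a weak, broad dependence on annual precipitation, so
    temperature carries more of the true signal than precipitation.
    """

    response_means: dict = field(
        default_factory=lambda: {"bio1": 5.0, "bio10": 13.0, "bio11": -4.0,
                                 "bio12": 800.0}
    )
    response_widths: dict = field(
        default_factory=lambda: {"bio1": 1.4, "bio10": 1.8, "bio11": 2.0,
                                 "bio12": 260.0}
    )
    n_presences: int = 99
    prevalence_scale: float = 1.0

    def __post_init__(self):
        if set(self.response_means) != set(self.response_widths):
            raise ValueError("response means and widths must cover the same variables")
        if any(w <= 0 for w in self.response_widths.values()):
            raise ValueError("response widths must be positive")
        if self.n_presences < 20:
            raise ValueError("need at least 20 presences")
        if not 0 < self.prevalence_scale <= 1:
            raise ValueError("prevalence_scale must be in (0, 1]")


@dataclass(frozen=True)
class ScenarioDelta:
    """Spatially uniform climate shift for one (GCM, RCP, period) triple."""

    gcm_id: str
    rcp_id: str
    period: str = "future"
    additive_shift: dict = field(default_factory=dict)
    multiplicative_shift: dict = field(default_factory=dict)

    def __post_init__(self):
        if any(f <= 0 for f in self.multiplicative_shift.values()):
            raise ValueError("multiplicative shifts must be positive")


# ---------------------------------------------------------------------------
# continuous environment

def _grf(shape, rng, autocorr_length):
    """Unit-variance Gaussian random field by Gaussian smoothing of noise."""
    noise = rng.standard_normal(shape)
    if autocorr_length <= 0:
        return noise
    sm = ndimage.gaussian_filter(noise, sigma=autocorr_length, mode="reflect")
    return sm / sm.std()


def horn_slope_aspect(elevation: Grid) -> tuple[Grid, Grid]:
    """Slope (degrees) and aspect (degrees, [0, 360)) by Horn's method.

    Horn's eight-neighbour finite differences on a 3x3 window; edge cells
    use replicated borders.  Cell size is converted from degrees to metres
    with the cosine of each row's latitude for the east-west spacing.
    Flat cells get the aspect sentinel -1.
    """
    z = np.pad(elevation.masked(), 1, mode="edge")
    a = z[:-2, :-2]; b = z[:-2, 1:-1]; c = z[:-2, 2:]
    d = z[1:-1, :-2]; f = z[1:-1, 2:]
    g = z[2:, :-2]; h = z[2:, 1:-1]; i = z[2:, 2:]

    t = elevation.transform
    rows = np.arange(elevation.n_rows)
    _, lat = t.cell_center(rows, np.zeros_like(rows))
    m_per_deg = EARTH_RADIUS_KM * 1000.0 * np.pi / 180.0
    dy = t.cell_size * m_per_deg
    dx = t.cell_size * m_per_deg * np.cos(np.radians(lat))[:, None]

    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * dx)
    dzdy = ((g + 2 * h + i) - (a + 2 * b + c)) / (8 * dy)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))

    # downslope azimuth: 0 = north, clockwise; dzdy is the array-southward
    # derivative, so the downslope vector is (-dzdx east, +dzdy north)
    aspect = np.degrees(np.arctan2(-dzdx, dzdy)) % 360.0
    flat = np.hypot(dzdx, dzdy) == 0
    aspect[flat] = -1.0

    nodata = ~elevation.valid_mask() | np.isnan(slope)
    slope = np.where(nodata, elevation.nodata, slope)
    aspect = np.where(nodata, elevation.nodata, aspect)
    return elevation.like(slope), elevation.like(aspect)


def generate_environment(spec: WorldSpec) -> GridStack:
    """Generate the continuous environmental layers.

    Layers: seven temperature/precipitation summaries used downstream
    (bio1, bio4, bio10, bio11, bio12, bio15, bio19), two deliberately
    collinear extras (bio5 ~ bio10, bio13 ~ bio12) so the collinearity
    screen has something to remove, elevation, and Horn slope/aspect.
    """
    rng = np.random.default_rng(spec.seed)
    shape = (spec.n_rows, spec.n_cols)
    t = spec.transform

    rows, cols = np.meshgrid(
        np.arange(spec.n_rows), np.arange(spec.n_cols), indexing="ij"
    )
    _, lat = t.cell_center(rows, cols)
    dlat = lat - (t.north - spec.n_rows * spec.cell_size)  # degrees above south edge

    L = spec.autocorr_length
    elev = 3000.0 + 1100.0 * _grf(shape, rng, L)
    elev = np.clip(elev, 200.0, None)

    # annual mean temperature: latitudinal gradient + elevational lapse + noise
    bio1 = (
        18.0 - 0.45 * dlat - 0.0055 * (elev - 1000.0) + 1.2 * _grf(shape, rng, L)
    )
    bio10 = bio1 + 8.5 + 0.8 * _grf(shape, rng, L)   # warmest-quarter mean
    bio11 = bio1 - 9.5 + 0.9 * _grf(shape, rng, L)   # coldest-quarter mean
    bio5 = bio10 + 4.0 + 0.5 * _grf(shape, rng, L)   # collinear with bio10
    bio4 = 6.5 + 0.12 * dlat + 0.5 * _grf(shape, rng, L)  # seasonality (deg C sd)

    bio12 = (
        750.0 + 22.0 * dlat + 0.04 * (elev - 3000.0) + 180.0 * _grf(shape, rng, L)
    )
    bio12 = np.clip(bio12, 30.0, None)
    bio13 = np.clip(0.22 * bio12 + 15.0 * _grf(shape, rng, L), 5.0, None)
    bio15 = 84.0 + 7.0 * _grf(shape, rng, L)
    bio19 = np.clip(45.0 + 0.04 * bio12 + 10.0 * _grf(shape, rng, L), 0.0, None)

    def mk(v):
        return Grid(values=v, transform=t)

    stack = GridStack({
        "bio1": mk(bio1), "bio4": mk(bio4), "bio5": mk(bio5),
        "bio10": mk(bio10), "bio11": mk(bio11), "bio12": mk(bio12),
        "bio13": mk(bio13), "bio15": mk(bio15), "bio19": mk(bio19),
        "elevation": mk(elev),
    })
    slope, aspect = horn_slope_aspect(stack["elevation"])
    stack.add("slope", slope)
    stack.add("aspect", aspect)
    return stack


def generate_categorical_layers(
    spec: WorldSpec, elevation: Grid, veg_noise: float = 0.45
) -> tuple[Grid, Grid]:
    """Integer-coded soil and vegetation mosaics (codes 1..K).

    Vegetation classes follow elevation bands (quantile bins of elevation
    plus a smooth perturbation), so the species' suitable vegetation is
    spatially coherent and static under climate scenarios.  Soil classes
    follow an independent smooth field with a weaker elevation pull.
    """
    if elevation.shape != (spec.n_rows, spec.n_cols):
        raise ValueError("elevation not co-registered with spec grid")
    rng = np.random.default_rng(spec.seed + 1)
    z = elevation.masked()
    zz = (z - np.nanmean(z)) / np.nanstd(z)

    veg_score = zz + veg_noise * _grf(z.shape, rng, spec.autocorr_length)
    soil_score = 0.9 * zz + 0.55 * _grf(z.shape, rng, spec.autocorr_length)

    def bin_classes(score, k):
        edges = np.nanquantile(score, np.linspace(0, 1, k + 1)[1:-1])
        classes = np.digitize(score, edges) + 1  # 1..k
        out = np.where(elevation.valid_mask(), classes, int(elevation.nodata))
        return elevation.like(out.astype(float))

    veg = bin_classes(veg_score, spec.n_veg_classes)
    soil = bin_classes(soil_score, spec.n_soil_classes)
    return soil, veg


# ---------------------------------------------------------------------------
# virtual species

def true_suitability(env: GridStack, vs: VirtualSpeciesSpec) -> Grid:
    """Ground-truth suitability: product of per-variable Gaussian responses.

    ``prod_v exp(-(x_v - mu_v)^2 / (2 sigma_v^2))`` in [0, 1]; NoData in any
    niche variable propagates.
    """
    missing = [v for v in vs.response_means if v not in env]
    if missing:
        raise KeyError(f"niche variables missing from stack: {missing}")
    suit = np.ones(env.shape)
    mask = env.combined_mask(list(vs.response_means))
    for var, mu in vs.response_means.items():
        sigma = vs.response_widths[var]
        x = env[var].masked()
        suit *= np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))
    ref = env[next(iter(vs.response_means))]
    out = np.where(mask, suit, ref.nodata)
    return ref.like(out)


def sample_occurrences(
    suit: Grid, vs: VirtualSpeciesSpec, seed: int
) -> OccurrenceSet:
    """Sample distinct presence cells with probability ~ suitability.

    Cells are drawn without replacement (no duplicate coordinates, mirroring
    occurrence cleaning) with weights ``suitability * prevalence_scale``;
    cell centers are returned.
    """
    rng = np.random.default_rng(seed)
    mask = suit.valid_mask()
    vals = suit.values
    if mask.any() and (vals[mask].min() < -1e-9 or vals[mask].max() > 1 + 1e-9):
        raise ValueError("suitability must lie in [0, 1]")
    rows, cols = np.nonzero(mask)
    w = np.clip(vals[rows, cols].astype(float), 0, 1) * vs.prevalence_scale
    eligible = w > 0
    if eligible.sum() < vs.n_presences:
        raise ValueError(
            f"only {int(eligible.sum())} cells with positive suitability; "
            f"cannot place {vs.n_presences} presences"
        )
    p = w / w.sum()
    pick = rng.choice(len(rows), size=vs.n_presences, replace=False, p=p)
    lon, lat = suit.transform.cell_center(rows[pick], cols[pick])
    return OccurrenceSet(
        lon=lon, lat=lat, source_tag="virtual-species",
        true_suitability=vals[rows[pick], cols[pick]].astype(float),
    )


# ---------------------------------------------------------------------------
# scenarios

def generate_future_stack(env: GridStack, delta: ScenarioDelta) -> GridStack:
    """Apply a scenario delta: shifted/scaled climate, static everything else.

    Soil, vegetation and topography are never touched (their change lags
    climate on these horizons), so layers without an entry in the delta are
    carried over unchanged (same array object semantics as a copy).
    """
    for name in list(delta.additive_shift) + list(delta.multiplicative_shift):
        if name not in env:
            raise KeyError(f"delta names unknown layer {name!r}")
    out = {}
    for name in env.names:
        g = env[name]
        if name in delta.additive_shift or name in delta.multiplicative_shift:
            vals = g.values.astype(float).copy()
            valid = g.valid_mask()
            vals[valid] *= delta.multiplicative_shift.get(name, 1.0)
            vals[valid] += delta.additive_shift.get(name, 0.0)
            out[name] = g.like(vals)
        else:
            out[name] = g.copy()
    return GridStack(out)


#: CMIP5-flavoured warming (deg C) by period and radiative-forcing pathway
WARMING_TABLE = {
    ("2050s", "RCP2.6"): 1.0, ("2050s", "RCP4.5"): 1.5,
    ("2050s", "RCP6.0"): 1.8, ("2050s", "RCP8.5"): 2.4,
    ("2070s", "RCP2.6"): 1.1, ("2070s", "RCP4.5"): 1.9,
    ("2070s", "RCP6.0"): 2.4, ("2070s", "RCP8.5"): 3.6,
}

#: per-model spread around the pathway mean (deg C)
GCM_OFFSETS = {"BCC-CSM1-1": -0.25, "CCSM4": 0.0, "MIROC5": 0.3}

TEMPERATURE_LAYERS = ("bio1", "bio5", "bio10", "bio11")
PRECIPITATION_LAYERS = ("bio12", "bio13", "bio19")


def default_scenarios(
    periods=("2050s", "2070s"),
    rcps=("RCP2.6", "RCP4.5", "RCP6.0", "RCP8.5"),
    gcms=("BCC-CSM1-1", "CCSM4", "MIROC5"),
) -> list[ScenarioDelta]:
    """The default scenario grid: warming plus a modest wetting trend.

    Temperature layers shift additively by the pathway warming plus a
    per-model offset; seasonality rises slightly with warming;
    precipitation layers scale up by 2.5 % per degree (high-altitude
    wetting).  One delta per (period, pathway, model).
    """
    deltas = []
    for period in periods:
        for rcp in rcps:
            base = WARMING_TABLE[(period, rcp)]
            for gcm in gcms:
                warm = base + GCM_OFFSETS[gcm]
                add = {v: warm for v in TEMPERATURE_LAYERS}
                add["bio4"] = 0.15 * warm
                mult = {v: 1.0 + 0.025 * warm for v in PRECIPITATION_LAYERS}
                deltas.append(ScenarioDelta(
                    gcm_id=gcm, rcp_id=rcp, period=period,
                    additive_shift=add, multiplicative_shift=mult,
                ))
    return deltas


# ---------------------------------------------------------------------------
# zones

def generate_zones(spec: WorldSpec, n_zones: int) -> Grid:
    """Partition the grid into contiguous rectangular zones (codes 1..n).

    The zone layout is the factor pair of ``n_zones`` closest to square:
    rows are split into bands and columns into strips with
    ``numpy.array_split`` semantics, so a 2x2 layout on an even grid gives
    equal-count quadrants.
    """
    n_cells = spec.n_rows * spec.n_cols
    if n_zones < 1:
        raise ValueError("n_zones must be >= 1")
    if n_zones > n_cells:
        raise ValueError("more zones than cells")
    best = (1, n_zones)
    for r in range(1, int(np.sqrt(n_zones)) + 1):
        if n_zones % r == 0:
            best = (r, n_zones // r)
    r_bands, c_strips = best
    if spec.n_rows < spec.n_cols:
        r_bands, c_strips = min(best), max(best)
    else:
        r_bands, c_strips = max(best), min(best)

    zone = np.zeros((spec.n_rows, spec.n_cols), dtype=float)
    row_edges = np.array_split(np.arange(spec.n_rows), r_bands)
    col_edges = np.array_split(np.arange(spec.n_cols), c_strips)
    code = 1
    for rband in row_edges:
        for cstrip in col_edges:
            zone[np.ix_(rband, cstrip)] = code
            code += 1
    return Grid(values=zone, transform=spec.transform, nodata=-9999.0)


def generate_world(
    spec: WorldSpec, vs: VirtualSpeciesSpec | None = None, n_zones: int = 6
):
    """Convenience: environment + categoricals + truth + occurrences + zones.

    Returns ``(stack, truth, occurrences, zones)`` where the stack includes
    the categorical ``soil`` and ``vegetation`` layers.
    """
    vs = vs or VirtualSpeciesSpec()
    stack = generate_environment(spec)
    soil, veg = generate_categorical_layers(spec, stack["elevation"])
    stack.add("soil", soil)
    stack.add("vegetation", veg)
    truth = true_suitability(stack, vs)
    occ = sample_occurrences(truth, vs, seed=spec.seed + 2)
    zones = generate_zones(spec, n_zones)
    return stack, truth, occ, zones
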