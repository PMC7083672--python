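import numpy as np
import pandas as pd
import pytest

from chs_sdm.grids import GridStack
from chs_sdm.habitat import MARGINAL, SUITABLE, UNSUITABLE
from chs_sdm.reporting import (cell_area_grid, response_curve,
                               transition_table, variable_importance,
                               zonal_area_table)
from tests.conftest import make_grid

R = 6371.0


class StubPredictor:
    """Duck-typed ensemble predictor driven by a plain function."""

    def __init__(self, variables, fn):
        self.variables = list(variables)
        self.fn = fn

    def predict(self, table):
        return np.clip(self.fn(table), 0, 1)


class TestCellArea:
    def test_equatorial_30_arcsec_cell_matches_integration_oracle(self):
        cell = 1 / 120  # 30 arc-seconds in degrees
        g = make_grid(np.zeros((2, 2)), west=0.0, north=cell, cell=cell)
        area = cell_area_grid(g)
        # Riemann-sum oracle of R^2 cos(phi) dphi dlambda over the cell
        phis = np.linspace(0, np.radians(cell), 20001)
        oracle = R**2 * np.radians(cell) * np.trapezoid(np.cos(phis), phis)
        assert area.values[0, 0] == pytest.approx(oracle, rel=1e-9)
        assert area.values[0, 0] == pytest.approx(0.86, abs=0.01)

    def test_rows_shrink_poleward(self):
        g = make_grid(np.zeros((10, 10)), west=0.0, north=60.0, cell=0.5)
        area = cell_area_grid(g)
        assert np.all(np.diff(area.values[:, 0]) > 0)  # toward equator

    def test_total_area_is_additive_over_any_partition(self, small_world):
        zones = small_world["zones"]
        area = cell_area_grid(zones)
        total = area.values.sum()
        by_zone = sum(area.values[zones.values == z].sum()
                      for z in np.unique(zones.values))
        assert by_zone == pytest.approx(total, rel=1e-12)


def random_chs(shape, seed, nodata_frac=0.0):
    rng = np.random.default_rng(seed)
    vals = rng.choice([UNSUITABLE, MARGINAL, SUITABLE], size=shape).astype(float)
    g = make_grid(vals, nodata=-1.0)
    if nodata_frac:
        mask = rng.random(shape) < nodata_frac
        g.values[mask] = -1.0
    return g


class TestZonalAreas:
    def test_single_zone_all_suitable(self):
        chs = make_grid(np.full((10, 10), float(SUITABLE)), nodata=-1.0)
        zones = make_grid(np.ones((10, 10)))
        areas = make_grid(np.ones((10, 10)))
        t = zonal_area_table(chs, zones, areas)
        row = t[(t.zone == 1) & (t["class"] == "suitable")]
        assert row["area_km2"].iloc[0] == pytest.approx(100.0)
        assert row["percent_of_zone"].iloc[0] == pytest.approx(100.0)

    def test_two_symmetric_zones_split_fifty_fifty(self):
        vals = np.zeros((10, 10))
        vals[:, ::2] = SUITABLE  # alternating columns
        chs = make_grid(vals, nodata=-1.0)
        zones = make_grid(np.r_[np.ones((5, 10)), np.full((5, 10), 2.0)])
        t = zonal_area_table(chs, zones, make_grid(np.ones((10, 10))))
        for z in (1, 2):
            for cls in ("suitable", "unsuitable"):
                row = t[(t.zone == z) & (t["class"] == cls)]
                assert row["percent_of_zone"].iloc[0] == pytest.approx(50.0)

    def test_matches_per_cell_tally_on_random_raster(self):
        chs = random_chs((20, 20), seed=1, nodata_frac=0.1)
        zones = make_grid(np.where(np.arange(400).reshape(20, 20) < 200, 1.0, 2.0))
        areas = cell_area_grid(chs)
        t = zonal_area_table(chs, zones, areas)
        for z in (1, 2):
            for code, cls in ((0, "unsuitable"), (1, "marginally suitable"),
                              (2, "suitable")):
                oracle = sum(
                    areas.values[r, c]
                    for r in range(20) for c in range(20)
                    if chs.values[r, c] == code and zones.values[r, c] == z)
                row = t[(t.zone == z) & (t["class"] == cls)]
                assert row["area_km2"].iloc[0] == pytest.approx(oracle)

    def test_percentages_sum_to_100_and_classes_to_zone_area(self):
        chs = random_chs((15, 15), seed=2, nodata_frac=0.2)
        zones = make_grid(np.ones((15, 15)))
        t = zonal_area_table(chs, zones, cell_area_grid(chs))
        for z in t.zone.unique():
            sub = t[t.zone == z]
            assert sub["percent_of_zone"].sum() == pytest.approx(100.0)


class TestTransitions:
    def test_identical_maps_are_diagonal(self):
        chs = random_chs((12, 12), seed=3)
        areas = make_grid(np.ones((12, 12)))
        m = transition_table(chs, chs, areas).to_numpy()
        assert np.all(m[~np.eye(3, dtype=bool)] == 0)

    def test_total_flip_lands_in_single_cell(self):
        a = make_grid(np.full((8, 8), float(SUITABLE)), nodata=-1.0)
        b = make_grid(np.full((8, 8), float(UNSUITABLE)), nodata=-1.0)
        m = transition_table(a, b, make_grid(np.ones((8, 8))))
        assert m.loc["suitable", "unsuitable"] == pytest.approx(64.0)
        assert m.to_numpy().sum() == pytest.approx(64.0)

    def test_marginals_reproduce_area_reports_exactly(self):
        a = random_chs((20, 20), seed=4, nodata_frac=0.05)
        b = random_chs((20, 20), seed=5, nodata_frac=0.05)
        areas = cell_area_grid(a)
        m = transition_table(a, b, areas)
        zones = make_grid(np.ones((20, 20)))
        valid_both = (a.values != -1) & (b.values != -1)
        for cls_idx, cls in enumerate(("unsuitable", "marginally suitable",
                                       "suitable")):
            oracle_a = areas.values[valid_both & (a.values == cls_idx)].sum()
            oracle_b = areas.values[valid_both & (b.values == cls_idx)].sum()
            assert m.loc[cls].sum() == pytest.approx(oracle_a, rel=1e-12)
            assert m[cls].sum() == pytest.approx(oracle_b, rel=1e-12)

    def test_geometry_mismatch_rejected(self):
        a = random_chs((10, 10), seed=6)
        b = random_chs((11, 10), seed=7)
        with pytest.raises(ValueError, match="co-registered"):
            transition_table(a, b, make_grid(np.ones((10, 10))))


class TestResponseCurves:
    def _stack(self, seed=0):
        rng = np.random.default_rng(seed)
        return GridStack({
            "t": make_grid(rng.uniform(-5, 5, (30, 30))),
            "p": make_grid(rng.uniform(0, 100, (30, 30))),
        })

    def test_predictor_ignoring_variable_gives_flat_curve(self):
        pred = StubPredictor(["t", "p"], lambda d: 0.6 * np.ones(len(d)))
        rc = response_curve(pred, self._stack(), "p")
        assert np.ptp(rc.probability) == 0.0
        assert rc.suitable_ranges() == [(pytest.approx(rc.values[0]),
                                         pytest.approx(rc.values[-1]))]

    def test_gaussian_response_peak_and_range_recovered(self):
        pred = StubPredictor(
            ["t", "p"], lambda d: np.exp(-(d["t"].to_numpy() - 1.0)**2 / 2))
        rc = response_curve(pred, self._stack(), "t", n_points=200)
        assert rc.peak == pytest.approx(1.0, abs=0.1)
        (lo, hi), = rc.suitable_ranges()
        # p > 0.3 for |t - 1| < sqrt(-2 ln 0.3) = 1.552
        assert lo == pytest.approx(1.0 - 1.552, abs=0.1)
        assert hi == pytest.approx(1.0 + 1.552, abs=0.1)

    def test_probabilities_bounded(self):
        pred = StubPredictor(["t", "p"],
                             lambda d: 2.0 * np.abs(np.sin(d["t"])))
        rc = response_curve(pred, self._stack(), "t")
        assert rc.probability.min() >= 0 and rc.probability.max() <= 1

    def test_constant_variable_warns_with_empty_curve(self):
        stack = GridStack({"t": make_grid(np.full((10, 10), 3.0)),
                           "p": make_grid(np.arange(100.0).reshape(10, 10))})
        pred = StubPredictor(["t", "p"], lambda d: np.ones(len(d)))
        with pytest.warns(UserWarning, match="constant"):
            rc = response_curve(pred, stack, "t")
        assert len(rc.values) == 0


class TestVariableImportance:
    def _stack(self, seed=1):
        rng = np.random.default_rng(seed)
        return GridStack({
            "used": make_grid(rng.standard_normal((25, 25))),
            "unused": make_grid(rng.standard_normal((25, 25))),
        })

    def test_irrelevant_variable_scores_near_zero(self):
        pred = StubPredictor(["used", "unused"],
                             lambda d: 1 / (1 + np.exp(-d["used"].to_numpy())))
        imp = variable_importance(pred, self._stack(), n_shuffles=3, seed=0)
        assert imp["unused"] < 0.02

    def test_single_variable_predictor_takes_all_importance(self):
        pred = StubPredictor(["used", "unused"],
                             lambda d: np.tanh(d["used"].to_numpy()) * 0.5 + 0.5)
        imp = variable_importance(pred, self._stack(), n_shuffles=3, seed=0)
        assert imp["used"] == pytest.approx(1.0, abs=0.02)

    def test_scores_sum_to_one(self):
        pred = StubPredictor(
            ["used", "unused"],
            lambda d: 0.5 + 0.2 * np.tanh(d["used"].to_numpy())
            + 0.1 * np.tanh(d["unused"].to_numpy()))
        imp = variable_importance(pred, self._stack(), n_shuffles=2, seed=1)
        assert imp.sum() == pytest.approx(1.0)
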