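import numpy as np
import pytest

from chs_sdm.grids import Grid, GridTransform
from chs_sdm.synthetic_world import (ScenarioDelta, VirtualSpeciesSpec,
                                     WorldSpec, default_scenarios,
                                     generate_categorical_layers,
                                     generate_environment,
                                     generate_future_stack, generate_world,
                                     generate_zones, horn_slope_aspect,
                                     sample_occurrences, true_suitability)
from tests.conftest import make_grid


def morans_i(values):
    """Brute-force lag-1 (rook) Moran's I."""
    z = values - values.mean()
    num = den = w_sum = 0.0
    nr, nc = z.shape
    for r in range(nr):
        for c in range(nc):
            for dr, dc in ((0, 1), (1, 0)):
                rr, cc = r + dr, c + dc
                if rr < nr and cc < nc:
                    num += 2 * z[r, c] * z[rr, cc]
                    w_sum += 2
    den = (z**2).sum()
    n = z.size
    return (n / w_sum) * (num / den)


class TestEnvironmentGenerator:
    def test_deterministic_given_seed(self, small_spec):
        s1 = generate_environment(small_spec)
        s2 = generate_environment(small_spec)
        for name in s1.names:
            np.testing.assert_array_equal(s1[name].values, s2[name].values)

    def test_layer_inventory(self, small_world):
        stack = small_world["stack"]
        continuous = [n for n in stack.names
                      if n not in ("soil", "vegetation", "slope", "aspect")]
        assert len(continuous) >= 9
        assert {"slope", "aspect", "elevation"} <= set(stack.names)
        assert np.all(stack["bio12"].masked() >= 0)  # precipitation-like

    def test_zero_autocorrelation_gives_white_noise(self):
        spec = WorldSpec(n_rows=40, n_cols=40, autocorr_length=0.0, seed=3)
        stack = generate_environment(spec)
        resid = stack["elevation"].values - stack["elevation"].values.mean()
        assert abs(morans_i(resid)) < 0.06

    def test_default_autocorrelation_is_strong(self, small_world):
        elev = small_world["stack"]["elevation"].values
        assert morans_i(elev) > 0.5

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            WorldSpec(n_rows=5, n_cols=50)


class TestSlopeAspect:
    def test_flat_elevation_gives_zero_slope_and_sentinel_aspect(self):
        flat = make_grid(np.full((12, 12), 1000.0))
        slope, aspect = horn_slope_aspect(flat)
        np.testing.assert_array_equal(slope.values, 0.0)
        np.testing.assert_array_equal(aspect.values, -1.0)

    def test_aspect_range(self, small_world):
        a = small_world["stack"]["aspect"].masked()
        a = a[a >= 0]
        assert a.min() >= 0.0 and a.max() < 360.0

    def test_north_facing_ramp(self):
        # elevation increasing southward -> downslope faces north (aspect 0)
        vals = np.arange(12)[:, None] * np.ones((1, 12)) * 100.0
        slope, aspect = horn_slope_aspect(make_grid(vals))
        assert np.allclose(aspect.values[5, 5], 0.0)
        assert slope.values[5, 5] > 0


class TestCategoricalLayers:
    def test_soil_codomain(self, small_spec, small_world):
        soil = small_world["stack"]["soil"]
        codes = np.unique(soil.values[soil.valid_mask()]).astype(int)
        assert set(codes) <= set(range(1, small_spec.n_soil_classes + 1))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            WorldSpec(n_veg_classes=1, suitable_veg_classes=frozenset())

    def test_suitable_subset_must_be_proper(self):
        with pytest.raises(ValueError, match="proper subset"):
            WorldSpec(n_veg_classes=3, suitable_veg_classes=frozenset({1, 2, 3}))

    def test_monotone_ramp_bins_at_terciles(self):
        spec = WorldSpec(n_rows=30, n_cols=30, n_veg_classes=3,
                         suitable_veg_classes=frozenset({2}), seed=1)
        ramp = make_grid(np.linspace(0, 3000, 900).reshape(30, 30))
        _, veg = generate_categorical_layers(spec, ramp, veg_noise=0.0)
        z = ramp.values
        edges = np.quantile((z - z.mean()) / z.std(), [1 / 3, 2 / 3])
        oracle = np.digitize((z - z.mean()) / z.std(), edges) + 1
        np.testing.assert_array_equal(veg.values, oracle)


class TestTrueSuitability:
    def test_peak_is_one_at_niche_optimum(self):
        vs = VirtualSpeciesSpec(response_means={"x": 2.0},
                                response_widths={"x": 1.0})
        from chs_sdm.grids import GridStack
        g = make_grid(np.full((10, 10), 2.0))
        suit = true_suitability(GridStack({"x": g}), vs)
        np.testing.assert_allclose(suit.values, 1.0)

    def test_one_sigma_offset_gives_exp_minus_half(self):
        vs = VirtualSpeciesSpec(response_means={"x": 0.0},
                                response_widths={"x": 2.5})
        from chs_sdm.grids import GridStack
        g = make_grid(np.full((10, 10), 2.5))
        suit = true_suitability(GridStack({"x": g}), vs)
        np.testing.assert_allclose(suit.values, np.exp(-0.5))

    def test_two_variables_multiply(self):
        from chs_sdm.grids import GridStack
        rng = np.random.default_rng(0)
        gx = make_grid(rng.uniform(-3, 3, (8, 8)))
        gy = make_grid(rng.uniform(-3, 3, (8, 8)))
        stack = GridStack({"x": gx, "y": gy})
        both = true_suitability(stack, VirtualSpeciesSpec(
            response_means={"x": 0.0, "y": 1.0},
            response_widths={"x": 1.0, "y": 2.0}))
        only_x = true_suitability(stack, VirtualSpeciesSpec(
            response_means={"x": 0.0}, response_widths={"x": 1.0}))
        only_y = true_suitability(stack, VirtualSpeciesSpec(
            response_means={"y": 1.0}, response_widths={"y": 2.0}))
        np.testing.assert_allclose(both.values, only_x.values * only_y.values)

    def test_bounded_and_nodata_propagates(self, small_world):
        suit = small_world["truth"]
        vals = suit.values[suit.valid_mask()]
        assert vals.min() >= 0 and vals.max() <= 1
        g = small_world["stack"]["bio1"].copy()
        g.values[0, 0] = g.nodata
        from chs_sdm.grids import GridStack
        stack2 = GridStack({"bio1": g})
        vs = VirtualSpeciesSpec(response_means={"bio1": 5.0},
                                response_widths={"bio1": 1.4})
        out = true_suitability(stack2, vs)
        assert not out.valid_mask()[0, 0]

    def test_missing_variable_is_error(self, small_world):
        vs = VirtualSpeciesSpec(response_means={"nope": 0.0},
                                response_widths={"nope": 1.0})
        with pytest.raises(KeyError, match="nope"):
            true_suitability(small_world["stack"], vs)


class TestOccurrenceSampling:
    def test_forced_cells_are_returned(self):
        vals = np.zeros((10, 10))
        vals[0, :10] = 0.0
        vals[3, 2:7] = 1.0
        vals[6, 0:10] = 1.0
        vals[8, 1:6] = 1.0
        suit = make_grid(vals)
        vs = VirtualSpeciesSpec(n_presences=20)
        occ = sample_occurrences(suit, vs, seed=0)
        rows, cols = suit.transform.cell_of(occ.lon, occ.lat)
        assert np.all(vals[rows, cols] == 1.0)
        assert len(set(zip(rows.tolist(), cols.tolist()))) == 20

    def test_default_config_yields_99_unique_points(self, small_world):
        vs = VirtualSpeciesSpec()
        assert vs.n_presences == 99
        occ = sample_occurrences(small_world["truth"], vs, seed=11)
        assert len(occ) == 99
        assert len({(x, y) for x, y in zip(occ.lon, occ.lat)}) == 99

    def test_presences_enriched_in_suitability(self, small_world):
        truth = small_world["truth"]
        vs = VirtualSpeciesSpec(n_presences=200)
        occ = sample_occurrences(truth, vs, seed=5)
        grid_mean = truth.values[truth.valid_mask()].mean()
        assert occ.true_suitability.mean() > grid_mean

    def test_too_few_eligible_cells_is_error(self):
        vals = np.zeros((10, 10))
        vals[0, 0] = 1.0
        with pytest.raises(ValueError, match="cannot place"):
            sample_occurrences(make_grid(vals), VirtualSpeciesSpec(), seed=0)


class TestScenarios:
    def test_identity_delta_changes_nothing(self, small_world):
        delta = ScenarioDelta("g", "r", additive_shift={"bio1": 0.0},
                              multiplicative_shift={"bio12": 1.0})
        fut = generate_future_stack(small_world["stack"], delta)
        for name in small_world["stack"].names:
            np.testing.assert_array_equal(
                fut[name].values, small_world["stack"][name].values)

    def test_additive_shift_is_exact(self, small_world):
        delta = ScenarioDelta("g", "r", additive_shift={"bio1": 2.0})
        fut = generate_future_stack(small_world["stack"], delta)
        diff = fut["bio1"].values - small_world["stack"]["bio1"].values
        np.testing.assert_allclose(
            diff[small_world["stack"]["bio1"].valid_mask()], 2.0)

    def test_topography_and_categoricals_static(self, small_world):
        delta = default_scenarios(periods=("2050s",))[0]
        fut = generate_future_stack(small_world["stack"], delta)
        for name in ("elevation", "slope", "aspect", "soil", "vegetation"):
            assert (fut[name].values.tobytes()
                    == small_world["stack"][name].values.tobytes())

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            ScenarioDelta("g", "r", multiplicative_shift={"bio12": 0.0})

    def test_default_grid_is_24_deltas(self):
        assert len(default_scenarios()) == 2 * 4 * 3


class TestZones:
    def test_single_zone_covers_everything(self, small_spec):
        z = generate_zones(small_spec, 1)
        np.testing.assert_array_equal(z.values, 1.0)

    def test_four_zones_on_even_grid_are_equal_quadrants(self, small_spec):
        z = generate_zones(small_spec, 4)
        codes, counts = np.unique(z.values, return_counts=True)
        assert len(codes) == 4
        assert np.all(counts == small_spec.n_rows * small_spec.n_cols // 4)
        assert z.values[0, 0] != z.values[0, -1] != z.values[-1, -1]

    def test_partition_is_exhaustive(self, small_spec):
        z = generate_zones(small_spec, 5)
        _, counts = np.unique(z.values, return_counts=True)
        assert counts.sum() == small_spec.n_rows * small_spec.n_cols

    def test_more_zones_than_cells_rejected(self, small_spec):
        with pytest.raises(ValueError, match="more zones"):
            generate_zones(small_spec, 10**6)


def test_world_generation_is_deterministic(small_spec):
    vs = VirtualSpeciesSpec(n_presences=30)
    a = generate_world(small_spec, vs)
    b = generate_world(small_spec, vs)
    for name in a[0].names:
        np.testing.assert_array_equal(a[0][name].values, b[0][name].values)
    np.testing.assert_array_equal(a[2].lon, b[2].lon)
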