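"""Covariate derivation, compositing, extraction and filtering."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point, box

from movesdm.env_matching import (CovariateSpec, ConfigurationError,
                                  MissingLayerError, build_prediction_grid,
                                  collinearity_filter, compute_distance_to,
                                  compute_rugosity, extract_covariates,
                                  geomorph_overlay, temporal_composite)
from movesdm.io_formats import EnvLayer, GridSpec

from conftest import flat_layer


def daily_layers(values, start="2022-05-01", nrow=6, ncol=6, name="sst"):
    gs = GridSpec(west=110.0, north=-20.0, dlon=0.5, dlat=0.5,
                  nrow=nrow, ncol=ncol)
    out = []
    for i, v in enumerate(values):
        day = pd.Timestamp(start) + pd.Timedelta(days=i)
        grid = np.full((nrow, ncol), float(v)) if np.isscalar(v) else np.asarray(v, float)
        out.append(EnvLayer(name, grid, gs,
                            time_window=(day, day + pd.Timedelta(days=1))))
    return out


class TestRugosity:
    def test_flat_seafloor_is_zero(self):
        assert (compute_rugosity(flat_layer(500.0)).grid == 0).all()

    def test_step_confined_to_window(self):
        layer = flat_layer(0.0, nrow=5, ncol=5)
        layer.grid[2, 2] = 100.0
        rug = compute_rugosity(layer, window=3)
        # cells whose 3x3 window touches (2,2)
        touched = np.zeros((5, 5), bool)
        touched[1:4, 1:4] = True
        assert (rug.grid[touched] > 0).all()
        assert (rug.grid[~touched] == 0).all()

    def test_hand_computed_neighbourhood_sd(self):
        layer = flat_layer(0.0, nrow=5, ncol=5)
        layer.grid[2, 2] = 100.0
        rug = compute_rugosity(layer, window=3)
        # centre window: eight zeros and one 100 -> population SD
        expect = np.std([0.0] * 8 + [100.0])
        assert rug.grid[2, 2] == pytest.approx(expect)
        # corner window has 4 cells, none touching the step
        assert rug.grid[0, 0] == 0.0

    def test_homogeneity_under_scaling(self):
        rng = np.random.default_rng(0)
        layer = flat_layer(0.0, nrow=8, ncol=8)
        layer.grid = rng.uniform(100, 4000, (8, 8))
        r1 = compute_rugosity(layer).grid
        layer2 = layer.with_grid(2.0 * layer.grid)
        assert np.allclose(compute_rugosity(layer2).grid, 2.0 * r1)

    def test_even_window_rejected(self):
        with pytest.raises(ConfigurationError):
            compute_rugosity(flat_layer(0.0), window=4)


class TestDistanceTo:
    def test_zero_on_feature(self):
        gs = GridSpec(west=0.0, north=1.0, dlon=1.0, dlat=1.0, nrow=2, ncol=2)
        template = EnvLayer("z", np.zeros((2, 2)), gs)
        d = compute_distance_to(Point(0.5, 0.5), template)
        assert d.grid[0, 0] == pytest.approx(0.0, abs=1e-9)

    def test_one_degree_at_equator(self):
        gs = GridSpec(west=0.0, north=0.5, dlon=1.0, dlat=1.0, nrow=1, ncol=2)
        template = EnvLayer("z", np.zeros((1, 2)), gs)
        d = compute_distance_to(Point(0.5, 0.0), template)
        assert d.grid[0, 1] == pytest.approx(111.195, rel=1e-3)

    def test_lipschitz_across_adjacent_cells(self):
        gs = GridSpec(west=0.0, north=1.0, dlon=0.1, dlat=0.1, nrow=10, ncol=10)
        template = EnvLayer("z", np.zeros((10, 10)), gs)
        d = compute_distance_to(Point(0.33, 0.77), template).grid
        diag = np.hypot(0.1, 0.1) * 111.32
        assert (np.abs(np.diff(d, axis=0)) <= diag + 1e-6).all()
        assert (np.abs(np.diff(d, axis=1)) <= diag + 1e-6).all()
        assert (d >= 0).all()

    def test_empty_features_rejected(self):
        from shapely.geometry import GeometryCollection
        with pytest.raises(ConfigurationError):
            compute_distance_to(GeometryCollection(), flat_layer())


class TestTemporalComposite:
    def test_five_day_mean(self):
        layers = daily_layers([1, 2, 3, 4, 5])
        comp = temporal_composite(layers, "composite_5d", pd.Timestamp("2022-05-03"))
        assert (comp.grid == 3.0).all()
        assert comp.time_window == (pd.Timestamp("2022-05-01"),
                                    pd.Timestamp("2022-05-06"))

    def test_masked_cell_uses_available_layers(self):
        vals = [np.full((6, 6), v) for v in (1.0, 2.0, 3.0, 4.0, 5.0)]
        vals[2][1, 1] = np.nan
        comp = temporal_composite(daily_layers(vals), "composite_5d",
                                  pd.Timestamp("2022-05-02"))
        assert comp.grid[0, 0] == 3.0
        assert comp.grid[1, 1] == pytest.approx((1 + 2 + 4 + 5) / 4)

    def test_constant_month_sd_zero(self):
        layers = daily_layers([7.0] * 20, start="2022-05-01")
        comp = temporal_composite(layers, "monthly_sd", pd.Timestamp("2022-05-10"))
        assert (comp.grid == 0.0).all()

    def test_outside_window_rejected(self):
        layers = daily_layers([1, 2, 3])
        with pytest.raises(MissingLayerError):
            temporal_composite(layers, "composite_5d", pd.Timestamp("2023-01-01"))


class TestExtractCovariates:
    def _rows(self, times, lon=110.7, lat=-20.7):
        return pd.DataFrame({"row_id": range(len(times)),
                             "time": pd.to_datetime(times),
                             "lon": lon, "lat": lat})

    def test_lagged_chlorophyll_window(self):
        # row at 05-20 with 14-day lag reads the block covering 05-06
        vals = [float(i) for i in range(30)]       # one value per day
        stacks = {"chl": daily_layers(vals, start="2022-05-01", name="chl")}
        spec = CovariateSpec("chl", "chl", "composite_5d", lag_days=14)
        ds = extract_covariates(self._rows(["2022-05-20"]), [spec], stacks)
        # 05-06 falls in block [05-06, 05-11) -> days 5..9 -> mean 7
        assert ds.frame["chl"].iloc[0] == pytest.approx(7.0)

    def test_lag_shift_invariance(self):
        vals = list(np.sin(np.arange(40)) + 2)
        rows = self._rows(["2022-05-20", "2022-05-29"])
        base = {"v": daily_layers(vals, start="2022-05-01", name="v")}
        earlier = {"v": daily_layers(vals, start="2022-04-24", name="v")}
        a = extract_covariates(rows, [CovariateSpec("v", "v", "composite_5d",
                                                    lag_days=0)], base)
        b = extract_covariates(rows, [CovariateSpec("v", "v", "composite_5d",
                                                    lag_days=7)], earlier)
        # dating the rasters 7 days earlier and lagging 7 days more reads
        # the same content
        assert np.allclose(a.frame["v"], b.frame["v"])

    def test_log_transform(self):
        stacks = {"chl": daily_layers([1.0] * 10, name="chl")}
        spec = CovariateSpec("chl", "chl", "composite_5d", transform="log")
        ds = extract_covariates(self._rows(["2022-05-03"]), [spec], stacks)
        assert ds.frame["chl"].iloc[0] == pytest.approx(0.0)

    def test_static_layer_ignores_time(self):
        stacks = {"bathy": flat_layer(700.0, west=110.0, north=-20.0, name="bathy")}
        spec = CovariateSpec("bathy", "bathy", "static")
        ds = extract_covariates(self._rows(["2022-05-03", "2023-01-01"]),
                                [spec], stacks)
        assert (ds.frame["bathy"] == 700.0).all()

    def test_month_column_and_missing_flag(self):
        stacks = {"bathy": flat_layer(1.0, name="bathy")}
        rows = self._rows(["2022-05-03"], lon=0.0, lat=0.0)   # off the grid
        ds = extract_covariates(rows, [CovariateSpec("bathy", "bathy")], stacks)
        assert ds.frame["month"].iloc[0] == 5
        assert bool(ds.frame["missing_any"].iloc[0])

    def test_unknown_layer_rejected(self):
        with pytest.raises(ConfigurationError):
            extract_covariates(self._rows(["2022-05-01"]),
                               [CovariateSpec("x", "nope")], {})


class TestCollinearityFilter:
    def _frame(self, n=400, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=n)
        return pd.DataFrame({"a": a, "b": a + 0.3 * rng.normal(size=n),
                             "c": rng.normal(size=n)})

    def test_high_correlation_drops_lower_importance(self):
        f = self._frame()
        kept, dropped = collinearity_filter(f, 0.6, {"a": 10, "b": 5, "c": 1},
                                            covariates=["a", "b", "c"])
        assert kept == ["a", "c"]
        assert dropped[0][0] == "b" and abs(dropped[0][2]) > 0.6

    def test_all_below_cutoff_is_identity(self):
        rng = np.random.default_rng(1)
        f = pd.DataFrame(rng.normal(size=(300, 3)), columns=list("abc"))
        kept, dropped = collinearity_filter(f, 0.6, {"a": 1, "b": 2, "c": 3},
                                            covariates=["a", "b", "c"])
        assert kept == ["a", "b", "c"] and dropped == []

    def test_mutually_correlated_trio_keeps_top_importance(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=500)
        f = pd.DataFrame({"x": base + 0.1 * rng.normal(size=500),
                          "y": base + 0.1 * rng.normal(size=500),
                          "z": base + 0.1 * rng.normal(size=500)})
        kept, _ = collinearity_filter(f, 0.6, {"x": 3, "y": 2, "z": 1},
                                      covariates=["x", "y", "z"])
        assert kept == ["x"]

    def test_no_remaining_pair_above_cutoff(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=400)
        f = pd.DataFrame({c: base * w + rng.normal(size=400)
                          for c, w in zip("abcdef", [2, 1.5, 1, 0.5, 0.1, 0])})
        kept, _ = collinearity_filter(f, 0.6, {c: i for i, c in enumerate("abcdef")},
                                      covariates=list("abcdef"))
        corr = f[kept].corr().to_numpy()
        np.fill_diagonal(corr, 0)
        assert np.abs(corr).max() <= 0.6


class TestPredictionGrid:
    def test_resampled_to_coarsest(self):
        fine = flat_layer(1.0, nrow=20, ncol=20, d=0.1, name="fine")
        coarse = flat_layer(2.0, nrow=5, ncol=5, d=0.4, name="coarse")
        specs = [CovariateSpec("fine", "fine"), CovariateSpec("coarse", "coarse")]
        grid = build_prediction_grid({"fine": fine, "coarse": coarse}, specs,
                                     ("2022-01-01", "2022-02-01"))
        assert grid.transform == coarse.transform
        assert np.allclose(grid.layers["fine"].grid, 1.0)

    def test_time_average_of_constant_layers(self):
        stacks = {"sst": daily_layers([2.0] * 5 + [4.0] * 5)}
        specs = [CovariateSpec("sst", "sst", "composite_5d")]
        grid = build_prediction_grid(stacks, specs,
                                     ("2022-05-01", "2022-05-11"))
        assert np.allclose(grid.layers["sst"].grid, 3.0)

    def test_aligned_input_is_identity(self):
        layer = flat_layer(7.0, nrow=6, ncol=6, d=0.5)
        grid = build_prediction_grid({"layer": layer},
                                     [CovariateSpec("layer", "layer")],
                                     ("2022-01-01", "2022-01-02"))
        assert np.allclose(grid.layers["layer"].grid, 7.0)
        assert grid.transform == layer.transform

    def test_region_clip_masks_outside(self):
        layer = flat_layer(1.0, nrow=10, ncol=10, west=110.0, north=-20.0, d=0.1)
        grid = build_prediction_grid({"v": layer}, [CovariateSpec("v", "v")],
                                     ("2022-01-01", "2022-01-02"),
                                     region_polygon=box(110.0, -20.5, 110.5, -20.0))
        g = grid.layers["v"].grid
        assert np.isfinite(g[:5, :5]).all()
        assert np.isnan(g[6:, 6:]).all()


class TestGeomorphOverlay:
    def _maps(self, binary_vals, class_vals):
        gs = GridSpec(110, -20, 0.5, 0.5, *np.asarray(binary_vals).shape)
        return (EnvLayer("b", np.asarray(binary_vals, float), gs),
                EnvLayer("c", np.asarray(class_vals, float), gs))

    def test_single_class_is_100(self):
        b, c = self._maps([[1, 1], [0, 0]], [[2, 2], [1, 3]])
        assert geomorph_overlay(b, c, {2: "slope"}) == {"slope": 100.0}

    def test_split_percentages(self):
        binary = np.ones((10, 10))
        classes = np.full((10, 10), 2.0)
        classes.ravel()[:7] = 3.0
        classes.ravel()[98:] = 1.0
        b, c = self._maps(binary, classes)
        out = geomorph_overlay(b, c, {1: "shelf", 2: "slope", 3: "deep"})
        assert out == {"shelf": 2.0, "slope": 91.0, "deep": 7.0}

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(0)
        b, c = self._maps(rng.integers(0, 2, (20, 20)),
                          rng.integers(1, 4, (20, 20)))
        assert sum(geomorph_overlay(b, c).values()) == pytest.approx(100.0, abs=1e-9)

    def test_no_suitable_cells_warns_empty(self):
        b, c = self._maps(np.zeros((3, 3)), np.ones((3, 3)))
        assert geomorph_overlay(b, c) == {}
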