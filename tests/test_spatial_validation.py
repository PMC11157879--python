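"""Variogram-driven kernels and spatially varying accuracy surfaces."""

import numpy as np
import pytest

from movesdm.geo import KM_PER_DEG, haversine_km
from movesdm.habitat_model import auc_score, kappa_score
from movesdm.io_formats import EnvLayer, GridSpec
from movesdm.spatial_validation import (AccuracySurface, KernelGeometry,
                                        VariogramSummary, accuracy_surface,
                                        empirical_variogram, kernel_rule,
                                        local_metrics, validate_map)


def scatter_points(n=400, seed=0, west=110.0, south=-25.0, span=3.0):
    rng = np.random.default_rng(seed)
    lons = west + rng.uniform(0, span, n)
    lats = south + rng.uniform(0, span, n)
    return lons, lats


GRID = GridSpec(west=110.0, north=-22.0, dlon=0.1, dlat=0.1, nrow=30, ncol=30)


class TestEmpiricalVariogram:
    def test_spatially_random_labels_flat(self):
        slopes = []
        for seed in range(20):
            lons, lats = scatter_points(200, seed)
            labels = np.random.default_rng(1000 + seed).integers(0, 2, 200)
            v = empirical_variogram(lons, lats, labels, seed=seed)
            slopes.append(abs(v.slope))
        # white noise has no rising limb on normalized axes
        assert np.median(slopes) < 0.2

    def test_smooth_threshold_field_range_recovered(self):
        # labels from a smooth N-S threshold field with ~50 km scale
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            lons, lats = scatter_points(500, seed, span=4.0)
            phase = rng.uniform(0, 2 * np.pi)
            wave = np.sin(2 * np.pi * lats * KM_PER_DEG / 200.0 + phase)
            labels = (wave > 0).astype(int)
            v = empirical_variogram(lons, lats, labels,
                                    bins_km=np.linspace(0, 220, 23), seed=seed)
            hits += 25.0 <= v.mean_range_km <= 150.0
        assert hits >= 8

    def test_duplicating_points_preserves_gamma(self):
        lons, lats = scatter_points(150, 3)
        labels = np.random.default_rng(3).integers(0, 2, 150)
        bins = np.linspace(0, 300, 13)
        v1 = empirical_variogram(lons, lats, labels, bins_km=bins)
        v2 = empirical_variogram(np.r_[lons, lons], np.r_[lats, lats],
                                 np.r_[labels, labels], bins_km=bins)
        ok = np.isfinite(v1.semivariances) & np.isfinite(v2.semivariances)
        assert np.allclose(v1.semivariances[ok], v2.semivariances[ok])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            empirical_variogram([0] * 10, [0] * 10, [0, 1] * 5)


class TestKernelRule:
    def test_high_slope_doubles_range(self):
        v = VariogramSummary(np.array([10.0]), np.array([1.0]), 50.0, 0.9, 1.0)
        k = kernel_rule(v)
        assert (k.size_km, k.centroid_spacing_km, k.rule_applied) == \
            (100.0, 50.0, "high_slope")

    def test_low_slope_halves_range(self):
        v = VariogramSummary(np.array([10.0]), np.array([1.0]), 50.0, 0.5, 1.0)
        k = kernel_rule(v)
        assert (k.size_km, k.centroid_spacing_km, k.rule_applied) == \
            (25.0, 12.5, "low_slope")

    def test_overlap_factor_identical_in_both_branches(self):
        for slope in (0.95, 0.3):
            k = kernel_rule(VariogramSummary(np.array([1.0]), np.array([1.0]),
                                             80.0, slope, 1.0))
            assert k.centroid_spacing_km / k.size_km == 0.5

    def test_boundary_slope_takes_high_branch(self):
        k = kernel_rule(VariogramSummary(np.array([1.0]), np.array([1.0]),
                                         40.0, 0.8, 1.0))
        assert k.rule_applied == "high_slope"


class TestLocalMetrics:
    def test_perfect_window(self):
        lons, lats = scatter_points(60, 5, span=0.3)
        labels = np.random.default_rng(5).integers(0, 2, 60)
        scores = np.where(labels == 1, 0.9, 0.1)
        geom = KernelGeometry(500.0, 250.0, "high_slope")
        kap, auc, n = local_metrics((110.15, -24.85), lons, lats, scores,
                                    labels, geom, 0.5)
        assert (kap, auc, n) == (1.0, 1.0, 60)

    def test_single_class_window_masked(self):
        lons, lats = scatter_points(40, 6, span=0.2)
        labels = np.ones(40, int)
        geom = KernelGeometry(500.0, 250.0, "high_slope")
        kap, auc, n = local_metrics((110.1, -24.9), lons, lats,
                                    np.random.default_rng(0).random(40),
                                    labels, geom, 0.5)
        assert np.isnan(kap) and np.isnan(auc)

    def test_window_auc_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(7)
        lons, lats = scatter_points(120, 7, span=1.0)
        labels = rng.integers(0, 2, 120)
        scores = np.round(rng.random(120), 2)
        geom = KernelGeometry(80.0, 40.0, "low_slope")
        centroid = (110.5, -24.5)
        kap, auc, n = local_metrics(centroid, lons, lats, scores, labels,
                                    geom, 0.5, min_points=5)
        inside = haversine_km(lons, lats, *centroid) <= 40.0
        pos = scores[inside & (labels == 1)]
        neg = scores[inside & (labels == 0)]
        oracle = np.mean([(p > q) + 0.5 * (p == q) for p in pos for q in neg])
        assert auc == pytest.approx(oracle, abs=1e-12)


class TestAccuracySurface:
    def _points(self, n=600, seed=8):
        rng = np.random.default_rng(seed)
        lons = 110.0 + rng.uniform(0, 3.0, n)
        lats = -25.0 + rng.uniform(0, 3.0, n)
        labels = rng.integers(0, 2, n)
        return lons, lats, labels, rng

    def test_whole_study_window_reproduces_global_metrics(self):
        lons, lats, labels, rng = self._points()
        scores = np.clip(0.6 * labels + rng.normal(0, 0.25, len(labels)), 0, 1)
        geom = KernelGeometry(5000.0, 2500.0, "high_slope")
        surf = accuracy_surface(lons, lats, scores, labels, geom, GRID, 0.5)
        g_auc = auc_score(scores, labels)
        g_kap = kappa_score(scores, labels, 0.5)
        ok = np.isfinite(surf.spatial_auc.grid)
        assert ok.any()
        assert np.abs(surf.spatial_auc.grid[ok] - g_auc).max() < 1e-9
        assert np.abs(surf.spatial_kappa.grid[ok] - g_kap).max() < 1e-9

    def test_uniform_quality_gives_flat_surface(self):
        sds = []
        for seed in range(10):
            lons, lats, labels, rng = self._points(800, seed)
            scores = np.clip(0.7 * labels + rng.normal(0, 0.2, len(labels)), 0, 1)
            geom = KernelGeometry(250.0, 125.0, "high_slope")
            surf = accuracy_surface(lons, lats, scores, labels, geom, GRID, 0.5)
            vals = surf.spatial_auc.grid[np.isfinite(surf.spatial_auc.grid)]
            sds.append(vals.std())
        assert np.median(sds) < 0.1

    def test_planted_degradation_found_in_correct_half(self):
        hits = 0
        for seed in range(5):
            lons, lats, labels, rng = self._points(900, 50 + seed)
            scores = np.clip(0.7 * labels + rng.normal(0, 0.15, len(labels)), 0, 1)
            east = lons > 111.5
            scores[east] = rng.random(east.sum())      # destroy skill in the east
            geom = KernelGeometry(220.0, 110.0, "high_slope")
            surf = accuracy_surface(lons, lats, scores, labels, geom, GRID, 0.5)
            LON, _ = np.meshgrid(GRID.cell_lons(), GRID.cell_lats())
            a = surf.spatial_auc.grid
            east_mean = np.nanmean(a[LON > 111.5])
            west_mean = np.nanmean(a[LON <= 111.5])
            hits += east_mean < west_mean
        assert hits >= 4

    def test_all_windows_sparse_is_an_error(self):
        lons, lats, labels, rng = self._points(100, 9)
        scores = rng.random(100)
        geom = KernelGeometry(30.0, 15.0, "low_slope")
        with pytest.raises(ValueError):
            accuracy_surface(lons, lats, scores, labels, geom, GRID, 0.5,
                             min_points=60)


class TestValidateMap:
    def _surface(self, kappa, auc):
        gs = GridSpec(110, -22, 1.0, 1.0, 2, 2)
        geom = KernelGeometry(100.0, 50.0, "high_slope")
        return AccuracySurface(EnvLayer("k", np.asarray(kappa, float), gs),
                               EnvLayer("a", np.asarray(auc, float), gs),
                               EnvLayer("n", np.full((2, 2), 99.0), gs),
                               geom, 20)

    def test_both_metrics_must_exceed_threshold(self):
        binary = EnvLayer("b", np.ones((2, 2)), GridSpec(110, -22, 1.0, 1.0, 2, 2))
        surf = self._surface([[0.5, 0.39], [0.9, np.nan]],
                             [[0.5, 0.9], [0.39, 0.9]])
        v = validate_map(binary, surf, 0.4)
        assert v.grid[0, 0] == 1          # both above
        assert v.grid[0, 1] == 0          # kappa below
        assert v.grid[1, 0] == 0          # auc below
        assert v.grid[1, 1] == 0          # masked accuracy -> not validated

    def test_validated_subset_of_binary(self):
        rng = np.random.default_rng(10)
        gs = GridSpec(110, -22, 0.5, 0.5, 8, 8)
        binary = EnvLayer("b", rng.integers(0, 2, (8, 8)).astype(float), gs)
        geom = KernelGeometry(100.0, 50.0, "high_slope")
        surf = AccuracySurface(EnvLayer("k", rng.uniform(-1, 1, (8, 8)), gs),
                               EnvLayer("a", rng.uniform(0, 1, (8, 8)), gs),
                               EnvLayer("n", np.full((8, 8), 50.0), gs), geom, 20)
        v = validate_map(binary, surf, 0.4)
        assert np.nansum(v.grid == 1) <= np.nansum(binary.grid == 1)
        assert not ((v.grid == 1) & (binary.grid == 0)).any()

    def test_monotone_in_accuracy_floor(self):
        rng = np.random.default_rng(11)
        gs = GridSpec(110, -22, 0.5, 0.5, 8, 8)
        binary = EnvLayer("b", np.ones((8, 8)), gs)
        geom = KernelGeometry(100.0, 50.0, "high_slope")
        surf = AccuracySurface(EnvLayer("k", rng.uniform(0, 1, (8, 8)), gs),
                               EnvLayer("a", rng.uniform(0, 1, (8, 8)), gs),
                               EnvLayer("n", np.full((8, 8), 50.0), gs), geom, 20)
        counts = [np.nansum(validate_map(binary, surf, t).grid == 1)
                  for t in (0.2, 0.4, 0.6, 0.8)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))
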