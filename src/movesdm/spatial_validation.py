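"""Stage 5: spatially varying accuracy (spatial Kappa / spatial AUC).

Global AUC and Kappa say nothing about *where* a habitat model can be
trusted. Here local versions of both metrics are computed inside a moving
circular window whose geometry is driven by the empirical variogram of the
presence/pseudo-absence data: strongly structured data (steep normalized
variogram slope) get a large window (2x the mean range) on a coarse lattice
(spacing = 1 range); weakly structured data get a small window (0.5x range)
on a fine lattice (0.25x range). Window centroids are evaluated on a square
lattice, rasterized by inverse-distance weighting of the four nearest
centroids, and the binary suitability map is masked to cells where both
local metrics clear an accuracy floor (default 0.4) - the "validated"
suitable habitat.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .geo import KM_PER_DEG, haversine_km
from .habitat_model import auc_score, kappa_score
from .io_formats import EnvLayer, GridSpec

log = logging.getLogger(__name__)


@dataclass
class VariogramSummary:
    bin_distances_km: np.ndarray
    semivariances: np.ndarray
    mean_range_km: float
    slope: float                    # on axes normalized to [0, 1]
    sill: float
    per_track_ranges_km: list[float] = field(default_factory=list)

    def __post_init__(self):
        if not (self.mean_range_km > 0 and np.isfinite(self.slope)):
            raise ValueError("invalid variogram summary")


@dataclass(frozen=True)
class KernelGeometry:
    size_km: float                  # window diameter
    centroid_spacing_km: float
    rule_applied: str               # high_slope | low_slope

    def __post_init__(self):
        if not (self.size_km > 0 and 0 < self.centroid_spacing_km <= self.size_km):
            raise ValueError("invalid kernel geometry")


@dataclass
class AccuracySurface:
    spatial_kappa: EnvLayer
    spatial_auc: EnvLayer
    n_local: EnvLayer
    geometry: KernelGeometry
    min_points: int


def _pairwise_gamma(lons, lats, z, edges_km):
    """Per-bin semivariance and pair counts for one point set."""
    n = len(z)
    gamma_sum = np.zeros(len(edges_km) - 1)
    counts = np.zeros(len(edges_km) - 1, dtype=int)
    iu, ju = np.triu_indices(n, k=1)
    d = haversine_km(lons[iu], lats[iu], lons[ju], lats[ju])
    sq = 0.5 * (z[iu] - z[ju]) ** 2
    which = np.digitize(d, edges_km) - 1
    # coincident points belong to the nugget, not to any lag bin
    ok = (which >= 0) & (which < len(edges_km) - 1) & (d > 0)
    np.add.at(gamma_sum, which[ok], sq[ok])
    np.add.at(counts, which[ok], 1)
    return gamma_sum, counts


def _range_from_gamma(h, gamma, counts):
    """First bin distance where gamma reaches 95% of the sill."""
    valid = counts > 0
    if valid.sum() < 3:
        return None, None
    hv, gv = h[valid], gamma[valid]
    tail = max(1, len(gv) // 3)
    sill = float(np.mean(gv[-tail:]))
    if sill <= 0:
        return None, sill
    above = np.nonzero(gv >= 0.95 * sill)[0]
    if len(above) == 0:
        return float(hv[-1]), sill      # no plateau: range = h_max
    return float(hv[above[0]]), sill


def empirical_variogram(lons, lats, labels, bins_km=None, track_ids=None,
                        min_pairs_per_bin: int = 10,
                        max_points: int = 2000, seed: int = 0) -> VariogramSummary:
    """Empirical semivariogram of the 0/1 presence/pseudo-absence labels.

    gamma(h) = mean over point pairs in distance bin h of (z_i - z_j)^2 / 2.
    The sill is the mean semivariance of the last third of the bins; the
    range is the first bin where gamma reaches 95% of the sill, computed per
    track and averaged (pooled fallback below 3 tracks); the slope is the
    least-squares slope of gamma/sill against h/h_max over bins up to the
    range, i.e. on axes normalized to [0, 1]. Underfilled bins trigger one
    round of bin widening with a warning.
    """
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    z = np.asarray(labels, dtype=float)
    if len(z) < 30:
        raise ValueError("empirical_variogram needs >= 30 points")
    if len(z) > max_points:
        rng = np.random.default_rng(seed)
        keep = rng.choice(len(z), size=max_points, replace=False)
        lons, lats, z = lons[keep], lats[keep], z[keep]
        track_ids = None if track_ids is None else np.asarray(track_ids)[keep]

    if bins_km is None:
        span = haversine_km(lons.min(), lats.min(), lons.max(), lats.max())
        bins_km = np.linspace(0.0, max(span / 2.0, 1.0), 16)
    edges = np.asarray(bins_km, dtype=float)

    gamma_sum, counts = _pairwise_gamma(lons, lats, z, edges)
    if (counts[:max(3, len(counts) // 2)] < min_pairs_per_bin).any():
        log.warning("empirical_variogram: underfilled bins, widening once")
        edges = edges[::2] if len(edges) > 6 else edges
        gamma_sum, counts = _pairwise_gamma(lons, lats, z, edges)
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = np.where(counts > 0, gamma_sum / np.maximum(counts, 1), np.nan)
    h = 0.5 * (edges[:-1] + edges[1:])

    pooled_range, sill = _range_from_gamma(h, gamma, counts)
    if pooled_range is None:
        raise ValueError("variogram could not be estimated (too few filled bins)")

    per_track = []
    if track_ids is not None:
        track_ids = np.asarray(track_ids)
        uniq = np.unique(track_ids)
        for tid in uniq:
            m = track_ids == tid
            if m.sum() < 30:
                continue
            gs, cs = _pairwise_gamma(lons[m], lats[m], z[m], edges)
            with np.errstate(invalid="ignore", divide="ignore"):
                g_t = np.where(cs > 0, gs / np.maximum(cs, 1), np.nan)
            r_t, _ = _range_from_gamma(h, g_t, cs)
            if r_t is not None and r_t > 0:
                per_track.append(r_t)
    if len(per_track) >= 3:
        mean_range = float(np.mean(per_track))
    else:
        mean_range = float(pooled_range)
    mean_range = max(mean_range, float(h[0]) if h[0] > 0 else 1.0)

    # normalized slope over the rising limb (h <= range); a flat variogram
    # has essentially no limb, so guarantee at least a few bins enter the
    # fit instead of extrapolating a line through one or two points
    filled = np.nonzero(counts > 0)[0]
    valid = (counts > 0) & (h <= mean_range)
    if valid.sum() < 3:
        valid = counts > 0          # flat variogram: fit the global trend
    x = h[valid] / h[filled].max()
    y = gamma[valid] / sill if sill > 0 else gamma[valid]
    slope = float(np.polyfit(x, y, 1)[0]) if valid.sum() >= 2 else 0.0

    return VariogramSummary(h, gamma, mean_range, slope, float(sill), per_track)


def kernel_rule(v: VariogramSummary, slope_criterion: float = 0.8) -> KernelGeometry:
    """Window geometry from the variogram: steep slope -> wide kernel.

    slope >= 0.8 (criterion): size 2x mean range, spacing 1x range;
    otherwise size 0.5x range, spacing 0.25x range. The boundary case
    (slope exactly 0.8) takes the high-slope branch.
    """
    if v.slope >= slope_criterion:
        return KernelGeometry(2.0 * v.mean_range_km, v.mean_range_km, "high_slope")
    return KernelGeometry(0.5 * v.mean_range_km, 0.25 * v.mean_range_km, "low_slope")


def local_metrics(centroid, lons, lats, scores, labels, geometry: KernelGeometry,
                  threshold: float, min_points: int = 20):
    """(kappa, auc, n_local) within size/2 of the centroid; NaN when undefined."""
    clon, clat = centroid
    d = haversine_km(lons, lats, clon, clat)
    m = d <= geometry.size_km / 2.0
    n_local = int(m.sum())
    y = labels[m]
    if n_local < min_points or len(np.unique(y)) < 2:
        return np.nan, np.nan, n_local
    s = scores[m]
    return kappa_score(s, y, threshold), auc_score(s, y), n_local


def accuracy_surface(lons, lats, scores, labels, geometry: KernelGeometry,
                     grid: GridSpec, threshold: float,
                     min_points: int = 20) -> AccuracySurface:
    """Moving-window spatial Kappa / spatial AUC rasters.

    Window centroids sit on a square lattice at the kernel's centroid
    spacing over the grid extent; each raster cell takes the
    inverse-distance-weighted mean of its 4 nearest evaluated centroids
    (unmasked ones only), and the n_local raster takes the nearest
    centroid's count. Cells whose nearest centroid saw fewer than
    ``min_points`` points are masked.
    """
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)

    lat_c = grid.center_lat
    dlat = geometry.centroid_spacing_km / KM_PER_DEG
    dlon = geometry.centroid_spacing_km / (KM_PER_DEG * max(np.cos(np.radians(lat_c)), 0.05))
    lon_min, lon_max = grid.west, grid.west + grid.ncol * grid.dlon
    lat_min, lat_max = grid.north - grid.nrow * grid.dlat, grid.north
    c_lons = np.arange(lon_min + dlon / 2, lon_max, dlon)
    c_lats = np.arange(lat_min + dlat / 2, lat_max, dlat)
    if len(c_lons) == 0:            # spacing wider than the study extent
        c_lons = np.array([(lon_min + lon_max) / 2.0])
    if len(c_lats) == 0:
        c_lats = np.array([(lat_min + lat_max) / 2.0])
    CLON, CLAT = np.meshgrid(c_lons, c_lats)
    cent = np.stack([CLON.ravel(), CLAT.ravel()], axis=1)

    kappas = np.full(len(cent), np.nan)
    aucs = np.full(len(cent), np.nan)
    ns = np.zeros(len(cent))
    for i, (clon, clat) in enumerate(cent):
        kappas[i], aucs[i], ns[i] = local_metrics(
            (clon, clat), lons, lats, scores, labels, geometry, threshold, min_points)
    if not np.isfinite(kappas).any() and not np.isfinite(aucs).any():
        raise ValueError("no window produced a defined metric")

    LONg, LATg = np.meshgrid(grid.cell_lons(), grid.cell_lats())
    cells = np.stack([LONg.ravel(), LATg.ravel()], axis=1)
    # scaled-planar 4-NN lookup (lattice is locally regular)
    scale = np.array([np.cos(np.radians(lat_c)), 1.0]) * KM_PER_DEG
    from scipy.spatial import cKDTree
    tree = cKDTree(cent * scale)
    k = min(4, len(cent))
    dist, idx = tree.query(cells * scale, k=k)
    dist = np.atleast_2d(dist.reshape(len(cells), k))
    idx = np.atleast_2d(idx.reshape(len(cells), k))

    def idw(values):
        v = values[idx]
        ok = np.isfinite(v)
        w = 1.0 / np.maximum(dist, 1e-9)
        w = np.where(ok, w, 0.0)
        tot = w.sum(axis=1)
        out = np.where(tot > 0, np.nansum(np.where(ok, v, 0.0) * w, axis=1)
                       / np.maximum(tot, 1e-300), np.nan)
        return out

    kap_r = idw(kappas)
    auc_r = idw(aucs)
    n_r = ns[idx[:, 0]]
    undef = n_r < min_points
    kap_r[undef] = np.nan
    auc_r[undef] = np.nan

    shape = (grid.nrow, grid.ncol)
    mk = EnvLayer("spatial_kappa", kap_r.reshape(shape), grid)
    ma = EnvLayer("spatial_auc", auc_r.reshape(shape), grid)
    mn = EnvLayer("n_local", n_r.reshape(shape), grid)
    return AccuracySurface(mk, ma, mn, geometry, min_points)


def validate_map(binary: EnvLayer, surface: AccuracySurface,
                 min_accuracy: float = 0.4) -> EnvLayer:
    """Suitable cells where *both* spatial metrics exceed the floor.

    Masked (undefined) accuracy cells are never validated, so the validated
    map is always a cellwise subset of the binary map.
    """
    if binary.grid.shape != surface.spatial_kappa.grid.shape:
        raise ValueError("rasters are not co-registered")
    b = binary.grid == 1
    k = surface.spatial_kappa.grid
    a = surface.spatial_auc.grid
    ok = np.isfinite(k) & np.isfinite(a) & (k > min_accuracy) & (a > min_accuracy)
    v = np.where(np.isfinite(binary.grid), (b & ok).astype(float), np.nan)
    out = binary.with_grid(v, name="validated")
    return out
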