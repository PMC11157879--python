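"""Stage 3: build, derive, lag and extract environmental covariates.

Dynamic remote-sensing variables are consumed as 5-day / 8-day block means
or monthly standard deviations rather than daily fields (mirroring composite
products used to beat cloud gaps); chlorophyll-a is taken with a 14-day lag
to allow for the trophic delay between primary production and zooplankton,
and is log transformed. Static seafloor variables (depth, rugosity,
distance to canyon / shelf break) are derived from bathymetry. Covariates
are matched to presence / pseudo-absence rows by cell lookup on the
composite whose window contains the (lagged) row time, and prediction grids
are period-averaged layers resampled to the coarsest resolution in the set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.ndimage import uniform_filter
from shapely.geometry.base import BaseGeometry

from .geo import haversine_km
from .io_formats import EnvLayer, GridSpec

log = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    pass


class MissingLayerError(KeyError):
    pass


@dataclass(frozen=True)
class CovariateSpec:
    """How one model covariate is built from a source layer.

    ``temporal_rule`` is one of static, composite_5d, composite_8d,
    monthly_sd. ``lag_days`` shifts the matching time backwards.
    """

    name: str
    source_layer: str
    temporal_rule: str = "static"
    transform: str = "none"            # none | log
    lag_days: int = 0
    behaviours: tuple[str, ...] = ("F", "M", "R")
    categorical: bool = False

    def __post_init__(self):
        if self.temporal_rule not in ("static", "composite_5d", "composite_8d", "monthly_sd"):
            raise ConfigurationError(f"bad temporal_rule {self.temporal_rule!r}")
        if self.transform not in ("none", "log"):
            raise ConfigurationError(f"bad transform {self.transform!r}")
        if self.lag_days < 0:
            raise ConfigurationError("lag_days must be >= 0")


@dataclass
class ModelDataset:
    """Presence/pseudo-absence rows with matched covariate columns."""

    frame: pd.DataFrame
    covariates: list[str]

    def complete_cases(self) -> pd.DataFrame:
        return self.frame[~self.frame["missing_any"]].reset_index(drop=True)


@dataclass
class PredictionGrid:
    """Co-registered period-averaged layers at the coarsest input resolution."""

    layers: dict[str, EnvLayer]
    period: tuple[pd.Timestamp, pd.Timestamp]
    region: str

    def __post_init__(self):
        specs = {l.transform for l in self.layers.values()}
        if len(specs) > 1:
            raise ValueError("prediction grid layers must share one grid")

    @property
    def transform(self) -> GridSpec:
        return next(iter(self.layers.values())).transform


def compute_rugosity(bathy: EnvLayer, window: int = 3) -> EnvLayer:
    """Neighbourhood standard deviation of depth (benthic heterogeneity).

    Edge cells use the neighbours available inside the grid; missing cells
    are excluded from their neighbours' statistics.
    """
    if window % 2 == 0 or window < 1:
        raise ConfigurationError("window must be odd and positive")
    z = bathy.grid
    finite = np.isfinite(z)
    z0 = np.where(finite, z, 0.0)
    size = window
    cnt = uniform_filter(finite.astype(float), size, mode="constant", cval=0.0)
    s1 = uniform_filter(z0, size, mode="constant", cval=0.0)
    s2 = uniform_filter(z0 ** 2, size, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = s1 / cnt
        var = np.maximum(s2 / cnt - mean ** 2, 0.0)
        rug = np.sqrt(var)
    rug[~finite] = np.nan
    rug[cnt <= 0] = np.nan
    out = bathy.with_grid(rug, name="rugosity")
    out.units = bathy.units
    return out


def compute_distance_to(features: BaseGeometry, template: EnvLayer) -> EnvLayer:
    """Great-circle distance (km) from each cell centre to the nearest
    feature edge; zero inside polygon features.

    The nearest point on the feature is found in lon/lat space and the
    distance to it measured with the haversine formula.
    """
    if features is None or features.is_empty:
        raise ConfigurationError("empty feature set")
    gs = template.transform
    lons = gs.cell_lons()
    lats = gs.cell_lats()
    LON, LAT = np.meshgrid(lons, lats)
    pts = shapely.points(LON.ravel(), LAT.ravel())
    lines = shapely.shortest_line(pts, features)
    coords = shapely.get_coordinates(lines).reshape(-1, 2, 2)
    near_lon, near_lat = coords[:, 1, 0], coords[:, 1, 1]
    d = haversine_km(LON.ravel(), LAT.ravel(), near_lon, near_lat)
    inside = shapely.covers(features, pts)
    d[inside] = 0.0
    out = template.with_grid(d.reshape(LAT.shape), name="distance")
    out.units = "km"
    out.time_window = None
    return out


def _layer_date(layer: EnvLayer) -> pd.Timestamp:
    if layer.time_window is None:
        raise ConfigurationError(f"layer {layer.name} is static")
    return pd.Timestamp(layer.time_window[0])


def temporal_composite(daily: list[EnvLayer], rule: str, at: pd.Timestamp) -> EnvLayer:
    """Block mean (composite_5d / composite_8d) or calendar-month SD.

    Block windows are fixed, non-overlapping k-day blocks anchored at the
    first daily layer's date. Cells missing in every contributing layer stay
    missing; otherwise the statistic uses the available values.
    """
    if not daily:
        raise MissingLayerError("no daily layers supplied")
    at = pd.Timestamp(at)
    dates = np.array([_layer_date(l) for l in daily])
    order = np.argsort(dates)
    daily = [daily[i] for i in order]
    dates = dates[order]

    if rule in ("composite_5d", "composite_8d"):
        k = 5 if rule == "composite_5d" else 8
        anchor = dates[0].normalize()
        idx = int(np.floor((at - anchor) / pd.Timedelta(days=1)) // k)
        w0 = anchor + pd.Timedelta(days=idx * k)
        w1 = w0 + pd.Timedelta(days=k)
        sel = [l for l, d in zip(daily, dates) if w0 <= d < w1]
        if not sel:
            raise MissingLayerError(f"no layers in window [{w0}, {w1})")
        stack = np.stack([l.grid for l in sel])
        with np.errstate(all="ignore"):
            grid = np.nanmean(stack, axis=0)
    elif rule == "monthly_sd":
        sel = [l for l, d in zip(daily, dates)
               if d.year == at.year and d.month == at.month]
        if not sel:
            raise MissingLayerError(f"no layers in month {at:%Y-%m}")
        w0 = at.normalize().replace(day=1)
        w1 = w0 + pd.offsets.MonthBegin(1)
        stack = np.stack([l.grid for l in sel])
        with np.errstate(all="ignore"):
            grid = np.nanstd(stack, axis=0)
    else:
        raise ConfigurationError(f"bad rule {rule!r}")
    out = daily[0].with_grid(grid)
    out.time_window = (pd.Timestamp(w0), pd.Timestamp(w1))
    return out


def _composite_for(spec: CovariateSpec, stacks: dict, at: pd.Timestamp,
                   cache: dict) -> EnvLayer:
    src = stacks.get(spec.source_layer)
    if src is None:
        raise ConfigurationError(f"spec {spec.name}: no layer {spec.source_layer!r}")
    if spec.temporal_rule == "static":
        if isinstance(src, list):
            raise ConfigurationError(f"{spec.name}: static rule on a dynamic stack")
        return src
    if not isinstance(src, list):
        raise ConfigurationError(f"{spec.name}: {spec.temporal_rule} needs daily layers")
    if spec.temporal_rule in ("composite_5d", "composite_8d"):
        k = 5 if spec.temporal_rule == "composite_5d" else 8
        anchor = min(_layer_date(l) for l in src).normalize()
        key = (spec.source_layer, spec.temporal_rule,
               int(np.floor((at - anchor) / pd.Timedelta(days=1)) // k))
    else:
        key = (spec.source_layer, spec.temporal_rule, (at.year, at.month))
    if key not in cache:
        cache[key] = temporal_composite(src, spec.temporal_rule, at)
    return cache[key]


def extract_covariates(rows: pd.DataFrame, specs: list[CovariateSpec],
                       stacks: dict) -> ModelDataset:
    """Match every design row with one value per covariate spec.

    The value is read from the composite whose window contains
    ``row.time - lag_days`` (cell containing the point, no interpolation).
    The natural-log transform is applied where specified. A ``month`` column
    is added. Rows with any missing covariate are retained and flagged.
    """
    out = rows.copy().reset_index(drop=True)
    times = pd.to_datetime(out["time"])
    out["month"] = times.dt.month
    cache: dict = {}
    names = []
    for spec in specs:
        vals = np.full(len(out), np.nan)
        if spec.temporal_rule == "static":
            layer = _composite_for(spec, stacks, pd.Timestamp(0), cache)
            vals = layer.sample(out["lon"].to_numpy(), out["lat"].to_numpy())
        else:
            eff = times - pd.Timedelta(days=spec.lag_days)
            if spec.temporal_rule in ("composite_5d", "composite_8d"):
                k = 5 if spec.temporal_rule == "composite_5d" else 8
                src = stacks.get(spec.source_layer)
                if not isinstance(src, list):
                    raise ConfigurationError(f"{spec.name}: needs daily layers")
                anchor = min(_layer_date(l) for l in src).normalize()
                block = ((eff - anchor) // pd.Timedelta(days=1)) // k
            else:
                block = eff.dt.year * 12 + eff.dt.month
            for b in np.unique(block):
                sel = (block == b).to_numpy()
                t_rep = eff[sel].iloc[0]
                try:
                    layer = _composite_for(spec, stacks, pd.Timestamp(t_rep), cache)
                except MissingLayerError:
                    continue
                vals[sel] = layer.sample(out.loc[sel, "lon"].to_numpy(),
                                         out.loc[sel, "lat"].to_numpy())
        if spec.transform == "log":
            with np.errstate(invalid="ignore", divide="ignore"):
                vals = np.where(vals > 0, np.log(vals), np.nan)
        out[spec.name] = vals
        names.append(spec.name)
    out["missing_any"] = out[names].isna().any(axis=1)
    n_miss = int(out["missing_any"].sum())
    if n_miss:
        log.info("extract_covariates: %d/%d rows flagged missing", n_miss, len(out))
    return ModelDataset(out, names)


def collinearity_filter(data: ModelDataset | pd.DataFrame, cutoff: float = 0.6,
                        importance: dict[str, float] | None = None,
                        covariates: list[str] | None = None):
    """Iteratively drop the lower-importance member of the worst collinear pair.

    While any pairwise Pearson |r| exceeds ``cutoff``, the pair with the
    largest |r| is found and its lower-importance member removed. Returns
    (kept names, list of (dropped, kept, r) records).
    """
    if isinstance(data, ModelDataset):
        frame, names = data.complete_cases(), list(data.covariates)
    else:
        frame, names = data, list(covariates)
    if importance is None:
        importance = {n: 0.0 for n in names}
    kept = [n for n in names]
    dropped = []
    while len(kept) >= 2:
        corr = frame[kept].corr(method="pearson").to_numpy()
        np.fill_diagonal(corr, 0.0)
        corr = np.nan_to_num(corr)
        i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        r = corr[i, j]
        if abs(r) <= cutoff:
            break
        a, b = kept[i], kept[j]
        loser = a if importance.get(a, 0.0) <= importance.get(b, 0.0) else b
        winner = b if loser == a else a
        kept.remove(loser)
        dropped.append((loser, winner, float(r)))
        log.info("collinearity_filter: dropped %s (|r|=%.2f with %s)", loser, abs(r), winner)
    return kept, dropped


def _resample(layer: EnvLayer, target: GridSpec, categorical: bool) -> EnvLayer:
    """Resample onto ``target``: bilinear for continuous, nearest for classes."""
    src = layer.transform
    tl_lon, tl_lat = np.meshgrid(target.cell_lons(), target.cell_lats())
    if categorical:
        row, col = src.rowcol(tl_lon.ravel(), tl_lat.ravel())
        ok = src.contains(tl_lon.ravel(), tl_lat.ravel())
        vals = np.full(tl_lon.size, np.nan)
        vals[ok] = layer.grid[row[ok], col[ok]]
    else:
        # bilinear on cell-centre coordinates
        fr = (src.north - tl_lat.ravel()) / src.dlat - 0.5
        fc = (tl_lon.ravel() - src.west) / src.dlon - 0.5
        r0 = np.clip(np.floor(fr).astype(int), 0, src.nrow - 1)
        c0 = np.clip(np.floor(fc).astype(int), 0, src.ncol - 1)
        r1 = np.clip(r0 + 1, 0, src.nrow - 1)
        c1 = np.clip(c0 + 1, 0, src.ncol - 1)
        wr = np.clip(fr - r0, 0.0, 1.0)
        wc = np.clip(fc - c0, 0.0, 1.0)
        g = layer.grid
        vals = ((1 - wr) * (1 - wc) * g[r0, c0] + (1 - wr) * wc * g[r0, c1]
                + wr * (1 - wc) * g[r1, c0] + wr * wc * g[r1, c1])
        outside = (fr < -0.5) | (fr > src.nrow - 0.5) | (fc < -0.5) | (fc > src.ncol - 0.5)
        vals[outside] = np.nan
    out = EnvLayer(layer.name, vals.reshape(target.nrow, target.ncol), target,
                   crs=layer.crs, time_window=layer.time_window, units=layer.units)
    return out


def build_prediction_grid(stacks: dict, specs: list[CovariateSpec],
                          period: tuple[pd.Timestamp, pd.Timestamp],
                          region: str | BaseGeometry = "",
                          region_polygon: BaseGeometry | None = None) -> PredictionGrid:
    """Period-average each dynamic layer, resample all to the coarsest grid.

    Dynamic layers are averaged cellwise over all daily layers with dates in
    ``period``; static layers pass through. Every layer is then resampled
    (bilinear, nearest for categorical specs) onto the grid of the
    coarsest-resolution layer and clipped to ``region_polygon`` if given.
    """
    start, end = pd.Timestamp(period[0]), pd.Timestamp(period[1])
    if end < start:
        raise ConfigurationError("empty period")
    if isinstance(region, BaseGeometry):
        region_polygon, region = region, ""
    averaged: dict[str, tuple[EnvLayer, bool]] = {}
    for spec in specs:
        src = stacks.get(spec.source_layer)
        if src is None:
            raise ConfigurationError(f"no layer {spec.source_layer!r}")
        if isinstance(src, list):
            sel = [l for l in src if start <= _layer_date(l) <= end]
            if not sel:
                raise MissingLayerError(f"{spec.source_layer}: no layers in period")
            with np.errstate(all="ignore"):
                if spec.temporal_rule == "monthly_sd":
                    # period average of the *monthly* SDs, not one long SD
                    keys = sorted({(d.year, d.month)
                                   for d in (_layer_date(l) for l in sel)})
                    monthly = []
                    for yy, mm in keys:
                        sub = [l for l in sel if _layer_date(l).year == yy
                               and _layer_date(l).month == mm]
                        monthly.append(np.nanstd(np.stack([l.grid for l in sub]),
                                                 axis=0))
                    grid = np.nanmean(np.stack(monthly), axis=0)
                else:
                    grid = np.nanmean(np.stack([l.grid for l in sel]), axis=0)
            layer = sel[0].with_grid(grid, name=spec.name)
            layer.time_window = (start, end)
        else:
            layer = src.with_grid(src.grid.copy(), name=spec.name)
        if spec.transform == "log":
            with np.errstate(invalid="ignore", divide="ignore"):
                layer.grid = np.where(layer.grid > 0, np.log(layer.grid), np.nan)
        averaged[spec.name] = (layer, spec.categorical)

    coarsest = max(averaged.values(), key=lambda lc: lc[0].resolution_km)[0]
    target = coarsest.transform
    layers = {name: _resample(layer, target, cat)
              for name, (layer, cat) in averaged.items()}
    if region_polygon is not None:
        LON, LAT = np.meshgrid(target.cell_lons(), target.cell_lats())
        inside = shapely.covers(region_polygon,
                                shapely.points(LON.ravel(), LAT.ravel()))
        mask = ~inside.reshape(LAT.shape)
        for layer in layers.values():
            layer.grid[mask] = np.nan
    return PredictionGrid(layers, (start, end), str(region))


def geomorph_overlay(binary_map: EnvLayer, classes: EnvLayer,
                     class_names: dict[int, str] | None = None) -> dict[str, float]:
    """Percentage of suitable cells falling in each geomorphic class."""
    if binary_map.grid.shape != classes.grid.shape:
        raise ValueError("rasters are not co-registered")
    suitable = binary_map.grid == 1
    cls = classes.grid
    valid = suitable & np.isfinite(cls)
    total = int(valid.sum())
    if total == 0:
        log.warning("geomorph_overlay: no suitable cells")
        return {}
    out = {}
    for c in np.unique(cls[valid]):
        key = class_names.get(int(c), str(int(c))) if class_names else str(int(c))
        out[key] = 100.0 * float(np.sum(valid & (cls == c))) / total
    return out
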