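"""Typed readers and writers for every external artefact the pipeline touches.

Tracks come in as CSV (one row per telemetry fix), environmental layers as
CF-style NetCDF rasters on a regular lon/lat grid, and region polygons as
GeoJSON. Everything downstream consumes the validated containers defined
here (:class:`RawTrack`, :class:`EnvLayer`, :class:`RegionSet`), never raw
files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import xarray as xr
from shapely.geometry import Point, shape
from shapely.geometry.base import BaseGeometry

from .geo import KM_PER_DEG, normalize_lon

log = logging.getLogger(__name__)

ARGOS_CLASSES = ("3", "2", "1", "0", "A", "B", "Z")
GPS_CLASS = "G"


class FormatError(ValueError):
    """Input file violates the expected format."""


class EmptyInputError(ValueError):
    """No valid rows/records remained after validation."""


@dataclass(frozen=True)
class RawFix:
    """A single telemetry fix with its Argos/GPS quality class."""

    animal_id: str
    time: pd.Timestamp
    lon: float
    lat: float
    source: str           # "argos" | "gps"
    loc_class: str        # 3,2,1,0,A,B,Z for Argos; G for GPS

    def __post_init__(self):
        if self.source == "gps" and self.loc_class != GPS_CLASS:
            raise ValueError(f"gps fix must have class G, got {self.loc_class}")
        if self.source == "argos" and self.loc_class not in ARGOS_CLASSES:
            raise ValueError(f"bad Argos class {self.loc_class!r}")


@dataclass
class RawTrack:
    """One animal's time-ordered, validated telemetry fixes."""

    animal_id: str
    fixes: list[RawFix]
    deploy_site: str | None = None

    def __post_init__(self):
        if len(self.fixes) < 2:
            raise ValueError("a track needs at least 2 fixes")
        times = self.times
        if not (np.diff(times.view("i8")) > 0).all():
            raise ValueError("fix timestamps must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time.to_datetime64() for f in self.fixes])

    @property
    def lons(self) -> np.ndarray:
        return np.array([f.lon for f in self.fixes])

    @property
    def lats(self) -> np.ndarray:
        return np.array([f.lat for f in self.fixes])

    @property
    def duration_days(self) -> float:
        dt = self.fixes[-1].time - self.fixes[0].time
        return dt.total_seconds() / 86400.0

    def __len__(self) -> int:
        return len(self.fixes)


@dataclass(frozen=True)
class GridSpec:
    """North-up rectilinear lon/lat grid. Values refer to cell centres."""

    west: float    # west edge of column 0
    north: float   # north edge of row 0
    dlon: float    # cell width, degrees (> 0)
    dlat: float    # cell height, degrees (> 0, rows run southward)
    nrow: int
    ncol: int

    def cell_lons(self) -> np.ndarray:
        return self.west + (np.arange(self.ncol) + 0.5) * self.dlon

    def cell_lats(self) -> np.ndarray:
        return self.north - (np.arange(self.nrow) + 0.5) * self.dlat

    def rowcol(self, lon, lat):
        """Indices of the cells containing the points (no interpolation)."""
        col = np.floor((np.asarray(lon, dtype=float) - self.west) / self.dlon).astype(int)
        row = np.floor((self.north - np.asarray(lat, dtype=float)) / self.dlat).astype(int)
        return row, col

    def contains(self, lon, lat):
        row, col = self.rowcol(lon, lat)
        return (row >= 0) & (row < self.nrow) & (col >= 0) & (col < self.ncol)

    @property
    def center_lat(self) -> float:
        return self.north - 0.5 * self.nrow * self.dlat

    def resolution_km(self) -> float:
        """Geometric-mean pixel size in km, evaluated at the grid centre."""
        dy = self.dlat * KM_PER_DEG
        dx = self.dlon * KM_PER_DEG * np.cos(np.radians(self.center_lat))
        return float(np.sqrt(dx * dy))


@dataclass
class EnvLayer:
    """A single georeferenced raster variable.

    ``grid`` is float with NaN flagging no-data cells; ``transform`` is the
    rectilinear :class:`GridSpec`. ``time_window`` is ``None`` for static
    layers, else a ``(start, end)`` pair of timestamps.
    """

    name: str
    grid: np.ndarray
    transform: GridSpec
    crs: str = "EPSG:4326"
    time_window: tuple[pd.Timestamp, pd.Timestamp] | None = None
    units: str = ""

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.shape != (self.transform.nrow, self.transform.ncol):
            raise ValueError("grid shape does not match transform")

    @property
    def resolution_km(self) -> float:
        return self.transform.resolution_km()

    @property
    def mask(self) -> np.ndarray:
        """True where the cell holds no data."""
        return np.isnan(self.grid)

    def sample(self, lon, lat) -> np.ndarray:
        """Value of the cell containing each point; NaN outside the grid."""
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        row, col = self.transform.rowcol(lon, lat)
        ok = self.transform.contains(lon, lat)
        out = np.full(lon.shape, np.nan)
        out[ok] = self.grid[row[ok], col[ok]]
        return out

    def with_grid(self, grid: np.ndarray, name: str | None = None) -> "EnvLayer":
        return replace(self, grid=np.asarray(grid, dtype=float),
                       name=self.name if name is None else name)


@dataclass
class Region:
    name: str
    polygon: BaseGeometry
    behaviour_scope: tuple[str, ...]
    precedence: int


@dataclass
class RegionSet:
    """Prioritised modelling regions; higher precedence wins on overlap."""

    regions: list[Region]

    def __post_init__(self):
        if len(self.regions) == 0:
            raise ValueError("empty RegionSet")
        prec = [r.precedence for r in self.regions]
        if len(set(prec)) != len(prec):
            raise ValueError("region precedences must be unique")
        for r in self.regions:
            if not r.polygon.is_valid:
                raise ValueError(f"invalid polygon for region {r.name}")

    def lookup(self, lon: float, lat: float, behaviour: str) -> str:
        """Highest-precedence region containing the point and scoping ``behaviour``."""
        pt = Point(lon, lat)
        best = None
        for r in self.regions:
            if behaviour in r.behaviour_scope and r.polygon.covers(pt):
                if best is None or r.precedence > best.precedence:
                    best = r
        return best.name if best is not None else "out_of_extent"

    def __getitem__(self, name: str) -> Region:
        for r in self.regions:
            if r.name == name:
                return r
        raise KeyError(name)


DEFAULT_COLUMNS = {
    "animal_id": "id", "time": "timestamp", "lon": "lon", "lat": "lat",
    "source": "source", "loc_class": "loc_class",
}


def read_track_csv(path, column_map: Mapping[str, str] | None = None) -> list[RawTrack]:
    """Read a telemetry CSV into one :class:`RawTrack` per animal.

    Rows with unparseable time/coordinates, out-of-range coordinates, or an
    inconsistent source/class pair are dropped and counted in the log.
    ``column_map`` maps the canonical field names (``animal_id``, ``time``,
    ``lon``, ``lat``, ``source``, ``loc_class``) onto the file's headers.
    """
    cmap = dict(DEFAULT_COLUMNS)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path)
    missing = [v for v in cmap.values() if v not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    df = df.rename(columns={v: k for k, v in cmap.items()})

    df["time"] = pd.to_datetime(df["time"], errors="coerce", utc=True).dt.tz_localize(None)
    df["lon"] = pd.to_numeric(df["lon"], errors="coerce")
    df["lat"] = pd.to_numeric(df["lat"], errors="coerce")
    df["source"] = df["source"].astype(str).str.lower()
    df["loc_class"] = df["loc_class"].astype(str).str.upper().str.strip()

    n0 = len(df)
    df = df.dropna(subset=["time", "lon", "lat"])
    df = df[(df["lat"] >= -90) & (df["lat"] <= 90)]
    df["lon"] = normalize_lon(df["lon"].to_numpy())
    ok_pair = ((df["source"] == "gps") & (df["loc_class"] == GPS_CLASS)) | (
        (df["source"] == "argos") & df["loc_class"].isin(ARGOS_CLASSES))
    df = df[ok_pair]
    dropped = n0 - len(df)
    if dropped:
        log.warning("read_track_csv: dropped %d invalid rows of %d", dropped, n0)
    if len(df) == 0:
        raise EmptyInputError(f"{path}: no valid rows")

    tracks = []
    for animal_id, g in df.groupby("animal_id", sort=True):
        g = g.sort_values("time")
        # collapse duplicate timestamps (keep first) so times strictly increase
        g = g[~g["time"].duplicated()]
        if len(g) < 2:
            log.warning("animal %s: fewer than 2 valid fixes, skipped", animal_id)
            continue
        fixes = [RawFix(str(animal_id), pd.Timestamp(r.time), float(r.lon),
                        float(r.lat), str(r.source), str(r.loc_class))
                 for r in g.itertuples()]
        tracks.append(RawTrack(str(animal_id), fixes))
    if not tracks:
        raise EmptyInputError(f"{path}: no animal with >= 2 valid fixes")
    return tracks


def write_track_csv(tracks: Sequence[RawTrack], path) -> None:
    rows = [{"id": t.animal_id, "timestamp": f.time.isoformat(), "lon": f.lon,
             "lat": f.lat, "source": f.source, "loc_class": f.loc_class}
            for t in tracks for f in t.fixes]
    pd.DataFrame(rows).to_csv(path, index=False)


def _layer_from_dataarray(da: xr.DataArray, name: str) -> EnvLayer:
    lats = da["lat"].values
    lons = da["lon"].values
    if lats[0] < lats[-1]:          # force north-up
        da = da.isel(lat=slice(None, None, -1))
        lats = da["lat"].values
    dlat = float(abs(lats[0] - lats[-1]) / (len(lats) - 1)) if len(lats) > 1 else 1.0
    dlon = float(abs(lons[-1] - lons[0]) / (len(lons) - 1)) if len(lons) > 1 else 1.0
    gs = GridSpec(west=float(lons[0] - dlon / 2), north=float(lats[0] + dlat / 2),
                  dlon=dlon, dlat=dlat, nrow=len(lats), ncol=len(lons))
    tw = None
    if "time_start" in da.attrs and "time_end" in da.attrs:
        tw = (pd.Timestamp(da.attrs["time_start"]), pd.Timestamp(da.attrs["time_end"]))
    crs = da.attrs.get("crs", "")
    if not crs:
        raise FormatError(f"layer {name!r} has no crs attribute")
    return EnvLayer(name=name, grid=da.values.astype(float), transform=gs,
                    crs=crs, time_window=tw, units=da.attrs.get("units", ""))


def read_env_layer(path, name: str) -> EnvLayer | list[EnvLayer]:
    """Read raster variable ``name`` from a NetCDF file.

    A 2-D (lat, lon) variable yields one :class:`EnvLayer`; a 3-D
    (time, lat, lon) variable yields one layer per time slice, each with its
    own ``time_window``.
    """
    with xr.open_dataset(path, engine="scipy") as ds:
        if name not in ds:
            raise FormatError(f"{path}: no variable {name!r}")
        da = ds[name].load()
    if "time" in da.dims:
        out = []
        for i in range(da.sizes["time"]):
            sl = da.isel(time=i)
            t = pd.Timestamp(sl["time"].values)
            sl = sl.drop_vars("time")
            sl.attrs.setdefault("time_start", t.isoformat())
            sl.attrs.setdefault("time_end", (t + pd.Timedelta(days=1)).isoformat())
            out.append(_layer_from_dataarray(sl, name))
        return out
    return _layer_from_dataarray(da, name)


def write_raster(layer: EnvLayer, path) -> None:
    """Write an :class:`EnvLayer` to NetCDF so :func:`read_env_layer` round-trips."""
    gs = layer.transform
    da = xr.DataArray(
        layer.grid,
        coords={"lat": gs.cell_lats(), "lon": gs.cell_lons()},
        dims=("lat", "lon"),
        name=layer.name,
        attrs={"crs": layer.crs, "units": layer.units},
    )
    if layer.time_window is not None:
        da.attrs["time_start"] = pd.Timestamp(layer.time_window[0]).isoformat()
        da.attrs["time_end"] = pd.Timestamp(layer.time_window[1]).isoformat()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    da.to_netcdf(path, engine="scipy")


def read_regions_geojson(path) -> RegionSet:
    """Load modelling regions from a GeoJSON FeatureCollection.

    Each feature needs properties ``name``, ``behaviour_scope`` (list) and
    ``precedence`` (int).
    """
    with open(path) as fh:
        gj = json.load(fh)
    regions = []
    for feat in gj.get("features", []):
        props = feat.get("properties", {})
        try:
            regions.append(Region(
                name=str(props["name"]),
                polygon=shape(feat["geometry"]),
                behaviour_scope=tuple(props["behaviour_scope"]),
                precedence=int(props["precedence"]),
            ))
        except KeyError as e:
            raise FormatError(f"{path}: feature missing property {e}") from e
    return RegionSet(regions)


def write_regions_geojson(rs: RegionSet, path) -> None:
    from shapely.geometry import mapping
    feats = [{"type": "Feature", "geometry": mapping(r.polygon),
              "properties": {"name": r.name, "behaviour_scope": list(r.behaviour_scope),
                             "precedence": r.precedence}}
             for r in rs.regions]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)
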