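"""Synthetic studies with recorded ground truth.

Generates a complete desk-scale study of a migratory marine megafauna
population on an eastern-boundary continental margin: a coastal bathymetry
with shelf / shelf-break / slope / basin zonation and canyon features,
dynamic SST, chlorophyll-a and sea-surface-height-anomaly fields, a known
("planted") logistic habitat-suitability surface, whales that alternate
between low-persistence area-restricted foraging bouts (entered and held
with probability rising in local habitat quality) and high-persistence
along-shore migration, and telemetry
observation with Argos class-specific error, irregular sampling and
transmission gaps. Every quantity needed to score a recovery test (true
suitability, per-step true persistence and behaviour, the planted effect
sizes) is recorded.

Defaults mirror the study conditions this pipeline targets: 38 tracks with
durations log-uniform between 8 and 384 days (median ~55), mixed Argos/GPS
observation, and >5-day gaps at a small daily probability.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import LineString, box

from .geo import KM_PER_DEG
from .io_formats import EnvLayer, GridSpec, RawFix, RawTrack, Region, RegionSet
from .track_processing import ARGOS_ERR95_KM, classify_behaviour

log = logging.getLogger(__name__)

ARGOS_DEFAULT_CLASS_PROBS = {"3": 0.10, "2": 0.15, "1": 0.20,
                             "0": 0.15, "A": 0.15, "B": 0.25}


@dataclass
class ScenarioConfig:
    """Knobs of the synthetic study; defaults are the study conditions."""

    seed: int = 0
    lon_min: float = 108.0
    lon_max: float = 116.0
    lat_min: float = -32.0
    lat_max: float = -14.0
    resolution_deg: float = 0.09          # ~10 km cells
    n_whales: int = 38
    duration_days_range: tuple[float, float] = (8.0, 384.0)
    true_beta: dict = field(default_factory=lambda: {
        "bathymetry": 3.0, "sst": 1.0, "intercept": -2.9})
    g_high: float = 0.92
    g_low: float = 0.3
    gap_prob: float = 0.02                # per-day chance of a > 5-day gap
    argos_fraction: float = 0.6
    class_probs: dict = field(default_factory=lambda: dict(ARGOS_DEFAULT_CLASS_PROBS))
    fixes_per_day: float = 4.0
    true_step_hours: float = 3.0
    start_date: str = "2022-03-01"
    start_window_days: int = 60
    # movement scales per true step
    v_migration_kmh: float = 4.0
    sigma_mig_km: float = 2.0
    sigma_ars_km: float = 3.0
    taxis_km: float = 2.5                 # ARS drift up the suitability gradient
    suitable_cut: float = 0.5             # quality scale for bout dynamics
    bout_mean_days: float = 6.0           # exponential foraging-bout duration
    refractory_mean_days: float = 3.0     # transit before the next bout
    bout_entry_prob: float = 0.5         # per-step entry chance inside a patch

    def __post_init__(self):
        if not (self.g_low < 0.8 <= self.g_high):
            raise ValueError("need g_low < 0.8 <= g_high")
        s = sum(self.class_probs.values())
        if abs(s - 1.0) > 1e-9:
            raise ValueError("class_probs must sum to 1")
        if not (0.0 <= self.argos_fraction <= 1.0 and 0.0 <= self.gap_prob <= 1.0):
            raise ValueError("probabilities must be valid")


@dataclass
class GroundTruth:
    true_suitability: EnvLayer
    true_tracks: list[pd.DataFrame]       # time, lon, lat, g_true, behaviour_true
    true_beta: dict


@dataclass
class Scenario:
    config: ScenarioConfig
    stacks: dict                          # name -> EnvLayer or list[EnvLayer]
    canyons: LineString
    regions: RegionSet
    extent: object                        # shapely polygon of the model extent
    tracks: list[RawTrack]
    truth: GroundTruth
    period: tuple[pd.Timestamp, pd.Timestamp]


def _grid_spec(cfg: ScenarioConfig) -> GridSpec:
    ncol = int(round((cfg.lon_max - cfg.lon_min) / cfg.resolution_deg))
    nrow = int(round((cfg.lat_max - cfg.lat_min) / cfg.resolution_deg))
    return GridSpec(west=cfg.lon_min, north=cfg.lat_max,
                    dlon=cfg.resolution_deg, dlat=cfg.resolution_deg,
                    nrow=nrow, ncol=ncol)


def _coast_lon(lats: np.ndarray, cfg: ScenarioConfig) -> np.ndarray:
    """Meandering coastline longitude (land to the east of it)."""
    amp = 0.06 * (cfg.lon_max - cfg.lon_min)
    return (cfg.lon_max - 0.12 * (cfg.lon_max - cfg.lon_min)
            + amp * np.sin(2.0 * np.pi * (lats - cfg.lat_min) / 9.0))


def _bathymetry(gs: GridSpec, cfg: ScenarioConfig, rng: np.random.Generator):
    """Depth (m, positive down), land mask and geomorphic classes.

    Cross-shore profile: shelf ramp 0-200 m over 80 km, slope ramp
    200-3800 m over the next 220 km, then flat basin; an along-shore
    texture (bounded, depth-proportional) keeps seafloor roughness from
    being a pure function of the cross-shore position while preserving
    monotone-offshore depth along every transect.
    """
    lons = gs.cell_lons()
    lats = gs.cell_lats()
    LON, LAT = np.meshgrid(lons, lats)
    coast = _coast_lon(lats, cfg)[:, None]
    x_km = (coast - LON) * KM_PER_DEG * np.cos(np.radians(LAT))  # offshore distance
    shelf_w, slope_w = 80.0, 220.0
    base = np.where(
        x_km < 0, np.nan,                                        # land
        np.where(x_km <= shelf_w, 200.0 * x_km / shelf_w,
                 np.where(x_km <= shelf_w + slope_w,
                          200.0 + 3600.0 * (x_km - shelf_w) / slope_w,
                          3800.0)))
    # along-shore roughness: two cosine harmonics, clipped so the
    # depth-proportional term never reverses the offshore gradient
    eta = np.zeros_like(lats)
    for _ in range(3):
        wl = rng.uniform(1.0, 2.5)
        eta += rng.normal(0, 0.5) * np.cos(2 * np.pi * lats / wl
                                           + rng.uniform(0, 2 * np.pi))
    eta = np.clip(eta, -1.5, 1.5)[:, None]
    depth = base + 300.0 * eta * np.minimum(base / 1000.0, 1.0)
    land = np.where(np.isnan(depth), 1.0, 0.0)
    geocls = np.where(np.isnan(depth), np.nan,
                      np.where(depth <= 200.0, 1.0,
                               np.where(depth <= 3000.0, 2.0, 3.0)))
    return depth, land, geocls


def _low_rank_modes(gs: GridSpec, n_modes: int, wavelength_deg: float, rng):
    """Mesoscale random spatial modes built from separable cosine bases.

    ``wavelength_deg`` sets the typical eddy scale; each mode is a plaid
    pattern with wavelengths within ~2x of it, so a sum of modes looks like
    a field of mesoscale anomalies rather than one domain-wide gradient.
    """
    lons = gs.cell_lons()
    lats = gs.cell_lats()
    modes = []
    for _ in range(n_modes):
        wx = wavelength_deg * rng.uniform(0.8, 2.0)
        wy = wavelength_deg * rng.uniform(0.8, 2.0)
        px, py = rng.uniform(0, 2 * np.pi, 2)
        m = np.outer(np.cos(2 * np.pi * lats / wy + py),
                     np.cos(2 * np.pi * lons / wx + px))
        modes.append(m / np.std(m))
    return np.stack(modes)


def _ar1_series(n_days: int, decorrelation_days: float, n_series: int, rng):
    a = np.exp(-1.0 / decorrelation_days)
    x = np.zeros((n_series, n_days))
    x[:, 0] = rng.normal(0, 1, n_series)
    innov = rng.normal(0, np.sqrt(1 - a * a), (n_series, n_days - 1))
    for t in range(1, n_days):
        x[:, t] = a * x[:, t - 1] + innov[:, t - 1]
    return x


def _sst_clim(LAT, day_of_year, cfg: ScenarioConfig):
    """Deterministic SST: latitudinal gradient plus a seasonal cycle."""
    base = 28.0 + 0.45 * (LAT - (-12.0))
    season = 1.0 * np.cos(2.0 * np.pi * (day_of_year - 45.0) / 365.25)
    return base + season


def make_env_stack(cfg: ScenarioConfig, period: tuple[pd.Timestamp, pd.Timestamp],
                   rng: np.random.Generator):
    """Static and daily environmental layers, plus canyon features.

    Returns (stacks, canyons). Daily dynamic layers: SST (gradient +
    seasonal cycle + slowly varying anomaly), chlorophyll-a (coastal
    enrichment, multiplicative anomalies with ~14-day autocorrelation) and
    SSHA (zero-mean low-rank Gaussian field with ~30-day autocorrelation).
    """
    gs = _grid_spec(cfg)
    depth, land, geocls = _bathymetry(gs, cfg, rng)
    lats = gs.cell_lats()
    lons = gs.cell_lons()
    LON, LAT = np.meshgrid(lons, lats)

    mk = lambda name, grid, units="": EnvLayer(name, grid, gs, units=units)
    stacks: dict = {
        "bathymetry": mk("bathymetry", depth, "m"),
        "land": mk("land", land),
        "geomorph": mk("geomorph", geocls),
    }

    # canyons: short cross-slope line features at fixed latitudes
    coast = _coast_lon(lats, cfg)
    canyon_lats = np.linspace(cfg.lat_min + 1.2, cfg.lat_max - 1.2, 9)
    lines = []
    for cl in canyon_lats:
        c_lon = float(np.interp(cl, lats[::-1], coast[::-1]))
        off0 = 60.0 / (KM_PER_DEG * np.cos(np.radians(cl)))
        off1 = 220.0 / (KM_PER_DEG * np.cos(np.radians(cl)))
        lines.append(LineString([(c_lon - off0, cl), (c_lon - off1, cl - 0.3)]))
    from shapely.ops import unary_union
    canyons = unary_union(lines)

    days = pd.date_range(period[0].normalize(), period[1].normalize(), freq="D")
    doy = days.dayofyear.to_numpy()

    sst_modes = _low_rank_modes(gs, 8, 2.0, rng)
    sst_amp = _ar1_series(len(days), 12.0, 8, rng) * (0.8 / np.sqrt(8))
    chl_modes = _low_rank_modes(gs, 8, 1.5, rng)
    chl_amp = _ar1_series(len(days), 14.0, 8, rng) * (0.4 / np.sqrt(8))
    ssha_modes = _low_rank_modes(gs, 10, 1.5, rng)
    ssha_amp = _ar1_series(len(days), 30.0, 10, rng) * (0.05 / np.sqrt(10))

    coast_col = coast[:, None]
    x_km = np.maximum((coast_col - LON) * KM_PER_DEG * np.cos(np.radians(LAT)), 0.0)
    chl_base = 0.08 + 0.6 * np.exp(-x_km / 60.0)
    ocean = land < 0.5

    sst_list, chl_list, ssha_list = [], [], []
    for i, day in enumerate(days):
        tw = (pd.Timestamp(day), pd.Timestamp(day) + pd.Timedelta(days=1))
        sst = _sst_clim(LAT, doy[i], cfg) + np.tensordot(sst_amp[:, i], sst_modes, 1)
        chl = chl_base * np.exp(np.tensordot(chl_amp[:, i], chl_modes, 1))
        ssha = np.tensordot(ssha_amp[:, i], ssha_modes, 1)
        for arr in (sst, chl, ssha):
            arr[~ocean] = np.nan
        sst_list.append(EnvLayer("sst", sst, gs, time_window=tw, units="degC"))
        chl_list.append(EnvLayer("chl", chl, gs, time_window=tw, units="mg m-3"))
        ssha_list.append(EnvLayer("ssha", ssha, gs, time_window=tw, units="m"))
    stacks["sst"] = sst_list
    stacks["chl"] = chl_list
    stacks["ssha"] = ssha_list
    return stacks, canyons


def true_suitability_layer(cfg: ScenarioConfig, stacks: dict,
                           period: tuple[pd.Timestamp, pd.Timestamp]) -> EnvLayer:
    """Planted habitat suitability: logistic in a slope-band depth feature
    and a monotone warm-water SST feature (climatological mean over the
    period).

    suitability = sigmoid(b_bathy * f_depth + b_sst * f_sst + b0) with
    f_depth = exp(-((depth - 700)/500)^2)   (slope-band preference) and
    f_sst = clip((sst - 19)/9, 0, 1)        (warm-water preference across
    the study domain's SST range), both in [0, 1].
    """
    gs = stacks["bathymetry"].transform
    depth = stacks["bathymetry"].grid
    LON, LAT = np.meshgrid(gs.cell_lons(), gs.cell_lats())
    mid = period[0] + (period[1] - period[0]) / 2
    sst = _sst_clim(LAT, float(pd.Timestamp(mid).dayofyear), cfg)
    f_depth = np.exp(-(((depth - 700.0) / 500.0) ** 2))
    f_sst = np.clip((sst - 19.0) / 9.0, 0.0, 1.0)
    beta = cfg.true_beta
    eta = beta["bathymetry"] * f_depth + beta["sst"] * f_sst + beta["intercept"]
    suit = 1.0 / (1.0 + np.exp(-eta))
    suit[~np.isfinite(depth)] = np.nan
    return EnvLayer("true_suitability", suit, gs)


def simulate_whale(suit: EnvLayer, land: EnvLayer, cfg: ScenarioConfig,
                   duration_days: float, t_start: pd.Timestamp,
                   rng: np.random.Generator) -> pd.DataFrame:
    """One noise-free regular track with per-step true persistence.

    Behavioural coupling with bout hysteresis: encountering suitable
    habitat (true suitability above ``suitable_cut``) starts a
    low-persistence area-restricted foraging bout of exponential duration,
    during which a weak taxis up the suitability gradient holds the whale
    near the patch; the bout is cut short if the whale drifts well outside
    suitable habitat. Between bouts the whale migrates along-shore with
    high persistence, with a refractory transit period before the next
    bout can start. The walk is reflected off land and the extent edges; a
    trapped walker is restarted from a fresh suitable cell.
    """
    gs = suit.transform
    step_h = cfg.true_step_hours
    n_steps = int(round(duration_days * 24.0 / step_h))
    ok = np.isfinite(suit.grid) & (suit.grid > cfg.suitable_cut)
    rows, cols = np.nonzero(ok)
    if len(rows) == 0:
        raise ValueError("no suitable start cell in scenario")
    # tagging happens at aggregations: start-cell probability scales with
    # habitat quality, not uniformly over all suitable cells
    start_w = suit.grid[rows, cols] ** 2
    start_w = start_w / start_w.sum()

    # suitability gradient (per km) for area-restricted taxis
    sg = np.nan_to_num(suit.grid, nan=0.0)
    gy_deg, gx_deg = np.gradient(sg, -gs.dlat, gs.dlon)
    lat_c = gs.center_lat
    gx_km = gx_deg / (KM_PER_DEG * np.cos(np.radians(lat_c)))
    gy_km = gy_deg / KM_PER_DEG

    def taxis(lon, lat):
        r, c = gs.rowcol(lon, lat)
        if not (0 <= r < gs.nrow and 0 <= c < gs.ncol):
            return np.zeros(2)
        v = np.array([gx_km[r, c], gy_km[r, c]])
        nrm = np.linalg.norm(v)
        return cfg.taxis_km * v / nrm if nrm > 1e-12 else np.zeros(2)

    for _restart in range(10):
        i = rng.choice(len(rows), p=start_w)
        lon = float(gs.cell_lons()[cols[i]])
        lat = float(gs.cell_lats()[rows[i]])
        d = rng.normal(0, cfg.sigma_ars_km, 2)          # km step vector (E, N)
        direction = 1.0 if rng.random() < 0.7 else -1.0  # mostly northbound
        out_lon, out_lat, out_g = [lon], [lat], []
        stuck = 0
        steps_per_day = 24.0 / step_h
        foraging = True        # deployments happen at known aggregations
        refractory = 0
        for t in range(n_steps):
            s_here = suit.sample(lon, lat)[0]
            s_val = float(s_here) if np.isfinite(s_here) else 0.0
            in_patch = s_val > cfg.suitable_cut
            if foraging:
                # quality-dependent giving-up: poor patches are left sooner
                # (mean residence = bout_mean_days at s = suitable_cut,
                # scaling with local suitability), and a whale that drifts
                # well off suitable habitat abandons the bout at once
                quality = np.clip(s_val / cfg.suitable_cut, 0.25, 2.5) ** 2
                leave_p = 1.0 / (cfg.bout_mean_days * steps_per_day * quality)
                if s_val < 0.2 * cfg.suitable_cut or rng.random() < leave_p:
                    foraging = False
                    refractory = int(rng.exponential(
                        cfg.refractory_mean_days * steps_per_day)) + 1
            elif refractory > 0:
                refractory -= 1
            else:
                # bout entry anywhere, with probability rising steeply in
                # local suitability: usage is a monotone dose-response of
                # habitat quality, not a hard patch threshold
                p_enter = cfg.bout_entry_prob * min(
                    (s_val / cfg.suitable_cut) ** 2, 1.8)
                if rng.random() < p_enter:
                    foraging = True
            ars = foraging
            g = cfg.g_low if ars else cfg.g_high
            mu = (np.array([0.0, direction * cfg.v_migration_kmh * step_h])
                  if not ars else taxis(lon, lat))
            sigma = cfg.sigma_ars_km if ars else cfg.sigma_mig_km
            for _try in range(25):
                cand = g * d + (1.0 - g) * mu + rng.normal(0, sigma, 2)
                nlon = lon + cand[0] / (KM_PER_DEG * np.cos(np.radians(lat)))
                nlat = lat + cand[1] / KM_PER_DEG
                on_land = np.isfinite(land.sample(nlon, nlat)[0]) and \
                    land.sample(nlon, nlat)[0] > 0.5
                inside = (gs.west < nlon < gs.west + gs.ncol * gs.dlon) and \
                    (gs.north - gs.nrow * gs.dlat < nlat < gs.north)
                if inside and not on_land:
                    break
                cand = -0.5 * cand                       # reflect and damp
            else:
                stuck += 1
                cand = np.zeros(2)
                nlon, nlat = lon, lat
            # turn around near the N/S extent edges
            if nlat > gs.north - 1.0:
                direction = -1.0
            elif nlat < gs.north - gs.nrow * gs.dlat + 1.0:
                direction = 1.0
            d = cand
            lon, lat = float(nlon), float(nlat)
            out_lon.append(lon)
            out_lat.append(lat)
            out_g.append(g)
        if stuck < n_steps // 4:
            break
        log.warning("simulate_whale: trapped walker, resampling start")
    times = [t_start + pd.Timedelta(hours=step_h * k) for k in range(n_steps + 1)]
    g_full = np.array([out_g[0]] + out_g)
    beh = [classify_behaviour(g if g < 0.8 else 1.0, la)
           for g, la in zip(g_full, out_lat)]
    return pd.DataFrame({"time": times, "lon": out_lon, "lat": out_lat,
                         "g_true": g_full, "behaviour_true": beh})


def add_observation_noise(true_track: pd.DataFrame, cfg: ScenarioConfig,
                          rng: np.random.Generator,
                          err_table: dict[str, float] = ARGOS_ERR95_KM,
                          animal_id: str = "w") -> RawTrack:
    """Telemetry observation: Poisson daily thinning, class-specific
    Gaussian error, and occasional > 5-day transmission gaps."""
    t0 = pd.Timestamp(true_track["time"].iloc[0])
    t1 = pd.Timestamp(true_track["time"].iloc[-1])
    n_days = max(int(np.ceil((t1 - t0) / pd.Timedelta(days=1))), 1)
    tt = (pd.to_datetime(true_track["time"]) - t0) / pd.Timedelta(hours=1)
    tt = tt.to_numpy()

    classes = list(cfg.class_probs.keys())
    probs = np.array([cfg.class_probs[c] for c in classes])

    fixes = []
    day = 0
    while day < n_days:
        if rng.random() < cfg.gap_prob:
            day += int(rng.uniform(5.0, 10.0)) + 1   # transmission gap
            continue
        k = rng.poisson(cfg.fixes_per_day)
        hours = np.sort(rng.uniform(day * 24.0, (day + 1) * 24.0, k))
        for h in hours:
            if h > tt[-1]:
                continue
            lon = float(np.interp(h, tt, true_track["lon"]))
            lat = float(np.interp(h, tt, true_track["lat"]))
            if rng.random() < cfg.argos_fraction:
                cls = classes[rng.choice(len(classes), p=probs)]
                src = "argos"
            else:
                cls, src = "G", "gps"
            sigma_km = err_table[cls] / 1.96
            dx, dy = rng.normal(0, sigma_km, 2)
            lon += dx / (KM_PER_DEG * np.cos(np.radians(lat)))
            lat += dy / KM_PER_DEG
            fixes.append(RawFix(animal_id, t0 + pd.Timedelta(hours=float(h)),
                                lon, lat, src, cls))
        day += 1
    if len(fixes) < 2:   # degenerate observation draw: keep first/last truth
        fixes = [RawFix(animal_id, t0, float(true_track["lon"].iloc[0]),
                        float(true_track["lat"].iloc[0]), "gps", "G"),
                 RawFix(animal_id, t1, float(true_track["lon"].iloc[-1]),
                        float(true_track["lat"].iloc[-1]), "gps", "G")]
    return RawTrack(animal_id, fixes)


def _draw_study_frame(cfg: ScenarioConfig):
    """Deployment dates, durations and the study period (seed-deterministic)."""
    rng = np.random.default_rng(cfg.seed)
    start0 = pd.Timestamp(cfg.start_date)
    starts = [start0 + pd.Timedelta(days=float(d))
              for d in np.sort(rng.uniform(0, cfg.start_window_days, cfg.n_whales))]
    lo, hi = cfg.duration_days_range
    durations = np.exp(rng.uniform(np.log(lo), np.log(hi), cfg.n_whales))
    period = (start0 - pd.Timedelta(days=31),
              max(s + pd.Timedelta(days=float(d)) for s, d in zip(starts, durations))
              + pd.Timedelta(days=1))
    return rng, starts, durations, period


def regenerate_env(cfg: ScenarioConfig):
    """Rebuild the environmental stacks of a recorded scenario config.

    Dynamic daily fields are deterministic functions of the config seed, so
    a materialized study only needs to store the config, not the fields.
    Returns (stacks, canyons, period).
    """
    rng, _starts, _durations, period = _draw_study_frame(cfg)
    stacks, canyons = make_env_stack(cfg, period, rng)
    return stacks, canyons, period


def margin_extent(cfg: ScenarioConfig, offshore_km: float = 500.0):
    """Regional model extent: the continental margin plus a basin buffer.

    Habitat models for a margin-associated species are bounded by a
    regional extent around the data rather than an arbitrary rectangle, to
    avoid extrapolating into open-ocean areas the design never samples.
    The polygon runs from the coast to ``offshore_km`` seaward of it.
    """
    from shapely.geometry import Polygon
    lats = np.linspace(cfg.lat_min, cfg.lat_max, 80)
    coast = _coast_lon(lats, cfg)
    west = coast - offshore_km / (KM_PER_DEG * np.cos(np.radians(lats)))
    east_pts = [(float(max(c, cfg.lon_min)), float(la))
                for c, la in zip(coast + 0.5, lats)]
    west_pts = [(float(max(w, cfg.lon_min)), float(la))
                for w, la in zip(west, lats)]
    poly = Polygon(west_pts + east_pts[::-1])
    return poly.intersection(box(cfg.lon_min, cfg.lat_min,
                                 cfg.lon_max, cfg.lat_max))


def make_scenario(cfg: ScenarioConfig | None = None,
                  out_dir: str | Path | None = None) -> Scenario:
    """Generate a full synthetic study; deterministic under ``cfg.seed``.

    With ``out_dir`` the study is also materialized to disk (tracks.csv,
    rasters/*.nc, truth/).
    """
    cfg = cfg or ScenarioConfig()
    rng, starts, durations, period = _draw_study_frame(cfg)
    stacks, canyons = make_env_stack(cfg, period, rng)
    suit = true_suitability_layer(cfg, stacks, period)

    true_tracks = []
    tracks = []
    for w in range(cfg.n_whales):
        tt = simulate_whale(suit, stacks["land"], cfg, float(durations[w]),
                            starts[w], rng)
        true_tracks.append(tt)
        tracks.append(add_observation_noise(tt, cfg, rng, animal_id=f"whale_{w:02d}"))

    extent = box(cfg.lon_min, cfg.lat_min, cfg.lon_max, cfg.lat_max)
    margin = margin_extent(cfg)
    regions = RegionSet([
        Region("study_foraging", margin, ("foraging", "foraging_reproduction"), 2),
        Region("study_migration", margin, ("migration",), 1),
    ])
    truth = GroundTruth(suit, true_tracks, dict(cfg.true_beta))
    scen = Scenario(cfg, stacks, canyons, regions, extent, tracks, truth, period)
    if out_dir is not None:
        write_scenario(scen, out_dir)
    return scen


def write_scenario(scen: Scenario, out_dir: str | Path) -> None:
    from .io_formats import write_raster, write_regions_geojson, write_track_csv
    out = Path(out_dir)
    (out / "rasters").mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    write_track_csv(scen.tracks, out / "tracks.csv")
    for name in ("bathymetry", "land", "geomorph"):
        write_raster(scen.stacks[name], out / "rasters" / f"{name}.nc")
    write_raster(scen.truth.true_suitability, out / "truth" / "true_suitability.nc")
    write_regions_geojson(scen.regions, out / "regions.geojson")
    pd.concat([t.assign(whale=i) for i, t in enumerate(scen.truth.true_tracks)]
              ).to_csv(out / "truth" / "true_tracks.csv", index=False)
    with open(out / "truth" / "true_beta.json", "w") as fh:
        json.dump(scen.truth.true_beta, fh, indent=2)


def true_state_at(true_track: pd.DataFrame, times) -> pd.DataFrame:
    """Ground-truth g/behaviour at arbitrary times (nearest true step)."""
    tt = pd.to_datetime(true_track["time"]).to_numpy()
    q = pd.to_datetime(times).to_numpy()
    idx = np.clip(np.searchsorted(tt, q), 0, len(tt) - 1)
    left = np.clip(idx - 1, 0, len(tt) - 1)
    use_left = np.abs(q - tt[left]) <= np.abs(tt[idx] - q)
    idx = np.where(use_left, left, idx)
    return true_track.iloc[idx][["g_true", "behaviour_true"]].reset_index(drop=True)
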