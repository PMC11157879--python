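"""Stage 2: constrained pseudo-absence (availability) track simulation.

The use-availability design contrasts each observed track against simulated
tracks representing where the animal could plausibly have gone. A pseudo
track starts at the real track's first location, has the same number of
steps and timestamps, resamples the real track's empirical step-length and
turning-angle distributions, is oriented toward the real track's end point,
and is perturbed by a uniform turning-angle offset (full width 180 or 300
degrees) that keeps simulated tracks from locking into coastal bays.
Candidates on land or outside the model extent are rejected and resampled.
Five pseudo tracks per real track give the model five pseudo-absence rows
per presence row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Point
from shapely.geometry.base import BaseGeometry

from .geo import (destination_point, haversine_km, initial_bearing_rad,
                  turn_angles_rad, wrap_angle)
from .io_formats import EnvLayer
from .track_processing import SSMTrack

log = logging.getLogger(__name__)

OFFSET_CHOICES_DEG = (180.0, 300.0)


class SimulationFailure(RuntimeError):
    """A pseudo track could not be placed after the retry budget."""


@dataclass
class MovementMetrics:
    """Empirical movement summaries of one smoothed track segment."""

    step_lengths_km: np.ndarray
    turn_angles_rad: np.ndarray
    n_steps: int
    start: tuple[float, float]      # (lon, lat)
    end: tuple[float, float]
    step_hours: float
    behaviour_sequence: list[str]
    times: list[pd.Timestamp]
    animal_id: str = ""

    def __post_init__(self):
        if self.step_lengths_km.size == 0 or self.turn_angles_rad.size == 0:
            raise ValueError("empty movement samples")
        if self.n_steps != len(self.behaviour_sequence) - 1 or self.n_steps < 2:
            raise ValueError("inconsistent step/behaviour counts")


@dataclass
class PseudoTrack:
    source_animal_id: str
    replicate: int
    locations: list[tuple[pd.Timestamp, float, float, str]]  # time, lon, lat, behaviour
    offset_deg: float
    seed: int

    @property
    def lons(self) -> np.ndarray:
        return np.array([p[1] for p in self.locations])

    @property
    def lats(self) -> np.ndarray:
        return np.array([p[2] for p in self.locations])


def extract_metrics(track: SSMTrack) -> MovementMetrics:
    """Empirical step lengths (km), signed turns, endpoints and behaviours."""
    if len(track) < 3:
        raise ValueError("extract_metrics needs >= 3 locations")
    lons, lats = track.lons, track.lats
    steps = haversine_km(lons[:-1], lats[:-1], lons[1:], lats[1:])
    turns = turn_angles_rad(lons, lats)
    return MovementMetrics(
        step_lengths_km=np.asarray(steps, dtype=float),
        turn_angles_rad=np.asarray(turns, dtype=float),
        n_steps=len(track) - 1,
        start=(float(lons[0]), float(lats[0])),
        end=(float(lons[-1]), float(lats[-1])),
        step_hours=track.step_hours,
        behaviour_sequence=[p.behaviour for p in track.locations],
        times=[p.time for p in track.locations],
        animal_id=track.animal_id,
    )


def _on_land(land_mask: EnvLayer | None, lon: float, lat: float) -> bool:
    if land_mask is None:
        return False
    v = land_mask.sample(lon, lat)[0]
    return bool(np.isfinite(v) and v > 0.5)


def simulate_pseudo_track(metrics: MovementMetrics, extent: BaseGeometry,
                          land_mask: EnvLayer | None, offset_deg: float,
                          bias_weight: float = 0.25,
                          rng_seed: int = 0,
                          max_attempts: int = 100) -> PseudoTrack:
    """Simulate one constrained, endpoint-oriented pseudo track.

    At each step the heading is a circular blend (weight ``bias_weight``) of
    the correlated-walk heading (previous heading plus a resampled turn) and
    the great-circle bearing to the source track's end point, then jittered
    by U(-offset/2, +offset/2). Step lengths are resampled with replacement.
    A candidate on land or outside ``extent`` is resampled up to
    ``max_attempts`` times, after which the heading is reflected toward the
    extent centroid; if even that fails repeatedly the simulation errors.
    """
    if offset_deg not in OFFSET_CHOICES_DEG:
        raise ValueError(f"offset_deg must be one of {OFFSET_CHOICES_DEG}")
    if not (0.0 <= bias_weight <= 1.0):
        raise ValueError("bias_weight in [0, 1]")
    lon, lat = metrics.start
    if not extent.covers(Point(lon, lat)):
        raise ValueError("start point outside extent")
    if _on_land(land_mask, lon, lat):
        raise ValueError("start point on land")

    rng = np.random.default_rng(rng_seed)
    end_lon, end_lat = metrics.end
    half = np.radians(offset_deg) / 2.0
    centroid = extent.centroid

    heading = initial_bearing_rad(lon, lat, end_lon, end_lat)
    out = [(metrics.times[0], lon, lat, metrics.behaviour_sequence[0])]
    hard_failures = 0
    for i in range(metrics.n_steps):
        placed = False
        for attempt in range(max_attempts + 1):
            if attempt < max_attempts:
                turn = rng.choice(metrics.turn_angles_rad)
                step = rng.choice(metrics.step_lengths_km)
                crw_heading = heading + turn
                to_end = initial_bearing_rad(lon, lat, end_lon, end_lat)
                # circular weighted blend of the two headings
                blended = np.arctan2(
                    (1 - bias_weight) * np.sin(crw_heading) + bias_weight * np.sin(to_end),
                    (1 - bias_weight) * np.cos(crw_heading) + bias_weight * np.cos(to_end))
                cand_heading = blended + rng.uniform(-half, half)
            else:
                # reflection fallback: head straight for the extent centroid
                step = float(np.median(metrics.step_lengths_km))
                cand_heading = initial_bearing_rad(lon, lat, centroid.x, centroid.y)
            nlon, nlat = destination_point(lon, lat, cand_heading, step)
            nlon, nlat = float(nlon), float(nlat)
            if extent.covers(Point(nlon, nlat)) and not _on_land(land_mask, nlon, nlat):
                lon, lat = nlon, nlat
                heading = float(wrap_angle(cand_heading))
                placed = True
                break
        if not placed:
            hard_failures += 1
            if hard_failures * max_attempts >= 100 * metrics.n_steps:
                raise SimulationFailure(
                    f"{metrics.animal_id}: stuck after {hard_failures} reflection failures")
            # stay in place for this step (degenerate but bounded)
        out.append((metrics.times[i + 1], lon, lat, metrics.behaviour_sequence[i + 1]))
    return PseudoTrack(metrics.animal_id, 0, out, offset_deg, rng_seed)


def _snap_off_land(land_mask: EnvLayer | None, lon: float, lat: float,
                   max_cells: int = 5) -> tuple[float, float] | None:
    """Nearest in-water cell centre within ``max_cells`` (smoothing can put
    a track's first location marginally on land)."""
    if not _on_land(land_mask, lon, lat):
        return lon, lat
    gs = land_mask.transform
    r0, c0 = gs.rowcol(lon, lat)
    best = None
    for dr in range(-max_cells, max_cells + 1):
        for dc in range(-max_cells, max_cells + 1):
            r, c = int(r0 + dr), int(c0 + dc)
            if not (0 <= r < gs.nrow and 0 <= c < gs.ncol):
                continue
            if land_mask.grid[r, c] > 0.5:
                continue
            d2 = dr * dr + dc * dc
            if best is None or d2 < best[0]:
                best = (d2, float(gs.cell_lons()[c]), float(gs.cell_lats()[r]))
    return None if best is None else (best[1], best[2])


def generate_design(tracks: list[SSMTrack], extent_by_region: dict[str, BaseGeometry],
                    land_mask: EnvLayer | None = None, n_per_track: int = 5,
                    bias_weight: float = 0.25, seed: int = 0) -> pd.DataFrame:
    """Presence rows plus ``n_per_track`` full-length pseudo tracks per track.

    Each pseudo track mirrors its whole source segment (same length and
    timestamps) and every simulated location inherits the source location's
    behaviour label and region tag element-wise; the per-behaviour models
    later slice rows by those inherited tags. Returns the design table with
    columns row_id, animal_id, replicate (0 = presence), time, lon, lat,
    behaviour, region, label, offset_deg, seed; the per-track offset (180
    or 300 degrees) and every RNG seed are recorded.
    """
    from shapely.ops import unary_union

    rng = np.random.default_rng(seed)
    rows = []
    for track in tracks:
        present = {p.region for p in track.locations} - {"out_of_extent"}
        polys = [extent_by_region[r] for r in present if r in extent_by_region]
        if not polys:
            log.warning("%s: no modelling region, skipped", track.animal_id)
            continue
        extent = unary_union(polys)
        for p in track.locations:
            rows.append({"animal_id": track.animal_id, "replicate": 0,
                         "time": p.time, "lon": p.lon, "lat": p.lat,
                         "behaviour": p.behaviour, "region": p.region,
                         "label": 1, "offset_deg": np.nan, "seed": np.nan})
        metrics = extract_metrics(track)
        snapped = _snap_off_land(land_mask, *metrics.start)
        if snapped is None:
            log.warning("%s: start stuck on land, pseudo tracks skipped",
                        track.animal_id)
            continue
        metrics.start = snapped
        offset = float(rng.choice(OFFSET_CHOICES_DEG))
        src_regions = [p.region for p in track.locations]
        for rep in range(1, n_per_track + 1):
            rep_seed = int(rng.integers(0, 2**31 - 1))
            try:
                pt = simulate_pseudo_track(metrics, extent, land_mask, offset,
                                           bias_weight, rep_seed)
            except (SimulationFailure, ValueError) as e:
                log.warning("%s replicate %d failed: %s", track.animal_id, rep, e)
                continue
            pt.replicate = rep
            for (t, lo, la, beh), reg in zip(pt.locations, src_regions):
                rows.append({"animal_id": track.animal_id, "replicate": rep,
                             "time": t, "lon": lo, "lat": la, "behaviour": beh,
                             "region": reg, "label": 0,
                             "offset_deg": offset, "seed": rep_seed})
    df = pd.DataFrame(rows)
    if len(df):
        df = df[df["region"] != "out_of_extent"].reset_index(drop=True)
    df.insert(0, "row_id", np.arange(len(df)))
    return df


def clip_to_extent(points: pd.DataFrame, extent: BaseGeometry) -> pd.DataFrame:
    """Drop rows whose (lon, lat) falls outside ``extent`` (closed boundary)."""
    keep = np.array([extent.covers(Point(lo, la))
                     for lo, la in zip(points["lon"], points["lat"])])
    dropped = int((~keep).sum())
    if dropped:
        log.info("clip_to_extent: removed %d of %d points", dropped, len(points))
    return points[keep].reset_index(drop=True)
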