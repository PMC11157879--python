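"""Stage 1: irregular, error-prone fixes -> regular smoothed tracks with
per-location move persistence, behaviour labels and region assignments.

The smoother is a discrete-time correlated-random-walk MAP estimator: latent
positions on a regular time grid follow

    x_{t+1} = x_t + phi * (x_t - x_{t-1}) + eta_t,   eta_t ~ N(0, sigma_p^2 I)

with fixed persistence-in-velocity ``phi`` and ``sigma_p`` profiled from the
data, and each observed fix is a Gaussian measurement of the linearly
interpolated latent position with a class-specific error scale (95th-centile
Argos radii divided by 1.96). For fixed variances this is a sparse linear
least-squares problem, solved exactly; the variance profile is iterated to a
fixed point.

Move persistence g in [0, 1] indexes autocorrelation in speed and direction:
displacements follow d_{t+1} ~ N(g_t * d_t, sigma_d^2 I) with logit(g)
evolving as a Gaussian random walk. The MAP path of g is found by
quasi-Newton optimisation with the two variances profiled by alternation.
Low g marks area-restricted behaviour (foraging / reproduction), high g
directed travel (migration); locations are labelled by a threshold on g
(default 0.8).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.linalg import solveh_banded
from scipy.optimize import minimize
from shapely.geometry import box

from .geo import KM_PER_DEG
from .io_formats import RawFix, RawTrack, Region, RegionSet

log = logging.getLogger(__name__)

#: 95th-percentile location error (km) per Argos class; GPS ("G") errors are
#: of the order of tens of metres.
ARGOS_ERR95_KM: dict[str, float] = {
    "3": 1.5, "2": 3.3, "1": 7.6, "0": 36.0,
    "A": 60.0, "B": 163.0, "Z": 220.0, "G": 0.03,
}

#: divisors of 24 used as admissible regular time steps (hours)
_STEP_CHOICES = np.array([1, 2, 3, 4, 6, 8, 12, 24], dtype=float)

BEHAVIOURS = ("foraging", "foraging_reproduction", "migration")


class DegenerateInputError(ValueError):
    """Input too small or too degenerate for the requested operation."""


@dataclass
class SSMLocation:
    time: pd.Timestamp
    lon: float
    lat: float
    g: float = np.nan
    behaviour: str = ""
    region: str = ""


@dataclass
class SSMTrack:
    """Regular-time-step smoothed track segment."""

    animal_id: str
    segment_id: int
    step_hours: float
    locations: list[SSMLocation]
    converged: bool = True
    neg_log_posterior: float = np.nan

    @property
    def lons(self) -> np.ndarray:
        return np.array([p.lon for p in self.locations])

    @property
    def lats(self) -> np.ndarray:
        return np.array([p.lat for p in self.locations])

    @property
    def times(self) -> np.ndarray:
        return np.array([p.time.to_datetime64() for p in self.locations])

    @property
    def g(self) -> np.ndarray:
        return np.array([p.g for p in self.locations])

    def __len__(self) -> int:
        return len(self.locations)


def split_on_gaps(track: RawTrack, max_gap_days: float = 5.0) -> list[RawTrack]:
    """Split a track at transmission gaps longer than ``max_gap_days``.

    Within each returned segment every inter-fix gap is <= ``max_gap_days``;
    the fixes are partitioned exactly and order is preserved. Fragments with
    fewer than 2 fixes are still returned as RawTrack-like fragments only if
    valid; single-fix fragments are dropped with a warning.
    """
    times = track.times.astype("datetime64[s]").astype(float)
    gaps_days = np.diff(times) / 86400.0
    cut_after = np.nonzero(gaps_days > max_gap_days)[0]
    bounds = [0, *(cut_after + 1), len(track.fixes)]
    segments = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        chunk = track.fixes[a:b]
        if len(chunk) < 2:
            log.warning("split_on_gaps: %s dropped single-fix fragment", track.animal_id)
            continue
        segments.append(RawTrack(track.animal_id, list(chunk), track.deploy_site))
    return segments


def choose_time_step(track: RawTrack) -> float:
    """Regular time step (hours) matched to the tag's mean daily fix rate.

    step = 24 / (fixes per day), clamped to [1, 24] h and rounded to the
    nearest divisor of 24 so the grid aligns with whole days.
    """
    dur = track.duration_days
    if dur <= 0:
        raise DegenerateInputError("track has zero duration")
    per_day = len(track) / dur
    raw = float(np.clip(24.0 / per_day, 1.0, 24.0))
    return float(_STEP_CHOICES[np.argmin(np.abs(_STEP_CHOICES - raw))])


def _obs_sigma_deg(fixes: list[RawFix], err_table: dict[str, float]):
    """Per-fix observation sigmas in degrees (lon, lat axes)."""
    err95 = np.array([err_table[f.loc_class] for f in fixes])
    sigma_km = err95 / 1.96
    lats = np.array([f.lat for f in fixes])
    sig_lat = sigma_km / KM_PER_DEG
    sig_lon = sigma_km / (KM_PER_DEG * np.maximum(np.cos(np.radians(lats)), 0.05))
    return sig_lon, sig_lat


def fit_ssm(segment: RawTrack, step_hours: float,
            err_table: dict[str, float] = ARGOS_ERR95_KM,
            phi: float = 0.7, n_profile_iter: int = 20,
            grad_tol: float = 1e-5) -> SSMTrack:
    """MAP-smooth one gap-free segment onto a regular time grid.

    Returns an :class:`SSMTrack` with ``g`` unset. Raises
    :class:`DegenerateInputError` for segments of fewer than 5 fixes.
    """
    if len(segment) < 5:
        raise DegenerateInputError("fit_ssm needs >= 5 fixes")
    if not (0.0 <= phi < 1.0):
        raise ValueError("phi must be in [0, 1)")

    t0 = segment.fixes[0].time
    step = pd.Timedelta(hours=step_hours)
    obs_t = (segment.times - t0.to_datetime64()) / np.timedelta64(1, "h")
    n_states = int(np.ceil(obs_t[-1] / step_hours)) + 1
    n_states = max(n_states, 3)
    grid_t = np.arange(n_states) * step_hours

    # interpolation weights: obs i sits between states k and k+1
    k = np.clip((obs_t / step_hours).astype(int), 0, n_states - 2)
    w = np.clip(obs_t / step_hours - k, 0.0, 1.0)
    n_obs = len(obs_t)
    rows = np.repeat(np.arange(n_obs), 2)
    cols = np.stack([k, k + 1], axis=1).ravel()
    vals = np.stack([1.0 - w, w], axis=1).ravel()
    H = sp.csr_matrix((vals, (rows, cols)), shape=(n_obs, n_states))

    # second-difference (CRW) penalty operator: x_{t+1} - (1+phi) x_t + phi x_{t-1}
    n_proc = n_states - 2
    if n_proc > 0:
        i = np.repeat(np.arange(n_proc), 3)
        j = np.stack([np.arange(n_proc), np.arange(n_proc) + 1,
                      np.arange(n_proc) + 2], axis=1).ravel()
        v = np.tile([phi, -(1.0 + phi), 1.0], n_proc)
        D = sp.csr_matrix((v, (i, j)), shape=(n_proc, n_states))
    else:
        D = sp.csr_matrix((0, n_states))

    sig_lon, sig_lat = _obs_sigma_deg(segment.fixes, err_table)
    sig_lon = np.maximum(sig_lon, 1e-6)
    sig_lat = np.maximum(sig_lat, 1e-6)

    obs = {"lon": (segment.lons, sig_lon), "lat": (segment.lats, sig_lat)}
    est = {}
    nlp = 0.0
    converged = True
    for axis, (y, sig) in obs.items():
        # initial sigma_p from the second differences of the *precise* fixes
        # (GPS and Argos classes 3/2/1): the interpolated full series is
        # noise-dominated for poor classes and would start EM in the
        # no-smoothing basin of the (bimodal) likelihood.
        good = np.array([err_table[f.loc_class] <= 10.0 for f in segment.fixes])
        if good.sum() >= 5:
            x = np.interp(grid_t, obs_t[good], y[good])
        else:
            x = np.interp(grid_t, obs_t, y)
        sigma_p = max(np.std(D @ x), 1e-4) if n_proc > 0 else 1e-4
        DtD = (D.T @ D).tocsc()
        Dt = sp.csc_matrix(D.T)
        for _ in range(n_profile_iter):
            # a fix measures the linearly interpolated latent position only
            # up to the movement within its time step: inflate the class
            # error by a bridge-variance discretization jitter (zero when
            # the fix falls on a grid node), so near-exact GPS fixes cannot
            # force the states to contort between nodes
            sig_eff = np.sqrt(sig ** 2 + w * (1.0 - w) * sigma_p ** 2)
            A_obs = sp.diags(1.0 / sig_eff) @ H
            b_obs = y / sig_eff
            AtA = (A_obs.T @ A_obs + DtD / sigma_p ** 2).tocsc()
            Atb = A_obs.T @ b_obs
            lu = spla.splu(AtA)
            x = lu.solve(Atb)
            if n_proc > 0:
                # EM update for the process variance: MAP residuals plus the
                # posterior-covariance trace term  tr(D Sigma D^T)
                Z = lu.solve(Dt.toarray())             # (n_states, n_proc)
                tr = float(np.sum(D.multiply(Z.T).toarray()))
                new_sigma = float(np.sqrt(
                    (np.sum((D @ x) ** 2) + tr) / n_proc))
                new_sigma = max(new_sigma, 1e-6)
                if abs(new_sigma - sigma_p) < 1e-6 * max(sigma_p, 1e-8):
                    sigma_p = new_sigma
                    break
                sigma_p = new_sigma
        r_obs = (H @ x - y) / sig_eff
        r_proc = (D @ x) / sigma_p if n_proc > 0 else np.zeros(0)
        nlp += 0.5 * float(r_obs @ r_obs + r_proc @ r_proc)
        grad = AtA @ x - Atb
        if float(np.linalg.norm(grad, np.inf)) >= grad_tol:
            converged = False
        est[axis] = x

    locs = [SSMLocation(time=t0 + i * step, lon=float(est["lon"][i]),
                        lat=float(est["lat"][i])) for i in range(n_states)]
    return SSMTrack(segment.animal_id, 0, step_hours, locs,
                    converged=converged, neg_log_posterior=nlp)


def _displacements_km(track: SSMTrack) -> np.ndarray:
    """Local-plane step vectors (km): dx east, dy north per step."""
    lons, lats = track.lons, track.lats
    mid = 0.5 * (lats[:-1] + lats[1:])
    dx = np.diff(lons) * KM_PER_DEG * np.cos(np.radians(mid))
    dy = np.diff(lats) * KM_PER_DEG
    return np.stack([dx, dy], axis=1)


def estimate_move_persistence(track: SSMTrack, n_outer: int = 8,
                              g_clip: float = 1e-4,
                              sigma_g2_max: float = 0.05) -> SSMTrack:
    """Fill per-location move persistence ``g`` by MAP on the logit scale.

    The autoregressive coefficient linking consecutive displacement vectors
    is modelled as a logit-Gaussian random walk; its path is optimised by
    L-BFGS with the innovation variance sigma_d^2 and the random-walk
    variance sigma_g^2 profiled by alternation (EM-style, with a Laplace
    posterior-covariance correction for sigma_g^2).

    ``sigma_g2_max`` caps the per-step logit drift variance. The cap acts as
    a prior on how fast behaviour can switch; it also sets the effective
    local-estimation window, and with it the small-sample bias of local AR
    coefficients. The default (0.05, logit drift SD ~0.22 per step) keeps
    multi-day behavioural phases smooth while still tracking abrupt regime
    switches within a few steps.
    """
    if not track.converged:
        raise DegenerateInputError("cannot estimate g on a non-converged fit")
    n = len(track)
    if n < 10:
        raise DegenerateInputError("estimate_move_persistence needs >= 10 locations")

    d = _displacements_km(track)          # (n-1, 2)
    d_prev, d_next = d[:-1], d[1:]        # pairs t -> t+1, length m = n-2
    m = len(d_prev)
    sq_prev = np.sum(d_prev ** 2, axis=1)

    # moment initialisation: per-transition projection ratio, clipped
    with np.errstate(divide="ignore", invalid="ignore"):
        g0 = np.sum(d_prev * d_next, axis=1) / np.where(sq_prev > 0, sq_prev, np.nan)
    g0 = np.clip(np.nan_to_num(g0, nan=0.5), g_clip, 1.0 - g_clip)
    z = np.log(g0 / (1.0 - g0))
    # light smoothing of the noisy moment estimates as the starting path
    if m >= 5:
        kernel = np.ones(5) / 5.0
        z = np.convolve(np.pad(z, 2, mode="edge"), kernel, mode="valid")

    resid0 = d_next - np.median(g0) * d_prev
    sigma_d2 = max(float(np.mean(resid0 ** 2)), 1e-6)
    sigma_g2 = 1.0

    def pack(z):
        g = 1.0 / (1.0 + np.exp(-z))
        return g

    ok = True
    for _ in range(n_outer):
        def objective(z):
            g = pack(z)
            r = d_next - g[:, None] * d_prev           # (m, 2)
            dz = np.diff(z)
            J = float(np.sum(r ** 2)) / (2.0 * sigma_d2) \
                + float(np.sum(dz ** 2)) / (2.0 * sigma_g2)
            # gradient
            dJ_dg = -np.sum(r * d_prev, axis=1) / sigma_d2
            dg_dz = g * (1.0 - g)
            grad = dJ_dg * dg_dz
            grad[:-1] += -dz / sigma_g2
            grad[1:] += dz / sigma_g2
            return J, grad

        res = minimize(objective, z, jac=True, method="L-BFGS-B",
                       options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8})
        z = res.x
        ok = ok and (res.status in (0, 1))
        g = pack(z)
        r = d_next - g[:, None] * d_prev
        sigma_d2 = max(float(np.mean(r ** 2)), 1e-8)
        dz = np.diff(z)
        # EM-style update for the random-walk variance: MAP increments plus
        # the Laplace posterior-covariance correction. The Gauss-Newton
        # Hessian of the objective in z is tridiagonal: a data diagonal plus
        # the random-walk graph Laplacian / sigma_g2.
        if m >= 3:
            h_data = sq_prev / sigma_d2 * (g * (1.0 - g)) ** 2
            lap_main = np.full(m, 2.0 / sigma_g2)
            lap_main[0] = lap_main[-1] = 1.0 / sigma_g2
            ab = np.zeros((2, m))
            ab[0, 1:] = -1.0 / sigma_g2           # superdiagonal
            ab[1] = h_data + lap_main + 1e-10
            cov = solveh_banded(ab, np.eye(m))
            var_d = (np.diag(cov)[:-1] + np.diag(cov)[1:]
                     - 2.0 * np.diag(cov, 1))
            sigma_g2 = float((np.sum(dz ** 2) + np.sum(var_d)) / len(dz))
        sigma_g2 = float(np.clip(sigma_g2, 1e-4, sigma_g2_max))

    g = np.clip(pack(z), g_clip, 1.0 - g_clip)
    # displacement t (x_{t-1} -> x_t) transitions carry g_t for t = 1..m;
    # every location carries one g: first two take the first estimate.
    g_full = np.empty(n)
    g_full[0] = g_full[1] = g[0]
    g_full[2:] = g
    for loc, gi in zip(track.locations, g_full):
        loc.g = float(gi)
    track.converged = track.converged and ok
    return track


def classify_behaviour(g: float, lat: float, threshold: float = 0.8,
                       tropics_lat: float = -11.5) -> str:
    """Label a location from its move persistence and latitude.

    g >= threshold -> migration. Low-persistence locations are foraging in
    Australian waters (lat <= -11.5) and foraging/reproduction in the
    Southeast Asia region north of that line.
    """
    if not (0.0 <= g <= 1.0):
        raise ValueError("g outside [0, 1]")
    if g >= threshold:
        return "migration"
    return "foraging" if lat <= tropics_lat else "foraging_reproduction"


def label_track(track: SSMTrack, threshold: float = 0.8) -> SSMTrack:
    """Apply :func:`classify_behaviour` to every location in place."""
    for loc in track.locations:
        loc.behaviour = classify_behaviour(loc.g, loc.lat, threshold)
    return track


def assign_region(loc: SSMLocation, regions: RegionSet) -> str:
    """Highest-precedence region containing the point and scoping its behaviour."""
    if not loc.behaviour:
        raise ValueError("location has no behaviour label")
    loc.region = regions.lookup(loc.lon, loc.lat, loc.behaviour)
    return loc.region


def assign_regions(track: SSMTrack, regions: RegionSet) -> SSMTrack:
    for loc in track.locations:
        assign_region(loc, regions)
    return track


def default_region_set() -> RegionSet:
    """Modelling regions for the Eastern Indian Ocean study area.

    Latitude/longitude boxes for the three Australian foraging regions, the
    Southeast Asia foraging/reproduction region and the two migration
    regions. The North West and South West foraging boxes overlap between
    23.6 and 28.8 deg S; precedence resolves the overlap in favour of the
    North West.
    """
    regions = [
        Region("NW_WA", box(105.0, -28.8, 130.0, -11.5), ("foraging",), 6),
        Region("SW_WA", box(105.0, -32.0, 120.0, -23.6), ("foraging",), 5),
        Region("Southern_Australia", box(116.0, -45.0, 150.0, -32.0), ("foraging",), 4),
        Region("SE_Asia", box(100.0, -11.5, 135.0, 10.0), ("foraging_reproduction",), 3),
        Region("WA_migration", box(105.0, -32.0, 130.0, -11.5), ("migration",), 2),
        Region("SA_migration", box(116.0, -45.0, 150.0, -32.0), ("migration",), 1),
    ]
    return RegionSet(regions)


def preprocess_tracks(tracks: list[RawTrack], regions: RegionSet,
                      max_gap_days: float = 5.0, g_threshold: float = 0.8,
                      err_table: dict[str, float] = ARGOS_ERR95_KM,
                      min_fixes: int = 10) -> list[SSMTrack]:
    """Full stage-1 pipeline: split, smooth, estimate g, label, assign regions.

    Non-converged or too-short segments are excluded with a log entry.
    """
    out = []
    for track in tracks:
        for seg_id, seg in enumerate(split_on_gaps(track, max_gap_days)):
            if len(seg) < max(min_fixes, 5):
                log.warning("%s segment %d: %d fixes, skipped",
                            track.animal_id, seg_id, len(seg))
                continue
            step = choose_time_step(seg)
            ssm = fit_ssm(seg, step, err_table)
            ssm.segment_id = seg_id
            if not ssm.converged:
                log.warning("%s segment %d: SSM did not converge, excluded",
                            track.animal_id, seg_id)
                continue
            if len(ssm) < 10:
                continue
            estimate_move_persistence(ssm)
            if not ssm.converged:
                log.warning("%s segment %d: persistence fit flagged, excluded",
                            track.animal_id, seg_id)
                continue
            label_track(ssm, g_threshold)
            assign_regions(ssm, regions)
            out.append(ssm)
    return out


def ssm_tracks_from_frame(df: pd.DataFrame) -> list[SSMTrack]:
    """Rebuild :class:`SSMTrack` objects from :func:`ssm_tracks_to_frame` output."""
    out = []
    for (animal_id, seg_id), g in df.groupby(["animal_id", "segment_id"], sort=True):
        g = g.sort_values("time")
        locs = [SSMLocation(pd.Timestamp(r.time), float(r.lon), float(r.lat),
                            float(r.g), str(r.behaviour), str(r.region))
                for r in g.itertuples()]
        out.append(SSMTrack(str(animal_id), int(seg_id),
                            float(g["step_hours"].iloc[0]), locs))
    return out


def ssm_tracks_to_frame(tracks: list[SSMTrack]) -> pd.DataFrame:
    rows = [{"animal_id": t.animal_id, "segment_id": t.segment_id,
             "step_hours": t.step_hours, "time": p.time, "lon": p.lon,
             "lat": p.lat, "g": p.g, "behaviour": p.behaviour,
             "region": p.region}
            for t in tracks for p in t.locations]
    return pd.DataFrame(rows)
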