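import numpy as np
import pandas as pd
import pytest

from movesdm.geo import KM_PER_DEG
from movesdm.io_formats import EnvLayer, GridSpec, RawFix, RawTrack


def make_track(lons, lats, step_hours=6.0, source="gps", cls="G",
               t0="2022-04-01", animal_id="w1"):
    """Regular-cadence RawTrack from coordinate arrays."""
    t0 = pd.Timestamp(t0)
    fixes = [RawFix(animal_id, t0 + pd.Timedelta(hours=i * step_hours),
                    float(lo), float(la), source, cls)
             for i, (lo, la) in enumerate(zip(lons, lats))]
    return RawTrack(animal_id, fixes)


def simulate_ar_track(g_seq, sigma_km=4.0, seed=0, d0_km=10.0,
                      lon0=110.0, lat0=-25.0):
    """Displacement-AR(1) path: d_{t+1} = g_t d_t + N(0, sigma^2 I)."""
    rng = np.random.default_rng(seed)
    lon, lat = lon0, lat0
    d = np.array([d0_km, 0.0])
    lons, lats = [lon], [lat]
    for g in g_seq:
        d = g * d + rng.normal(0, sigma_km, 2)
        lon += d[0] / (KM_PER_DEG * np.cos(np.radians(lat)))
        lat += d[1] / KM_PER_DEG
        lons.append(lon)
        lats.append(lat)
    return np.array(lons), np.array(lats)


def flat_layer(value=0.0, nrow=20, ncol=20, west=110.0, north=-20.0,
               d=0.1, name="layer"):
    gs = GridSpec(west=west, north=north, dlon=d, dlat=d, nrow=nrow, ncol=ncol)
    return EnvLayer(name, np.full((nrow, ncol), float(value)), gs)


@pytest.fixture(scope="session")
def small_scenario():
    """One compact synthetic study shared by the slower integration tests."""
    from movesdm.synthetic import ScenarioConfig, make_scenario
    cfg = ScenarioConfig(seed=7, n_whales=6, duration_days_range=(20, 90),
                         start_window_days=30)
    return make_scenario(cfg)
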