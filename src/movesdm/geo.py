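"""Great-circle geometry on the WGS84 sphere.

All coordinates are WGS84 longitude/latitude in decimal degrees; longitudes
are kept in [-180, 180). Distances are great-circle (haversine) kilometres —
the tracks handled here span tens of degrees of latitude, so planar
approximations are not used anywhere in the package.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088
#: kilometres per degree of latitude (and of longitude at the equator)
KM_PER_DEG = EARTH_RADIUS_KM * np.pi / 180.0


def normalize_lon(lon):
    """Wrap longitudes into [-180, 180)."""
    return (np.asarray(lon) + 180.0) % 360.0 - 180.0


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points (element-wise)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def initial_bearing_rad(lon1, lat1, lon2, lat2):
    """Initial great-circle bearing from point 1 to point 2.

    Radians, clockwise from true north, in (-pi, pi].
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    y = np.sin(dlon) * np.cos(lat2)
    x = np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(dlon)
    return np.arctan2(y, x)


def destination_point(lon, lat, bearing_rad, distance_km):
    """Point reached travelling ``distance_km`` on ``bearing_rad`` from (lon, lat)."""
    lat1 = np.radians(np.asarray(lat, dtype=float))
    lon1 = np.radians(np.asarray(lon, dtype=float))
    delta = np.asarray(distance_km, dtype=float) / EARTH_RADIUS_KM
    theta = np.asarray(bearing_rad, dtype=float)
    lat2 = np.arcsin(np.sin(lat1) * np.cos(delta)
                     + np.cos(lat1) * np.sin(delta) * np.cos(theta))
    lon2 = lon1 + np.arctan2(np.sin(theta) * np.sin(delta) * np.cos(lat1),
                             np.cos(delta) - np.sin(lat1) * np.sin(lat2))
    return normalize_lon(np.degrees(lon2)), np.degrees(lat2)


def wrap_angle(angle):
    """Wrap an angle in radians into (-pi, pi]."""
    a = np.mod(-np.asarray(angle) + np.pi, 2.0 * np.pi)
    return -(a - np.pi)


def turn_angles_rad(lons, lats):
    """Signed turning angles of a path (positive = clockwise / right turn).

    For n points returns n - 2 angles: the change in bearing at each interior
    point, wrapped to (-pi, pi].
    """
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    b = initial_bearing_rad(lons[:-1], lats[:-1], lons[1:], lats[1:])
    return wrap_angle(np.diff(b))


def km_to_deg_lat(km):
    """Kilometres to degrees of latitude."""
    return np.asarray(km, dtype=float) / KM_PER_DEG


def km_to_deg_lon(km, lat):
    """Kilometres to degrees of longitude at latitude ``lat``."""
    c = np.cos(np.radians(np.asarray(lat, dtype=float)))
    return np.asarray(km, dtype=float) / (KM_PER_DEG * np.maximum(c, 1e-9))
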