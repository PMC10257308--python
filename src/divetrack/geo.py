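"""Great-circle and local-projection helpers on the WGS84 mean sphere.

All public functions accept scalars or numpy arrays of latitudes/longitudes in
decimal degrees and return metres (distances) or radians (bearings).  A mean
Earth radius of 6371.0088 km is used throughout; for the coastal-shelf scales
this package operates at (tens of km) the spherical error is negligible
relative to GPS fix error.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_M = 6_371_008.8


def haversine_m(lat1, lon1, lat2, lon2):
    """Great-circle distance in metres between WGS84 points (degrees)."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(np.asarray(lon2) - np.asarray(lon1))
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def initial_bearing_rad(lat1, lon1, lat2, lon2):
    """Initial great-circle bearing, radians clockwise from true north in [0, 2pi)."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dlam = np.radians(np.asarray(lon2) - np.asarray(lon1))
    y = np.sin(dlam) * np.cos(p2)
    x = np.cos(p1) * np.sin(p2) - np.sin(p1) * np.cos(p2) * np.cos(dlam)
    return np.mod(np.arctan2(y, x), 2.0 * np.pi)


def destination_point(lat, lon, bearing_rad, distance_m):
    """Point reached from (lat, lon) on bearing (rad) after distance_m metres."""
    delta = np.asarray(distance_m) / EARTH_RADIUS_M
    phi1 = np.radians(lat)
    lam1 = np.radians(lon)
    phi2 = np.arcsin(
        np.sin(phi1) * np.cos(delta) + np.cos(phi1) * np.sin(delta) * np.cos(bearing_rad)
    )
    lam2 = lam1 + np.arctan2(
        np.sin(bearing_rad) * np.sin(delta) * np.cos(phi1),
        np.cos(delta) - np.sin(phi1) * np.sin(phi2),
    )
    return np.degrees(phi2), np.degrees(np.mod(lam2 + np.pi, 2.0 * np.pi) - np.pi)


def local_scale_m_per_deg(lat):
    """(metres per degree latitude, metres per degree longitude) at latitude ``lat``.

    Equirectangular scaling — adequate for converting dead-reckoned offsets of a
    few km to degrees; segments longer than ~10 km should use haversine_m for
    distances instead.
    """
    m_per_deg_lat = EARTH_RADIUS_M * np.pi / 180.0
    m_per_deg_lon = m_per_deg_lat * np.cos(np.radians(lat))
    return m_per_deg_lat, m_per_deg_lon


def enu_offset_m(lat_ref, lon_ref, lat, lon):
    """East/north offset in metres of (lat, lon) from a reference point."""
    mlat, mlon = local_scale_m_per_deg(lat_ref)
    dlon = np.mod(np.asarray(lon) - lon_ref + 180.0, 360.0) - 180.0
    return dlon * mlon, (np.asarray(lat) - lat_ref) * mlat


def offset_to_latlon(lat_ref, lon_ref, east_m, north_m):
    """Inverse of :func:`enu_offset_m`."""
    mlat, mlon = local_scale_m_per_deg(lat_ref)
    return lat_ref + np.asarray(north_m) / mlat, lon_ref + np.asarray(east_m) / mlon


def wrap_heading(theta):
    """Wrap an angle in radians into [0, 2pi).

    np.mod(x, 2*pi) can return exactly 2*pi for tiny negative x; fold that
    edge case back to 0 so the half-open interval holds.
    """
    w = np.mod(theta, 2.0 * np.pi)
    return np.where(w >= 2.0 * np.pi, 0.0, w)
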