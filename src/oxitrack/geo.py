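"""Spherical-earth geometry primitives.

All distances use the haversine formula on a sphere of radius
``EARTH_RADIUS_KM`` = 6371.0 km, the conventional mean Earth radius in
movement ecology.  At foraging-trip scales (tens of km) the departure from
an ellipsoidal geodesic is far below GPS noise.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "EARTH_RADIUS_KM",
    "haversine_km",
    "initial_bearing_rad",
    "wrap_angle",
    "destination_point",
]


def _check_coords(lat, lon) -> None:
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if not (np.all(np.isfinite(lat)) and np.all(np.isfinite(lon))):
        raise ValueError("coordinates must be finite")
    if np.any(np.abs(lat) > 90.0):
        raise ValueError("latitude out of [-90, 90]")
    if np.any(np.abs(lon) > 180.0):
        raise ValueError("longitude out of [-180, 180]")


def haversine_km(a, b):
    """Great-circle distance between points ``a = (lat, lon)`` and ``b``.

    Accepts scalars or equal-length arrays of latitudes/longitudes in
    decimal degrees; returns km.  Symmetric and non-negative.
    """
    lat1, lon1 = a
    lat2, lon2 = b
    _check_coords(lat1, lon1)
    _check_coords(lat2, lon2)
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(np.asarray(lon2, dtype=float) - np.asarray(lon1, dtype=float))
    h = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    # clip guards rounding at antipodal points
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def initial_bearing_rad(a, b):
    """Initial compass bearing (radians clockwise from north) from a to b."""
    lat1, lon1 = a
    lat2, lon2 = b
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dlam = np.radians(np.asarray(lon2, dtype=float) - np.asarray(lon1, dtype=float))
    x = np.sin(dlam) * np.cos(phi2)
    y = np.cos(phi1) * np.sin(phi2) - np.sin(phi1) * np.cos(phi2) * np.cos(dlam)
    return np.arctan2(x, y)


def wrap_angle(theta):
    """Wrap angle(s) to the half-open interval (-pi, pi]."""
    theta = np.asarray(theta, dtype=float)
    wrapped = np.mod(theta + np.pi, 2.0 * np.pi) - np.pi
    wrapped = np.where(wrapped == -np.pi, np.pi, wrapped)
    if wrapped.ndim == 0:
        return float(wrapped)
    return wrapped


def destination_point(lat, lon, bearing_rad, dist_km):
    """Advance from (lat, lon) along ``bearing_rad`` by ``dist_km``.

    Small-step equirectangular approximation: exact meridional scaling,
    parallel scaling by cos(lat).  Error is O((d/R)^2), i.e. < 1 m for
    steps up to ~10 km, which is the regime of the track simulator.
    """
    dlat = dist_km * np.cos(bearing_rad) / (np.pi / 180.0 * EARTH_RADIUS_KM)
    coslat = np.cos(np.radians(lat))
    coslat = np.maximum(coslat, 1e-9)
    dlon = dist_km * np.sin(bearing_rad) / (np.pi / 180.0 * EARTH_RADIUS_KM * coslat)
    return lat + dlat, lon + dlon
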