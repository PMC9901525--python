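"""Spherical geometry primitives shared across modules.

All distances use the IUGG mean Earth radius on a sphere; the sub-0.5%
difference from an ellipsoid is irrelevant at the daily-displacement scale of
the analysis and keeps every quantity checkable against closed forms.
"""

from __future__ import annotations

import numpy as np

from .config import EARTH_RADIUS_KM


def gc_dist_km(lon1, lat1, lon2, lat2, radius_km: float = EARTH_RADIUS_KM):
    """Great-circle distance (km) via the numerically stable atan2 form.

    Broadcasts over array inputs in decimal degrees.
    """
    lo1, la1, lo2, la2 = (np.deg2rad(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlon = lo2 - lo1
    num = np.hypot(
        np.cos(la2) * np.sin(dlon),
        np.cos(la1) * np.sin(la2) - np.sin(la1) * np.cos(la2) * np.cos(dlon),
    )
    den = np.sin(la1) * np.sin(la2) + np.cos(la1) * np.cos(la2) * np.cos(dlon)
    return radius_km * np.arctan2(num, den)


def initial_bearing_deg(lon1, lat1, lon2, lat2):
    """Initial great-circle bearing, degrees clockwise from geographic north."""
    lo1, la1, lo2, la2 = (np.deg2rad(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlon = lo2 - lo1
    y = np.sin(dlon) * np.cos(la2)
    x = np.cos(la1) * np.sin(la2) - np.sin(la1) * np.cos(la2) * np.cos(dlon)
    return np.rad2deg(np.arctan2(y, x)) % 360.0


def destination_point(lon, lat, bearing_deg, dist_km, radius_km: float = EARTH_RADIUS_KM):
    """Point reached travelling ``dist_km`` along an initial bearing."""
    la1 = np.deg2rad(np.asarray(lat, dtype=float))
    lo1 = np.deg2rad(np.asarray(lon, dtype=float))
    brg = np.deg2rad(np.asarray(bearing_deg, dtype=float))
    d = np.asarray(dist_km, dtype=float) / radius_km
    la2 = np.arcsin(np.sin(la1) * np.cos(d) + np.cos(la1) * np.sin(d) * np.cos(brg))
    lo2 = lo1 + np.arctan2(
        np.sin(brg) * np.sin(d) * np.cos(la1),
        np.cos(d) - np.sin(la1) * np.sin(la2),
    )
    return (np.rad2deg(lo2) + 180.0) % 360.0 - 180.0, np.rad2deg(la2)
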