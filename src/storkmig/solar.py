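"""Solar position (NOAA low-accuracy algorithm).

Used to decide whether a fix falls in daylight: the duty cycle records only
while the sun is above the horizon, and night roosts are taken from the last
daylight fix of the day.  Accuracy of the approximation (~0.1 deg elevation)
is far below anything that matters at a 20-minute fix interval.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["sun_elevation", "daylight_window_utc", "is_daylight"]


def _fractional_year(doy: np.ndarray, hour_utc: np.ndarray) -> np.ndarray:
    return 2.0 * np.pi / 365.0 * (doy - 1 + (hour_utc - 12.0) / 24.0)


def _declination(g: np.ndarray) -> np.ndarray:
    return (
        0.006918
        - 0.399912 * np.cos(g)
        + 0.070257 * np.sin(g)
        - 0.006758 * np.cos(2 * g)
        + 0.000907 * np.sin(2 * g)
        - 0.002697 * np.cos(3 * g)
        + 0.00148 * np.sin(3 * g)
    )


def _equation_of_time_min(g: np.ndarray) -> np.ndarray:
    return 229.18 * (
        0.000075
        + 0.001868 * np.cos(g)
        - 0.032077 * np.sin(g)
        - 0.014615 * np.cos(2 * g)
        - 0.040849 * np.sin(2 * g)
    )


def sun_elevation(lat: np.ndarray, lon: np.ndarray, times) -> np.ndarray:
    """Solar elevation angle in degrees for UTC timestamps.

    Parameters are broadcast together; ``times`` is anything
    ``pandas.DatetimeIndex`` accepts (assumed UTC).
    """
    t = pd.DatetimeIndex(times)
    if t.tz is not None:
        t = t.tz_convert("UTC").tz_localize(None)
    doy = t.dayofyear.to_numpy(dtype=float)
    minutes = (
        t.hour.to_numpy(dtype=float) * 60.0
        + t.minute.to_numpy(dtype=float)
        + t.second.to_numpy(dtype=float) / 60.0
    )
    g = _fractional_year(doy, minutes / 60.0)
    decl = _declination(g)
    eqt = _equation_of_time_min(g)
    lat_r = np.deg2rad(np.asarray(lat, dtype=float))
    tst = minutes + eqt + 4.0 * np.asarray(lon, dtype=float)  # true solar time, min
    ha = np.deg2rad(tst / 4.0 - 180.0)  # hour angle
    sin_el = np.sin(lat_r) * np.sin(decl) + np.cos(lat_r) * np.cos(decl) * np.cos(ha)
    return np.rad2deg(np.arcsin(np.clip(sin_el, -1.0, 1.0)))


def is_daylight(lat, lon, times) -> np.ndarray:
    """True where the sun is above the horizon."""
    return sun_elevation(lat, lon, times) > 0.0


def daylight_window_utc(lat: float, lon: float, date) -> tuple[float, float]:
    """(sunrise, sunset) in UTC minutes-of-day for one site and date.

    Returns (nan, nan) under polar night and (0, 1440) under midnight sun;
    neither occurs on the Iberia-Sahel corridor.
    """
    doy = float(pd.Timestamp(date).dayofyear)
    g = _fractional_year(np.array([doy]), np.array([12.0]))
    decl = float(_declination(g)[0])
    eqt = float(_equation_of_time_min(g)[0])
    lat_r = np.deg2rad(lat)
    cos_ha = -np.tan(lat_r) * np.tan(decl)
    if cos_ha > 1.0:
        return (np.nan, np.nan)
    if cos_ha < -1.0:
        return (0.0, 1440.0)
    ha = np.rad2deg(np.arccos(cos_ha))
    sunrise = 720.0 - 4.0 * (lon + ha) - eqt
    sunset = 720.0 - 4.0 * (lon - ha) - eqt
    return (sunrise, sunset)
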