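"""Weather annotation and flight kinematics.

Fixes are annotated with 925-mB zonal/meridional wind and boundary layer
height by spatial bilinear interpolation at the nearest grid hour.  Wind
direction uses the "blowing toward" convention (degrees clockwise from
geographic north), matching the eastward(+)/westward(-) sign language of the
zonal component; wind support is the projection of the wind vector on the
bird's travel direction (positive = tailwind).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr

from . import config
from ._geo import gc_dist_km, initial_bearing_deg


def _axis_fraction(axis: np.ndarray, x: np.ndarray, name: str):
    """Bracketing indices and interpolation weight along one monotone axis."""
    if np.any(x < axis[0]) or np.any(x > axis[-1]):
        raise ValueError(f"fix outside grid bounds on axis {name!r}")
    i = np.clip(np.searchsorted(axis, x, side="right") - 1, 0, len(axis) - 2)
    f = (x - axis[i]) / (axis[i + 1] - axis[i])
    return i, f


def interpolate_weather(grid: xr.Dataset, lon, lat, time) -> pd.DataFrame:
    """Bilinear (u925, v925, blh) at each (lon, lat), nearest grid hour.

    Vectorised over fixes; exact at grid nodes and exact for fields affine in
    lon and lat.  Raises naming the offending axis for out-of-bounds fixes.
    """
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    t = pd.DatetimeIndex(np.atleast_1d(time))
    if t.tz is not None:
        t = t.tz_convert("UTC").tz_localize(None)
    t = t.as_unit("ns")
    tax = pd.DatetimeIndex(grid["time"].values).as_unit("ns")
    tnum = tax.asi8
    x = t.asi8
    if x.min() < tnum[0] or x.max() > tnum[-1]:
        raise ValueError("fix outside grid bounds on axis 'time'")
    ti = np.clip(np.searchsorted(tnum, x), 0, len(tnum) - 1)
    ti_lo = np.clip(ti - 1, 0, len(tnum) - 1)
    nearer_lo = np.abs(x - tnum[ti_lo]) <= np.abs(tnum[ti] - x)
    ti = np.where(nearer_lo, ti_lo, ti)

    lon_ax = grid["lon"].values.astype(float)
    lat_ax = grid["lat"].values.astype(float)
    i, fx = _axis_fraction(lon_ax, lon, "lon")
    j, fy = _axis_fraction(lat_ax, lat, "lat")
    out = {}
    for v in ("u925", "v925", "blh"):
        arr = grid[v].transpose("time", "lat", "lon").values
        v00 = arr[ti, j, i]
        v01 = arr[ti, j, i + 1]
        v10 = arr[ti, j + 1, i]
        v11 = arr[ti, j + 1, i + 1]
        out[v] = (v00 * (1 - fx) * (1 - fy) + v01 * fx * (1 - fy)
                  + v10 * (1 - fx) * fy + v11 * fx * fy)
    return pd.DataFrame(out)


def wind_speed_direction(u, v):
    """(speed m/s, direction deg) from zonal/meridional components.

    Direction is where the air is moving toward, clockwise from north
    (0 = northward, 90 = eastward).  Calm air (u = v = 0) gives speed 0 and
    direction NaN (undefined).
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    speed = np.hypot(u, v)
    direction = np.rad2deg(np.arctan2(u, v)) % 360.0
    direction = np.where(speed == 0.0, np.nan, direction)
    return speed, direction


def wind_support(u, v, track_bearing_deg):
    """Wind component along the track bearing (m/s); positive = tailwind."""
    b = np.deg2rad(np.asarray(track_bearing_deg, dtype=float))
    return np.asarray(u, dtype=float) * np.sin(b) + np.asarray(v, dtype=float) * np.cos(b)


def step_kinematics(tracks: pd.DataFrame,
                    max_gap_min: float = config.MAX_STEP_GAP_MIN) -> pd.DataFrame:
    """Ground speed, bearing and longitudinal speed between consecutive fixes.

    One row per step (attributed to the step's first fix), per bird.  Steps
    longer than ``max_gap_min`` or with non-positive time difference are
    skipped.  Longitudinal speed is the eastward component of the ground
    velocity: distance * sin(bearing) / dt, so |longitudinal| <= ground speed.
    """
    rows = []
    for bird, sub in tracks.groupby("bird_id", sort=True):
        sub = sub.sort_values("timestamp")
        lon = sub["lon"].to_numpy()
        lat = sub["lat"].to_numpy()
        t = pd.DatetimeIndex(sub["timestamp"]).asi8 / 1e9
        dt = np.diff(t)
        ok = (dt > 0) & (dt <= max_gap_min * 60.0)
        dist_m = gc_dist_km(lon[:-1], lat[:-1], lon[1:], lat[1:]) * 1000.0
        brg = initial_bearing_deg(lon[:-1], lat[:-1], lon[1:], lat[1:])
        speed = np.where(ok, dist_m / np.where(dt > 0, dt, np.nan), np.nan)
        rows.append(pd.DataFrame({
            "bird_id": bird,
            "timestamp": sub["timestamp"].iloc[:-1].to_numpy(),
            "ground_speed_ms": speed,
            "bearing": np.where(ok, brg, np.nan),
            "longitudinal_speed_ms": speed * np.sin(np.deg2rad(brg)),
        })[ok])
    if not rows:
        return pd.DataFrame(columns=["bird_id", "timestamp", "ground_speed_ms",
                                     "bearing", "longitudinal_speed_ms"])
    return pd.concat(rows, ignore_index=True)


def annotate_tracks(tracks: pd.DataFrame, grid: xr.Dataset,
                    flight_only_bearing: bool = True) -> pd.DataFrame:
    """Annotate fixes with interpolated weather and derived wind variables.

    Adds ``u925, v925, blh, wind_speed, wind_direction`` and, where a step
    bearing is defined, ``bearing`` and ``wind_support``.
    """
    out = tracks.sort_values(["bird_id", "timestamp"]).reset_index(drop=True)
    met = interpolate_weather(grid, out["lon"].to_numpy(), out["lat"].to_numpy(),
                              out["timestamp"].to_numpy())
    out = pd.concat([out, met.set_index(out.index)], axis=1)
    speed, direction = wind_speed_direction(out["u925"], out["v925"])
    out["wind_speed"] = speed
    out["wind_direction"] = direction
    steps = step_kinematics(out)
    key = ["bird_id", "timestamp"]
    out = out.merge(steps[key + ["bearing", "ground_speed_ms", "longitudinal_speed_ms"]],
                    on=key, how="left")
    out["wind_support"] = wind_support(out["u925"], out["v925"], out["bearing"])
    return out


def daily_means(annotated: pd.DataFrame,
                flight_col: str = "flight") -> pd.DataFrame:
    """Per-bird-day means over flight fixes: zonal wind and longitudinal speed.

    Used by the flight-direction model ("did wind direction push birds
    east/west").  Days without flight fixes are omitted (flagged upstream by
    their absence); sample counts are attached.
    """
    ann = annotated
    if flight_col in ann.columns:
        ann = ann[ann[flight_col] == True]  # noqa: E712
    ann = ann[ann["longitudinal_speed_ms"].notna()]
    dates = pd.DatetimeIndex(ann["timestamp"]).tz_localize(None).normalize()
    grp = ann.assign(date=dates).groupby(["bird_id", "date"])
    out = grp.agg(
        mean_zonal_wind=("u925", "mean"),
        mean_longitudinal_speed=("longitudinal_speed_ms", "mean"),
        mean_wind_support=("wind_support", "mean"),
        mean_blh=("blh", "mean"),
        n_fixes=("u925", "size"),
    ).reset_index()
    return out
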