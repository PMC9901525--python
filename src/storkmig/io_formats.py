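"""Readers and writers for the pipeline's on-disk formats.

Tracking and acceleration data travel as CSV with Movebank-style column names
(remappable), weather grids as CF-style NetCDF (classic format) or long CSV,
and routes as GeoJSON.  This module validates and normalises; it contains no
science.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

logger = logging.getLogger(__name__)

#: default Movebank-like on-disk column names -> canonical names
TRACK_COLUMNS = {
    "individual-local-identifier": "bird_id",
    "timestamp": "timestamp",
    "location-long": "lon",
    "location-lat": "lat",
    "ground-speed": "ground_speed",
    "burst-id": "burst_id",
}
_MANDATORY = ("bird_id", "timestamp", "lon", "lat")

ACCEL_COLUMNS = ("burst_id", "bird_id", "sample_index", "ax", "ay", "az",
                 "sample_rate", "logger_type")


class FormatError(ValueError):
    """Malformed or invalid input file."""


# --------------------------------------------------------------------- tracks

def read_tracks(path: str | Path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a tracking CSV into a validated, canonically named table.

    Rows are sorted by (bird_id, timestamp); exact duplicates of
    (bird_id, timestamp) are dropped with a logged count.  Raises
    :class:`FormatError` for missing mandatory columns, unparseable
    timestamps (reported with CSV line number) or out-of-range coordinates.
    """
    cmap = column_map or TRACK_COLUMNS
    df = pd.read_csv(path, dtype={c: str for c in cmap if "identifier" in c or "burst" in c})
    df = df.rename(columns=cmap)
    for col in _MANDATORY:
        if col not in df.columns:
            raise FormatError(f"missing mandatory column: {col!r}")
    ts = pd.to_datetime(df["timestamp"], utc=True, errors="coerce", format="ISO8601")
    bad = ts.isna() & df["timestamp"].notna()
    if bad.any():
        # +2: header line plus 1-based indexing
        lines = (df.index[bad] + 2).tolist()
        raise FormatError(f"unparseable timestamp at line(s) {lines[:10]}")
    df["timestamp"] = ts
    lat = pd.to_numeric(df["lat"])
    lon = pd.to_numeric(df["lon"])
    if (lat.abs() > 90).any():
        raise FormatError("latitude outside [-90, 90]")
    if (lon.abs() > 180).any():
        raise FormatError("longitude outside [-180, 180]")
    df["lat"], df["lon"] = lat, lon
    if "ground_speed" not in df.columns:
        df["ground_speed"] = np.nan
    if "burst_id" not in df.columns:
        df["burst_id"] = np.nan
    df["burst_id"] = df["burst_id"].astype(object)
    n0 = len(df)
    df = df.drop_duplicates(subset=["bird_id", "timestamp"], keep="first")
    if len(df) < n0:
        logger.warning("dropped %d duplicate (bird_id, timestamp) rows", n0 - len(df))
    df = df.sort_values(["bird_id", "timestamp"], kind="mergesort").reset_index(drop=True)
    return df[["bird_id", "timestamp", "lon", "lat", "ground_speed", "burst_id"]]


def write_tracks(tracks: pd.DataFrame, path: str | Path,
                 column_map: dict[str, str] | None = None) -> None:
    """Write a canonical track table back to the Movebank-style CSV dialect."""
    cmap = column_map or TRACK_COLUMNS
    inv = {v: k for k, v in cmap.items()}
    out = tracks.rename(columns=inv).copy()
    tcol = inv.get("timestamp", "timestamp")
    out[tcol] = pd.DatetimeIndex(tracks["timestamp"]).strftime("%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------- accel

def read_accel(path: str | Path) -> pd.DataFrame:
    """Read long-format acceleration samples (one row per sample)."""
    df = pd.read_csv(path, dtype={"burst_id": str, "bird_id": str, "logger_type": str})
    missing = [c for c in ACCEL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing mandatory column(s): {missing}")
    df = df.sort_values(["burst_id", "sample_index"], kind="mergesort").reset_index(drop=True)
    for bid, grp in df.groupby("burst_id", sort=False):
        idx = grp["sample_index"].to_numpy()
        if not np.array_equal(idx, np.arange(len(idx))):
            raise FormatError(f"burst {bid!r}: sample_index not contiguous from 0")
        if grp["sample_rate"].nunique() != 1:
            raise FormatError(f"burst {bid!r}: multiple sample rates")
    return df


def write_accel(accel: pd.DataFrame, path: str | Path) -> None:
    accel.to_csv(path, index=False)


# -------------------------------------------------------------------- weather

_WEATHER_VARS = ("u925", "v925", "blh")


def _check_regular(axis: np.ndarray, name: str) -> None:
    if len(axis) > 1:
        steps = np.diff(axis.astype(float))
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise FormatError(f"non-regular {name} axis spacing")
        if steps[0] <= 0:
            raise FormatError(f"{name} axis not strictly increasing after sort")


def read_weather_grid(path: str | Path) -> xr.Dataset:
    """Read an hourly weather grid from CF NetCDF (classic) or long CSV.

    Returns an ``xarray.Dataset`` with coords (time, lat, lon) sorted
    ascending and variables u925 (m/s, eastward+), v925 (m/s, northward+),
    blh (m).
    """
    path = Path(path)
    if path.suffix.lower() in (".nc", ".cdf", ".netcdf"):
        ds = xr.open_dataset(path, engine="scipy").load()
    else:
        df = pd.read_csv(path)
        need = {"lon", "lat", "time", *_WEATHER_VARS}
        missing = need - set(df.columns)
        if missing:
            raise FormatError(f"missing weather column(s): {sorted(missing)}")
        df["time"] = pd.to_datetime(df["time"], utc=True).dt.tz_localize(None)
        df = df.set_index(["time", "lat", "lon"])
        if df.index.duplicated().any():
            raise FormatError("duplicate (time, lat, lon) cells")
        ds = df[list(_WEATHER_VARS)].to_xarray()
    ds = ds.sortby(["time", "lat", "lon"])
    for name in ("lon", "lat"):
        _check_regular(ds[name].values, name)
    if ds["time"].size > 1:
        _check_regular(ds["time"].values.astype("datetime64[s]").astype(float), "time")
    for v in _WEATHER_VARS:
        if v not in ds:
            raise FormatError(f"missing weather variable {v!r}")
        if np.isnan(ds[v].values).any():
            raise FormatError(f"missing cells in {v!r} inside declared bounds")
    ds["u925"].attrs.setdefault("units", "m s-1")
    ds["v925"].attrs.setdefault("units", "m s-1")
    ds["blh"].attrs.setdefault("units", "m")
    return ds


def write_weather_grid(grid: xr.Dataset, path: str | Path) -> None:
    """Write a weather grid as NetCDF3 (``.nc``) or long CSV (anything else)."""
    path = Path(path)
    if path.suffix.lower() in (".nc", ".cdf", ".netcdf"):
        grid.to_netcdf(path, engine="scipy")
    else:
        df = grid[list(_WEATHER_VARS)].to_dataframe().reset_index()
        df.to_csv(path, index=False)


# -------------------------------------------------------------------- geojson

def write_geojson_routes(tracks: pd.DataFrame, events, path: str | Path) -> None:
    """Export one LineString per bird-year plus leg-boundary points.

    ``events`` is an iterable of :class:`storkmig.segmentation.MigrationEvent`
    (or anything with the same attributes).  Coordinates are rounded to 6
    decimal places (~0.1 m).
    """
    features = []
    known = set(tracks["bird_id"].unique())
    for ev in events:
        if ev.bird_id not in known:
            raise FormatError(f"unknown bird id {ev.bird_id!r}")
        sub = tracks[tracks["bird_id"] == ev.bird_id]
        coords = [[round(x, 6), round(y, 6)] for x, y in zip(sub["lon"], sub["lat"])]
        features.append({
            "type": "Feature",
            "properties": {"bird_id": ev.bird_id, "year": int(ev.year),
                           "start_date": str(ev.start_date), "end_date": str(ev.end_date)},
            "geometry": {"type": "LineString", "coordinates": coords},
        })
        for name, pt in (("gibraltar_crossing", ev.leg1_crossing),
                         ("atlas_crossing", ev.leg2_crossing),
                         ("destination", ev.destination)):
            if pt is not None:
                features.append({
                    "type": "Feature",
                    "properties": {"bird_id": ev.bird_id, "boundary": name},
                    "geometry": {"type": "Point",
                                 "coordinates": [round(pt[0], 6), round(pt[1], 6)]},
                })
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}))
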