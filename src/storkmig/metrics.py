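"""Per-leg and whole-migration performance metrics.

Six performance metrics per bird-year and leg: duration (days), counts of
migratory and stopover days, beeline (orthodromic) distance, cumulative
distance over daylight fixes on migratory days, route straightness
(beeline / cumulative, in (0, 1]) and mean flight ODBA.  The whole-migration
beeline is routed through the Strait of Gibraltar crossing, since a single
great circle from Iberia to the Sahel would cut across the Atlantic.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import config
from ._geo import gc_dist_km
from .segmentation import MigrationEvent

logger = logging.getLogger(__name__)

LEGS = (1, 2, 3)

#: upper clip applied to straightness before beta-family modelling
STRAIGHTNESS_CLIP = 1.0 - 1e-9


def great_circle_km(lon1, lat1, lon2, lat2) -> float | np.ndarray:
    """Great-circle distance in km (sphere, IUGG mean radius)."""
    return gc_dist_km(lon1, lat1, lon2, lat2)


def _window_fixes(tracks: pd.DataFrame, bird_id: str, t0, t1) -> pd.DataFrame:
    sub = tracks[tracks["bird_id"] == bird_id]
    days = pd.DatetimeIndex(sub["timestamp"]).tz_localize(None).normalize()
    return sub[np.asarray((days >= t0) & (days <= t1))].sort_values("timestamp")


def beeline_km(tracks: pd.DataFrame, event: MigrationEvent, leg) -> float:
    """Beeline (orthodromic) distance for one leg or the whole migration.

    ``leg='all'``: distance from the first migration fix to the Gibraltar
    crossing plus crossing to destination.  ``leg=k``: distance from the
    first fix of the leg to the first fix of the next leg (leg 3 ends at the
    last migration fix).
    """
    if event.leg1_crossing is None or event.destination is None:
        raise ValueError("event lacks crossing points or destination")
    bounds = event.leg_bounds()
    if leg == "all":
        first = _window_fixes(tracks, event.bird_id, event.start_date, event.start_date)
        if len(first) == 0:
            raise ValueError("no fixes on the migration start day")
        p0 = (first["lon"].iloc[0], first["lat"].iloc[0])
        gx, gy = event.leg1_crossing
        dx, dy = event.destination
        return float(gc_dist_km(p0[0], p0[1], gx, gy) + gc_dist_km(gx, gy, dx, dy))
    t0, t1 = bounds[leg]
    start = _window_fixes(tracks, event.bird_id, t0, t0)
    if len(start) == 0:
        raise ValueError(f"no fixes on the first day of leg {leg}")
    p0 = (start["lon"].iloc[0], start["lat"].iloc[0])
    if leg == 3:
        end = _window_fixes(tracks, event.bird_id, t1, t1)
        if len(end) == 0:
            raise ValueError("no fixes on the last migration day")
        p1 = (end["lon"].iloc[-1], end["lat"].iloc[-1])
    else:
        nxt0, _ = bounds[leg + 1]
        nxt = _window_fixes(tracks, event.bird_id, nxt0, nxt0)
        if len(nxt) == 0:
            raise ValueError(f"no fixes on the first day of leg {leg + 1}")
        p1 = (nxt["lon"].iloc[0], nxt["lat"].iloc[0])
    return float(gc_dist_km(p0[0], p0[1], p1[0], p1[1]))


def cumulative_km(tracks: pd.DataFrame, daily: pd.DataFrame, bird_id: str,
                  t0, t1) -> float:
    """Sum of consecutive-fix distances within each migratory day in [t0, t1].

    Stopover and stationary days contribute nothing; distances never span
    day boundaries (the overnight roost-to-roost hop is not travel).
    """
    sub = _window_fixes(tracks, bird_id, t0, t1)
    if len(sub) == 0:
        return 0.0
    days = pd.DatetimeIndex(sub["timestamp"]).tz_localize(None).normalize()
    dd = daily[(daily["bird_id"] == bird_id)]
    migratory_days = set(pd.DatetimeIndex(dd.loc[dd["day_type"] == "migratory", "date"]))
    total = 0.0
    lon = sub["lon"].to_numpy()
    lat = sub["lat"].to_numpy()
    day_arr = days.to_numpy()
    seg = gc_dist_km(lon[:-1], lat[:-1], lon[1:], lat[1:])
    same_day = day_arr[1:] == day_arr[:-1]
    mig_arr = np.array(sorted(migratory_days), dtype="datetime64[ns]")
    is_mig = np.isin(day_arr[1:], mig_arr) if mig_arr.size else \
        np.zeros(len(day_arr) - 1, dtype=bool)
    total = float(np.sum(seg * (same_day & is_mig)))
    return total


def straightness(beeline: float, cumulative: float,
                 clip: float = STRAIGHTNESS_CLIP) -> float:
    """Route straightness = beeline / cumulative, clipped into (0, clip].

    Raises on zero cumulative distance (undefined ratio).  Values above the
    clip (possible from spherical rounding on near-straight routes) are
    clipped with a logged count so the beta model's open support holds.
    """
    if cumulative <= 0:
        raise ValueError("straightness undefined for zero cumulative distance")
    s = beeline / cumulative
    if s > clip:
        logger.info("straightness %.6f clipped to %.9f", s, clip)
        s = clip
    return float(s)


def mean_flight_odba(classified: pd.DataFrame, bird_id: str, t0, t1) -> float:
    """Mean burst ODBA over accelerometer-labelled flight bursts in a window.

    Speed-rule flight fixes carry no accelerometer data and are excluded.
    Returns NaN (flagged by the caller) when no qualifying burst exists.
    Averaging is per burst, not per fix.
    """
    sub = _window_fixes(classified, bird_id, t0, t1)
    fl = sub[(sub["label_source"] == "accelerometer") & (sub["flight"] == True)]  # noqa: E712
    if len(fl) == 0:
        return float("nan")
    per_burst = fl.groupby("burst_id")["odba"].first()
    return float(per_burst.mean())


def _complete_coverage(daily: pd.DataFrame, bird_id: str, t0, t1) -> bool:
    dd = daily[(daily["bird_id"] == bird_id) & (daily["date"] >= t0) & (daily["date"] <= t1)]
    full = pd.date_range(t0, t1, freq="D")
    return len(dd) == len(full) and not dd["gap"].any()


def summarise(tracks: pd.DataFrame, events: list[MigrationEvent],
              daily: pd.DataFrame, classified: pd.DataFrame | None = None,
              annotated: pd.DataFrame | None = None,
              ages: dict[str, str] | None = None) -> pd.DataFrame:
    """One row per bird-year-leg (legs 1-3 plus 'all') of performance metrics.

    Birds with unresolved diagnostics or incomplete daily coverage are
    emitted with missing metric fields rather than dropped, so inclusion
    filtering stays auditable.  ``annotated`` (optional) supplies per-fix
    weather columns (``blh``, ``wind_support``, ``u925``) averaged over
    migratory-day fixes per leg.
    """
    rows = []
    src_all = classified if classified is not None else tracks
    for ev in events:
        # pre-filter the large per-fix tables once per bird, not per metric
        btracks = tracks[tracks["bird_id"] == ev.bird_id]
        src = src_all[src_all["bird_id"] == ev.bird_id]
        bann = annotated[annotated["bird_id"] == ev.bird_id] \
            if annotated is not None else None
        bdaily = daily[daily["bird_id"] == ev.bird_id]
        age = (ages or {}).get(ev.bird_id)
        base = {"bird_id": ev.bird_id, "year": ev.year, "age": age}
        if not ev.complete or ev.leg1_end_date is None or ev.leg2_end_date is None:
            for leg in (*LEGS, "all"):
                rows.append({**base, "leg": leg,
                             "diagnostic": "; ".join(ev.diagnostics) or "incomplete"})
            continue
        bounds = ev.leg_bounds()
        windows = {**bounds, "all": (ev.start_date, ev.end_date)}
        for leg, (t0, t1) in windows.items():
            row = {**base, "leg": leg, "start_date": t0,
                   "start_date_julian": int(pd.Timestamp(t0).dayofyear)}
            if not _complete_coverage(bdaily, ev.bird_id, t0, t1):
                row["diagnostic"] = "incomplete daily coverage"
                rows.append(row)
                continue
            dd = bdaily[(bdaily["date"] >= t0) & (bdaily["date"] <= t1)]
            n_mig = int((dd["day_type"] == "migratory").sum())
            n_stop = int((dd["day_type"] == "stopover").sum())
            bee = beeline_km(btracks, ev, leg)
            cum = cumulative_km(btracks, bdaily, ev.bird_id, t0, t1)
            row.update({
                "duration_days": (pd.Timestamp(t1) - pd.Timestamp(t0)).days + 1,
                "migratory_days": n_mig,
                "stopover_days": n_stop,
                "beeline_km": bee,
                "cumulative_km": cum,
                "straightness": straightness(bee, cum) if cum > 0 else np.nan,
                "mean_flight_odba": mean_flight_odba(src, ev.bird_id, t0, t1)
                if classified is not None else np.nan,
                "diagnostic": "",
            })
            if leg == "all":
                row["destination_lon"], row["destination_lat"] = ev.destination
            if annotated is not None:
                ann = _window_fixes(bann, ev.bird_id, t0, t1)
                days = pd.DatetimeIndex(ann["timestamp"]).tz_localize(None).normalize()
                mig_days = pd.DatetimeIndex(
                    dd.loc[dd["day_type"] == "migratory", "date"]).to_numpy()
                ann = ann[np.isin(days.to_numpy(), mig_days)] if mig_days.size else ann.iloc[:0]
                for col, name in (("blh", "mean_blh"), ("wind_support", "mean_wind_support"),
                                  ("u925", "mean_zonal_wind")):
                    row[name] = float(ann[col].mean()) if col in ann and len(ann) else np.nan
            rows.append(row)
    return pd.DataFrame(rows)
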