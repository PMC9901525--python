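"""Migration segmentation from daily roost displacements.

The track is reduced to one night roost per bird-day (the last daylight fix
of the calendar day, UTC).  The displacement assigned to a day is the
great-circle distance from the previous night's roost to that day's roost,
i.e. the distance travelled during the day.  Migration starts on the first of
three consecutive days with displacement above 60 km after the bird has left
the breeding range (90% kernel isopleth of pre-migration locations), and the
wintering period starts on the first of three consecutive days below 60 km
after arrival in the wintering range; the end of migration is the day before
that.  Within the migration window, days above 37 km are migratory and the
rest are stopover days.

The window is then partitioned into three barrier legs: leg 1 ends the day
the bird first reaches latitude <= 36 (Strait of Gibraltar), leg 2 ends the
day it first satisfies lat <= 0.58 * lon + 36.12 (Atlas Mountains line), and
leg 3 runs to the end of migration south of the Sahara.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import MultiPolygon, Point, Polygon
from skimage import measure

from . import config
from ._geo import gc_dist_km
from .solar import is_daylight

__all__ = [
    "MigrationEvent", "RangePolygon", "night_roosts", "estimate_range_kernel",
    "detect_migration_window", "classify_days", "partition_legs", "segment_cohort",
]


@dataclass
class MigrationEvent:
    """Start/end and barrier-leg structure of one bird-year migration."""

    bird_id: str
    year: int
    start_date: pd.Timestamp | None = None
    end_date: pd.Timestamp | None = None
    destination: tuple[float, float] | None = None  # (lon, lat)
    leg1_end_date: pd.Timestamp | None = None
    leg1_crossing: tuple[float, float] | None = None
    leg2_end_date: pd.Timestamp | None = None
    leg2_crossing: tuple[float, float] | None = None
    diagnostics: list[str] = field(default_factory=list)

    @property
    def complete(self) -> bool:
        return self.start_date is not None and self.end_date is not None

    def leg_bounds(self) -> dict[int, tuple[pd.Timestamp, pd.Timestamp]]:
        """Inclusive [first, last] day of each leg; legs partition the window."""
        if not (self.complete and self.leg1_end_date is not None
                and self.leg2_end_date is not None):
            raise ValueError("event lacks complete leg structure")
        day = pd.Timedelta(days=1)
        return {
            1: (self.start_date, self.leg1_end_date),
            2: (self.leg1_end_date + day, self.leg2_end_date),
            3: (self.leg2_end_date + day, self.end_date),
        }


@dataclass
class RangePolygon:
    """Kernel utilisation-distribution isopleth (e.g. 90% breeding range)."""

    level: float
    polygon: Polygon | MultiPolygon
    label: str = ""

    def contains(self, lon: float, lat: float) -> bool:
        return self.polygon.contains(Point(lon, lat))


# ---------------------------------------------------------------- night roosts

def night_roosts(tracks: pd.DataFrame, daylight_filter: bool = True) -> pd.DataFrame:
    """Daily roost positions and between-roost displacements per bird.

    Roost = last daylight fix of each UTC calendar day.  Calendar days with
    no fixes inherit the previous roost with ``gap=True``.  The returned
    frame has one row per bird-day with columns ``bird_id, date, lon, lat,
    gap, displacement_km`` where displacement is the distance from the
    previous day's roost to this day's (NaN on each bird's first day).
    """
    if len(tracks) == 0:
        raise ValueError("empty track")
    t = tracks
    if daylight_filter:
        keep = is_daylight(t["lat"].to_numpy(), t["lon"].to_numpy(),
                           t["timestamp"].to_numpy())
        if keep.any():
            t = t[keep]
    t = t.sort_values(["bird_id", "timestamp"], kind="mergesort")
    dates = pd.DatetimeIndex(t["timestamp"]).tz_localize(None).normalize()
    roosts = (
        t.assign(date=dates)[["bird_id", "date", "lon", "lat"]]
        .groupby(["bird_id", "date"], sort=True)
        .last()
        .reset_index()
    )
    out = []
    for bird, grp in roosts.groupby("bird_id", sort=True):
        grp = grp.sort_values("date")
        full = pd.date_range(grp["date"].iloc[0], grp["date"].iloc[-1], freq="D")
        grp = grp.set_index("date").reindex(full)
        gap = grp["lon"].isna()
        grp[["lon", "lat"]] = grp[["lon", "lat"]].ffill()
        disp = gc_dist_km(grp["lon"].shift(1), grp["lat"].shift(1),
                          grp["lon"], grp["lat"])
        out.append(pd.DataFrame({
            "bird_id": bird, "date": full, "lon": grp["lon"].to_numpy(),
            "lat": grp["lat"].to_numpy(), "gap": gap.to_numpy(),
            "displacement_km": np.asarray(disp),
        }))
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------- kernel range

_KM_PER_DEG_LAT = 110.574


def _iso_kde(train: np.ndarray, query: np.ndarray, h: float,
             chunk: int = 4000) -> np.ndarray:
    """Isotropic bivariate Gaussian KDE evaluated at query points (2, m)."""
    tx, ty = train
    out = np.empty(query.shape[1])
    norm = train.shape[1] * 2.0 * np.pi * h * h
    for i in range(0, query.shape[1], chunk):
        qx = query[0, i:i + chunk][:, None]
        qy = query[1, i:i + chunk][:, None]
        d2 = (qx - tx[None, :]) ** 2 + (qy - ty[None, :]) ** 2
        out[i:i + chunk] = np.exp(-0.5 * d2 / (h * h)).sum(axis=1) / norm
    return out


def estimate_range_kernel(lon, lat, level: float = config.KERNEL_LEVEL,
                          min_fixes: int = 30, grid_n: int = 96,
                          label: str = "") -> RangePolygon:
    """Kernel-density range polygon at the given utilisation isopleth.

    Coordinates are projected to local kilometres, smoothed with a bivariate
    Gaussian kernel at the reference (n^(-1/6)) bandwidth, and the smallest
    density isopleth containing ``level`` of the probability mass is traced
    back to a lon/lat polygon.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if not 0.0 < level < 1.0:
        raise ValueError("isopleth level must be in (0, 1); 1.0 is an open isopleth")
    if lon.size < min_fixes:
        raise ValueError(
            f"need >= {min_fixes} fixes for a kernel range (got {lon.size}); "
            "consider a centroid-radius fallback")
    lon0, lat0 = lon.mean(), lat.mean()
    kx = _KM_PER_DEG_LAT * np.cos(np.deg2rad(lat0))
    x = (lon - lon0) * kx
    y = (lat - lat0) * _KM_PER_DEG_LAT
    xy = np.vstack([x, y])
    # degenerate (zero-variance) clouds get a tiny jitter-free fallback box
    if np.linalg.matrix_rank(np.cov(xy)) < 2:
        eps = 1.0 / kx / 100.0
        poly = Polygon([(lon0 - eps, lat0 - eps), (lon0 + eps, lat0 - eps),
                        (lon0 + eps, lat0 + eps), (lon0 - eps, lat0 + eps)])
        return RangePolygon(level=level, polygon=poly, label=label)
    # isotropic reference bandwidth (href): h = mean marginal SD * n^(-1/6)
    h = 0.5 * (x.std(ddof=1) + y.std(ddof=1)) * lon.size ** (-1.0 / 6.0)
    pad = 3.0 * h
    span = max(x.max() - x.min(), y.max() - y.min()) + 2 * pad
    n_grid = int(np.clip(np.ceil(span / (h / 3.0)), grid_n, 512))
    gx = np.linspace(x.min() - pad, x.max() + pad, n_grid)
    gy = np.linspace(y.min() - pad, y.max() + pad, n_grid)
    gxx, gyy = np.meshgrid(gx, gy)
    dens = _iso_kde(xy, np.vstack([gxx.ravel(), gyy.ravel()]), h).reshape(gxx.shape)
    # smallest density isopleth enclosing `level` of the (gridded) mass
    flat = np.sort(dens.ravel())[::-1]
    cum = np.cumsum(flat)
    k = int(np.searchsorted(cum, level * cum[-1]))
    thresh = float(flat[min(k, flat.size - 1)])
    polys = []
    for contour in measure.find_contours(dens, thresh):
        cx = np.interp(contour[:, 1], np.arange(n_grid), gx)
        cy = np.interp(contour[:, 0], np.arange(n_grid), gy)
        if len(cx) >= 4:
            p = Polygon(zip(cx / kx + lon0, cy / _KM_PER_DEG_LAT + lat0))
            if p.is_valid and p.area > 0:
                polys.append(p)
    if not polys:
        raise ValueError("no closed isopleth found; grid too coarse for these fixes")
    geom = polys[0] if len(polys) == 1 else MultiPolygon(_drop_holes(polys))
    return RangePolygon(level=level, polygon=geom, label=label)


def _drop_holes(polys: list[Polygon]) -> list[Polygon]:
    """Keep only outer rings (contours nested inside another are holes)."""
    outer = []
    for p in polys:
        if not any(q.contains(p) for q in polys if q is not p):
            outer.append(p)
    return outer


# ----------------------------------------------------------- window detection

def _in_range(roost_lon, roost_lat, poly) -> np.ndarray:
    """Vector membership for a RangePolygon or (lon, lat, radius_km) fallback."""
    if isinstance(poly, RangePolygon):
        return np.array([poly.contains(lo, la) for lo, la in zip(roost_lon, roost_lat)])
    lon0, lat0, radius_km = poly
    return np.asarray(gc_dist_km(roost_lon, roost_lat, lon0, lat0)) <= radius_km


def _first_run_start(mask: np.ndarray, run: int) -> int | None:
    """Index of the first position beginning ``run`` consecutive True values."""
    if mask.size < run:
        return None
    conv = np.convolve(mask.astype(int), np.ones(run, dtype=int), mode="valid")
    hits = np.nonzero(conv == run)[0]
    return int(hits[0]) if hits.size else None


def detect_migration_window(
    daily: pd.DataFrame,
    breeding_range,
    wintering_range,
    displacement_km: float = config.MIGRATION_DISPLACEMENT_KM,
    consecutive_days: int = config.CONSECUTIVE_DAYS,
) -> MigrationEvent:
    """Detect start and end of autumn migration for one bird's daily series.

    ``breeding_range`` / ``wintering_range`` are :class:`RangePolygon` objects
    or ``(lon, lat, radius_km)`` centroid fallbacks.  Returns a
    :class:`MigrationEvent` with only start/end/destination set; if no
    qualifying run exists the corresponding field stays None and a diagnostic
    is recorded (incomplete migration).
    """
    d = daily.sort_values("date").reset_index(drop=True)
    bird = str(d["bird_id"].iloc[0])
    year = int(pd.Timestamp(d["date"].iloc[0]).year)
    ev = MigrationEvent(bird_id=bird, year=year)
    disp = d["displacement_km"].to_numpy()
    lon = d["lon"].to_numpy()
    lat = d["lat"].to_numpy()

    outside = ~_in_range(lon, lat, breeding_range)
    if not outside.any():
        ev.diagnostics.append("never left breeding range")
        return ev
    i_dep = int(np.argmax(outside))
    fast = (disp > displacement_km) & ~np.isnan(disp)
    fast_after = fast.copy()
    fast_after[:i_dep] = False
    i0 = _first_run_start(fast_after, consecutive_days)
    if i0 is None:
        ev.diagnostics.append("no qualifying departure run (incomplete migration)")
        return ev
    ev.start_date = pd.Timestamp(d["date"].iloc[i0])

    inside_w = _in_range(lon, lat, wintering_range)
    inside_w[: i0 + 1] = False
    if not inside_w.any():
        ev.diagnostics.append("never reached wintering range")
        return ev
    i_arr = int(np.argmax(inside_w))
    slow = (disp < displacement_km) & ~np.isnan(disp)
    slow_after = slow.copy()
    slow_after[:i_arr] = False
    i1 = _first_run_start(slow_after, consecutive_days)
    if i1 is None:
        ev.diagnostics.append("no qualifying arrival run (incomplete migration)")
        return ev
    ev.end_date = pd.Timestamp(d["date"].iloc[i1 - 1])
    ev.destination = (float(lon[i1 - 1]), float(lat[i1 - 1]))
    return ev


def classify_days(daily: pd.DataFrame, event: MigrationEvent,
                  stopover_km: float = config.STOPOVER_DISPLACEMENT_KM) -> pd.DataFrame:
    """Assign day types: migratory (> ``stopover_km``) or stopover inside the
    migration window, stationary outside."""
    if not event.complete:
        raise ValueError("event has no complete migration window")
    d = daily.copy()
    inside = (d["date"] >= event.start_date) & (d["date"] <= event.end_date)
    migratory = inside & (d["displacement_km"] > stopover_km)
    d["day_type"] = np.where(~inside, "stationary",
                             np.where(migratory, "migratory", "stopover"))
    return d


# ------------------------------------------------------------- leg partition

def _interp_crossing(p0, p1, w0: float, w1: float) -> tuple[float, float]:
    """Linear crossing of the zero of a field w on the segment p0 -> p1."""
    f = w0 / (w0 - w1)
    return (float(p0[0] + f * (p1[0] - p0[0])), float(p0[1] + f * (p1[1] - p0[1])))


def partition_legs(tracks: pd.DataFrame, event: MigrationEvent,
                   gibraltar_lat: float = config.GIBRALTAR_LAT,
                   atlas_slope: float = config.ATLAS_SLOPE,
                   atlas_intercept: float = config.ATLAS_INTERCEPT) -> MigrationEvent:
    """Fill leg-boundary dates and interpolated crossing points on the event.

    Leg 1 ends on the first day with a fix at latitude <= ``gibraltar_lat``;
    leg 2 ends on the first later day with a fix south of the Atlas line
    ``lat = atlas_slope * lon + atlas_intercept``.  Crossing points are
    linearly interpolated on the track segment straddling each boundary.
    Boundaries never crossed leave the fields None with a diagnostic.
    """
    if not event.complete:
        raise ValueError("event has no complete migration window")
    sub = tracks[tracks["bird_id"] == event.bird_id].sort_values("timestamp")
    days = pd.DatetimeIndex(sub["timestamp"]).tz_localize(None).normalize()
    inwin = np.asarray((days >= event.start_date) & (days <= event.end_date))
    sub = sub[inwin]
    days = days[inwin]
    lon = sub["lon"].to_numpy()
    lat = sub["lat"].to_numpy()

    w1 = lat - gibraltar_lat  # <= 0 once past the Strait
    idx1 = np.nonzero(w1 <= 0)[0]
    if idx1.size == 0:
        event.diagnostics.append("never crossed the Strait latitude")
        return event
    i1 = int(idx1[0])
    event.leg1_end_date = pd.Timestamp(days[i1])
    if i1 > 0:
        event.leg1_crossing = _interp_crossing(
            (lon[i1 - 1], lat[i1 - 1]), (lon[i1], lat[i1]), w1[i1 - 1], w1[i1])
    else:
        event.leg1_crossing = (float(lon[i1]), float(lat[i1]))

    w2 = lat - (atlas_slope * lon + atlas_intercept)
    w2_masked = w2.copy()
    w2_masked[: i1 + 1] = np.inf  # only after the Strait crossing
    idx2 = np.nonzero(w2_masked <= 0)[0]
    if idx2.size == 0:
        event.diagnostics.append("never crossed the Atlas line")
        return event
    i2 = int(idx2[0])
    event.leg2_end_date = pd.Timestamp(days[i2])
    if i2 > 0 and np.isfinite(w2[i2 - 1]):
        event.leg2_crossing = _interp_crossing(
            (lon[i2 - 1], lat[i2 - 1]), (lon[i2], lat[i2]), w2[i2 - 1], w2[i2])
    else:
        event.leg2_crossing = (float(lon[i2]), float(lat[i2]))
    return event


# ------------------------------------------------------------------ pipeline

def segment_cohort(tracks: pd.DataFrame,
                   breeding_months: tuple[int, ...] = (6,),
                   wintering_months: tuple[int, ...] = (10,),
                   kernel_level: float = config.KERNEL_LEVEL,
                   max_kernel_fixes: int = 300,
                   thresholds: config.Thresholds | None = None,
                   ) -> tuple[list[MigrationEvent], pd.DataFrame]:
    """Segment every bird in a cohort: kernels, window, day types, legs.

    Breeding/wintering ranges are per-bird kernel isopleths of the fixes in
    the stated months (June and October by analogy with the field protocol),
    thinned to at most ``max_kernel_fixes`` evenly spaced fixes for the
    density estimate.  Returns the event list and the day-typed daily table.
    """
    thr = thresholds or config.Thresholds()
    daily = night_roosts(tracks)
    events: list[MigrationEvent] = []
    daily_out = []
    months = pd.DatetimeIndex(tracks["timestamp"]).tz_localize(None).month
    for bird, d in daily.groupby("bird_id", sort=True):
        sub = tracks[tracks["bird_id"] == bird]
        m = months[tracks["bird_id"] == bird]
        ranges = {}
        for name, sel_months in (("breeding", breeding_months),
                                 ("wintering", wintering_months)):
            pts = sub[np.isin(m, sel_months)]
            if len(pts) >= 30:
                step = max(len(pts) // max_kernel_fixes, 1)
                pts = pts.iloc[::step]
                ranges[name] = estimate_range_kernel(
                    pts["lon"], pts["lat"], level=kernel_level, label=name)
            else:  # centroid-radius fallback around first/last roost
                anchor = d.iloc[0] if name == "breeding" else d.iloc[-1]
                ranges[name] = (float(anchor["lon"]), float(anchor["lat"]), 30.0)
        ev = detect_migration_window(
            d, ranges["breeding"], ranges["wintering"],
            displacement_km=thr.migration_displacement_km,
            consecutive_days=thr.consecutive_days)
        if ev.complete:
            ev = partition_legs(tracks, ev, gibraltar_lat=thr.gibraltar_lat,
                                atlas_slope=thr.atlas_slope,
                                atlas_intercept=thr.atlas_intercept)
            daily_out.append(classify_days(d, ev, stopover_km=thr.stopover_displacement_km))
        else:
            dd = d.copy()
            dd["day_type"] = "stationary"
            daily_out.append(dd)
        events.append(ev)
    return events, pd.concat(daily_out, ignore_index=True)
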