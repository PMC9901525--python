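"""Synthetic biologging inputs with known ground truth.

Generates the three inputs the analysis consumes — a GPS track table on the
field duty cycle (bursts of 9 fixes at 1 Hz every 20 minutes during
daylight), matched tri-axial acceleration bursts, and an hourly gridded wind
/ boundary-layer field — for a cohort of birds migrating from Iberia through
the Strait of Gibraltar and over the Atlas into the Sahel, with stopovers.

The movement model is deliberately simple: waypoint-following with Gaussian
daily-distance noise and a night roost held from the last daylight fix to the
next morning.  During leg-3 (Sahara) flight days the realised daily eastward
displacement additionally drifts with the local zonal wind at a configurable
coupling (m/s of longitudinal speed per m/s of zonal wind), and the mean
zonal wind itself declines linearly through the season (late-season
easterlies, the Harmattan pattern), so late birds are pushed west.  Every
construction-level quantity (true start/end dates, leg-crossing dates, day
types, burst behaviours, destination) is recorded as ground truth.

``simulate_model_data`` is a separate generator for mixed-model recovery
studies: it draws responses directly from a stated gaussian or beta-logit
mixed model so printed coefficients can be used as generating truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from ._geo import gc_dist_km
from .solar import daylight_window_utc

__all__ = [
    "SimConfig", "GroundTruth", "default_signatures", "simulate_wind_field",
    "simulate_accel_burst", "simulate_cohort", "simulate_model_data",
]

_KM_PER_DEG_LAT = 110.574


def default_signatures() -> dict:
    """Per-logger, per-behaviour acceleration signatures (g).

    ``mean`` is the static (postural/gravitational) component, ``sd`` the
    dynamic noise amplitude.  Flapping has the highest dynamic amplitude and
    resting the lowest, so expected ODBA orders
    resting < foraging < soaring < flapping.  Logger B sensors read slightly
    hotter, motivating the per-manufacturer classifiers.
    """
    base = {
        "resting": {"mean": (0.0, 0.0, 1.0), "sd": 0.01},
        "foraging": {"mean": (0.25, 0.0, 0.95), "sd": 0.03},
        "soaring": {"mean": (0.0, 0.2, 0.95), "sd": 0.07},
        "flapping": {"mean": (0.0, 0.0, 0.85), "sd": 0.18},
    }
    scaled = {
        k: {"mean": tuple(1.05 * m for m in v["mean"]), "sd": 1.15 * v["sd"]}
        for k, v in base.items()
    }
    return {"A": base, "B": scaled}


@dataclass
class SimConfig:
    """Study conditions for the cohort generator.

    Defaults emulate the field protocol: 16 adults and 59 juveniles departing
    Iberia between early July and early September (juveniles on average a few
    days earlier), daily migratory displacements around 170 km, long
    stopovers concentrated before the Sahara, and a zonal wind that turns
    easterly late in the season.
    """

    seed: int = 0
    n_adults: int = 16
    n_juveniles: int = 59
    season_start: str = "2016-06-21"
    season_end: str = "2016-10-31"
    start_date_range: tuple[str, str] = ("2016-07-07", "2016-09-04")
    adult_departure_mean_doy: float = 223.0   # ~10 August
    juvenile_departure_mean_doy: float = 217.0  # ~4 August
    departure_sd_days: float = 13.0
    #: polyline: Iberia nest area, Gibraltar, Atlas, central Sahara, Sahel
    route_waypoints: tuple = (
        (-8.0, 39.6), (-5.6, 36.0), (-6.5, 32.35), (-7.2, 26.0), (-6.8, 15.8),
    )
    nest_jitter_km: float = 1.0
    sahel_arrival_lat: float = 16.6
    stopover_prob_leg: dict = field(default_factory=lambda: {1: 0.55, 2: 0.45, 3: 0.10})
    forced_migratory_days: int = 3
    daily_distance_km_mean: float = 170.0
    daily_distance_km_sd: float = 25.0
    #: stopover days return to the same night roost (local foraging trips are
    #: not resolved); any net stopover drift would leak into the beeline while
    #: stopover movement is excluded from the cumulative distance
    stopover_displacement_km: float = 0.0
    #: SD (km) of the day-to-day lateral offset from the route axis; produces
    #: realistic route straightness around 0.7 instead of near-beeline tracks
    route_meander_km: float = 120.0
    #: m/s of realised longitudinal speed per m/s of zonal wind during leg-3
    #: flight; the default is calibrated so the longitudinal-speed regression
    #: slope matches the published flight-direction model, not a measured fact
    drift_coefficient: float = 1.674
    # wind / boundary-layer field
    lon_bounds: tuple[float, float] = (-18.0, 12.0)
    lat_bounds: tuple[float, float] = (8.0, 46.0)
    grid_step_deg: float = 1.0
    #: zonal wind at season start and its linear decline (strengthening
    #: easterlies late in the season); at this slope the implied shift of the
    #: destination longitude is ~-0.13 deg per day of later departure
    u0_ms: float = 0.5
    u_slope_per_day: float = -0.02
    u_lat_gradient: float = 0.0
    wind_noise_sd: float = 0.5
    v0_ms: float = 0.0
    blh0_m: float = 1800.0
    blh_seasonal_slope: float = -5.0
    blh_noise_sd: float = 50.0
    # duty cycle
    burst_len: int = 9
    sample_rate_hz: float = 1.0
    fix_interval_min: float = 20.0
    with_accel: bool = True
    travel_start_after_sunrise_min: float = 120.0
    travel_end_before_sunset_min: float = 60.0
    soaring_fraction: float = 0.7
    behaviour_signatures: dict = field(default_factory=default_signatures)
    signature_noise_scale: float = 1.0
    logger_types: tuple = ("A", "B")

    def validate(self) -> None:
        if self.departure_sd_days < 0 or self.daily_distance_km_sd < 0 \
                or self.wind_noise_sd < 0 or self.blh_noise_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        for p in self.stopover_prob_leg.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("stopover probabilities must be in [0, 1]")
        if pd.Timestamp(self.start_date_range[0]) > pd.Timestamp(self.start_date_range[1]):
            raise ValueError("start_date_range must be ordered")
        lons = [w[0] for w in self.route_waypoints]
        lats = [w[1] for w in self.route_waypoints]
        if min(lons) < self.lon_bounds[0] or max(lons) > self.lon_bounds[1] \
                or min(lats) < self.lat_bounds[0] or max(lats) > self.lat_bounds[1]:
            raise ValueError("weather domain smaller than the route bounding box")


@dataclass
class GroundTruth:
    """Construction-level truth for a simulated cohort."""

    birds: pd.DataFrame    # start/end/leg dates, destination, age, logger
    days: pd.DataFrame     # per bird-day true day type and end-of-day position
    bursts: pd.DataFrame   # per burst true behaviour
    coefficients: dict     # generating parameters relevant to model recovery


# ------------------------------------------------------------------ wind grid

def simulate_wind_field(config: SimConfig, rng: np.random.Generator | None = None
                        ) -> xr.Dataset:
    """Hourly (u925, v925, blh) grid over the simulated domain and season.

    Mean zonal wind drifts linearly with day-of-season and optionally with
    latitude; boundary layer height declines linearly; i.i.d. Gaussian noise
    per cell on top.  Deterministic under a fixed config seed.
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    times = pd.date_range(config.season_start, config.season_end, freq="h", tz=None)
    lats = np.arange(config.lat_bounds[0], config.lat_bounds[1] + 1e-9, config.grid_step_deg)
    lons = np.arange(config.lon_bounds[0], config.lon_bounds[1] + 1e-9, config.grid_step_deg)
    day = ((times - times[0]) / pd.Timedelta(days=1)).to_numpy()
    shape = (len(times), len(lats), len(lons))
    u = (config.u0_ms + config.u_slope_per_day * day)[:, None, None] \
        + config.u_lat_gradient * (lats - lats.mean())[None, :, None] \
        + np.zeros(shape)
    if config.wind_noise_sd > 0:
        u = u + rng.normal(0.0, config.wind_noise_sd, shape)
    v = np.full(shape, config.v0_ms)
    if config.wind_noise_sd > 0:
        v = v + rng.normal(0.0, config.wind_noise_sd, shape)
    blh = (config.blh0_m + config.blh_seasonal_slope * day)[:, None, None] + np.zeros(shape)
    if config.blh_noise_sd > 0:
        blh = blh + rng.normal(0.0, config.blh_noise_sd, shape)
    blh = np.clip(blh, 50.0, None)
    return xr.Dataset(
        {
            "u925": (("time", "lat", "lon"), u, {"units": "m s-1"}),
            "v925": (("time", "lat", "lon"), v, {"units": "m s-1"}),
            "blh": (("time", "lat", "lon"), blh, {"units": "m"}),
        },
        coords={"time": times, "lat": lats, "lon": lons},
    )


# -------------------------------------------------------------- accel bursts

def simulate_accel_burst(behaviour: str, logger_type: str,
                         rng: np.random.Generator,
                         config: SimConfig | None = None) -> np.ndarray:
    """One (burst_len, 3) tri-axial burst for a behaviour and logger type."""
    cfg = config or SimConfig()
    try:
        sig = cfg.behaviour_signatures[logger_type][behaviour]
    except KeyError as exc:
        raise ValueError(f"unknown behaviour or logger type: {exc}") from exc
    sd = sig["sd"] * cfg.signature_noise_scale
    return np.asarray(sig["mean"], dtype=float) + rng.normal(0.0, sd, (cfg.burst_len, 3))


def simulate_labelled_bursts(n_per_class: int, logger_type: str, seed: int = 0,
                             config: SimConfig | None = None):
    """Balanced labelled bursts for classifier training: (list of arrays, labels)."""
    cfg = config or SimConfig(seed=seed)
    rng = np.random.default_rng(seed)
    bursts, labels = [], []
    for beh in sorted(cfg.behaviour_signatures[logger_type]):
        for _ in range(n_per_class):
            bursts.append(simulate_accel_burst(beh, logger_type, rng, cfg))
            labels.append(beh)
    return bursts, np.asarray(labels)


# ------------------------------------------------------------------- cohort

def _polyline_interp(cum_km: np.ndarray, pts: np.ndarray, s: float) -> np.ndarray:
    """Position (lon, lat) at arc length s along the waypoint polyline."""
    s = min(max(s, 0.0), float(cum_km[-1]))
    i = int(np.clip(np.searchsorted(cum_km, s, side="right") - 1, 0, len(cum_km) - 2))
    f = (s - cum_km[i]) / (cum_km[i + 1] - cum_km[i])
    return pts[i] + f * (pts[i + 1] - pts[i])


def _grid_u_at(grid_u: np.ndarray, tnum: np.ndarray, lats: np.ndarray,
               lons: np.ndarray, when: pd.Timestamp, lon: float, lat: float) -> float:
    """Nearest-hour bilinear zonal wind lookup (generator-internal)."""
    ti = int(np.clip(np.searchsorted(tnum, when.value), 0, len(tnum) - 1))
    if ti > 0 and abs(when.value - tnum[ti - 1]) <= abs(tnum[ti] - when.value):
        ti -= 1
    i = int(np.clip(np.searchsorted(lons, lon, side="right") - 1, 0, len(lons) - 2))
    j = int(np.clip(np.searchsorted(lats, lat, side="right") - 1, 0, len(lats) - 2))
    fx = np.clip((lon - lons[i]) / (lons[i + 1] - lons[i]), 0, 1)
    fy = np.clip((lat - lats[j]) / (lats[j + 1] - lats[j]), 0, 1)
    u = grid_u[ti]
    return float(u[j, i] * (1 - fx) * (1 - fy) + u[j, i + 1] * fx * (1 - fy)
                 + u[j + 1, i] * (1 - fx) * fy + u[j + 1, i + 1] * fx * fy)


def simulate_cohort(config: SimConfig | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame, xr.Dataset, GroundTruth]:
    """Simulate a full cohort: tracks, acceleration, weather, ground truth.

    Fixes are emitted only between local sunrise and sunset at the field duty
    cycle; the night roost is the position held from the last daylight fix to
    the first of the next day.  See the module docstring for the movement
    model.
    """
    cfg = config or SimConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    grid = simulate_wind_field(cfg, rng)
    grid_u = grid["u925"].values
    tnum = pd.DatetimeIndex(grid["time"].values).asi8
    glat = grid["lat"].values.astype(float)
    glon = grid["lon"].values.astype(float)

    season = pd.date_range(cfg.season_start, cfg.season_end, freq="D")
    d0 = pd.Timestamp(cfg.start_date_range[0]).dayofyear
    d1 = pd.Timestamp(cfg.start_date_range[1]).dayofyear
    year = pd.Timestamp(cfg.season_start).year
    burst_sec = (cfg.burst_len - 1) / cfg.sample_rate_hz

    birds = [(f"A{i+1:02d}", "adult") for i in range(cfg.n_adults)] + \
            [(f"J{i+1:02d}", "juvenile") for i in range(cfg.n_juveniles)]

    trk_parts, acc_parts = [], []
    truth_birds, truth_days, truth_bursts = [], [], []

    for bird_id, age in birds:
        logger_type = cfg.logger_types[int(rng.integers(len(cfg.logger_types)))]
        mean_doy = cfg.adult_departure_mean_doy if age == "adult" \
            else cfg.juvenile_departure_mean_doy
        doy = int(np.clip(round(rng.normal(mean_doy, cfg.departure_sd_days)), d0, d1))
        depart = pd.Timestamp(year, 1, 1) + pd.Timedelta(days=doy - 1)

        pts = np.asarray(cfg.route_waypoints, dtype=float)
        jit = rng.normal(0.0, cfg.nest_jitter_km, 2)
        nest = pts[0] + np.array([jit[0] / (_KM_PER_DEG_LAT * np.cos(np.deg2rad(pts[0][1]))),
                                  jit[1] / _KM_PER_DEG_LAT])
        pts[0] = nest
        seg = gc_dist_km(pts[:-1, 0], pts[:-1, 1], pts[1:, 0], pts[1:, 1])
        cum = np.concatenate([[0.0], np.cumsum(seg)])

        s_km = 0.0
        lon_off = 0.0
        pos = nest.copy()
        phase = "pre"
        mig_day_count = 0
        t_start = t_end = t_leg1 = t_leg2 = None
        dest = None

        day_records = []  # (date, day_type, P0, P1, dist_km)
        for date in season:
            P0 = pos.copy()
            if phase == "pre" and date >= depart:
                phase = "migrating"
                t_start = date
            if phase == "migrating":
                leg = 3 if P0[1] <= 0.58 * P0[0] + 36.12 else (2 if P0[1] <= 36.0 else 1)
                forced = mig_day_count < cfg.forced_migratory_days
                stop = (not forced) and rng.random() < cfg.stopover_prob_leg.get(leg, 0.0)
                if stop:
                    ang = rng.uniform(0, 2 * np.pi)
                    d = abs(rng.normal(0.0, cfg.stopover_displacement_km)) \
                        if cfg.stopover_displacement_km > 0 else 0.0
                    pos = P0 + np.array([
                        d * np.cos(ang) / (_KM_PER_DEG_LAT * np.cos(np.deg2rad(P0[1]))),
                        d * np.sin(ang) / _KM_PER_DEG_LAT])
                    day_type, dist = "stopover", d
                else:
                    mig_day_count += 1
                    dist = float(np.clip(rng.normal(cfg.daily_distance_km_mean,
                                                    cfg.daily_distance_km_sd), 80.0, 300.0))
                    s_km += dist
                    base = _polyline_interp(cum, pts, s_km)
                    if cfg.route_meander_km > 0:
                        ahead = _polyline_interp(cum, pts, s_km + 10.0)
                        ck = np.cos(np.deg2rad(base[1]))
                        fwd = np.array([(ahead[0] - base[0]) * ck, ahead[1] - base[1]])
                        nrm = np.linalg.norm(fwd)
                        if nrm > 0:
                            perp = np.array([-fwd[1], fwd[0]]) / nrm
                            L = rng.normal(0.0, cfg.route_meander_km)
                            base = base + np.array([
                                perp[0] * L / (_KM_PER_DEG_LAT * ck),
                                perp[1] * L / _KM_PER_DEG_LAT])
                    if leg == 3:
                        sr, ss = daylight_window_utc(P0[1], P0[0], date)
                        t_fl0 = sr + cfg.travel_start_after_sunrise_min
                        t_fl1 = ss - cfg.travel_end_before_sunset_min
                        flight_s = max((t_fl1 - t_fl0) * 60.0, 0.0)
                        noon = date + pd.Timedelta(hours=12)
                        u = _grid_u_at(grid_u, tnum, glat, glon, noon, P0[0], P0[1])
                        dkm = cfg.drift_coefficient * u * flight_s / 1000.0
                        lon_off += dkm / (_KM_PER_DEG_LAT * np.cos(np.deg2rad(P0[1])))
                    pos = base + np.array([lon_off, 0.0])
                    dist = float(gc_dist_km(P0[0], P0[1], pos[0], pos[1]))
                    day_type = "migratory"
                if pos[1] <= cfg.sahel_arrival_lat:
                    phase = "wintering"
                    t_end = date
                    dest = pos.copy()
                if t_leg1 is None and pos[1] <= 36.0:
                    t_leg1 = date
                if t_leg1 is not None and t_leg2 is None \
                        and pos[1] <= 0.58 * pos[0] + 36.12:
                    t_leg2 = date
            else:  # pre or wintering: hold around a fixed anchor with small jitter
                anchor = nest if phase == "pre" else dest
                jit = rng.normal(0.0, 0.5, 2)
                pos = anchor + np.array([jit[0] / (_KM_PER_DEG_LAT * np.cos(np.deg2rad(anchor[1]))),
                                         jit[1] / _KM_PER_DEG_LAT])
                day_type = "stationary"
                dist = float(gc_dist_km(P0[0], P0[1], pos[0], pos[1]))
            day_records.append((date, day_type, P0, pos.copy(), dist if phase != "pre" else 0.0))

        truth_birds.append({
            "bird_id": bird_id, "age": age, "logger_type": logger_type,
            "start_date": t_start, "end_date": t_end,
            "leg1_end_date": t_leg1, "leg2_end_date": t_leg2,
            "destination_lon": dest[0] if dest is not None else np.nan,
            "destination_lat": dest[1] if dest is not None else np.nan,
        })

        # ---- emit fixes and bursts for this bird
        sig = cfg.behaviour_signatures[logger_type]
        for di, (date, day_type, P0, P1, dist) in enumerate(day_records):
            truth_days.append({"bird_id": bird_id, "date": date, "day_type": day_type,
                               "lon": P1[0], "lat": P1[1]})
            sr, ss = daylight_window_utc(P0[1], P0[0], date)
            if not np.isfinite(sr):
                continue
            first = sr + 5.0
            last = ss - 5.0 - burst_sec / 60.0
            if last <= first:
                continue
            b_start = np.ceil(np.arange(first, last, cfg.fix_interval_min))
            nb = len(b_start)
            t_fl0 = sr + cfg.travel_start_after_sunrise_min
            t_fl1 = ss - cfg.travel_end_before_sunset_min
            # fix times in minutes-of-day, (nb, burst_len)
            offs = np.arange(cfg.burst_len) / cfg.sample_rate_hz / 60.0
            tmin = b_start[:, None] + offs[None, :]
            frac = np.clip((tmin - t_fl0) / max(t_fl1 - t_fl0, 1e-9), 0.0, 1.0)
            lon = P0[0] + frac * (P1[0] - P0[0])
            lat = P0[1] + frac * (P1[1] - P0[1])
            moving = (frac > 0) & (frac < 1)
            if day_type == "migratory":
                v_kmh = dist / max((t_fl1 - t_fl0) / 60.0, 1e-6)
            else:
                v_kmh = cfg.stopover_displacement_km / max((t_fl1 - t_fl0) / 60.0, 1e-6)
            speed = np.where(moving, v_kmh, 0.2) + rng.normal(0, 0.1, tmin.shape)
            speed = np.clip(speed, 0.0, None)

            mid_moving = moving[:, cfg.burst_len // 2]
            if day_type == "migratory":
                beh = np.where(mid_moving,
                               np.where(rng.random(nb) < cfg.soaring_fraction,
                                        "soaring", "flapping"),
                               np.where(rng.random(nb) < 0.5, "foraging", "resting"))
            else:
                beh = np.where(rng.random(nb) < 0.5, "foraging", "resting")

            bids = np.array([f"{bird_id}:{di}:{k}" for k in range(nb)], dtype=object)
            # exact nanosecond arithmetic: whole-minute burst starts plus
            # whole-sample offsets (float-minute rounding would alias the
            # 1 Hz fixes onto duplicate seconds)
            ns = (date.value
                  + np.round(b_start * 60e9).astype("int64")[:, None]
                  + np.round(np.arange(cfg.burst_len) * 1e9
                             / cfg.sample_rate_hz).astype("int64")[None, :])
            ts = ns.astype("datetime64[ns]").ravel()
            trk_parts.append((bird_id, ts, lon.ravel(), lat.ravel(), speed.ravel(),
                              np.repeat(bids, cfg.burst_len)))
            truth_bursts.append((bird_id, bids, beh))
            if cfg.with_accel:
                means = np.array([sig[b]["mean"] for b in beh])  # (nb, 3)
                sds = np.array([sig[b]["sd"] for b in beh]) * cfg.signature_noise_scale
                samples = means[:, None, :] + rng.normal(
                    0.0, 1.0, (nb, cfg.burst_len, 3)) * sds[:, None, None]
                acc_parts.append((np.repeat(bids, cfg.burst_len), bird_id,
                                  np.tile(np.arange(cfg.burst_len), nb),
                                  samples, logger_type))

    tracks = pd.DataFrame({
        "bird_id": np.concatenate([np.repeat(p[0], len(p[1])) for p in trk_parts]),
        "timestamp": np.concatenate([p[1] for p in trk_parts]),
        "lon": np.concatenate([p[2] for p in trk_parts]),
        "lat": np.concatenate([p[3] for p in trk_parts]),
        "ground_speed": np.concatenate([p[4] for p in trk_parts]),
        "burst_id": np.concatenate([p[5] for p in trk_parts]),
    })
    tracks["timestamp"] = pd.DatetimeIndex(tracks["timestamp"]).tz_localize("UTC")
    if acc_parts:
        accel = pd.DataFrame({
            "burst_id": np.concatenate([p[0] for p in acc_parts]),
            "bird_id": np.concatenate([np.repeat(p[1], len(p[0])) for p in acc_parts]),
            "sample_index": np.concatenate([p[2] for p in acc_parts]),
            "ax": np.concatenate([p[3][:, :, 0].ravel() for p in acc_parts]),
            "ay": np.concatenate([p[3][:, :, 1].ravel() for p in acc_parts]),
            "az": np.concatenate([p[3][:, :, 2].ravel() for p in acc_parts]),
            "sample_rate": cfg.sample_rate_hz,
            "logger_type": np.concatenate([np.repeat(p[4], len(p[0])) for p in acc_parts]),
        })
    else:
        accel = pd.DataFrame(
            columns=["burst_id", "bird_id", "sample_index", "ax", "ay", "az",
                     "sample_rate", "logger_type"])
    bursts_df = pd.DataFrame({
        "bird_id": np.concatenate([np.repeat(p[0], len(p[1])) for p in truth_bursts]),
        "burst_id": np.concatenate([p[1] for p in truth_bursts]),
        "behaviour": np.concatenate([p[2] for p in truth_bursts]),
    }) if truth_bursts else pd.DataFrame(columns=["bird_id", "burst_id", "behaviour"])
    truth = GroundTruth(
        birds=pd.DataFrame(truth_birds),
        days=pd.DataFrame(truth_days),
        bursts=bursts_df,
        coefficients={"drift_coefficient": cfg.drift_coefficient,
                      "u_slope_per_day": cfg.u_slope_per_day},
    )
    return tracks, accel, grid, truth


# ------------------------------------------------------------- model recovery

def simulate_model_data(
    fixed_effects: dict[str, float],
    random_effect_sds: dict[str, float],
    residual_sd: float = 1.0,
    n_birds: int = 75,
    n_obs_per_bird: int = 1,
    family: str = "gaussian",
    seed: int = 0,
    *,
    beta_precision: float | None = None,
    n_years: int = 2,
    date_range: tuple[float, float] = (203.0, 277.0),
    juvenile_fraction: float = 0.78,
    wind_mean: float = -1.0,
    wind_sd: float = 3.0,
    scale_date: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Draw a dataset from a stated mixed model, recording the truth.

    ``fixed_effects`` maps term names to generating coefficients; recognised
    terms are ``intercept``, ``date`` (per Julian day, or per SD when
    ``scale_date``), ``age`` (juvenile offset), ``wind`` and ``date_wind``.
    ``family`` is ``gaussian`` (identity link) or ``beta`` (logit link;
    requires ``beta_precision``).  Bird and year random intercepts are drawn
    with the given SDs (zero allowed; negative rejected).
    """
    for name, sd in {**random_effect_sds, "residual": residual_sd}.items():
        if sd < 0:
            raise ValueError(f"negative SD for {name!r}")
    if family not in ("gaussian", "beta"):
        raise ValueError(f"unknown family {family!r}")
    if family == "beta" and (beta_precision is None or beta_precision <= 0):
        raise ValueError("beta family requires a positive precision parameter")
    rng = np.random.default_rng(seed)
    n = n_birds * n_obs_per_bird
    bird = np.repeat(np.arange(n_birds), n_obs_per_bird)
    year = rng.integers(0, n_years, n_birds)[bird]
    juv = (rng.random(n_birds) < juvenile_fraction).astype(float)[bird]
    date = rng.uniform(*date_range, n)
    date_cov = date.copy()
    date_scale = (date.mean(), date.std(ddof=1))
    if scale_date:
        date_cov = (date - date_scale[0]) / date_scale[1]
    wind = rng.normal(wind_mean, wind_sd, n)

    eta = np.full(n, fixed_effects.get("intercept", 0.0))
    eta += fixed_effects.get("date", 0.0) * date_cov
    eta += fixed_effects.get("age", 0.0) * juv
    eta += fixed_effects.get("wind", 0.0) * wind
    eta += fixed_effects.get("date_wind", 0.0) * date_cov * wind
    b_bird = rng.normal(0.0, random_effect_sds.get("bird", 0.0), n_birds)
    b_year = rng.normal(0.0, random_effect_sds.get("year", 0.0), n_years)
    eta = eta + b_bird[bird] + b_year[year]

    if family == "gaussian":
        y = eta + (rng.normal(0.0, residual_sd, n) if residual_sd > 0 else 0.0)
    else:
        mu = 1.0 / (1.0 + np.exp(-eta))
        phi = beta_precision
        y = rng.beta(mu * phi, (1.0 - mu) * phi)
    df = pd.DataFrame({
        "bird": [f"b{i:03d}" for i in bird],
        "year": [f"y{i}" for i in year],
        "age": np.where(juv == 1.0, "juvenile", "adult"),
        "date": date,
        "date_s": (date - date_scale[0]) / date_scale[1],
        "wind": wind,
        "y": y,
    })
    truth = {"fixed_effects": dict(fixed_effects),
             "random_effect_sds": dict(random_effect_sds),
             "residual_sd": residual_sd, "family": family,
             "beta_precision": beta_precision, "date_scale": date_scale,
             "scale_date": scale_date}
    return df, truth
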