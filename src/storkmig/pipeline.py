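"""End-to-end orchestration: simulate -> classify -> segment -> annotate ->
metrics -> fit -> report, with provenance.

Each stage reads/writes plain CSV (weather optionally NetCDF) inside one
artifact directory; a resolved copy of the run configuration and a versions
manifest are written next to the outputs so a run can be reproduced exactly.
Per-stage counts of dropped or flagged records are logged, keeping inclusion
filters auditable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import behaviour, io_formats, metrics, segmentation, weather
from .config import RunConfig
from .synthetic import SimConfig, simulate_cohort, simulate_labelled_bursts

logger = logging.getLogger(__name__)

STAGE_ORDER = ("simulate", "classify", "segment", "annotate", "metrics", "fit", "report")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""


def _versions_manifest() -> dict:
    import importlib.metadata as im
    out = {}
    for pkg in ("storkmig", "numpy", "scipy", "pandas", "statsmodels",
                "scikit-learn", "xarray", "shapely"):
        try:
            out[pkg] = im.version(pkg)
        except im.PackageNotFoundError:
            out[pkg] = "unknown"
    return out


def run_pipeline(config: RunConfig) -> Path:
    """Execute the enabled stages and return the artifact directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "resolved_config.yaml")
    (out / "versions.json").write_text(json.dumps(_versions_manifest(), indent=2))
    state: dict = {}
    for stage in STAGE_ORDER:
        if stage not in config.stages:
            continue
        try:
            _STAGES[stage](config, out, state)
        except Exception as err:
            raise StageError(f"stage {stage!r} failed: {err}") from err
    return out


def _stage_simulate(config: RunConfig, out: Path, state: dict) -> None:
    sim = SimConfig(seed=config.seed, **config.simulate)
    tracks, accel, grid, truth = simulate_cohort(sim)
    io_formats.write_tracks(tracks, out / "tracks.csv")
    io_formats.write_accel(accel, out / "accel.csv")
    io_formats.write_weather_grid(grid, out / "weather.nc")
    truth.birds.to_csv(out / "ground_truth_birds.csv", index=False)
    truth.days.to_csv(out / "ground_truth_days.csv", index=False)
    truth.bursts.to_csv(out / "ground_truth_bursts.csv", index=False)
    state.update(tracks=tracks, accel=accel, grid=grid, truth=truth, sim=sim)
    logger.info("simulate: %d fixes, %d accel rows, %d birds",
                len(tracks), len(accel), truth.birds.shape[0])


def _load_inputs(config: RunConfig, out: Path, state: dict) -> None:
    if "tracks" not in state:
        path = config.tracks_path or out / "tracks.csv"
        state["tracks"] = io_formats.read_tracks(path)
    if "accel" not in state and (config.accel_path or (out / "accel.csv").exists()):
        state["accel"] = io_formats.read_accel(config.accel_path or out / "accel.csv")
    if "grid" not in state and (config.weather_path or (out / "weather.nc").exists()):
        state["grid"] = io_formats.read_weather_grid(config.weather_path or out / "weather.nc")


def _stage_classify(config: RunConfig, out: Path, state: dict) -> None:
    _load_inputs(config, out, state)
    tracks = state["tracks"]
    accel = state.get("accel")
    classifiers = {}
    reports = {}
    sim = state.get("sim") or SimConfig(seed=config.seed, **config.simulate)
    loggers = sorted(accel["logger_type"].unique()) if accel is not None and len(accel) \
        else list(sim.logger_types)
    for lt in loggers:
        bursts, labels = simulate_labelled_bursts(250, lt, seed=config.seed, config=sim)
        feats = pd.DataFrame([behaviour.extract_burst_features(b, sim.sample_rate_hz)
                              for b in bursts], columns=behaviour.FEATURE_NAMES)
        clf, rep = behaviour.train_behaviour_classifier(feats, labels, lt, seed=config.seed)
        classifiers[lt] = clf
        reports[lt] = rep.to_dict()
    (out / "classifier_report.json").write_text(json.dumps(reports, indent=2))
    classified = behaviour.classify_fixes(tracks, accel, classifiers,
                                          flight_speed_kmh=config.thresholds.flight_speed_kmh)
    frac = behaviour.speed_rule_flight_fraction(classified)
    logger.info("classify: %.1f%% of flight labels from the speed rule", 100 * frac)
    classified.to_csv(out / "classified.csv", index=False)
    state["classified"] = classified


def _stage_segment(config: RunConfig, out: Path, state: dict) -> None:
    _load_inputs(config, out, state)
    events, daily = segmentation.segment_cohort(
        state["tracks"], thresholds=config.thresholds,
        kernel_level=config.thresholds.kernel_level)
    rows = []
    for ev in events:
        rows.append({
            "bird_id": ev.bird_id, "year": ev.year, "start_date": ev.start_date,
            "end_date": ev.end_date, "leg1_end_date": ev.leg1_end_date,
            "leg2_end_date": ev.leg2_end_date,
            "destination_lon": None if ev.destination is None else ev.destination[0],
            "destination_lat": None if ev.destination is None else ev.destination[1],
            "diagnostics": "; ".join(ev.diagnostics),
        })
    pd.DataFrame(rows).to_csv(out / "events.csv", index=False)
    daily.to_csv(out / "daily.csv", index=False)
    n_bad = sum(not ev.complete for ev in events)
    logger.info("segment: %d/%d complete migrations", len(events) - n_bad, len(events))
    state["events"], state["daily"] = events, daily
    io_formats.write_geojson_routes(state["tracks"],
                                    [e for e in events if e.complete],
                                    out / "routes.geojson")


def _stage_annotate(config: RunConfig, out: Path, state: dict) -> None:
    _load_inputs(config, out, state)
    if "daily" not in state:
        raise ValueError("annotate requires segment outputs (daily day types)")
    src = state.get("classified", state["tracks"])
    daily = state["daily"]
    mig = daily[daily["day_type"] == "migratory"][["bird_id", "date"]]
    days = pd.DatetimeIndex(src["timestamp"]).tz_localize(None).normalize()
    key = pd.MultiIndex.from_arrays([src["bird_id"], days])
    keep = key.isin(pd.MultiIndex.from_frame(mig))
    sub = src[keep]
    logger.info("annotate: %d of %d fixes on migratory days", len(sub), len(src))
    annotated = weather.annotate_tracks(sub, state["grid"])
    annotated.to_csv(out / "annotated.csv", index=False)
    state["annotated"] = annotated


def _stage_metrics(config: RunConfig, out: Path, state: dict) -> None:
    for need in ("events", "daily"):
        if need not in state:
            raise ValueError(f"metrics requires segment outputs ({need} missing)")
    tracks = state["tracks"]
    ages = {b: ("adult" if str(b).startswith("A") else "juvenile")
            for b in tracks["bird_id"].unique()}
    if "truth" in state:
        ages = dict(zip(state["truth"].birds["bird_id"], state["truth"].birds["age"]))
    summaries = metrics.summarise(
        tracks, [e for e in state["events"] if e.complete], state["daily"],
        classified=state.get("classified"), annotated=state.get("annotated"),
        ages=ages)
    accel = state.get("accel")
    if accel is not None and len(accel):
        loggers = accel.groupby("bird_id")["logger_type"].first()
        summaries["logger_type"] = summaries["bird_id"].map(loggers)
    summaries.to_csv(out / "leg_summaries.csv", index=False)
    state["summaries"] = summaries
    n_flag = int((summaries.get("diagnostic", "") != "").sum())
    logger.info("metrics: %d rows, %d flagged", len(summaries), n_flag)


def _stage_fit(config: RunConfig, out: Path, state: dict) -> None:
    from .models import run_model_battery
    if "summaries" not in state:
        raise ValueError("fit requires metrics outputs (leg_summaries missing)")
    summaries = state["summaries"]
    daily_flight = None
    if "annotated" in state:
        dm = weather.daily_means(state["annotated"])
        leg3 = summaries[summaries["leg"] == 3][["bird_id", "start_date",
                                                 "start_date_julian", "age", "year"]]
        leg3 = leg3.rename(columns={"start_date_julian": "leg3_start_julian",
                                    "start_date": "leg3_start"})
        dm = dm.merge(leg3, on="bird_id", how="inner")
        dm = dm[dm["date"] >= dm["leg3_start"]]
        daily_flight = dm
        dm.to_csv(out / "daily_flight.csv", index=False)
    models = run_model_battery(summaries, daily_flight)
    models.to_csv(out / "models.csv", index=False)
    state["models"] = models
    n_err = int((models["error"] != "").sum())
    logger.info("fit: %d term rows, %d failed models", len(models), n_err)


def _stage_report(config: RunConfig, out: Path, state: dict) -> None:
    if "summaries" not in state:
        raise ValueError("report requires metrics outputs")
    rep = make_report(state["summaries"])
    rep.to_csv(out / "report_summary.csv", index=False)
    state["report"] = rep


_STAGES = {
    "simulate": _stage_simulate,
    "classify": _stage_classify,
    "segment": _stage_segment,
    "annotate": _stage_annotate,
    "metrics": _stage_metrics,
    "fit": _stage_fit,
    "report": _stage_report,
}

_REPORT_METRICS = ("duration_days", "migratory_days", "stopover_days",
                   "beeline_km", "straightness", "mean_flight_odba")


def make_report(leg_summaries: pd.DataFrame) -> pd.DataFrame:
    """Per-age, per-leg means and standard errors of the performance metrics.

    Mirrors the cohort-characteristics summary layout: one row per
    (leg, age), mean and SE per metric; SE is empty for single-bird cells.
    """
    rows = []
    for (leg, age), grp in leg_summaries.groupby(["leg", "age"], dropna=False):
        row = {"leg": leg, "age": age, "n_birds": grp["bird_id"].nunique()}
        for m in _REPORT_METRICS:
            if m not in grp.columns:
                continue
            vals = grp[m].dropna().to_numpy(dtype=float)
            row[f"{m}_mean"] = vals.mean() if len(vals) else np.nan
            row[f"{m}_se"] = (vals.std(ddof=1) / np.sqrt(len(vals))
                              if len(vals) > 1 else np.nan)
        if leg == "all" and "destination_lon" in grp.columns:
            row["destination_lon_mean"] = grp["destination_lon"].mean()
            row["destination_lat_mean"] = grp["destination_lat"].mean()
        rows.append(row)
    return pd.DataFrame(rows)
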