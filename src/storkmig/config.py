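"""Central configuration: every scientific threshold used by the pipeline.

All constants that encode an analysis decision (displacement thresholds,
barrier definitions, the ODBA smoothing window, the flight speed rule, the
kernel isopleth level) live here so a run can be reproduced or re-parameterised
from a single structured config file.  Modules take these as keyword arguments
whose defaults reference this module; nothing else hard-codes them.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

# --- analysis constants (defaults mirror the published protocol) -------------

#: displacement (km) between consecutive night roosts above which a day counts
#: toward starting migration / below which it counts toward wintering
MIGRATION_DISPLACEMENT_KM = 60.0
#: number of consecutive qualifying days required to start/stop migration
CONSECUTIVE_DAYS = 3
#: within-migration displacement (km) separating migratory from stopover days
STOPOVER_DISPLACEMENT_KM = 37.0
#: ground speed (km/h) above which a fix without accelerometer data is "flight"
FLIGHT_SPEED_KMH = 5.0
#: latitude of the Strait of Gibraltar barrier (end of leg 1)
GIBRALTAR_LAT = 36.0
#: Atlas Mountains barrier: crossed when lat <= ATLAS_SLOPE * lon + ATLAS_INTERCEPT
ATLAS_SLOPE = 0.58
ATLAS_INTERCEPT = 36.12
#: kernel utilisation-distribution isopleth for breeding/wintering ranges
KERNEL_LEVEL = 0.90
#: running-mean window (seconds) for the dynamic acceleration component
ODBA_WINDOW_S = 4.0
#: IUGG mean Earth radius (km) for all great-circle distances
EARTH_RADIUS_KM = 6371.0088
#: maximum gap (minutes) between consecutive fixes for step kinematics
MAX_STEP_GAP_MIN = 40.0


@dataclass
class Thresholds:
    """Bundle of the analysis constants, overridable per run."""

    migration_displacement_km: float = MIGRATION_DISPLACEMENT_KM
    consecutive_days: int = CONSECUTIVE_DAYS
    stopover_displacement_km: float = STOPOVER_DISPLACEMENT_KM
    flight_speed_kmh: float = FLIGHT_SPEED_KMH
    gibraltar_lat: float = GIBRALTAR_LAT
    atlas_slope: float = ATLAS_SLOPE
    atlas_intercept: float = ATLAS_INTERCEPT
    kernel_level: float = KERNEL_LEVEL
    odba_window_s: float = ODBA_WINDOW_S
    max_step_gap_min: float = MAX_STEP_GAP_MIN


@dataclass
class RunConfig:
    """Full pipeline run configuration (paths, stages, seed, thresholds)."""

    seed: int = 0
    out_dir: str = "run_out"
    stages: list[str] = field(
        default_factory=lambda: [
            "simulate", "classify", "segment", "annotate", "metrics", "fit", "report",
        ]
    )
    thresholds: Thresholds = field(default_factory=Thresholds)
    # simulation block is passed through to synthetic.SimConfig as kwargs
    simulate: dict = field(default_factory=dict)
    tracks_path: str | None = None
    accel_path: str | None = None
    weather_path: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        thr = Thresholds(**raw.pop("thresholds", {}))
        return cls(thresholds=thr, **raw)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
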