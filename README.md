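# storkmig

Analysis pipeline for GPS + tri-axial accelerometer biologging of soaring-bird
autumn migration, built around the white stork (*Ciconia ciconia*) system:
birds leaving Iberia, crossing the Strait of Gibraltar and the Atlas
Mountains, and finishing in the Sahel. The package asks how the *timing* of
migration shapes performance (duration, distance, route straightness, flight
energy expenditure), the weather a bird meets en route, and where in the
Sahel it ends up.

It is aimed at movement ecologists who have Movebank-style tracking tables
and gridded weather fields, and at methodologists who want a fully synthetic,
ground-truthed test bed for this class of analysis: every pipeline stage can
be driven by a built-in cohort simulator whose true departure dates, leg
crossings, behaviours and destinations are known.

## What it computes

**Behaviour and energetics.** Per burst of tri-axial acceleration (9 samples
at 1 Hz every 20 min during daylight), Overall Dynamic Body Acceleration:

    ODBA = mean over samples of Σ_axes | a_i − running_mean_4s(a_i) |

a standard proxy for movement energy expenditure. A random forest per logger
manufacturer classifies bursts into foraging / resting / soaring / flapping;
soaring and flapping merge into *flight*, and fixes without a burst fall back
to the rule "flight iff ground speed > 5 km/h".

**Migration segmentation.** Night roost = last daylight fix of the day; a
bird starts migrating on the first of 3 consecutive days moving > 60 km
between roosts after leaving the breeding range (90% kernel isopleth), and
stops the day before the first of 3 consecutive days moving < 60 km inside
the wintering range. Days within migration split at 37 km into migratory vs
stopover. The window partitions into three barrier legs: leg 1 to latitude
36°N (Strait of Gibraltar), leg 2 to the Atlas line `lat = 0.58·lon + 36.12`,
leg 3 to the Sahel.

**Metrics.** Per bird-year-leg: duration, migratory/stopover day counts,
great-circle beeline (whole-route beeline is routed through the Gibraltar
crossing), cumulative daylight distance on migratory days, straightness =
beeline/cumulative ∈ (0, 1], and mean flight ODBA.

**Weather.** Fixes on migratory days are annotated with 925-mB zonal (u) and
meridional (v) wind and boundary layer height by spatial bilinear
interpolation at the nearest grid hour; wind support = u·sin(bearing) +
v·cos(bearing) (positive = tailwind); longitudinal speed = eastward component
of ground velocity.

**Models.** The timing battery: 18 performance models (gaussian LMMs with
bird and year random intercepts; straightness as a beta GLMM with logit link,
implemented in-module by Laplace approximation; flight ODBA adds a
logger-type random intercept), 6 destination models, 9 weather models, and
one flight-direction model (daily longitudinal speed ~ leg-3 start date ×
zonal wind). Wald z tests, Nakagawa–Schielzeth marginal/conditional R², and
VIF screening (< 2) throughout.

## Worked example

```python
from storkmig.config import RunConfig
from storkmig.pipeline import run_pipeline

cfg = RunConfig(seed=7, out_dir="demo_run",
                simulate={"n_adults": 4, "n_juveniles": 8})
art = run_pipeline(cfg)   # simulate -> classify -> segment -> annotate
                          # -> metrics -> fit -> report
```

or from the shell: `storkmig run --seed 7 --out demo_run`. The artifact
directory then contains, among others, `leg_summaries.csv`:

```
bird_id  leg  duration_days  migratory_days  stopover_days  beeline_km  straightness  mean_flight_odba
A01        3             10              10              0     1876.5          0.807             0.207
A02        3             13              12              1     2148.4          0.789             0.213
```

Read: bird A01 crossed the Sahara (leg 3) in 10 days, all migratory, along a
route 1/0.807 ≈ 1.24 times longer than the 1876-km beeline, spending 0.207 g
of dynamic acceleration per flight burst. `models.csv` holds the fitted
battery; on a drift-coupled cohort the destination-longitude model shows the
signature negative date slope (later birds end further west — −0.101 °/day,
SE 0.025, p = 0.0001 on the 12-bird demo above), because late-season
easterlies push Sahara crossings westward.

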