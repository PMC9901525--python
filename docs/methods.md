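# Methods

This note documents the models and procedures storkmig implements, the
choices made where the protocol left room, and what the synthetic test bed
does and does not establish about real data.

## Acceleration, ODBA and behaviour classification

A burst is a fixed-rate tri-axial record (default 9 samples at 1 Hz) taken
simultaneously with a GPS fix. The dynamic component per axis is the
deviation from a **centred running mean of round(4 s × sample rate)
samples**, truncated at burst edges; per-sample ODBA sums the absolute
deviations over the three axes and the burst statistic is the **mean** over
samples. Three conventions needed fixing:

* *Absolute values before summing.* Without |·| the statistic is ≈ 0 by
  construction; we take absolute deviations, the standard ODBA definition.
* *Centred, truncated window.* A trailing 4-s window would discard almost
  half of a 9-s burst; centring with edge truncation uses every sample. For
  an even window of w samples the centre covers `[i − w//2, i + w − w//2 − 1]`.
* *Mean, not sum, per burst.* Makes bursts of different lengths comparable.

Numerically, the first sample is subtracted per axis before filtering
(deviations from a running mean are shift-invariant), so constant bursts give
exactly zero rather than accumulated floating-point residue.

Behaviour is classified per burst by a random forest (200 trees) on a
19-dimensional summary vector: per-axis mean/SD/min/max, per-axis
dynamic-component SD, burst ODBA, and the three pairwise axis correlations
(zeroed, flagged, for bursts shorter than 2 samples or constant axes). One
forest per logger manufacturer, because accelerometer scale differs between
sensor brands. The train/held-out protocol is a stratified 75/25 split at a
fixed seed. Fixes without a burst use the ground-speed fallback, *flight*
iff speed strictly exceeds 5 km/h; the fraction of flight labels supplied by
this rule is reported with every classification run. Speed-rule flight fixes
carry no accelerometer data, so they are excluded from mean flight ODBA.

## Segmentation

Daily displacement is the distance travelled during a day: from the previous
night's roost (last daylight fix of the previous calendar day, UTC; sun
elevation > 0 by the NOAA low-accuracy solar position) to the day's own
roost. Days without fixes inherit the previous roost and are flagged as
gaps. Start of migration: first day of the first run of ≥ 3 consecutive
days with displacement > 60 km (strict) occurring at or after the first
roost outside the breeding range. Start of wintering: the same with < 60 km
inside the wintering range; end of migration is the day before, and the
destination is that day's roost. Inside the window, days split at 37 km
(strict) into migratory vs stopover.

Ranges are 90% kernel-density isopleths of the fixes in a configurable
calendar month (June for breeding, October for wintering), with an isotropic
Gaussian kernel at the reference bandwidth h = ½(SDx + SDy)·n^(−1/6) in a
local-km projection; the isopleth is the smallest density contour holding
90% of the gridded mass, traced with marching squares onto a lon/lat
polygon. Fixes are thinned to ≤ 300 evenly spaced points per kernel (the
density surface is insensitive to this at these sample sizes) and a
centroid-radius fallback (30 km) is used when fewer than 30 fixes exist in
the defining month. A full covariance kernel was rejected: one distant
outlier makes the kernel ellipse nearly singular and the isopleth
disintegrates; the isotropic reference bandwidth is also what the field's
standard home-range tooling uses.

Leg boundaries: leg 1 ends the first day with a fix at latitude ≤ 36
(Strait of Gibraltar); leg 2 ends the first later day with a fix at
lat ≤ 0.58·lon + 36.12 (Atlas Mountains line, read with y = latitude and
x = longitude in decimal degrees); each next leg starts the following day,
so legs exactly partition the window. Crossing *points* are linearly
interpolated on the track segment straddling the boundary, hence lie on the
defining curve by construction.

## Metrics

All distances are spherical great circles at the IUGG mean radius
6371.0088 km (an ellipsoid differs by < 0.5% at these scales and the sphere
keeps every value checkable against closed forms). The whole-migration
beeline is distance(first migration fix → Gibraltar crossing) +
distance(crossing → destination), because a single great circle from Iberia
to the Sahel crosses open ocean; per-leg beelines run from the first fix of
the leg to the first fix of the next (leg 3 to the last migration fix).
Cumulative distance sums consecutive-fix distances within migratory days
only; the timing covariate is the day-of-year of the leg's first day;
straightness is clipped at 1 − 1e−9 (with a logged count) so the beta
model's open support holds. Only windows with complete daily coverage are
summarised; incomplete bird-legs are emitted with missing fields and a
diagnostic, never dropped silently, so the inclusion filter is auditable.
Mean flight ODBA averages per burst (not per fix).

## Weather annotation

Spatial bilinear interpolation on the four surrounding nodes at the nearest
grid hour. "Hourly data with bilinear interpolation" is most plausibly
spatial-only; linear-in-time matching is a switch away but changes nothing
when fields vary slowly within an hour. Wind direction uses the
blowing-toward convention (clockwise from north) to match the
eastward-positive zonal sign language; wind support is the projection of
(u, v) on the track bearing; longitudinal speed is great-circle distance ×
sin(initial bearing) / Δt, so |longitudinal| ≤ ground speed identically.
Steps longer than 40 min between fixes are skipped. Leg-level weather means
are taken over migratory-day fixes, daily means over flight fixes only.

## Mixed models

Gaussian LMMs are fitted by REML through statsmodels: a single random factor
uses the native random-intercept formulation; crossed factors (bird, year,
optionally logger type) use one variance component per factor within a
single supergroup — the standard crossed-intercepts construction. Wald z
statistics and two-sided normal p-values per fixed effect; for single-df
terms this is identical to the Wald χ² convention of R's car package.
Nakagawa–Schielzeth R²: marginal = var(Xβ̂)/(var(Xβ̂) + Σ random variances +
residual); conditional moves the random variances into the numerator, so
conditional ≥ marginal always. Singular (boundary) fits are flagged, not
hidden. With only two year levels the year variance is weakly identified and
can be estimated far from truth — expected behaviour of variance components
with two groups, and harmless for the fixed-effect estimates, which remain
unbiased (verified by replicate simulation).

The straightness model is a **beta GLMM with logit link** written in-module,
since no installed Python package provides one: random intercepts are
integrated out by a Laplace approximation; the conditional modes are found
by Fisher scoring with step halving (expected-information weights
φ²m²(ψ′(μφ) + ψ′((1−μ)φ)), m = μ(1−μ), are positive definite, making the
inner problem well behaved); the outer optimisation is L-BFGS-B over
(β, log φ, log σ per factor), started from logit-scale least squares and a
moment estimate of φ. Standard errors come from the numerically
differentiated Hessian of the Laplace objective. A fixed-effects beta
regression (statsmodels BetaModel) serves as an independent oracle in the
zero-variance reduction test. Pseudo-R² is reported as unavailable for this
family. The date covariate is z-scored per fitted dataset (sample SD,
ddof = 1) exactly where the original tables scale it: the duration,
migratory-day, stopover-day, straightness and ODBA models; beeline,
destination, weather and flight-direction models use raw Julian day.

The full battery is 18 performance models (6 metrics × 3 legs) + 6
destination models + 9 weather models + 1 flight-direction interaction
model; single-model failures are recorded per row and the battery continues.

## Synthetic cohort generator

The generator emulates the study design, not stork physiology: its purpose
is known ground truth for every quantity the pipeline estimates.

* **Duty cycle**: bursts of 9 GPS + acceleration fixes at 1 Hz every 20 min
  strictly between local sunrise and sunset; the night roost holds from the
  last daylight fix to the next morning.
* **Movement**: waypoint-following (Iberia → Gibraltar → Atlas → Sahara →
  Sahel) with Gaussian daily distances (170 ± 25 km), per-leg stopover
  probabilities concentrated before the Sahara (0.55/0.45/0.10), the first
  three migration days forced migratory (departure commitment), and a
  lateral route meander (SD 120 km day-to-day offset from the route axis)
  that yields realistic straightness around 0.6–0.8 instead of near-beeline
  tracks. Stopover days return to the same roost: local foraging trips are
  not resolved, and any net stopover drift would enter the beeline while
  stopover movement is excluded from the cumulative distance by definition.
  Within a day the bird moves linearly between roosts during a travel window
  from 2 h after sunrise to 1 h before sunset (thermal soaring hours); no
  within-day movement model exists in the protocol, so this stand-in is the
  simplest consistent with daily-scale displacement.
* **Cohort**: 16 adults and 59 juveniles by default, departures drawn around
  10 August (adults) and 4 August (juveniles), SD 13 days, truncated to the
  observed 7 July – 4 September range. Age affects only the departure
  distribution by default.
* **Weather**: hourly 1° grid; zonal wind declines linearly through the
  season (0.5 m/s at the solstice, −0.02 m/s per day — the late-season
  easterly/Harmattan pattern) with i.i.d. cell noise (SD 0.5 m/s); boundary
  layer height declines 5 m/day from 1800 m.
* **Wind drift**: on migratory days south of the Atlas line the realised
  eastward displacement adds drift × u × (flight seconds), drift =
  1.674 (m/s longitudinal per m/s zonal) — a calibration chosen so the
  regression of daily longitudinal speed on zonal wind reproduces the
  published flight-direction slope, not a measured fact. Under the default
  seasonal slope this implies the destination longitude shifts ≈ −0.13° per
  day of later departure, and the cohort shows the signature negative
  date–longitude correlation.
* **Acceleration signatures**: static (postural) mean plus isotropic
  Gaussian dynamic noise per behaviour; dynamic SDs 0.01/0.03/0.07/0.18 g
  (resting/foraging/soaring/flapping) give mean flight ODBA ≈ 0.2 g and the
  strict ODBA ordering resting < foraging < soaring < flapping; logger B
  reads 15% hotter, motivating the per-manufacturer forests.

What passing tests on this generator show: the estimators recover what they
are pointed at — segmentation dates to the day, geometry invariants,
regression coefficients within Monte-Carlo error. What they do not show:
robustness to GPS error (none is simulated), irregular duty cycles, partial
migration, mortality, thermals, topography, or behavioural misclassification
structure in real accelerometry; the behaviour classes here are far more
separable than hand-labelled field bursts.

`simulate_model_data` is a separate, direct generator for the model
structures themselves (gaussian-identity and beta-logit with bird/year
random intercepts); it is what the coefficient-recovery benchmarks use, so
published coefficients can serve as generating truth without routing through
the movement model.

## Problem sizes and numerical settings

Suite and benchmark sizes are chosen for a single CPU: the segmentation
check runs 100 birds over a full season (GPS only); model-calibration uses
500 replicate LMM fits of 30 birds × 4 observations; coefficient-recovery
benchmarks average 50 replicate fits (100 birds × 10 days for the
flight-direction LMM, 150 bird-years for the straightness GLMM). KDE grids
adapt to the bandwidth (≥ 96, ≤ 512 nodes per axis). Beta-GLMM inner
Fisher scoring converges at |step| < 1e−10 (cap 200 iterations); outer
L-BFGS-B bounds log φ ∈ [−2, 12] and log σ ∈ [−7, 3]. The zero-variance
LMM→OLS reduction is exact to ~1e−12 when the variance estimate lands on
the boundary; the test size (300 birds × 5) keeps the boundary estimate
small enough for 1e−4 relative agreement.

## Known limitations

* The exact feature set of the original behaviour classifier is not public;
  ours is a standard summary-statistics set, and the reported accuracies are
  for the synthetic stand-in.
* Whether the original ODBA summed or averaged within bursts, and the exact
  wind-support formula of its cited references, are interpreted as mean and
  projection respectively; both are switches/documented conventions.
* The beta GLMM uses a Laplace approximation, not adaptive quadrature; with
  ≥ 2 observations per random level at these variance scales the difference
  is far below the Monte-Carlo error of the recovery checks.
* Destination models fit each bird once; the bird random intercept is then
  confounded with the residual and is retained only for structural fidelity.
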