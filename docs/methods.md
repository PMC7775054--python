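# Methods

## Model overview and assumptions

`phenorisk` is a process-based, temperature-only simulator. Its two
components share one daily loop over gridded Tmin/Tmax but are otherwise
independent:

1. **Phenology** — linear (degree-day) development through four life
   stages (egg, larva, pupa, adult) plus a separately parameterized
   overwintering stage, per cohort, per grid cell.
2. **Climatic suitability** — linear accumulation of cold and heat
   stress units compared against moderate and severe limits.

Core assumptions: development rate is linear in temperature between the
lower and upper developmental thresholds (no nonlinear or supra-optimal
response); all individuals in a cohort develop in synchrony; the run
starts at a fixed date (e.g. January 1) with the whole population in the
overwintering stage at zero accumulated degree-days; temperature is the
only driver (no photoperiod, moisture, dispersal, or biotic factors).
Migration, diapause triggers, and distributed-delay generation spreading
are out of scope.

## Degree-day methods

Two daily methods, selected by the species parameter `calctype`:

- **average**: `clamp((Tmin+Tmax)/2, LDT, UDT) − LDT`.
- **triangle**: the day is modeled as a triangular trajectory from Tmin
  to Tmax and back over 24 h. Closed form: with span = Tmax − Tmin, the
  area above LDT is `(Tmin+Tmax)/2 − LDT` when Tmin ≥ LDT, else
  `(Tmax − LDT)² / (2·span)`; when Tmax > UDT the lobe
  `(Tmax − UDT)² / (2·span)` is removed (horizontal cutoff — removed,
  not reflected, matching the standard US "single triangle with upper
  threshold" convention). A constant-temperature day (Tmin = Tmax) is
  defined by the continuity limit `clamp(T, LDT, UDT) − LDT`.

Both are bounded in [0, UDT − LDT] and monotone in Tmin and Tmax; the
triangle closed form is verified in the tests against 1-minute numeric
integration of the clipped trajectory (max error < 1e-5 DDC over 10,000
random tuples; tolerance asserted at 0.01 DDC). Non-finite temperatures
propagate as missing rather than zero, so absent weather never looks
like a cold day; days with Tmin > Tmax are repaired by swapping, with a
logged warning.

## Cohorts

The overwintering emergence distribution (mean `distro_mean`, variance
`distro_var`, bounds `xdist1`/`xdist2`, shape normal or lognormal) is
discretized by partitioning [xdist1, xdist2] into n equal-width bins;
each cohort's emergence requirement is the bin midpoint and its weight
the truncated distribution's probability mass in the bin, renormalized
to sum to 1. This midpoint/bin-mass rule is the simplest scheme that
reproduces "n cohorts approximating a normal distribution"; n = 1
degenerates to a single cohort at the mean. For the lognormal shape,
`distro_mean`/`distro_var` are interpreted as the mean and variance of
the xdist1-shifted variate itself and converted internally to log-scale
parameters (the shipped species both use the normal shape). Weights are
checked against numeric integration in the tests, and the weighted mean
emergence converges to the truncated-distribution mean (within 0.5 DDC
at n = 101).

## Daily time step

Each day, the active stage's degree-days (at that stage's thresholds)
are added to the within-stage accumulator. When the requirement — the
cohort's emergence DD for overwintering, the stage duration otherwise —
is reached, the insect transitions to the next stage and the excess DD
carries into the new accumulator. Numerical choices:

- **At most one transition per calendar day**: daily data cannot resolve
  sub-day multi-stage progress, and this prevents one hot day from
  skipping a stage entirely.
- **Carryover across differing thresholds**: when stages have different
  thresholds the excess is transferred as-is (both shipped species use
  common thresholds, making the scales identical); this is a documented
  approximation rather than a rescaling.
- **Events**: the first day the within-stage accumulator reaches the
  stage's event threshold is recorded per (generation, stage), for
  generations 0 .. `max_event_generations` − 1 (default 4; generation 0
  is the overwintering generation). The overwintering event is
  emergence, i.e. completion of the cohort's requirement. Event tables
  are finalized only after the last day. On a transition day the new
  stage's event can fire from carried-over DD.
- **Generations**: the counter increments at every transition *into* the
  egg stage (oviposition), including an overwintering adult's first
  eggs. Generations beyond the event limit are still counted for
  voltinism.
- **Missing days** freeze the state (per-cell missing-day counts are
  reported); cells with no data at all become nodata in every output.

Cross-cohort combination: per sampled day the population fraction in
each (generation, stage) is the sum of member cohorts' weights; event
maps report the earliest day and the cohort-weighted average day
(weights renormalized over cohorts that recorded the event, rounded to
the nearest day; an unweighted mean is available via a flag). Stage maps
are kept for the middle cohort (index ⌈n/2⌉), which represents the
largest population share under a symmetric emergence distribution.
Accumulated degree-days are summed at the larval thresholds for the
first cohort only — representative for all cohorts, and identical across
stages when thresholds are common.

## Climatic suitability

Daily cold stress is max(0, Tcold − Tmin) and heat stress
max(0, Tmax − Theat), with one threshold pair for all life stages,
accumulated by plain summation over the entire run — consecutive days
are not weighted more than non-consecutive ones and the accumulator
never resets (an exponential weekly-compounding alternative used by
other suitability tools is deliberately not implemented; the linear
daily rule is this model's contract). Classification uses the
strictly-greater convention: accumulation must *exceed* a limit to
exclude, so boundary equality is not excluded. Severe-excluded cells are
always a subset of moderate-or-worse cells because the limits are
ordered, and a cell's class never de-escalates within a run. Masked
phenology layers replace excluded cells with sentinel codes (moderate
−1, severe −2); for cosmetic comparability, stress maps can be linearly
rescaled so the grid maximum is 1000.

## Grid pipeline

The vectorized grid engine (`raster.run_grid`) holds per-cohort state
arrays over all cells and applies the same per-day rules as the scalar
engine; the two implementations are independent code paths and the tests
assert they agree cell-for-cell. Because the computation has no spatial
coupling, splitting the grid into tiles and mosaicking
(`tile_and_mosaic`) is bit-identical to an untiled run for any tile
count — this determinism contract replaces any prescribed parallel
scheduling. Sampled outputs are taken on days 1, 1+k, 1+2k, … for
k ∈ {1, 2, 7, 10, 14, 30}, plus always the final day (event maps need
the full period). Grids are north-up with cell-center registration;
day-of-year is 1-based and leap years follow the real calendar. The
middle-cohort stage map uses the integer code 10·generation + stage
index (overwintering 0, egg 1, larva 2, pupa 3, adult 4), recorded in
the run manifest.

GeoTIFF I/O is implemented directly over `tifffile`, writing standard
georeferencing tags (ModelPixelScale, ModelTiepoint, a WGS84
GeoKeyDirectory, GDAL nodata) and a JSON ImageDescription with band
dates; PNG maps are minimal categorical/continuous renderings with a
legend, not publication cartography. Event-date maps label color-bar
ticks as calendar month-day.

## Synthetic weather

The generator produces the study conditions for all spatial tests: daily
mean at south-edge row offset r on day d is

    base_mean − lat_gradient·r − seasonal_amplitude·(1 − cos(2π(d − 196)/365)) + noise,

with Tmin/Tmax = mean ∓ diurnal_range/2 and i.i.d. Gaussian noise shared
by Tmin and Tmax (preserving Tmin ≤ Tmax), reproducible per seed. Day
196 (mid-July) is the warmest by construction and days 13/14 the
coldest. Defaults (20×20 cells, base_mean 33 °C, gradient 1.6 °C/row,
amplitude 12 °C, diurnal range 10 °C, noise 2 °C) were chosen to span
continental-US-like conditions on a desk-scale grid — sub-tropical
summers at the south edge through severe-winter northern plains — so
that the apple-moth parameters produce both a northern cold-exclusion
band and a southern heat-exclusion band with voltinism rising from 0 to
about 7 southward. The generator deliberately omits topography, spatial
noise correlation, humidity and real weather systems; passing tests
therefore demonstrate the engine's contracts (monotonicity, contiguity,
determinism) under idealized forcing, not predictive skill on real
weather.

When only monthly temperature normals are available,
`synth.monthly_to_daily` interpolates linearly between month midpoints
(periodic across year boundaries) and then iteratively adds smooth
per-month corrections until every month's daily mean matches its input
within 0.01 °C (capped at 100 iterations, which in practice converges in
a handful; non-convergence raises with the residual). The contract is
the mean-preservation property, not a particular smoother.

## Parameters that matter

| Parameter | Units | Meaning |
|---|---|---|
| `*LDT`, `*UDT` | °C | per-stage lower/upper developmental thresholds |
| `eggDD`, `larvaeDD`, `pupDD`, `adultDD` | DDC | stage durations |
| `*EventDD` | DDC | within-stage event thresholds |
| `owstage` | — | overwintering stage (egg/larva/pupa/adult) |
| `distro_mean/var`, `xdist1/2`, `distro_shape` | DDC | emergence distribution |
| `coldstress_threshold`, `heatstress_threshold` | °C | stress onset temperatures |
| `*_units_max1`, `*_units_max2` | DDC | moderate and severe stress limits |
| `calctype` | — | `average` or `triangle` |
| `max_event_generations` | — | generations with event tracking (default 4) |

Fahrenheit parameter files (`units: F`) have thresholds rounded to the
nearest integer °F before conversion — the long-standing US convention
for communicating degree-day models — while degree-day-valued parameters
scale by 5/9; Celsius inputs are never rounded.

## Problem sizes and limitations

Tests and the acceptance script run at desk scale (up to 20×20 cells ×
365 days × 7 cohorts, and 10,000 tuples for the degree-day oracle),
which exercises every code path in seconds; the engine itself is
resolution-agnostic. Known limitations: no moisture or photoperiod
response, no migration, no distributed delay (generation overlap does
not grow over the season, so event maps are most reliable for the first
few generations), linear development only, and a fixed region-wide start
date.
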