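# phenorisk

Daily time-step degree-day phenology and temperature-stress climatic
suitability mapping for insect pests, on gridded daily Tmin/Tmax.

`phenorisk` answers the two questions pest surveillance and IPM programs
ask about an insect: **where** could it establish, and **when** will each
life stage and key activity (spring emergence, first egg laying, egg
hatch) occur there? It is aimed at biosecurity surveillance planners,
extension entomologists, and biocontrol practitioners who need gridded,
within-season guidance rather than coarse climate-normal maps.

## The model

**Phenology.** Development is physiological time: each day contributes

- *simple average with horizontal cutoff*: DD = clamp((Tmin+Tmax)/2, LDT, UDT) − LDT, or
- *single triangle with upper threshold*: the day is a triangular
  trajectory from Tmin to Tmax and back over 24 h; DD is the time-average
  of the trajectory clipped to [LDT, UDT], minus LDT,

where LDT/UDT are the stage's lower/upper developmental thresholds. The
insect cycles egg → larva → pupa → adult → egg, entered through a
separately parameterized overwintering stage; each stage completes after
a fixed DD duration, excess DD carries into the next stage, and a
generation is counted at every oviposition (adult → egg). Population
variability in overwintering emergence is represented by *cohorts*: the
emergence-DD distribution (truncated normal or lognormal on
[xdist1, xdist2]) is discretized into n bins, each a population fraction
that develops in synchrony. Per-stage *event* thresholds (DD within the
stage) yield phenological event maps — the day of year the event first
occurs, reported as the earliest and the cohort-weighted average date
across cohorts.

**Climatic suitability.** Each day, cold stress units max(0, Tcold − Tmin)
and heat stress units max(0, Tmax − Theat) accumulate linearly over the
whole run. Cells whose accumulation exceeds the moderate limit (max1) are
*moderate-excluded* (only short-term establishment); beyond the severe
limit (max2) they are *severe-excluded* (no establishment). The potential
distribution is the cells not excluded at the chosen level; every
phenology output (except accumulated DD) is also written masked by
severe-only and severe-plus-moderate exclusion.

Parameter files for two well-studied invasive moths ship with the
package: the light brown apple moth (*Epiphyas postvittana*,
overwintering larva) and the small tomato borer (*Neoleucinodes
elegantalis*, overwintering adult).

## Worked example

```python
import phenorisk as pr

epos = pr.load_bundled_species("epiphyas_postvittana")
traj = pr.run_cohort([(17.2, 17.2)] * 365, epos, cohort_ow_dd=210.0)
print("voltinism:", pr.voltinism(traj))
print("overwintering emergence day:", traj.events[(0, "overwintering")])
print("first gen-1 egg-hatch day:", traj.events[(1, "egg")])
```

prints

```
voltinism: 5
overwintering emergence day: 21
first gen-1 egg-hatch day: 54
```

At a constant 17.2 °C the triangle method yields 10 DDC/day (thresholds
7.2/31.1 °C). The middle cohort needs 210 DDC to finish overwintering
(day 21), then pupa (128 DDC) and adult-to-oviposition (71 DDC) bring the
first egg laying to day 41; with 734 DDC per full generation, five
generations complete within the year. The generation-1 egg-hatch event
(126 DDC into the egg stage) lands on day 54.

The same engine runs over grids. From a shell:

```bash
phenorisk synth --out wx --rows 20 --cols 20 --days 365 --seed 1
phenorisk cohorts src/phenorisk/data/epiphyas_postvittana.yaml -n 7
cat > run.yaml <<CFG
species: src/phenorisk/data/epiphyas_postvittana.yaml
weather: wx
n_cohorts: 7
sample_every: 30
n_tiles: 4
events: [[egg, 1]]
output_dir: out
CFG
phenorisk run --config run.yaml
```

which writes multi-band GeoTIFFs (one band per sampled day: accumulated
DD, middle-cohort stage/generation codes, population fractions, stress
accumulations and exclusion classes), single-band voltinism and
event-date rasters with their stress-masked variants, PNG summary maps,
and a JSON run manifest. On the synthetic north–south gradient the maps
reproduce the expected continental pattern: a contiguous cold-excluded
band in the north, a heat-excluded band in the south, and voltinism
rising from 0 to ~7 generations southward.

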