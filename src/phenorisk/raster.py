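"""Gridded orchestration: weather cubes, the vectorized grid engine,
tiling/mosaicking, and multi-layer raster + summary-map output.

The grid engine steps through each day of the run and updates every grid
cell's per-cohort life-stage state and the cell's cold/heat stress
accumulations, exactly as the scalar engine in :mod:`phenorisk.phenology`
does for a single location — the computation is strictly per-cell, which
is what makes tiled and untiled runs bit-identical.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .degree_days import dd_method
from .geotiff import GridGeometry, read_geotiff, write_geotiff
from .params import STAGES, CohortSet, SpeciesParams, make_cohorts
from .phenology import ALL_STAGES, OVERWINTERING, STAGE_INDEX, sample_days
from .stress import (ExclusionClass, StressField, apply_exclusion_mask,
                     classify_exclusion, daily_cold_stress, daily_heat_stress,
                     scale_stress)

logger = logging.getLogger(__name__)

NODATA_INT = -9999

#: Allowed output sampling intervals, in days.
SAMPLE_INTERVALS = (1, 2, 7, 10, 14, 30)


class WeatherGapError(ValueError):
    """Requested dates are missing from the weather source."""


@dataclass
class WeatherCube:
    """Daily Tmin/Tmax raster series with dates and grid geometry.

    ``tmin``/``tmax`` are (n_days, n_rows, n_cols) arrays. Dates must be
    consecutive calendar days. Element-wise Tmin > Tmax violations are
    repaired by swapping (logged); units other than Celsius are converted
    on construction.
    """

    dates: list
    tmin: np.ndarray
    tmax: np.ndarray
    geometry: GridGeometry
    units: str = "C"

    def __post_init__(self):
        self.tmin = np.asarray(self.tmin, dtype=float)
        self.tmax = np.asarray(self.tmax, dtype=float)
        if self.tmin.shape != self.tmax.shape or self.tmin.ndim != 3:
            raise ValueError("tmin and tmax must be matching 3-D arrays")
        if len(self.dates) != self.tmin.shape[0]:
            raise ValueError("number of dates must equal the number of day grids")
        gaps = [b for a, b in zip(self.dates[:-1], self.dates[1:]) if (b - a).days != 1]
        if gaps:
            raise WeatherGapError(f"weather dates are not consecutive around: {gaps[:5]}")
        if self.units.upper() == "F":
            self.tmin = (self.tmin - 32.0) * 5.0 / 9.0
            self.tmax = (self.tmax - 32.0) * 5.0 / 9.0
            self.units = "C"
        elif self.units.upper() != "C":
            raise ValueError(f"unsupported temperature units {self.units!r}")
        swapped = self.tmin > self.tmax
        if np.any(swapped):
            logger.warning("Tmin > Tmax at %d cell-day(s); swapping",
                           int(np.count_nonzero(swapped)))
            lo = np.where(swapped, self.tmax, self.tmin)
            hi = np.where(swapped, self.tmin, self.tmax)
            self.tmin, self.tmax = lo, hi

    @property
    def n_days(self) -> int:
        return self.tmin.shape[0]

    @property
    def shape(self):
        return self.tmin.shape[1:]

    def crop(self, extent) -> "WeatherCube":
        """Crop to a geographic (xmin, ymin, xmax, ymax) extent."""
        nr, nc = self.shape
        r0, r1, c0, c1 = self.geometry.window(extent, nr, nc)
        return self.subgrid(r0, r1, c0, c1)

    def subgrid(self, r0, r1, c0, c1) -> "WeatherCube":
        return WeatherCube(
            dates=list(self.dates),
            tmin=self.tmin[:, r0:r1, c0:c1].copy(),
            tmax=self.tmax[:, r0:r1, c0:c1].copy(),
            geometry=self.geometry.sub(r0, c0), units="C")

    def cell_series(self, row: int, col: int):
        """Per-day (tmin, tmax) pairs for one cell, for the point engine."""
        return list(zip(self.tmin[:, row, col], self.tmax[:, row, col]))

    def save(self, directory) -> dict:
        """Write stacked per-variable GeoTIFFs (tmin.tif, tmax.tif)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        labels = [d.isoformat() for d in self.dates]
        out = {}
        for name, arr in (("tmin", self.tmin), ("tmax", self.tmax)):
            out[name] = write_geotiff(directory / f"{name}.tif", arr.astype(np.float32),
                                      self.geometry, band_labels=labels,
                                      meta={"units": "C", "variable": name})
        return out


def read_weather(source, extent=None, dates=None) -> WeatherCube:
    """Read a weather cube from GeoTIFFs.

    ``source`` is a directory containing either stacked ``tmin.tif`` /
    ``tmax.tif`` (one band per day, ISO-date band labels) or per-day
    pairs named ``tmin_YYYY-MM-DD.tif`` / ``tmax_YYYY-MM-DD.tif``.
    ``dates`` may be a (start, end) pair restricting the period; missing
    days raise :class:`WeatherGapError` listing them. ``extent`` crops
    geographically. Fahrenheit sources (``units: F`` in metadata) are
    converted to Celsius.
    """
    source = Path(source)
    if (source / "tmin.tif").exists():
        cube = _read_stacked(source)
    else:
        cube = _read_pairs(source)
    if dates is not None:
        start, end = dates
        have = {d: i for i, d in enumerate(cube.dates)}
        want = [start + dt.timedelta(days=i) for i in range((end - start).days + 1)]
        missing = [d for d in want if d not in have]
        if missing:
            raise WeatherGapError(
                "weather source is missing "
                f"{len(missing)} requested day(s): {[d.isoformat() for d in missing[:10]]}")
        idx = [have[d] for d in want]
        cube = WeatherCube(dates=want, tmin=cube.tmin[idx], tmax=cube.tmax[idx],
                           geometry=cube.geometry, units="C")
    if extent is not None:
        cube = cube.crop(extent)
    return cube


def _read_stacked(source: Path) -> WeatherCube:
    tmin, geom, labels, meta = read_geotiff(source / "tmin.tif")
    tmax, _, labels2, meta2 = read_geotiff(source / "tmax.tif")
    if labels is None or labels2 is None:
        raise WeatherGapError("stacked weather files must carry date band labels")
    if labels != labels2:
        raise WeatherGapError("tmin.tif and tmax.tif date bands differ")
    dates = [dt.date.fromisoformat(s) for s in labels]
    units = (meta or {}).get("units", "C")
    return WeatherCube(dates=dates, tmin=tmin, tmax=tmax, geometry=geom, units=units)


def _read_pairs(source: Path) -> WeatherCube:
    files = sorted(source.glob("tmin_*.tif"))
    if not files:
        raise WeatherGapError(f"no weather rasters found in {source}")
    dates, tmins, tmaxs = [], [], []
    geom = units = None
    for f in files:
        day = dt.date.fromisoformat(f.stem.split("_", 1)[1])
        tmn, geom, _, meta = read_geotiff(f)
        partner = source / f"tmax_{day.isoformat()}.tif"
        if not partner.exists():
            raise WeatherGapError(f"missing tmax raster for {day.isoformat()}")
        tmx, _, _, _ = read_geotiff(partner)
        dates.append(day)
        tmins.append(tmn[0])
        tmaxs.append(tmx[0])
        units = (meta or {}).get("units", units or "C")
    return WeatherCube(dates=dates, tmin=np.stack(tmins), tmax=np.stack(tmaxs),
                       geometry=geom, units=units or "C")


@dataclass
class RunConfig:
    """Run configuration mirroring the CLI flags."""

    n_cohorts: int = 7
    sample_every: int = 30
    events: list | None = None      #: [(stage, generation), ...] to render
    n_tiles: int = 1
    seed: int = 1
    extent: tuple | None = None
    weighted_events: bool = True
    output_dir: str | None = None

    def validate(self, params: SpeciesParams | None = None) -> None:
        if self.n_cohorts < 1:
            raise ValueError("n_cohorts must be >= 1")
        if self.sample_every not in SAMPLE_INTERVALS:
            raise ValueError(
                f"sample_every must be one of {SAMPLE_INTERVALS}, got {self.sample_every}")
        if self.n_tiles < 1:
            raise ValueError("n_tiles must be >= 1")
        if params is not None and self.events:
            for stage, gen in self.events:
                if stage not in ALL_STAGES:
                    raise ValueError(f"unknown event stage {stage!r}")
                if not 0 <= gen < params.max_event_generations:
                    raise ValueError(
                        f"event generation {gen} outside [0, {params.max_event_generations})")


@dataclass
class GridOutputs:
    """All gridded results of one run (or one tile)."""

    sample_days: np.ndarray         #: sampled days of year
    sample_dates: list
    geometry: GridGeometry
    accum_dd: np.ndarray            #: (S, nr, nc) larval-threshold accumulated DD
    mid_stage_code: np.ndarray      #: (S, nr, nc) int16; 10*generation + stage index
    fractions: dict                 #: (gen, stage) -> (S, nr, nc) population fraction
    cold_accum: np.ndarray
    heat_accum: np.ndarray
    cold_class: np.ndarray          #: (S, nr, nc) int8 exclusion class
    heat_class: np.ndarray
    all_class: np.ndarray
    voltinism: np.ndarray           #: (nr, nc) int16, middle cohort
    events_earliest: dict           #: (gen, stage) -> (nr, nc) day of year (NaN unset)
    events_average: dict
    missing_days: np.ndarray        #: (nr, nc) int
    nodata_mask: np.ndarray         #: (nr, nc) bool
    params: SpeciesParams
    cohorts: CohortSet

    def stress_field(self, step: int = -1) -> StressField:
        """Stress state as of a sampled step (default: end of run)."""
        return StressField(self.cold_accum[step], self.heat_accum[step],
                           self.cold_class[step], self.heat_class[step])

    def masked(self, layer, mode: str, step: int = -1):
        """Phenology layer with exclusion sentinels at the given step."""
        return apply_exclusion_mask(layer, self.stress_field(step), mode)


def _threshold_tables(params: SpeciesParams):
    """Per-stage-code (0=OW..4=adult) thresholds, durations, events, successors."""
    ow = params.ow_stage
    order = [ow] + list(STAGES)  # code 0 borrows the OW stage's thresholds
    ldt = np.array([params.stage_ldt[s] for s in order])
    udt = np.array([params.stage_udt[s] for s in order])
    dur = np.array([np.inf] + [params.stage_dd[s] for s in STAGES])  # OW set per cohort
    event = np.array([np.inf] + [params.event_dd[s] for s in STAGES])
    nxt = np.empty(5, dtype=np.int8)
    nxt[0] = STAGE_INDEX[STAGES[(STAGES.index(ow) + 1) % 4]]
    for i, s in enumerate(STAGES):
        nxt[i + 1] = STAGE_INDEX[STAGES[(i + 1) % 4]]
    return ldt, udt, dur, event, nxt


def run_grid(cube: WeatherCube, params: SpeciesParams, config: RunConfig) -> GridOutputs:
    """Run the daily time step over every grid cell.

    Produces, per sampled day: accumulated degree-days (first cohort,
    larval thresholds — representative for all cohorts), the middle
    cohort's stage+generation code map, per-(generation, stage)
    population fractions from cohort weights, and stress accumulations
    with exclusion classes. At run end: the voltinism grid (middle
    cohort) and earliest/average event-day grids across cohorts.
    """
    config.validate(params)
    cohorts = make_cohorts(params, config.n_cohorts)
    if config.extent is not None:
        cube = cube.crop(config.extent)

    nd = cube.n_days
    nr, nc = cube.shape
    ncell = nr * nc
    tmin = cube.tmin.reshape(nd, ncell)
    tmax = cube.tmax.reshape(nd, ncell)
    maxgen = params.max_event_generations
    start_day = cube.dates[0].timetuple().tm_yday

    sdays = sample_days(nd, config.sample_every, start_day)
    offsets = sdays - start_day
    offset_pos = {int(o): i for i, o in enumerate(offsets)}
    n_samp = len(sdays)

    ldt, udt, dur, event_thr, nxt = _threshold_tables(params)
    dd_fn = dd_method(params.calctype)
    pairs = {}
    for code in range(5):
        pairs.setdefault((ldt[code], udt[code]), []).append(code)

    valid_day = np.isfinite(tmin) & np.isfinite(tmax)
    missing = (~valid_day).sum(axis=0)
    nodata_mask = missing == nd

    # stress is cohort-independent: accumulate, sample, classify
    cold_cum = np.nancumsum(
        np.where(valid_day, daily_cold_stress(tmin, params.coldstress_threshold), 0.0), axis=0)
    heat_cum = np.nancumsum(
        np.where(valid_day, daily_heat_stress(tmax, params.heatstress_threshold), 0.0), axis=0)
    cold_accum = cold_cum[offsets]
    heat_accum = heat_cum[offsets]
    cold_class = classify_exclusion(cold_accum, params.coldstress_units_max1,
                                    params.coldstress_units_max2)
    heat_class = classify_exclusion(heat_accum, params.heatstress_units_max1,
                                    params.heatstress_units_max2)

    n_coh = cohorts.n
    mid = cohorts.middle_index
    stage = np.zeros((n_coh, ncell), dtype=np.int8)
    accum = np.zeros((n_coh, ncell))
    gen = np.zeros((n_coh, ncell), dtype=np.int16)
    events = np.full((n_coh, maxgen * 5, ncell), np.nan, dtype=np.float32)
    codes_at_samples = np.zeros((n_coh, n_samp, ncell), dtype=np.int16)

    cum_dd = np.zeros(ncell)
    accum_dd_out = np.zeros((n_samp, ncell))
    cells = np.arange(ncell)
    larva_code = STAGE_INDEX["larva"]

    for i in range(nd):
        day = start_day + i
        dd5 = np.empty((5, ncell))
        for (lo, hi), codes in pairs.items():
            val = dd_fn(tmin[i], tmax[i], lo, hi)
            for code in codes:
                dd5[code] = val
        valid = valid_day[i]
        cum_dd = np.where(valid, cum_dd + dd5[larva_code], cum_dd)

        for k in range(n_coh):
            st = stage[k]
            ac = accum[k]
            gn = gen[k]
            dd_act = dd5[st, cells]
            ac = np.where(valid, ac + dd_act, ac)

            ow_req = cohorts.emergence_dd[k]
            thr = np.where(st == 0, ow_req, event_thr[st])
            idx = np.minimum(gn.astype(np.intp) * 5 + st, maxgen * 5 - 1)
            rec = (valid & (gn < maxgen) & (ac >= thr)
                   & np.isnan(events[k][idx, cells]))
            if rec.any():
                events[k][idx[rec], cells[rec]] = day

            req = np.where(st == 0, ow_req, dur[st])
            tr = valid & (ac >= req)
            if tr.any():
                new_st = np.where(tr, nxt[st], st)
                gn = gn + (tr & (new_st == 1))
                ac = np.where(tr, ac - req, ac)
                st = new_st
                thr2 = event_thr[st]
                idx2 = np.minimum(gn.astype(np.intp) * 5 + st, maxgen * 5 - 1)
                rec2 = (tr & (gn < maxgen) & (ac >= thr2)
                        & np.isnan(events[k][idx2, cells]))
                if rec2.any():
                    events[k][idx2[rec2], cells[rec2]] = day
            stage[k] = st
            accum[k] = ac
            gen[k] = gn

        pos = offset_pos.get(i)
        if pos is not None:
            accum_dd_out[pos] = cum_dd
            codes_at_samples[:, pos, :] = 10 * gen.astype(np.int16) + stage

    # population fractions per (generation, stage) per sampled day
    fractions: dict = {}
    for k in range(n_coh):
        w = cohorts.weight[k]
        for code in np.unique(codes_at_samples[k]):
            g, s_idx = divmod(int(code), 10)
            key = (g, ALL_STAGES[s_idx])
            arr = fractions.setdefault(key, np.zeros((n_samp, ncell)))
            arr += w * (codes_at_samples[k] == code)

    # event maps: earliest and cohort-weighted average day across cohorts
    events_earliest, events_average = {}, {}
    w_col = cohorts.weight[:, None]
    for g in range(maxgen):
        for s_idx in range(5):
            ev = events[:, g * 5 + s_idx, :].astype(float)  # (n_coh, ncell)
            got = np.isfinite(ev)
            if not got.any():
                continue
            key = (g, ALL_STAGES[s_idx])
            earliest = np.where(got.any(axis=0),
                                np.where(got, ev, np.inf).min(axis=0), np.nan)
            ws = np.where(got, w_col if config.weighted_events else 1.0, 0.0)
            tot = ws.sum(axis=0)
            avg = np.where(tot > 0, np.round(np.nansum(ws * ev, axis=0)
                                             / np.where(tot > 0, tot, 1.0)), np.nan)
            events_earliest[key] = earliest.reshape(nr, nc)
            events_average[key] = avg.reshape(nr, nc)

    volt = gen[mid].astype(np.int16)

    def _shape(a):
        return a.reshape((-1, nr, nc)) if a.ndim == 2 else a.reshape(nr, nc)

    accum_dd_g = _shape(accum_dd_out)
    mid_codes = codes_at_samples[mid].astype(np.int16).reshape(n_samp, nr, nc)
    nod = nodata_mask.reshape(nr, nc)
    accum_dd_g[:, nod] = np.nan
    mid_codes[:, nod] = NODATA_INT
    volt = volt.reshape(nr, nc)
    volt[nod] = NODATA_INT
    fr = {}
    for key, arr in fractions.items():
        a = arr.reshape(n_samp, nr, nc)
        a[:, nod] = np.nan
        fr[key] = a
    for d in (events_earliest, events_average):
        for key in d:
            d[key][nod] = np.nan

    return GridOutputs(
        sample_days=sdays, sample_dates=[cube.dates[int(o)] for o in offsets],
        geometry=cube.geometry,
        accum_dd=accum_dd_g, mid_stage_code=mid_codes, fractions=fr,
        cold_accum=cold_accum.reshape(n_samp, nr, nc),
        heat_accum=heat_accum.reshape(n_samp, nr, nc),
        cold_class=cold_class.reshape(n_samp, nr, nc),
        heat_class=heat_class.reshape(n_samp, nr, nc),
        all_class=np.maximum(cold_class, heat_class).reshape(n_samp, nr, nc),
        voltinism=volt,
        events_earliest=events_earliest, events_average=events_average,
        missing_days=missing.reshape(nr, nc), nodata_mask=nod,
        params=params, cohorts=cohorts,
    )


def _tile_layout(n_tiles: int):
    r = int(np.floor(np.sqrt(n_tiles)))
    while n_tiles % r:
        r -= 1
    return r, n_tiles // r


def tile_and_mosaic(cube: WeatherCube, params: SpeciesParams, config: RunConfig,
                    n_tiles: int | None = None) -> GridOutputs:
    """Run the grid in tiles and mosaic the results.

    Per-cell computation has no spatial coupling, so the mosaic is
    bit-identical to an untiled :func:`run_grid` for any tiling.
    """
    if n_tiles is None:
        n_tiles = config.n_tiles
    if config.extent is not None:
        cube = cube.crop(config.extent)
        config = dataclasses.replace(config, extent=None)
    if n_tiles == 1:
        return run_grid(cube, params, config)

    nr, nc = cube.shape
    tr, tc = _tile_layout(n_tiles)
    row_edges = np.linspace(0, nr, tr + 1).astype(int)
    col_edges = np.linspace(0, nc, tc + 1).astype(int)
    tiles = []
    for i in range(tr):
        for j in range(tc):
            r0, r1 = row_edges[i], row_edges[i + 1]
            c0, c1 = col_edges[j], col_edges[j + 1]
            if r1 <= r0 or c1 <= c0:
                continue
            sub = cube.subgrid(r0, r1, c0, c1)
            tiles.append(((r0, r1, c0, c1), run_grid(sub, params, config)))

    first = tiles[0][1]
    n_samp = len(first.sample_days)

    def mosaic(getter, fill, dtype=float, per_day=True):
        shape = (n_samp, nr, nc) if per_day else (nr, nc)
        out = np.full(shape, fill, dtype=dtype)
        for (r0, r1, c0, c1), t in tiles:
            block = getter(t)
            if block is None:
                continue
            if per_day:
                out[:, r0:r1, c0:c1] = block
            else:
                out[r0:r1, c0:c1] = block
        return out

    frac_keys = set()
    ev_keys = set()
    for _, t in tiles:
        frac_keys.update(t.fractions)
        ev_keys.update(t.events_earliest)

    fractions = {}
    for key in frac_keys:
        fractions[key] = mosaic(lambda t, k=key: t.fractions.get(k), 0.0)
        for (r0, r1, c0, c1), t in tiles:  # keep nodata cells NaN even when key absent
            if key not in t.fractions:
                fractions[key][:, r0:r1, c0:c1][:, t.nodata_mask] = np.nan
    events_earliest, events_average = {}, {}
    for key in ev_keys:
        events_earliest[key] = mosaic(lambda t, k=key: t.events_earliest.get(k),
                                      np.nan, per_day=False)
        events_average[key] = mosaic(lambda t, k=key: t.events_average.get(k),
                                     np.nan, per_day=False)

    return GridOutputs(
        sample_days=first.sample_days, sample_dates=first.sample_dates,
        geometry=cube.geometry,
        accum_dd=mosaic(lambda t: t.accum_dd, np.nan),
        mid_stage_code=mosaic(lambda t: t.mid_stage_code, NODATA_INT, dtype=np.int16),
        fractions=fractions,
        cold_accum=mosaic(lambda t: t.cold_accum, np.nan),
        heat_accum=mosaic(lambda t: t.heat_accum, np.nan),
        cold_class=mosaic(lambda t: t.cold_class, 0, dtype=np.int8),
        heat_class=mosaic(lambda t: t.heat_class, 0, dtype=np.int8),
        all_class=mosaic(lambda t: t.all_class, 0, dtype=np.int8),
        voltinism=mosaic(lambda t: t.voltinism, NODATA_INT, dtype=np.int16, per_day=False),
        events_earliest=events_earliest, events_average=events_average,
        missing_days=mosaic(lambda t: t.missing_days, 0, dtype=int, per_day=False),
        nodata_mask=mosaic(lambda t: t.nodata_mask, False, dtype=bool, per_day=False),
        params=params, cohorts=first.cohorts,
    )


def _doy_label(day, year: int) -> str:
    """Calendar month-day label for a day of year (e.g. 60 -> 'Mar-01')."""
    if not np.isfinite(day):
        return "n/a"
    d = dt.date(year, 1, 1) + dt.timedelta(days=int(day) - 1)
    return d.strftime("%b-%d")


def _masked_per_day(outputs: GridOutputs, layers: np.ndarray, mode: str) -> np.ndarray:
    """Mask each sampled-day band with that day's exclusion classes."""
    out = np.empty_like(np.asarray(layers, dtype=float))
    for i in range(layers.shape[0]):
        out[i] = outputs.masked(layers[i], mode, step=i)
    return out


def write_outputs(outputs: GridOutputs, directory, config: RunConfig | None = None,
                  make_png: bool = True, point_cells=None) -> dict:
    """Write multi-layer GeoTIFFs, summary PNG maps, and a run manifest.

    One GeoTIFF per output family with one band per sampled day (band
    names are dates); event-day maps are single-band with earliest and
    average variants. Every phenology family except accumulated
    degree-days also gets masked variants under both exclusion modes
    (suffixes ``_masked-severe`` for severe-only and ``_masked-all`` for
    severe-plus-moderate). Returns a mapping of logical names to paths.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    geom = outputs.geometry
    labels = [d.isoformat() for d in outputs.sample_dates]
    year = outputs.sample_dates[-1].year
    written = {}

    def tif(name, data, dtype, band_labels=None, nodata=None, meta=None):
        p = write_geotiff(directory / f"{name}.tif", data, geom,
                          band_labels=band_labels, nodata=nodata, meta=meta, dtype=dtype)
        written[name] = p

    def pheno_family(name, data, dtype, band_labels=None, nodata=None, per_day=True):
        """Write a phenology family plus its two stress-masked variants."""
        tif(name, data, dtype, band_labels, nodata)
        for suffix, mode in (("masked-severe", "severe_only"),
                             ("masked-all", "severe_and_moderate")):
            if per_day:
                masked = _masked_per_day(outputs, data.astype(float), mode)
            else:
                masked = outputs.masked(data.astype(float), mode, step=-1)
            tif(f"{name}_{suffix}", masked, np.float32, band_labels, nodata)

    tif("accumdd", outputs.accum_dd, np.float32, labels)  # never masked
    pheno_family("stage_midcohort", outputs.mid_stage_code, np.int16, labels,
                 nodata=NODATA_INT)
    for (g, s), arr in sorted(outputs.fractions.items()):
        pheno_family(f"fraction_g{g}_{s}", arr, np.float32, labels)
    pheno_family("voltinism", outputs.voltinism, np.int16, nodata=NODATA_INT,
                 per_day=False)

    tif("coldstress", outputs.cold_accum, np.float32, labels)
    tif("heatstress", outputs.heat_accum, np.float32, labels)
    tif("coldstress_scaled", scale_stress(np.nan_to_num(outputs.cold_accum[-1])),
        np.float32)
    tif("heatstress_scaled", scale_stress(np.nan_to_num(outputs.heat_accum[-1])),
        np.float32)
    tif("exclusion_cold", outputs.cold_class, np.int8, labels)
    tif("exclusion_heat", outputs.heat_class, np.int8, labels)
    tif("exclusion_all", outputs.all_class, np.int8, labels)

    wanted = None
    if config is not None and config.events:
        wanted = {(g, s) for s, g in config.events}
    for key in sorted(outputs.events_earliest):
        if wanted is not None and key not in wanted:
            continue
        g, s = key
        pheno_family(f"event_g{g}_{s}_earliest", outputs.events_earliest[key],
                     np.float32, per_day=False)
        pheno_family(f"event_g{g}_{s}_average", outputs.events_average[key],
                     np.float32, per_day=False)

    if make_png:
        _write_pngs(outputs, directory, written, wanted, year)

    if point_cells:
        _write_point_csv(outputs, directory, point_cells, written)

    manifest = {
        "package": {"name": "phenorisk", "version": __version__},
        "species": dataclasses.asdict(outputs.params),
        "config": dataclasses.asdict(config) if config is not None else None,
        "n_cohorts": outputs.cohorts.n,
        "cohort_emergence_dd": outputs.cohorts.emergence_dd.tolist(),
        "cohort_weights": outputs.cohorts.weight.tolist(),
        "sample_days": outputs.sample_days.tolist(),
        "sample_dates": labels,
        "stage_code_legend": {
            "description": "integer code = 10 * generation + stage index",
            "stage_index": dict(STAGE_INDEX),
        },
        "exclusion_legend": {"0": "suitable", "1": "excl.-moderate", "2": "excl.-severe",
                             "mask_sentinels": {"moderate": -1, "severe": -2}},
        "nodata": {"int": NODATA_INT, "float": geom.nodata},
        "files": {k: str(v.name) for k, v in written.items()},
    }
    mpath = directory / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    written["manifest"] = mpath
    return written


def _write_pngs(outputs, directory, written, wanted, year):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import BoundaryNorm, ListedColormap

    extent = outputs.geometry.extent(*outputs.voltinism.shape)
    mpl_extent = (extent[0], extent[2], extent[1], extent[3])

    fig, ax = plt.subplots(figsize=(6, 5))
    volt = np.where(outputs.voltinism == NODATA_INT, np.nan,
                    outputs.voltinism.astype(float))
    im = ax.imshow(volt, extent=mpl_extent, interpolation="nearest", cmap="viridis")
    fig.colorbar(im, ax=ax, label="generations per year")
    ax.set_title(f"Voltinism — {outputs.params.name}")
    fig.savefig(directory / "voltinism.png", dpi=120)
    plt.close(fig)
    written["voltinism_png"] = directory / "voltinism.png"

    cmap = ListedColormap(["#2c7fb8", "#fec44f", "#de2d26"])
    norm = BoundaryNorm([-0.5, 0.5, 1.5, 2.5], cmap.N)
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(outputs.all_class[-1], extent=mpl_extent, interpolation="nearest",
                   cmap=cmap, norm=norm)
    cbar = fig.colorbar(im, ax=ax, ticks=[0, 1, 2])
    cbar.ax.set_yticklabels(["suitable", "excl.-moderate", "excl.-severe"])
    ax.set_title(f"Climate stress exclusion — {outputs.params.name}")
    fig.savefig(directory / "suitability.png", dpi=120)
    plt.close(fig)
    written["suitability_png"] = directory / "suitability.png"

    for key in sorted(outputs.events_average):
        if wanted is not None and key not in wanted:
            continue
        g, s = key
        arr = outputs.events_average[key]
        if not np.isfinite(arr).any():
            continue
        fig, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(arr, extent=mpl_extent, interpolation="nearest", cmap="plasma")
        cbar = fig.colorbar(im, ax=ax)
        ticks = cbar.get_ticks()
        cbar.set_ticks(ticks)
        cbar.ax.set_yticklabels([_doy_label(t, year) for t in ticks])
        ax.set_title(f"Average event date — gen {g} {s} — {outputs.params.name}")
        name = f"event_g{g}_{s}_average.png"
        fig.savefig(directory / name, dpi=120)
        plt.close(fig)
        written[f"event_g{g}_{s}_average_png"] = directory / name

def _write_point_csv(outputs, directory, point_cells, written):
    import pandas as pd

    rows = []
    for (r, c) in point_cells:
        for i, day in enumerate(outputs.sample_days):
            code = int(outputs.mid_stage_code[i, r, c])
            rows.append({
                "row": r, "col": c, "day_of_year": int(day),
                "date": outputs.sample_dates[i].isoformat(),
                "accum_dd": float(outputs.accum_dd[i, r, c]),
                "mid_stage_code": code,
                "generation": code // 10 if code != NODATA_INT else None,
                "stage": ALL_STAGES[code % 10] if code != NODATA_INT else None,
                "cold_accum": float(outputs.cold_accum[i, r, c]),
                "heat_accum": float(outputs.heat_accum[i, r, c]),
                "exclusion": int(outputs.all_class[i, r, c]),
            })
    path = directory / "point_trajectories.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    written["point_trajectories"] = path
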