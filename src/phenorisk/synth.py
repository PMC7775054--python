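"""Synthetic gridded daily weather and mean-preserving monthly interpolation.

The generator emulates the large-scale structure of mid-latitude daily
Tmin/Tmax grids: a north-south temperature gradient, a sinusoidal
seasonal cycle peaking in mid-July (day 196), a fixed diurnal range, and
optional Gaussian day-to-day noise. It deliberately omits topography,
spatial noise correlation and weather systems — it exists so that the
whole pipeline is testable without downloading real temperature data.

Also provided is a mean-preserving monthly-to-daily interpolation: daily
values are linearly interpolated between month midpoints (periodic in the
year) and then iteratively corrected with smooth per-month adjustments
until every month's daily mean matches the input, for use when only
monthly temperature normals are available.
"""

from __future__ import annotations

import calendar
import datetime as dt
from dataclasses import dataclass

import numpy as np

from .geotiff import GridGeometry
from .raster import WeatherCube

#: Day of year of the default seasonal peak (mid-July, northern hemisphere).
PEAK_DOY = 196


@dataclass
class SynthSpec:
    """Controls for the synthetic weather generator.

    ``base_mean`` is the daily mean temperature (deg C) at the south edge
    on the warmest day of the year; each row northward is
    ``lat_gradient`` degrees cooler. The seasonal cycle subtracts up to
    ``2 * seasonal_amplitude`` degrees in mid-winter. Tmin/Tmax are the
    daily mean -/+ half the diurnal range. Defaults are sized to span
    continental-US-like conditions (severe winter cold in the north,
    sub-tropical summers in the south) on a small grid.
    """

    n_rows: int = 20
    n_cols: int = 20
    n_days: int = 365
    base_mean: float = 33.0
    lat_gradient: float = 1.6
    seasonal_amplitude: float = 12.0
    diurnal_range: float = 10.0
    noise_sd: float = 2.0
    seed: int = 0
    start: dt.date = dt.date(2018, 1, 1)
    peak_doy: int = PEAK_DOY
    geometry: GridGeometry = None

    def __post_init__(self):
        if self.n_days < 1 or self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid and period sizes must be >= 1")
        if self.diurnal_range < 0 or self.noise_sd < 0:
            raise ValueError("diurnal_range and noise_sd must be non-negative")
        if self.geometry is None:
            # CONUS-like placement; 0.25 degree cells, origin in the interior west
            self.geometry = GridGeometry(x0=-100.0, y0=45.0, dx=0.25, dy=0.25)


def generate(spec: SynthSpec) -> WeatherCube:
    """Generate a reproducible synthetic :class:`~phenorisk.raster.WeatherCube`.

    The daily mean at south-edge row offset ``r`` (rows count northward
    from the south edge) on day-of-year ``d`` is::

        base_mean - lat_gradient * r
                  - seasonal_amplitude * (1 - cos(2 pi (d - peak_doy) / 365))
                  + noise

    so day ``peak_doy`` is the warmest and days ~13/14 the coldest. The
    same noise draw applies to Tmin and Tmax, preserving Tmin <= Tmax.
    Output arrays are north-up (row 0 = northernmost = coolest).
    """
    rng = np.random.default_rng(spec.seed)
    dates = [spec.start + dt.timedelta(days=i) for i in range(spec.n_days)]
    doy = np.array([d.timetuple().tm_yday for d in dates], dtype=float)

    south_offset = np.arange(spec.n_rows - 1, -1, -1, dtype=float)  # north-up rows
    seasonal = spec.seasonal_amplitude * (1.0 - np.cos(2.0 * np.pi * (doy - spec.peak_doy) / 365.0))
    mean = (spec.base_mean
            - spec.lat_gradient * south_offset[None, :, None]
            - seasonal[:, None, None]
            + np.zeros((1, 1, spec.n_cols)))
    if spec.noise_sd > 0:
        mean = mean + rng.normal(0.0, spec.noise_sd,
                                 size=(spec.n_days, spec.n_rows, spec.n_cols))
    half = spec.diurnal_range / 2.0
    return WeatherCube(dates=dates, tmin=mean - half, tmax=mean + half,
                       geometry=spec.geometry, units="C")


def _month_midpoints(year: int):
    """Day-of-year centers of the 12 months (1-based, fractional)."""
    lengths = np.array([calendar.monthrange(year, m)[1] for m in range(1, 13)], dtype=float)
    starts = np.concatenate([[0.0], np.cumsum(lengths)[:-1]])
    return starts + (lengths + 1) / 2.0, lengths


def _interp_matrix(year: int) -> np.ndarray:
    """(n_days, 12) periodic linear interpolation weights at month midpoints."""
    mids, lengths = _month_midpoints(year)
    n_days = int(lengths.sum())
    days = np.arange(1, n_days + 1, dtype=float)
    # periodic extension: previous December and next January midpoints
    ext_mids = np.concatenate([[mids[-1] - n_days], mids, [mids[0] + n_days]])
    ext_idx = np.concatenate([[11], np.arange(12), [0]])
    w = np.zeros((n_days, 12))
    seg = np.searchsorted(ext_mids, days, side="right") - 1
    lo = ext_mids[seg]
    hi = ext_mids[seg + 1]
    frac = (days - lo) / (hi - lo)
    for d in range(n_days):
        w[d, ext_idx[seg[d]]] += 1.0 - frac[d]
        w[d, ext_idx[seg[d] + 1]] += frac[d]
    return w


def _month_mean_matrix(year: int) -> np.ndarray:
    """(12, n_days) operator taking daily values to monthly means."""
    mids, lengths = _month_midpoints(year)
    n_days = int(lengths.sum())
    m = np.zeros((12, n_days))
    start = 0
    for i, ln in enumerate(lengths.astype(int)):
        m[i, start:start + ln] = 1.0 / ln
        start += ln
    return m


class InterpolationError(RuntimeError):
    """Mean-preserving correction failed to converge."""


def monthly_to_daily(monthly_means, year: int, tol: float = 0.01,
                     max_iter: int = 100) -> np.ndarray:
    """Mean-preserving monthly-to-daily temperature interpolation.

    ``monthly_means`` has 12 values along its first axis (any trailing
    cell dimensions). Daily values are interpolated linearly between
    month midpoints, periodic across year boundaries, then iteratively
    adjusted with smooth additive corrections until each month's daily
    mean matches its input within ``tol`` degrees C.
    """
    monthly = np.asarray(monthly_means, dtype=float)
    if monthly.shape[0] != 12:
        raise ValueError("monthly_means must have 12 values along the first axis")
    if not np.all(np.isfinite(monthly)):
        raise ValueError("monthly means must be finite")

    w = _interp_matrix(year)
    mmean = _month_mean_matrix(year)
    flat = monthly.reshape(12, -1)
    daily = w @ flat
    for _ in range(max_iter):
        resid = flat - mmean @ daily
        worst = float(np.max(np.abs(resid)))
        if worst <= tol:
            out_shape = (daily.shape[0],) + monthly.shape[1:]
            return daily.reshape(out_shape)
        daily = daily + w @ resid
    raise InterpolationError(
        f"monthly-mean correction did not converge within {max_iter} iterations "
        f"(max residual {worst:.4f} C)")
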