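"""Daily degree-day calculation from Tmin/Tmax with lower and upper thresholds.

Two standard methods are provided, both operating point-wise or
element-wise over arrays:

* ``average`` — simple average with a horizontal cutoff at the upper
  threshold: the day's mean temperature is clamped to [LDT, UDT] and the
  excess over LDT is the day's degree-days.
* ``triangle`` — single triangle with upper threshold: the day is modeled
  as a triangular temperature trajectory from Tmin up to Tmax and back
  over 24 h; degree-days are the time-average of the trajectory clipped
  to [LDT, UDT], minus LDT. The area above UDT is removed (horizontal
  cutoff), not reflected.

Non-finite temperatures propagate as NaN so that missing weather never
masquerades as a cold day. Inputs with Tmin > Tmax are repaired by
swapping, with a logged warning.
"""

from __future__ import annotations

import logging

import numpy as np

from .params import STAGES, SpeciesParams, ParameterError

logger = logging.getLogger(__name__)


class ConfigError(ParameterError):
    """Unknown degree-day calculation method."""


def _repair(tmin, tmax):
    tmin = np.asarray(tmin, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    swapped = tmin > tmax
    if np.any(swapped):
        logger.warning("Tmin > Tmax for %d value(s); swapping", int(np.count_nonzero(swapped)))
        lo = np.where(swapped, tmax, tmin)
        hi = np.where(swapped, tmin, tmax)
        return lo, hi
    return tmin, tmax


def dd_simple_average(tmin, tmax, ldt: float, udt: float):
    """Simple-average degree-days with horizontal cutoff at ``udt``.

    Returns ``clamp((tmin+tmax)/2, ldt, udt) - ldt``; bounded in
    [0, udt - ldt]. NaN inputs yield NaN.
    """
    if not ldt < udt:
        raise ParameterError("lower threshold must be below upper threshold")
    tmin, tmax = _repair(tmin, tmax)
    m = 0.5 * (tmin + tmax)
    out = np.clip(m, ldt, udt) - ldt
    out = np.where(np.isnan(m), np.nan, out)
    return out if out.ndim else float(out)


def dd_single_triangle(tmin, tmax, ldt: float, udt: float):
    """Single-triangle degree-days with upper threshold.

    Closed form of the time-average of the clipped triangular trajectory:
    with span = tmax - tmin > 0 and ldt < tmax, the uncapped area is
    ``(tmin+tmax)/2 - ldt`` if tmin >= ldt else ``(tmax-ldt)^2 / (2 span)``;
    when tmax > udt the lobe ``(tmax-udt)^2 / (2 span)`` above the upper
    threshold is removed. A constant-temperature day (tmin == tmax) is the
    continuity limit ``clamp(tmin, ldt, udt) - ldt`` (floored at 0).
    Bounded in [0, udt - ldt]; NaN inputs yield NaN.
    """
    if not ldt < udt:
        raise ParameterError("lower threshold must be below upper threshold")
    tmin, tmax = _repair(tmin, tmax)
    scalar = tmin.ndim == 0 and tmax.ndim == 0
    tmin, tmax = np.broadcast_arrays(np.atleast_1d(tmin), np.atleast_1d(tmax))

    span = tmax - tmin
    safe_span = np.where(span > 0, span, 1.0)

    base = np.where(
        tmin >= ldt,
        0.5 * (tmin + tmax) - ldt,
        (tmax - ldt) ** 2 / (2.0 * safe_span),
    )
    cap = np.where(tmax > udt, (tmax - udt) ** 2 / (2.0 * safe_span), 0.0)
    out = base - cap

    const_day = np.clip(tmin, ldt, udt) - ldt  # tmin == tmax limit
    out = np.where(span == 0, const_day, out)
    out = np.where(tmax <= ldt, 0.0, out)
    out = np.where(tmin >= udt, udt - ldt, out)
    out = np.clip(out, 0.0, udt - ldt)
    out = np.where(np.isnan(tmin) | np.isnan(tmax), np.nan, out)
    return float(out[0]) if scalar else out


_METHODS = {
    "average": dd_simple_average,
    "triangle": dd_single_triangle,
}


def dd_method(calctype: str):
    """Return the degree-day function named by ``calctype``."""
    try:
        return _METHODS[calctype]
    except KeyError:
        raise ConfigError(
            f"unknown degree-day calculation method {calctype!r}; "
            f"expected one of {sorted(_METHODS)}") from None


def daily_stage_dd(tmin, tmax, params: SpeciesParams) -> dict:
    """Per-stage daily degree-days using each stage's own thresholds.

    Applies the method named by ``params.calctype``. When all stages share
    thresholds, all entries are equal (computed once).
    """
    fn = dd_method(params.calctype)
    out = {}
    cache = {}
    for s in STAGES:
        key = (params.stage_ldt[s], params.stage_udt[s])
        if key not in cache:
            cache[key] = fn(tmin, tmax, *key)
        out[s] = cache[key]
    return out
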