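"""Cold/heat stress accumulation and moderate/severe exclusion classes.

Climatic suitability is delineated by temperature stress: each day, cold
stress units are the shortfall of Tmin below the cold stress threshold
and heat stress units are the excess of Tmax above the heat stress
threshold. Stress accumulates linearly across the entire run — daily
units are simply summed, with no extra weighting of consecutive days and
no within-run reset. A location whose accumulation exceeds the moderate
limit (max1) is moderate-excluded (short-term establishment only); one
exceeding the severe limit (max2) is severe-excluded (no establishment).
A single threshold pair applies to all life stages. Boundary equality
with a limit is classified as not excluded (strictly-greater convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np


class ExclusionClass(IntEnum):
    NONE = 0
    MODERATE_EXCLUDED = 1
    SEVERE_EXCLUDED = 2


#: Sentinel codes substituted into masked phenology layers.
SENTINEL_MODERATE = -1
SENTINEL_SEVERE = -2


def daily_cold_stress(tmin, threshold: float):
    """Daily cold stress units: ``max(0, threshold - tmin)``; NaN propagates."""
    tmin = np.asarray(tmin, dtype=float)
    out = np.where(np.isnan(tmin), np.nan, np.maximum(0.0, threshold - tmin))
    return out if out.ndim else float(out)


def daily_heat_stress(tmax, threshold: float):
    """Daily heat stress units: ``max(0, tmax - threshold)``; NaN propagates."""
    tmax = np.asarray(tmax, dtype=float)
    out = np.where(np.isnan(tmax), np.nan, np.maximum(0.0, tmax - threshold))
    return out if out.ndim else float(out)


def accumulate_stress(daily_units):
    """Running sum of daily stress units along the first axis.

    Never resets within a run; missing (NaN) days contribute nothing but
    do not reset the trace.
    """
    daily = np.asarray(daily_units, dtype=float)
    if daily.size == 0:
        raise ValueError("daily stress sequence must be non-empty")
    return np.nancumsum(daily, axis=0)


def classify_exclusion(accum, max1: float, max2: float):
    """Exclusion class from accumulated stress.

    NONE if accum <= max1, MODERATE_EXCLUDED if max1 < accum <= max2,
    SEVERE_EXCLUDED if accum > max2.
    """
    if not max1 < max2:
        raise ValueError("stress limits must satisfy max1 < max2")
    accum = np.asarray(accum, dtype=float)
    out = np.where(accum > max2, int(ExclusionClass.SEVERE_EXCLUDED),
                   np.where(accum > max1, int(ExclusionClass.MODERATE_EXCLUDED),
                            int(ExclusionClass.NONE)))
    if out.ndim == 0:
        return ExclusionClass(int(out))
    return out.astype(np.int8)


@dataclass
class StressField:
    """Accumulated stress and exclusion classes over a grid (or scalars)."""

    cold_accum: np.ndarray
    heat_accum: np.ndarray
    cold_class: np.ndarray
    heat_class: np.ndarray

    @property
    def all_class(self):
        """Combined class: the more severe of cold and heat."""
        return np.maximum(self.cold_class, self.heat_class)

    @classmethod
    def from_accumulations(cls, cold_accum, heat_accum, params) -> "StressField":
        return cls(
            cold_accum=np.asarray(cold_accum, dtype=float),
            heat_accum=np.asarray(heat_accum, dtype=float),
            cold_class=classify_exclusion(cold_accum, params.coldstress_units_max1,
                                          params.coldstress_units_max2),
            heat_class=classify_exclusion(heat_accum, params.heatstress_units_max1,
                                          params.heatstress_units_max2),
        )


def apply_exclusion_mask(pheno_layer, stress: StressField, mode: str):
    """Mask a phenology layer by climate-stress exclusion.

    ``mode`` is ``"severe_only"`` or ``"severe_and_moderate"``. Excluded
    cells are replaced by sentinel codes (severe -> -2, moderate -> -1);
    all other cells pass through unchanged. Accumulated degree-day layers
    are by convention never masked (the caller enforces this).
    """
    if mode not in ("severe_only", "severe_and_moderate"):
        raise ValueError(f"unknown exclusion mode {mode!r}")
    layer = np.array(pheno_layer, dtype=float, copy=True)
    cls = np.asarray(stress.all_class)
    if cls.ndim and cls.shape != layer.shape[layer.ndim - cls.ndim:]:
        raise ValueError("phenology layer and stress field grids do not match")
    layer[..., cls == ExclusionClass.SEVERE_EXCLUDED] = SENTINEL_SEVERE
    if mode == "severe_and_moderate":
        layer[..., cls == ExclusionClass.MODERATE_EXCLUDED] = SENTINEL_MODERATE
    return layer


def scale_stress(accum):
    """Linearly rescale a non-negative stress grid onto [0, 1000].

    The grid maximum maps to 1000; an all-zero grid stays all-zero.
    """
    accum = np.asarray(accum, dtype=float)
    if np.any(accum < 0):
        raise ValueError("stress accumulations must be non-negative")
    top = np.nanmax(accum) if accum.size else 0.0
    if not np.isfinite(top) or top == 0:
        return np.zeros_like(accum)
    return accum * (1000.0 / top)
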