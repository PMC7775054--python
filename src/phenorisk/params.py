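"""Species parameter schema and overwintering cohort discretization.

A species is described by a flat key--value parameter file (YAML mapping)
whose keys are the standard degree-day model codes: per-stage lower and
upper developmental thresholds (``eggLDT`` .. ``adultUDT``), per-stage
durations in degree-days Celsius (``eggDD``, ``larvaeDD``, ``pupDD``,
``adultDD``), per-stage phenological-event thresholds (``eggEventDD`` ..),
cold/heat stress thresholds and limits, and the five parameters of the
overwintering emergence distribution (``distro_mean``, ``distro_var``,
``xdist1``, ``xdist2``, ``distro_shape``).

Emergence variability is represented by discretizing that distribution
into *cohorts*: population fractions that each complete the overwintering
stage at a fixed degree-day requirement and then develop in synchrony.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import yaml
from scipy import stats

#: Developmental stages in cyclic order (egg -> larva -> pupa -> adult -> egg).
STAGES = ("egg", "larva", "pupa", "adult")


class ParameterError(ValueError):
    """Base class for species-parameter problems."""


class SchemaError(ParameterError):
    """A required key is missing or a value cannot be interpreted."""


class ValidationError(ParameterError):
    """A parameter value violates a model invariant."""


# Standard parameter codes per stage; "pupDD" (not "pupaeDD") is conventional.
_STAGE_CODES = {
    "egg": {"ldt": "eggLDT", "udt": "eggUDT", "dd": "eggDD", "event": "eggEventDD"},
    "larva": {"ldt": "larvaeLDT", "udt": "larvaeUDT", "dd": "larvaeDD", "event": "larvaeEventDD"},
    "pupa": {"ldt": "pupaeLDT", "udt": "pupaeUDT", "dd": "pupDD", "event": "pupaeEventDD"},
    "adult": {"ldt": "adultLDT", "udt": "adultUDT", "dd": "adultDD", "event": "adultEventDD"},
}

_OW_ALIASES = {
    "egg": "egg", "eggs": "egg",
    "larva": "larva", "larvae": "larva",
    "pupa": "pupa", "pupae": "pupa",
    "adult": "adult", "adults": "adult",
}

_OW_DD_CODES = {"OWeggDD": "egg", "OWlarvaeDD": "larva", "OWpupDD": "pupa", "OWadultDD": "adult"}

_SCALAR_CODES = (
    "coldstress_threshold", "coldstress_units_max1", "coldstress_units_max2",
    "heatstress_threshold", "heatstress_units_max1", "heatstress_units_max2",
    "distro_mean", "distro_var", "xdist1", "xdist2",
)


@dataclass
class SpeciesParams:
    """Full parameter set for one species.

    Temperatures are degrees Celsius, durations and event thresholds are
    degree-days Celsius (DDC). ``event_dd[s]`` is the within-stage DD at
    which the stage's phenological event (e.g. first egg laying for
    adults) is recorded. The overwintering stage's event fires when the
    cohort completes its overwintering requirement (emergence), so it
    carries no fixed threshold here.
    """

    name: str
    stage_ldt: dict
    stage_udt: dict
    stage_dd: dict
    ow_stage: str
    event_dd: dict
    coldstress_threshold: float
    coldstress_units_max1: float
    coldstress_units_max2: float
    heatstress_threshold: float
    heatstress_units_max1: float
    heatstress_units_max2: float
    distro_mean: float
    distro_var: float
    xdist1: float
    xdist2: float
    distro_shape: str = "normal"
    calctype: str = "triangle"
    max_event_generations: int = 4

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        """Raise :class:`ValidationError` naming the first violated invariant."""
        if self.ow_stage not in STAGES:
            raise ValidationError(f"ow_stage must be one of {STAGES}, got {self.ow_stage!r}")
        for s in STAGES:
            for table, what in ((self.stage_ldt, "LDT"), (self.stage_udt, "UDT"),
                                (self.stage_dd, "DD"), (self.event_dd, "EventDD")):
                if s not in table:
                    raise SchemaError(f"missing {what} for stage {s!r}")
            if not self.stage_ldt[s] < self.stage_udt[s]:
                raise ValidationError(
                    f"stage {s!r}: lower threshold must be below upper "
                    f"({self.stage_ldt[s]} >= {self.stage_udt[s]})")
            if not self.stage_dd[s] > 0:
                raise ValidationError(f"stage {s!r}: duration must be positive")
            if not 0 <= self.event_dd[s] <= self.stage_dd[s]:
                raise ValidationError(
                    f"stage {s!r}: event threshold must lie in [0, stage duration] "
                    f"({self.event_dd[s]} vs {self.stage_dd[s]})")
        if not self.coldstress_units_max1 < self.coldstress_units_max2:
            raise ValidationError(
                "cold stress limits must be ordered: moderate (max1) < severe (max2) "
                f"({self.coldstress_units_max1} >= {self.coldstress_units_max2})")
        if not self.heatstress_units_max1 < self.heatstress_units_max2:
            raise ValidationError(
                "heat stress limits must be ordered: moderate (max1) < severe (max2) "
                f"({self.heatstress_units_max1} >= {self.heatstress_units_max2})")
        if not self.xdist1 <= self.distro_mean <= self.xdist2:
            raise ValidationError(
                "emergence distribution mean must lie within [xdist1, xdist2] "
                f"({self.xdist1} <= {self.distro_mean} <= {self.xdist2} fails)")
        if self.distro_var < 0:
            raise ValidationError("emergence distribution variance must be non-negative")
        if self.distro_shape not in ("normal", "lognormal"):
            raise ValidationError(f"distro_shape must be 'normal' or 'lognormal', got {self.distro_shape!r}")
        if self.calctype not in ("average", "triangle"):
            raise ValidationError(f"calctype must be 'average' or 'triangle', got {self.calctype!r}")
        if self.max_event_generations < 1:
            raise ValidationError("max_event_generations must be >= 1")

    def with_updates(self, **kwargs) -> "SpeciesParams":
        return replace(self, **kwargs)


@dataclass
class CohortSet:
    """Discretized overwintering emergence distribution.

    ``emergence_dd[i]`` is cohort *i*'s degree-day requirement to complete
    the overwintering stage (accumulated from the run's fixed start date);
    ``weight[i]`` is the population fraction it represents.
    """

    emergence_dd: np.ndarray
    weight: np.ndarray

    def __post_init__(self):
        self.emergence_dd = np.asarray(self.emergence_dd, dtype=float)
        self.weight = np.asarray(self.weight, dtype=float)
        if self.emergence_dd.shape != self.weight.shape or self.emergence_dd.ndim != 1:
            raise ValidationError("emergence_dd and weight must be matching 1-D arrays")
        if np.any(np.diff(self.emergence_dd) <= 0):
            raise ValidationError("cohort emergence_dd values must be strictly increasing")
        if np.any(self.weight <= 0):
            raise ValidationError("all cohort weights must be positive")
        if abs(float(self.weight.sum()) - 1.0) > 1e-9:
            raise ValidationError("cohort weights must sum to 1 within 1e-9")

    @property
    def n(self) -> int:
        return self.emergence_dd.size

    @property
    def middle_index(self) -> int:
        """Index of the middle cohort (the ceil(n/2)-th cohort, 0-based)."""
        return self.n // 2


def _fahrenheit_to_celsius_threshold(value: float) -> float:
    # Integer-F rounding before conversion is the long-standing US convention
    # for communicating degree-day model thresholds.
    return (round(float(value)) - 32.0) * 5.0 / 9.0


def _coerce_float(raw: dict, key: str) -> float:
    try:
        return float(raw[key])
    except KeyError:
        raise SchemaError(f"missing required key {key!r}") from None
    except (TypeError, ValueError):
        raise SchemaError(f"key {key!r} must be numeric, got {raw[key]!r}") from None


def load_params(path) -> SpeciesParams:
    """Load and validate a species parameter file.

    The file is a flat YAML mapping using the standard parameter codes.
    Temperatures may be Celsius (default) or Fahrenheit (``units: F``);
    Fahrenheit thresholds are rounded to the nearest integer F before
    conversion and Fahrenheit degree-day values are scaled by 5/9.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"parameter file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise SchemaError(f"parameter file must be a flat key-value mapping: {path}")
    return params_from_dict(raw, default_name=path.stem)


def params_from_dict(raw: dict, default_name: str = "species") -> SpeciesParams:
    """Build :class:`SpeciesParams` from a flat mapping of parameter codes."""
    units = str(raw.get("units", "C")).upper()
    if units not in ("C", "F"):
        raise SchemaError(f"units must be 'C' or 'F', got {raw.get('units')!r}")
    temp = _fahrenheit_to_celsius_threshold if units == "F" else float
    dd_scale = 5.0 / 9.0 if units == "F" else 1.0

    ow_stage = None
    if "owstage" in raw:
        ow_stage = _OW_ALIASES.get(str(raw["owstage"]).lower())
        if ow_stage is None:
            raise SchemaError(f"owstage must be a life stage name, got {raw['owstage']!r}")
    else:
        # The overwintering stage may instead be flagged by which OW<stage>DD
        # code is present (its value is cohort-dependent and may be 'varies').
        for code, stage in _OW_DD_CODES.items():
            if code in raw:
                ow_stage = stage
                break
    if ow_stage is None:
        raise SchemaError("missing required key 'owstage' (or an OW<stage>DD code)")

    stage_ldt, stage_udt, stage_dd, event_dd = {}, {}, {}, {}
    for s, codes in _STAGE_CODES.items():
        stage_ldt[s] = temp(_coerce_float(raw, codes["ldt"]))
        stage_udt[s] = temp(_coerce_float(raw, codes["udt"]))
        stage_dd[s] = _coerce_float(raw, codes["dd"]) * dd_scale
        event_dd[s] = _coerce_float(raw, codes["event"]) * dd_scale

    scalars = {}
    for key in _SCALAR_CODES:
        v = _coerce_float(raw, key)
        if key.endswith("threshold"):
            scalars[key] = temp(v)
        else:
            scalars[key] = v * dd_scale

    return SpeciesParams(
        name=str(raw.get("name", default_name)),
        stage_ldt=stage_ldt, stage_udt=stage_udt,
        stage_dd=stage_dd, ow_stage=ow_stage, event_dd=event_dd,
        distro_shape=str(raw.get("distro_shape", "normal")).lower(),
        calctype=str(raw.get("calctype", "triangle")).lower(),
        max_event_generations=int(raw.get("max_event_generations", 4)),
        **scalars,
    )


def bundled_species_path(name: str) -> Path:
    """Path to a species parameter file shipped with the package.

    ``name`` is e.g. ``"epiphyas_postvittana"`` or ``"neoleucinodes_elegantalis"``.
    """
    ref = resources.files("phenorisk").joinpath("data", f"{name}.yaml")
    with resources.as_file(ref) as p:
        return Path(p)


def load_bundled_species(name: str) -> SpeciesParams:
    return load_params(bundled_species_path(name))


def _emergence_distribution(params: SpeciesParams):
    """Continuous emergence distribution implied by the distro parameters.

    For ``normal`` this is Normal(distro_mean, distro_var). For
    ``lognormal`` the variate is shifted by xdist1 and distro_mean /
    distro_var are the mean and variance of the (shifted) variate itself,
    converted internally to log-scale parameters.
    """
    if params.distro_shape == "normal":
        return stats.norm(loc=params.distro_mean, scale=math.sqrt(params.distro_var))
    m = params.distro_mean - params.xdist1
    if m <= 0:
        raise ParameterError(
            "lognormal emergence distribution requires distro_mean > xdist1")
    sigma2 = math.log1p(params.distro_var / (m * m))
    mu = math.log(m) - sigma2 / 2.0
    return stats.lognorm(s=math.sqrt(sigma2), loc=params.xdist1, scale=math.exp(mu))


def make_cohorts(params: SpeciesParams, n: int) -> CohortSet:
    """Discretize the overwintering emergence distribution into ``n`` cohorts.

    The range [xdist1, xdist2] is partitioned into ``n`` equal-width bins;
    each cohort's emergence requirement is the bin midpoint and its weight
    is the probability mass of the (truncated, renormalized) distribution
    within the bin. ``n=1`` returns one cohort at ``distro_mean``.
    """
    if n < 1:
        raise ParameterError("number of cohorts must be >= 1")
    if n == 1:
        return CohortSet(np.array([params.distro_mean]), np.array([1.0]))
    if params.distro_var == 0:
        raise ParameterError(
            "degenerate emergence distribution: distro_var = 0 supports only one cohort")
    if params.xdist2 <= params.xdist1:
        raise ParameterError("emergence bounds must satisfy xdist1 < xdist2")

    dist = _emergence_distribution(params)
    edges = np.linspace(params.xdist1, params.xdist2, n + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    cdf = dist.cdf(edges)
    mass = np.diff(cdf)
    total = cdf[-1] - cdf[0]
    if total <= 0 or np.any(mass <= 0):
        raise ParameterError(
            "emergence distribution has (near-)zero mass in some bin on "
            "[xdist1, xdist2]; widen the bounds or reduce the cohort count")
    return CohortSet(mids, mass / mass.sum())
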