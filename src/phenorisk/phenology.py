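"""Per-cohort daily time-step life-stage simulation and cross-cohort summaries.

The simulated insect passes through four stages in the cyclic order
egg -> larva -> pupa -> adult -> egg, entered via a separately
parameterized overwintering stage. Each cohort starts the run in the
overwintering stage with zero accumulated degree-days at a fixed start
date (such as January 1); the overwintering requirement is the cohort's
emergence degree-days. A full generation is counted at each oviposition,
i.e. whenever the active stage transitions into the egg stage.

Every day, the active stage's degree-days (computed with that stage's own
thresholds) are added to the within-stage accumulator. When the stage
requirement is reached the insect moves to the next stage, carrying the
excess degree-days into the new stage's accumulator; at most one
transition can occur per calendar day, since daily data cannot resolve
sub-day multi-stage progress. The first day on which the within-stage
accumulator reaches the stage's event threshold is recorded per
(generation, stage) for the first ``max_event_generations`` generations.
The overwintering event is emergence: it fires on the day the cohort
completes its overwintering requirement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .degree_days import daily_stage_dd
from .params import STAGES, CohortSet, SpeciesParams

#: Name of the overwintering pseudo-stage.
OVERWINTERING = "overwintering"

#: Integer codes used in stage maps (overwintering=0, egg=1, ... adult=4).
STAGE_INDEX = {OVERWINTERING: 0, "egg": 1, "larva": 2, "pupa": 3, "adult": 4}
ALL_STAGES = (OVERWINTERING,) + STAGES


def next_stage(stage: str, ow_stage: str) -> str:
    """Successor of ``stage`` in the life cycle.

    The overwintering stage behaves as its parameterized stage: an
    overwintering larva proceeds to pupa, an overwintering adult to egg.
    """
    effective = ow_stage if stage == OVERWINTERING else stage
    return STAGES[(STAGES.index(effective) + 1) % len(STAGES)]


def stage_cycle(params: SpeciesParams) -> list:
    """Ordered stage sequence for one full cycle, entered via overwintering.

    E.g. for an overwintering larva: ``[overwintering, pupa, adult, egg,
    larva]``; the generation count increments at the adult -> egg step.
    """
    seq = [OVERWINTERING]
    s = next_stage(OVERWINTERING, params.ow_stage)
    for _ in STAGES:
        seq.append(s)
        s = next_stage(s, params.ow_stage)
    return seq


@dataclass
class PhenoState:
    """Mutable per-cohort simulation state for one location."""

    stage: str = OVERWINTERING
    stage_dd: float = 0.0          #: degree-days accumulated within the active stage
    generation: int = 0            #: 0 = overwintering generation
    cum_dd: float = 0.0            #: season-total DD at the larval thresholds
    events: dict = field(default_factory=dict)  #: (generation, stage) -> day of year
    missing_days: int = 0

    def stage_code(self) -> int:
        """Integer map code: 10 * generation + stage index."""
        return 10 * self.generation + STAGE_INDEX[self.stage]


def _maybe_record_event(state: PhenoState, params: SpeciesParams,
                        cohort_ow_dd: float, day: int) -> None:
    if state.generation >= params.max_event_generations:
        return
    threshold = cohort_ow_dd if state.stage == OVERWINTERING else params.event_dd[state.stage]
    key = (state.generation, state.stage)
    if key not in state.events and state.stage_dd >= threshold:
        state.events[key] = day


def advance_day(state: PhenoState, daily_dd: dict, params: SpeciesParams,
                cohort_ow_dd: float, day: int) -> PhenoState:
    """Advance ``state`` by one day given per-stage degree-days.

    ``daily_dd`` maps each developmental stage to that day's degree-days
    at its thresholds (the overwintering stage uses its parameterized
    stage's entry). A non-finite value freezes the state for the day and
    counts it as missing. The state is updated in place and returned.
    """
    effective = params.ow_stage if state.stage == OVERWINTERING else state.stage
    dd = daily_dd[effective]
    if not np.isfinite(dd):
        state.missing_days += 1
        return state

    state.stage_dd += dd
    state.cum_dd += daily_dd["larva"]
    _maybe_record_event(state, params, cohort_ow_dd, day)

    required = cohort_ow_dd if state.stage == OVERWINTERING else params.stage_dd[state.stage]
    if state.stage_dd >= required:
        excess = state.stage_dd - required
        nxt = next_stage(state.stage, params.ow_stage)
        if nxt == "egg":
            state.generation += 1
        state.stage = nxt
        state.stage_dd = excess
        _maybe_record_event(state, params, cohort_ow_dd, day)
    return state


@dataclass
class CohortTrajectory:
    """Sampled daily states and final event table of one cohort."""

    days: np.ndarray               #: sampled days of year (strictly increasing)
    stages: list                   #: stage name at each sampled day
    generations: np.ndarray        #: generation count at each sampled day
    events: dict                   #: (generation, stage) -> day of year
    voltinism: int                 #: final generation counter
    cohort_ow_dd: float
    missing_days: int = 0
    cum_dd: np.ndarray | None = None  #: larval-threshold accumulated DD at sampled days

    def stage_codes(self) -> np.ndarray:
        g = np.asarray(self.generations)
        s = np.array([STAGE_INDEX[x] for x in self.stages])
        return 10 * g + s


def sample_days(n_days: int, sample_every: int, start_day: int = 1) -> np.ndarray:
    """Sampled days of year: start, start+k, ... plus always the final day."""
    offsets = list(range(0, n_days, sample_every))
    if offsets[-1] != n_days - 1:
        offsets.append(n_days - 1)
    return start_day + np.asarray(offsets)


def run_cohort(weather, params: SpeciesParams, cohort_ow_dd: float,
               sample_every: int = 1, start_day: int = 1,
               dates=None) -> CohortTrajectory:
    """Run the daily time step for one cohort over a weather sequence.

    ``weather`` is a sequence of (tmin, tmax) pairs in Celsius, one per
    consecutive day starting at day-of-year ``start_day``. If ``dates``
    (calendar dates) are given they must be consecutive. The event table
    is finalized only after the last day, since the whole period must be
    scanned for potential event days.
    """
    weather = list(weather)
    if not weather:
        raise ValueError("weather sequence must be non-empty")
    if dates is not None:
        dates = list(dates)
        if len(dates) != len(weather):
            raise ValueError("dates and weather lengths differ")
        deltas = {(b - a).days for a, b in zip(dates[:-1], dates[1:])}
        if deltas - {1}:
            raise ValueError("weather dates must be consecutive calendar days")
        start_day = dates[0].timetuple().tm_yday

    state = PhenoState()
    sdays = sample_days(len(weather), sample_every, start_day)
    sset = set(int(d) for d in sdays)
    stages, gens, cums = [], [], []
    for i, (tmin, tmax) in enumerate(weather):
        day = start_day + i
        dd = daily_stage_dd(tmin, tmax, params)
        advance_day(state, dd, params, cohort_ow_dd, day)
        if day in sset:
            stages.append(state.stage)
            gens.append(state.generation)
            cums.append(state.cum_dd)
    return CohortTrajectory(
        days=sdays, stages=stages, generations=np.asarray(gens, dtype=int),
        events=dict(state.events), voltinism=state.generation,
        cohort_ow_dd=cohort_ow_dd, missing_days=state.missing_days,
        cum_dd=np.asarray(cums),
    )


def voltinism(traj: CohortTrajectory) -> int:
    """Number of generations completed over the run (final generation count)."""
    return traj.voltinism


@dataclass
class PopulationSummary:
    """Cross-cohort population summary on a shared sampling grid."""

    days: np.ndarray
    #: (generation, stage) -> population fraction per sampled day
    fractions: dict
    #: (generation, stage) -> earliest event day of year across cohorts
    events_earliest: dict
    #: (generation, stage) -> average (cohort-weighted, rounded) event day
    events_average: dict
    #: stage codes of the middle cohort per sampled day
    middle_stage_codes: np.ndarray
    middle_voltinism: int


def combine_cohorts(trajectories, cohorts: CohortSet,
                    weighted: bool = True) -> PopulationSummary:
    """Combine per-cohort trajectories into a population summary.

    Per sampled day, the population fraction in each (generation, stage)
    is the sum of the weights of cohorts in that state. Per event, the
    earliest day is the minimum across cohorts that recorded it and the
    average day is the cohort-weighted mean over those cohorts (weights
    renormalized; unweighted mean if ``weighted`` is False), rounded to
    the nearest integer day. Stage maps are retained only for the middle
    cohort.
    """
    trajectories = list(trajectories)
    if len(trajectories) != cohorts.n:
        raise ValueError("one trajectory per cohort is required")
    days0 = trajectories[0].days
    for t in trajectories[1:]:
        if len(t.days) != len(days0) or np.any(t.days != days0):
            raise ValueError("all trajectories must share the same sampling grid")

    fractions: dict = {}
    for w, traj in zip(cohorts.weight, trajectories):
        for i in range(len(days0)):
            key = (int(traj.generations[i]), traj.stages[i])
            arr = fractions.setdefault(key, np.zeros(len(days0)))
            arr[i] += w

    keys = set()
    for t in trajectories:
        keys.update(t.events)
    earliest, average = {}, {}
    for key in keys:
        ds = np.array([t.events.get(key, np.nan) for t in trajectories], dtype=float)
        ws = np.where(np.isfinite(ds), cohorts.weight if weighted else 1.0, 0.0)
        earliest[key] = int(np.nanmin(ds))
        average[key] = int(round(float(np.nansum(ws * ds) / ws.sum())))

    mid = trajectories[cohorts.middle_index]
    return PopulationSummary(
        days=days0, fractions=fractions,
        events_earliest=earliest, events_average=average,
        middle_stage_codes=mid.stage_codes(), middle_voltinism=mid.voltinism,
    )
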