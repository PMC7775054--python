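import datetime as dt

import numpy as np
import pytest

import phenorisk as pr
from phenorisk.phenology import OVERWINTERING, PhenoState, sample_days


def constant_weather(temp, n_days):
    return [(float(temp), float(temp))] * n_days


class TestStageCycle:
    def test_overwintering_larva(self, epos):
        assert pr.stage_cycle(epos) == [OVERWINTERING, "pupa", "adult", "egg", "larva"]

    def test_overwintering_adult(self, nele):
        assert pr.stage_cycle(nele) == [OVERWINTERING, "egg", "larva", "pupa", "adult"]

    def test_overwintering_egg(self, epos):
        p = epos.with_updates(ow_stage="egg")
        assert pr.stage_cycle(p) == [OVERWINTERING, "larva", "pupa", "adult", "egg"]


class TestAdvanceDay:
    def hand_run(self, params, ow_dd, dd_per_day, n_days):
        state = PhenoState()
        dd = {s: dd_per_day for s in ("egg", "larva", "pupa", "adult")}
        log = []
        for day in range(1, n_days + 1):
            pr.advance_day(state, dd, params, ow_dd, day)
            log.append((day, state.stage, state.generation, state.stage_dd))
        return state, log

    def test_apple_moth_middle_cohort_timeline(self, epos):
        """10 DDC/day: OW done day 21, pupa day 34 (2 DDC carry), adult day 41."""
        state, log = self.hand_run(epos, 210.0, 10.0, 60)
        by_day = {d: (s, g, a) for d, s, g, a in log}
        assert by_day[21][0] == "pupa"          # OW larva -> pupa at 210 DDC
        assert by_day[20][0] == OVERWINTERING
        assert by_day[34] == ("adult", 0, 2.0)  # 130 >= 128, 2 DDC carried
        assert by_day[41][0] == "egg"
        assert by_day[41][1] == 1               # oviposition increments generation
        assert state.events[(1, "egg")] == 54   # 1 + 10*(54-41) >= 126
        assert state.events[(0, OVERWINTERING)] == 21

    def test_zero_dd_is_identity(self, epos):
        state = PhenoState(stage="larva", stage_dd=50.0, generation=1)
        dd = {s: 0.0 for s in ("egg", "larva", "pupa", "adult")}
        pr.advance_day(state, dd, epos, 210.0, 5)
        assert (state.stage, state.stage_dd, state.generation) == ("larva", 50.0, 1)
        assert state.events == {}

    def test_missing_day_freezes_state(self, epos):
        state = PhenoState(stage="larva", stage_dd=50.0)
        dd = {s: np.nan for s in ("egg", "larva", "pupa", "adult")}
        pr.advance_day(state, dd, epos, 210.0, 5)
        assert state.stage_dd == 50.0
        assert state.missing_days == 1


class TestRunCohort:
    def test_voltinism_at_constant_17_2(self, epos):
        traj = pr.run_cohort(constant_weather(17.2, 365), epos, 210.0)
        assert pr.voltinism(traj) == 5

    def test_no_development_at_lower_threshold(self, epos):
        traj = pr.run_cohort(constant_weather(7.2, 365), epos, 210.0)
        assert pr.voltinism(traj) == 0
        assert traj.stages[-1] == OVERWINTERING

    def test_tomato_borer_overwintering_adult(self, nele):
        """Constant 30 C is 21.11 DDC/day; the 50-DDC requirement ends day 3."""
        traj = pr.run_cohort(constant_weather(30.0, 20), nele, 50.0)
        assert traj.events[(0, OVERWINTERING)] == 3
        assert traj.stages[2] == "egg"     # day 3: OW adult -> egg
        assert traj.generations[2] == 1

    @pytest.mark.parametrize("temp", [10.0, 12.5, 15.0, 17.2, 20.0, 22.5, 25.0, 28.0])
    def test_constant_temperature_closed_form(self, epos, temp):
        """Voltinism = 1 + floor((365 d - D_first)/G) for daily DD d.

        D_first = 210 + 128 + 71 DDC to first oviposition for the middle
        cohort; G = 734 DDC per full generation.
        """
        d = temp - 7.2
        d_first = 210.0 + epos.stage_dd["pupa"] + epos.stage_dd["adult"]
        g_dd = sum(epos.stage_dd.values())
        expected = int(max(0, 1 + np.floor((365 * d - d_first) / g_dd))) \
            if 365 * d >= d_first else 0
        traj = pr.run_cohort(constant_weather(temp, 365), epos, 210.0)
        assert pr.voltinism(traj) == expected

    def test_event_days_nondecreasing_in_generation(self, epos):
        traj = pr.run_cohort(constant_weather(20.0, 365), epos, 210.0)
        for stage in ("egg", "larva", "pupa", "adult"):
            days = [traj.events[(g, stage)] for g in range(4)
                    if (g, stage) in traj.events]
            assert days == sorted(days)

    def test_later_cohorts_have_later_events(self, epos):
        cube = constant_weather(17.2, 365)
        t1 = pr.run_cohort(cube, epos, 115.7)
        t2 = pr.run_cohort(cube, epos, 304.3)
        shared = set(t1.events) & set(t2.events)
        assert shared
        assert all(t2.events[k] >= t1.events[k] for k in shared)

    def test_nonconsecutive_dates_rejected(self, epos):
        dates = [dt.date(2018, 1, 1), dt.date(2018, 1, 3)]
        with pytest.raises(ValueError, match="consecutive"):
            pr.run_cohort(constant_weather(15, 2), epos, 210.0, dates=dates)

    def test_sampling_grid_includes_final_day(self):
        assert sample_days(365, 30).tolist() == [1 + 30 * k for k in range(13)] + [365]
        assert sample_days(10, 1).tolist() == list(range(1, 11))


class TestCombineCohorts:
    def run_all(self, epos, n=7, temp=17.2):
        cs = pr.make_cohorts(epos, n)
        trajs = [pr.run_cohort(constant_weather(temp, 365), epos, e, sample_every=7)
                 for e in cs.emergence_dd]
        return cs, trajs

    def test_identical_trajectories_degenerate(self, epos):
        cs = pr.make_cohorts(epos, 3)
        traj = pr.run_cohort(constant_weather(17.2, 365), epos, 210.0)
        summary = pr.combine_cohorts([traj] * 3, cs)
        for key, frac in summary.fractions.items():
            assert set(np.unique(frac)) <= {0.0, 1.0}
        for key in summary.events_earliest:
            assert summary.events_earliest[key] == summary.events_average[key]

    def test_fractions_sum_to_one_each_day(self, epos):
        cs, trajs = self.run_all(epos)
        summary = pr.combine_cohorts(trajs, cs)
        total = sum(summary.fractions.values())
        np.testing.assert_allclose(total, 1.0, atol=1e-9)

    def test_earliest_leads_average(self, epos):
        cs, trajs = self.run_all(epos)
        summary = pr.combine_cohorts(trajs, cs)
        key = (1, "egg")
        assert summary.events_earliest[key] < summary.events_average[key]
        for k in summary.events_earliest:
            assert summary.events_earliest[k] <= summary.events_average[k]

    def test_two_cohort_average_arithmetic(self, epos):
        days = np.array([1, 2])
        mk = lambda event_day: pr.CohortTrajectory(
            days=days, stages=["egg", "egg"], generations=np.array([1, 1]),
            events={(1, "egg"): event_day}, voltinism=1, cohort_ow_dd=0.0)
        cs = pr.CohortSet(np.array([100.0, 200.0]), np.array([0.5, 0.5]))
        summary = pr.combine_cohorts([mk(100), mk(110)], cs)
        assert summary.events_earliest[(1, "egg")] == 100
        assert summary.events_average[(1, "egg")] == 105

    def test_middle_cohort_is_retained(self, epos):
        cs, trajs = self.run_all(epos)
        summary = pr.combine_cohorts(trajs, cs)
        np.testing.assert_array_equal(summary.middle_stage_codes,
                                      trajs[3].stage_codes())
        assert summary.middle_voltinism == trajs[3].voltinism

    def test_mismatched_sampling_rejected(self, epos):
        cs = pr.make_cohorts(epos, 2)
        t1 = pr.run_cohort(constant_weather(17.2, 365), epos, 150.0, sample_every=7)
        t2 = pr.run_cohort(constant_weather(17.2, 365), epos, 250.0, sample_every=14)
        with pytest.raises(ValueError, match="sampling"):
            pr.combine_cohorts([t1, t2], cs)
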