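"""Cost schedule, per-catheter formulas, and trajectory accrual.

The accrual engine is checked against an independent brute-force ledger:
for each subject, walk the fourteen calendar days one by one, look up which
state occupies each day, and sum unit costs from the schedule directly.
"""

import math

import pytest

from pvcea import (
    BASE,
    SCENARIO_1,
    SCENARIO_2,
    Arm,
    CostSchedule,
    HealthState,
    TransitionalEvent,
    arm_mean_cost,
    cohort_cost_table,
    event_cost,
    per_patient,
    second_catheter_days,
    state_day_cost,
    terminal_removal_cost,
    trajectory_cost,
)

from conftest import make_trajectory

S = HealthState
E = TransitionalEvent


# ---------------------------------------------------------------------------
# independent ledger oracle
# ---------------------------------------------------------------------------


def ledger_oracle(traj, sched, include_complications=True):
    """Day-by-day enumeration of one subject's per-catheter cost."""
    arm = traj.arm.value
    total = 0.0
    # first-catheter days: walk days 1..14, charge if S1 occupies any part
    s1 = traj.segments[0]
    for day in range(1, int(sched.horizon) + 1):
        lo, hi = day - 1.0, float(day)
        if s1.entry < hi and s1.exit > lo:
            total += sched.daily_use[arm]
            if day == 1:
                total += sched.placement_initial[arm]
    ev = traj.first_catheter_event
    if ev is not None:
        total += sched.removal[arm]
        if ev.is_unscheduled_complication and include_complications:
            total += sched.treatment[ev.value] + sched.placement_second[arm]
    # second catheter: fractional days of the S3 episode
    for seg in traj.segments:
        if seg.state is S.S3_NOEVENT_PVC2:
            total += sched.daily_use[arm] * (seg.exit - seg.entry)
    if traj.terminal in ("discharged", "dead"):
        pre_absorb = traj.segments[-2].state if len(traj.segments) > 1 else None
        if pre_absorb in (S.S1_NOEVENT_PVC1, S.S3_NOEVENT_PVC2):
            total += sched.removal[arm]
    return total


# ---------------------------------------------------------------------------
# unit-cost formulas (published cost tables)
# ---------------------------------------------------------------------------


class TestUnitCosts:
    @pytest.mark.parametrize(
        "state,day,arm,expected",
        [
            (S.S1_NOEVENT_PVC1, 1, Arm.BDS, 23.01),  # 9.74 + 13.27
            (S.S1_NOEVENT_PVC1, 1, Arm.SDS, 20.51),  # 8.20 + 12.31
            (S.S1_NOEVENT_PVC1, 2, Arm.SDS, 12.31),
            (S.S2_NOEVENT_NOPVC, 1, Arm.SDS, 0.0),
            (S.S2_NOEVENT_NOPVC, 5, Arm.BDS, 0.0),
            (S.S3_NOEVENT_PVC2, 3, Arm.BDS, 13.27),
            (S.S4_DISCHARGE, 2, Arm.SDS, 0.0),
            (S.S5_DEATH, 2, Arm.BDS, 0.0),
        ],
    )
    def test_state_day_cost(self, schedule, state, day, arm, expected):
        assert state_day_cost(state, day, arm, schedule) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "event,arm,expected",
        [
            (E.E4_DISLODGEMENT, Arm.BDS, 17.73),  # 2.26 + 5.49 + 9.98
            (E.E5_PHLEBITIS, Arm.BDS, 24.51),
            (E.E6_DIFFUSION, Arm.BDS, 16.33),
            (E.E7_LOCAL_INFECTION, Arm.BDS, 24.51),
            (E.E8_OCCLUSION, Arm.BDS, 15.91),
            (E.E1_SCHEDULED_REMOVAL, Arm.SDS, 2.32),
            (E.E2_USELESS, Arm.BDS, 2.26),
        ],
    )
    def test_event_cost(self, schedule, event, arm, expected):
        assert event_cost(event, arm, schedule) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize(
        "event,published_sds",
        [
            (E.E4_DISLODGEMENT, 16.25),
            (E.E5_PHLEBITIS, 23.03),
            (E.E6_DIFFUSION, 14.85),
            (E.E7_LOCAL_INFECTION, 23.03),
            (E.E8_OCCLUSION, 14.43),
        ],
    )
    def test_event_cost_component_sum_near_published_sds(
        self, schedule, event, published_sds
    ):
        """The published standard-arm cells carry a 1-cent rounding drift;
        the component sum is canonical."""
        assert event_cost(event, Arm.SDS, schedule) == pytest.approx(
            published_sds, abs=0.011
        )

    def test_event_additive_identity(self, schedule):
        for arm in Arm:
            a = arm.value
            for ev in E:
                if ev.is_unscheduled_complication:
                    assert event_cost(ev, arm, schedule) == pytest.approx(
                        schedule.removal[a]
                        + schedule.treatment[ev.value]
                        + schedule.placement_second[a]
                    )

    @pytest.mark.parametrize(
        "args,expected", [((14, 14), 0.0), ((5, 14), 9.0), ((2.5, 14), 11.5)]
    )
    def test_second_catheter_days(self, args, expected):
        assert second_catheter_days(*args) == expected

    def test_second_catheter_days_rejects_late_placement(self):
        with pytest.raises(ValueError):
            second_catheter_days(15.0, 14.0)

    @pytest.mark.parametrize(
        "cost,arm,expected",
        [
            (16.25, Arm.SDS, 24.38),
            (17.73, Arm.BDS, 23.05),
            (20.51, Arm.SDS, 30.76),
            (23.01, Arm.BDS, 29.91),
            (0.0, Arm.SDS, 0.0),
            (0.0, Arm.BDS, 0.0),
        ],
    )
    def test_per_patient_scaling(self, schedule, cost, arm, expected):
        assert per_patient(cost, arm, schedule) == expected

    @pytest.mark.parametrize(
        "event,t_end,terminal,arm,expected",
        [
            (E.E4_DISLODGEMENT, 9.0, "discharged", Arm.SDS, 2.32),  # from S3
            (E.E1_SCHEDULED_REMOVAL, 9.0, "discharged", Arm.SDS, 0.0),  # from S2
            (E.E5_PHLEBITIS, 9.0, "dead", Arm.BDS, 2.26),
            (E.E4_DISLODGEMENT, None, "censored", Arm.SDS, 0.0),
        ],
    )
    def test_terminal_removal(self, schedule, event, t_end, terminal, arm, expected):
        traj = make_trajectory(arm=arm, t1=2.0, event=event, t_end=t_end, terminal=terminal)
        assert terminal_removal_cost(traj, arm, schedule) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# trajectory accrual
# ---------------------------------------------------------------------------


class TestTrajectoryCost:
    def test_matches_ledger_oracle_exactly(self, default_cohort, schedule):
        for traj in default_cohort:
            bd = trajectory_cost(traj, schedule, BASE)
            assert bd.total == pytest.approx(ledger_oracle(traj, schedule), abs=1e-9), (
                traj.subject_id
            )

    def test_hand_trajectory_ledger(self, schedule):
        # bundled arm: S1 through day 2, dislodgement, S3 until discharge day 14
        traj = make_trajectory(
            arm=Arm.BDS, t1=2.0, event=E.E4_DISLODGEMENT, t_end=14.0 - 1e-9
        )
        bd = trajectory_cost(traj, schedule, BASE)
        expected = (
            9.74 + 2 * 13.27          # placement + two started S1 days
            + 2.26 + 5.49 + 9.98       # removal + treatment + 2nd placement
            + 13.27 * (12.0 - 1e-9)    # second catheter, fractional days
            + 2.26                     # removal before discharge
        )
        assert bd.total == pytest.approx(expected, abs=1e-6)

    def test_no_complication_scenario_removes_exactly_complication_costs(
        self, schedule
    ):
        traj = make_trajectory(arm=Arm.BDS, t1=2.0, event=E.E4_DISLODGEMENT, t_end=9.0)
        base = trajectory_cost(traj, schedule, BASE).total
        s2 = trajectory_cost(traj, schedule, SCENARIO_2).total
        assert base - s2 == pytest.approx(5.49 + 9.98)

    def test_no_complication_scenario_equality_iff_uncomplicated(
        self, default_cohort, schedule
    ):
        for traj in default_cohort[::7]:
            base = trajectory_cost(traj, schedule, BASE).total
            s2 = trajectory_cost(traj, schedule, SCENARIO_2).total
            assert s2 <= base + 1e-12
            if traj.had_unscheduled_removal:
                assert s2 < base
            else:
                assert s2 == pytest.approx(base)

    def test_window_extension_never_decreases_total(self, default_cohort, schedule):
        windows = [(0.0, 3.0), (0.0, 7.0), (0.0, 14.0)]
        for traj in default_cohort[::13]:
            totals = [
                trajectory_cost(traj, schedule, BASE, window=w).total for w in windows
            ]
            assert totals == sorted(totals)

    def test_empty_window_zeroes_everything(self, schedule):
        traj = make_trajectory(arm=Arm.SDS, t1=2.0, event=E.E5_PHLEBITIS, t_end=9.0)
        bd = trajectory_cost(traj, schedule, BASE, window=(2.0, 2.0))
        assert bd.total == 0.0
        assert (bd.placement, bd.daily_use, bd.removal, bd.treatment, bd.second_catheter) == (
            0.0,
        ) * 5

    def test_breakdown_total_is_component_sum(self, default_cohort, schedule):
        for traj in default_cohort[:50]:
            bd = trajectory_cost(traj, schedule)
            assert bd.total == pytest.approx(
                bd.placement + bd.daily_use + bd.removal + bd.treatment + bd.second_catheter,
                abs=1e-9,
            )


class TestArmMeans:
    def test_mean_of_one(self, schedule):
        traj = make_trajectory(arm=Arm.SDS, t1=2.0, event=E.E1_SCHEDULED_REMOVAL, t_end=5.0)
        expected = per_patient(
            trajectory_cost(traj, schedule).total, Arm.SDS, schedule
        )
        assert arm_mean_cost([traj], Arm.SDS, schedule) == expected

    def test_mean_of_two(self, schedule):
        a = make_trajectory("A", Arm.SDS, t1=1.0, event=E.E1_SCHEDULED_REMOVAL, t_end=5.0)
        b = make_trajectory("B", Arm.SDS, t1=3.0, event=E.E5_PHLEBITIS, t_end=9.0)
        totals = [
            per_patient(trajectory_cost(t, schedule).total, Arm.SDS, schedule)
            for t in (a, b)
        ]
        assert arm_mean_cost([a, b], Arm.SDS, schedule) == pytest.approx(
            sum(totals) / 2
        )

    def test_empty_arm_errors(self, schedule):
        with pytest.raises(ValueError):
            arm_mean_cost([], Arm.SDS, schedule)

    def test_scenario1_keeps_short_complicated_catheters(self, schedule):
        short_complicated = make_trajectory(
            "A", Arm.SDS, t1=0.5, event=E.E4_DISLODGEMENT, t_end=9.0
        )
        short_plain = make_trajectory("B", Arm.SDS, t1=0.5, event=E.E1_SCHEDULED_REMOVAL, t_end=9.0)
        long_plain = make_trajectory("C", Arm.SDS, t1=2.0, event=E.E1_SCHEDULED_REMOVAL, t_end=9.0)
        table = cohort_cost_table(
            [short_complicated, short_plain, long_plain], schedule, SCENARIO_1
        )
        assert sorted(table["subject_id"]) == ["A", "C"]

    def test_schedule_yaml_round_trip(self, schedule, tmp_path):
        path = tmp_path / "costs.yaml"
        schedule.to_file(path)
        assert CostSchedule.from_file(path) == schedule
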