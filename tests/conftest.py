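import pytest

from pvcea import (
    Arm,
    CohortConfig,
    CostSchedule,
    HealthState,
    PatientTrajectory,
    Segment,
    TransitionalEvent,
    generate_cohort,
)

S = HealthState
E = TransitionalEvent


@pytest.fixture(scope="session")
def schedule():
    return CostSchedule.default()


@pytest.fixture(scope="session")
def default_cohort():
    """One trial-sized cohort (495 + 494 subjects) under default conditions."""
    return generate_cohort(CohortConfig(seed=0))


@pytest.fixture(scope="session")
def big_cohort():
    """10,000 subjects per arm, for checks where trial-size noise dominates."""
    return generate_cohort(
        CohortConfig(n_per_arm={"SDS": 10_000, "BDS": 10_000}, seed=7)
    )


def make_trajectory(
    sid="T-1",
    arm=Arm.SDS,
    t1=2.0,
    event=None,
    t_end=None,
    terminal=None,
    horizon=14.0,
):
    """Hand-build a valid trajectory.

    ``event=None`` means censored in state 1; otherwise the subject moves to
    S2 (E1-E3) or S3 (E4-E8) at ``t1`` and, if ``t_end`` is given, is
    absorbed there (``terminal`` "discharged"/"dead", default discharged).
    """
    if event is None:
        return PatientTrajectory(
            sid, arm, (Segment(S.S1_NOEVENT_PVC1, 0.0, horizon),),
            None, None, None, "censored",
        )
    unscheduled = event.is_unscheduled_complication
    mid = S.S3_NOEVENT_PVC2 if unscheduled else S.S2_NOEVENT_NOPVC
    segs = [Segment(S.S1_NOEVENT_PVC1, 0.0, t1)]
    if t_end is None:
        segs.append(Segment(mid, t1, horizon))
        term = "censored"
    else:
        term = terminal or "discharged"
        absorbing = S.S5_DEATH if term == "dead" else S.S4_DISCHARGE
        segs.append(Segment(mid, t1, t_end))
        segs.append(Segment(absorbing, t_end, horizon))
    return PatientTrajectory(
        sid, arm, tuple(segs), event, t1,
        t1 if unscheduled else None, term,
    )
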