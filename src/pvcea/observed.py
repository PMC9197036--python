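"""Observed-prevalence side of the multi-state analysis.

The analysis deliberately reports *observed* state occupancy (the analogue of
a prevalence table of observed numbers and percentages at a set of times),
not occupancy derived from an estimated transition-intensity matrix.  This
module computes occupancy tables on a time grid, per-arm mean sojourn times,
the pooled transient-state sojourn used as the reporting cycle length, and
observed transition counts.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from typing import Sequence

import pandas as pd

from .cohort import PatientTrajectory
from .states import Arm, HealthState, LEGAL_TRANSITIONS

__all__ = [
    "OccupancyTable",
    "SojournSummary",
    "occupancy_table",
    "mean_sojourn",
    "markov_cycle_length",
    "transition_counts",
]

TRANSIENT_STATES = (
    HealthState.S1_NOEVENT_PVC1,
    HealthState.S2_NOEVENT_NOPVC,
    HealthState.S3_NOEVENT_PVC2,
)


@dataclasses.dataclass(frozen=True)
class OccupancyTable:
    """Fractions of subjects in each state at each grid time, per arm."""

    times: tuple[float, ...]
    fractions: pd.DataFrame  # index (arm, time_days), columns state codes
    n_subjects: dict[str, int]

    def fraction(self, arm: Arm, state: HealthState, time: float) -> float:
        return float(self.fractions.loc[(arm.value, time), state.value])

    def to_tidy(self) -> pd.DataFrame:
        """Tidy export: columns arm, state, time_days, fraction, n."""
        long = (
            self.fractions.stack()
            .rename("fraction")
            .reset_index()
            .rename(columns={"level_2": "state"})
        )
        long["n"] = long["arm"].map(self.n_subjects)
        return long[["arm", "state", "time_days", "fraction", "n"]]


@dataclasses.dataclass(frozen=True)
class SojournSummary:
    """Mean sojourn (days) and contributing-subject count per arm and state."""

    table: pd.DataFrame  # index (arm, state), columns mean_days, n

    def mean(self, arm: Arm, state: HealthState) -> float:
        return float(self.table.loc[(arm.value, state.value), "mean_days"])


def _split_arms(cohort: Sequence[PatientTrajectory]) -> dict[Arm, list[PatientTrajectory]]:
    arms: dict[Arm, list[PatientTrajectory]] = {a: [] for a in Arm}
    for traj in cohort:
        arms[traj.arm].append(traj)
    return arms


def occupancy_table(
    cohort: Sequence[PatientTrajectory],
    times: Sequence[float],
    horizon: float = 14.0,
) -> OccupancyTable:
    """Observed state-occupancy fractions at each time, per arm.

    Occupancy at an entry instant follows the half-open convention: the
    subject is in the *new* state at its entry time.  Censored subjects count
    in their last observed state up to the censoring time.
    """
    if not cohort:
        raise ValueError("occupancy_table requires a non-empty cohort")
    times = [float(t) for t in times]
    if any(t < 0 or t > horizon for t in times):
        raise ValueError(f"occupancy times must lie in [0, {horizon}]")
    arms = _split_arms(cohort)
    rows = []
    index = []
    for arm, trajs in arms.items():
        if not trajs:
            continue
        for t in times:
            counts = Counter(traj.state_at(t) for traj in trajs)
            rows.append({s.value: counts.get(s, 0) / len(trajs) for s in HealthState})
            index.append((arm.value, t))
    frame = pd.DataFrame(
        rows, index=pd.MultiIndex.from_tuples(index, names=["arm", "time_days"])
    )
    return OccupancyTable(
        times=tuple(times),
        fractions=frame,
        n_subjects={a.value: len(trajs) for a, trajs in arms.items() if trajs},
    )


def mean_sojourn(
    cohort: Sequence[PatientTrajectory],
    state: HealthState,
    arm: Arm | None = None,
    unscheduled_only: bool = False,
) -> float:
    """Arithmetic mean of (possibly censored-at-horizon) sojourns in a state.

    ``unscheduled_only`` restricts to subjects with an unscheduled removal,
    the subgroup whose first-catheter durations the published adjustment
    coefficient is built from.
    """
    durations = []
    for traj in cohort:
        if arm is not None and traj.arm is not arm:
            continue
        if unscheduled_only and not traj.had_unscheduled_removal:
            continue
        d = traj.sojourn(state)
        if d is not None:
            durations.append(d)
    if not durations:
        raise ValueError(
            f"state {state.value} never visited in the selected subjects "
            "(no visits, as opposed to zero total duration)"
        )
    return sum(durations) / len(durations)


def markov_cycle_length(cohort: Sequence[PatientTrajectory]) -> float:
    """Pooled mean transient-state sojourn, used as the reporting grid step."""
    if not cohort:
        raise ValueError("markov_cycle_length requires a non-empty cohort")
    durations = [
        seg.exit - seg.entry
        for traj in cohort
        for seg in traj.segments
        if seg.state in TRANSIENT_STATES
    ]
    return sum(durations) / len(durations)


def sojourn_summary(cohort: Sequence[PatientTrajectory]) -> SojournSummary:
    rows = {}
    for arm in Arm:
        for state in TRANSIENT_STATES:
            durs = [
                traj.sojourn(state)
                for traj in cohort
                if traj.arm is arm and traj.sojourn(state) is not None
            ]
            if durs:
                rows[(arm.value, state.value)] = {
                    "mean_days": sum(durs) / len(durs),
                    "n": len(durs),
                }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index = pd.MultiIndex.from_tuples(table.index, names=["arm", "state"])
    return SojournSummary(table=table)


def transition_counts(cohort: Sequence[PatientTrajectory]) -> pd.DataFrame:
    """Observed transition counts per arm (rows from-state, columns to-state).

    Absorbing rows are structurally zero; an illegal move raises an integrity
    error naming the subject.
    """
    states = [s.value for s in HealthState]
    frames = {}
    for arm in Arm:
        frames[arm.value] = pd.DataFrame(0, index=states, columns=states)
    for traj in cohort:
        for prev, nxt in zip(traj.segments, traj.segments[1:]):
            if nxt.state not in LEGAL_TRANSITIONS[prev.state]:
                raise ValueError(
                    f"illegal transition {prev.state.value}->{nxt.state.value} "
                    f"for subject {traj.subject_id}"
                )
            frames[traj.arm.value].loc[prev.state.value, nxt.state.value] += 1
    out = pd.concat(frames, names=["arm", "from_state"])
    return out
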