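"""Cost schedule and trajectory-level cost accrual.

Unit costs (Euro 2022, per patient-catheter) follow the hospital's published
schedule: initial placement, removal/replacement, second-catheter placement,
per-24 h daily use, and a fixed treatment cost per complication type.  The
antiseptic component is already folded into these unit costs as the trial's
patient-weighted average, so no chlorhexidine/povidone-iodine split exists.

Accrual rules:

* State 1 (first catheter): day 1 costs placement + one daily use; every
  further *started* day of catheter presence costs one daily use.
* Routine removals (E1-E3) cost the removal only; complications (E4-E8) cost
  removal + complication treatment + second-catheter placement.
* State 2 (no catheter) is free; state 3 (second catheter) accrues daily use
  over the fractional duration of the second-catheter episode.  When the
  second catheter's removal date is unknown (subject still in state 3 at the
  horizon) the episode runs to the horizon, i.e. its duration is
  horizon - placement day.
* Discharge or death with a catheter in place costs one removal; subjects
  censored at the horizon are still hospitalised, so no terminal removal is
  observed or charged.

Per-catheter costs scale to per-patient costs through the arm's mean
catheters-per-patient coefficient (1.5 standard, 1.3 bundled), rounded to
cents half-even at reporting; internal arithmetic keeps full precision.
"""

from __future__ import annotations

import dataclasses
import json
import math
from decimal import ROUND_HALF_EVEN, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .cohort import PatientTrajectory
from .states import Arm, HealthState, TransitionalEvent, UNSCHEDULED_EVENTS

__all__ = [
    "CostSchedule",
    "Scenario",
    "BASE",
    "SCENARIO_1",
    "SCENARIO_2",
    "CostBreakdown",
    "state_day_cost",
    "event_cost",
    "second_catheter_days",
    "terminal_removal_cost",
    "per_patient",
    "trajectory_cost",
    "cohort_cost_table",
    "arm_mean_cost",
]


_DEFAULT_SCHEDULE = {
    "placement_initial": {"SDS": 8.20, "BDS": 9.74},
    "removal": {"SDS": 2.32, "BDS": 2.26},
    "placement_second": {"SDS": 8.45, "BDS": 9.98},
    "daily_use": {"SDS": 12.31, "BDS": 13.27},
    "treatment": {
        "E4": 5.49,   # dislodgement
        "E5": 12.27,  # phlebitis
        "E6": 4.09,   # diffusion
        "E7": 12.27,  # local infection
        "E8": 3.67,   # occlusion
    },
    "catheters_per_patient": {"SDS": 1.5, "BDS": 1.3},
    "horizon": 14.0,
}


@dataclasses.dataclass(frozen=True)
class CostSchedule:
    """Unit costs (EUR) per arm plus the catheters-per-patient coefficients."""

    placement_initial: dict
    removal: dict
    placement_second: dict
    daily_use: dict
    treatment: dict  # per complication event code E4..E8
    catheters_per_patient: dict
    horizon: float = 14.0

    @classmethod
    def default(cls) -> "CostSchedule":
        return cls(**{k: (dict(v) if isinstance(v, dict) else v) for k, v in _DEFAULT_SCHEDULE.items()})

    def validate(self) -> None:
        for field in ("placement_initial", "removal", "placement_second", "daily_use"):
            for arm in Arm:
                if getattr(self, field)[arm.value] < 0:
                    raise ValueError(f"{field}[{arm.value}] must be >= 0")
        for code in ("E4", "E5", "E6", "E7", "E8"):
            if self.treatment[code] < 0:
                raise ValueError(f"treatment[{code}] must be >= 0")
        for arm in Arm:
            if self.catheters_per_patient[arm.value] < 1:
                raise ValueError(f"catheters_per_patient[{arm.value}] must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CostSchedule":
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "CostSchedule":
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yaml", ".yml")) else json.loads(text)
        sched = cls.from_dict(data)
        sched.validate()
        return sched

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


@dataclasses.dataclass(frozen=True)
class Scenario:
    """Analysis scenario: subject-inclusion rule and cost-component switches.

    * ``BASE``: 0-14 day horizon, every subject, all cost components.
    * ``SCENARIO_1``: restrict to subjects whose first catheter lasted more
      than 24 h, or at most 24 h but with a studied complication (the 2-14
      PVC-day observation window acts as this inclusion rule).
    * ``SCENARIO_2``: every subject, but complication-specific costs
      (treatment + second-catheter placement) are excluded.
    """

    label: str
    min_uncomplicated_duration: float = 0.0  # days; inclusion carve-out below
    include_complication_costs: bool = True

    def includes(self, trajectory: PatientTrajectory) -> bool:
        if self.min_uncomplicated_duration <= 0:
            return True
        s1 = trajectory.segments[0]
        duration = s1.exit - s1.entry
        return (
            duration > self.min_uncomplicated_duration
            or trajectory.had_unscheduled_removal
        )


BASE = Scenario("base")
SCENARIO_1 = Scenario("s1", min_uncomplicated_duration=1.0)
SCENARIO_2 = Scenario("s2", include_complication_costs=False)

SCENARIOS = {"base": BASE, "s1": SCENARIO_1, "s2": SCENARIO_2}


@dataclasses.dataclass(frozen=True)
class CostBreakdown:
    """Per-subject cost components (EUR, per catheter unless scaled)."""

    subject_id: str
    arm: Arm
    placement: float
    daily_use: float
    removal: float
    treatment: float
    second_catheter: float

    @property
    def total(self) -> float:
        return (
            self.placement
            + self.daily_use
            + self.removal
            + self.treatment
            + self.second_catheter
        )


# ---------------------------------------------------------------------------
# unit-cost operations
# ---------------------------------------------------------------------------


def state_day_cost(
    state: HealthState, day_index: int, arm: Arm, schedule: CostSchedule
) -> float:
    """Cost of one started day in a state (per catheter).

    Day 1 in state 1 is placement + one daily use; later state-1 days and
    state-3 days are one daily use; state 2 and the absorbing states are free
    (the terminal removal is handled separately).
    """
    if day_index < 1:
        raise ValueError("day_index is 1-based")
    a = arm.value
    if state is HealthState.S1_NOEVENT_PVC1:
        extra = schedule.placement_initial[a] if day_index == 1 else 0.0
        return extra + schedule.daily_use[a]
    if state is HealthState.S3_NOEVENT_PVC2:
        return schedule.daily_use[a]
    return 0.0


def event_cost(
    event: TransitionalEvent, arm: Arm, schedule: CostSchedule
) -> float:
    """Cost attached to a first-catheter transitional event (per catheter)."""
    if not isinstance(event, TransitionalEvent):
        raise ValueError(f"unknown event {event!r}")
    a = arm.value
    if event.is_unscheduled_complication:
        return (
            schedule.removal[a]
            + schedule.treatment[event.value]
            + schedule.placement_second[a]
        )
    return schedule.removal[a]


def second_catheter_days(placement_day: float, horizon: float = 14.0) -> float:
    """Assumed second-catheter duration when its removal date is unknown:
    the difference between the censored horizon and the placement day."""
    if placement_day < 0 or placement_day > horizon:
        raise ValueError(
            f"placement_day must lie in [0, {horizon}], got {placement_day}"
        )
    return horizon - placement_day


def terminal_removal_cost(
    trajectory: PatientTrajectory, arm: Arm, schedule: CostSchedule
) -> float:
    """Removal cost at discharge/death if a catheter is then in place."""
    if trajectory.terminal == "censored":
        return 0.0
    # state occupied immediately before absorption
    for prev, nxt in zip(trajectory.segments, trajectory.segments[1:]):
        if nxt.state.is_absorbing:
            return schedule.removal[arm.value] if prev.state.has_catheter else 0.0
    # absorbed without a recorded preceding segment cannot occur for a valid
    # trajectory (it starts transient); treat defensively as no catheter
    return 0.0


def per_patient(per_catheter_cost: float, arm: Arm, schedule: CostSchedule) -> float:
    """Scale a per-catheter cost by the arm's catheters-per-patient
    coefficient and round to cents (half-even)."""
    if per_catheter_cost < 0:
        raise ValueError("per-catheter cost must be >= 0")
    scaled = per_catheter_cost * schedule.catheters_per_patient[arm.value]
    return float(
        Decimal(repr(scaled)).quantize(Decimal("0.01"), rounding=ROUND_HALF_EVEN)
    )


# ---------------------------------------------------------------------------
# trajectory accrual
# ---------------------------------------------------------------------------


def _started_days(start: float, stop: float, window: tuple[float, float]) -> int:
    """Number of started whole days [k-1, k) intersected by [start, stop)
    clipped to the window."""
    lo = max(start, window[0])
    hi = min(stop, window[1])
    if hi <= lo:
        return 0
    first = math.floor(lo) + 1  # day index containing lo
    last = math.ceil(hi)  # day index containing hi (exclusive end counts back)
    if hi == math.floor(hi):
        last = int(hi)
    return max(0, last - first + 1)


def trajectory_cost(
    trajectory: PatientTrajectory,
    schedule: CostSchedule,
    scenario: Scenario = BASE,
    window: tuple[float, float] | None = None,
) -> CostBreakdown:
    """Accrue one subject's cost components (per catheter, unscaled).

    ``window`` optionally clips day-level accrual (and gates point costs) to
    a sub-interval of the horizon; by default the full 0-horizon interval is
    used and scenarios act through their inclusion rule and component
    switches.
    """
    trajectory.validate(schedule.horizon)
    win = window if window is not None else (0.0, schedule.horizon)
    arm = trajectory.arm
    a = arm.value

    placement = daily = removal = treatment = second = 0.0

    for seg in trajectory.segments:
        if seg.state is HealthState.S1_NOEVENT_PVC1:
            n_days = _started_days(seg.entry, seg.exit, win)
            daily += schedule.daily_use[a] * n_days
            if n_days > 0 and seg.entry >= win[0]:
                placement += schedule.placement_initial[a]
        elif seg.state is HealthState.S3_NOEVENT_PVC2:
            lo = max(seg.entry, win[0])
            hi = min(seg.exit, win[1])
            if hi > lo:
                second += schedule.daily_use[a] * (hi - lo)

    ev = trajectory.first_catheter_event
    if ev is not None and win[0] <= trajectory.event_time <= win[1]:
        removal += schedule.removal[a]
        if ev.is_unscheduled_complication and scenario.include_complication_costs:
            treatment += schedule.treatment[ev.value]
            second += schedule.placement_second[a]

    term = terminal_removal_cost(trajectory, arm, schedule)
    if term and win[0] < trajectory.segments[-1].entry <= win[1]:
        removal += term

    if win[0] >= win[1]:
        placement = daily = removal = treatment = second = 0.0

    return CostBreakdown(
        subject_id=trajectory.subject_id,
        arm=arm,
        placement=placement,
        daily_use=daily,
        removal=removal,
        treatment=treatment,
        second_catheter=second,
    )


def cohort_cost_table(
    cohort: Iterable[PatientTrajectory],
    schedule: CostSchedule,
    scenario: Scenario = BASE,
    scale_to_patient: bool = True,
) -> pd.DataFrame:
    """Per-subject cost breakdowns for the subjects a scenario includes.

    Columns: subject_id, arm, included components, ``total`` (per catheter)
    and ``total_per_patient`` (coefficient-scaled, rounded to cents).
    """
    rows = []
    for traj in cohort:
        if not scenario.includes(traj):
            continue
        bd = trajectory_cost(traj, schedule, scenario)
        row = {
            "subject_id": bd.subject_id,
            "arm": bd.arm.value,
            "placement": bd.placement,
            "daily_use": bd.daily_use,
            "removal": bd.removal,
            "treatment": bd.treatment,
            "second_catheter": bd.second_catheter,
            "total": bd.total,
        }
        if scale_to_patient:
            row["total_per_patient"] = per_patient(bd.total, bd.arm, schedule)
        rows.append(row)
    if not rows:
        raise ValueError("scenario includes no subjects")
    return pd.DataFrame(rows)


def arm_mean_cost(
    cohort: Sequence[PatientTrajectory],
    arm: Arm,
    schedule: CostSchedule,
    scenario: Scenario = BASE,
) -> float:
    """Mean per-patient (coefficient-scaled) cost over one arm's included
    subjects, without catheter-time adjustment (see the reporting layer)."""
    table = cohort_cost_table(
        [t for t in cohort if t.arm is arm], schedule, scenario
    )
    return float(table["total_per_patient"].mean())
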