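"""Synthetic-cohort generation and trajectory containers.

No public individual-patient database exists for the trial this analysis
emulates, so every downstream stage is driven by a synthetic cohort with the
published marginal structure: two arms (495 standard-device and 494
bundled-device subjects), arm-specific first-catheter sojourn means (1.8269 /
2.1226 days), arm-specific unscheduled-removal probabilities (235/495 and
172/494), a configurable mixture over the five complication types,
discharge/death absorption, and censoring at a 14-day horizon.

Sojourn distributions: only the means are published.  The first-catheter
(state 1) sojourn defaults to a gamma with shape 2, which reproduces the
published state-1 occupancy fractions at 1.4/2.8/4.2 days; states 2 and 3
default to exponential (no published shape information).  Family and shape
are configurable per state group.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

from .states import (
    SCHEDULED_EVENTS,
    UNSCHEDULED_EVENTS,
    Arm,
    HealthState,
    LEGAL_TRANSITIONS,
    TransitionalEvent,
)

__all__ = [
    "CohortConfig",
    "ConfigurationError",
    "CohortIntegrityError",
    "Segment",
    "PatientTrajectory",
    "ObservationRecord",
    "generate_cohort",
    "trajectory_to_observations",
    "write_cohort",
    "read_cohort",
]

_FAMILIES = ("exponential", "gamma", "weibull")


class ConfigurationError(ValueError):
    """Invalid generator configuration; the message names the field."""


class CohortIntegrityError(ValueError):
    """A trajectory or serialized cohort violates its invariants."""


@dataclasses.dataclass(frozen=True)
class CohortConfig:
    """All generator parameters, defaulting to the published trial conditions.

    Probabilities and means are per arm, keyed ``{"SDS": ..., "BDS": ...}``.
    ``event_mix_scheduled`` / ``event_mix_unscheduled`` are the conditional
    type distributions over E1-E3 and E4-E8 given the removal class.
    """

    n_per_arm: dict = dataclasses.field(
        default_factory=lambda: {"SDS": 495, "BDS": 494}
    )
    sojourn_mean_s1: dict = dataclasses.field(
        default_factory=lambda: {"SDS": 1.8269, "BDS": 2.1226}
    )
    sojourn_mean_s2: dict = dataclasses.field(
        default_factory=lambda: {"SDS": 3.59, "BDS": 3.85}
    )
    sojourn_mean_s3: dict = dataclasses.field(
        default_factory=lambda: {"SDS": 7.79, "BDS": 7.77}
    )
    p_unscheduled: dict = dataclasses.field(
        default_factory=lambda: {"SDS": 235 / 495, "BDS": 172 / 494}
    )
    p_death: dict = dataclasses.field(
        default_factory=lambda: {"SDS": 5 / 495, "BDS": 8 / 494}
    )
    event_mix_scheduled: tuple = (1 / 3, 1 / 3, 1 / 3)
    event_mix_unscheduled: tuple = (0.2, 0.2, 0.2, 0.2, 0.2)
    horizon: float = 14.0
    sojourn_family_s1: str = "gamma"
    sojourn_shape_s1: float = 2.0
    sojourn_family_late: str = "exponential"
    sojourn_shape_late: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        for field in ("n_per_arm",):
            for arm in Arm:
                n = getattr(self, field)[arm.value]
                if not isinstance(n, (int, np.integer)) or n < 0:
                    raise ConfigurationError(
                        f"{field}[{arm.value}] must be a non-negative integer, got {n!r}"
                    )
        for field in ("sojourn_mean_s1", "sojourn_mean_s2", "sojourn_mean_s3"):
            for arm in Arm:
                m = getattr(self, field)[arm.value]
                if not m > 0:
                    raise ConfigurationError(
                        f"{field}[{arm.value}] must be > 0, got {m!r}"
                    )
        for field in ("p_unscheduled", "p_death"):
            for arm in Arm:
                p = getattr(self, field)[arm.value]
                if not 0.0 <= p <= 1.0:
                    raise ConfigurationError(
                        f"{field}[{arm.value}] must be in [0, 1], got {p!r}"
                    )
        for field, k in (("event_mix_scheduled", 3), ("event_mix_unscheduled", 5)):
            mix = getattr(self, field)
            if len(mix) != k:
                raise ConfigurationError(f"{field} must have {k} entries")
            if any(p < 0 for p in mix):
                raise ConfigurationError(f"{field} entries must be >= 0")
            if abs(sum(mix) - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"{field} must sum to 1 within 1e-9, got {sum(mix)!r}"
                )
        if not self.horizon > 0:
            raise ConfigurationError(f"horizon must be > 0, got {self.horizon!r}")
        for field in ("sojourn_family_s1", "sojourn_family_late"):
            if getattr(self, field) not in _FAMILIES:
                raise ConfigurationError(
                    f"{field} must be one of {_FAMILIES}, got {getattr(self, field)!r}"
                )
        for field in ("sojourn_shape_s1", "sojourn_shape_late"):
            if not getattr(self, field) > 0:
                raise ConfigurationError(f"{field} must be > 0")

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["event_mix_scheduled"] = list(self.event_mix_scheduled)
        d["event_mix_unscheduled"] = list(self.event_mix_unscheduled)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        for key in ("event_mix_scheduled", "event_mix_unscheduled"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "CohortConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yaml", ".yml")) else json.loads(text)
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2))


@dataclasses.dataclass(frozen=True)
class Segment:
    """A half-open occupancy interval [entry, exit) in one state.

    The final segment of a trajectory is closed at the horizon: an absorbing
    state persists, and a censored subject counts in its last state up to and
    including the censoring time.
    """

    state: HealthState
    entry: float
    exit: float


@dataclasses.dataclass(frozen=True)
class PatientTrajectory:
    subject_id: str
    arm: Arm
    segments: tuple[Segment, ...]
    first_catheter_event: TransitionalEvent | None
    event_time: float | None
    second_catheter_placement_day: float | None
    terminal: str  # "discharged" | "dead" | "censored"

    def validate(self, horizon: float = 14.0) -> None:
        if not self.segments:
            raise CohortIntegrityError(f"{self.subject_id}: empty trajectory")
        segs = self.segments
        if segs[0].state is not HealthState.S1_NOEVENT_PVC1 or segs[0].entry != 0.0:
            raise CohortIntegrityError(
                f"{self.subject_id}: trajectory must start at time 0 in S1"
            )
        prev_exit = 0.0
        for i, seg in enumerate(segs):
            if seg.entry != prev_exit if i else seg.entry != 0.0:
                raise CohortIntegrityError(
                    f"{self.subject_id}: segment {i} entry {seg.entry} != previous exit"
                )
            if not seg.exit > seg.entry:
                raise CohortIntegrityError(
                    f"{self.subject_id}: segment {i} times not strictly increasing"
                )
            if seg.entry > horizon or seg.exit > horizon:
                raise CohortIntegrityError(
                    f"{self.subject_id}: segment {i} exceeds horizon {horizon}"
                )
            if i:
                if seg.state not in LEGAL_TRANSITIONS[segs[i - 1].state]:
                    raise CohortIntegrityError(
                        f"{self.subject_id}: illegal transition "
                        f"{segs[i - 1].state.value} -> {seg.state.value}"
                    )
            prev_exit = seg.exit
        has_s3 = any(s.state is HealthState.S3_NOEVENT_PVC2 for s in segs)
        ev = self.first_catheter_event
        if has_s3 != (ev is not None and ev.is_unscheduled_complication):
            raise CohortIntegrityError(
                f"{self.subject_id}: S3 segment must exist iff the first-catheter "
                "event is an unscheduled complication (E4-E8)"
            )
        if self.terminal not in ("discharged", "dead", "censored"):
            raise CohortIntegrityError(
                f"{self.subject_id}: unknown terminal {self.terminal!r}"
            )

    @property
    def had_unscheduled_removal(self) -> bool:
        ev = self.first_catheter_event
        return ev is not None and ev.is_unscheduled_complication

    def state_at(self, t: float) -> HealthState:
        """State occupied at time t (half-open [entry, exit); the last
        segment is closed so absorbing/censored occupancy persists)."""
        last = self.segments[-1]
        for seg in self.segments:
            if seg.entry <= t < seg.exit:
                return seg.state
        if t >= last.entry:
            return last.state
        raise ValueError(f"time {t} before trajectory start")

    def sojourn(self, state: HealthState) -> float | None:
        """Total time spent in ``state`` (None if never visited)."""
        durs = [s.exit - s.entry for s in self.segments if s.state is state]
        return sum(durs) if durs else None


@dataclasses.dataclass(frozen=True)
class ObservationRecord:
    """One long-format panel row: (subject, observation time, observed state)."""

    subject_id: str
    time: float
    state: HealthState


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _draw_sojourns(
    rng: np.random.Generator, n: int, mean: float, family: str, shape: float
) -> np.ndarray:
    if family == "exponential":
        return rng.exponential(mean, n)
    if family == "gamma":
        return rng.gamma(shape, mean / shape, n)
    if family == "weibull":
        # scale chosen so the mean equals the requested mean
        scale = mean / math.gamma(1.0 + 1.0 / shape)
        return scale * rng.weibull(shape, n)
    raise ConfigurationError(f"unknown sojourn family {family!r}")


def _build_trajectory(
    subject_id: str,
    arm: Arm,
    t1: float,
    event: TransitionalEvent | None,
    late_sojourn: float,
    dies: bool,
    horizon: float,
) -> PatientTrajectory:
    S = HealthState
    if t1 >= horizon:  # censored while the first catheter is still in place
        return PatientTrajectory(
            subject_id, arm, (Segment(S.S1_NOEVENT_PVC1, 0.0, horizon),),
            None, None, None, "censored",
        )
    assert event is not None
    unscheduled = event.is_unscheduled_complication
    mid_state = S.S3_NOEVENT_PVC2 if unscheduled else S.S2_NOEVENT_NOPVC
    second_day = t1 if unscheduled else None
    t_end = t1 + late_sojourn
    segs = [Segment(S.S1_NOEVENT_PVC1, 0.0, t1)]
    if t_end >= horizon:
        segs.append(Segment(mid_state, t1, horizon))
        return PatientTrajectory(
            subject_id, arm, tuple(segs), event, t1, second_day, "censored"
        )
    absorbing = S.S5_DEATH if dies else S.S4_DISCHARGE
    segs.append(Segment(mid_state, t1, t_end))
    segs.append(Segment(absorbing, t_end, horizon))
    return PatientTrajectory(
        subject_id, arm, tuple(segs), event, t1, second_day,
        "dead" if dies else "discharged",
    )


def generate_cohort(config: CohortConfig) -> list[PatientTrajectory]:
    """Generate one synthetic cohort (both arms, deterministic under seed).

    Per subject: draw the state-1 sojourn; if it ends before the horizon,
    draw the removal class (unscheduled complication vs routine removal),
    then the event type from the conditional mix; then the state-2 or state-3
    sojourn; if absorption occurs before the horizon, the subject dies with
    the arm's death probability and is otherwise discharged.  Everything is
    censored at the horizon.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    cohort: list[PatientTrajectory] = []
    for arm in (Arm.SDS, Arm.BDS):
        n = config.n_per_arm[arm.value]
        t1 = _draw_sojourns(
            rng, n, config.sojourn_mean_s1[arm.value],
            config.sojourn_family_s1, config.sojourn_shape_s1,
        )
        unscheduled = rng.random(n) < config.p_unscheduled[arm.value]
        idx_sched = rng.choice(3, size=n, p=np.asarray(config.event_mix_scheduled))
        idx_unsch = rng.choice(5, size=n, p=np.asarray(config.event_mix_unscheduled))
        s2 = _draw_sojourns(
            rng, n, config.sojourn_mean_s2[arm.value],
            config.sojourn_family_late, config.sojourn_shape_late,
        )
        s3 = _draw_sojourns(
            rng, n, config.sojourn_mean_s3[arm.value],
            config.sojourn_family_late, config.sojourn_shape_late,
        )
        dies = rng.random(n) < config.p_death[arm.value]
        for i in range(n):
            event = (
                UNSCHEDULED_EVENTS[idx_unsch[i]]
                if unscheduled[i]
                else SCHEDULED_EVENTS[idx_sched[i]]
            )
            cohort.append(
                _build_trajectory(
                    f"{arm.value}-{i + 1:04d}", arm,
                    float(t1[i]), event,
                    float(s3[i] if unscheduled[i] else s2[i]),
                    bool(dies[i]), config.horizon,
                )
            )
    for traj in cohort:
        traj.validate(config.horizon)
    return cohort


# ---------------------------------------------------------------------------
# panel observation scheme
# ---------------------------------------------------------------------------


def trajectory_to_observations(
    trajectory: PatientTrajectory,
    grid: Sequence[float],
    horizon: float = 14.0,
) -> list[ObservationRecord]:
    """Observe a trajectory at the given times (long-format panel rows)."""
    grid = list(grid)
    if any(b < a for a, b in zip(grid, grid[1:])):
        raise ValueError("observation grid must be sorted ascending")
    if grid and (grid[0] < 0 or grid[-1] > horizon):
        raise ValueError(f"observation times must lie in [0, {horizon}]")
    return [
        ObservationRecord(trajectory.subject_id, float(t), trajectory.state_at(t))
        for t in grid
    ]


# ---------------------------------------------------------------------------
# cohort serialisation (long-format state CSV + per-subject event log)
# ---------------------------------------------------------------------------


def write_cohort(directory: str | Path, cohort: Iterable[PatientTrajectory]) -> None:
    """Write ``states.csv`` (subject_id,time_days,state: one row per segment
    entry) and ``events.csv`` (per-subject event log) under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "states.csv", "w") as fh:
        fh.write("subject_id,time_days,state\n")
        for traj in cohort:
            for seg in traj.segments:
                fh.write(f"{traj.subject_id},{seg.entry!r},{seg.state.value}\n")
    with open(directory / "events.csv", "w") as fh:
        fh.write(
            "subject_id,arm,event_code,event_time_days,second_pvc_day,terminal,horizon_days\n"
        )
        for traj in cohort:
            ev = traj.first_catheter_event.value if traj.first_catheter_event else ""
            et = repr(traj.event_time) if traj.event_time is not None else ""
            sd = (
                repr(traj.second_catheter_placement_day)
                if traj.second_catheter_placement_day is not None
                else ""
            )
            horizon = traj.segments[-1].exit
            fh.write(
                f"{traj.subject_id},{traj.arm.value},{ev},{et},{sd},"
                f"{traj.terminal},{horizon!r}\n"
            )


def _parse_error(path: Path, lineno: int, msg: str) -> CohortIntegrityError:
    return CohortIntegrityError(f"{path}:{lineno}: {msg}")


def read_cohort(directory: str | Path) -> list[PatientTrajectory]:
    """Reload a cohort written by :func:`write_cohort` (exact round-trip)."""
    directory = Path(directory)
    states_path = directory / "states.csv"
    events_path = directory / "events.csv"

    state_by_code = {s.value: s for s in HealthState}
    event_by_code = {e.value: e for e in TransitionalEvent}

    obs: dict[str, list[tuple[float, HealthState]]] = {}
    with open(states_path) as fh:
        header = fh.readline().strip()
        if header != "subject_id,time_days,state":
            raise _parse_error(states_path, 1, f"unexpected header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split(",")
            if len(parts) != 3:
                raise _parse_error(states_path, lineno, "expected 3 columns")
            sid, t_str, code = parts
            try:
                t = float(t_str)
            except ValueError:
                raise _parse_error(states_path, lineno, f"bad time {t_str!r}") from None
            if code not in state_by_code:
                raise _parse_error(states_path, lineno, f"unknown state {code!r}")
            rows = obs.setdefault(sid, [])
            if rows and t <= rows[-1][0]:
                raise _parse_error(
                    states_path, lineno, f"subject {sid} rows out of time order"
                )
            rows.append((t, state_by_code[code]))

    cohort: list[PatientTrajectory] = []
    with open(events_path) as fh:
        fh.readline()
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split(",")
            if len(parts) != 7:
                raise _parse_error(events_path, lineno, "expected 7 columns")
            sid, arm_s, ev_s, et_s, sd_s, terminal, hor_s = parts
            if sid not in obs:
                raise _parse_error(events_path, lineno, f"no state rows for {sid}")
            try:
                arm = Arm(arm_s)
            except ValueError:
                raise _parse_error(events_path, lineno, f"unknown arm {arm_s!r}") from None
            if ev_s and ev_s not in event_by_code:
                raise _parse_error(events_path, lineno, f"unknown event {ev_s!r}")
            horizon = float(hor_s)
            rows = obs[sid]
            segs = []
            for i, (t, state) in enumerate(rows):
                exit_t = rows[i + 1][0] if i + 1 < len(rows) else horizon
                segs.append(Segment(state, t, exit_t))
            traj = PatientTrajectory(
                sid, arm, tuple(segs),
                event_by_code[ev_s] if ev_s else None,
                float(et_s) if et_s else None,
                float(sd_s) if sd_s else None,
                terminal,
            )
            try:
                traj.validate(horizon)
            except CohortIntegrityError as exc:
                raise _parse_error(events_path, lineno, str(exc)) from None
            cohort.append(traj)
    return cohort
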