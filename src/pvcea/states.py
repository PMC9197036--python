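"""Health states, transitional events and trial arms.

The patient-trajectory model has five health states. A subject starts with a
first peripheral venous catheter (PVC) in place (S1). The first catheter is
removed through one of eight transitional events: three "routine" removals
(scheduled end of use, catheter no longer useful, suspected infection) after
which no new catheter is placed (S2), and five complications (dislodgement,
phlebitis, diffusion, local infection, occlusion) that force an unscheduled
removal and the insertion of a second catheter (S3). Discharge (S4) and death
(S5) are absorbing.
"""

from __future__ import annotations

import enum


class HealthState(enum.Enum):
    """The five Markov states of the catheter trajectory model."""

    S1_NOEVENT_PVC1 = "S1"
    S2_NOEVENT_NOPVC = "S2"
    S3_NOEVENT_PVC2 = "S3"
    S4_DISCHARGE = "S4"
    S5_DEATH = "S5"

    @property
    def is_absorbing(self) -> bool:
        return self in (HealthState.S4_DISCHARGE, HealthState.S5_DEATH)

    @property
    def has_catheter(self) -> bool:
        """True if a catheter is in place while occupying this state."""
        return self in (HealthState.S1_NOEVENT_PVC1, HealthState.S3_NOEVENT_PVC2)


class TransitionalEvent(enum.Enum):
    """The eight events that end the first-catheter episode.

    E1-E3 end the episode without a replacement catheter; E4-E8 are the
    studied complications, each triggering insertion of a second catheter.
    """

    E1_SCHEDULED_REMOVAL = "E1"
    E2_USELESS = "E2"
    E3_SUSPECTED_INFECTION = "E3"
    E4_DISLODGEMENT = "E4"
    E5_PHLEBITIS = "E5"
    E6_DIFFUSION = "E6"
    E7_LOCAL_INFECTION = "E7"
    E8_OCCLUSION = "E8"

    @property
    def is_unscheduled_complication(self) -> bool:
        return self in UNSCHEDULED_EVENTS


SCHEDULED_EVENTS: tuple[TransitionalEvent, ...] = (
    TransitionalEvent.E1_SCHEDULED_REMOVAL,
    TransitionalEvent.E2_USELESS,
    TransitionalEvent.E3_SUSPECTED_INFECTION,
)

UNSCHEDULED_EVENTS: tuple[TransitionalEvent, ...] = (
    TransitionalEvent.E4_DISLODGEMENT,
    TransitionalEvent.E5_PHLEBITIS,
    TransitionalEvent.E6_DIFFUSION,
    TransitionalEvent.E7_LOCAL_INFECTION,
    TransitionalEvent.E8_OCCLUSION,
)


class Arm(enum.Enum):
    """Randomisation arm: standard devices vs bundled innovative devices."""

    SDS = "SDS"
    BDS = "BDS"


#: Legal state-to-state moves (observed model structure).  Absorbing states
#: have no outgoing edges.
LEGAL_TRANSITIONS: dict[HealthState, frozenset[HealthState]] = {
    HealthState.S1_NOEVENT_PVC1: frozenset(
        {
            HealthState.S2_NOEVENT_NOPVC,
            HealthState.S3_NOEVENT_PVC2,
            HealthState.S4_DISCHARGE,
            HealthState.S5_DEATH,
        }
    ),
    HealthState.S2_NOEVENT_NOPVC: frozenset(
        {HealthState.S4_DISCHARGE, HealthState.S5_DEATH}
    ),
    HealthState.S3_NOEVENT_PVC2: frozenset(
        {HealthState.S4_DISCHARGE, HealthState.S5_DEATH}
    ),
    HealthState.S4_DISCHARGE: frozenset(),
    HealthState.S5_DEATH: frozenset(),
}
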