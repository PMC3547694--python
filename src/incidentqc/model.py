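"""Domain types for major-incident decision logs.

A regional medical command-and-control log is one record per declared
major incident: the incident category, the alert time, the timestamped
command decisions made during the response, how much of the management
organisation was activated, and how long it stayed active.  Decision
events are coded to a closed vocabulary of 11 decision kinds, one per
performance indicator in the quality-control rubric.
"""

from __future__ import annotations

import datetime
import enum
import warnings
from dataclasses import dataclass, field, replace


class IncidentCategory(str, enum.Enum):
    """The nine categories major incidents are classified into."""

    ACCIDENT = "accident"
    THREAT = "threat"
    FIRE = "fire"
    HOSPITAL_INFRASTRUCTURE = "hospital_infrastructure"
    CBRNE = "cbrne"
    INFECTIOUS = "infectious"
    WEATHER_ALERT = "weather_alert"
    SUPPORT_OTHER_REGION = "support_other_region"
    INCIDENT_ABROAD = "incident_abroad"


class DecisionKind(str, enum.Enum):
    """The 11 command decisions the rubric measures, in indicator order."""

    DECLARE_MAJOR_INCIDENT = "declare_major_incident"
    SET_STAFF_ALERT_LEVEL = "set_staff_alert_level"
    SEND_ADDITIONAL_RESOURCES = "send_additional_resources"
    DESIGNATE_RECEIVING_HOSPITALS = "designate_receiving_hospitals"
    CONTACT_SCENE_COMMAND = "contact_scene_command"
    PRELIMINARY_REFERRAL_DECISION = "preliminary_referral_decision"
    FIRST_MEDIA_INFORMATION = "first_media_information"
    FORMULATE_RESPONSE_GUIDELINES = "formulate_response_guidelines"
    CONFIRM_REFERRAL_INFORMATION = "confirm_referral_information"
    ASSESS_OWN_RESOURCES = "assess_own_resources"
    NOTIFY_REFERRAL_DECISION = "notify_referral_decision"


class StaffingExtent(str, enum.Enum):
    """How much of the regional management organisation was activated."""

    DDO_ONLY = "ddo_only"
    DDO_PLUS_REGIONAL_MO = "ddo_plus_regional_mo"
    PLUS_STAFF_FUNCTIONS = "plus_staff_functions"
    FULL_MANAGEMENT_GROUP = "full_management_group"


class _Sentinel:
    __slots__ = ("_name",)

    def __init__(self, name: str) -> None:
        self._name = name

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return self._name


#: The record contains no event of the requested kind.
ABSENT = _Sentinel("ABSENT")
#: The decision is documented but carries no usable timestamp.
UNTIMED = _Sentinel("UNTIMED")


@dataclass(frozen=True)
class DecisionEvent:
    """One documented command decision.

    ``minutes`` is the latency from the incident alert, in minutes; ``None``
    means the decision was recorded without a usable timestamp (a decision
    "made but never documented with a time"), which later marks the
    incident's documentation as incomplete.
    """

    kind: DecisionKind
    minutes: float | None
    note: str | None = None

    def __post_init__(self) -> None:
        if self.minutes is not None and self.minutes < 0:
            raise ValueError(
                f"event {self.kind.value!r}: minutes-from-alert must be >= 0, "
                f"got {self.minutes}"
            )

    @property
    def timestamp_present(self) -> bool:
        return self.minutes is not None


@dataclass
class IncidentRecord:
    """One major incident's command-and-control log.

    Events are deduplicated on construction: the rubric asks when each
    decision was *first* made, so among duplicate events of one kind the
    earliest timestamped one is kept (with a warning).
    """

    incident_id: str
    category: IncidentCategory
    alert_time: datetime.datetime | None = None
    events: list[DecisionEvent] = field(default_factory=list)
    staffing_extent: StaffingExtent = StaffingExtent.DDO_ONLY
    active_minutes: float = 0.0
    casualties: int | None = None
    receiving_hospitals: int | None = None
    hospital_plan_activated: bool | None = None
    #: Explicit applicability override; ``None`` defers to the category rule.
    applicable_override: bool | None = None

    def __post_init__(self) -> None:
        if self.active_minutes < 0:
            raise ValueError(
                f"incident {self.incident_id!r}: active_minutes must be >= 0"
            )
        if self.casualties is not None and self.casualties < 0:
            raise ValueError(f"incident {self.incident_id!r}: casualties must be >= 0")
        if self.receiving_hospitals is not None and self.receiving_hospitals < 0:
            raise ValueError(
                f"incident {self.incident_id!r}: receiving_hospitals must be >= 0"
            )
        self.events = _dedupe_events(self.incident_id, self.events)

    def event_of(self, kind: DecisionKind) -> DecisionEvent | None:
        for ev in self.events:
            if ev.kind is kind:
                return ev
        return None


def _dedupe_events(
    incident_id: str, events: list[DecisionEvent]
) -> list[DecisionEvent]:
    """Keep one event per kind: the earliest timestamped, else the first."""
    by_kind: dict[DecisionKind, DecisionEvent] = {}
    dupes = False
    for ev in events:
        kept = by_kind.get(ev.kind)
        if kept is None:
            by_kind[ev.kind] = ev
            continue
        dupes = True
        if ev.minutes is not None and (kept.minutes is None or ev.minutes < kept.minutes):
            by_kind[ev.kind] = ev
    if dupes:
        warnings.warn(
            f"incident {incident_id!r}: duplicate decision events; "
            "keeping the earliest timestamped event of each kind",
            stacklevel=3,
        )
    return list(by_kind.values())


def elapsed_minutes(
    record: IncidentRecord, kind: DecisionKind
) -> float | _Sentinel:
    """Minutes from alert to the decision of ``kind``.

    Returns :data:`ABSENT` if the record holds no such event and
    :data:`UNTIMED` if the event exists but has no usable timestamp.
    """
    ev = record.event_of(kind)
    if ev is None:
        return ABSENT
    if ev.minutes is None:
        return UNTIMED
    return ev.minutes


def copy_record(record: IncidentRecord, **changes) -> IncidentRecord:
    """Shallow copy with field overrides (events list is re-validated)."""
    return replace(record, **changes)
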