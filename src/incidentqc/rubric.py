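"""The 11-indicator time-standard rubric and the 0/1/2 scoring engine.

Each performance indicator names one command decision and a stipulated
time standard in minutes from the incident alert.  An indicator scores

* **2** — the decision is documented and was made within the standard
  (inclusive: elapsed time exactly equal to the standard still scores 2),
* **1** — the decision is documented but was made after the standard,
* **0** — the decision does not appear in the log at all.

A decision documented without a usable timestamp is *unevaluable*; by
default it marks the incident's documentation incomplete, which excludes
the incident from the scored cohort (poor documentation is excluded, not
imputed).  ``lenient_timeless=True`` instead scores such decisions 1
(made, but not demonstrably on time).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, TYPE_CHECKING

import numpy as np

from .model import ABSENT, UNTIMED, DecisionKind, IncidentRecord, elapsed_minutes

if TYPE_CHECKING:  # pragma: no cover
    from .cohort import ScoreMatrix


@dataclass(frozen=True)
class IndicatorDefinition:
    """One rubric item: a decision kind plus its time standard."""

    id: int
    label: str
    kind: DecisionKind
    standard_minutes: float

    def __post_init__(self) -> None:
        if self.standard_minutes <= 0:
            raise ValueError(f"indicator {self.id}: standard_minutes must be > 0")


_BUILTIN = (
    (1, "Declaration of major incident", DecisionKind.DECLARE_MAJOR_INCIDENT, 1.0),
    (2, "Decision on level of alert for staff", DecisionKind.SET_STAFF_ALERT_LEVEL, 3.0),
    (3, "Decision on sending additional resources to scene",
     DecisionKind.SEND_ADDITIONAL_RESOURCES, 3.0),
    (4, "Decision on receiving hospitals",
     DecisionKind.DESIGNATE_RECEIVING_HOSPITALS, 5.0),
    (5, "Establishing contact with incident officers at scene",
     DecisionKind.CONTACT_SCENE_COMMAND, 10.0),
    (6, "Decision on preliminary referrals",
     DecisionKind.PRELIMINARY_REFERRAL_DECISION, 10.0),
    (7, "First information to media", DecisionKind.FIRST_MEDIA_INFORMATION, 15.0),
    (8, "Formulate general guidelines for response",
     DecisionKind.FORMULATE_RESPONSE_GUIDELINES, 15.0),
    (9, "Ensuring adequate information for decision on referrals",
     DecisionKind.CONFIRM_REFERRAL_INFORMATION, 20.0),
    (10, "Assessment if resources in own organization are adequate",
     DecisionKind.ASSESS_OWN_RESOURCES, 30.0),
    (11, "Notify decision on referrals to receiving hospitals",
     DecisionKind.NOTIFY_REFERRAL_DECISION, 40.0),
)


def builtin_rubric() -> list[IndicatorDefinition]:
    """The built-in 11-indicator set with its stipulated time standards."""
    return [IndicatorDefinition(*row) for row in _BUILTIN]


def load_rubric(path: str | Path) -> list[IndicatorDefinition]:
    """Load an alternative rubric from a JSON config.

    The file holds a list of ``{"id", "label", "kind", "standard_minutes"}``
    objects; this enables modified indicator sets (e.g. for incident types
    the built-in set does not fit) without code changes.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = json.load(fh)
    defs = [
        IndicatorDefinition(
            id=int(item["id"]),
            label=str(item["label"]),
            kind=DecisionKind(item["kind"]),
            standard_minutes=float(item["standard_minutes"]),
        )
        for item in raw
    ]
    validate_rubric(defs)
    return defs


def validate_rubric(rubric: Sequence[IndicatorDefinition]) -> None:
    """Require a full 11-item set with ids 1..11 and distinct kinds."""
    if len(rubric) != 11 or sorted(d.id for d in rubric) != list(range(1, 12)):
        raise ValueError("rubric must contain exactly 11 indicators with ids 1..11")
    if len({d.kind for d in rubric}) != 11:
        raise ValueError("rubric indicators must target 11 distinct decision kinds")


@dataclass(frozen=True)
class IndicatorScore:
    """Score for one indicator on one incident.

    ``value`` is 0, 1 or 2; ``None`` means unevaluable (decision documented
    without a timestamp).  ``elapsed`` is the decision latency in minutes
    where known.
    """

    indicator_id: int
    value: int | None
    elapsed: float | None = None

    @property
    def unevaluable(self) -> bool:
        return self.value is None


@dataclass(frozen=True)
class ScoreVector:
    """All 11 indicator scores for one incident, in indicator-id order."""

    incident_id: str
    scores: tuple[IndicatorScore, ...]

    def __post_init__(self) -> None:
        if len(self.scores) != 11:
            raise ValueError("a score vector holds exactly 11 indicator scores")

    @property
    def complete(self) -> bool:
        return not any(s.unevaluable for s in self.scores)

    @property
    def values(self) -> tuple[int | None, ...]:
        return tuple(s.value for s in self.scores)


def score_indicator(
    record: IncidentRecord,
    definition: IndicatorDefinition,
    *,
    lenient_timeless: bool = False,
) -> IndicatorScore:
    """Apply one indicator's time standard to one incident."""
    elapsed = elapsed_minutes(record, definition.kind)
    if elapsed is ABSENT:
        return IndicatorScore(definition.id, 0)
    if elapsed is UNTIMED:
        return IndicatorScore(definition.id, 1 if lenient_timeless else None)
    value = 2 if elapsed <= definition.standard_minutes else 1
    return IndicatorScore(definition.id, value, elapsed=elapsed)


def score_incident(
    record: IncidentRecord,
    rubric: Sequence[IndicatorDefinition] | None = None,
    *,
    lenient_timeless: bool = False,
) -> ScoreVector:
    """Score one incident against the full 11-indicator rubric."""
    rubric = list(rubric) if rubric is not None else builtin_rubric()
    validate_rubric(rubric)
    ordered = sorted(rubric, key=lambda d: d.id)
    return ScoreVector(
        incident_id=record.incident_id,
        scores=tuple(
            score_indicator(record, d, lenient_timeless=lenient_timeless)
            for d in ordered
        ),
    )


@dataclass(frozen=True)
class AggregateScores:
    """Per-indicator means and the met / not-met split over all cells."""

    indicator_ids: tuple[int, ...]
    means: np.ndarray  # shape (11,), each in [0, 2]
    n_incidents: int
    n_cells: int  # 11 * n_incidents
    n_not_met: int  # cells scoring 0
    n_met: int  # cells scoring 1 or 2 ("met completely or partly")

    @property
    def met_fraction(self) -> float:
        return self.n_met / self.n_cells


def aggregate_scores(matrix: "ScoreMatrix") -> AggregateScores:
    """Column means and 0-vs-{1,2} counts for a complete score matrix."""
    cells = np.asarray(matrix.cells)
    if cells.size == 0:
        raise ValueError("cannot aggregate an empty score matrix")
    n_incidents, n_ind = cells.shape
    n_cells = cells.size
    n_not_met = int((cells == 0).sum())
    return AggregateScores(
        indicator_ids=tuple(matrix.indicator_ids),
        means=cells.mean(axis=0),
        n_incidents=n_incidents,
        n_cells=n_cells,
        n_not_met=n_not_met,
        n_met=n_cells - n_not_met,
    )
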