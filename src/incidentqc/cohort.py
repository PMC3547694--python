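"""Case-flow filtering and descriptive summaries of an incident cohort.

The scored cohort is built in two independent filter stages:

1. **Applicability** — the rubric targets incidents that directly or
   indirectly involve casualties (accidents, fires, threats, CBRNE
   events); other categories (hospital-infrastructure interference,
   infectious events, weather alerts, support to another region,
   incidents abroad) have different characteristics and time frames, so
   the indicator set is not applied to them.  A per-record override flag
   can force either outcome for logs where applicability was adjudicated
   case by case.
2. **Documentation completeness** — incidents with any unevaluable
   indicator (a decision documented without a usable timestamp) are
   excluded rather than imputed.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import IncidentCategory, IncidentRecord, StaffingExtent
from .rubric import IndicatorDefinition, ScoreVector, builtin_rubric, score_incident

#: Categories the indicator set applies to as a set.
APPLICABLE_CATEGORIES = frozenset(
    {
        IncidentCategory.ACCIDENT,
        IncidentCategory.FIRE,
        IncidentCategory.THREAT,
        IncidentCategory.CBRNE,
    }
)

#: "4 h or less" activation cutoff, inclusive.
FOUR_HOURS_MINUTES = 240.0


@dataclass(frozen=True)
class CohortFlow:
    """Counts surviving each filter stage of the study case flow."""

    n_total: int
    n_not_applicable: int
    n_applicable: int
    n_incomplete: int
    n_scoreable: int

    def __post_init__(self) -> None:
        if self.n_total != self.n_not_applicable + self.n_applicable:
            raise ValueError("flow violates n_total = n_not_applicable + n_applicable")
        if self.n_applicable != self.n_incomplete + self.n_scoreable:
            raise ValueError(
                "flow violates n_applicable = n_incomplete + n_scoreable"
            )

    def as_dict(self) -> dict[str, int]:
        return {
            "n_total": self.n_total,
            "n_not_applicable": self.n_not_applicable,
            "n_applicable": self.n_applicable,
            "n_incomplete": self.n_incomplete,
            "n_scoreable": self.n_scoreable,
        }


@dataclass(frozen=True)
class ScoreMatrix:
    """Complete incidents x indicators matrix of {0,1,2} scores.

    Rows are incidents (the blocks of the blocked ANOVA), columns are
    indicators (the treatments); the matrix is rectangular with one
    observation per cell.
    """

    incident_ids: tuple[str, ...]
    indicator_ids: tuple[int, ...]
    cells: np.ndarray  # shape (n_incidents, n_indicators), ints in {0,1,2}

    def __post_init__(self) -> None:
        cells = np.asarray(self.cells, dtype=int)
        object.__setattr__(self, "cells", cells)
        if cells.ndim != 2:
            raise ValueError("cells must be a 2-D matrix")
        if cells.shape != (len(self.incident_ids), len(self.indicator_ids)):
            raise ValueError("cells shape must match incident and indicator labels")
        if cells.size and (cells.min() < 0 or cells.max() > 2):
            raise ValueError("scores must lie in {0, 1, 2}")

    @property
    def n_incidents(self) -> int:
        return len(self.incident_ids)

    @property
    def n_indicators(self) -> int:
        return len(self.indicator_ids)


@dataclass(frozen=True)
class DescriptiveSummary:
    """Cohort-level descriptive statistics."""

    category_counts: dict[IncidentCategory, int]
    staffing_counts: dict[StaffingExtent, int]
    duration_median_minutes: float
    frac_leq_4h: float
    casualty_total: int
    n_multi_hospital: int
    n_hospital_plan: int

    def as_dict(self) -> dict:
        return {
            "category_counts": {c.value: n for c, n in self.category_counts.items()},
            "staffing_counts": {s.value: n for s, n in self.staffing_counts.items()},
            "duration_median_minutes": self.duration_median_minutes,
            "frac_leq_4h": self.frac_leq_4h,
            "casualty_total": self.casualty_total,
            "n_multi_hospital": self.n_multi_hospital,
            "n_hospital_plan": self.n_hospital_plan,
        }


def classify_applicability(record: IncidentRecord) -> tuple[bool, str]:
    """Decide whether the indicator set applies to an incident.

    Returns ``(applicable, reason)``.  An explicit per-record override
    takes precedence over the category rule.
    """
    if record.applicable_override is not None:
        return (
            record.applicable_override,
            f"explicit override ({'applicable' if record.applicable_override else 'not applicable'})",
        )
    if record.category in APPLICABLE_CATEGORIES:
        return True, f"category {record.category.value!r} involves casualties"
    return False, (
        f"category {record.category.value!r} has different characteristics "
        "and time frames"
    )


@dataclass(frozen=True)
class FilterDecision:
    """Per-incident audit record of the cohort filters."""

    incident_id: str
    applicable: bool
    applicability_reason: str
    complete: bool | None  # None when not scored (not applicable)
    included: bool


def case_flow_decisions(
    records: Sequence[IncidentRecord],
    rubric: Sequence[IndicatorDefinition] | None = None,
    *,
    lenient_timeless: bool = False,
) -> tuple[list[FilterDecision], list[ScoreVector]]:
    """Run both filters, keeping a per-incident audit trail.

    Returns the decisions for every record plus the score vectors of the
    incidents surviving both filters, in input order.
    """
    rubric = list(rubric) if rubric is not None else builtin_rubric()
    decisions: list[FilterDecision] = []
    kept: list[ScoreVector] = []
    for rec in records:
        applicable, reason = classify_applicability(rec)
        if not applicable:
            decisions.append(FilterDecision(rec.incident_id, False, reason, None, False))
            continue
        vec = score_incident(rec, rubric, lenient_timeless=lenient_timeless)
        decisions.append(
            FilterDecision(rec.incident_id, True, reason, vec.complete, vec.complete)
        )
        if vec.complete:
            kept.append(vec)
    return decisions, kept


def build_cohort(
    records: Sequence[IncidentRecord],
    rubric: Sequence[IndicatorDefinition] | None = None,
    *,
    lenient_timeless: bool = False,
) -> tuple[CohortFlow, ScoreMatrix]:
    """Apply the applicability and completeness filters and assemble scores.

    Raises ``ValueError`` naming the emptied stage if no incident survives.
    """
    if not records:
        raise ValueError("cannot build a cohort from zero records")
    ids = [r.incident_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("incident_id values must be unique within a cohort")

    rubric = list(rubric) if rubric is not None else builtin_rubric()
    decisions, kept = case_flow_decisions(
        records, rubric, lenient_timeless=lenient_timeless
    )
    n_total = len(records)
    n_not_applicable = sum(1 for d in decisions if not d.applicable)
    n_applicable = n_total - n_not_applicable
    n_scoreable = len(kept)
    n_incomplete = n_applicable - n_scoreable
    if n_applicable == 0:
        raise ValueError("no incidents survived the applicability filter")
    if n_scoreable == 0:
        raise ValueError("no incidents survived the documentation-completeness filter")

    flow = CohortFlow(n_total, n_not_applicable, n_applicable, n_incomplete, n_scoreable)
    indicator_ids = tuple(sorted(d.id for d in rubric))
    matrix = ScoreMatrix(
        incident_ids=tuple(v.incident_id for v in kept),
        indicator_ids=indicator_ids,
        cells=np.array([[s.value for s in v.scores] for v in kept], dtype=int),
    )
    return flow, matrix


def descriptive_summary(records: Sequence[IncidentRecord]) -> DescriptiveSummary:
    """Category, staffing, duration and casualty summaries for a cohort."""
    if not records:
        raise ValueError("cannot summarize zero records")
    category_counts = {c: 0 for c in IncidentCategory}
    staffing_counts = {s: 0 for s in StaffingExtent}
    durations: list[float] = []
    casualty_total = 0
    n_multi = 0
    n_plan = 0
    for rec in records:
        category_counts[rec.category] += 1
        staffing_counts[rec.staffing_extent] += 1
        durations.append(rec.active_minutes)
        if rec.casualties:
            casualty_total += rec.casualties
        if rec.receiving_hospitals is not None and rec.receiving_hospitals > 1:
            n_multi += 1
        if rec.hospital_plan_activated:
            n_plan += 1
    return DescriptiveSummary(
        category_counts=category_counts,
        staffing_counts=staffing_counts,
        duration_median_minutes=float(statistics.median(durations)),
        frac_leq_4h=sum(1 for d in durations if d <= FOUR_HOURS_MINUTES)
        / len(durations),
        casualty_total=casualty_total,
        n_multi_hospital=n_multi,
        n_hospital_plan=n_plan,
    )
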