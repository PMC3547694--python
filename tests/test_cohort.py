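"""Case-flow filters and descriptive summaries."""

import numpy as np
import pytest

from incidentqc.cohort import (
    CohortFlow,
    build_cohort,
    classify_applicability,
    descriptive_summary,
)
from incidentqc.model import (
    DecisionEvent,
    DecisionKind,
    IncidentCategory,
    IncidentRecord,
    StaffingExtent,
)
from incidentqc.simulate import SyntheticConfig, generate_cohort, calibration_preset


def rec(i, category, events=(), **kw):
    return IncidentRecord(
        incident_id=f"mi-{i}", category=category, events=list(events), **kw
    )


FULL_EVENTS = [
    DecisionEvent(k, 0.0)
    for k in DecisionKind
]


class TestApplicability:
    @pytest.mark.parametrize(
        "category,expected",
        [
            (IncidentCategory.ACCIDENT, True),
            (IncidentCategory.FIRE, True),
            (IncidentCategory.THREAT, True),
            (IncidentCategory.CBRNE, True),
            (IncidentCategory.WEATHER_ALERT, False),
            (IncidentCategory.HOSPITAL_INFRASTRUCTURE, False),
            (IncidentCategory.INFECTIOUS, False),
            (IncidentCategory.SUPPORT_OTHER_REGION, False),
            (IncidentCategory.INCIDENT_ABROAD, False),
        ],
    )
    def test_category_rule(self, category, expected):
        applicable, reason = classify_applicability(rec(1, category))
        assert applicable is expected
        assert reason

    def test_override_beats_category(self):
        r = rec(1, IncidentCategory.ACCIDENT, applicable_override=False)
        assert classify_applicability(r)[0] is False
        r = rec(2, IncidentCategory.WEATHER_ALERT, applicable_override=True)
        assert classify_applicability(r)[0] is True


class TestBuildCohort:
    def test_fully_documented_applicable_records(self):
        records = [rec(i, IncidentCategory.ACCIDENT, FULL_EVENTS) for i in range(3)]
        flow, matrix = build_cohort(records)
        assert flow.as_dict() == {
            "n_total": 3,
            "n_not_applicable": 0,
            "n_applicable": 3,
            "n_incomplete": 0,
            "n_scoreable": 3,
        }
        assert matrix.cells.shape == (3, 11)
        assert (matrix.cells == 2).all()

    def test_applicability_filter(self):
        records = [
            rec(1, IncidentCategory.ACCIDENT, FULL_EVENTS),
            rec(2, IncidentCategory.WEATHER_ALERT, FULL_EVENTS),
        ]
        flow, _ = build_cohort(records)
        assert (flow.n_total, flow.n_not_applicable, flow.n_applicable,
                flow.n_incomplete, flow.n_scoreable) == (2, 1, 1, 0, 1)

    def test_incomplete_documentation_excluded(self):
        records = [
            rec(1, IncidentCategory.FIRE, FULL_EVENTS),
            rec(2, IncidentCategory.FIRE,
                [DecisionEvent(DecisionKind.DECLARE_MAJOR_INCIDENT, None)]),
        ]
        flow, matrix = build_cohort(records)
        assert flow.n_incomplete == 1 and flow.n_scoreable == 1
        assert matrix.incident_ids == ("mi-1",)

    def test_zero_scoreable_names_stage(self):
        with pytest.raises(ValueError, match="applicability"):
            build_cohort([rec(1, IncidentCategory.WEATHER_ALERT)])
        with pytest.raises(ValueError, match="completeness"):
            build_cohort(
                [rec(1, IncidentCategory.FIRE,
                     [DecisionEvent(DecisionKind.DECLARE_MAJOR_INCIDENT, None)])]
            )

    def test_duplicate_ids_rejected(self):
        records = [rec(1, IncidentCategory.FIRE), rec(1, IncidentCategory.FIRE)]
        with pytest.raises(ValueError, match="unique"):
            build_cohort(records)

    @pytest.mark.parametrize("seed", [3, 17, 91])
    def test_flow_conservation_on_generated_cohorts(self, seed):
        cfg = SyntheticConfig(
            n_incidents=40,
            indicator_models=calibration_preset().indicator_models,
            p_incomplete=0.3,
        )
        records = generate_cohort(cfg, seed=seed)
        flow, matrix = build_cohort(records)
        assert flow.n_total == flow.n_not_applicable + flow.n_applicable
        assert flow.n_applicable == flow.n_incomplete + flow.n_scoreable
        assert matrix.cells.shape == (flow.n_scoreable, 11)

    def test_filter_order_independence(self):
        """Applicability and completeness are independent predicates."""
        cfg = SyntheticConfig(
            n_incidents=60,
            indicator_models=calibration_preset().indicator_models,
            p_incomplete=0.4,
        )
        records = generate_cohort(cfg, seed=5)
        flow, _ = build_cohort(records)
        # completeness applied first, applicability second
        from incidentqc.rubric import score_incident

        complete = [r for r in records if score_incident(r).complete]
        survivors = [r for r in complete if classify_applicability(r)[0]]
        assert len(survivors) == flow.n_scoreable

    def test_flow_invariant_enforced(self):
        with pytest.raises(ValueError):
            CohortFlow(10, 3, 8, 2, 6)


class TestDescriptiveSummary:
    def test_median_and_cutoff(self):
        records = [
            rec(i, IncidentCategory.FIRE, active_minutes=m)
            for i, m in enumerate([30, 60, 90])
        ]
        s = descriptive_summary(records)
        assert s.duration_median_minutes == 60
        assert s.frac_leq_4h == 1.0

    def test_four_hour_cutoff_is_240_inclusive(self):
        records = [
            rec(i, IncidentCategory.FIRE, active_minutes=m)
            for i, m in enumerate([60, 120, 300])
        ]
        assert descriptive_summary(records).frac_leq_4h == pytest.approx(2 / 3)
        records = [rec(9, IncidentCategory.FIRE, active_minutes=240.0)]
        assert descriptive_summary(records).frac_leq_4h == 1.0

    def test_staffing_and_category_counts_sum_to_total(self):
        records = [
            rec(1, IncidentCategory.FIRE, staffing_extent=StaffingExtent.DDO_ONLY),
            rec(2, IncidentCategory.FIRE, staffing_extent=StaffingExtent.DDO_ONLY),
            rec(3, IncidentCategory.THREAT,
                staffing_extent=StaffingExtent.FULL_MANAGEMENT_GROUP),
        ]
        s = descriptive_summary(records)
        assert s.staffing_counts[StaffingExtent.DDO_ONLY] == 2
        assert s.staffing_counts[StaffingExtent.FULL_MANAGEMENT_GROUP] == 1
        assert sum(s.staffing_counts.values()) == 3
        assert sum(s.category_counts.values()) == 3

    def test_casualty_and_hospital_tallies(self):
        records = [
            rec(1, IncidentCategory.FIRE, casualties=10, receiving_hospitals=2,
                hospital_plan_activated=True),
            rec(2, IncidentCategory.FIRE, casualties=5, receiving_hospitals=1,
                hospital_plan_activated=False),
        ]
        s = descriptive_summary(records)
        assert s.casualty_total == 15
        assert s.n_multi_hospital == 1
        assert s.n_hospital_plan == 1

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            descriptive_summary([])
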