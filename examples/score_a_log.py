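"""Parse a small hand-written incident log and score it against the rubric.

Builds a two-incident JSON-lines log in memory, parses it, and prints the
0/1/2 score each command decision earns against its time standard.
"""

from incidentqc import builtin_rubric, score_incident
from incidentqc.io import loads_jsonl

LOG = """\
{"incident_id": "mi-A", "category": "accident", "alert_time": "2008-03-01T10:00:00+00:00", "events": [{"kind": "declare_major_incident", "time": "2008-03-01T10:00:30+00:00"}, {"kind": "set_staff_alert_level", "minutes": 2.0}, {"kind": "designate_receiving_hospitals", "minutes": 7.0}, {"kind": "contact_scene_command", "minutes": 9.0}], "staffing_extent": "ddo_plus_regional_mo", "active_minutes": 90, "casualties": 12, "receiving_hospitals": 2}
{"incident_id": "mi-B", "category": "fire", "events": [{"kind": "declare_major_incident", "minutes": 0.8}, {"kind": "first_media_information", "minutes": 45.0}], "staffing_extent": "ddo_only", "active_minutes": 45}
"""

records = loads_jsonl(LOG)
rubric = builtin_rubric()

for record in records:
    vec = score_incident(record, rubric)
    print(f"\nincident {record.incident_id} ({record.category.value}):")
    for score, d in zip(vec.scores, rubric):
        where = "-" if score.elapsed is None else f"{score.elapsed:5.1f} min"
        print(
            f"  {d.id:>2}. {d.label:<55} std {d.standard_minutes:>4.0f} min"
            f"  at {where:>9}  -> {score.value}"
        )
    total = sum(s.value for s in vec.scores)
    print(f"  total score {total}/22 "
          "(2 = decision on time, 1 = made late, 0 = never documented)")
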