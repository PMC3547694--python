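"""Replicate the study case flow on the 130-incident fixture cohort.

Generates the flow-replica preset (130 incidents: 28 adjudicated not
applicable, 36 with incomplete documentation), applies both cohort
filters, and prints the surviving counts plus the met / not-met split of
all 726 indicator scores.
"""

from incidentqc import aggregate_scores, build_cohort, generate_cohort, percent
from incidentqc.simulate import flow_replica_preset

records = generate_cohort(flow_replica_preset())
flow, matrix = build_cohort(records)

print("case flow:")
print(f"  declared major incidents        {flow.n_total}")
print(f"  indicator set not applicable    {flow.n_not_applicable}"
      f"  ({percent(flow.n_not_applicable, flow.n_total)}%)")
print(f"  applicable                      {flow.n_applicable}"
      f"  ({percent(flow.n_applicable, flow.n_total)}%)")
print(f"  incomplete documentation        {flow.n_incomplete}")
print(f"  scoreable cohort                {flow.n_scoreable}")

agg = aggregate_scores(matrix)
print(f"\nindicator scores collected: {agg.n_cells} "
      f"({agg.n_incidents} incidents x 11 indicators)")
print(f"  met completely or partly (1-2): {agg.n_met} "
      f"({percent(agg.n_met, agg.n_cells)}%)")
print(f"  not met at all (0):             {agg.n_not_met} "
      f"({percent(agg.n_not_met, agg.n_cells)}%)")
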