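"""End-to-end pipeline: load or simulate a cohort, score, filter, compare,
and write a report bundle.

The bundle mirrors the shape of a published quality-control analysis:
the case-flow counts, the descriptive summary, a per-indicator table
(mean score against each time standard), the met / not-met split with
percentages, the blocked ANOVA table, the Tukey pairwise comparisons and
the underline display of indicator groups.  Percentages are printed as
round-half-up integers and are always recomputable from the numerator
and denominator emitted alongside them.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import io as logio
from .cohort import (
    CohortFlow,
    ScoreMatrix,
    build_cohort,
    case_flow_decisions,
    descriptive_summary,
)
from .inference import TukeyResult, rcb_anova, tukey_hsd, underline_display
from .model import IncidentRecord
from .rubric import (
    AggregateScores,
    IndicatorDefinition,
    aggregate_scores,
    builtin_rubric,
    load_rubric,
)
from .simulate import flow_replica_preset, generate_cohort, calibration_preset

PRESETS = {"calibration": calibration_preset, "flow": flow_replica_preset}


def percent(numerator: float, denominator: float) -> int:
    """Integer percentage, round-half-up (so 102/130 -> 78, 446/726 -> 61)."""
    if denominator == 0:
        raise ZeroDivisionError("percentage of an empty denominator")
    frac = Decimal(numerator) * 100 / Decimal(denominator)
    return int(frac.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run."""

    inputs: tuple[str, ...] = ()
    preset: str | None = None
    rubric_path: str | None = None
    alpha: float = 0.05
    out_dir: str = "reports"
    seed: int | None = None
    fmt: str = "csv"  # "csv" or "json" for tabular outputs

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie strictly between 0 and 1")
        if bool(self.inputs) == (self.preset is not None):
            raise ValueError("give exactly one of --input or --preset")
        if self.preset is not None and self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}; choose from {sorted(PRESETS)}")
        if self.fmt not in ("csv", "json"):
            raise ValueError("format must be 'csv' or 'json'")


def indicator_table(
    matrix: ScoreMatrix,
    rubric: Sequence[IndicatorDefinition],
    agg: AggregateScores | None = None,
) -> pd.DataFrame:
    """Per-indicator report table: label, standard, mean score, score counts."""
    agg = agg if agg is not None else aggregate_scores(matrix)
    by_id = {d.id: d for d in rubric}
    rows = []
    for col, ind_id in enumerate(matrix.indicator_ids):
        d = by_id[ind_id]
        col_scores = matrix.cells[:, col]
        rows.append(
            {
                "indicator_id": ind_id,
                "label": d.label,
                "standard_minutes": d.standard_minutes,
                "mean_score": float(agg.means[col]),
                "n_score_0": int((col_scores == 0).sum()),
                "n_score_1": int((col_scores == 1).sum()),
                "n_score_2": int((col_scores == 2).sum()),
            }
        )
    return pd.DataFrame(rows)


def _write_table(frame: pd.DataFrame, path_base: Path, fmt: str) -> Path:
    if fmt == "json":
        path = path_base.with_suffix(".json")
        frame.to_json(path, orient="records", indent=2)
    else:
        path = path_base.with_suffix(".csv")
        frame.to_csv(path, index=False)
    return path


@dataclass(frozen=True)
class ReportBundle:
    """Computed results plus the paths of everything written."""

    records: list[IncidentRecord]
    flow: CohortFlow
    matrix: ScoreMatrix
    aggregate: AggregateScores
    tukey: TukeyResult
    paths: dict[str, Path]


def load_records(config: RunConfig) -> list[IncidentRecord]:
    if config.preset is not None:
        preset_cfg = PRESETS[config.preset]()
        return generate_cohort(preset_cfg, seed=config.seed)
    records: list[IncidentRecord] = []
    for path in config.inputs:
        records.extend(logio.read_log(path))
    return records


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Run the full analysis and write the report bundle to ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rubric = (
        load_rubric(config.rubric_path)
        if config.rubric_path is not None
        else builtin_rubric()
    )

    records = load_records(config)
    if config.preset is not None:
        logio.write_jsonl(records, out / "cohort.jsonl")

    decisions, _ = case_flow_decisions(records, rubric)
    flow, matrix = build_cohort(records, rubric)
    summary = descriptive_summary(records)
    agg = aggregate_scores(matrix)
    anova = rcb_anova(matrix)
    tukey = tukey_hsd(matrix, alpha=config.alpha)

    paths: dict[str, Path] = {}
    with open(out / "filter_log.jsonl", "w", encoding="utf-8") as fh:
        for d in decisions:
            fh.write(json.dumps(dataclasses.asdict(d)) + "\n")
    paths["filter_log"] = out / "filter_log.jsonl"

    flow_doc = flow.as_dict() | {
        "pct_applicable": percent(flow.n_applicable, flow.n_total),
        "pct_not_applicable": percent(flow.n_not_applicable, flow.n_total),
    }
    (out / "cohort_flow.json").write_text(json.dumps(flow_doc, indent=2))
    paths["cohort_flow"] = out / "cohort_flow.json"

    summary_doc = summary.as_dict() | {
        "pct_leq_4h": percent(round(summary.frac_leq_4h * len(records)), len(records)),
        "n_incidents": len(records),
    }
    (out / "descriptive_summary.json").write_text(json.dumps(summary_doc, indent=2))
    paths["descriptive_summary"] = out / "descriptive_summary.json"

    paths["indicator_table"] = _write_table(
        indicator_table(matrix, rubric, agg), out / "indicator_table", config.fmt
    )

    met_doc = {
        "n_indicator_scores": agg.n_cells,
        "n_incidents": agg.n_incidents,
        "n_met_completely_or_partly": agg.n_met,
        "pct_met_completely_or_partly": percent(agg.n_met, agg.n_cells),
        "n_not_met": agg.n_not_met,
        "pct_not_met": percent(agg.n_not_met, agg.n_cells),
    }
    (out / "met_summary.json").write_text(json.dumps(met_doc, indent=2))
    paths["met_summary"] = out / "met_summary.json"

    paths["anova"] = _write_table(
        anova.to_frame().reset_index(), out / "anova", config.fmt
    )
    paths["tukey_pairs"] = _write_table(tukey.pairs, out / "tukey_pairs", config.fmt)

    (out / "indicator_groups.txt").write_text(underline_display(tukey) + "\n")
    paths["indicator_groups"] = out / "indicator_groups.txt"

    return ReportBundle(
        records=records,
        flow=flow,
        matrix=matrix,
        aggregate=agg,
        tukey=tukey,
        paths=paths,
    )
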