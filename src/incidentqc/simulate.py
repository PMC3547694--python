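"""Seeded generator of synthetic incident cohorts.

No real command-and-control logs are distributed with this package, so
analyses are exercised on synthetic cohorts whose statistical structure
matches the published summary of the real material:

* a nine-category incident mix (default: the published classification of
  130 incidents),
* per-indicator score distributions, parameterised either directly as
  ``(p0, p1, p2)`` or by a target mean and a "late share" (the fraction
  of met decisions that were late), inverted exactly by
  :func:`mean_matched_distribution`,
* decision latencies drawn so that re-scoring a generated record always
  recovers the drawn score: an on-time decision (score 2) is uniform on
  ``[0, standard)``, a late decision (score 1) is
  ``standard * (1 + Exponential(1))``, strictly beyond the standard,
* an under-documentation mechanism (one decision recorded without a
  usable timestamp) that makes a record incomplete, either at a fixed
  probability or as an exact per-cohort count,
* log-normal activation durations (default median 60 min, with spread
  calibrated so about 75% of incidents close within 4 h).

Randomness is a single integer seed; each record consumes an independent
substream derived from the seed and the record's index, so cohorts are
reproducible and stable under record reordering.
"""

from __future__ import annotations

import datetime
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .cohort import APPLICABLE_CATEGORIES
from .model import (
    DecisionEvent,
    IncidentCategory,
    IncidentRecord,
    StaffingExtent,
)
from .rubric import IndicatorDefinition, builtin_rubric

#: Published mean scores used as generator calibration targets, by indicator id.
PUBLISHED_MEAN_SCORES: dict[int, float] = {
    1: 1.48, 2: 1.41, 3: 1.32, 4: 1.63, 5: 1.53,
    6: 0.86, 7: 0.75, 8: 0.18, 9: 0.93, 10: 0.03, 11: 0.97,
}

#: Published classification of 130 major incidents, by category.
PUBLISHED_CATEGORY_COUNTS: dict[IncidentCategory, int] = {
    IncidentCategory.ACCIDENT: 48,
    IncidentCategory.THREAT: 37,
    IncidentCategory.FIRE: 23,
    IncidentCategory.HOSPITAL_INFRASTRUCTURE: 15,
    IncidentCategory.CBRNE: 2,
    IncidentCategory.INFECTIOUS: 2,
    IncidentCategory.WEATHER_ALERT: 1,
    IncidentCategory.SUPPORT_OTHER_REGION: 1,
    IncidentCategory.INCIDENT_ABROAD: 1,
}

#: Staffing-extent counts over the 130 incidents (DDO alone, +regional MO,
#: +staff functions, full management group).
STAFFING_COUNTS: dict[StaffingExtent, int] = {
    StaffingExtent.DDO_ONLY: 50,
    StaffingExtent.DDO_PLUS_REGIONAL_MO: 36,
    StaffingExtent.PLUS_STAFF_FUNCTIONS: 34,
    StaffingExtent.FULL_MANAGEMENT_GROUP: 10,
}

#: Log-normal spread of activation durations: with median 60 min this puts
#: 75% of incidents at or under 4 h, matching the published 98/130.
DEFAULT_DURATION_SIGMA = math.log(4.0) / 0.6744897501960817

_EPOCH = datetime.datetime(2006, 1, 1, tzinfo=datetime.timezone.utc)


def mean_matched_distribution(m: float, late_share: float) -> tuple[float, float, float]:
    """Invert a target mean score into a ``(p0, p1, p2)`` distribution.

    With ``p_met`` the probability the decision is made at all and
    ``late_share`` the fraction of made decisions that are late, the
    expected score is ``p1 + 2 p2 = (2 - late_share) * p_met``; solving
    for ``p_met = m / (2 - late_share)`` matches the mean exactly.
    Feasible only for ``0 <= m <= 2 - late_share``.
    """
    if not 0.0 <= late_share <= 1.0:
        raise ValueError("late_share must lie in [0, 1]")
    if m < 0.0 or m > 2.0 - late_share:
        raise ValueError(
            f"target mean {m} infeasible for late_share {late_share} "
            f"(needs 0 <= m <= {2.0 - late_share})"
        )
    p_met = m / (2.0 - late_share)
    p1 = late_share * p_met
    p2 = (1.0 - late_share) * p_met
    return (1.0 - p_met, p1, p2)


@dataclass(frozen=True)
class IndicatorModel:
    """Score distribution for one indicator in the generator."""

    indicator_id: int
    p0: float
    p1: float
    p2: float

    def __post_init__(self) -> None:
        probs = (self.p0, self.p1, self.p2)
        if any(p < -1e-12 or p > 1 + 1e-12 for p in probs):
            raise ValueError(f"indicator {self.indicator_id}: probabilities not in [0,1]")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError(
                f"indicator {self.indicator_id}: probabilities must sum to 1"
            )

    @property
    def mean_score(self) -> float:
        return self.p1 + 2.0 * self.p2

    @classmethod
    def mean_matched(
        cls, indicator_id: int, target_mean: float, late_share: float = 0.3
    ) -> "IndicatorModel":
        p0, p1, p2 = mean_matched_distribution(target_mean, late_share)
        return cls(indicator_id, p0, p1, p2)


@dataclass(frozen=True)
class SyntheticConfig:
    """Full description of one synthetic cohort's generating process.

    ``category_mix`` maps categories to exact integer counts (summing to
    ``n_incidents``) or to probabilities (summing to 1).  The preset
    fields reproduce study-flow fixtures exactly: when
    ``explicit_applicability_flags`` is set, every record in a
    non-applicable category plus ``n_extra_not_applicable`` applicable-
    category records carry an explicit not-applicable override, and
    ``n_forced_incomplete`` applicable records (an exact count, not a
    probability) are made under-documented.
    """

    n_incidents: int
    category_mix: dict[IncidentCategory, float] = field(
        default_factory=lambda: {
            c: n / sum(PUBLISHED_CATEGORY_COUNTS.values())
            for c, n in PUBLISHED_CATEGORY_COUNTS.items()
        }
    )
    indicator_models: tuple[IndicatorModel, ...] = ()
    p_incomplete: float = 0.0
    duration_median_minutes: float = 60.0
    duration_sigma: float = DEFAULT_DURATION_SIGMA
    seed: int = 0
    explicit_applicability_flags: bool = False
    n_extra_not_applicable: int = 0
    n_forced_incomplete: int | None = None

    def __post_init__(self) -> None:
        if self.n_incidents <= 0:
            raise ValueError("n_incidents must be positive")
        if not 0.0 <= self.p_incomplete <= 1.0:
            raise ValueError("p_incomplete must lie in [0, 1]")
        if self.duration_median_minutes <= 0 or self.duration_sigma <= 0:
            raise ValueError("duration law parameters must be positive")
        if len(self.indicator_models) != 11 or sorted(
            m.indicator_id for m in self.indicator_models
        ) != list(range(1, 12)):
            raise ValueError("need 11 indicator models with ids 1..11")
        vals = list(self.category_mix.values())
        if any(v < 0 for v in vals):
            raise ValueError("category mix entries must be non-negative")
        if all(float(v).is_integer() for v in vals):
            if int(sum(vals)) != self.n_incidents:
                raise ValueError("integer category counts must sum to n_incidents")
        elif abs(sum(vals) - 1.0) > 1e-9:
            raise ValueError("category probabilities must sum to 1")

    # -- JSON round-trip -------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        obj = {
            "n_incidents": self.n_incidents,
            "category_mix": {c.value: v for c, v in self.category_mix.items()},
            "indicator_models": [
                {"indicator_id": m.indicator_id, "p0": m.p0, "p1": m.p1, "p2": m.p2}
                for m in self.indicator_models
            ],
            "p_incomplete": self.p_incomplete,
            "duration_median_minutes": self.duration_median_minutes,
            "duration_sigma": self.duration_sigma,
            "seed": self.seed,
            "explicit_applicability_flags": self.explicit_applicability_flags,
            "n_extra_not_applicable": self.n_extra_not_applicable,
            "n_forced_incomplete": self.n_forced_incomplete,
        }
        text = json.dumps(obj, indent=2)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SyntheticConfig":
        text = (
            Path(source).read_text(encoding="utf-8")
            if isinstance(source, Path) or "\n" not in str(source) and Path(source).exists()
            else str(source)
        )
        obj = json.loads(text)
        return cls(
            n_incidents=obj["n_incidents"],
            category_mix={
                IncidentCategory(k): v for k, v in obj["category_mix"].items()
            },
            indicator_models=tuple(
                IndicatorModel(
                    m["indicator_id"], m["p0"], m["p1"], m["p2"]
                )
                for m in obj["indicator_models"]
            ),
            p_incomplete=obj.get("p_incomplete", 0.0),
            duration_median_minutes=obj.get("duration_median_minutes", 60.0),
            duration_sigma=obj.get("duration_sigma", DEFAULT_DURATION_SIGMA),
            seed=obj.get("seed", 0),
            explicit_applicability_flags=obj.get("explicit_applicability_flags", False),
            n_extra_not_applicable=obj.get("n_extra_not_applicable", 0),
            n_forced_incomplete=obj.get("n_forced_incomplete"),
        )


def _calibrated_models(late_share: float = 0.3) -> tuple[IndicatorModel, ...]:
    return tuple(
        IndicatorModel.mean_matched(i, PUBLISHED_MEAN_SCORES[i], late_share)
        for i in range(1, 12)
    )


def _largest_remainder(counts: dict, total: int) -> dict:
    """Scale integer counts to a new total, preserving proportions."""
    keys = list(counts)
    weights = np.array([counts[k] for k in keys], dtype=float)
    quotas = weights / weights.sum() * total
    base = np.floor(quotas).astype(int)
    short = total - int(base.sum())
    order = np.argsort(-(quotas - base), kind="stable")
    for idx in order[:short]:
        base[idx] += 1
    return {k: int(b) for k, b in zip(keys, base)}


def calibration_preset(late_share: float = 0.3, seed: int = 20120817) -> SyntheticConfig:
    """A 66-incident fully documented cohort calibrated to the published
    per-indicator mean scores.

    All incidents fall in applicable categories (the published applicable
    mix scaled to 66 by largest remainder) and no record is
    under-documented, so every generated incident is scoreable.
    """
    applicable = {
        c: PUBLISHED_CATEGORY_COUNTS[c]
        for c in (
            IncidentCategory.ACCIDENT,
            IncidentCategory.THREAT,
            IncidentCategory.FIRE,
            IncidentCategory.CBRNE,
        )
    }
    return SyntheticConfig(
        n_incidents=66,
        category_mix=_largest_remainder(applicable, 66),
        indicator_models=_calibrated_models(late_share),
        p_incomplete=0.0,
        seed=seed,
    )


def flow_replica_preset(late_share: float = 0.3, seed: int = 20120817) -> SyntheticConfig:
    """The 130-incident study-flow replica fixture.

    Produces exactly 130 records of which 28 carry an explicit
    not-applicable override (all 20 records in non-applicable categories
    plus 8 applicable-category records, mirroring case-by-case
    adjudication) and 36 applicable records are forced under-documented,
    leaving 66 scoreable.  The flow counts are exact, not stochastic.
    """
    return SyntheticConfig(
        n_incidents=130,
        category_mix=dict(PUBLISHED_CATEGORY_COUNTS),
        indicator_models=_calibrated_models(late_share),
        p_incomplete=0.0,
        seed=seed,
        explicit_applicability_flags=True,
        n_extra_not_applicable=8,
        n_forced_incomplete=36,
    )


def _assign_categories(
    config: SyntheticConfig, rng: np.random.Generator
) -> list[IncidentCategory]:
    vals = list(config.category_mix.values())
    cats = list(config.category_mix.keys())
    if all(float(v).is_integer() for v in vals):
        out: list[IncidentCategory] = []
        for c, n in config.category_mix.items():
            out.extend([c] * int(n))
        return out
    probs = np.array(vals, dtype=float)
    draws = rng.choice(len(cats), size=config.n_incidents, p=probs / probs.sum())
    return [cats[i] for i in draws]


_STAFF_LEVELS = list(STAFFING_COUNTS)
_STAFF_PROBS = np.array([STAFFING_COUNTS[s] for s in _STAFF_LEVELS], dtype=float)
_STAFF_PROBS /= _STAFF_PROBS.sum()


def _draw_events(
    rng: np.random.Generator,
    models: Sequence[IndicatorModel],
    rubric: Sequence[IndicatorDefinition],
) -> list[DecisionEvent]:
    by_id = {d.id: d for d in rubric}
    events: list[DecisionEvent] = []
    for model in sorted(models, key=lambda m: m.indicator_id):
        defn = by_id[model.indicator_id]
        score = int(rng.choice(3, p=(model.p0, model.p1, model.p2)))
        if score == 0:
            continue
        if score == 2:
            minutes = float(rng.uniform(0.0, defn.standard_minutes))
        else:
            excess = float(rng.exponential(1.0))
            while excess == 0.0:  # keep strictly beyond the standard
                excess = float(rng.exponential(1.0))
            minutes = defn.standard_minutes * (1.0 + excess)
        events.append(DecisionEvent(kind=defn.kind, minutes=minutes))
    return events


def _make_incomplete(record: IncidentRecord) -> None:
    """Strip the timestamp from one decision (documented but untimed)."""
    if record.events:
        ev = record.events[0]
        record.events[0] = DecisionEvent(kind=ev.kind, minutes=None, note=ev.note)
    else:
        record.events.append(
            DecisionEvent(
                kind=builtin_rubric()[0].kind,
                minutes=None,
                note="decision noted without time",
            )
        )


def generate_cohort(
    config: SyntheticConfig, seed: int | None = None
) -> list[IncidentRecord]:
    """Draw a full cohort of incident records from a generator config.

    ``seed`` overrides ``config.seed``.  Each record is drawn from its own
    substream keyed by the record index, so a fixed seed yields an
    identical cohort regardless of how the list is later reordered.
    """
    root_seed = config.seed if seed is None else seed
    rubric = builtin_rubric()
    cat_rng = np.random.Generator(
        np.random.PCG64(np.random.SeedSequence(root_seed, spawn_key=(0xC0DE,)))
    )
    categories = _assign_categories(config, cat_rng)

    # resolve the explicit-flag plan before any per-record draw
    override_flags: dict[int, bool] = {}
    forced_incomplete: set[int] = set()
    applicable_idx = [
        i for i, c in enumerate(categories) if c in APPLICABLE_CATEGORIES
    ]
    if config.explicit_applicability_flags:
        extra = applicable_idx[-config.n_extra_not_applicable:] if config.n_extra_not_applicable else []
        for i, c in enumerate(categories):
            if c not in APPLICABLE_CATEGORIES or i in set(extra):
                override_flags[i] = False
        applicable_idx = [i for i in applicable_idx if i not in override_flags]
    if config.n_forced_incomplete is not None:
        if config.n_forced_incomplete > len(applicable_idx):
            raise ValueError("n_forced_incomplete exceeds applicable record count")
        forced_incomplete = set(applicable_idx[: config.n_forced_incomplete])

    width = len(str(config.n_incidents))
    records: list[IncidentRecord] = []
    for i, category in enumerate(categories):
        rng = np.random.Generator(
            np.random.PCG64(np.random.SeedSequence(root_seed, spawn_key=(i,)))
        )
        applicable = override_flags.get(
            i, category in APPLICABLE_CATEGORIES
        )
        events = _draw_events(rng, config.indicator_models, rubric)
        duration = float(
            rng.lognormal(math.log(config.duration_median_minutes), config.duration_sigma)
        )
        casualties = None
        hospitals = None
        plan = None
        if applicable:
            casualties = int(
                np.clip(round(rng.lognormal(math.log(7.0), 1.1)), 3, 135)
            )
            multi = rng.random() < 35.0 / 130.0
            hospitals = int(2 + rng.poisson(0.7)) if multi else 1
            plan = bool(rng.random() < 15.0 / 130.0)
        record = IncidentRecord(
            incident_id=f"mi-{i + 1:0{width}d}",
            category=category,
            alert_time=_EPOCH + datetime.timedelta(days=11 * i, minutes=int(rng.integers(0, 1440))),
            events=events,
            staffing_extent=_STAFF_LEVELS[
                int(rng.choice(len(_STAFF_LEVELS), p=_STAFF_PROBS))
            ],
            active_minutes=round(duration, 1),
            casualties=casualties,
            receiving_hospitals=hospitals,
            hospital_plan_activated=plan,
            applicable_override=override_flags.get(i),
        )
        if i in forced_incomplete or (
            config.n_forced_incomplete is None
            and config.p_incomplete > 0.0
            and rng.random() < config.p_incomplete
        ):
            _make_incomplete(record)
        records.append(record)
    return records
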