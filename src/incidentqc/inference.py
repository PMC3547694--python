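"""Randomized-complete-block ANOVA and Tukey HSD for indicator comparison.

The scored cohort is a complete two-way layout with one observation per
cell: incidents are blocks (b rows), indicators are treatments
(a columns).  The additive model

    y_ij = mu + tau_j + beta_i + eps_ij

gives the standard decomposition SS_total = SS_treatment + SS_block +
SS_error with degrees of freedom a-1, b-1 and (a-1)(b-1).  Because no
cell is replicated there is no interaction term; block variation between
incidents (some incidents are handled well across the board, some badly)
is removed from the error before indicators are compared.

Pairwise treatment comparisons use Tukey's honestly-significant-
difference procedure: with equal replication b per treatment the single
threshold ``HSD = q_{1-alpha, a, (a-1)(b-1)} * sqrt(MS_error / b)``
controls the familywise error rate over all a(a-1)/2 comparisons, and
an adjusted p-value per pair follows from the studentized range
distribution of |mean difference| / sqrt(MS_error / b).

Because the threshold is one constant, non-significance is an interval
property of the sorted means, so the familiar "underlining" display is
exact: every maximal contiguous run of sorted means whose range is at
most the HSD forms one line, and two treatments are non-significantly
different if and only if they share a line.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import ScoreMatrix

__all__ = [
    "AnovaTable",
    "TukeyResult",
    "rcb_anova",
    "studentized_range_quantile",
    "tukey_hsd",
    "line_grouping",
    "underline_display",
]


@dataclass(frozen=True)
class AnovaTable:
    """Two-way ANOVA table for a randomized complete block design."""

    ss_treatment: float
    df_treatment: int
    ms_treatment: float
    f_treatment: float
    p_treatment: float
    ss_block: float
    df_block: int
    ms_block: float
    f_block: float
    p_block: float
    ss_error: float
    df_error: int
    ms_error: float
    ss_total: float
    df_total: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("treatment", self.ss_treatment, self.df_treatment, self.ms_treatment,
             self.f_treatment, self.p_treatment),
            ("block", self.ss_block, self.df_block, self.ms_block,
             self.f_block, self.p_block),
            ("error", self.ss_error, self.df_error, self.ms_error,
             math.nan, math.nan),
            ("total", self.ss_total, self.df_total, math.nan, math.nan, math.nan),
        ]
        return pd.DataFrame(
            rows, columns=["source", "sum_sq", "df", "mean_sq", "F", "p"]
        ).set_index("source")


def _as_cells(matrix: ScoreMatrix | np.ndarray) -> np.ndarray:
    if isinstance(matrix, ScoreMatrix):
        return np.asarray(matrix.cells, dtype=float)
    return np.asarray(matrix, dtype=float)


def _treatment_labels(matrix: ScoreMatrix | np.ndarray, a: int) -> list:
    if isinstance(matrix, ScoreMatrix):
        return list(matrix.indicator_ids)
    return list(range(a))


def rcb_anova(matrix: ScoreMatrix | np.ndarray) -> AnovaTable:
    """Two-way ANOVA with one observation per cell (blocks x treatments).

    Rows of ``matrix`` are blocks (incidents), columns are treatments
    (indicators).  Requires at least 2 rows and 2 columns.
    """
    y = _as_cells(matrix)
    if y.ndim != 2:
        raise ValueError("matrix must be 2-D (blocks x treatments)")
    b, a = y.shape
    if a < 2 or b < 2:
        raise ValueError("need at least 2 treatments and 2 blocks")

    grand = y.mean()
    col_means = y.mean(axis=0)
    row_means = y.mean(axis=1)

    ss_treat = b * float(((col_means - grand) ** 2).sum())
    ss_block = a * float(((row_means - grand) ** 2).sum())
    ss_total = float(((y - grand) ** 2).sum())
    ss_error = ss_total - ss_treat - ss_block
    # additive decomposition can go a hair negative through roundoff
    if ss_error < 0:
        ss_error = max(ss_error, -1e-9 * max(ss_total, 1.0))
        ss_error = max(ss_error, 0.0)

    df_treat, df_block = a - 1, b - 1
    df_error = df_treat * df_block
    ms_treat = ss_treat / df_treat
    ms_block = ss_block / df_block
    ms_error = ss_error / df_error

    if ms_error == 0.0:
        warnings.warn(
            "zero error variance: F and p reported as exact limits", stacklevel=2
        )
        f_treat = math.inf if ms_treat > 0 else 0.0
        f_block = math.inf if ms_block > 0 else 0.0
        p_treat = 0.0 if ms_treat > 0 else 1.0
        p_block = 0.0 if ms_block > 0 else 1.0
    else:
        f_treat = ms_treat / ms_error
        f_block = ms_block / ms_error
        p_treat = float(stats.f.sf(f_treat, df_treat, df_error))
        p_block = float(stats.f.sf(f_block, df_block, df_error))

    return AnovaTable(
        ss_treatment=ss_treat, df_treatment=df_treat, ms_treatment=ms_treat,
        f_treatment=f_treat, p_treatment=p_treat,
        ss_block=ss_block, df_block=df_block, ms_block=ms_block,
        f_block=f_block, p_block=p_block,
        ss_error=ss_error, df_error=df_error, ms_error=ms_error,
        ss_total=ss_total, df_total=a * b - 1,
    )


def studentized_range_quantile(p: float, k: int, df: float) -> float:
    """Quantile of the studentized range distribution of ``k`` means.

    ``q`` such that P(Q <= q) = p for the range of ``k`` independent
    standard-normal means divided by an independent chi estimate of the
    standard error on ``df`` degrees of freedom.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie strictly between 0 and 1")
    if k < 2:
        raise ValueError("k must be >= 2")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(stats.studentized_range.ppf(p, k, df))


@dataclass(frozen=True)
class TukeyResult:
    """All-pairs Tukey HSD comparison of the treatment (indicator) means."""

    alpha: float
    q_critical: float
    hsd: float
    means: pd.Series  # treatment label -> mean
    pairs: pd.DataFrame  # one row per unordered pair
    groups: list[tuple]  # underline groups, each a tuple of treatment labels


def tukey_hsd(
    matrix: ScoreMatrix | np.ndarray, alpha: float = 0.05
) -> TukeyResult:
    """Tukey HSD over treatment columns of a complete blocked layout.

    Uses the blocked-design ``MS_error`` on ``(a-1)(b-1)`` degrees of
    freedom; with equal replication ``b`` per treatment a pair differs
    significantly iff its |mean difference| exceeds the HSD.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie strictly between 0 and 1")
    y = _as_cells(matrix)
    table = rcb_anova(y)
    b, a = y.shape
    labels = _treatment_labels(matrix, a)
    col_means = y.mean(axis=0)

    se = math.sqrt(table.ms_error / b)
    q_crit = studentized_range_quantile(1.0 - alpha, a, table.df_error)
    hsd = q_crit * se
    if table.ms_error == 0.0:
        warnings.warn(
            "zero error variance: every nonzero mean difference is flagged "
            "significant",
            stacklevel=2,
        )

    rows = []
    for i, j in itertools.combinations(range(a), 2):
        diff = col_means[j] - col_means[i]
        if se > 0:
            q_stat = abs(diff) / se
            p_adj = float(stats.studentized_range.sf(q_stat, a, table.df_error))
        else:
            q_stat = math.inf if diff != 0 else 0.0
            p_adj = 0.0 if diff != 0 else 1.0
        rows.append(
            {
                "treatment_i": labels[i],
                "treatment_j": labels[j],
                "mean_i": col_means[i],
                "mean_j": col_means[j],
                "mean_diff": diff,
                "q_stat": q_stat,
                "p_adj": min(p_adj, 1.0),
                "significant": abs(diff) > hsd,
            }
        )
    pairs = pd.DataFrame(rows)

    groups = line_grouping(col_means, hsd, labels=labels)
    return TukeyResult(
        alpha=alpha,
        q_critical=q_crit,
        hsd=hsd,
        means=pd.Series(col_means, index=labels, name="mean"),
        pairs=pairs,
        groups=groups,
    )


def line_grouping(
    means: Sequence[float], hsd: float, labels: Sequence | None = None
) -> list[tuple]:
    """Underline groups: maximal runs of sorted means spanning <= ``hsd``.

    Sorts the means ascending and emits every maximal contiguous run whose
    max - min is at most ``hsd``; each group is reported as a tuple of the
    original treatment labels in ascending-mean order.  Two treatments
    share a group iff their means do not differ significantly.
    """
    if hsd < 0:
        raise ValueError("hsd must be >= 0")
    means = np.asarray(means, dtype=float)
    n = means.size
    if labels is None:
        labels = list(range(n))
    if len(labels) != n:
        raise ValueError("labels must match means in length")
    order = np.argsort(means, kind="stable")
    sorted_means = means[order]

    # end(i) = furthest index reachable from i; nondecreasing in i, so a
    # run is maximal exactly when its end strictly exceeds the previous one
    runs: list[tuple[int, int]] = []  # [start, end] inclusive, in sorted order
    j = 0
    for i in range(n):
        j = max(j, i)
        while j + 1 < n and sorted_means[j + 1] - sorted_means[i] <= hsd:
            j += 1
        if not runs or j > runs[-1][1]:
            runs.append((i, j))
    groups = [tuple(labels[order[k]] for k in range(s, e + 1)) for s, e in runs]
    return groups


def underline_display(result: TukeyResult, width: int = 6) -> str:
    """Text rendering of the underline groups, means sorted ascending.

    Treatments on one line of dashes do not differ significantly.
    """
    order = result.means.sort_values(kind="stable")
    labels = list(order.index)
    header = "".join(f"{str(lab):>{width}}" for lab in labels)
    mean_row = "".join(f"{m:>{width}.2f}" for m in order.to_numpy())
    lines = [header, mean_row]
    pos = {lab: k for k, lab in enumerate(labels)}
    for grp in result.groups:
        cols = sorted(pos[lab] for lab in grp)
        lo, hi = cols[0], cols[-1]
        line = " " * (lo * width) + "-" * ((hi - lo + 1) * width)
        lines.append(line)
    return "\n".join(lines)
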