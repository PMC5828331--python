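"""Per-cell summaries and column aggregates for three-group competency surveys.

Each survey "cell" is one (item, group, dimension) combination; its summary
is the arithmetic mean of the available 1-9 scores, a dispersion estimate
(interquartile range by default, sample standard deviation as an option),
and the number of contributing respondents.  Column-level aggregates (the
overall mean across items, the extreme items, cross-group utility means,
response-rate arithmetic) operate on collections of these summaries, so
they work equally on summaries computed from respondent-level data and on
published group-level means.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .survey_model import (
    ALLOWED_PAIRS,
    LEARNER_GROUPS,
    Dimension,
    Group,
    ResponseSet,
)

__all__ = [
    "SummaryStat",
    "ColumnAggregate",
    "round_half_away",
    "cell_summary",
    "summarize",
    "column_mean",
    "column_extremes",
    "cross_group_mean",
    "response_rate",
    "scatter_export",
    "summary_frame",
]

DISPERSION_ESTIMATORS = ("iqr", "sd")


def round_half_away(x: float, ndigits: int) -> float:
    """Round with halves away from zero (report convention), not banker's."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SummaryStat:
    """One survey-table cell: mean (disp), n, for an (item, group, dimension).

    ``mean`` and ``dispersion`` are ``None`` when no respondent contributed
    (n = 0): an empty cell is flagged as undefined, never fabricated.
    """

    item_id: str
    group: Group
    dimension: Dimension
    mean: float | None
    dispersion: float | None
    n: int

    def __post_init__(self) -> None:
        if self.n == 0:
            if self.mean is not None:
                raise ValueError("n = 0 requires an undefined (None) mean")
        else:
            if self.mean is None or not (1.0 <= self.mean <= 9.0):
                raise ValueError(f"mean {self.mean!r} outside the 1-9 scale")
            if self.dispersion is not None and self.dispersion < 0:
                raise ValueError("dispersion must be >= 0")


@dataclass(frozen=True)
class ColumnAggregate:
    """Overall mean and extreme items of one group+dimension column."""

    group: Group
    dimension: Dimension
    overall_mean: float
    min_items: tuple[tuple[str, float], ...]
    max_items: tuple[tuple[str, float], ...]


def cell_summary(
    rs: ResponseSet,
    item_id: str,
    group: Group,
    dimension: Dimension,
    estimator: str = "iqr",
) -> SummaryStat:
    """Summarize one (item, group, dimension) cell of a response set.

    ``estimator`` selects the dispersion measure: ``"iqr"`` (Q3 - Q1, linear
    interpolation between order statistics) or ``"sd"`` (sample standard
    deviation, ddof = 1; undefined for n = 1).
    """
    if dimension not in ALLOWED_PAIRS[group]:
        raise ValueError(
            f"dimension {dimension.value!r} is not surveyed for group {group.value!r}"
        )
    if estimator not in DISPERSION_ESTIMATORS:
        raise ValueError(f"unknown dispersion estimator {estimator!r}")
    scores = np.asarray(rs.scores(item_id, group, dimension), dtype=float)
    if scores.size == 0:
        return SummaryStat(item_id, group, dimension, None, None, 0)
    mean = float(scores.mean())
    if estimator == "iqr":
        q1, q3 = np.percentile(scores, [25, 75], method="linear")
        disp: float | None = float(q3 - q1)
    else:
        disp = float(scores.std(ddof=1)) if scores.size > 1 else None
    return SummaryStat(item_id, group, dimension, mean, disp, int(scores.size))


def summarize(rs: ResponseSet, estimator: str = "iqr") -> list[SummaryStat]:
    """All cell summaries: every item crossed with every permitted pairing."""
    out = []
    for item_id in rs.items:
        for group in Group:
            for dim in sorted(ALLOWED_PAIRS[group], key=lambda d: d.value):
                out.append(cell_summary(rs, item_id, group, dim, estimator))
    return out


def _one_column(summaries: Sequence[SummaryStat]) -> tuple[Group, Dimension]:
    if not summaries:
        raise ValueError("empty summary collection")
    keys = {(s.group, s.dimension) for s in summaries}
    if len(keys) != 1:
        raise ValueError(f"summaries span multiple columns: {sorted(k[0].value + '/' + k[1].value for k in keys)}")
    return next(iter(keys))


def column_mean(summaries: Sequence[SummaryStat]) -> float:
    """Unweighted mean of per-item means for one group+dimension column, 2 d.p.

    Items are weighted equally regardless of per-cell n; this is the
    definition under which the published overall-mean row is reproducible
    from the printed cell means.
    """
    _one_column(summaries)
    means = [s.mean for s in summaries if s.mean is not None]
    if not means:
        raise ValueError("no defined cell means in column")
    return round_half_away(float(np.mean(means)), 2)


def column_extremes(summaries: Sequence[SummaryStat]) -> ColumnAggregate:
    """Items attaining the minimum and maximum mean; ties returned in full."""
    group, dim = _one_column(summaries)
    defined = [s for s in summaries if s.mean is not None]
    if not defined:
        raise ValueError("no defined cell means in column")
    lo = min(s.mean for s in defined)
    hi = max(s.mean for s in defined)
    min_items = tuple(
        (s.item_id, s.mean) for s in sorted(defined, key=lambda s: s.item_id) if s.mean == lo
    )
    max_items = tuple(
        (s.item_id, s.mean) for s in sorted(defined, key=lambda s: s.item_id) if s.mean == hi
    )
    overall = float(np.mean([s.mean for s in defined]))
    return ColumnAggregate(group, dim, overall, min_items, max_items)


def cross_group_mean(item_id: str, summaries: Iterable[SummaryStat]) -> float:
    """Unweighted mean of the three group means of one item's utility, 1 d.p."""
    per_group: dict[Group, float] = {}
    for s in summaries:
        if s.item_id != item_id or s.dimension is not Dimension.UTILITY:
            continue
        if s.mean is None:
            raise ValueError(f"undefined utility mean for {item_id!r} / {s.group.value}")
        per_group[s.group] = s.mean
    missing = [g.value for g in Group if g not in per_group]
    if missing:
        raise ValueError(f"item {item_id!r}: missing utility summary for group(s) {missing}")
    return round_half_away(float(np.mean([per_group[g] for g in Group])), 1)


def response_rate(invited: int, responded: int) -> float:
    """Percent of invited participants who responded, 1 d.p."""
    if invited <= 0:
        raise ValueError("invited must be > 0")
    if not 0 <= responded <= invited:
        raise ValueError("responded must lie in [0, invited]")
    return round_half_away(100.0 * responded / invited, 1)


def scatter_export(summaries: Sequence[SummaryStat]) -> pd.DataFrame:
    """Per-item (autonomy mean, utility mean) pairs for each learner group.

    This is the data behind the autonomy-vs-utility scatter view: one record
    per (item, learner group), values echoing the cell summaries exactly.
    """
    by_key = {(s.item_id, s.group, s.dimension): s for s in summaries}
    rows = []
    item_ids = list(dict.fromkeys(s.item_id for s in summaries))
    for group in LEARNER_GROUPS:
        for item_id in item_ids:
            a = by_key.get((item_id, group, Dimension.AUTONOMY))
            u = by_key.get((item_id, group, Dimension.UTILITY))
            if a is None or u is None:
                continue
            rows.append(
                {
                    "item_id": item_id,
                    "group": group.value,
                    "autonomy_mean": a.mean,
                    "utility_mean": u.mean,
                }
            )
    return pd.DataFrame(rows, columns=["item_id", "group", "autonomy_mean", "utility_mean"])


def summary_frame(summaries: Sequence[SummaryStat], rs: ResponseSet | None = None) -> pd.DataFrame:
    """Tabular view of cell summaries with per-column OVERALL rows appended."""
    rows = [
        {
            "item_id": s.item_id,
            "label": rs.items[s.item_id].label if rs and s.item_id in rs.items else s.item_id,
            "group": s.group.value,
            "dimension": s.dimension.value,
            "mean": None if s.mean is None else round_half_away(s.mean, 1),
            "dispersion": None if s.dispersion is None else round_half_away(s.dispersion, 1),
            "n": s.n,
        }
        for s in summaries
    ]
    overall_rows = []
    for (group, dim), col in _group_columns(summaries).items():
        try:
            om = column_mean(col)
        except ValueError:
            continue
        overall_rows.append(
            {
                "item_id": "OVERALL",
                "label": "OVERALL",
                "group": group.value,
                "dimension": dim.value,
                "mean": om,
                "dispersion": None,
                "n": sum(s.n for s in col),
            }
        )
    return pd.DataFrame(
        rows + overall_rows,
        columns=["item_id", "label", "group", "dimension", "mean", "dispersion", "n"],
    )


def _group_columns(
    summaries: Sequence[SummaryStat],
) -> dict[tuple[Group, Dimension], list[SummaryStat]]:
    cols: dict[tuple[Group, Dimension], list[SummaryStat]] = {}
    for s in summaries:
        cols.setdefault((s.group, s.dimension), []).append(s)
    return cols
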