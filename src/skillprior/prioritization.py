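"""Ranking and report assembly: the full priority table.

Items are ordered by descending overall desirability; ties are broken
alphabetically by item label so the ordering is deterministic, and items
whose score is undefined (no valid paired ratings in some group) are listed
after all scored items.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .descriptive_stats import SummaryStat, round_half_away
from .desirability import DesirabilityRow
from .survey_model import Dimension, Group, ResponseSet

__all__ = ["PriorityTable", "rank_items", "build_report"]


@dataclass
class PriorityTable:
    """Ordered priority listing with provenance metadata.

    ``frame`` holds one row per item with rank 1..n (rank 1 = highest
    priority); ``metadata`` records the scoring strategy, component weights
    and, for synthetic inputs, the generator seed.
    """

    frame: pd.DataFrame
    metadata: dict

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False, float_format="%.4f")

    def to_text(self) -> str:
        """Plain-text aligned table with a metadata header."""
        buf = io.StringIO()
        for k, v in self.metadata.items():
            buf.write(f"# {k}: {v}\n")
        buf.write(self.frame.to_string(index=False))
        buf.write("\n")
        return buf.getvalue()


def rank_items(
    rows: Sequence[DesirabilityRow],
    labels: Mapping[str, str] | None = None,
) -> PriorityTable:
    """Rank desirability rows by descending overall score.

    Ties at equal overall score are broken by ascending item label;
    undefined items come last (still ranked, flagged by a null score).
    """
    labels = labels or {}

    def label_of(r: DesirabilityRow) -> str:
        return labels.get(r.item_id, r.item_id)

    ordered = sorted(
        rows,
        key=lambda r: (
            0 if r.defined else 1,
            -(r.overall if r.overall is not None else 0.0),
            label_of(r),
        ),
    )
    strategy = ordered[0].strategy if ordered else None
    weights = ordered[0].weights if ordered else None
    frame = pd.DataFrame(
        [
            {
                "rank": i,
                "item_id": r.item_id,
                "label": label_of(r),
                "d_faculty": r.d_faculty,
                "d_student": r.d_student,
                "d_junior": r.d_junior,
                "D_overall": r.overall,
            }
            for i, r in enumerate(ordered, start=1)
        ],
        columns=["rank", "item_id", "label", "d_faculty", "d_student", "d_junior", "D_overall"],
    )
    return PriorityTable(frame, {"strategy": strategy, "weights": weights})


def build_report(
    rs: ResponseSet,
    summaries: Sequence[SummaryStat],
    rows: Sequence[DesirabilityRow],
    metadata: Mapping | None = None,
) -> PriorityTable:
    """Join ranked desirability scores with per-group cell summaries.

    Every cell of the result traces to a cell summary or a desirability
    component; the three inputs must describe the same item set.
    """
    items_rs = set(rs.items)
    items_rows = {r.item_id for r in rows}
    items_sum = {s.item_id for s in summaries}
    if items_rs != items_rows or items_rs != items_sum:
        diff = sorted((items_rs ^ items_rows) | (items_rs ^ items_sum))
        raise ValueError(f"item sets differ between inputs: {diff}")

    labels = {iid: it.label for iid, it in rs.items.items()}
    table = rank_items(rows, labels)
    by_key = {(s.item_id, s.group, s.dimension): s for s in summaries}

    def cell(item_id: str, group: Group, dim: Dimension, attr: str) -> float | None:
        s = by_key.get((item_id, group, dim))
        if s is None:
            return None
        v = getattr(s, attr)
        return None if v is None else (round_half_away(v, 1) if attr != "n" else v)

    extra_cols = {
        "essentialness_faculty": (Group.FACULTY, Dimension.ESSENTIALNESS),
        "autonomy_student": (Group.STUDENT, Dimension.AUTONOMY),
        "autonomy_junior": (Group.JUNIOR_DOCTOR, Dimension.AUTONOMY),
        "utility_faculty": (Group.FACULTY, Dimension.UTILITY),
        "utility_student": (Group.STUDENT, Dimension.UTILITY),
        "utility_junior": (Group.JUNIOR_DOCTOR, Dimension.UTILITY),
    }
    frame = table.frame.copy()
    for col, (group, dim) in extra_cols.items():
        frame[col + "_mean"] = [cell(i, group, dim, "mean") for i in frame["item_id"]]
        frame[col + "_disp"] = [cell(i, group, dim, "dispersion") for i in frame["item_id"]]
    meta = dict(table.metadata)
    meta.update(metadata or {})
    return PriorityTable(frame, meta)
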