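"""Desirability scoring: the prioritization core.

Curriculum priority is framed as a multi-response optimization: a skill is
a high simulation-training priority when faculty deem it essential, when
learners report low mastery of it, and when all groups consider it suitable
for teaching by simulation.  Each group's judgment is standardized to the
unit interval and the three group scores are combined by geometric mean —
the Derringer-Suich construction for composite desirability.

Per-response forms (inputs are 1-9 ratings):

    faculty:  d = sqrt( (utility - 1)/8 * (essentialness - 1)/8 )
    learner:  d = sqrt( (utility - 1)/8 * (9 - autonomy)/8 )

Both factors map onto [0, 1]; the learner form reverses autonomy, because a
*low* self-perceived mastery indicates a training gap.  Overall desirability
is the geometric mean of the three group scores,

    D = (d_faculty * d_student * d_junior)^(1/3),

ranging from 0 (lowest priority) to 1 (highest priority); a weighted
geometric mean generalizes this when the components should not count
equally.

Group-level aggregation is not uniquely determined by the composite's
definition and is exposed as a strategy: compute d per respondent from that
respondent's own paired ratings and average ("per_respondent_mean", the
default), or evaluate d once on the group's mean ratings
("of_group_means").  Because the composite is concave, the per-respondent
average is never larger than the of-group-means value on the same data
(Jensen's inequality).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .survey_model import (
    Dimension,
    Group,
    ResponseSet,
)
from .descriptive_stats import SummaryStat

__all__ = [
    "AGGREGATION_STRATEGIES",
    "DesirabilityRow",
    "d_faculty",
    "d_learner",
    "d_overall",
    "weighted_desirability",
    "group_desirability",
    "score_items",
    "score_from_summaries",
]

AGGREGATION_STRATEGIES = ("per_respondent_mean", "of_group_means")

#: Component order of the overall score: (faculty, student, junior doctor).
DEFAULT_WEIGHTS = (1.0, 1.0, 1.0)


def _check_rating(value: float, name: str) -> float:
    value = float(value)
    if not 1.0 <= value <= 9.0:
        raise ValueError(f"{name} must lie in [1, 9], got {value}")
    return value


def d_faculty(essentialness: float, utility: float) -> float:
    """Faculty desirability of one skill: high when essential and simulable."""
    e = _check_rating(essentialness, "essentialness")
    u = _check_rating(utility, "utility")
    return math.sqrt((u - 1.0) / 8.0 * (e - 1.0) / 8.0)


def d_learner(autonomy: float, utility: float) -> float:
    """Learner desirability: high when mastery is low and the skill is simulable."""
    a = _check_rating(autonomy, "autonomy")
    u = _check_rating(utility, "utility")
    return math.sqrt((u - 1.0) / 8.0 * (9.0 - a) / 8.0)


def d_overall(d_teachers: float, d_students: float, d_junior: float) -> float:
    """Equal-weight geometric mean of the three group desirabilities."""
    for name, v in (("d_teachers", d_teachers), ("d_students", d_students), ("d_junior", d_junior)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    return (d_teachers * d_students * d_junior) ** (1.0 / 3.0)


def weighted_desirability(components: Sequence[tuple[float, float]]) -> float:
    """Weighted geometric mean ``(prod v_i^w_i)^(1/sum w_i)`` of [0,1] values.

    With equal weights this reduces to :func:`d_overall`; a zero weight
    removes a component entirely.
    """
    if not components:
        raise ValueError("at least one (value, weight) component required")
    values = np.array([c[0] for c in components], dtype=float)
    weights = np.array([c[1] for c in components], dtype=float)
    if (weights < 0).any():
        raise ValueError("weights must be >= 0")
    wsum = weights.sum()
    if wsum == 0:
        raise ValueError("weights must not all be zero")
    if ((values < 0) | (values > 1)).any():
        raise ValueError("component values must lie in [0, 1]")
    active = weights > 0
    if (values[active] == 0).any():
        return 0.0
    return float(np.exp(np.sum(weights[active] * np.log(values[active])) / wsum))


def _d_for_group(group: Group, non_utility: float, utility: float) -> float:
    if group is Group.FACULTY:
        return d_faculty(non_utility, utility)
    return d_learner(non_utility, utility)


def group_desirability(
    rs: ResponseSet,
    item_id: str,
    group: Group,
    strategy: str = "per_respondent_mean",
) -> float | None:
    """One group's desirability for one item, or None when undefined.

    ``per_respondent_mean`` evaluates d on each respondent's own paired
    ratings (a respondent contributes only if they rated both of their
    group's dimensions for the item) and averages; ``of_group_means``
    evaluates d once on the two group mean ratings.  With no valid paired
    ratings the score is undefined and ``None`` is returned.
    """
    if strategy not in AGGREGATION_STRATEGIES:
        raise ValueError(f"unknown aggregation strategy {strategy!r}")
    pairs = rs.paired_scores(item_id, group)
    if not pairs:
        return None
    if strategy == "per_respondent_mean":
        return float(np.mean([_d_for_group(group, nv, u) for _, nv, u in pairs]))
    mean_nv = float(np.mean([nv for _, nv, _ in pairs]))
    mean_u = float(np.mean([u for _, _, u in pairs]))
    return _d_for_group(group, mean_nv, mean_u)


@dataclass(frozen=True)
class DesirabilityRow:
    """Per-item desirability components and their weighted combination.

    Undefined components (a group with no paired ratings) propagate: the
    overall score is ``None`` and the item sorts after all scored items.
    """

    item_id: str
    d_faculty: float | None
    d_student: float | None
    d_junior: float | None
    overall: float | None
    strategy: str
    weights: tuple[float, float, float]

    @property
    def defined(self) -> bool:
        return self.overall is not None


def _combine(
    ds: tuple[float | None, float | None, float | None],
    weights: tuple[float, float, float],
) -> float | None:
    if any(d is None for d in ds):
        return None
    return weighted_desirability(list(zip(ds, weights)))  # type: ignore[arg-type]


def score_items(
    rs: ResponseSet,
    strategy: str = "per_respondent_mean",
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
) -> list[DesirabilityRow]:
    """Score every item in a response set: three group d's plus the combination."""
    rows = []
    for item_id in rs.items:
        df = group_desirability(rs, item_id, Group.FACULTY, strategy)
        ds = group_desirability(rs, item_id, Group.STUDENT, strategy)
        dj = group_desirability(rs, item_id, Group.JUNIOR_DOCTOR, strategy)
        rows.append(
            DesirabilityRow(
                item_id, df, ds, dj, _combine((df, ds, dj), weights), strategy, tuple(weights)
            )
        )
    return rows


def score_from_summaries(
    summaries: Sequence[SummaryStat],
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
) -> list[DesirabilityRow]:
    """Of-group-means scoring from cell summaries alone.

    This is the only scoring path available when respondent-level data are
    not at hand (e.g. a published table of group means); it evaluates each
    group's d on the reported mean ratings.
    """
    by_key: dict[tuple[str, Group, Dimension], SummaryStat] = {
        (s.item_id, s.group, s.dimension): s for s in summaries
    }
    item_ids = list(dict.fromkeys(s.item_id for s in summaries))
    rows = []
    for item_id in item_ids:

        def mean_of(group: Group, dim: Dimension) -> float | None:
            s = by_key.get((item_id, group, dim))
            return None if s is None else s.mean

        def d_of(group: Group, dim: Dimension) -> float | None:
            nv = mean_of(group, dim)
            u = mean_of(group, Dimension.UTILITY)
            if nv is None or u is None:
                return None
            return _d_for_group(group, nv, u)

        df = d_of(Group.FACULTY, Dimension.ESSENTIALNESS)
        ds = d_of(Group.STUDENT, Dimension.AUTONOMY)
        dj = d_of(Group.JUNIOR_DOCTOR, Dimension.AUTONOMY)
        rows.append(
            DesirabilityRow(
                item_id, df, ds, dj, _combine((df, ds, dj), weights),
                "of_group_means", tuple(weights),
            )
        )
    return rows
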