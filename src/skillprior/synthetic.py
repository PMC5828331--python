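"""Synthetic three-group survey generator.

Emulates the study structure the analysis assumes: three invited cohorts
(defaults 43 faculty, 53 students, 102 junior doctors), all-or-nothing
respondent-level participation with probability 0.667, and integer 1-9
ratings produced by adding Gaussian noise to per-item latent means, rounding
to the nearest integer and clamping to the scale.  Faculty rate
essentialness and utility; each learner group rates autonomy and utility,
with an optional within-respondent correlation between the two dimensions.

The generator gives every pipeline stage respondent-level input with known
ground truth, which also enables planted-ranking recovery experiments: pairs
of item profiles constructed so one must outrank the other are generated and
the pipeline is asked to recover the planted order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .survey_model import (
    ALLOWED_PAIRS,
    Dimension,
    Group,
    RatingRecord,
    Respondent,
    ResponseSet,
    SkillItem,
)

__all__ = [
    "DEFAULT_GROUP_SIZES",
    "DEFAULT_RESPONSE_PROB",
    "ItemProfile",
    "SyntheticConfig",
    "generate_survey",
    "make_recovery_scenario",
    "high_priority_profile",
    "low_priority_profile",
]

#: Invited cohort sizes of the study design this generator emulates.
DEFAULT_GROUP_SIZES: Mapping[Group, int] = {
    Group.FACULTY: 43,
    Group.STUDENT: 53,
    Group.JUNIOR_DOCTOR: 102,
}

#: Overall participation probability (the study's ~66.7% response rate).
DEFAULT_RESPONSE_PROB = 0.667

_ID_PREFIX = {Group.FACULTY: "F", Group.STUDENT: "S", Group.JUNIOR_DOCTOR: "J"}


@dataclass(frozen=True)
class ItemProfile:
    """Latent rating means of one item, per (group, dimension) pairing.

    ``corr`` is the within-respondent correlation between a respondent's two
    dimension ratings (same noise draw structure for every group); real
    surveys plausibly correlate them but the magnitude is unknown, so the
    default is 0.
    """

    item_id: str
    means: Mapping[tuple[Group, Dimension], float]
    label: str = ""
    corr: float = 0.0

    def __post_init__(self) -> None:
        for (group, dim), m in self.means.items():
            if dim not in ALLOWED_PAIRS[group]:
                raise ValueError(
                    f"{self.item_id}: latent mean for impermissible pairing "
                    f"({group.value}, {dim.value})"
                )
            if not 1.0 <= m <= 9.0:
                raise ValueError(f"{self.item_id}: latent mean {m} outside [1, 9]")
        if not -1.0 <= self.corr <= 1.0:
            raise ValueError("corr must lie in [-1, 1]")


def _uniform_profile(
    item_id: str, essentialness: float, autonomy: float, utility: float, corr: float = 0.0
) -> ItemProfile:
    """Profile with one essentialness, one autonomy (both learner groups) and
    one utility (all groups) latent mean."""
    means = {
        (Group.FACULTY, Dimension.ESSENTIALNESS): essentialness,
        (Group.FACULTY, Dimension.UTILITY): utility,
        (Group.STUDENT, Dimension.AUTONOMY): autonomy,
        (Group.STUDENT, Dimension.UTILITY): utility,
        (Group.JUNIOR_DOCTOR, Dimension.AUTONOMY): autonomy,
        (Group.JUNIOR_DOCTOR, Dimension.UTILITY): utility,
    }
    return ItemProfile(item_id, means, label=item_id, corr=corr)


def high_priority_profile(item_id: str, corr: float = 0.0) -> ItemProfile:
    """A skill faculty deem essential, learners have not mastered, and all
    groups consider highly simulable — the archetypal training gap."""
    return _uniform_profile(item_id, essentialness=8.0, autonomy=2.0, utility=8.0, corr=corr)


def low_priority_profile(item_id: str, corr: float = 0.0) -> ItemProfile:
    """Equally essential and simulable, but learners already feel competent."""
    return _uniform_profile(item_id, essentialness=8.0, autonomy=8.0, utility=8.0, corr=corr)


@dataclass(frozen=True)
class SyntheticConfig:
    """Everything that determines a generated survey, including the seed."""

    seed: int
    items: Sequence[ItemProfile]
    group_sizes: Mapping[Group, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    response_prob: float = DEFAULT_RESPONSE_PROB
    noise_sd: float = 1.5
    skip_prob: float = 0.0

    def __post_init__(self) -> None:
        if not self.items:
            raise ValueError("at least one item profile required")
        ids = [p.item_id for p in self.items]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate item_id in profiles")
        for g, n in self.group_sizes.items():
            if n < 0:
                raise ValueError(f"group size for {g.value} must be >= 0")
        if not 0.0 <= self.response_prob <= 1.0:
            raise ValueError("response_prob must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.skip_prob <= 1.0:
            raise ValueError("skip_prob must lie in [0, 1]")


def generate_survey(config: SyntheticConfig) -> ResponseSet:
    """Draw one complete synthetic survey, reproducible from the seed.

    Each invited respondent participates with probability ``response_prob``
    (all-or-nothing); each participant rates every item on both of their
    group's dimensions unless skipped with ``skip_prob`` per rating.  A
    score is the latent mean plus N(0, noise_sd) noise, rounded to the
    nearest integer and clamped to [1, 9].
    """
    rng = np.random.default_rng(config.seed)
    rs = ResponseSet()
    for profile in config.items:
        rs.items[profile.item_id] = SkillItem(
            profile.item_id, profile.label or profile.item_id
        )

    for group in Group:  # fixed iteration order keeps the stream reproducible
        invited = config.group_sizes.get(group, 0)
        responded = rng.random(invited) < config.response_prob
        dims = sorted(ALLOWED_PAIRS[group], key=lambda d: d.value)
        for i in range(invited):
            if not responded[i]:
                continue
            rid = f"{_ID_PREFIX[group]}{i + 1:03d}"
            rs.respondents[rid] = Respondent(rid, group)
            for profile in config.items:
                z = rng.standard_normal(2)
                rho = profile.corr
                eps = np.array(
                    [z[0], rho * z[0] + math.sqrt(max(0.0, 1.0 - rho * rho)) * z[1]]
                )
                skip = rng.random(2) < config.skip_prob
                for k, dim in enumerate(dims):
                    mean = profile.means.get((group, dim))
                    if mean is None or skip[k]:
                        continue
                    raw = mean + config.noise_sd * eps[k]
                    score = int(np.clip(np.rint(raw), 1, 9))
                    rs.ratings.append(RatingRecord(rid, profile.item_id, dim, score))
    return rs


def make_recovery_scenario(
    n_high: int,
    n_low: int,
    seed: int,
    noise_sd: float = 1.5,
    group_sizes: Mapping[Group, int] | None = None,
    response_prob: float = DEFAULT_RESPONSE_PROB,
) -> tuple[ResponseSet, list[str]]:
    """Planted-ranking scenario: high-priority vs already-mastered skills.

    Generates ``n_high`` items with latent profile (essentialness 8,
    autonomy 2, utility 8) and ``n_low`` items with (8, 8, 8), so the true
    priority order puts every high item before every low item.  Returns the
    survey and the planted high-before-low item ordering.
    """
    if n_high + n_low < 2:
        raise ValueError("need at least two items for a recovery scenario")
    profiles = [high_priority_profile(f"high_{i + 1:02d}") for i in range(n_high)]
    profiles += [low_priority_profile(f"low_{i + 1:02d}") for i in range(n_low)]
    config = SyntheticConfig(
        seed=seed,
        items=profiles,
        group_sizes=dict(group_sizes or DEFAULT_GROUP_SIZES),
        response_prob=response_prob,
        noise_sd=noise_sd,
    )
    planted = [p.item_id for p in profiles]
    return generate_survey(config), planted
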