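"""Packaged reference fixtures: published group-level survey results.

The package ships two small read-only CSVs derived from a published
three-group procedural-skills survey:

* ``table2_means.csv`` — per-item group *means* and dispersions for the 40
  initial-list skills (essentialness for faculty, autonomy for the two
  learner groups, utility for all three), plus the printed overall
  desirability score of each item.  The underlying respondent-level data
  were never published, so this fixture exercises only means-based code
  paths (column aggregates, of-group-means scoring); respondent-level
  paths are exercised with :mod:`skillprior.synthetic` surveys instead.
* ``table3_suggestions.csv`` — per-group occurrence counts of the 22
  respondent-suggested new technical skills.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .descriptive_stats import SummaryStat
from .survey_model import (
    Dimension,
    Group,
    SuggestionCategory,
    SuggestionRecord,
)
from .synthetic import ItemProfile

__all__ = [
    "reference_means_frame",
    "reference_summaries",
    "reference_labels",
    "reference_printed_desirability",
    "reference_suggestions",
    "reference_item_profiles",
]

_COLUMNS: list[tuple[Group, Dimension]] = [
    (Group.FACULTY, Dimension.ESSENTIALNESS),
    (Group.STUDENT, Dimension.AUTONOMY),
    (Group.JUNIOR_DOCTOR, Dimension.AUTONOMY),
    (Group.FACULTY, Dimension.UTILITY),
    (Group.STUDENT, Dimension.UTILITY),
    (Group.JUNIOR_DOCTOR, Dimension.UTILITY),
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("skillprior.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


def reference_means_frame() -> pd.DataFrame:
    """The raw means fixture as a DataFrame, one row per skill."""
    return _read("table2_means.csv")


def reference_summaries() -> list[SummaryStat]:
    """The means fixture as cell summaries (n unknown, recorded as 0-free 1).

    The published table reports no per-cell n; summaries carry n = 1 as a
    placeholder meaning "a defined published mean", which keeps the
    undefined-cell flagging semantics intact.
    """
    df = reference_means_frame()
    out: list[SummaryStat] = []
    for row in df.itertuples(index=False):
        for group, dim in _COLUMNS:
            mean = getattr(row, f"{group.value}_{dim.value}_mean")
            disp = getattr(row, f"{group.value}_{dim.value}_disp")
            out.append(SummaryStat(row.item_id, group, dim, float(mean), float(disp), 1))
    return out


def reference_labels() -> dict[str, str]:
    df = reference_means_frame()
    return dict(zip(df["item_id"], df["label"]))


def reference_printed_desirability() -> dict[str, float]:
    """The published overall desirability column, keyed by item id.

    Kept for comparison only: these values were computed from unpublished
    respondent-level data and are not reproducible from the group means.
    """
    df = reference_means_frame()
    return dict(zip(df["item_id"], df["printed_desirability"]))


def reference_suggestions() -> list[SuggestionRecord]:
    """The suggestion-counts fixture expanded to one record per occurrence."""
    df = _read("table3_suggestions.csv")
    out: list[SuggestionRecord] = []
    for row in df.itertuples(index=False):
        for group in Group:
            for _ in range(int(getattr(row, group.value))):
                out.append(
                    SuggestionRecord(
                        respondent_group=group,
                        raw_text=row.coded_label,
                        coded_label=row.coded_label,
                        category=SuggestionCategory(row.category),
                    )
                )
    return out


def reference_item_profiles(corr: float = 0.0) -> list[ItemProfile]:
    """Latent item profiles matching the published group means.

    A convenience for generating surveys whose cell means resemble the
    published table; respondent-level dispersion cannot be validated against
    any published data, so this is a fixture, not a calibration.
    """
    df = reference_means_frame()
    out = []
    for row in df.itertuples(index=False):
        means = {
            (group, dim): float(getattr(row, f"{group.value}_{dim.value}_mean"))
            for group, dim in _COLUMNS
        }
        out.append(ItemProfile(row.item_id, means, label=row.label, corr=corr))
    return out
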