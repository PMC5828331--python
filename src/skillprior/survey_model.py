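"""Domain types, long-format CSV I/O, and structural validation.

A competency survey collects 1-9 ratings from three respondent groups:
faculty rate each skill's *essentialness* (how important it is that a
graduate performs it autonomously), learners (recently graduated students
and junior doctors) rate their own *autonomy* (self-perceived mastery),
and every group rates *utility* (suitability of the skill for teaching by
simulation).  The atomic datum is one respondent's integer score for one
skill on one dimension; everything downstream consumes the validated
:class:`ResponseSet` container defined here.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Group",
    "Dimension",
    "ALLOWED_PAIRS",
    "LEARNER_GROUPS",
    "SkillItem",
    "Respondent",
    "RatingRecord",
    "ResponseSet",
    "SuggestionRecord",
    "SuggestionCategory",
    "SuggestionTally",
    "ValidationReport",
    "SurveyFormatError",
    "load_responses",
    "load_items",
    "load_suggestions",
    "write_responses",
    "write_items",
    "validate_responses",
    "tally_suggestions",
]


class Group(str, enum.Enum):
    """The three respondent populations."""

    FACULTY = "faculty"
    STUDENT = "student"
    JUNIOR_DOCTOR = "junior_doctor"


class Dimension(str, enum.Enum):
    """The three rated dimensions of each skill."""

    ESSENTIALNESS = "essentialness"
    AUTONOMY = "autonomy"
    UTILITY = "utility"


#: Which dimensions each group is surveyed on.  Faculty judge importance
#: (essentialness); learners judge their own mastery (autonomy); everyone
#: judges suitability for simulation teaching (utility).
ALLOWED_PAIRS: Mapping[Group, frozenset[Dimension]] = {
    Group.FACULTY: frozenset({Dimension.ESSENTIALNESS, Dimension.UTILITY}),
    Group.STUDENT: frozenset({Dimension.AUTONOMY, Dimension.UTILITY}),
    Group.JUNIOR_DOCTOR: frozenset({Dimension.AUTONOMY, Dimension.UTILITY}),
}

LEARNER_GROUPS = (Group.STUDENT, Group.JUNIOR_DOCTOR)

SCORE_MIN, SCORE_MAX = 1, 9

RESPONSE_COLUMNS = ["respondent_id", "group", "item_id", "dimension", "score"]


class SurveyFormatError(ValueError):
    """Raised when a survey file violates the format or its invariants."""


class ItemOrigin(str, enum.Enum):
    INITIAL_LIST = "initial_list"
    RESPONDENT_SUGGESTED = "respondent_suggested"


@dataclass(frozen=True)
class SkillItem:
    """One procedural skill on the survey."""

    item_id: str
    label: str
    origin: ItemOrigin = ItemOrigin.INITIAL_LIST

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError(f"item {self.item_id!r}: label must be non-empty")


@dataclass(frozen=True)
class Respondent:
    respondent_id: str
    group: Group


@dataclass(frozen=True)
class RatingRecord:
    """One respondent's 1-9 score for one skill on one dimension."""

    respondent_id: str
    item_id: str
    dimension: Dimension
    score: int


class SuggestionCategory(str, enum.Enum):
    NEW_TECHNICAL = "new_technical"
    NON_TECHNICAL = "non_technical"
    DUPLICATION = "duplication"
    REPLICATION = "replication"


@dataclass(frozen=True)
class SuggestionRecord:
    """One free-text suggestion, already coded by a human reviewer."""

    respondent_group: Group
    raw_text: str
    coded_label: str = ""
    category: SuggestionCategory = SuggestionCategory.NEW_TECHNICAL

    def __post_init__(self) -> None:
        if self.category is SuggestionCategory.NEW_TECHNICAL and not self.coded_label:
            raise ValueError("new_technical suggestion requires a coded_label")


@dataclass
class ResponseSet:
    """Validated container of items, respondents and ratings.

    The constructor does not validate; use :func:`validate_responses` to
    check invariants, or :func:`load_responses`, which validates and raises.
    """

    items: dict[str, SkillItem] = field(default_factory=dict)
    respondents: dict[str, Respondent] = field(default_factory=dict)
    ratings: list[RatingRecord] = field(default_factory=list)

    # -- convenience accessors -------------------------------------------------

    def scores(self, item_id: str, group: Group, dimension: Dimension) -> list[int]:
        """All scores for one (item, group, dimension) cell, in input order."""
        return [
            r.score
            for r in self.ratings
            if r.item_id == item_id
            and r.dimension == dimension
            and self.respondents[r.respondent_id].group == group
        ]

    def paired_scores(
        self, item_id: str, group: Group
    ) -> list[tuple[str, int, int]]:
        """Per-respondent (respondent_id, non-utility score, utility score) pairs.

        Only respondents who rated *both* of their group's dimensions for the
        item contribute; unpaired ratings are excluded here (they still count
        for descriptive statistics).
        """
        other_dim = next(d for d in ALLOWED_PAIRS[group] if d is not Dimension.UTILITY)
        by_resp: dict[str, dict[Dimension, int]] = {}
        for r in self.ratings:
            if r.item_id != item_id:
                continue
            if self.respondents[r.respondent_id].group != group:
                continue
            by_resp.setdefault(r.respondent_id, {})[r.dimension] = r.score
        out = []
        for rid in sorted(by_resp):
            d = by_resp[rid]
            if other_dim in d and Dimension.UTILITY in d:
                out.append((rid, d[other_dim], d[Dimension.UTILITY]))
        return out

    def group_counts(self) -> Counter:
        return Counter(r.group for r in self.respondents.values())

    def sorted_key(self) -> list[tuple]:
        """Canonical sorted view of the rating triples, for equivalence checks."""
        return sorted(
            (r.respondent_id, r.item_id, r.dimension.value, r.score)
            for r in self.ratings
        )


@dataclass
class ValidationReport:
    """Outcome of structural validation: exact counts plus any violations."""

    n_respondents_by_group: dict[str, int]
    n_items: int
    n_ratings_by_dimension: dict[str, int]
    violations: list[str]

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_responses(rs: ResponseSet) -> ValidationReport:
    """Check every structural invariant; violations are reported, not thrown."""
    violations: list[str] = []
    seen: set[tuple[str, str, str]] = set()
    for r in rs.ratings:
        if r.respondent_id not in rs.respondents:
            violations.append(f"rating references unknown respondent {r.respondent_id!r}")
            continue
        if r.item_id not in rs.items:
            violations.append(f"rating references unknown item {r.item_id!r}")
        group = rs.respondents[r.respondent_id].group
        if r.dimension not in ALLOWED_PAIRS[group]:
            violations.append(
                f"dimension {r.dimension.value!r} not permitted for group "
                f"{group.value!r} (respondent {r.respondent_id!r}, item {r.item_id!r})"
            )
        if not (isinstance(r.score, int) and SCORE_MIN <= r.score <= SCORE_MAX):
            violations.append(
                f"score {r.score!r} out of range [{SCORE_MIN}, {SCORE_MAX}] "
                f"(respondent {r.respondent_id!r}, item {r.item_id!r})"
            )
        triple = (r.respondent_id, r.item_id, r.dimension.value)
        if triple in seen:
            violations.append(f"duplicate rating for {triple}")
        seen.add(triple)

    by_group = Counter(r.group.value for r in rs.respondents.values())
    by_dim = Counter(r.dimension.value for r in rs.ratings)
    return ValidationReport(
        n_respondents_by_group={g.value: by_group.get(g.value, 0) for g in Group},
        n_items=len(rs.items),
        n_ratings_by_dimension={d.value: by_dim.get(d.value, 0) for d in Dimension},
        violations=violations,
    )


# -- CSV I/O -------------------------------------------------------------------


def _parse_enum(cls, value: str, row: int, field_name: str):
    try:
        return cls(value)
    except ValueError:
        raise SurveyFormatError(
            f"row {row}: invalid {field_name} {value!r} "
            f"(expected one of {[m.value for m in cls]})"
        ) from None


def load_responses(
    path: str | Path, items_path: str | Path | None = None
) -> ResponseSet:
    """Read a long-format ratings CSV into a validated :class:`ResponseSet`.

    The file is UTF-8 with one header row naming the columns
    ``respondent_id, group, item_id, dimension, score``.  Row order never
    affects the result.  Malformed rows raise :class:`SurveyFormatError`
    naming the row number and field; duplicates and forbidden
    group/dimension pairs are rejected.

    When ``items_path`` is given it must be an ``items.csv``
    (``item_id, label, origin``); otherwise item labels default to the id.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    missing = [c for c in RESPONSE_COLUMNS if c not in df.columns]
    if missing:
        raise SurveyFormatError(f"{path}: missing required column(s) {missing}")

    rs = ResponseSet()
    if items_path is not None:
        rs.items = {it.item_id: it for it in load_items(items_path)}

    seen: dict[tuple[str, str, str], int] = {}
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        group = _parse_enum(Group, row.group, idx, "group")
        dim = _parse_enum(Dimension, row.dimension, idx, "dimension")
        try:
            score = int(row.score)
            if str(row.score).strip() != str(score):  # reject '7.0', '7.5'
                raise ValueError
        except ValueError:
            raise SurveyFormatError(
                f"row {idx}: score {row.score!r} is not an integer"
            ) from None
        if not SCORE_MIN <= score <= SCORE_MAX:
            raise SurveyFormatError(
                f"row {idx}: score {score} out of range [{SCORE_MIN}, {SCORE_MAX}]"
            )
        if dim not in ALLOWED_PAIRS[group]:
            raise SurveyFormatError(
                f"row {idx}: dimension {dim.value!r} not permitted for group {group.value!r}"
            )
        prev = rs.respondents.get(row.respondent_id)
        if prev is not None and prev.group is not group:
            raise SurveyFormatError(
                f"row {idx}: respondent {row.respondent_id!r} appears in two groups"
            )
        triple = (row.respondent_id, row.item_id, dim.value)
        if triple in seen:
            raise SurveyFormatError(
                f"row {idx}: duplicate rating for {triple} (first at row {seen[triple]})"
            )
        seen[triple] = idx
        rs.respondents.setdefault(row.respondent_id, Respondent(row.respondent_id, group))
        if row.item_id not in rs.items:
            if items_path is not None:
                raise SurveyFormatError(
                    f"row {idx}: item {row.item_id!r} not in items file"
                )
            rs.items[row.item_id] = SkillItem(row.item_id, row.item_id)
        rs.ratings.append(RatingRecord(row.respondent_id, row.item_id, dim, score))

    report = validate_responses(rs)
    if not report.ok:
        raise SurveyFormatError("; ".join(report.violations))
    return rs


def write_responses(rs: ResponseSet, path: str | Path) -> None:
    """Write the long-format ratings CSV (inverse of :func:`load_responses`)."""
    rows = [
        {
            "respondent_id": r.respondent_id,
            "group": rs.respondents[r.respondent_id].group.value,
            "item_id": r.item_id,
            "dimension": r.dimension.value,
            "score": r.score,
        }
        for r in rs.ratings
    ]
    pd.DataFrame(rows, columns=RESPONSE_COLUMNS).to_csv(path, index=False)


def load_items(path: str | Path) -> list[SkillItem]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    for col in ("item_id", "label"):
        if col not in df.columns:
            raise SurveyFormatError(f"{path}: missing required column {col!r}")
    items: list[SkillItem] = []
    seen: set[str] = set()
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        if row.item_id in seen:
            raise SurveyFormatError(f"row {idx}: duplicate item_id {row.item_id!r}")
        seen.add(row.item_id)
        origin = (
            _parse_enum(ItemOrigin, row.origin, idx, "origin")
            if "origin" in df.columns and row.origin
            else ItemOrigin.INITIAL_LIST
        )
        items.append(SkillItem(row.item_id, row.label, origin))
    return items


def write_items(items: Iterable[SkillItem], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"item_id": it.item_id, "label": it.label, "origin": it.origin.value}
            for it in items
        ]
    ).to_csv(path, index=False)


def load_suggestions(path: str | Path) -> list[SuggestionRecord]:
    """Read an already-coded suggestions CSV (group, raw_text, coded_label, category)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    for col in ("group", "raw_text", "coded_label", "category"):
        if col not in df.columns:
            raise SurveyFormatError(f"{path}: missing required column {col!r}")
    out = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        group = _parse_enum(Group, row.group, idx, "group")
        cat = _parse_enum(SuggestionCategory, row.category, idx, "category")
        try:
            out.append(SuggestionRecord(group, row.raw_text, row.coded_label, cat))
        except ValueError as exc:
            raise SurveyFormatError(f"row {idx}: {exc}") from None
    return out


# -- suggestion tallies --------------------------------------------------------


@dataclass
class SuggestionTally:
    """Counts of coded free-text suggestions.

    ``label_counts`` maps each new-technical coded label to its per-group and
    total occurrence counts; ``category_totals`` partitions *all* input
    records by category.
    """

    label_counts: pd.DataFrame  # columns: coded_label, faculty, student, junior_doctor, total
    category_totals: dict[str, int]

    @property
    def n_distinct_labels(self) -> int:
        return len(self.label_counts)

    @property
    def grand_total(self) -> int:
        return int(self.label_counts["total"].sum()) if len(self.label_counts) else 0


def tally_suggestions(records: Sequence[SuggestionRecord]) -> SuggestionTally:
    """Tally coded suggestions per label (new-technical only) and per category."""
    cat_totals = Counter(r.category.value for r in records)
    counts: dict[str, Counter] = {}
    order: list[str] = []
    for r in records:
        if r.category is not SuggestionCategory.NEW_TECHNICAL:
            continue
        if r.coded_label not in counts:
            counts[r.coded_label] = Counter()
            order.append(r.coded_label)
        counts[r.coded_label][r.respondent_group.value] += 1
    rows = []
    for label in order:
        c = counts[label]
        per_group = {g.value: c.get(g.value, 0) for g in Group}
        rows.append({"coded_label": label, **per_group, "total": sum(per_group.values())})
    cols = ["coded_label", *[g.value for g in Group], "total"]
    df = pd.DataFrame(rows, columns=cols)
    df = df.sort_values(["total", "coded_label"], ascending=[False, True]).reset_index(
        drop=True
    )
    return SuggestionTally(df, {c.value: cat_totals.get(c.value, 0) for c in SuggestionCategory})
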