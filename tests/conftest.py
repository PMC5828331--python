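from __future__ import annotations

import pytest

from skillprior.survey_model import (
    Dimension,
    Group,
    RatingRecord,
    Respondent,
    ResponseSet,
    SkillItem,
)


def make_response_set(ratings: list[tuple[str, Group, str, Dimension, int]]) -> ResponseSet:
    """Build a ResponseSet from (respondent, group, item, dimension, score) tuples."""
    rs = ResponseSet()
    for rid, group, item_id, dim, score in ratings:
        rs.respondents.setdefault(rid, Respondent(rid, group))
        rs.items.setdefault(item_id, SkillItem(item_id, item_id.replace("_", " ")))
        rs.ratings.append(RatingRecord(rid, item_id, dim, score))
    return rs


@pytest.fixture
def tiny_survey() -> ResponseSet:
    """Two items, two respondents per group, fully paired ratings."""
    E, A, U = Dimension.ESSENTIALNESS, Dimension.AUTONOMY, Dimension.UTILITY
    F, S, J = Group.FACULTY, Group.STUDENT, Group.JUNIOR_DOCTOR
    rows = []
    for item, (e1, e2, a1, a2, u) in {
        "suturing": (8, 6, 2, 4, 7),
        "ecg": (5, 5, 7, 7, 6),
    }.items():
        rows += [
            ("f1", F, item, E, e1), ("f1", F, item, U, u),
            ("f2", F, item, E, e2), ("f2", F, item, U, u),
            ("s1", S, item, A, a1), ("s1", S, item, U, u),
            ("s2", S, item, A, a2), ("s2", S, item, U, u),
            ("j1", J, item, A, a1), ("j1", J, item, U, u),
            ("j2", J, item, A, a2), ("j2", J, item, U, u),
        ]
    return make_response_set(rows)
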