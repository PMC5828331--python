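"""Desirability transforms: closed forms, grid identities, aggregation."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from skillprior.desirability import (
    d_faculty,
    d_learner,
    d_overall,
    group_desirability,
    score_from_summaries,
    score_items,
    weighted_desirability,
)
from skillprior.descriptive_stats import summarize
from skillprior.survey_model import Dimension, Group
from skillprior.synthetic import SyntheticConfig, generate_survey, high_priority_profile

from conftest import make_response_set

GRID = list(itertools.product(range(1, 10), repeat=2))  # the 81 integer pairs


class TestClosedForms:
    @pytest.mark.parametrize(
        "e, u, want",
        [(9, 9, 1.0), (1, 5, 0.0), (1, 9, 0.0), (5, 1, 0.0), (5, 5, 0.5), (7.6, 7.8, 0.8374)],
    )
    def test_faculty_form(self, e, u, want):
        assert d_faculty(e, u) == pytest.approx(want, abs=5e-5)

    @pytest.mark.parametrize(
        "a, u, want", [(1, 9, 1.0), (9, 5, 0.0), (9, 9, 0.0), (5, 5, 0.5)]
    )
    def test_learner_form(self, a, u, want):
        assert d_learner(a, u) == pytest.approx(want, abs=1e-12)

    @pytest.mark.parametrize("x", [0.0, 0.3, 0.77, 1.0])
    def test_overall_idempotent_on_equal_components(self, x):
        assert d_overall(x, x, x) == pytest.approx(x)

    def test_overall_annihilator_and_top(self):
        assert d_overall(1, 1, 1) == 1.0
        assert d_overall(0, 0.4, 0.9) == 0.0

    @pytest.mark.parametrize("fn", [d_faculty, d_learner])
    @pytest.mark.parametrize("bad", [0.5, 9.5, -1, 10])
    def test_out_of_range_ratings_rejected(self, fn, bad):
        with pytest.raises(ValueError):
            fn(bad, 5)
        with pytest.raises(ValueError):
            fn(5, bad)

    def test_overall_rejects_out_of_range_components(self):
        with pytest.raises(ValueError):
            d_overall(1.1, 0.5, 0.5)


class TestIntegerGridIdentities:
    def test_range_and_monotonicity_exhaustive(self):
        for a, u in GRID:
            assert 0.0 <= d_faculty(a, u) <= 1.0
            assert 0.0 <= d_learner(a, u) <= 1.0
        for a, u in GRID:
            if a < 9:
                assert d_faculty(a + 1, u) >= d_faculty(a, u)  # more essential, higher
                assert d_learner(a + 1, u) <= d_learner(a, u)  # more mastered, lower
            if u < 9:
                assert d_faculty(a, u + 1) >= d_faculty(a, u)
                assert d_learner(a, u + 1) >= d_learner(a, u)

    def test_reflection_symmetry_exhaustive(self):
        for a, u in GRID:
            assert d_learner(a, u) == pytest.approx(d_faculty(10 - a, u), abs=1e-12)

    def test_geometric_mean_bounds(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            ds = rng.random(3)
            D = d_overall(*ds)
            assert min(ds) - 1e-12 <= D <= max(ds) + 1e-12
        x = 0.42
        assert d_overall(x, x, x) == pytest.approx(x)


class TestWeightedDesirability:
    def test_equal_weights_reduce_to_overall(self):
        vals = (0.2, 0.5, 0.9)
        assert weighted_desirability(list(zip(vals, (1, 1, 1)))) == pytest.approx(
            d_overall(*vals)
        )

    def test_degenerate_weight_selects_component(self):
        assert weighted_desirability([(0.3, 1), (0.8, 0), (0.1, 0)]) == pytest.approx(0.3)

    def test_two_to_one_weighting_closed_form(self):
        # (0.25^2 * 1.0^1)^(1/3) = 0.25^(2/3)
        got = weighted_desirability([(0.25, 2), (1.0, 1)])
        assert got == pytest.approx(0.25 ** (2 / 3), abs=5e-5)
        assert got == pytest.approx(0.3969, abs=5e-5)

    def test_zero_value_with_positive_weight_annihilates(self):
        assert weighted_desirability([(0.0, 1), (0.9, 2)]) == 0.0

    @pytest.mark.parametrize(
        "components", [[], [(0.5, -1)], [(0.5, 0), (0.6, 0)], [(1.5, 1)]]
    )
    def test_invalid_components_rejected(self, components):
        with pytest.raises(ValueError):
            weighted_desirability(components)


class TestGroupAggregation:
    def test_degenerate_group_both_strategies_agree(self):
        rows = [
            (f"s{i}", Group.STUDENT, "it", dim, score)
            for i in range(5)
            for dim, score in ((Dimension.AUTONOMY, 3), (Dimension.UTILITY, 7))
        ]
        rs = make_response_set(rows)
        want = d_learner(3, 7)
        for strategy in ("per_respondent_mean", "of_group_means"):
            assert group_desirability(rs, "it", Group.STUDENT, strategy) == pytest.approx(want)

    def test_of_group_means_on_published_row_means(self):
        # evaluating the faculty form on group means 7.6 / 7.8 gives 0.8374 --
        # visibly above the respondent-level published score, as concavity demands
        rows = [
            ("f1", Group.FACULTY, "it", Dimension.ESSENTIALNESS, 7),
            ("f1", Group.FACULTY, "it", Dimension.UTILITY, 8),
            ("f2", Group.FACULTY, "it", Dimension.ESSENTIALNESS, 8),
            ("f2", Group.FACULTY, "it", Dimension.UTILITY, 8),
        ]
        rs = make_response_set(rows)
        got = group_desirability(rs, "it", Group.FACULTY, "of_group_means")
        assert got == pytest.approx(d_faculty(7.5, 8.0))

    def test_per_respondent_mean_equals_naive_loop_oracle(self):
        for seed in range(5):
            rs = generate_survey(
                SyntheticConfig(seed=seed, items=[high_priority_profile("a")], noise_sd=2.0)
            )
            for group in Group:
                got = group_desirability(rs, "a", group, "per_respondent_mean")
                # independent oracle: explicit loop over respondents
                ds = []
                for rid, resp in rs.respondents.items():
                    if resp.group is not group:
                        continue
                    mine = {r.dimension: r.score for r in rs.ratings if r.respondent_id == rid and r.item_id == "a"}
                    if len(mine) < 2:
                        continue
                    u = mine[Dimension.UTILITY]
                    if group is Group.FACULTY:
                        ds.append(d_faculty(mine[Dimension.ESSENTIALNESS], u))
                    else:
                        ds.append(d_learner(mine[Dimension.AUTONOMY], u))
                assert got == pytest.approx(sum(ds) / len(ds))

    def test_jensen_ordering_on_random_groups(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            n = rng.integers(3, 30)
            rows = []
            for i in range(n):
                rows.append((f"s{i}", Group.STUDENT, "it", Dimension.AUTONOMY, int(rng.integers(1, 10))))
                rows.append((f"s{i}", Group.STUDENT, "it", Dimension.UTILITY, int(rng.integers(1, 10))))
            rs = make_response_set(rows)
            per = group_desirability(rs, "it", Group.STUDENT, "per_respondent_mean")
            of = group_desirability(rs, "it", Group.STUDENT, "of_group_means")
            assert per <= of + 1e-12

    def test_unpaired_respondents_excluded(self):
        rows = [
            ("s1", Group.STUDENT, "it", Dimension.AUTONOMY, 1),
            ("s1", Group.STUDENT, "it", Dimension.UTILITY, 9),
            ("s2", Group.STUDENT, "it", Dimension.AUTONOMY, 9),  # no utility rating
        ]
        rs = make_response_set(rows)
        assert group_desirability(rs, "it", Group.STUDENT) == pytest.approx(1.0)

    def test_no_pairs_is_undefined(self):
        rs = make_response_set([("s1", Group.STUDENT, "it", Dimension.AUTONOMY, 5)])
        assert group_desirability(rs, "it", Group.STUDENT) is None

    def test_unknown_strategy_rejected(self, tiny_survey):
        with pytest.raises(ValueError, match="strategy"):
            group_desirability(tiny_survey, "suturing", Group.STUDENT, "median")


class TestScoreItems:
    def test_components_and_combination(self, tiny_survey):
        rows = {r.item_id: r for r in score_items(tiny_survey)}
        r = rows["suturing"]
        assert r.d_faculty == pytest.approx((d_faculty(8, 7) + d_faculty(6, 7)) / 2)
        assert r.d_student == pytest.approx((d_learner(2, 7) + d_learner(4, 7)) / 2)
        assert r.overall == pytest.approx(d_overall(r.d_faculty, r.d_student, r.d_junior))

    def test_undefined_component_propagates(self):
        rs = make_response_set(
            [
                ("f1", Group.FACULTY, "it", Dimension.ESSENTIALNESS, 8),
                ("f1", Group.FACULTY, "it", Dimension.UTILITY, 8),
            ]
        )
        (row,) = score_items(rs)
        assert row.d_faculty is not None and row.d_student is None and row.overall is None

    def test_score_from_summaries_matches_of_group_means(self, tiny_survey):
        via_summaries = {r.item_id: r for r in score_from_summaries(summarize(tiny_survey))}
        via_rs = {r.item_id: r for r in score_items(tiny_survey, "of_group_means")}
        for item_id, r in via_rs.items():
            assert via_summaries[item_id].overall == pytest.approx(r.overall)
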