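import dataclasses
import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mapsmini.audit import Category, ItemDefinition, Level, default_catalog
from mapsmini.scoring import (
    ParticipantScore,
    ScoreConfig,
    aggregate_item,
    assign_quintiles,
    percent_of_max,
    score_bike_facility,
    total_score,
)

from conftest import make_route


def catalog_item(catalog, item_id):
    return next(i for i in catalog if i.item_id == item_id)


class TestBikeFacility:
    @pytest.mark.parametrize("facility,expected", [
        ("none", 0),
        ("sharrows", 0),           # markings without physical protection
        ("painted_lane", 1),
        ("physically_protected", 2),
    ])
    def test_protection_graded_scoring(self, facility, expected):
        assert score_bike_facility(facility) == expected

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            score_bike_facility("gravel_path")


class TestAggregateItem:
    def test_segment_item_is_mean_over_segments(self, catalog):
        route = make_route(seg_responses=[{"sidewalk": 1.0}, {"sidewalk": 0.0}])
        assert aggregate_item(route, catalog_item(catalog, "sidewalk")) == 0.5

    def test_crossing_item_missing_on_crossing_free_route(self, catalog):
        route = make_route(cross_responses=[])
        assert aggregate_item(route, catalog_item(catalog, "crosswalk")) is None

    def test_constant_responses_average_to_constant(self, catalog):
        route = make_route(seg_responses=[{"street_lights": 1.0}] * 3)
        assert aggregate_item(route, catalog_item(catalog, "street_lights")) == 1.0

    def test_permutation_invariance(self, catalog):
        responses = [{"sidewalk": float(v)} for v in (1, 0, 0, 1, 1)]
        item = catalog_item(catalog, "sidewalk")
        base = aggregate_item(make_route(seg_responses=responses), item)
        rng = random.Random(3)
        for _ in range(5):
            rng.shuffle(responses)
            assert aggregate_item(make_route(seg_responses=responses), item) == base


def full_route(values_by_level):
    """One segment, one crossing, responses filled for all 14 binary items
    according to values_by_level (maps item_id -> 0/1)."""
    catalog = default_catalog()
    seg, cross, route = {}, {}, {}
    for it in catalog:
        if it.category is Category.BICYCLE_FACILITIES:
            route[it.item_id] = 0.0
            continue
        v = float(values_by_level.get(it.item_id, 0))
        {Level.ROUTE: route, Level.SEGMENT: seg, Level.CROSSING: cross}[it.level][it.item_id] = v
    return make_route(seg_responses=[seg], cross_responses=[cross], route_responses=route)


class TestTotalScore:
    def test_all_minimum_scores_zero_percent(self):
        score = total_score(full_route({}))
        assert score.total == 0 and score.percent_of_max == 0.0

    def test_all_maximum_scores_full_percent(self, catalog):
        in_total = ScoreConfig().in_total_ids()
        score = total_score(full_route({i: 1 for i in in_total}))
        assert score.percent_of_max == 100.0
        assert score.max_possible == 12  # 14 tabled items minus the 2 aesthetics items

    def test_hand_summed_half_scored_route(self):
        in_total = ScoreConfig().in_total_ids()
        assert len(in_total) == 12
        score = total_score(full_route({i: 1 for i in in_total[:6]}))
        assert score.total == 6 and score.max_possible == 12
        assert score.percent_of_max == pytest.approx(50.0)

    def test_renormalization_on_crossing_free_route(self):
        route = full_route({"sidewalk": 1})
        route.crossings = []  # the three crossing items become missing
        score = total_score(route)
        assert score.max_possible == 9  # 12 minus 3 crossing items
        assert score.percent_of_max == pytest.approx(100.0 / 9)

    def test_fail_policy_raises_on_missing_in_total_item(self):
        route = full_route({})
        route.crossings = []
        cfg = ScoreConfig(missing_policy="fail")
        with pytest.raises(ValueError, match="crosswalk"):
            total_score(route, cfg)

    def test_bike_item_flag_extends_total(self):
        route = full_route({})
        route.route_responses["bike_facility"] = 2.0
        cfg = ScoreConfig(include_bike_in_total=True)
        score = total_score(route, cfg)
        assert score.max_possible == 14 and score.total == 2.0

    def test_degenerate_catalog_rejected(self):
        catalog = [dataclasses.replace(it, in_total=False) for it in default_catalog()]
        with pytest.raises(ValueError, match="degenerate"):
            ScoreConfig(catalog=catalog)


class TestPercentOfMax:
    def test_bounds_and_direct_division(self):
        assert percent_of_max(0, 12) == 0.0
        assert percent_of_max(12, 12) == 100.0
        assert percent_of_max(4.5, 13) == pytest.approx(100 * 4.5 / 13)

    @pytest.mark.parametrize("total,maximum", [(1, 0), (5, -1), (13, 12), (-1, 12)])
    def test_invalid_inputs_rejected(self, total, maximum):
        with pytest.raises(ValueError):
            percent_of_max(total, maximum)


def scores_from_percents(percents):
    return [ParticipantScore(f"P{i}", {}, p, 100.0, p) for i, p in enumerate(percents)]


class TestQuintiles:
    def test_five_distinct_scores_span_quintiles(self):
        out = assign_quintiles(scores_from_percents([10, 20, 30, 40, 50]))
        assert [s.quintile for s in out] == [1, 2, 3, 4, 5]

    def test_hundred_distinct_scores_give_even_fifths(self):
        rng = np.random.default_rng(5)
        percents = rng.permutation(100).astype(float)
        out = assign_quintiles(scores_from_percents(percents))
        counts = np.bincount([s.quintile for s in out], minlength=6)[1:]
        assert list(counts) == [20] * 5
        # quintile is monotone in the score
        order = np.argsort(percents)
        qs = np.array([s.quintile for s in out])[order]
        assert (np.diff(qs) >= 0).all()

    def test_total_tie_shares_one_quintile(self):
        out = assign_quintiles(scores_from_percents([40.0] * 9))
        assert {s.quintile for s in out} == {3}

    def test_too_few_participants_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            assign_quintiles(scores_from_percents([1, 2, 3, 4]))


in_total_ids = ScoreConfig().in_total_ids()


class TestScoringProperties:
    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(values=st.lists(st.sampled_from(in_total_ids), min_size=0, max_size=12,
                           unique=True),
           bumped=st.sampled_from(in_total_ids))
    def test_single_response_increase_is_weakly_monotone(self, values, bumped):
        base = total_score(full_route({i: 1 for i in values}))
        raised = total_score(full_route({i: 1 for i in set(values) | {bumped}}))
        assert raised.total >= base.total
        assert raised.percent_of_max >= base.percent_of_max
        assert 0.0 <= raised.percent_of_max <= 100.0

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.lists(st.sampled_from(in_total_ids), min_size=0, max_size=12, unique=True))
    def test_constant_item_addition_preserves_perfect_and_bounds(self, values):
        """Adding an always-scored binary item moves percent toward its own
        100% contribution: perfect routes stay perfect, others cannot
        overtake a route they trailed."""
        route = full_route({i: 1 for i in values})
        base = total_score(route)
        extra = ItemDefinition("always_on", "Always on", Level.ROUTE, Category.STREETSCAPE)
        cfg = ScoreConfig(catalog=default_catalog() + [extra])
        route.route_responses["always_on"] = 1.0
        augmented = total_score(route, cfg)
        assert augmented.max_possible == base.max_possible + 1
        if base.percent_of_max == 100.0:
            assert augmented.percent_of_max == 100.0
        else:
            assert augmented.percent_of_max > base.percent_of_max

    def test_constant_item_addition_preserves_ranks(self):
        rng = np.random.default_rng(9)
        routes = []
        for _ in range(20):
            chosen = [i for i in in_total_ids if rng.random() < 0.5]
            routes.append(full_route({i: 1 for i in chosen}))
        base = [total_score(r).percent_of_max for r in routes]
        extra = ItemDefinition("always_on", "Always on", Level.ROUTE, Category.STREETSCAPE)
        cfg = ScoreConfig(catalog=default_catalog() + [extra])
        for r in routes:
            r.route_responses["always_on"] = 1.0
        augmented = [total_score(r, cfg).percent_of_max for r in routes]
        assert list(np.argsort(base, kind="stable")) == list(np.argsort(augmented, kind="stable"))
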