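import math

import pytest

from carex import (
    MiningParams,
    RankWeights,
    Rule,
    RuleSet,
    explain_instance,
    mine_rules,
    prune_by_generality,
    rank_rules,
    rule_matches_instance,
)
from carex.explain import ordered_display_items
from carex.items import Interval, Item


def make_rule(items, confidence=0.5, commonality=0.1, actionable=False, interventions=()):
    lhs = tuple(items)
    action_items = lhs[:1] if actionable else ()
    return Rule(
        lhs, 1, commonality, confidence, 100, int(100 * confidence),
        actionable=actionable, interventions=tuple(interventions),
        actionable_items=action_items,
    )


RULE3 = make_rule(
    [
        Item("primary_asthma_diagnoses_12m", Interval(8, 10)),
        Item("no_shows_12m", Interval(6, math.inf)),
    ],
    actionable=True,
)


class TestRuleMatchesInstance:
    def test_patient_satisfying_both_range_items_matches(self):
        patient = {"primary_asthma_diagnoses_12m": 8, "no_shows_12m": 7}
        assert rule_matches_instance(RULE3, patient)

    def test_too_few_no_shows_fails(self):
        patient = {"primary_asthma_diagnoses_12m": 8, "no_shows_12m": 5}
        assert not rule_matches_instance(RULE3, patient)

    def test_missing_value_never_matches(self):
        patient = {"primary_asthma_diagnoses_12m": 8, "no_shows_12m": float("nan")}
        assert not rule_matches_instance(RULE3, patient)

    def test_absent_feature_is_an_error(self):
        with pytest.raises(KeyError, match="no_shows_12m"):
            rule_matches_instance(RULE3, {"primary_asthma_diagnoses_12m": 8})


class TestRankRules:
    def test_actionable_outranks_higher_confidence_nonactionable(self):
        weak_actionable = make_rule([Item("a", "1")], confidence=0.3, actionable=True)
        strong_plain = make_rule([Item("b", "1")], confidence=0.9)
        assert rank_rules([strong_plain, weak_actionable]) == [weak_actionable, strong_plain]

    def test_shorter_rule_first_all_else_equal(self):
        short = make_rule([Item("a", "1")], confidence=0.5)
        long = make_rule([Item("b", "1"), Item("c", "1"), Item("d", "1")], confidence=0.5)
        assert rank_rules([long, short]) == [short, long]

    def test_smaller_overlap_selected_second_when_stats_tie(self):
        first = make_rule([Item("a", "1"), Item("b", "1")], confidence=0.9)
        overlapping = make_rule([Item("b", "1"), Item("c", "1")], confidence=0.5)
        fresh = make_rule([Item("d", "1"), Item("e", "1")], confidence=0.5)
        ranked = rank_rules([first, overlapping, fresh])
        assert ranked[0] == first
        # exhaustive check of both candidate orders under the greedy score:
        # fresh shares 0/2 items with the shown set, overlapping shares 1/2
        assert ranked[1] == fresh and ranked[2] == overlapping

    def test_output_is_permutation_invariant_to_input_order(self):
        rules = [
            make_rule([Item("a", "1")], confidence=0.4, actionable=True),
            make_rule([Item("b", "1")], confidence=0.8),
            make_rule([Item("c", "1"), Item("d", "1")], confidence=0.6),
        ]
        fwd = rank_rules(rules)
        rev = rank_rules(list(reversed(rules)))
        assert fwd == rev
        assert sorted(r.key() for r in fwd) == sorted(r.key() for r in rules)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            RankWeights(0, 0, 0, 0)

    def test_display_items_order_actionable_unseen_first(self):
        rule = Rule(
            (Item("a", "1"), Item("b", "1"), Item("c", "1"), Item("d", "1")),
            1, 0.1, 0.5, 10, 5,
            actionable=True,
            actionable_items=(Item("b", "1"), Item("d", "1")),
        )
        from carex.items import canonical_key

        seen = {canonical_key(Item("a", "1")), canonical_key(Item("d", "1"))}
        ordered = ordered_display_items(rule, seen)
        assert ordered == (Item("b", "1"), Item("c", "1"), Item("d", "1"), Item("a", "1"))


class TestExplainInstance:
    def linked_toy_rules(self, toy10, toy_catalog, toy_params, prune=True):
        rs = mine_rules(toy10, 1, toy_catalog, toy_params)
        return prune_by_generality(rs, 0.15) if prune else rs

    def test_post_prune_instance_matches_single_rule(self, toy10, toy_catalog, toy_params):
        rs = self.linked_toy_rules(toy10, toy_catalog, toy_params)
        expl = explain_instance({"A": 1, "B": 0}, rs, instance_id="p1")
        assert expl.n_matched == 1
        assert expl.explained

    def test_nonmatching_instance_gets_empty_explanation(self, toy10, toy_catalog, toy_params):
        rs = self.linked_toy_rules(toy10, toy_catalog, toy_params)
        expl = explain_instance({"A": 0, "B": 1}, rs)
        assert expl.n_matched == 0
        assert expl.interventions == ()
        assert not expl.explained

    def test_pre_prune_instance_matches_two_rules(self, toy10, toy_catalog, toy_params):
        rs = self.linked_toy_rules(toy10, toy_catalog, toy_params, prune=False)
        expl = explain_instance({"A": 1, "B": 1}, rs, top_k=None)
        assert expl.n_matched == 2
        rematched = [rule_matches_instance(r, {"A": 1, "B": 1}) for r in expl.matched_rules]
        assert all(rematched)

    def test_top_k_truncates_display_but_not_count(self, toy10, toy_catalog, toy_params):
        rs = self.linked_toy_rules(toy10, toy_catalog, toy_params, prune=False)
        expl = explain_instance({"A": 1, "B": 1}, rs, top_k=1)
        assert len(expl.matched_rules) == 1
        assert expl.n_matched == 2

    def test_matched_set_equals_brute_force_scan(self, toy10, toy_catalog, toy_params):
        rs = self.linked_toy_rules(toy10, toy_catalog, toy_params, prune=False)
        instance = {"A": 1, "B": 0}
        expl = explain_instance(instance, rs, top_k=None)
        expected = {r.key() for r in rs.rules if rule_matches_instance(r, instance)}
        assert {r.key() for r in expl.matched_rules} == expected

    def test_shrinking_ruleset_never_increases_matches(self, toy10, toy_catalog, toy_params):
        full = self.linked_toy_rules(toy10, toy_catalog, toy_params, prune=False)
        pruned = prune_by_generality(full, 0.15)
        for instance in ({"A": 1, "B": 1}, {"A": 1, "B": 0}, {"A": 0, "B": 0}):
            n_full = explain_instance(instance, full).n_matched
            n_pruned = explain_instance(instance, pruned).n_matched
            assert n_pruned <= n_full

    def test_distinct_actionable_items_union(self):
        r1 = make_rule([Item("a", "1"), Item("b", "1")], actionable=True)
        r2 = make_rule([Item("a", "1"), Item("c", "1")], actionable=True)
        rs = RuleSet((r1, r2), MiningParams())
        expl = explain_instance({"a": 1, "b": 1, "c": 1}, rs, top_k=None)
        assert set(expl.distinct_actionable_items) == {Item("a", "1")}
        assert expl.n_actionable_matched == 2
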