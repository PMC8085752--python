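import numpy as np
import pytest

from carex import (
    MiningParams,
    ResidualCurve,
    Rule,
    RuleSet,
    filter_by_whitelist,
    mine_rules,
    prune_by_generality,
    residual_curve,
    suggest_tau,
)
from carex.items import Item


def make_rule(features, confidence, commonality=0.5):
    lhs = tuple(Item(f, "1") for f in sorted(features))
    n_sat = 100
    n_pos = int(confidence * n_sat)
    return Rule(lhs, 1, commonality, confidence, n_sat, n_pos)


def make_set(rules, maxlen=5):
    return RuleSet(tuple(rules), MiningParams(max_lhs_items=maxlen))


def oracle_removed(rules, tau):
    """All-pairs generality check, independent of the subset-enumeration path."""
    out = set()
    for q1 in rules:
        for q2 in rules:
            if (
                q2.rhs == q1.rhs
                and set(q2.lhs) < set(q1.lhs)
                and q2.confidence >= q1.confidence - tau
            ):
                out.add(q1)
    return out


class TestPruneByGenerality:
    def test_toy_mined_set_leaves_single_general_rule(self, toy10, toy_catalog, toy_params):
        rs = mine_rules(toy10, 1, toy_catalog, toy_params)
        pruned = prune_by_generality(rs, 0.15)
        assert [r.lhs for r in pruned.rules] == [(Item("A", "1"),)]

    def test_specific_rule_survives_when_generalizer_trails_beyond_tau(self):
        q2 = make_rule(["a"], 0.50)
        q1 = make_rule(["a", "b"], 0.70)
        pruned = prune_by_generality(make_set([q2, q1]), 0.15)
        assert set(pruned.rules) == {q2, q1}  # 0.50 < 0.70 - 0.15

    def test_empty_ruleset_passes_through(self):
        assert len(prune_by_generality(make_set([]), 0.15)) == 0

    def test_invalid_tau_rejected(self):
        with pytest.raises(ValueError):
            prune_by_generality(make_set([make_rule(["a"], 0.5)]), 1.5)

    def test_single_pass_uses_input_set_not_survivors(self):
        # a -> ab -> abc chain: ab is removed by a, but ab still removes abc
        a = make_rule(["a"], 0.60)
        ab = make_rule(["a", "b"], 0.90)  # survives vs a (0.60 < 0.75)
        abc = make_rule(["a", "b", "c"], 0.95)  # removed by ab (0.90 >= 0.80)
        pruned = prune_by_generality(make_set([a, ab, abc]), 0.15)
        assert set(pruned.rules) == {a, ab}

    def test_matches_all_pairs_oracle_on_random_sets(self):
        rng = np.random.default_rng(3)
        feats = list("abcde")
        for _ in range(50):
            rules = {}
            for _ in range(rng.integers(2, 12)):
                k = int(rng.integers(1, 4))
                sel = tuple(sorted(rng.choice(feats, size=k, replace=False)))
                rules[sel] = make_rule(sel, float(np.round(rng.uniform(0.2, 1.0), 2)))
            ruleset = make_set(list(rules.values()))
            tau = float(np.round(rng.uniform(0, 0.4), 2))
            pruned = set(prune_by_generality(ruleset, tau).rules)
            expected = set(ruleset.rules) - oracle_removed(ruleset.rules, tau)
            assert pruned == expected

    def test_subset_property_and_stats_untouched(self, toy10, toy_catalog, toy_params):
        rs = mine_rules(toy10, 1, toy_catalog, toy_params)
        pruned = prune_by_generality(rs, 0.0)
        assert set(pruned.rules) <= set(rs.rules)

    def test_tau_monotonicity(self):
        rng = np.random.default_rng(9)
        rules = [
            make_rule(sel, float(np.round(rng.uniform(0.2, 1.0), 2)))
            for sel in [("a",), ("b",), ("a", "b"), ("a", "c"), ("a", "b", "c")]
        ]
        ruleset = make_set(rules)
        prev = None
        for tau in (0.0, 0.1, 0.2, 0.5, 1.0):
            cur = set(prune_by_generality(ruleset, tau).rules)
            if prev is not None:
                assert cur <= prev
            prev = cur

    def test_rerun_on_own_output_is_stable(self, toy10, toy_catalog, toy_params):
        rs = mine_rules(toy10, 1, toy_catalog, toy_params)
        once = prune_by_generality(rs, 0.15)
        twice = prune_by_generality(once, 0.15)
        assert twice.rules == once.rules


class TestWhitelistFilter:
    def test_rule_with_nonwhitelisted_item_removed(self):
        r1 = make_rule(["a"], 0.5)
        r2 = make_rule(["a", "b"], 0.5)
        out = filter_by_whitelist(make_set([r1, r2]), [Item("a", "1")])
        assert set(out.rules) == {r1}

    def test_fully_whitelisted_rules_unchanged(self):
        r = make_rule(["a", "b"], 0.5)
        out = filter_by_whitelist(make_set([r]), [Item("a", "1"), Item("b", "1")])
        assert out.rules == (r,)

    def test_empty_whitelist_empties_ruleset(self):
        out = filter_by_whitelist(make_set([make_rule(["a"], 0.5)]), [])
        assert len(out) == 0


class TestResidualCurve:
    def test_toy_curve_constant_because_tie_fires_at_zero(self, toy10, toy_catalog, toy_params):
        rs = mine_rules(toy10, 1, toy_catalog, toy_params)
        curve = residual_curve(rs, [0.0, 0.1, 0.2])
        assert curve.counts == (1, 1, 1)

    def test_two_rule_curve_counts(self):
        q2 = make_rule(["a"], 0.50)
        q1 = make_rule(["a", "b"], 0.70)
        curve = residual_curve(make_set([q2, q1]), [0.1, 0.2, 0.3])
        # at tau=0.2 the generalizer is within reach (0.50 >= 0.70-0.20)
        assert curve.counts == (2, 1, 1)

    def test_single_rule_curve_is_constant(self):
        curve = residual_curve(make_set([make_rule(["a"], 0.5)]), [0.0, 0.1, 0.2])
        assert curve.counts == (1, 1, 1)

    def test_unsorted_grid_rejected(self, toy10, toy_catalog, toy_params):
        rs = mine_rules(toy10, 1, toy_catalog, toy_params)
        with pytest.raises(ValueError):
            residual_curve(rs, [0.2, 0.1])

    def test_counts_nonincreasing_invariant_enforced(self):
        with pytest.raises(ValueError):
            ResidualCurve(((0.1, 5), (0.2, 7)))


class TestSuggestTau:
    def test_knee_of_fast_then_slow_decline(self):
        curve = ResidualCurve(
            ((0.05, 1000), (0.10, 200), (0.15, 100), (0.20, 95), (0.25, 90))
        )
        assert suggest_tau(curve) == 0.15

    def test_linear_log_decline_warns_and_returns_smallest_interior(self):
        counts = [1024 >> i for i in range(5)]  # exactly log-linear
        curve = ResidualCurve(tuple((0.05 * (i + 1), c) for i, c in enumerate(counts)))
        with pytest.warns(UserWarning):
            tau = suggest_tau(curve)
        assert tau == pytest.approx(0.10)

    def test_constant_curve_warns_and_returns_smallest(self):
        curve = ResidualCurve(((0.1, 7), (0.2, 7), (0.3, 7)))
        with pytest.warns(UserWarning, match="constant"):
            assert suggest_tau(curve) == 0.1

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            suggest_tau(ResidualCurve(((0.1, 10), (0.2, 5))))
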