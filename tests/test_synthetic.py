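import numpy as np
import pandas as pd
import pytest

from carex import (
    MiningParams,
    PlantedRule,
    SyntheticSpec,
    brute_force_mine,
    build_item_catalog,
    expected_rule_stats,
    generate_cohort,
    generate_scores,
    mine_rules,
    rule_stats,
    summarize_outcome,
)
from carex.items import Item

SMALL = SyntheticSpec(n_instances=20_000, seed=1)


class TestSpecValidation:
    def test_negative_rate_closed_form(self):
        pr = PlantedRule(2, 0.5, 0.3)
        q = pr.negative_rate(0.02)
        assert q == pytest.approx(0.5 * 0.02 * (1 / 0.3 - 1) / 0.98)
        assert q == pytest.approx(0.02381, abs=1e-5)

    def test_uninformative_confidence_equals_prevalence(self):
        # f = π makes the lhs rate identical in both classes (independence)
        pi = 0.02
        pr = PlantedRule(2, 0.4, pi)
        assert pr.negative_rate(pi) == pytest.approx(pr.commonality)

    def test_infeasible_targets_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            SyntheticSpec(
                prevalence=0.5,
                planted_rules=(PlantedRule(2, 1.0, 0.3),),
            )

    def test_expected_stats_se_formulas(self):
        spec = SyntheticSpec(n_instances=50_000, prevalence=0.02)
        est = expected_rule_stats(spec)
        assert len(est) == 2
        assert est[0]["se_commonality"] == pytest.approx(np.sqrt(0.25 / 1000), abs=1e-6)

    def test_certain_commonality_has_zero_se(self):
        spec = SyntheticSpec(planted_rules=(PlantedRule(2, 1.0, 0.5),))
        assert expected_rule_stats(spec)[0]["se_commonality"] == 0.0


class TestGenerateCohort:
    def test_same_seed_reproduces_identical_tables(self):
        c1, t1 = generate_cohort(SMALL)
        c2, t2 = generate_cohort(SMALL)
        pd.testing.assert_frame_equal(c1.data, c2.data)
        assert t1 == t2

    def test_different_seed_differs(self):
        c1, _ = generate_cohort(SMALL)
        c2, _ = generate_cohort(SyntheticSpec(n_instances=20_000, seed=2))
        assert not c1.data.equals(c2.data)

    def test_prevalence_within_three_se(self):
        cohort, _ = generate_cohort(SMALL)
        pi, n = SMALL.prevalence, SMALL.n_instances
        se = np.sqrt(pi * (1 - pi) / n)
        assert abs(cohort.outcome.mean() - pi) <= 3 * se

    def test_planted_conjunction_rates_near_targets(self):
        # checked at the generator's default (study-condition) size, where
        # the +-3 SE band is the stated recovery guarantee
        spec = SyntheticSpec(seed=1)
        cohort, truth = generate_cohort(spec)
        est = expected_rule_stats(spec)
        for j, pr in enumerate(spec.planted_rules):
            c, f, n_sat, _ = rule_stats(spec.rule_items(j), 1, cohort)
            assert abs(c - pr.commonality) <= 3 * est[j]["se_commonality"]
            assert abs(f - pr.confidence) <= 3 * est[j]["se_confidence"]

    def test_subrule_contamination_creates_strict_subset_support(self):
        cohort, _ = generate_cohort(SMALL)
        item = SMALL.rule_items(0)[0]
        single = rule_stats([item], 1, cohort)
        full = rule_stats(SMALL.rule_items(0), 1, cohort)
        assert single[2] > full[2]  # the single item fires beyond the conjunction

    def test_truth_sheet_documents_rules(self):
        _, truth = generate_cohort(SMALL)
        assert len(truth["planted_rules"]) == 2
        assert truth["planted_rules"][0]["confidence"] == 0.3


class TestRecoveryByMining:
    def test_planted_rules_recovered_with_stats_in_band(self):
        """Mining below the targets must surface every planted lhs with
        estimated commonality/confidence within 3 binomial SEs."""
        params = MiningParams(min_commonality=0.05, min_confidence=0.1, max_lhs_items=2)
        for seed in (11, 12):
            spec = SyntheticSpec(n_instances=20_000, seed=seed)
            cohort, _ = generate_cohort(spec)
            catalog = build_item_catalog(
                cohort,
                top_features=[f for j in range(2) for f in spec.rule_features(j)],
            )
            mined = mine_rules(cohort, 1, catalog, params)
            by_lhs = {frozenset(r.lhs): r for r in mined.rules}
            est = expected_rule_stats(spec)
            for j, pr in enumerate(spec.planted_rules):
                rule = by_lhs.get(frozenset(spec.rule_items(j)))
                assert rule is not None, f"planted rule {j} not mined (seed {seed})"
                assert abs(rule.commonality - pr.commonality) <= 3 * est[j]["se_commonality"]
                assert abs(rule.confidence - pr.confidence) <= 3 * est[j]["se_confidence"]

    def test_no_signal_control_yields_no_confident_rules(self):
        """With nothing planted, no rule should reach confidence ≥ 3π."""
        counts = []
        for seed in (21, 22, 23):
            spec = SyntheticSpec(
                n_instances=50_000, planted_rules=(), n_noise_features=4, seed=seed
            )
            cohort, _ = generate_cohort(spec)
            catalog = build_item_catalog(
                cohort, top_features=[f"noise{i}" for i in range(4)]
            )
            params = MiningParams(
                min_commonality=0.01, min_confidence=3 * spec.prevalence, max_lhs_items=2
            )
            counts.append(len(mine_rules(cohort, 1, catalog, params)))
        assert sorted(counts)[len(counts) // 2] == 0  # median across seeds


class TestGenerateScores:
    def test_scores_deterministic_and_aligned(self):
        cohort, _ = generate_cohort(SMALL)
        s1 = generate_scores(cohort, SMALL)
        s2 = generate_scores(cohort, SMALL)
        pd.testing.assert_series_equal(s1, s2)
        assert len(s1) == len(cohort)

    def test_scores_informative(self):
        cohort, _ = generate_cohort(SMALL)
        s = generate_scores(cohort, SMALL)
        y = pd.Series(cohort.outcome.to_numpy(), index=cohort.ids().to_numpy())
        assert s[y == 1].mean() > s[y == 0].mean() + 0.5
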