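"""Per-instance explanations: match rules to a patient and rank them.

A rule *suits* a patient when every left-hand-side item is satisfied by the
patient's feature values (missing never satisfies). Every suiting rule is
one reason why the black-box model's high-risk call makes sense; the ranked
top few are displayed, with interventions next to actionable rules.

The ranking realizes the display guidance for rule lists — actionable rules
first; then, greedily, prefer short, high-confidence, high-commonality
rules whose items add information not already shown — as an explicit
weighted score, since only the pairwise preferences (not a formula) are
prescribed. Weights are fully configurable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import pandas as pd

from .items import Item, canonical_key
from .mining import Rule, RuleSet

__all__ = [
    "RankWeights",
    "Explanation",
    "rule_matches_instance",
    "rank_rules",
    "ordered_display_items",
    "explain_instance",
]


@dataclass(frozen=True)
class RankWeights:
    """Non-negative weights of the four graded ranking factors.

    ``brevity`` penalizes extra left-hand-side items, ``confidence`` and
    ``commonality`` reward precise and high-coverage rules, ``redundancy``
    penalizes items already shown in higher-ranked rules. Actionability is
    a strict tier, not a weight.
    """

    brevity: float = 1.0
    confidence: float = 1.0
    commonality: float = 1.0
    redundancy: float = 1.0

    def __post_init__(self) -> None:
        vals = (self.brevity, self.confidence, self.commonality, self.redundancy)
        if any(v < 0 for v in vals):
            raise ValueError("rank weights must be non-negative")
        if all(v == 0 for v in vals):
            raise ValueError("rank weights must not all be zero")


def rule_matches_instance(rule: Rule, instance: Mapping[str, Any] | pd.Series) -> bool:
    """True iff every left-hand-side item is satisfied by the instance."""
    for it in rule.lhs:
        if it.feature not in instance:
            raise KeyError(f"feature {it.feature!r} absent from instance")
        if not it.matches(instance[it.feature]):
            return False
    return True


def _score(rule: Rule, seen: set, weights: RankWeights, max_lhs_items: int) -> float:
    s = rule.n_items
    brevity = (s - 1) / (max_lhs_items - 1) if max_lhs_items > 1 else 0.0
    overlap = sum(1 for it in rule.lhs if canonical_key(it) in seen) / s
    return (
        weights.confidence * rule.confidence
        + weights.commonality * rule.commonality
        - weights.brevity * brevity
        - weights.redundancy * overlap
    )


def rank_rules(
    matched: Sequence[Rule],
    weights: RankWeights = RankWeights(),
    max_lhs_items: int = 5,
) -> list[Rule]:
    """Order matched rules for display.

    Actionable rules come strictly before nonactionable ones. Within each
    tier the next rule is the one maximizing the weighted score given the
    items already shown; ties break on canonical left-hand-side order. The
    output is a permutation of the input, invariant to input order.
    """
    ranked: list[Rule] = []
    seen: set = set()
    for tier in (True, False):
        pool = sorted((r for r in matched if r.actionable is tier), key=Rule.key)
        while pool:
            best = max(
                enumerate(pool),
                key=lambda ir: (_score(ir[1], seen, weights, max_lhs_items), -ir[0]),
            )[0]
            rule = pool.pop(best)
            ranked.append(rule)
            seen.update(canonical_key(it) for it in rule.lhs)
    return ranked


def ordered_display_items(rule: Rule, seen_before: set) -> tuple[Item, ...]:
    """Left-hand-side items in display order: actionable-and-unseen first,
    then unseen, then actionable-seen, then seen; canonical order within
    each group. ``seen_before`` holds canonical keys of items shown in
    higher-ranked rules."""
    actionable = {canonical_key(it) for it in rule.actionable_items}

    def group(it: Item) -> int:
        a = canonical_key(it) in actionable
        unseen = canonical_key(it) not in seen_before
        if a and unseen:
            return 0
        if unseen:
            return 1
        if a:
            return 2
        return 3

    return tuple(sorted(rule.lhs, key=lambda it: (group(it), it.sort_key())))


@dataclass(frozen=True)
class Explanation:
    """All rules suiting one instance, ranked, with actionable content.

    ``matched_rules`` holds the displayed (top-k) rules in rank order while
    the counts and distinct-item/intervention unions cover *every* suiting
    rule, so coverage statistics do not depend on the display depth.
    """

    instance_id: Any
    matched_rules: tuple[Rule, ...]
    display_items: tuple[tuple[Item, ...], ...]
    n_matched: int
    n_actionable_matched: int
    distinct_actionable_items: tuple[Item, ...]
    interventions: tuple[str, ...]

    @property
    def explained(self) -> bool:
        return self.n_matched >= 1

    def to_json(self) -> dict:
        return {
            "instance_id": self.instance_id,
            "n_matched": self.n_matched,
            "n_actionable_matched": self.n_actionable_matched,
            "distinct_actionable_items": [it.to_json() for it in self.distinct_actionable_items],
            "interventions": list(self.interventions),
            "matched_rules": [r.to_json() for r in self.matched_rules],
            "display_items": [[it.to_json() for it in row] for row in self.display_items],
        }

    def describe(self, max_rules: int | None = None) -> str:
        lines = [f"instance {self.instance_id}: {self.n_matched} rule(s) suit "
                 f"({self.n_actionable_matched} actionable)"]
        rows = self.matched_rules if max_rules is None else self.matched_rules[:max_rules]
        for rule, items in zip(rows, self.display_items):
            lhs = " AND ".join(it.describe() for it in items)
            flag = "actionable" if rule.actionable else "nonactionable"
            lines.append(f"  [{flag}] {lhs}  (conf={rule.confidence:.3f}, comm={rule.commonality:.4f})")
            for t in rule.interventions:
                lines.append(f"      -> {t}")
        return "\n".join(lines)


def explain_instance(
    instance: Mapping[str, Any] | pd.Series,
    ruleset: RuleSet,
    weights: RankWeights = RankWeights(),
    top_k: int | None = 3,
    instance_id: Any = None,
) -> Explanation:
    """Assemble the explanation for one (typically predicted-positive) instance.

    Matching is exhaustive over the rule set; ranking follows
    :func:`rank_rules`; ``matched_rules`` is truncated to ``top_k`` for
    display (``None`` keeps all) while ``n_matched`` reports the full count.
    """
    matched = [r for r in ruleset.rules if rule_matches_instance(r, instance)]
    ranked = rank_rules(matched, weights, ruleset.params.max_lhs_items)

    distinct: dict[tuple, Item] = {}
    interventions: list[str] = []
    n_actionable = 0
    for r in ranked:
        if r.actionable:
            n_actionable += 1
        for it in r.actionable_items:
            distinct.setdefault(canonical_key(it), it)
        for t in r.interventions:
            if t not in interventions:
                interventions.append(t)

    shown = ranked if top_k is None else ranked[:top_k]
    seen: set = set()
    display_items = []
    for r in shown:
        display_items.append(ordered_display_items(r, seen))
        seen.update(canonical_key(it) for it in r.lhs)

    return Explanation(
        instance_id=instance_id,
        matched_rules=tuple(shown),
        display_items=tuple(display_items),
        n_matched=len(matched),
        n_actionable_matched=n_actionable,
        distinct_actionable_items=tuple(
            sorted(distinct.values(), key=Item.sort_key)
        ),
        interventions=tuple(interventions),
    )
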