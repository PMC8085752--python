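"""Class-association-rule mining.

A rule is a conjunction of items ``r_1 AND ... AND r_s → u`` whose right-hand
side is a fixed outcome value (by default the poor outcome, ``u = 1``). Two
class-conditional statistics govern mining:

* **commonality** — the fraction of outcome-``u`` instances whose features
  satisfy the left-hand side (class-conditional support; recall-like);
* **confidence** — the fraction of instances satisfying the left-hand side
  that carry outcome ``u`` (precision-like).

``mine_rules`` is an Apriori-style level-wise search. Commonality is
anti-monotone (adding an item can only shrink the satisfying set), so
candidate left-hand sides are pruned on the minimum-commonality threshold;
confidence is *not* anti-monotone and filters only at rule emission.
``brute_force_mine`` is the exhaustive enumerator with the identical
contract, kept as an independent oracle for small catalogs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .items import MISSING, Interval, Item, canonical_key, canonical_lhs

__all__ = [
    "MiningParams",
    "Rule",
    "RuleSet",
    "build_item_catalog",
    "item_match_vector",
    "rule_stats",
    "mine_rules",
    "brute_force_mine",
]

BRUTE_FORCE_CATALOG_GUARD = 20


@dataclass(frozen=True)
class MiningParams:
    """The five tunables of the mining/pruning process.

    Defaults are the study settings for a hard-to-predict ~2%-prevalence
    outcome: minimum commonality 0.08%, minimum confidence 25%, at most 5
    left-hand-side items, confidence-difference threshold τ = 0.15, and
    rules built over the 50 most important features.
    """

    min_commonality: float = 0.0008
    min_confidence: float = 0.25
    max_lhs_items: int = 5
    confidence_diff_threshold: float = 0.15
    n_top_features: int = 50

    def __post_init__(self) -> None:
        for name in ("min_commonality", "min_confidence", "confidence_diff_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.max_lhs_items < 1:
            raise ValueError("max_lhs_items must be >= 1")
        if self.n_top_features < 1:
            raise ValueError("n_top_features must be >= 1")


@dataclass(frozen=True)
class Rule:
    """One class association rule with its training-set statistics."""

    lhs: tuple[Item, ...]
    rhs: int
    commonality: float
    confidence: float
    n_satisfying: int
    n_satisfying_positive: int
    actionable: bool = False
    interventions: tuple[str, ...] = ()
    actionable_items: tuple[Item, ...] = ()

    @property
    def n_items(self) -> int:
        return len(self.lhs)

    def key(self) -> tuple:
        return (tuple(it.sort_key() for it in self.lhs), self.rhs)

    def describe(self) -> str:
        lhs = " AND ".join(it.describe() for it in self.lhs)
        return (
            f"{lhs} -> outcome={self.rhs}  "
            f"(commonality={self.commonality:.4f}, confidence={self.confidence:.4f})"
        )

    def to_json(self) -> dict:
        return {
            "lhs": [it.to_json() for it in self.lhs],
            "rhs": self.rhs,
            "commonality": self.commonality,
            "confidence": self.confidence,
            "n_satisfying": self.n_satisfying,
            "n_satisfying_positive": self.n_satisfying_positive,
            "actionable": self.actionable,
            "interventions": list(self.interventions),
            "actionable_items": [it.to_json() for it in self.actionable_items],
        }

    @classmethod
    def from_json(cls, obj: dict) -> "Rule":
        return cls(
            lhs=tuple(Item.from_json(o) for o in obj["lhs"]),
            rhs=int(obj["rhs"]),
            commonality=float(obj["commonality"]),
            confidence=float(obj["confidence"]),
            n_satisfying=int(obj["n_satisfying"]),
            n_satisfying_positive=int(obj["n_satisfying_positive"]),
            actionable=bool(obj.get("actionable", False)),
            interventions=tuple(obj.get("interventions", ())),
            actionable_items=tuple(Item.from_json(o) for o in obj.get("actionable_items", ())),
        )


@dataclass(frozen=True)
class RuleSet:
    rules: tuple[Rule, ...]
    params: MiningParams
    provenance: str = ""

    def __post_init__(self) -> None:
        keys = [r.key() for r in self.rules]
        if len(set(keys)) != len(keys):
            raise ValueError("rules must be unique by (lhs, rhs)")

    def __len__(self) -> int:
        return len(self.rules)

    def to_json(self, path: str | Path) -> None:
        obj = {
            "params": self.params.__dict__,
            "provenance": self.provenance,
            "rules": [r.to_json() for r in self.rules],
        }
        Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RuleSet":
        obj = json.loads(Path(path).read_text())
        return cls(
            rules=tuple(Rule.from_json(o) for o in obj["rules"]),
            params=MiningParams(**obj["params"]),
            provenance=obj.get("provenance", ""),
        )


def table_fingerprint(train: CohortTable) -> str:
    h = hashlib.sha256()
    h.update(pd.util.hash_pandas_object(train.data, index=False).to_numpy().tobytes())
    h.update(",".join(c.name for c in train.schema.columns).encode())
    return h.hexdigest()[:16]


def build_item_catalog(
    train: CohortTable,
    top_features: Sequence[str] | None = None,
    whitelist: Iterable[Item] | None = None,
) -> list[Item]:
    """All (feature, level) items over the allowed features.

    ``top_features`` restricts to the most important features of the upstream
    model; ``whitelist`` (clinician-labeled values/ranges) intersects the
    catalog. The explicit ``"missing"`` level never becomes an item.
    """
    feat_names = set(train.schema.feature_names)
    if top_features is None:
        features = list(train.schema.feature_names)
    else:
        unknown = [f for f in top_features if f not in feat_names]
        if unknown:
            raise KeyError(f"top_features not in schema: {unknown}")
        features = list(top_features)
    if whitelist is not None:
        wl = list(whitelist)
        unknown = sorted({it.feature for it in wl} - feat_names)
        if unknown:
            raise KeyError(f"whitelist references unknown feature(s): {unknown}")
        wl_keys = {canonical_key(it) for it in wl}
    items: list[Item] = []
    for feat in features:
        levels = sorted({str(v) for v in train.data[feat].dropna()} - {MISSING})
        for lvl in levels:
            it = Item(feat, lvl)
            if whitelist is not None and canonical_key(it) not in wl_keys:
                continue
            items.append(it)
    items = sorted(set(items), key=Item.sort_key)
    if not items:
        raise ValueError("empty item catalog")
    return items


def item_match_vector(item: Item, data: pd.DataFrame) -> np.ndarray:
    """Boolean vector of rows satisfying ``item``; missing never matches."""
    if item.feature not in data.columns:
        raise KeyError(f"feature {item.feature!r} absent from table")
    col = data[item.feature]
    if isinstance(item.value, Interval) and pd.api.types.is_numeric_dtype(col):
        v = col.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            return (v >= item.value.lo) & (v < item.value.hi)
    if not isinstance(item.value, Interval):
        arr = col.to_numpy()
        out = np.array([str(x) == item.value for x in arr], dtype=bool)
        out &= ~col.isna().to_numpy()
        out &= np.array([not (isinstance(x, str) and x == MISSING) for x in arr], dtype=bool)
        return out
    return np.array([item.matches(x) for x in col.to_numpy()], dtype=bool)


def rule_stats(
    lhs: Sequence[Item],
    rhs: int,
    train: CohortTable,
) -> tuple[float, float, int, int]:
    """(commonality, confidence, n_satisfying, n_satisfying_positive).

    Confidence is reported as 0.0 (zero-coverage sentinel) when no instance
    satisfies the left-hand side.
    """
    pos = (train.outcome == rhs).to_numpy()
    n_pos = int(pos.sum())
    if n_pos == 0:
        raise ValueError(f"no training instance with outcome {rhs!r}")
    sat = np.ones(len(train), dtype=bool)
    for it in lhs:
        sat &= item_match_vector(it, train.data)
    n_sat = int(sat.sum())
    n_sat_pos = int((sat & pos).sum())
    commonality = n_sat_pos / n_pos
    confidence = n_sat_pos / n_sat if n_sat else 0.0
    return commonality, confidence, n_sat, n_sat_pos


def _emit(
    lhs: tuple[Item, ...],
    rhs: int,
    n_sat: int,
    n_sat_pos: int,
    n_pos: int,
    params: MiningParams,
) -> Rule | None:
    commonality = n_sat_pos / n_pos
    confidence = n_sat_pos / n_sat if n_sat else 0.0
    if n_sat_pos < 1:
        return None  # a rule never observed with the outcome is vacuous
    if commonality >= params.min_commonality and confidence >= params.min_confidence:
        return Rule(lhs, rhs, commonality, confidence, n_sat, n_sat_pos)
    return None


def _sorted_ruleset(rules: list[Rule], params: MiningParams, provenance: str) -> RuleSet:
    rules = sorted(rules, key=lambda r: (r.n_items, r.key()))
    return RuleSet(tuple(rules), params, provenance)


def mine_rules(
    train: CohortTable,
    rhs: int,
    catalog: Sequence[Item],
    params: MiningParams,
) -> RuleSet:
    """Level-wise (Apriori-style) mining of all rules over ``catalog``.

    Emits exactly the rules with 1 ≤ s ≤ ``max_lhs_items`` items (one item
    per feature) whose commonality and confidence clear the thresholds.
    Candidate growth is pruned on commonality only.
    """
    items = sorted(set(catalog), key=Item.sort_key)
    if not items:
        raise ValueError("empty item catalog")
    pos = (train.outcome == rhs).to_numpy()
    n_pos = int(pos.sum())
    if n_pos == 0:
        raise ValueError(f"no training instance with outcome {rhs!r}")

    vectors = np.column_stack([item_match_vector(it, train.data) for it in items])
    features = [it.feature for it in items]
    emitted: list[Rule] = []

    # level 1
    frontier: dict[tuple[int, ...], np.ndarray] = {}
    for j in range(len(items)):
        sat = vectors[:, j]
        n_sat, n_sat_pos = int(sat.sum()), int((sat & pos).sum())
        rule = _emit((items[j],), rhs, n_sat, n_sat_pos, n_pos, params)
        if rule is not None:
            emitted.append(rule)
        if n_sat_pos / n_pos >= params.min_commonality:
            frontier[(j,)] = sat

    level = 1
    while frontier and level < params.max_lhs_items:
        survivors = set(frontier)
        next_frontier: dict[tuple[int, ...], np.ndarray] = {}
        keys = sorted(frontier)
        for a, b in combinations(keys, 2):
            if a[:-1] != b[:-1]:
                continue
            cand = tuple(sorted(set(a) | set(b)))
            feats = [features[j] for j in cand]
            if len(set(feats)) != len(feats):
                continue
            if any(cand[:i] + cand[i + 1 :] not in survivors for i in range(len(cand))):
                continue
            sat = np.logical_and.reduce(vectors[:, list(cand)], axis=1)
            n_sat, n_sat_pos = int(sat.sum()), int((sat & pos).sum())
            lhs = tuple(items[j] for j in cand)
            rule = _emit(lhs, rhs, n_sat, n_sat_pos, n_pos, params)
            if rule is not None:
                emitted.append(rule)
            if n_sat_pos / n_pos >= params.min_commonality:
                next_frontier[cand] = sat
        frontier = next_frontier
        level += 1

    return _sorted_ruleset(emitted, params, table_fingerprint(train))


def brute_force_mine(
    train: CohortTable,
    rhs: int,
    catalog: Sequence[Item],
    params: MiningParams,
) -> RuleSet:
    """Exhaustive enumeration oracle; identical contract to :func:`mine_rules`.

    Guarded to small catalogs (≤ 20 items) since it enumerates every item
    combination up to ``max_lhs_items``.
    """
    items = sorted(set(catalog), key=Item.sort_key)
    if len(items) > BRUTE_FORCE_CATALOG_GUARD:
        raise ValueError(
            f"brute_force_mine is limited to {BRUTE_FORCE_CATALOG_GUARD} items, got {len(items)}"
        )
    if not items:
        raise ValueError("empty item catalog")
    n_pos = int((train.outcome == rhs).sum())
    if n_pos == 0:
        raise ValueError(f"no training instance with outcome {rhs!r}")
    emitted: list[Rule] = []
    max_s = min(params.max_lhs_items, len(items))
    for s in range(1, max_s + 1):
        for combo in combinations(items, s):
            feats = [it.feature for it in combo]
            if len(set(feats)) != len(feats):
                continue
            commonality, confidence, n_sat, n_sat_pos = rule_stats(combo, rhs, train)
            rule = _emit(tuple(combo), rhs, n_sat, n_sat_pos, n_pos, params)
            if rule is not None:
                emitted.append(rule)
    return _sorted_ruleset(emitted, params, table_fingerprint(train))
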