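"""Synthetic imbalanced cohorts with planted association rules.

Real cohorts of this kind (EHR-derived, ~2% positive prevalence, mixed
continuous/categorical features) are private, so every pipeline stage is
exercised on generated data whose ground truth is known in closed form.

Each planted rule is a conjunction of binary items on its own disjoint
feature set. Among positives the full conjunction holds with probability
``c`` (the target commonality); among negatives with

    q = c · π · (1/f − 1) / (1 − π)

which makes the rule's expected confidence exactly ``f`` at prevalence
``π``. Outside the planted conjunction, individual items still fire
independently at a contamination rate — so strict sub-rules of a planted
rule exist and generality pruning has real work to do — but a draw in which
*all* items fire by chance is broken by clearing one item, keeping the
conjunction probabilities exact. Noise features are independent of the
outcome. Everything is deterministic under the spec's seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import CohortTable, ColumnSpec, FeatureSchema
from .items import Item

__all__ = ["PlantedRule", "SyntheticSpec", "generate_cohort", "expected_rule_stats",
           "generate_scores"]


@dataclass(frozen=True)
class PlantedRule:
    n_lhs_features: int = 2
    commonality: float = 0.5
    confidence: float = 0.3

    def __post_init__(self) -> None:
        if self.n_lhs_features < 1:
            raise ValueError("planted rule needs >= 1 feature")
        if not 0 < self.commonality <= 1 or not 0 < self.confidence <= 1:
            raise ValueError("target commonality/confidence must be in (0, 1]")

    def negative_rate(self, prevalence: float) -> float:
        """Conjunction rate among negatives giving expected confidence f."""
        c, f, pi = self.commonality, self.confidence, prevalence
        return c * pi * (1.0 / f - 1.0) / (1.0 - pi)


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions: cohort size, imbalance and planted signal.

    Defaults emulate the target regime — a large cohort at ~2% prevalence
    with two planted rules of moderate commonality and confidence well
    above prevalence, binary noise features, and a couple of continuous
    noise features so discretization runs too.
    """

    n_instances: int = 50_000
    prevalence: float = 0.02
    planted_rules: tuple[PlantedRule, ...] = (
        PlantedRule(2, 0.5, 0.3),
        PlantedRule(2, 0.2, 0.4),
    )
    n_noise_features: int = 6
    noise_rate: float = 0.10
    item_contamination_rate: float = 0.10
    n_continuous_features: int = 2
    years: tuple[int, ...] = (2012, 2013, 2014, 2015, 2016, 2017)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        if self.n_instances < 1:
            raise ValueError("n_instances must be >= 1")
        for j, pr in enumerate(self.planted_rules):
            q = pr.negative_rate(self.prevalence)
            if q > 1.0:
                raise ValueError(
                    f"planted rule {j} infeasible: c·π·(1/f−1)/(1−π) = {q:.4f} > 1 "
                    f"(c={pr.commonality}, f={pr.confidence}, π={self.prevalence})"
                )

    def rule_features(self, j: int) -> list[str]:
        return [f"rule{j}_item{i}" for i in range(self.planted_rules[j].n_lhs_features)]

    def rule_items(self, j: int) -> list[Item]:
        return [Item(f, "1") for f in self.rule_features(j)]

    def schema(self) -> FeatureSchema:
        cols = [ColumnSpec("pid", "categorical", "id"),
                ColumnSpec("year", "continuous", "year")]
        for j in range(len(self.planted_rules)):
            cols += [ColumnSpec(f, "categorical") for f in self.rule_features(j)]
        cols += [ColumnSpec(f"noise{i}", "categorical")
                 for i in range(self.n_noise_features)]
        cols += [ColumnSpec(f"cont{i}", "continuous")
                 for i in range(self.n_continuous_features)]
        cols.append(ColumnSpec("outcome", "categorical", "outcome"))
        return FeatureSchema(tuple(cols))


def generate_cohort(spec: SyntheticSpec) -> tuple[CohortTable, dict]:
    """Draw one cohort; returns the table and its ground-truth sheet."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_instances
    y = (rng.random(n) < spec.prevalence).astype(int)
    data: dict[str, np.ndarray] = {
        "pid": np.arange(1, n + 1),
        "year": rng.choice(np.asarray(spec.years), size=n),
    }
    # conjunction rate among negatives from the *realized* positive count, so
    # the expected confidence equals the target conditionally on this cohort
    # (the nominal closed form holds in expectation either way)
    pi_hat = float(y.mean()) if 0 < y.sum() < n else spec.prevalence
    truth_rules = []
    for j, pr in enumerate(spec.planted_rules):
        q = min(pr.negative_rate(pi_hat), 1.0)
        p_conj = np.where(y == 1, pr.commonality, q)
        conj = rng.random(n) < p_conj
        feats = spec.rule_features(j)
        cols = np.zeros((n, len(feats)), dtype=int)
        cols[conj] = 1
        free = ~conj
        noise = rng.random((int(free.sum()), len(feats))) < spec.item_contamination_rate
        if len(feats) > 1:
            all_on = noise.all(axis=1)
            if all_on.any():
                kill = rng.integers(0, len(feats), size=int(all_on.sum()))
                noise[np.flatnonzero(all_on), kill] = False
        else:
            noise[:] = False  # single-item rule: any chance firing changes c/f
        cols[free] = noise.astype(int)
        for k, f in enumerate(feats):
            data[f] = cols[:, k]
        truth_rules.append({
            "items": [it.to_json() for it in spec.rule_items(j)],
            "commonality": pr.commonality,
            "confidence": pr.confidence,
            "negative_rate_q": q,
        })
    for i in range(spec.n_noise_features):
        data[f"noise{i}"] = (rng.random(n) < spec.noise_rate).astype(int)
    for i in range(spec.n_continuous_features):
        data[f"cont{i}"] = np.round(rng.normal(50.0, 10.0, size=n), 3)
    data["outcome"] = y
    schema = spec.schema()
    df = pd.DataFrame({c.name: data[c.name] for c in schema.columns})
    truth = {
        "seed": spec.seed,
        "n_instances": n,
        "prevalence": spec.prevalence,
        "n_positive": int(y.sum()),
        "planted_rules": truth_rules,
    }
    return CohortTable(df, schema), truth


def expected_rule_stats(spec: SyntheticSpec) -> list[dict]:
    """Targets plus binomial standard errors at the spec's size, per rule.

    ``se_commonality = sqrt(c(1−c)/(nπ))`` (the commonality estimate
    averages over ~nπ positives); ``se_confidence`` uses the expected
    number of satisfying instances ``nπc/f``.
    """
    out = []
    n, pi = spec.n_instances, spec.prevalence
    for j, pr in enumerate(spec.planted_rules):
        c, f = pr.commonality, pr.confidence
        n_sat = n * pi * c / f
        out.append({
            "rule": j,
            "items": [it.to_json() for it in spec.rule_items(j)],
            "commonality": c,
            "confidence": f,
            "se_commonality": math.sqrt(c * (1 - c) / (n * pi)),
            "se_confidence": math.sqrt(f * (1 - f) / n_sat) if n_sat > 0 else 0.0,
        })
    return out


def generate_scores(
    cohort: CohortTable,
    spec: SyntheticSpec,
    seed: int | None = None,
    signal: float = 2.0,
) -> pd.Series:
    """Seeded stand-in for the external black-box classifier's risk scores.

    Scores load on the planted conjunctions and (with weight ``signal``) on
    the outcome itself, plus unit Gaussian noise — an imperfect but
    informative ranker, as the method assumes. Indexed by instance id.
    """
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    n = len(cohort)
    score = rng.normal(0.0, 1.0, size=n)
    y = cohort.outcome.to_numpy()
    score = score + signal * y
    for j in range(len(spec.planted_rules)):
        conj = np.ones(n, dtype=bool)
        for f in spec.rule_features(j):
            conj &= cohort.data[f].to_numpy() == 1
        score = score + 1.0 * conj
    ids = cohort.ids().to_numpy()
    return pd.Series(np.round(score, 6), index=ids, name="score")


def truth_to_json(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
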