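"""Rule pruning: confidence-difference generality pruning, whitelist
filtering, and the residual-rule curve used to pick τ.

The generality prune removes a specific rule q1 whenever a strictly more
general rule q2 (left-hand side a strict subset, same right-hand side)
exists in the input set with confidence(q2) ≥ confidence(q1) − τ. The
comparison is a single pass against the *input* set, so removal decisions
are order-independent: a specific rule is dropped even if its generalizer
is itself dropped by a yet more general rule.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from .items import Item, canonical_key
from .mining import Rule, RuleSet

__all__ = [
    "prune_by_generality",
    "filter_by_whitelist",
    "ResidualCurve",
    "residual_curve",
    "suggest_tau",
]


def _lhs_key(rule: Rule) -> frozenset:
    return frozenset(canonical_key(it) for it in rule.lhs)


def prune_by_generality(ruleset: RuleSet, tau: float) -> RuleSet:
    """Drop every rule subsumed (within τ confidence) by a more general one.

    A rule is kept iff no strict-subset rule with the same right-hand side in
    the input set has confidence ≥ its own confidence − τ. Stats and order of
    the surviving rules are untouched.
    """
    if not 0.0 <= tau <= 1.0:
        raise ValueError(f"tau must be in [0, 1], got {tau}")
    by_key: dict[tuple, float] = {}
    for r in ruleset.rules:
        by_key[(_lhs_key(r), r.rhs)] = r.confidence

    def removed(rule: Rule) -> bool:
        keys = sorted(_lhs_key(rule))
        for size in range(1, len(keys)):
            for sub in combinations(keys, size):
                conf = by_key.get((frozenset(sub), rule.rhs))
                if conf is not None and conf >= rule.confidence - tau:
                    return True
        return False

    survivors = tuple(r for r in ruleset.rules if not removed(r))
    return RuleSet(survivors, ruleset.params, ruleset.provenance)


def filter_by_whitelist(ruleset: RuleSet, whitelist: Sequence[Item]) -> RuleSet:
    """Keep exactly the rules whose every left-hand-side item is whitelisted."""
    wl = {canonical_key(it) for it in whitelist}
    survivors = tuple(
        r for r in ruleset.rules if all(canonical_key(it) in wl for it in r.lhs)
    )
    return RuleSet(survivors, ruleset.params, ruleset.provenance)


@dataclass(frozen=True)
class ResidualCurve:
    """Residual rule count after generality pruning, per τ grid point."""

    grid: tuple[tuple[float, int], ...]

    def __post_init__(self) -> None:
        taus = [t for t, _ in self.grid]
        if taus != sorted(set(taus)):
            raise ValueError("τ grid must be strictly increasing")
        counts = [c for _, c in self.grid]
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise ValueError("residual counts must be non-increasing in τ")

    @property
    def taus(self) -> tuple[float, ...]:
        return tuple(t for t, _ in self.grid)

    @property
    def counts(self) -> tuple[int, ...]:
        return tuple(c for _, c in self.grid)


def residual_curve(ruleset: RuleSet, tau_grid: Sequence[float]) -> ResidualCurve:
    """Evaluate |prune_by_generality(ruleset, τ)| over an ascending τ grid."""
    taus = list(tau_grid)
    if taus != sorted(set(taus)):
        raise ValueError("τ grid must be sorted ascending without duplicates")
    points = tuple((float(t), len(prune_by_generality(ruleset, t))) for t in taus)
    return ResidualCurve(points)


def suggest_tau(curve: ResidualCurve) -> float:
    """Advisory transition point of the residual-rule curve.

    Returns the grid τ farthest (perpendicular distance, axes normalized to
    [0, 1]) from the chord joining the curve's endpoints, computed on the
    log-count scale because residual counts typically span orders of
    magnitude. Flat or linear curves carry no knee; the smallest (interior
    where possible) τ is returned with a warning. τ remains a configuration
    value — this is a suggestion, not a fit.
    """
    if len(curve.grid) < 3:
        raise ValueError("need at least 3 grid points to locate a transition")
    taus = np.asarray(curve.taus, dtype=float)
    counts = np.asarray(curve.counts, dtype=float)
    if np.all(counts == counts[0]):
        warnings.warn("residual curve is constant; no transition point", stacklevel=2)
        return float(taus[0])
    y = np.log(np.maximum(counts, 1.0))
    x_n = (taus - taus[0]) / (taus[-1] - taus[0])
    y_n = (y - y.min()) / (y.max() - y.min()) if y.max() > y.min() else np.zeros_like(y)
    p0 = np.array([x_n[0], y_n[0]])
    p1 = np.array([x_n[-1], y_n[-1]])
    chord = p1 - p0
    norm = float(np.hypot(*chord))
    dist = np.abs(chord[0] * (p0[1] - y_n) - (p0[0] - x_n) * chord[1]) / norm
    if np.all(dist < 1e-12):
        warnings.warn("residual curve has no knee (linear decline)", stacklevel=2)
        return float(taus[1] if len(taus) > 2 else taus[0])
    return float(taus[int(np.argmax(dist))])
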