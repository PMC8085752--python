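"""Items: the atomic feature-value / feature-range conditions rules are built from.

An item is a pair ``(feature, condition)``. The condition is either a
categorical level (compared by equality) or a half-open numeric interval
``[lo, hi)`` (compared by containment). Clinician-facing phrasings such as
"≥6 no shows" map to ``[6, inf)`` and "8 or 9 diagnoses" to ``[8, 10)`` on
integer-valued features.

Items are frozen and canonicalized so that set operations, deduplication and
stable ordering are well defined across mining, pruning, catalogs and
whitelists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Any, Iterable

MISSING = "missing"


@dataclass(frozen=True, order=True)
class Interval:
    """Half-open interval ``[lo, hi)``; a value exactly at a cut goes right.

    ``lo`` may be ``-inf`` and ``hi`` may be ``inf``. Degenerate (empty)
    intervals are rejected.
    """

    lo: float
    hi: float

    def __post_init__(self) -> None:
        lo, hi = float(self.lo), float(self.hi)
        object.__setattr__(self, "lo", lo)
        object.__setattr__(self, "hi", hi)
        if not lo < hi:
            raise ValueError(f"empty interval [{lo}, {hi})")

    def contains(self, value: float) -> bool:
        return self.lo <= value < self.hi

    def label(self) -> str:
        lo = "-inf" if math.isinf(self.lo) else _fmt(self.lo)
        hi = "inf" if math.isinf(self.hi) else _fmt(self.hi)
        return f"[{lo}, {hi})"


def _fmt(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


@dataclass(frozen=True)
class Item:
    """One condition ``(feature, value)`` on a single feature.

    ``value`` is a string level for categorical conditions or an
    :class:`Interval` for numeric range conditions.
    """

    feature: str
    value: str | Interval

    def __post_init__(self) -> None:
        if isinstance(self.value, Interval):
            return
        object.__setattr__(self, "value", str(self.value))

    @property
    def is_interval(self) -> bool:
        return isinstance(self.value, Interval)

    def matches(self, cell: Any) -> bool:
        """True iff ``cell`` satisfies this condition; missing never matches."""
        if cell is None or (isinstance(cell, float) and math.isnan(cell)):
            return False
        if isinstance(cell, str) and cell == MISSING:
            return False
        if isinstance(self.value, Interval):
            if isinstance(cell, str):
                # a discretized bin label matches its own interval exactly
                if cell == self.value.label():
                    return True
                try:
                    cell = float(cell)
                except ValueError:
                    return False
            try:
                return self.value.contains(float(cell))
            except (TypeError, ValueError):
                return False
        return str(cell) == self.value

    def sort_key(self) -> tuple:
        if isinstance(self.value, Interval):
            return (self.feature, 1, self.value.lo, self.value.hi, "")
        return (self.feature, 0, 0.0, 0.0, self.value)

    def describe(self) -> str:
        if isinstance(self.value, Interval):
            return f"{self.feature} in {self.value.label()}"
        return f"{self.feature} = {self.value}"

    def to_json(self) -> dict:
        if isinstance(self.value, Interval):
            lo = None if math.isinf(self.value.lo) else self.value.lo
            hi = None if math.isinf(self.value.hi) else self.value.hi
            return {"feature": self.feature, "interval": [lo, hi]}
        return {"feature": self.feature, "value": self.value}

    @classmethod
    def from_json(cls, obj: dict) -> "Item":
        if "interval" in obj:
            lo, hi = obj["interval"]
            lo = -math.inf if lo is None else float(lo)
            hi = math.inf if hi is None else float(hi)
            return cls(obj["feature"], Interval(lo, hi))
        if "value" not in obj:
            raise ValueError(f"item needs 'value' or 'interval': {obj!r}")
        return cls(obj["feature"], str(obj["value"]))


_LABEL_RE = __import__("re").compile(r"^\[(-inf|[-+0-9.eE]+), (inf|[-+0-9.eE]+)\)$")


def parse_interval_label(label: str) -> Interval | None:
    """Recover the :class:`Interval` encoded by a bin label like ``"[5, inf)"``."""
    m = _LABEL_RE.match(label)
    if m is None:
        return None
    lo = -math.inf if m.group(1) == "-inf" else float(m.group(1))
    hi = math.inf if m.group(2) == "inf" else float(m.group(2))
    try:
        return Interval(lo, hi)
    except ValueError:
        return None


def canonical_key(item: Item) -> tuple:
    """Identity key under which a bin-label item and the equal interval item
    coincide; used to intersect catalogs with whitelists and intervention
    catalogs regardless of which encoding their files used."""
    if isinstance(item.value, Interval):
        return (item.feature, "i", item.value.lo, item.value.hi)
    iv = parse_interval_label(item.value)
    if iv is not None:
        return (item.feature, "i", iv.lo, iv.hi)
    return (item.feature, "v", item.value)


def canonical_lhs(items: Iterable[Item]) -> tuple[Item, ...]:
    """Deduplicate and sort items into the canonical left-hand-side order.

    Raises if two items constrain the same feature: a conjunction of two
    disjoint conditions on one feature is empty, and of nested ones redundant.
    """
    out = sorted(set(items), key=Item.sort_key)
    feats = [it.feature for it in out]
    if len(set(feats)) != len(feats):
        dup = sorted({f for f in feats if feats.count(f) > 1})
        raise ValueError(f"multiple items on feature(s) {dup} in one left-hand side")
    return tuple(out)
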