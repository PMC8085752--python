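"""Clinician-authored item → intervention catalog.

An item is *actionable* when the catalog links it to at least one
intervention; a rule is actionable when its left-hand side contains at
least one actionable item. Intervention texts are opaque strings and
matching is by canonical item identity only — authoring or validating the
clinical content is out of scope. An editable example catalog transcribed
from published asthma-care example rules ships with the package.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable

from .items import Item, canonical_key
from .mining import Rule, RuleSet

logger = logging.getLogger(__name__)

__all__ = ["InterventionCatalog", "load_catalog", "example_catalog_path", "link_rules"]


@dataclass(frozen=True)
class InterventionCatalog:
    """Mapping from canonical items to deduplicated intervention texts."""

    entries: tuple[tuple[Item, tuple[str, ...]], ...]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[Item, Iterable[str]]]) -> "InterventionCatalog":
        merged: dict[tuple, tuple[Item, list[str]]] = {}
        for item, texts in pairs:
            key = canonical_key(item)
            slot = merged.setdefault(key, (item, []))
            for t in texts:
                if t not in slot[1]:
                    slot[1].append(t)
        entries = tuple(
            (item, tuple(texts)) for item, texts in
            sorted(merged.values(), key=lambda p: p[0].sort_key())
        )
        return cls(entries)

    def __len__(self) -> int:
        return len(self.entries)

    def interventions_for(self, item: Item) -> tuple[str, ...]:
        key = canonical_key(item)
        for it, texts in self.entries:
            if canonical_key(it) == key:
                return texts
        return ()

    def is_actionable(self, item: Item) -> bool:
        return len(self.interventions_for(item)) > 0

    def actionable_items(self) -> tuple[Item, ...]:
        return tuple(it for it, texts in self.entries if texts)


def load_catalog(path: str | Path, known_features: Iterable[str] | None = None) -> InterventionCatalog:
    """Read a catalog JSON: ``[{feature, value|interval, interventions: [...]}]``.

    Duplicate items are merged with their interventions deduplicated.
    Entries on features not in ``known_features`` (when given) are kept but
    logged, so a catalog written for a wider schema still loads.
    """
    raw = json.loads(Path(path).read_text())
    if not isinstance(raw, list):
        raise ValueError("catalog must be a JSON list of entries")
    pairs: list[tuple[Item, list[str]]] = []
    known = set(known_features) if known_features is not None else None
    for i, entry in enumerate(raw):
        try:
            item = Item.from_json(entry)
            texts = entry.get("interventions", [])
            if not isinstance(texts, list) or not all(isinstance(t, str) for t in texts):
                raise ValueError("'interventions' must be a list of strings")
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"malformed catalog entry at index {i}: {exc}") from exc
        if known is not None and item.feature not in known:
            logger.warning("catalog entry %d uses unknown feature %r", i, item.feature)
        pairs.append((item, list(texts)))
    return InterventionCatalog.from_pairs(pairs)


def example_catalog_path() -> Path:
    """Path of the bundled example asthma intervention catalog."""
    return Path(resources.files("carex").joinpath("data/example_catalog.json"))


def link_rules(ruleset: RuleSet, catalog: InterventionCatalog) -> RuleSet:
    """Attach interventions and actionability to every rule.

    Each rule carries the deduplicated union of its actionable items'
    interventions; ``actionable`` is true iff ≥1 left-hand-side item is
    actionable. Left-hand sides, right-hand sides and stats are untouched.
    """
    index = {canonical_key(it): texts for it, texts in catalog.entries}
    linked = []
    for rule in ruleset.rules:
        texts: list[str] = []
        actionable_items: list[Item] = []
        for it in rule.lhs:
            ivs = index.get(canonical_key(it), ())
            if ivs:
                actionable_items.append(it)
                for t in ivs:
                    if t not in texts:
                        texts.append(t)
        linked.append(
            replace(
                rule,
                actionable=bool(actionable_items),
                interventions=tuple(texts),
                actionable_items=tuple(actionable_items),
            )
        )
    return RuleSet(tuple(linked), ruleset.params, ruleset.provenance)
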