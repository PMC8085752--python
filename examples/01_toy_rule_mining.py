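"""Mine and prune class association rules on a ten-row toy cohort.

The cohort is small enough to count by hand: two binary features A and B,
two of ten instances positive. Mining with minimum commonality 0.5 and
minimum confidence 0.4 yields three rules; confidence-difference pruning
at tau = 0.15 removes the two specific rules because the general rule
{A=1} explains the same positives with equal confidence.
"""

import pandas as pd

from carex import (
    CohortTable,
    ColumnSpec,
    FeatureSchema,
    MiningParams,
    mine_rules,
    prune_by_generality,
    summarize_outcome,
)
from carex.items import Item

rows = [(1, 1, 1), (1, 0, 1), (1, 1, 0), (1, 0, 0), (0, 1, 0), (0, 1, 0)] + [(0, 0, 0)] * 4
schema = FeatureSchema.from_columns(
    [
        ColumnSpec("pid", "categorical", "id"),
        ColumnSpec("year", "continuous", "year"),
        ColumnSpec("A", "categorical"),
        ColumnSpec("B", "categorical"),
        ColumnSpec("outcome", "categorical", "outcome"),
    ]
)
cohort = CohortTable(
    pd.DataFrame(
        [{"pid": str(i + 1), "year": 2012, "A": a, "B": b, "outcome": y}
         for i, (a, b, y) in enumerate(rows)]
    ),
    schema,
)

summary = summarize_outcome(cohort)
print(f"cohort: {summary.n_total} instances, {summary.n_positive} positive "
      f"({summary.prevalence_pct}%)")

catalog = [Item("A", "1"), Item("B", "1"), Item("B", "0")]
params = MiningParams(min_commonality=0.5, min_confidence=0.4, max_lhs_items=2)
mined = mine_rules(cohort, rhs=1, catalog=catalog, params=params)
print(f"\nmined {len(mined)} rules (commonality >= 0.5, confidence >= 0.4):")
for r in mined.rules:
    print(" ", r.describe())

pruned = prune_by_generality(mined, tau=0.15)
print(f"\nafter generality pruning at tau=0.15: {len(pruned)} rule")
for r in pruned.rules:
    print(" ", r.describe())
print("\nThe two 2-item rules were dropped: the 1-item rule is more general")
print("and its confidence trails neither by more than tau.")
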