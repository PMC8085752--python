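"""Explain one high-risk patient with clinically phrased rules.

Builds two range-item rules in the style of published asthma examples —
"8 or 9 primary asthma diagnoses AND >= 6 no-shows" and ">= 89 asthma
relievers filled" — links them to the bundled example intervention
catalog, and prints the ranked explanation for a patient record.
Actionable rules rank first and each carries its interventions.
"""

import math

from carex import (
    MiningParams,
    Rule,
    RuleSet,
    example_catalog_path,
    explain_instance,
    link_rules,
    load_catalog,
)
from carex.items import Interval, Item

rules = RuleSet(
    (
        Rule(
            lhs=(
                Item("no_shows_12m", Interval(6, math.inf)),
                Item("primary_asthma_diagnoses_12m", Interval(8, 10)),
            ),
            rhs=1, commonality=0.02, confidence=0.41,
            n_satisfying=200, n_satisfying_positive=82,
        ),
        Rule(
            lhs=(Item("asthma_relievers_filled_12m", Interval(89, math.inf)),),
            rhs=1, commonality=0.01, confidence=0.55,
            n_satisfying=90, n_satisfying_positive=50,
        ),
        Rule(
            lhs=(Item("race", "black_or_african_american"),),
            rhs=1, commonality=0.15, confidence=0.30,
            n_satisfying=5000, n_satisfying_positive=1500,
        ),
    ),
    MiningParams(),
)
rules = link_rules(rules, load_catalog(example_catalog_path()))

patient = {
    "no_shows_12m": 7,
    "primary_asthma_diagnoses_12m": 8,
    "asthma_relievers_filled_12m": 91,
    "race": "black_or_african_american",
}
explanation = explain_instance(patient, rules, top_k=3, instance_id="patient-0001")
print(explanation.describe())
print(f"\ndistinct actionable items: "
      f"{[it.describe() for it in explanation.distinct_actionable_items]}")
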