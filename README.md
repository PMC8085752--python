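# carex — Class Association Rule EXplanations

`carex` produces automatic, human-readable explanations for the predictions of
any black-box classifier on imbalanced tabular cohorts — the setting of
clinical risk models that flag, say, the ~2% of asthma patients headed for a
hospital visit next year. Instead of attributing the score to features, it
mines **class association rules** from the training data and shows each
high-risk patient the rules that suit them, each rule optionally linked to
concrete care-management interventions authored by clinicians.

It is written for epidemiologists and clinical data scientists who already
have a risk model (XGBoost or anything else that emits scores) and need
explanations that front-line care managers can read and act on.

## The method

A rule has the form

```
r1 AND r2 AND ... AND rs  →  u
```

where each item `ri = (g, v)` is a feature–value or feature–range condition
and `u` is the poor outcome (`u = 1`). Two class-conditional statistics govern
mining over the training set:

- **commonality** `= P(r1 ∧ … ∧ rs | y = u)` — the fraction of poor-outcome
  instances satisfying the left-hand side (class-conditional support);
- **confidence** `= P(y = u | r1 ∧ … ∧ rs)` — the fraction of satisfying
  instances with the poor outcome (precision).

Continuous features are discretized by entropy/MDL binary splitting fitted on
training rows only. An Apriori-style level-wise search (commonality is
anti-monotone; confidence filters at emission) keeps every rule with
`commonality ≥ c_min`, `confidence ≥ f_min` and at most `s_max` items. Three
reduction techniques follow:

1. **generality pruning** — drop a specific rule `q1` whenever a strictly more
   general rule `q2` (left-hand side a strict subset, same outcome) has
   `conf(q2) ≥ conf(q1) − τ`; τ is chosen at the transition point of the
   residual-rule-count curve,
2. **top-k features** — rules are built only over the most important features
   of the upstream model,
3. **whitelisting** — only clinician-labeled values/ranges plausibly
   positively correlated with the poor outcome form rules.

Default thresholds are the study settings for the hard ~2%-prevalence regime:
`c_min = 0.08%`, `f_min = 25%`, `s_max = 5`, `τ = 0.15`, top 50 features. At
evaluation time the classifier's scores are binarized at the top-10% cutoff
and, for every predicted-positive patient, all suiting rules are ranked
(actionable first, then a greedy score balancing brevity, confidence,
commonality and novelty of items). Coverage is reported as the fraction of
true positives explained by ≥1 rule, per-patient rule/item statistics, and
three patient distributions.

Because the cohorts this method was designed for are private, the package
ships a synthetic-cohort generator that plants rules of prescribed
commonality and confidence in an imbalanced population, giving every stage a
closed-form ground truth.

## Worked example

`python examples/01_toy_rule_mining.py` mines a ten-row cohort (two binary
features, 2/10 positive) and prints:

```
mined 3 rules (commonality >= 0.5, confidence >= 0.4):
  A = 1 -> outcome=1  (commonality=1.0000, confidence=0.5000)
  A = 1 AND B = 0 -> outcome=1  (commonality=0.5000, confidence=0.5000)
  A = 1 AND B = 1 -> outcome=1  (commonality=0.5000, confidence=0.5000)

after generality pruning at tau=0.15: 1 rule
  A = 1 -> outcome=1  (commonality=1.0000, confidence=0.5000)
```

All four positives-satisfying instances carry `A = 1`, so that one-item rule
covers every poor outcome (commonality 1.0) with confidence 0.5; both two-item
specializations add no confidence and are pruned.

`python examples/04_explain_patient.py` ranks rules for one patient record:

```
instance patient-0001: 3 rule(s) suit (2 actionable)
  [actionable] asthma_relievers_filled_12m in [89, inf)  (conf=0.550, comm=0.0100)
      -> Tailor prescribed medications; suggest the patient maximize adherence ...
  [actionable] no_shows_12m in [6, inf) AND primary_asthma_diagnoses_12m in [8, 10)  (conf=0.410, comm=0.0200)
      -> Give the patient social resources to handle socioeconomic challenges ...
      -> Offer the patient suggestions on how to improve asthma control.
  [nonactionable] race = black_or_african_american  (conf=0.300, comm=0.1500)
```

Actionable rules outrank the nonactionable one despite its higher
commonality, and each actionable rule carries the interventions of its items.
`examples/02_synthetic_recovery.py` and `examples/03_full_pipeline.py` show
planted-rule recovery and the end-to-end pipeline (split → discretize → mine
→ prune → link → explain → evaluate).

A thin CLI mirrors the library: `carex simulate | discretize | mine | prune |
explain | evaluate | run` (see `carex --help`).

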