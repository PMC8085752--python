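# Methods

This note documents the statistical procedure `carex` implements, the
choices made where the design was genuinely open, and what the synthetic
cohorts do and do not establish.

## Model and assumptions

The method explains binary-outcome predictions on instance-per-row cohorts
where each row is a (patient, index year) pair: features summarize the index
year, the outcome refers to the succeeding year and is encoded upstream. The
explanation model is separate from the prediction model: any classifier may
produce the risk scores, and a rule set mined from the same training data
supplies the reasons. A rule `r1 AND … AND rs → u` suits a patient when every
left-hand-side item is satisfied; suiting rules *are* the explanation. The
approach assumes the poor outcome is rare (defaults are tuned to ~2%
prevalence) and that confidence well above prevalence marks an informative
rule.

Commonality (class-conditional support) and confidence (precision) are
estimated by direct counting. Commonality is anti-monotone under item
addition, which justifies Apriori-style candidate pruning; confidence is not,
and is only applied when a rule is emitted. A left-hand side contains at most
one item per feature: with disjoint discretized bins a second item on the
same feature is either contradictory or redundant. Rules whose left-hand
side satisfies no positive training instance are vacuous and never emitted,
whatever the thresholds.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `min_commonality` | 0.0008 | smallest fraction of poor-outcome instances a rule must cover |
| `min_confidence` | 0.25 | smallest precision; must sit well above prevalence |
| `max_lhs_items` | 5 | readability bound on rule length |
| `confidence_diff_threshold` (τ) | 0.15 | margin for generality pruning |
| `n_top_features` | 50 | features (by upstream importance) allowed into rules |
| `top_fraction` | 0.10 | score cutoff: top decile labeled positive |
| `top_k` | 3 | rules displayed per patient (all are counted) |

The commonality/confidence defaults are deliberately low: the harder the
outcome is to predict, the lower these thresholds must be for the rule set to
reach most correctly flagged patients. All are overridable everywhere.

τ is a configuration value. `suggest_tau` is advisory: it returns the grid
point of the residual-rule curve farthest (perpendicular distance, axes
normalized to [0, 1]) from the chord joining the endpoints, computed on the
log-count scale because residual counts typically span orders of magnitude.
Flat or log-linear curves have no knee; the smallest (interior where
possible) τ is returned with a warning.

## Discretization

Continuous features are cut by recursive binary splitting on class-entropy
gain with the Fayyad–Irani MDL stopping criterion, fitted on training rows
only; candidate cuts are midpoints between adjacent distinct values, and the
vectorized scan is tested against an exhaustive entropy-scan oracle.
Equal-frequency binning is available as an unsupervised fallback. Bins are
half-open `[a, b)` — a value at a cut goes right — so printed conditions like
"≥ 6" map to `[6, ∞)` and "8 or 9" (integers) to `[8, 10)`. Missing values
form an explicit `missing` category that satisfies no item. Features with
fewer than two distinct values get a single bin with a warning.

## Pruning semantics

Generality pruning is a single pass against the *input* rule set: `q1` is
removed if any strict-subset rule `q2` with the same outcome in the input has
`conf(q2) ≥ conf(q1) − τ`, whether or not `q2` itself survives. This makes
the operation order-independent and gives clean laws (output ⊆ input;
τ₁ ≤ τ₂ ⇒ prune(τ₂) ⊆ prune(τ₁)), verified against an all-pairs oracle.
Generality means strict left-hand-side subset only; a wider interval on the
same feature is not treated as more general, because discretized bins are
disjoint. The pipeline default order is mine over top-k features →
τ-pruning → whitelist filtering; a `whitelist_first` switch restricts the
item catalog before mining instead, which changes efficiency, not the final
set, when mining is exhaustive over whitelisted items.

## Ranking

The display guidance for rule lists fixes pairwise preferences but no
formula, so ranking is an explicit two-tier greedy scheme: actionable rules
strictly first; within a tier, repeatedly select the rule maximizing
`w_conf·confidence + w_comm·commonality − w_brev·(s−1)/(s_max−1)
− w_red·(fraction of items already shown)`, with default weights (1,1,1,1)
and ties broken by canonical left-hand-side order. Within a displayed rule,
items are ordered actionable-and-unseen, unseen, actionable-seen, seen. The
weights are exposed, not asserted — any non-negative, not-all-zero setting
is valid.

## Evaluation conventions

The top-fraction cutoff labels exactly `k = round(fraction·n)` instances
positive, ties broken by ascending instance id (tie handling at the decile
boundary is otherwise unspecified). Coverage fractions are percentages with
two decimals; per-patient means carry sample (n−1) standard deviations and
are taken over *explained* true positives (whether such means should average
over all true positives is ambiguous; the denominator used is recorded in the
output counts). The three patient distributions — by suiting rules, by
actionable suiting rules, by distinct actionable items — are histograms over
all true positives and each sums to their number. A run or subgroup with
zero true positives is flagged `undefined` rather than reported as 0%.
Per-patient distinct-item and intervention unions cover every suiting rule,
not only the displayed top-k.

## Synthetic cohorts

`SyntheticSpec` defaults are the study conditions: 50,000 instances at 2%
prevalence, two planted 2-item rules with (commonality, confidence) targets
(0.5, 0.3) and (0.2, 0.4), six binary noise features with 10% marginals, two
Gaussian continuous noise features, index years 2012–2017. Each planted rule
owns a disjoint feature set, so its statistics have exact closed forms. The
full conjunction is set with probability `c` among positives; among
negatives the rate is `q = c·π̂·(1/f − 1)/(1 − π̂)`, computed from the
*realized* positive count π̂ so the target confidence holds exactly
conditionally on the drawn outcomes (the nominal closed form with π holds in
expectation and is what `expected_rule_stats` reports, together with
binomial standard errors). Outside the conjunction, items fire independently
at a 10% contamination rate — so strict sub-rules exist and generality
pruning is exercised — with all-items-by-chance draws broken by clearing one
item, keeping the conjunction rate exact; single-item planted rules receive
no contamination since any would shift their targets. A seeded score
generator (Gaussian noise plus loadings on outcome and planted conjunctions)
stands in for the external classifier.

These cohorts establish correctness of counting, mining, pruning, matching
and evaluation under known ground truth. They do not emulate real EHR
marginals, feature correlations, temporal drift, or informative missingness;
passing recovery tests says nothing about the clinical usefulness of rules
on real cohorts, which depends on the upstream model and the intervention
catalog.

## Problem sizes and numerics

Tests and the acceptance script run at 10–50,000 instances with item
catalogs of ≤ 22 items and rule lengths ≤ 3–5 — sizes chosen so exhaustive
oracles (brute-force mining, all-pairs pruning checks) remain feasible
alongside the production paths they verify. Statistics are exact integer
ratios in double precision; threshold comparisons are plain `≥` with no
epsilon, and the miner and the brute-force oracle compute them identically,
so equivalence checks compare bit-identical floats. Pipeline outputs are
byte-reproducible for a fixed config and seed (sorted JSON keys, no
timestamps, default float repr).

## Known limitations

- Mining is in-memory and single-threaded; catalogs of hundreds of items at
  `max_lhs_items = 5` will not scale to the tens of millions of rules the
  method can generate on large private cohorts.
- The residual-curve knee is a heuristic; τ should be reviewed on a plot.
- Interval whitelist/catalog items match discretized data only when they
  coincide with bin boundaries (matching is by canonical item identity, not
  overlap).
- The bundled intervention catalog is an editable example, not clinical
  guidance.
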