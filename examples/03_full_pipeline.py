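"""End-to-end run: split, discretize, mine, prune, link, explain, evaluate.

Builds a synthetic cohort and external risk scores, writes them to a
temporary directory, and drives the whole pipeline from a RunConfig. The
manifest records the rule count after each pruning stage; the metrics file
holds the explanation-coverage numbers over the true positives of the
top-10% risk cutoff.
"""

import json
import tempfile
from pathlib import Path

import pandas as pd

from carex import (
    PlantedRule,
    RunConfig,
    SyntheticSpec,
    generate_cohort,
    generate_scores,
    run_full_pipeline,
)
from carex.cohort import write_cohort

tmp = Path(tempfile.mkdtemp())
spec = SyntheticSpec(
    n_instances=20_000,
    prevalence=0.02,
    planted_rules=(PlantedRule(2, 0.5, 0.3), PlantedRule(2, 0.2, 0.4)),
    n_noise_features=4,
    n_continuous_features=2,
    seed=17,
)
cohort, _ = generate_cohort(spec)
write_cohort(cohort, tmp / "cohort.csv")
spec.schema().to_json(tmp / "schema.json")
scores = generate_scores(cohort, spec)
pd.DataFrame({"id": scores.index, "score": scores.to_numpy()}).to_csv(
    tmp / "scores.csv", index=False
)
(tmp / "catalog.json").write_text(json.dumps([
    {"feature": "rule0_item0", "value": "1", "interventions": ["tailor medications"]},
    {"feature": "rule1_item0", "value": "1", "interventions": ["care management"]},
]))

config = RunConfig(
    cohort=str(tmp / "cohort.csv"),
    schema_file=str(tmp / "schema.json"),
    scores=str(tmp / "scores.csv"),
    catalog=str(tmp / "catalog.json"),
    out_dir=str(tmp / "run"),
    top_features=[f"rule{j}_item{i}" for j in range(2) for i in range(2)]
    + ["noise0", "noise1"],
    min_commonality=0.05,
    min_confidence=0.1,
    max_lhs_items=3,
    seed=17,
)
out = run_full_pipeline(config)

manifest = json.loads((out / "manifest.json").read_text())
metrics = json.loads((out / "metrics.json").read_text())
prune = manifest["stages"]["prune"]
print(f"rules: {prune['n_rules_mined']} mined -> "
      f"{prune['n_rules_after_tau']} after tau={config.tau} pruning")
print(f"test split: {manifest['stages']['predict']['n_scored']} instances, "
      f"{manifest['stages']['predict']['n_predicted_positive']} predicted positive "
      f"(top {config.top_fraction:.0%}), {metrics['n_tp']} true positives")
print(f"explained fraction of true positives: {metrics['explained_fraction_tp']}%")
print(f"mean rules per explained patient: {metrics['mean_rules_per_explained']:.2f} "
      f"(SD {metrics['sd_rules_per_explained']:.2f})")
print(f"run artifacts in {out}")
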