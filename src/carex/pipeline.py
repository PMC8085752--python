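"""One-command orchestration of the full study design on any cohort:
split → discretize → mine → prune → link interventions → explain → evaluate.

Every stage writes its artifact into the run directory as it completes, so
an aborted run preserves partial outputs; the manifest records the config
hash and the rule counts at each pruning stage (mined → τ-pruned →
whitelist-filtered). Outputs are byte-reproducible for a fixed config and
seed: no timestamps, sorted JSON keys, default float repr.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .cohort import CohortTable, FeatureSchema, load_cohort, summarize_outcome, temporal_split
from .discretize import (
    BinningMap,
    DiscretizationParams,
    apply_discretization,
    fit_discretization,
)
from .evaluation import CoverageMetrics, PredictionRun, coverage_metrics
from .explain import Explanation, RankWeights, explain_instance
from .interventions import link_rules, load_catalog
from .items import Item
from .mining import MiningParams, RuleSet, build_item_catalog, mine_rules
from .pruning import filter_by_whitelist, prune_by_generality

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_full_pipeline", "load_whitelist"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")


class RunConfig(BaseModel):
    """Configuration of one end-to-end run; defaults are the study settings."""

    cohort: str
    schema_file: str
    scores: str
    catalog: str
    whitelist: Optional[str] = None
    top_features: Optional[list[str]] = None
    out_dir: str = "carex_run"

    train_years: list[int] = Field(default_factory=lambda: [2012, 2013, 2014, 2015, 2016])
    test_years: list[int] = Field(default_factory=lambda: [2017])

    min_commonality: float = 0.0008
    min_confidence: float = 0.25
    max_lhs_items: int = 5
    tau: float = 0.15
    n_top_features: int = 50
    whitelist_first: bool = False
    rhs: int = 1

    discretization_method: str = "mdl"
    top_fraction: float = 0.10
    top_k: Optional[int] = 3
    explain_all: bool = False  # research flag: explain every instance, not only predicted positives
    seed: int = 0

    def mining_params(self) -> MiningParams:
        return MiningParams(
            min_commonality=self.min_commonality,
            min_confidence=self.min_confidence,
            max_lhs_items=self.max_lhs_items,
            confidence_diff_threshold=self.tau,
            n_top_features=self.n_top_features,
        )

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        return cls(**yaml.safe_load(Path(path).read_text()))


def load_whitelist(path: str | Path) -> list[Item]:
    raw = json.loads(Path(path).read_text())
    if not isinstance(raw, list):
        raise ValueError("whitelist must be a JSON list of items")
    return [Item.from_json(o) for o in raw]


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def run_full_pipeline(config: RunConfig) -> Path:
    """Execute every stage; returns the run directory.

    Any stage failure raises :class:`PipelineError` naming the stage, with
    the artifacts of completed stages left in place.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "carex_version": __version__,
        "config": config.model_dump(),
        "config_hash": config.config_hash(),
        "stages": {},
    }

    def stage(name: str):
        class _Ctx:
            def __enter__(self):
                logger.info("stage %s", name)

            def __exit__(self, exc_type, exc, tb):
                if exc is not None and not isinstance(exc, PipelineError):
                    _write_json(manifest, out / "manifest.json")
                    raise PipelineError(name, str(exc)) from exc
                return False

        return _Ctx()

    with stage("load"):
        schema = FeatureSchema.from_json(config.schema_file)
        cohort = load_cohort(config.cohort, schema)
        manifest["stages"]["load"] = {
            "n_rows": len(cohort),
            "prevalence_pct": summarize_outcome(cohort).prevalence_pct,
        }

    with stage("split"):
        train, test = temporal_split(cohort, config.train_years, config.test_years)
        manifest["stages"]["split"] = {"n_train": len(train), "n_test": len(test)}

    with stage("discretize"):
        binning = fit_discretization(
            train, DiscretizationParams(method=config.discretization_method)
        )
        binning.to_json(out / "bins.json")
        train_d = apply_discretization(train, binning)
        test_d = apply_discretization(test, binning)
        manifest["stages"]["discretize"] = {
            "n_binned_features": sum(1 for cs in binning.cuts.values() if cs)
        }

    with stage("mine"):
        whitelist = load_whitelist(config.whitelist) if config.whitelist else None
        top = config.top_features
        if top is not None:
            top = top[: config.n_top_features]
        catalog = build_item_catalog(
            train_d,
            top_features=top,
            whitelist=whitelist if config.whitelist_first else None,
        )
        mined = mine_rules(train_d, config.rhs, catalog, config.mining_params())
        manifest["stages"]["mine"] = {"n_items": len(catalog), "n_rules_mined": len(mined)}

    with stage("prune"):
        pruned = prune_by_generality(mined, config.tau)
        if whitelist is not None:
            filtered = filter_by_whitelist(pruned, whitelist)
        else:
            filtered = pruned
        manifest["stages"]["prune"] = {
            "n_rules_mined": len(mined),
            "n_rules_after_tau": len(pruned),
            "n_rules_after_whitelist": len(filtered),
        }

    with stage("interventions"):
        catalog_iv = load_catalog(config.catalog, known_features=schema.feature_names)
        linked = link_rules(filtered, catalog_iv)
        linked.to_json(out / "rules.json")
        manifest["stages"]["interventions"] = {
            "n_catalog_items": len(catalog_iv),
            "n_actionable_rules": sum(r.actionable for r in linked.rules),
        }

    with stage("predict"):
        scores_df = pd.read_csv(config.scores, dtype={"id": str})
        if not {"id", "score"} <= set(scores_df.columns):
            raise ValueError("scores file needs columns: id, score")
        scores = pd.Series(
            scores_df["score"].astype(float).to_numpy(), index=scores_df["id"]
        )
        test_ids = test_d.ids().astype(str)
        truth = pd.Series(test_d.outcome.to_numpy(), index=test_ids)
        scores = scores.reindex(truth.index)
        if scores.isna().any():
            raise ValueError("scores missing for some test instances")
        run = PredictionRun.from_scores(scores, truth, config.top_fraction)
        manifest["stages"]["predict"] = {
            "n_scored": len(run.frame),
            "n_predicted_positive": len(run.predicted_positive_ids),
            "n_true_positive": len(run.true_positive_ids),
        }

    with stage("explain"):
        weights = RankWeights()
        targets = (
            list(test_ids) if config.explain_all else run.predicted_positive_ids
        )
        target_set = set(targets)
        explanations: list[Explanation] = []
        rows = test_d.data
        with (out / "explanations.jsonl").open("w") as fh:
            for i, iid in enumerate(test_ids):
                if iid not in target_set:
                    continue
                expl = explain_instance(
                    rows.iloc[i], linked, weights, config.top_k, instance_id=iid
                )
                explanations.append(expl)
                fh.write(json.dumps(expl.to_json(), sort_keys=True) + "\n")
        manifest["stages"]["explain"] = {
            "n_explained_instances": sum(e.explained for e in explanations),
            "n_target_instances": len(explanations),
        }

    with stage("evaluate"):
        metrics = coverage_metrics(run, explanations)
        _write_json(metrics.to_json(), out / "metrics.json")
        manifest["stages"]["evaluate"] = {
            "explained_fraction_tp": metrics.explained_fraction_tp,
            "n_tp": metrics.n_tp,
        }

    _write_json(manifest, out / "manifest.json")
    return out
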