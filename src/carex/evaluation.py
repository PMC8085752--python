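"""Evaluation of explanation coverage under the study design.

The upstream classifier is binarized by a top-fraction cutoff (the study
labels the top 10% of risk scores positive). Coverage is then measured on
the true positives: the fraction offered at least one rule-based
explanation, the per-patient rule and actionable-item statistics, and the
three patient distributions (by number of actionable suiting rules, number
of distinct actionable items, and number of suiting rules).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .explain import Explanation

__all__ = [
    "PredictionRun",
    "CoverageMetrics",
    "classify_top_fraction",
    "coverage_metrics",
    "subgroup_metrics",
]


def classify_top_fraction(scores: pd.Series, fraction: float) -> pd.Series:
    """Label exactly ``k = round(fraction · n)`` highest-scoring instances 1.

    Ties at the cutoff break deterministically by ascending instance id
    (the series index). Returns an int 0/1 series aligned with ``scores``.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    n = len(scores)
    if n == 0:
        raise ValueError("need at least one score")
    k = int(math.floor(fraction * n + 0.5))
    order = sorted(scores.index, key=lambda i: (-scores[i], i))
    chosen = set(order[:k])
    return pd.Series([1 if i in chosen else 0 for i in scores.index],
                     index=scores.index, dtype=int)


@dataclass(frozen=True)
class PredictionRun:
    """Aligned per-instance risk scores, binarized predictions and truth."""

    frame: pd.DataFrame  # columns: score, predicted, truth; index = instance id

    def __post_init__(self) -> None:
        need = {"score", "predicted", "truth"}
        if not need <= set(self.frame.columns):
            raise ValueError(f"prediction frame needs columns {sorted(need)}")
        if not self.frame.index.is_unique:
            raise ValueError("instance ids must be unique")

    @classmethod
    def from_scores(
        cls, scores: pd.Series, truth: pd.Series, top_fraction: float
    ) -> "PredictionRun":
        truth = truth.reindex(scores.index)
        if truth.isna().any():
            raise ValueError("truth missing for some scored instances")
        predicted = classify_top_fraction(scores, top_fraction)
        return cls(pd.DataFrame({"score": scores, "predicted": predicted,
                                 "truth": truth.astype(int)}))

    @property
    def true_positive_ids(self) -> list:
        m = (self.frame["predicted"] == 1) & (self.frame["truth"] == 1)
        return list(self.frame.index[m])

    @property
    def predicted_positive_ids(self) -> list:
        return list(self.frame.index[self.frame["predicted"] == 1])

    @property
    def truth_positive_ids(self) -> list:
        return list(self.frame.index[self.frame["truth"] == 1])


@dataclass(frozen=True)
class CoverageMetrics:
    """Explanation coverage over one prediction run.

    Percentages are rounded to 2 decimals; means/SDs (sample, n−1) are taken
    over the *explained* true positives. Histograms are keyed by the count
    value and each sums to the number of true positives. ``undefined`` marks
    a run (or subgroup) with zero true positives, where the fractions have
    no denominator.
    """

    n_tp: int
    n_explained_tp: int
    n_truth_pos: int
    n_explained_truth_pos: int
    explained_fraction_tp: float | None
    explained_fraction_all_pos: float | None
    mean_rules_per_explained: float | None
    sd_rules_per_explained: float | None
    mean_distinct_actionable_items: float | None
    sd_distinct_actionable_items: float | None
    dist_actionable_rules: dict[int, int]
    dist_distinct_items: dict[int, int]
    dist_rules: dict[int, int]
    undefined: bool = False

    def to_json(self) -> dict:
        out = {k: getattr(self, k) for k in (
            "n_tp", "n_explained_tp", "n_truth_pos", "n_explained_truth_pos",
            "explained_fraction_tp", "explained_fraction_all_pos",
            "mean_rules_per_explained", "sd_rules_per_explained",
            "mean_distinct_actionable_items", "sd_distinct_actionable_items",
            "undefined")}
        for k in ("dist_actionable_rules", "dist_distinct_items", "dist_rules"):
            out[k] = {str(key): v for key, v in sorted(getattr(self, k).items())}
        return out


def _hist(values: Iterable[int]) -> dict[int, int]:
    out: dict[int, int] = {}
    for v in values:
        out[int(v)] = out.get(int(v), 0) + 1
    return dict(sorted(out.items()))


def _mean_sd(values: Sequence[float]) -> tuple[float | None, float | None]:
    if not values:
        return None, None
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    return mean, sd


def coverage_metrics(
    run: PredictionRun, explanations: Iterable[Explanation]
) -> CoverageMetrics:
    """Coverage statistics over the run's true positives.

    ``explained_fraction_tp`` divides by the true positives;
    ``explained_fraction_all_pos`` divides by *all* truth-positive
    instances (explanations generally exist only for predicted positives,
    so this fraction is the method's reach over everyone who went on to
    the poor outcome).
    """
    by_id: dict[Hashable, Explanation] = {}
    for e in explanations:
        if e.instance_id in by_id:
            raise ValueError(f"duplicate explanation for instance {e.instance_id!r}")
        by_id[e.instance_id] = e
    missing = [i for i in run.predicted_positive_ids if i not in by_id]
    if missing:
        raise ValueError(f"missing explanations for predicted positives: {missing[:5]}")

    tp_ids = run.true_positive_ids
    n_tp = len(tp_ids)
    truth_pos = run.truth_positive_ids
    n_explained_truth_pos = sum(
        1 for i in truth_pos if i in by_id and by_id[i].explained
    )

    if n_tp == 0:
        return CoverageMetrics(
            n_tp=0, n_explained_tp=0, n_truth_pos=len(truth_pos),
            n_explained_truth_pos=n_explained_truth_pos,
            explained_fraction_tp=None,
            explained_fraction_all_pos=(
                round(100.0 * n_explained_truth_pos / len(truth_pos), 2)
                if truth_pos else None),
            mean_rules_per_explained=None, sd_rules_per_explained=None,
            mean_distinct_actionable_items=None, sd_distinct_actionable_items=None,
            dist_actionable_rules={}, dist_distinct_items={}, dist_rules={},
            undefined=True,
        )

    tp_expl = [by_id[i] for i in tp_ids]
    explained = [e for e in tp_expl if e.explained]
    mean_rules, sd_rules = _mean_sd([e.n_matched for e in explained])
    mean_items, sd_items = _mean_sd(
        [len(e.distinct_actionable_items) for e in explained]
    )
    return CoverageMetrics(
        n_tp=n_tp,
        n_explained_tp=len(explained),
        n_truth_pos=len(truth_pos),
        n_explained_truth_pos=n_explained_truth_pos,
        explained_fraction_tp=round(100.0 * len(explained) / n_tp, 2),
        explained_fraction_all_pos=(
            round(100.0 * n_explained_truth_pos / len(truth_pos), 2)
            if truth_pos else None),
        mean_rules_per_explained=mean_rules,
        sd_rules_per_explained=sd_rules,
        mean_distinct_actionable_items=mean_items,
        sd_distinct_actionable_items=sd_items,
        dist_actionable_rules=_hist(e.n_actionable_matched for e in tp_expl),
        dist_distinct_items=_hist(len(e.distinct_actionable_items) for e in tp_expl),
        dist_rules=_hist(e.n_matched for e in tp_expl),
    )


def subgroup_metrics(
    run: PredictionRun,
    explanations: Iterable[Explanation],
    groups: Mapping[Hashable, Hashable],
) -> dict[Hashable, CoverageMetrics]:
    """Coverage per subgroup (e.g., children vs adults); every instance in
    the run must carry a group label. Subgroups with zero true positives
    come back flagged undefined rather than as zeros."""
    unlabeled = [i for i in run.frame.index if i not in groups]
    if unlabeled:
        raise KeyError(f"instances without group label: {unlabeled[:5]}")
    explanations = list(explanations)
    out: dict[Hashable, CoverageMetrics] = {}
    for label in sorted({groups[i] for i in run.frame.index}, key=str):
        ids = [i for i in run.frame.index if groups[i] == label]
        sub_run = PredictionRun(run.frame.loc[ids])
        sub_expl = [e for e in explanations if e.instance_id in set(ids)]
        out[label] = coverage_metrics(sub_run, sub_expl)
    return out


def metrics_to_json(metrics: CoverageMetrics, path: str | Path) -> None:
    Path(path).write_text(json.dumps(metrics.to_json(), indent=2, sort_keys=True) + "\n")
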