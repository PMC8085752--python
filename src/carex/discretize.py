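"""Supervised discretization of continuous features.

Continuous features are converted to categorical bins before rule mining.
The default method is entropy-based recursive binary splitting with the
minimum-description-length (MDL) stopping criterion of Fayyad & Irani:
a candidate cut is accepted only when the class-entropy gain exceeds the
MDL cost of encoding the extra partition. An unsupervised equal-frequency
fallback is available for cohorts whose outcome is too sparse to drive
entropy splits.

Bins are half-open intervals ``[a, b)``; a value exactly at a cut point goes
to the right bin. Missing values map to the explicit ``"missing"`` category
and never satisfy any value or range item.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import CohortTable, FeatureSchema
from .items import MISSING, Interval

__all__ = [
    "DiscretizationParams",
    "BinningMap",
    "DiscretizedCohort",
    "fit_discretization",
    "apply_discretization",
    "entropy",
    "mdl_accepts_split",
    "best_cut",
]


@dataclass(frozen=True)
class DiscretizationParams:
    method: str = "mdl"  # "mdl" | "quantile"
    n_bins: int = 4  # quantile fallback only
    max_cuts: int | None = None  # safety cap per feature; None = unlimited

    def __post_init__(self) -> None:
        if self.method not in {"mdl", "quantile"}:
            raise ValueError(f"unknown discretization method {self.method!r}")


def entropy(labels: np.ndarray) -> float:
    """Shannon entropy (bits) of a class-label vector."""
    if labels.size == 0:
        return 0.0
    _, counts = np.unique(labels, return_counts=True)
    p = counts / labels.size
    return float(-(p * np.log2(p)).sum())


def mdl_accepts_split(y: np.ndarray, y_left: np.ndarray, y_right: np.ndarray) -> bool:
    """Fayyad–Irani MDL test: accept the binary split iff the information
    gain pays for the partition's description length."""
    n = y.size
    ent_s = entropy(y)
    ent_l, ent_r = entropy(y_left), entropy(y_right)
    gain = ent_s - (y_left.size * ent_l + y_right.size * ent_r) / n
    k = np.unique(y).size
    k_l = np.unique(y_left).size
    k_r = np.unique(y_right).size
    delta = np.log2(3.0**k - 2.0) - (k * ent_s - k_l * ent_l - k_r * ent_r)
    threshold = (np.log2(n - 1.0) + delta) / n
    return gain > threshold


def _xlogx(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def best_cut(values: np.ndarray, y: np.ndarray) -> tuple[float, float] | None:
    """Cut (midpoint between adjacent distinct values) minimizing the
    weighted class entropy; returns (cut, weighted_entropy) or None.

    Vectorized over all candidate boundaries via cumulative per-class
    counts; ties on entropy go to the leftmost cut.
    """
    distinct, inverse = np.unique(values, return_inverse=True)
    if distinct.size < 2:
        return None
    classes, y_idx = np.unique(y, return_inverse=True)
    # per-distinct-value class counts, then cumulative counts left of each boundary
    counts = np.zeros((distinct.size, classes.size))
    np.add.at(counts, (inverse, y_idx), 1.0)
    cum = np.cumsum(counts, axis=0)[:-1]  # boundary after each distinct value but the last
    n = float(values.size)
    n_left = cum.sum(axis=1)
    n_right = n - n_left
    ent_left = -(_xlogx(cum / n_left[:, None])).sum(axis=1)
    ent_right = -(_xlogx((counts.sum(axis=0) - cum) / n_right[:, None])).sum(axis=1)
    weighted = (n_left * ent_left + n_right * ent_right) / n
    i = int(np.argmin(weighted))
    cut = float((distinct[i] + distinct[i + 1]) / 2.0)
    return cut, float(weighted[i])


def _mdl_cuts(values: np.ndarray, y: np.ndarray, budget: int | None) -> list[float]:
    if budget is not None and budget <= 0:
        return []
    found = best_cut(values, y)
    if found is None:
        return []
    cut, _ = found
    left = values < cut
    if not mdl_accepts_split(y, y[left], y[~left]):
        return []
    sub_budget = None if budget is None else budget - 1
    left_cuts = _mdl_cuts(values[left], y[left], sub_budget)
    if sub_budget is not None:
        sub_budget -= len(left_cuts)
    right_cuts = _mdl_cuts(values[~left], y[~left], sub_budget)
    return sorted(left_cuts + [cut] + right_cuts)


def _quantile_cuts(values: np.ndarray, n_bins: int) -> list[float]:
    qs = np.quantile(values, np.linspace(0, 1, n_bins + 1)[1:-1])
    return sorted(set(float(q) for q in qs))


@dataclass(frozen=True)
class BinningMap:
    """Per-feature ordered cut points; bins partition the real line."""

    cuts: dict[str, tuple[float, ...]]

    def __post_init__(self) -> None:
        for feat, cs in self.cuts.items():
            if list(cs) != sorted(set(cs)):
                raise ValueError(f"cut points for {feat!r} not strictly increasing")

    def intervals(self, feature: str) -> list[Interval]:
        cs = self.cuts[feature]
        edges = [-np.inf, *cs, np.inf]
        return [Interval(a, b) for a, b in zip(edges[:-1], edges[1:])]

    def labels(self, feature: str) -> list[str]:
        return [iv.label() for iv in self.intervals(feature)]

    def bin_value(self, feature: str, value) -> str:
        if pd.isna(value):
            return MISSING
        if isinstance(value, str):
            # idempotence: already a label of this map (or explicit missing)
            if value == MISSING or value in self.labels(feature):
                return value
            value = float(value)
        for iv in self.intervals(feature):
            if iv.contains(float(value)):
                return iv.label()
        raise AssertionError("intervals partition the line")  # pragma: no cover

    def to_json(self, path: str | Path) -> None:
        obj = {f: list(cs) for f, cs in sorted(self.cuts.items())}
        Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "BinningMap":
        obj = json.loads(Path(path).read_text())
        return cls({f: tuple(float(c) for c in cs) for f, cs in obj.items()})


@dataclass
class DiscretizedCohort(CohortTable):
    """A cohort whose continuous features have been replaced by bin labels."""

    binning: BinningMap | None = field(default=None, repr=False)


def fit_discretization(
    train: CohortTable,
    params: DiscretizationParams = DiscretizationParams(),
) -> BinningMap:
    """Learn cut points for every continuous feature from training rows only.

    Features with fewer than two distinct observed values get zero cuts
    (single bin) with a warning. Missing values are ignored while fitting.
    """
    y_all = train.outcome.to_numpy()
    cuts: dict[str, tuple[float, ...]] = {}
    for feat in train.schema.continuous_features:
        col = pd.to_numeric(train.data[feat], errors="coerce").to_numpy(dtype=float)
        ok = ~np.isnan(col)
        values, y = col[ok], y_all[ok]
        if np.unique(values).size < 2:
            warnings.warn(f"feature {feat!r} has <2 distinct values; single bin", stacklevel=2)
            cuts[feat] = ()
            continue
        if params.method == "mdl":
            cs = _mdl_cuts(values, y, params.max_cuts)
        else:
            cs = _quantile_cuts(values, params.n_bins)
            if params.max_cuts is not None:
                cs = cs[: params.max_cuts]
        cuts[feat] = tuple(cs)
    return BinningMap(cuts)


def apply_discretization(cohort: CohortTable, binning: BinningMap) -> DiscretizedCohort:
    """Replace every continuous value by its bin label; idempotent.

    Categorical features pass through (missing values become ``"missing"``).
    Row count, order, outcome and year columns are preserved exactly.
    """
    missing_feats = [f for f in cohort.schema.continuous_features if f not in binning.cuts]
    if missing_feats:
        raise KeyError(f"features absent from binning map: {missing_feats}")
    df = cohort.data.copy()
    for feat in cohort.schema.continuous_features:
        col = df[feat]
        labels = binning.labels(feat)
        if not pd.api.types.is_numeric_dtype(col):
            known = set(labels) | {MISSING}
            if set(col.dropna().astype(str)) <= known:  # already this map's labels
                df[feat] = np.where(col.isna(), MISSING, col.astype(str))
                continue
            col = pd.to_numeric(col, errors="raise")
        v = col.to_numpy(dtype=float)
        idx = np.searchsorted(np.asarray(binning.cuts[feat], dtype=float), v, side="right")
        out = np.asarray(labels, dtype=object)[np.clip(idx, 0, len(labels) - 1)]
        out[np.isnan(v)] = MISSING
        df[feat] = out
    for feat in cohort.schema.categorical_features:
        col = df[feat]
        df[feat] = np.where(col.isna(), MISSING, col.astype(str))
    return DiscretizedCohort(df, cohort.schema, binning=binning)
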