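"""Cohort tables: loading, validation, outcome summaries and temporal splits.

A cohort is one row per (patient, index year) instance: feature columns
(continuous or categorical), a binary outcome column describing the
succeeding year, and the index-year column. Outcomes are encoded upstream;
this package never recomputes them.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

KINDS = {"continuous", "categorical"}
ROLES = {"feature", "outcome", "year", "id"}


class SchemaError(ValueError):
    """The schema itself, or a file's header against it, is invalid."""


class CohortValidationError(ValueError):
    """Row-level content violates the cohort contract."""


@dataclass(frozen=True)
class ColumnSpec:
    name: str
    kind: str  # continuous | categorical
    role: str = "feature"  # feature | outcome | year | id

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise SchemaError(f"unknown kind {self.kind!r} for column {self.name!r}")
        if self.role not in ROLES:
            raise SchemaError(f"unknown role {self.role!r} for column {self.name!r}")


@dataclass(frozen=True)
class FeatureSchema:
    """Column specifications; exactly one outcome and one year column."""

    columns: tuple[ColumnSpec, ...]

    def __post_init__(self) -> None:
        names = [c.name for c in self.columns]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate column names in schema")
        for role in ("outcome", "year"):
            n = sum(c.role == role for c in self.columns)
            if n != 1:
                raise SchemaError(f"schema needs exactly one {role} column, found {n}")
        if sum(c.role == "id" for c in self.columns) > 1:
            raise SchemaError("schema allows at most one id column")

    @classmethod
    def from_columns(cls, columns: Iterable[ColumnSpec]) -> "FeatureSchema":
        return cls(tuple(columns))

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureSchema":
        entries = json.loads(Path(path).read_text())
        return cls(tuple(ColumnSpec(e["name"], e["kind"], e.get("role", "feature")) for e in entries))

    def to_json(self, path: str | Path) -> None:
        entries = [{"name": c.name, "kind": c.kind, "role": c.role} for c in self.columns]
        Path(path).write_text(json.dumps(entries, indent=2) + "\n")

    @property
    def outcome(self) -> str:
        return next(c.name for c in self.columns if c.role == "outcome")

    @property
    def year(self) -> str:
        return next(c.name for c in self.columns if c.role == "year")

    @property
    def id_column(self) -> str | None:
        return next((c.name for c in self.columns if c.role == "id"), None)

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.columns if c.role == "feature")

    @property
    def continuous_features(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.columns if c.role == "feature" and c.kind == "continuous")

    @property
    def categorical_features(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.columns if c.role == "feature" and c.kind == "categorical")


@dataclass
class CohortTable:
    """A validated instance-per-row table plus its schema."""

    data: pd.DataFrame
    schema: FeatureSchema
    rejected: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        missing = [c.name for c in self.schema.columns if c.name not in self.data.columns]
        if missing:
            raise SchemaError(f"columns missing from table: {missing}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def outcome(self) -> pd.Series:
        return self.data[self.schema.outcome]

    @property
    def year(self) -> pd.Series:
        return self.data[self.schema.year]

    def ids(self) -> pd.Series:
        idc = self.schema.id_column
        if idc is not None:
            return self.data[idc]
        return pd.Series(self.data.index, index=self.data.index, name="id")


@dataclass(frozen=True)
class PrevalenceSummary:
    n_total: int
    n_positive: int
    prevalence_pct: float

    def __post_init__(self) -> None:
        if not 0 <= self.n_positive <= self.n_total:
            raise ValueError("need 0 <= n_positive <= n_total")

    @classmethod
    def from_counts(cls, n_positive: int, n_total: int) -> "PrevalenceSummary":
        if n_total <= 0:
            raise ValueError("empty cohort: prevalence undefined")
        return cls(n_total, n_positive, round(100.0 * n_positive / n_total, 2))


def load_cohort(path: str | Path, schema: FeatureSchema) -> CohortTable:
    """Read a delimited cohort file and validate it against ``schema``.

    Rows whose outcome or year does not parse as a number are rejected and
    reported (``CohortTable.rejected``); a parseable but non-binary outcome is
    a hard validation error naming the offending data row (1-based).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=True)
    missing = [c.name for c in schema.columns if c.name not in df.columns]
    if missing:
        raise SchemaError(f"header of {path.name} lacks schema column(s): {missing}")

    out_col, yr_col = schema.outcome, schema.year
    outcome = pd.to_numeric(df[out_col], errors="coerce")
    year = pd.to_numeric(df[yr_col], errors="coerce")
    bad = outcome.isna() | year.isna()
    rejected = df.loc[bad].copy()
    if len(rejected):
        logger.warning("rejected %d row(s) with unparseable outcome/year", len(rejected))
    df = df.loc[~bad].copy()
    outcome, year = outcome[~bad], year[~bad]

    nonbinary = ~outcome.isin([0, 1])
    if nonbinary.any():
        row = int(nonbinary.idxmax()) + 1  # 1-based data row
        raise CohortValidationError(
            f"non-binary outcome value {df[out_col].loc[nonbinary.idxmax()]!r} on row {row}"
        )
    df[out_col] = outcome.astype(int)
    df[yr_col] = year.astype(int)
    for name in schema.continuous_features:
        df[name] = pd.to_numeric(df[name], errors="coerce")

    idc = schema.id_column
    if idc is not None and len(df):
        dup = df.duplicated(subset=[idc, yr_col])
        if dup.any():
            raise CohortValidationError(
                f"duplicate (id, year) pair on row {int(dup.idxmax()) + 1}"
            )
    df = df.reset_index(drop=True)
    return CohortTable(df, schema, rejected=rejected if len(rejected) else None)


def summarize_outcome(cohort: CohortTable) -> PrevalenceSummary:
    """Counts and prevalence (percent, 2 decimals) of the positive outcome."""
    if len(cohort) == 0:
        raise ValueError("empty cohort: prevalence undefined")
    n_total = len(cohort)
    n_positive = int((cohort.outcome == 1).sum())
    return PrevalenceSummary.from_counts(n_positive, n_total)


def temporal_split(
    cohort: CohortTable,
    train_years: Iterable[int],
    test_years: Iterable[int],
) -> tuple[CohortTable, CohortTable]:
    """Split by index year; rows in neither year set are dropped (and logged)."""
    train_years, test_years = set(train_years), set(test_years)
    overlap = train_years & test_years
    if overlap:
        raise ValueError(f"train and test years overlap: {sorted(overlap)}")
    years = cohort.year
    in_train = years.isin(list(train_years))
    in_test = years.isin(list(test_years))
    n_dropped = int((~in_train & ~in_test).sum())
    if n_dropped:
        logger.warning("temporal_split dropped %d row(s) outside both year sets", n_dropped)
    train = CohortTable(cohort.data.loc[in_train].reset_index(drop=True), cohort.schema)
    test = CohortTable(cohort.data.loc[in_test].reset_index(drop=True), cohort.schema)
    return train, test


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    sep = "\t" if str(path).lower().endswith((".tsv", ".tab")) else ","
    cohort.data.to_csv(path, sep=sep, index=False)
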