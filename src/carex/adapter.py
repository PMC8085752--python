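"""Optional gradient-boosting adapter for the upstream classifier slot.

The explanation method is model-agnostic — users normally bring their own
per-instance risk scores and feature-importance ranking. For convenience
this adapter trains an xgboost classifier on a (discretizable) cohort,
returns scores aligned with instance ids, and extracts the top-k features
by importance. It is not part of the method's contract and xgboost is only
imported when the adapter is used.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import CohortTable

__all__ = ["GradientBoostingAdapter"]


class GradientBoostingAdapter:
    def __init__(self, seed: int = 0, **xgb_params):
        try:
            import xgboost  # noqa: F401
        except ImportError as exc:  # pragma: no cover
            raise ImportError("the gradient-boosting adapter requires xgboost") from exc
        self.seed = seed
        self.params = dict(
            n_estimators=50, max_depth=3, learning_rate=0.2,
            random_state=seed, n_jobs=1, **xgb_params,
        )
        self.model = None
        self.feature_names_: list[str] = []

    def _matrix(self, cohort: CohortTable) -> pd.DataFrame:
        X = cohort.data[list(cohort.schema.feature_names)].copy()
        for c in X.columns:
            X[c] = pd.to_numeric(X[c], errors="coerce")
        return X

    def fit(self, train: CohortTable) -> "GradientBoostingAdapter":
        from xgboost import XGBClassifier

        X = self._matrix(train)
        self.feature_names_ = list(X.columns)
        self.model = XGBClassifier(**self.params)
        self.model.fit(X.to_numpy(), train.outcome.to_numpy())
        return self

    def score(self, cohort: CohortTable) -> pd.Series:
        X = self._matrix(cohort)[self.feature_names_]
        proba = self.model.predict_proba(X.to_numpy())[:, 1]
        return pd.Series(proba, index=cohort.ids().to_numpy(), name="score")

    def top_features(self, k: int) -> list[str]:
        imp = np.asarray(self.model.feature_importances_)
        order = np.argsort(-imp, kind="stable")
        return [self.feature_names_[i] for i in order[:k]]
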