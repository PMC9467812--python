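"""Random-forest importance ranking and top-k descriptor selection.

A regression random forest fit on pIC50 scores each descriptor by normalized
mean impurity decrease; the top-k descriptors (k = 224 by default, matching
the published operating-variable count) become the decision variables of the
downstream optimization.  A packaged fixture carries the published ranking of
those 224 descriptors for report- and selection-shape tests.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestRegressor
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted

from .preprocess import descriptor_columns

#: Published operating-variable count.
DEFAULT_K = 224
DEFAULT_N_TREES = 500

_FIXTURE = "published_importances.csv"


@dataclass
class ImportanceRanking:
    """Descriptors ordered by importance, descending; name breaks ties."""

    entries: list[tuple[str, float]]
    n_trees: int | None = None
    seed: int | None = None

    def __post_init__(self):
        self.entries = sorted(self.entries, key=lambda e: (-e[1], e[0]))

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.entries]

    @property
    def scores(self) -> np.ndarray:
        return np.array([s for _, s in self.entries])

    def top_k(self, k: int) -> list[str]:
        if not 0 <= k <= len(self.entries):
            raise ValueError(f"k={k} outside [0, {len(self.entries)}]")
        return self.names[:k]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.entries, columns=["descriptor", "importance"]).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path, **meta) -> "ImportanceRanking":
        df = pd.read_csv(path)
        return cls(entries=list(df.itertuples(index=False, name=None)), **meta)


class ImportanceSelector(SelectorMixin, BaseEstimator):
    """Select the k most important descriptors under a regression forest.

    sklearn-style transformer: ``fit(X, y)`` ranks columns, ``transform``
    keeps the top k.  Columns are ranked on a lexicographically sorted view
    so the result does not depend on input column order.
    """

    def __init__(self, k: int = DEFAULT_K, n_trees: int = DEFAULT_N_TREES, seed: int = 0):
        self.k = k
        self.n_trees = n_trees
        self.seed = seed

    def fit(self, X: pd.DataFrame, y=None):
        if y is None:
            raise ValueError("target (pIC50) is required")
        y = np.asarray(y, dtype=float)
        if len(X) < 2:
            raise ValueError("need at least 2 samples")
        if np.ptp(y) == 0:
            raise ValueError("target is constant; importances undefined")
        cols = sorted(descriptor_columns(X)) if isinstance(X, pd.DataFrame) else None
        if cols is None:
            raise ValueError("ImportanceSelector requires a DataFrame input")
        if not 0 <= self.k <= len(cols):
            raise ValueError(f"k={self.k} exceeds the {len(cols)} descriptors")
        forest = RandomForestRegressor(
            n_estimators=self.n_trees, random_state=self.seed, n_jobs=1
        )
        forest.fit(X[cols].to_numpy(dtype=float), y)
        self.ranking_ = ImportanceRanking(
            entries=list(zip(cols, forest.feature_importances_.astype(float))),
            n_trees=self.n_trees,
            seed=self.seed,
        )
        self.selected_ = self.ranking_.top_k(self.k)
        self.feature_names_in_ = np.asarray(list(X.columns), dtype=object)
        return self

    def _get_support_mask(self) -> np.ndarray:
        check_is_fitted(self, "selected_")
        chosen = set(self.selected_)
        return np.array([c in chosen for c in self.feature_names_in_])

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "selected_")
        return X[self.selected_]


def rank_features(
    table: pd.DataFrame,
    target: str = "pIC50",
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
) -> ImportanceRanking:
    """Importance ranking of all descriptor columns against ``target``."""
    sel = ImportanceSelector(k=0, n_trees=n_trees, seed=seed)
    sel.fit(table, table[target])
    return sel.ranking_


def select_top_k(ranking: ImportanceRanking, k: int = DEFAULT_K) -> list[str]:
    """The k highest-importance descriptor names, descending."""
    return ranking.top_k(k)


def load_published_ranking() -> ImportanceRanking:
    """Packaged published ranking of the 224 retained descriptors.

    The published table lists descriptors from lowest to highest
    contribution; the returned ranking is re-sorted descending.
    """
    ref = importlib.resources.files("qsaropt.data") / _FIXTURE
    with importlib.resources.as_file(ref) as path:
        ranking = ImportanceRanking.from_csv(path)
    if len(ranking) != DEFAULT_K:
        raise RuntimeError(f"fixture corrupt: {len(ranking)} entries, expected {DEFAULT_K}")
    return ranking
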