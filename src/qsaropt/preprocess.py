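"""Descriptor-table cleaning: sparse-column removal, min-max scaling, label selection.

Molecular descriptors arrive on wildly different scales (counts, logP values,
surface areas in the hundreds), so every descriptor is mapped to [0, 1] by
min-max normalization; the per-column (min, max) pairs are retained so that
optimized candidates can be reported back in real units.  Columns that are
mostly literal zeros carry little information and are dropped outright, on
raw values, before scaling.  Of the two activity annotations only pIC50 is
kept: IC50 is its deterministic transform and would be redundant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .objective import ADMET_PROPERTIES

#: Columns that are never treated as descriptors.
NON_DESCRIPTOR_COLUMNS = ("compound_id", "IC50", "pIC50", *ADMET_PROPERTIES)

#: Default zero-fraction at or above which a column counts as "mostly zero".
SPARSE_THRESHOLD = 0.9


def descriptor_columns(table: pd.DataFrame) -> list[str]:
    """Names of the descriptor columns, preserving table order."""
    return [c for c in table.columns if c not in NON_DESCRIPTOR_COLUMNS]


def _check_numeric(table: pd.DataFrame, cols: list[str]) -> None:
    block = table[cols]
    non_numeric = [c for c in cols if not pd.api.types.is_numeric_dtype(block[c])]
    if non_numeric:
        raise ValueError(f"non-numeric descriptor columns: {non_numeric[:5]}")
    if block.isna().any().any():
        bad = block.columns[block.isna().any()].tolist()
        raise ValueError(f"missing values in descriptor columns: {bad[:5]}")


@dataclass
class NormalizationParams:
    """Per-descriptor (min, max) in original units; inverts the [0, 1] scaling."""

    minima: dict[str, float]
    maxima: dict[str, float]
    degenerate: list[str] = field(default_factory=list)  # zero-range columns

    def to_json(self, path: str | Path) -> None:
        payload = {
            c: {"min": self.minima[c], "max": self.maxima[c]} for c in self.minima
        }
        Path(path).write_text(json.dumps({"columns": payload, "degenerate": self.degenerate}, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "NormalizationParams":
        raw = json.loads(Path(path).read_text())
        cols = raw["columns"]
        return cls(
            minima={c: v["min"] for c, v in cols.items()},
            maxima={c: v["max"] for c, v in cols.items()},
            degenerate=raw.get("degenerate", []),
        )


@dataclass
class CleaningReport:
    """What the cleaning stage removed, and the decided stage order."""

    columns_dropped: list[str]
    zero_fractions: dict[str, float]
    labels_dropped: list[str]
    rows_in: int
    rows_out: int
    order: str = "drop_sparse_raw_then_normalize"

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


class MinMaxNormalizer(BaseEstimator, TransformerMixin):
    """Columnwise min-max scaling of descriptor columns to [0, 1].

    Operates on DataFrames and leaves identifier/label columns untouched.
    Zero-range (constant) columns map to 0 and are flagged in
    ``params_.degenerate``.  ``inverse_transform`` restores original units.
    """

    def fit(self, X: pd.DataFrame, y=None):
        cols = descriptor_columns(X)
        if not cols:
            raise ValueError("table has no descriptor columns")
        _check_numeric(X, cols)
        mins = X[cols].min()
        maxs = X[cols].max()
        degenerate = [c for c in cols if maxs[c] == mins[c]]
        self.params_ = NormalizationParams(
            minima={c: float(mins[c]) for c in cols},
            maxima={c: float(maxs[c]) for c in cols},
            degenerate=degenerate,
        )
        self.feature_names_in_ = np.asarray(cols, dtype=object)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "params_")
        out = X.copy()
        p = self.params_
        for c in p.minima:
            rng = p.maxima[c] - p.minima[c]
            if rng == 0:
                out[c] = 0.0
            else:
                out[c] = (X[c].to_numpy(dtype=float) - p.minima[c]) / rng
        return out

    def inverse_transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "params_")
        out = X.copy()
        p = self.params_
        for c in p.minima:
            if c not in out.columns:
                continue
            rng = p.maxima[c] - p.minima[c]
            out[c] = out[c].to_numpy(dtype=float) * rng + p.minima[c]
        return out

    def inverse_transform_vector(self, x: np.ndarray, names: list[str]) -> np.ndarray:
        """Real-unit values of one normalized decision vector."""
        check_is_fitted(self, "params_")
        p = self.params_
        return np.array(
            [x[i] * (p.maxima[c] - p.minima[c]) + p.minima[c] for i, c in enumerate(names)]
        )


class SparseColumnDropper(BaseEstimator, TransformerMixin):
    """Drop descriptor columns whose fraction of literal zeros is >= threshold.

    Zero detection uses exact equality on raw (pre-normalization) values.
    """

    def __init__(self, threshold: float = SPARSE_THRESHOLD):
        self.threshold = threshold

    def fit(self, X: pd.DataFrame, y=None):
        if not 0 < self.threshold <= 1:
            raise ValueError("threshold must lie in (0, 1]")
        cols = descriptor_columns(X)
        _check_numeric(X, cols)
        zf = {c: float((X[c].to_numpy() == 0).mean()) for c in cols}
        dropped = [c for c in cols if zf[c] >= self.threshold]
        if len(dropped) == len(cols):
            raise ValueError("all descriptor columns are mostly zero; nothing survives")
        self.zero_fractions_ = zf
        self.columns_to_drop_ = dropped
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "columns_to_drop_")
        return X.drop(columns=[c for c in self.columns_to_drop_ if c in X.columns])

    def report(self, rows: int) -> CleaningReport:
        check_is_fitted(self, "columns_to_drop_")
        return CleaningReport(
            columns_dropped=list(self.columns_to_drop_),
            zero_fractions={c: self.zero_fractions_[c] for c in self.columns_to_drop_},
            labels_dropped=[],
            rows_in=rows,
            rows_out=rows,
        )


# -- functional wrappers ----------------------------------------------------

def minmax_normalize(table: pd.DataFrame) -> tuple[pd.DataFrame, NormalizationParams]:
    """Scale every descriptor column to [0, 1]; return the per-column params."""
    norm = MinMaxNormalizer().fit(table)
    return norm.transform(table), norm.params_


def inverse_normalize(table: pd.DataFrame, params: NormalizationParams) -> pd.DataFrame:
    norm = MinMaxNormalizer()
    norm.params_ = params
    return norm.inverse_transform(table)


def drop_sparse_columns(
    table: pd.DataFrame, zero_fraction_threshold: float = SPARSE_THRESHOLD
) -> tuple[pd.DataFrame, CleaningReport]:
    """Remove mostly-zero descriptor columns (exact zeros on raw values)."""
    dropper = SparseColumnDropper(zero_fraction_threshold).fit(table)
    return dropper.transform(table), dropper.report(rows=len(table))


def select_activity_label(table: pd.DataFrame) -> pd.DataFrame:
    """Keep pIC50 as the only activity annotation; drop IC50 if present."""
    if "pIC50" not in table.columns:
        raise ValueError("table has no pIC50 column")
    return table.drop(columns=["IC50"], errors="ignore")


def clean_table(
    table: pd.DataFrame, zero_fraction_threshold: float = SPARSE_THRESHOLD
) -> tuple[pd.DataFrame, NormalizationParams, CleaningReport]:
    """Full cleaning pass: label selection, sparse drop on raw values, scaling."""
    rows_in = len(table)
    had_ic50 = "IC50" in table.columns
    table = select_activity_label(table)
    table, report = drop_sparse_columns(table, zero_fraction_threshold)
    table, params = minmax_normalize(table)
    if had_ic50:
        report.labels_dropped = ["IC50"]
    report.rows_in = rows_in
    report.rows_out = len(table)
    return table, params, report
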