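"""Report shaping: metric tables, candidate table, and the JSON run report."""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd

from .objective import ADMET_PROPERTIES
from .surrogates import ClassificationMetrics, RegressionMetrics


def regression_table(metrics: RegressionMetrics) -> pd.DataFrame:
    """One-row activity-metrics table: MSE, MAPE, MAE."""
    return pd.DataFrame(
        [
            {
                "Biological activity": "pIC50",
                "MSE": metrics.MSE,
                "MAPE": metrics.MAPE,
                "MAE": metrics.MAE,
            }
        ]
    )


def classification_table(metrics: dict[str, ClassificationMetrics]) -> pd.DataFrame:
    """Five-row ADMET metrics table: accuracy, precision, recall, F1."""
    rows = []
    for prop in ADMET_PROPERTIES:
        m = metrics[prop]
        rows.append(
            {
                "ADMET": prop,
                "Accuracy": m.accuracy,
                "Precision": m.precision,
                "Recall": m.recall,
                "F1 score": m.f1,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class RunReport:
    """Config echo plus the headline numbers of one pipeline run."""

    profile: str
    seed: int
    n_rows: int
    n_descriptors_raw: int
    n_descriptors_clean: int
    n_selected: int
    pIC50_source: float
    best_fitness: float
    best_objective: dict
    validation_regression: dict
    validation_admet: dict[str, dict]
    config: dict

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, default=str))


def run_report(res) -> RunReport:
    from .preprocess import descriptor_columns

    return RunReport(
        profile=res.config.profile,
        seed=res.config.seed,
        n_rows=len(res.table),
        n_descriptors_raw=len(descriptor_columns(res.table)),
        n_descriptors_clean=len(descriptor_columns(res.cleaned)),
        n_selected=len(res.selected),
        pIC50_source=res.pIC50_source,
        best_fitness=res.optimization.best_fitness,
        best_objective=res.optimization.feasibility["objective"],
        validation_regression=res.validation_regression.to_dict(),
        validation_admet={p: m.to_dict() for p, m in res.validation_admet.items()},
        config=asdict(res.config),
    )
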