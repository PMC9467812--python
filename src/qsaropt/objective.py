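"""Composite clinical-property objective for candidate optimization.

A candidate is a decision vector ``X = (x_1, ..., x_d)`` of min-max normalized
molecular-descriptor values, each constrained to [0, 1].  Its quality combines
two surrogate outputs:

* the quantitative activity surrogate ``psi(X)`` predicting pIC50, clipped to
  the physically meaningful range [0, 10] (``Psi``), and
* five binary ADMET marks ``phi_p(X)`` (1 = favorable), whose sum is zeroed
  below the acceptability threshold of three favorable properties (``Phi``).

The single-objective fitness maximized by the genetic algorithm is
``F(X) = Psi(X) + Phi(X)``, bounded in [0, 15].  A candidate is additionally
flagged feasible on activity when its clipped prediction is at least the
maximum pIC50 observed in the source corpus.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

ADMET_PROPERTIES = ("Caco2", "CYP3A4", "hERG", "HOB", "MN")

#: Sum of favorable ADMET marks below which Phi collapses to zero.
ADMET_ACCEPT_THRESHOLD = 3

#: Valid pIC50 range; activity predictions outside it are zeroed, not clipped
#: to the boundary — an out-of-range surrogate output is treated as worthless.
PIC50_RANGE = (0.0, 10.0)


def phi_modified(marks: Sequence[int] | np.ndarray) -> float:
    """Thresholded ADMET score: the mark sum, or 0 when fewer than 3 are favorable.

    Parameters
    ----------
    marks : sequence of 5 binary values (1 = favorable property).

    Returns
    -------
    float in {0, 3, 4, 5}.
    """
    m = np.asarray(marks)
    if m.shape[-1] != len(ADMET_PROPERTIES):
        raise ValueError(f"expected {len(ADMET_PROPERTIES)} marks, got {m.shape[-1]}")
    if not np.isin(m, (0, 1)).all():
        raise ValueError("ADMET marks must be binary 0/1")
    s = m.sum(axis=-1)
    out = np.where(s >= ADMET_ACCEPT_THRESHOLD, s, 0).astype(float)
    return float(out) if out.ndim == 0 else out


def psi_modified(psi_raw: float | np.ndarray) -> float | np.ndarray:
    """Clipped activity score: the raw prediction inside [0, 10], else 0."""
    raw = np.asarray(psi_raw, dtype=float)
    if not np.isfinite(raw).all():
        raise ValueError("activity prediction must be finite")
    lo, hi = PIC50_RANGE
    out = np.where((raw < lo) | (raw > hi), 0.0, raw)
    return float(out) if out.ndim == 0 else out


@dataclass
class ObjectiveValue:
    """Full accounting of one candidate's objective evaluation."""

    psi_raw: float
    Psi: float
    marks: dict[str, int]
    Phi: float
    F: float
    feasible_activity: bool
    pIC50_source: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ConstraintReport:
    """Per-coordinate box-constraint status plus the activity constraint."""

    box_satisfied: bool
    box_violations: list[int] = field(default_factory=list)
    activity_satisfied: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


class ClinicalObjective:
    """Bind trained surrogates into the composite fitness ``F = Psi + Phi``.

    Parameters
    ----------
    activity_model : object with ``predict(X) -> (n,) array`` of raw pIC50.
    admet_models : mapping property name -> object with
        ``predict_proba(X) -> (n, 2)`` or ``predict(X) -> (n,)`` binary.
    pIC50_source : maximum pIC50 in the corpus the surrogates were fit on;
        reference point of the activity-feasibility constraint.
    feature_names : descriptor names, in the order the models expect; used to
        reject decision vectors built against a different variable ordering.
    hard_activity_filter : if True, candidates with ``Psi < pIC50_source``
        receive fitness 0 instead of only an infeasibility flag.
    """

    def __init__(
        self,
        activity_model,
        admet_models: Mapping[str, object],
        pIC50_source: float,
        feature_names: Sequence[str] | None = None,
        hard_activity_filter: bool = False,
    ):
        missing = set(ADMET_PROPERTIES) - set(admet_models)
        if missing:
            raise ValueError(f"missing ADMET models: {sorted(missing)}")
        self.activity_model = activity_model
        self.admet_models = dict(admet_models)
        self.pIC50_source = float(pIC50_source)
        self.feature_names = list(feature_names) if feature_names is not None else None
        self.hard_activity_filter = hard_activity_filter

    # -- surrogate plumbing ------------------------------------------------
    def _check_x(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.feature_names is not None and X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"decision vector has {X.shape[1]} coordinates, models expect "
                f"{len(self.feature_names)}"
            )
        if (X < 0).any() or (X > 1).any():
            raise ValueError("decision-vector coordinates must lie in [0, 1]")
        return X

    def _admet_marks(self, X: np.ndarray) -> np.ndarray:
        """(n, 5) binary marks; probability >= 0.5 maps to the favorable mark."""
        cols = []
        for prop in ADMET_PROPERTIES:
            model = self.admet_models[prop]
            if hasattr(model, "predict_proba"):
                proba = np.asarray(model.predict_proba(X))
                p1 = proba[:, 1] if proba.ndim == 2 else proba
                cols.append((p1 >= 0.5).astype(int))
            else:
                cols.append(np.asarray(model.predict(X)).astype(int))
        return np.column_stack(cols)

    # -- public API --------------------------------------------------------
    def evaluate(self, x: np.ndarray) -> ObjectiveValue:
        """Evaluate one candidate, returning the full objective breakdown."""
        X = self._check_x(x)
        psi_raw = float(np.asarray(self.activity_model.predict(X)).ravel()[0])
        Psi = float(psi_modified(psi_raw))
        marks_row = self._admet_marks(X)[0]
        Phi = float(phi_modified(marks_row))
        F = Psi + Phi
        feasible = Psi >= self.pIC50_source
        if self.hard_activity_filter and not feasible:
            F = 0.0
        return ObjectiveValue(
            psi_raw=psi_raw,
            Psi=Psi,
            marks={p: int(m) for p, m in zip(ADMET_PROPERTIES, marks_row)},
            Phi=Phi,
            F=F,
            feasible_activity=feasible,
            pIC50_source=self.pIC50_source,
        )

    def fitness(self, X: np.ndarray) -> np.ndarray:
        """Vectorized fitness ``F`` for a population matrix (n, d).

        Identical to per-row :meth:`evaluate`, but with one batched surrogate
        call per model; the GA's inner loop uses this path.
        """
        X = self._check_x(X)
        psi_raw = np.asarray(self.activity_model.predict(X), dtype=float).ravel()
        Psi = psi_modified(psi_raw)
        Phi = phi_modified(self._admet_marks(X))
        F = np.asarray(Psi) + np.asarray(Phi)
        if self.hard_activity_filter:
            F = np.where(np.asarray(Psi) >= self.pIC50_source, F, 0.0)
        if not np.isfinite(F).all():
            bad = X[~np.isfinite(F)][0]
            raise FloatingPointError(f"non-finite fitness for candidate {bad}")
        return F

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return self.fitness(X)


def evaluate_objective(
    x: np.ndarray,
    activity_model,
    admet_models: Mapping[str, object],
    pIC50_source: float,
    feature_names: Sequence[str] | None = None,
) -> ObjectiveValue:
    """Functional form of :meth:`ClinicalObjective.evaluate`."""
    return ClinicalObjective(
        activity_model, admet_models, pIC50_source, feature_names
    ).evaluate(x)


def check_constraints(x: np.ndarray, obj: ObjectiveValue) -> ConstraintReport:
    """Report box-constraint and activity-constraint satisfaction; never mutates x."""
    x = np.asarray(x, dtype=float).ravel()
    violations = np.nonzero((x < 0) | (x > 1))[0].tolist()
    return ConstraintReport(
        box_satisfied=not violations,
        box_violations=violations,
        activity_satisfied=obj.Psi >= obj.pIC50_source,
    )
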