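"""Synthetic compound-corpus generator with known ground truth.

Emulates the statistical shape of an inhibitory-potency screening corpus:
~2000 compounds by ~1400 numeric molecular descriptors with wildly
heterogeneous scales, a sizeable fraction of near-zero-sparse columns, a
pIC50 activity label in [0, 10], and five binary ADMET labels (Caco-2,
CYP3A4, hERG, HOB, MN; 1 = favorable) with controllable class imbalance —
HOB deliberately the most imbalanced.

Activity is a known linear function of a small informative descriptor subset
(plus Gaussian noise, clipped to [0, 10]); ADMET labels are Bernoulli draws
from logistic rules over the same informative pool, so that changing the
operating variables moves activity and ADMET jointly.  The generator returns
the :class:`GroundTruth` alongside the table, giving every downstream stage —
cleaning, feature selection, surrogate training, and the genetic search — an
exact oracle for parameter-recovery tests.

Descriptor marginals are a mixture of uniform, lognormal, and
spike-at-zero columns, each multiplied by a lognormal per-column scale.
The informative descriptors are uniform-type, so their generator-normalized
value is exactly ``raw / scale``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .objective import ADMET_PROPERTIES, phi_modified

# Independent RNG streams derived from the user seed, so that e.g. label
# regeneration does not depend on how many descriptor draws preceded it.
_STREAM_DESCRIPTORS = 1
_STREAM_TRUTH = 2
_STREAM_NOISE = 3
_STREAM_LABELS = 4

DESCRIPTOR_PREFIX = "D"


@dataclass
class GeneratorConfig:
    """Corpus-shape parameters of the synthetic screening dataset.

    Defaults emulate the study corpus: 1974 compounds, 1361 descriptors.
    ``admet_imbalance`` orders positive-class (favorable) proportions as
    (Caco2, CYP3A4, hERG, HOB, MN); HOB defaults to 0.10, the most
    imbalanced, mirroring its weakest classification performance.
    """

    n_samples: int = 1974
    n_descriptors: int = 1361
    sparse_fraction: float = 0.25
    n_informative: int = 20
    noise_sd: float = 0.5
    admet_imbalance: tuple[float, ...] = (0.25, 0.50, 0.45, 0.10, 0.35)
    include_ic50: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples <= 0 or self.n_descriptors <= 0 or self.n_informative <= 0:
            raise ValueError("counts must be positive")
        if not 0 <= self.sparse_fraction <= 1:
            raise ValueError("sparse_fraction must lie in [0, 1]")
        if len(self.admet_imbalance) != len(ADMET_PROPERTIES):
            raise ValueError("admet_imbalance needs one proportion per property")
        if not all(0 < p < 1 for p in self.admet_imbalance):
            raise ValueError("admet_imbalance proportions must lie in (0, 1)")
        n_uniform = self._n_uniform()
        if self.n_informative > n_uniform:
            raise ValueError(
                f"n_informative={self.n_informative} exceeds the "
                f"{n_uniform} uniform-type descriptors available"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    def _n_sparse(self) -> int:
        return int(round(self.sparse_fraction * self.n_descriptors))

    def _n_uniform(self) -> int:
        # non-sparse columns split evenly between uniform and lognormal types,
        # uniform taking the remainder
        return self.n_descriptors - self._n_sparse() - (self.n_descriptors - self._n_sparse()) // 2


@dataclass
class GroundTruth:
    """Latent generative model behind a synthetic corpus.

    Coordinates are generator-normalized values ``u in [0, 1]`` of the
    informative descriptors (``u = raw / scale``).  Activity is
    ``clip(intercept + coeffs . u, 0, 10)``; each ADMET property's favorable
    probability is ``sigmoid(intercept_p + weights_p . u)`` and its
    deterministic mark is 1 when that probability is at least 1/2.
    """

    descriptor_names: list[str]
    informative: list[str]
    activity_intercept: float
    activity_coefficients: dict[str, float]
    scales: dict[str, float]  # per informative descriptor: raw = scale * u
    admet_weights: dict[str, dict[str, float]]
    admet_intercepts: dict[str, float]
    noise_sd: float
    seed: int

    # -- coordinate handling ----------------------------------------------
    def _info_values(self, x) -> np.ndarray:
        """Extract informative coordinates from a full vector, Series or dict."""
        if isinstance(x, Mapping):
            vals = np.array([x[n] for n in self.informative], dtype=float)
        elif isinstance(x, pd.Series):
            vals = x.reindex(self.informative).to_numpy(dtype=float)
        else:
            x = np.asarray(x, dtype=float).ravel()
            if x.size == len(self.descriptor_names):
                idx = [self.descriptor_names.index(n) for n in self.informative]
                vals = x[idx]
            elif x.size == len(self.informative):
                vals = x
            else:
                raise ValueError(
                    f"vector length {x.size} matches neither the full descriptor "
                    f"count {len(self.descriptor_names)} nor the informative "
                    f"count {len(self.informative)}"
                )
        if np.isnan(vals).any():
            raise ValueError("missing informative coordinates")
        return vals

    def normalize_real(self, real: Mapping[str, float] | pd.Series) -> dict[str, float]:
        """Map raw-unit informative values to generator-normalized [0, 1]."""
        out = {}
        for name in self.informative:
            v = float(real[name]) / self.scales[name]
            out[name] = float(np.clip(v, 0.0, 1.0))
        return out

    # -- oracles -----------------------------------------------------------
    def true_activity(self, x) -> float | np.ndarray:
        u = np.atleast_2d([self._info_values(r) for r in x] if np.ndim(x) == 2 else self._info_values(x))
        w = np.array([self.activity_coefficients[n] for n in self.informative])
        latent = self.activity_intercept + u @ w
        act = np.clip(latent, 0.0, 10.0)
        return float(act[0]) if np.ndim(x) != 2 else act

    def true_marks(self, x) -> dict[str, int]:
        u = self._info_values(x)
        marks = {}
        for prop in ADMET_PROPERTIES:
            w = self.admet_weights[prop]
            latent = self.admet_intercepts[prop] + sum(
                w[n] * u[i] for i, n in enumerate(self.informative) if n in w
            )
            marks[prop] = int(latent >= 0.0)
        return marks

    def true_objective(self, x) -> "TrueObjectiveValue":
        """Ground-truth analogue of the composite fitness F = Psi + Phi."""
        x_arr = np.asarray(x, dtype=float) if not isinstance(x, (Mapping, pd.Series)) else x
        if not isinstance(x_arr, (Mapping, pd.Series)):
            if (x_arr < 0).any() or (x_arr > 1).any():
                raise ValueError("coordinates must lie in [0, 1]")
        Psi = float(self.true_activity(x))
        marks = self.true_marks(x)
        Phi = float(phi_modified([marks[p] for p in ADMET_PROPERTIES]))
        return TrueObjectiveValue(Psi=Psi, marks=marks, Phi=Phi, F=Psi + Phi)

    # -- serialization -----------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1, default=list))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class TrueObjectiveValue:
    Psi: float
    marks: dict[str, int]
    Phi: float
    F: float


def _column_layout(cfg: GeneratorConfig) -> tuple[list[str], list[str], list[str]]:
    """Deterministic column typing: uniform, lognormal, then sparse blocks."""
    names = [f"{DESCRIPTOR_PREFIX}{i + 1:04d}" for i in range(cfg.n_descriptors)]
    n_sparse = cfg._n_sparse()
    n_uniform = cfg._n_uniform()
    uniform = names[:n_uniform]
    lognorm = names[n_uniform : cfg.n_descriptors - n_sparse]
    sparse = names[cfg.n_descriptors - n_sparse :]
    return uniform, lognorm, sparse


def _calibrate_intercept(latent0: np.ndarray, rate: float) -> float:
    """Intercept c with mean(sigmoid(latent0 + c)) == rate, by root finding."""

    def gap(c: float) -> float:
        return float(expit(latent0 + c).mean() - rate)

    lo, hi = -50.0, 50.0
    return float(brentq(gap, lo, hi, xtol=1e-10))


def generate_dataset(config: GeneratorConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw a synthetic screening corpus and its generative ground truth.

    Returns a table with ``compound_id``, the descriptor columns, ``pIC50``
    (and ``IC50`` in nM when configured) and the five binary ADMET labels,
    plus the :class:`GroundTruth` that produced it.  Identical config and
    seed reproduce the table exactly.
    """
    config.validate()
    n = config.n_samples
    rng_desc = np.random.default_rng(np.random.SeedSequence((config.seed, _STREAM_DESCRIPTORS)))
    rng_truth = np.random.default_rng(np.random.SeedSequence((config.seed, _STREAM_TRUTH)))
    rng_noise = np.random.default_rng(np.random.SeedSequence((config.seed, _STREAM_NOISE)))

    uniform_cols, lognorm_cols, sparse_cols = _column_layout(config)
    all_names = uniform_cols + lognorm_cols + sparse_cols

    # heavy-tailed per-column scales: spans several orders of magnitude,
    # the heterogeneity that motivates min-max normalization downstream
    scales = rng_desc.lognormal(mean=1.0, sigma=2.0, size=config.n_descriptors)
    scale_map = dict(zip(all_names, scales))

    data: dict[str, np.ndarray] = {}
    u_uniform = rng_desc.uniform(size=(n, len(uniform_cols)))
    for j, name in enumerate(uniform_cols):
        data[name] = u_uniform[:, j] * scale_map[name]
    for name in lognorm_cols:
        data[name] = rng_desc.lognormal(mean=0.0, sigma=1.0, size=n) * scale_map[name]
    n_zero = int(np.floor(0.95 * n))
    for name in sparse_cols:
        col = rng_desc.lognormal(mean=0.0, sigma=1.0, size=n) * scale_map[name]
        zero_idx = rng_desc.permutation(n)[:n_zero]
        col[zero_idx] = 0.0
        data[name] = col

    # ground truth over the informative (uniform-type) descriptors
    informative = uniform_cols[: config.n_informative]
    u_info = u_uniform[:, : config.n_informative]
    signs = rng_truth.choice([-1.0, 1.0], size=config.n_informative)
    coeffs = signs * rng_truth.uniform(0.3, 1.0, size=config.n_informative)
    intercept = 5.0
    latent = intercept + u_info @ coeffs
    pic50 = np.clip(latent + rng_noise.normal(0.0, config.noise_sd, size=n), 0.0, 10.0)

    admet_weights: dict[str, dict[str, float]] = {}
    admet_intercepts: dict[str, float] = {}
    n_support = min(6, config.n_informative)
    for prop, rate in zip(ADMET_PROPERTIES, config.admet_imbalance):
        support = rng_truth.choice(config.n_informative, size=n_support, replace=False)
        w = rng_truth.choice([-1.0, 1.0], size=n_support) * rng_truth.uniform(2.0, 5.0, size=n_support)
        latent0 = u_info[:, support] @ w
        admet_intercepts[prop] = _calibrate_intercept(latent0, rate)
        admet_weights[prop] = {informative[s]: float(wj) for s, wj in zip(support, w)}

    gt = GroundTruth(
        descriptor_names=all_names,
        informative=list(informative),
        activity_intercept=intercept,
        activity_coefficients={n_: float(c) for n_, c in zip(informative, coeffs)},
        scales={n_: float(scale_map[n_]) for n_ in informative},
        admet_weights=admet_weights,
        admet_intercepts=admet_intercepts,
        noise_sd=config.noise_sd,
        seed=config.seed,
    )

    labels = regenerate_labels(gt, pd.DataFrame({n_: data[n_] for n_ in informative}))

    table = pd.DataFrame(data, columns=all_names)
    table.insert(0, "compound_id", [f"CMP{i + 1:05d}" for i in range(n)])
    if config.include_ic50:
        table["IC50"] = 10.0 ** (9.0 - pic50)  # nM
    table["pIC50"] = pic50
    for prop in ADMET_PROPERTIES:
        table[prop] = labels[prop]
    return table, gt


def regenerate_labels(gt: GroundTruth, descriptors_raw: pd.DataFrame) -> pd.DataFrame:
    """Re-draw the ADMET labels from the ground truth's seeded logistic rules.

    ``descriptors_raw`` carries the informative descriptors in raw units; the
    draw uses an RNG stream derived solely from the ground-truth seed, so the
    labels of the original table are reproduced bit for bit.
    """
    u = pd.DataFrame(
        {n: descriptors_raw[n].to_numpy(dtype=float) / gt.scales[n] for n in gt.informative}
    ).to_numpy()
    rng = np.random.default_rng(np.random.SeedSequence((gt.seed, _STREAM_LABELS)))
    out = {}
    info_idx = {n: i for i, n in enumerate(gt.informative)}
    for prop in ADMET_PROPERTIES:
        w = gt.admet_weights[prop]
        latent = gt.admet_intercepts[prop] + sum(
            wj * u[:, info_idx[n_]] for n_, wj in w.items()
        )
        out[prop] = (rng.uniform(size=len(u)) < expit(latent)).astype(int)
    return pd.DataFrame(out)


def true_objective(x, gt: GroundTruth) -> TrueObjectiveValue:
    """Functional wrapper over :meth:`GroundTruth.true_objective`."""
    return gt.true_objective(x)


def save_dataset(table: pd.DataFrame, path: str | Path) -> None:
    """Write the corpus CSV with a stable float format (byte-reproducible)."""
    table.to_csv(path, index=False, float_format="%.10g")


def load_dataset(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
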