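"""Surrogate property models: a pIC50 regressor and five binary ADMET classifiers.

Both tasks share a lightweight 1-D convolutional backbone in the mobile
inverted-bottleneck style: the 224 selected descriptors are treated as a
one-channel sequence passed through depthwise-separable inverted-residual
blocks with squeeze-excitation and hard-swish, then globally pooled into a
dense head producing one scalar.  The regressor trains with mean-square-error
loss; the classifiers append a sigmoid and train with binary cross entropy,
after oversampling the minority class of the training split to parity.

Training follows a fixed protocol: Adam with a cosine-annealed learning rate
(ceiling 1e-4), 100 epochs, batches of 10, and an 80/15/5 train/test/validation
row split.  Tests and the desk-scale pipeline profile use a narrower backbone
and fewer epochs through the same code path.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.metrics import mean_absolute_error, mean_squared_error
from sklearn.utils.validation import check_is_fitted

from . import nn
from .preprocess import descriptor_columns

BlockSpec = tuple[int, int, int, bool, str, int]  # expand, out, kernel, se, act, stride


@dataclass
class BackboneSpec:
    """Architecture of the shared convolutional backbone.

    ``blocks`` rows are (expansion channels, output channels, kernel span,
    squeeze-excitation flag, activation name, stride).  The default widens
    16 -> 96 channels over six inverted-residual blocks and stays far below
    the 2M-parameter lightweight contract.
    """

    input_dim: int = 224
    stem_width: int = 16
    blocks: tuple[BlockSpec, ...] = (
        (16, 16, 3, True, "relu", 2),
        (64, 24, 3, False, "relu", 2),
        (72, 24, 3, False, "relu", 1),
        (96, 40, 5, True, "hswish", 2),
        (160, 48, 5, True, "hswish", 1),
        (192, 96, 5, True, "hswish", 2),
    )
    head_hidden: int = 128
    task: str = "regression"  # or "binary"

    @classmethod
    def small(cls, input_dim: int, task: str = "regression") -> "BackboneSpec":
        """Narrow profile for desk-scale runs and tests."""
        return cls(
            input_dim=input_dim,
            stem_width=16,
            blocks=(
                (16, 16, 3, True, "relu", 1),
                (48, 24, 3, False, "relu", 2),
                (72, 32, 5, True, "hswish", 2),
            ),
            head_hidden=64,
            task=task,
        )


class Backbone(nn.Module):
    """Stem conv -> inverted-residual stack -> global pool -> dense head."""

    def __init__(self, spec: BackboneSpec, rng: np.random.Generator):
        self.spec = spec
        layers: list[nn.Module] = [
            nn.Conv1d(1, spec.stem_width, 3, stride=2, rng=rng),
            nn.BatchNorm1d(spec.stem_width),
            nn.HardSwish(),
        ]
        c = spec.stem_width
        for expand, out, kernel, se, act, stride in spec.blocks:
            layers.append(nn.InvertedResidual(c, expand, out, kernel, stride, se, act, rng=rng))
            c = out
        layers.append(nn.GlobalAvgPool1d())
        self.features = nn.Sequential(layers)
        self.head = nn.Sequential(
            [nn.Linear(c, spec.head_hidden, rng=rng), nn.HardSwish(), nn.Linear(spec.head_hidden, 1, rng=rng)]
        )
        self.out_act = nn.Sigmoid() if spec.task == "binary" else None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim == 2:
            x = x[:, None, :]
        if x.shape[2] != self.spec.input_dim:
            raise ValueError(f"expected input length {self.spec.input_dim}, got {x.shape[2]}")
        out = self.head(self.features(x))
        return self.out_act(out) if self.out_act is not None else out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self.out_act is not None:
            grad = self.out_act.backward(grad)
        return self.features.backward(self.head.backward(grad))


def build_backbone(spec: BackboneSpec, seed: int = 0) -> Backbone:
    """Construct (seeded) the model mapping a descriptor vector to one scalar."""
    return Backbone(spec, np.random.default_rng(np.random.SeedSequence((seed, 11))))


@dataclass
class TrainConfig:
    """Optimization protocol shared by all six surrogates."""

    epochs: int = 100
    batch_size: int = 10
    lr: float = 1e-4
    split: tuple[float, float, float] = (0.80, 0.15, 0.05)
    seed: int = 0

    def validate(self) -> None:
        if self.epochs < 0 or self.batch_size <= 0 or self.lr <= 0:
            raise ValueError("epochs must be >= 0, batch size and lr positive")
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


def split_dataset(
    table: pd.DataFrame,
    fractions: tuple[float, float, float] = (0.80, 0.15, 0.05),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive train/test/validation row partition.

    Sizes are round(n*f) for train and test; validation takes the remainder.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n = len(table)
    n_train = int(round(n * fractions[0]))
    n_test = int(round(n * fractions[1]))
    n_val = n - n_train - n_test
    if min(n_train, n_test, n_val) <= 0:
        raise ValueError(f"empty partition for n={n} at fractions {fractions}")
    perm = np.random.default_rng(np.random.SeedSequence((seed, 7))).permutation(n)
    idx_train = perm[:n_train]
    idx_test = perm[n_train : n_train + n_test]
    idx_val = perm[n_train + n_test :]
    return (
        table.iloc[np.sort(idx_train)],
        table.iloc[np.sort(idx_test)],
        table.iloc[np.sort(idx_val)],
    )


def balance_classes(train: pd.DataFrame, label: str, seed: int = 0) -> pd.DataFrame:
    """Oversample the minority class to parity (sampling with replacement).

    Applied to the training split only; evaluation splits are never expanded.
    """
    counts = train[label].value_counts()
    if set(counts.index) - {0, 1} or len(counts) < 2:
        raise ValueError(f"label {label!r} must contain both binary classes")
    if counts[0] == counts[1]:
        return train
    minority = int(counts.idxmin())
    deficit = int(counts.max() - counts.min())
    pool = train.index[train[label] == minority].to_numpy()
    rng = np.random.default_rng(np.random.SeedSequence((seed, 13)))
    extra = rng.choice(pool, size=deficit, replace=True)
    return pd.concat([train, train.loc[extra]], axis=0)


class _ConvNetEstimator(BaseEstimator):
    """Shared fit loop of the two surrogate estimators (sklearn-style)."""

    _task = "regression"

    def __init__(
        self,
        spec: BackboneSpec | None = None,
        epochs: int = 100,
        batch_size: int = 10,
        lr: float = 1e-4,
        seed: int = 0,
    ):
        self.spec = spec
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.seed = seed

    def _loss(self, pred, y):
        return nn.mse_loss(pred, y) if self._task == "regression" else nn.bce_loss(pred, y)

    def _coerce(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy(dtype=float)
        return np.atleast_2d(np.asarray(X, dtype=float))

    def fit(self, X, y):
        X = self._coerce(X)
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[0] != y.size:
            raise ValueError("X and y disagree on sample count")
        spec = self.spec or BackboneSpec(input_dim=X.shape[1], task=self._task)
        if spec.task != self._task:
            spec = BackboneSpec(**{**asdict(spec), "task": self._task})
        if spec.input_dim != X.shape[1]:
            raise ValueError(f"spec expects {spec.input_dim} descriptors, X has {X.shape[1]}")
        self.model_ = build_backbone(spec, seed=self.seed)
        self.n_features_in_ = X.shape[1]
        self.loss_trace_ = []
        # regression targets are standardized internally so the randomly
        # initialized head starts near the corpus mean; predictions are
        # mapped back to pIC50 units
        if self._task == "regression":
            self._y_mean = float(y.mean())
            self._y_scale = float(y.std()) or 1.0
            y = (y - self._y_mean) / self._y_scale
        else:
            self._y_mean, self._y_scale = 0.0, 1.0
        rng = np.random.default_rng(np.random.SeedSequence((self.seed, 17)))
        opt = nn.Adam(self.model_.parameters(), lr=self.lr)
        sched = nn.CosineAnnealingLR(self.lr, total_epochs=max(1, self.epochs))
        n = X.shape[0]
        self.model_.set_training(True)
        for epoch in range(self.epochs):
            opt.lr = sched.lr_at(epoch)
            order = rng.permutation(n)
            epoch_losses = []
            for start in range(0, n, self.batch_size):
                batch = order[start : start + self.batch_size]
                pred = self.model_(X[batch])
                loss, grad = self._loss(pred, y[batch])
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"training diverged at epoch {epoch}: loss={loss!r}"
                    )
                self.model_.zero_grad()
                self.model_.backward(grad)
                opt.step()
                epoch_losses.append(loss)
            self.loss_trace_.append(float(np.mean(epoch_losses)))
        if self.epochs:
            self._recalibrate_batchnorm(X)
        self.model_.set_training(False)
        return self

    def _recalibrate_batchnorm(self, X: np.ndarray) -> None:
        """Replace minibatch running statistics with exact training-set stats.

        Minibatches of 10 leave the normalization layers with noisy running
        estimates; one full-data forward pass pins them to the population
        values the evaluation mode should use.
        """
        bn_layers = [m for m in self.model_.modules() if isinstance(m, nn.BatchNorm1d)]
        saved = [(bn.momentum) for bn in bn_layers]
        for bn in bn_layers:
            bn.momentum = 1.0
        self.model_.set_training(True)
        self.model_(X)
        for bn, mom in zip(bn_layers, saved):
            bn.momentum = mom

    def _forward(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        X = self._coerce(X)
        self.model_.set_training(False)
        # evaluate in chunks so population-scale calls stay memory-bounded
        outs = [self.model_(X[i : i + 512]).ravel() for i in range(0, X.shape[0], 512)]
        return np.concatenate(outs)


class ActivityRegressor(_ConvNetEstimator, RegressorMixin):
    """Quantitative pIC50 surrogate (conv backbone, MSE loss)."""

    _task = "regression"

    def predict(self, X) -> np.ndarray:
        return self._forward(X) * self._y_scale + self._y_mean


class AdmetClassifier(_ConvNetEstimator, ClassifierMixin):
    """Binary ADMET surrogate (sigmoid head, BCE loss, threshold 0.5)."""

    _task = "binary"

    def fit(self, X, y):
        y = np.asarray(y)
        self.classes_ = np.array([0, 1])
        if set(np.unique(y)) - {0, 1}:
            raise ValueError("labels must be binary 0/1")
        return super().fit(X, y)

    def predict_proba(self, X) -> np.ndarray:
        p1 = self._forward(X)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self._forward(X) >= 0.5).astype(int)


# -- protocol wrappers ------------------------------------------------------

def _xy(table: pd.DataFrame, label: str, features: Sequence[str] | None):
    cols = list(features) if features is not None else descriptor_columns(table)
    return table[cols], table[label].to_numpy(dtype=float)


def train_activity(
    train: pd.DataFrame,
    test: pd.DataFrame,
    cfg: TrainConfig,
    features: Sequence[str] | None = None,
    spec: BackboneSpec | None = None,
) -> tuple[ActivityRegressor, "RegressionMetrics"]:
    """Fit the pIC50 surrogate on the training split; report test metrics."""
    cfg.validate()
    Xtr, ytr = _xy(train, "pIC50", features)
    model = ActivityRegressor(
        spec=spec, epochs=cfg.epochs, batch_size=cfg.batch_size, lr=cfg.lr, seed=cfg.seed
    ).fit(Xtr, ytr)
    Xte, yte = _xy(test, "pIC50", features)
    return model, evaluate_regression(model.predict(Xte), yte)


def train_admet(
    train: pd.DataFrame,
    test: pd.DataFrame,
    property_name: str,
    cfg: TrainConfig,
    features: Sequence[str] | None = None,
    spec: BackboneSpec | None = None,
) -> tuple[AdmetClassifier, "ClassificationMetrics"]:
    """Fit one ADMET classifier with minority oversampling on the train split."""
    cfg.validate()
    balanced = balance_classes(train, property_name, seed=cfg.seed)
    Xtr, ytr = _xy(balanced, property_name, features)
    model = AdmetClassifier(
        spec=spec, epochs=cfg.epochs, batch_size=cfg.batch_size, lr=cfg.lr, seed=cfg.seed
    ).fit(Xtr, ytr)
    Xte, yte = _xy(test, property_name, features)
    return model, evaluate_classification(model.predict(Xte), yte.astype(int))


# -- metrics ---------------------------------------------------------------

@dataclass
class RegressionMetrics:
    MSE: float
    MAPE: float
    MAE: float
    n_zero_labels_excluded: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ClassificationMetrics:
    accuracy: float
    precision: float
    recall: float
    f1: float

    def to_dict(self) -> dict:
        return asdict(self)


def evaluate_regression(predictions, labels) -> RegressionMetrics:
    """MSE / MAPE / MAE; MAPE averages over nonzero labels only."""
    pred = np.asarray(predictions, dtype=float).ravel()
    y = np.asarray(labels, dtype=float).ravel()
    if pred.size == 0 or pred.size != y.size:
        raise ValueError("predictions and labels must be equal-length and non-empty")
    nz = y != 0
    mape = float(np.mean(np.abs((pred[nz] - y[nz]) / y[nz]))) if nz.any() else float("nan")
    return RegressionMetrics(
        MSE=float(mean_squared_error(y, pred)),
        MAPE=mape,
        MAE=float(mean_absolute_error(y, pred)),
        n_zero_labels_excluded=int((~nz).sum()),
    )


def evaluate_classification(predicted, true) -> ClassificationMetrics:
    """Accuracy/precision/recall/F1 from confusion counts; 0 when undefined."""
    p = np.asarray(predicted).ravel().astype(int)
    t = np.asarray(true).ravel().astype(int)
    if p.size == 0 or p.size != t.size:
        raise ValueError("predictions and labels must be equal-length and non-empty")
    tp = int(((p == 1) & (t == 1)).sum())
    fp = int(((p == 1) & (t == 0)).sum())
    fn = int(((p == 0) & (t == 1)).sum())
    tn = int(((p == 0) & (t == 0)).sum())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return ClassificationMetrics(
        accuracy=(tp + tn) / p.size, precision=precision, recall=recall, f1=f1
    )
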