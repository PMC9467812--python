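"""Surrogate training protocol: splits, balancing, backbone, metrics, learning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn import metrics as skm

from qsaropt.surrogates import (
    ActivityRegressor,
    AdmetClassifier,
    BackboneSpec,
    TrainConfig,
    balance_classes,
    build_backbone,
    evaluate_classification,
    evaluate_regression,
    split_dataset,
)


def frame_of(n, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({"A": rng.uniform(size=n), "pIC50": rng.uniform(size=n)})


class TestSplit:
    @pytest.mark.parametrize("n,expected", [(1974, (1579, 296, 99)), (20, (16, 3, 1))])
    def test_partition_sizes(self, n, expected):
        parts = split_dataset(frame_of(n), (0.80, 0.15, 0.05), seed=0)
        assert tuple(len(p) for p in parts) == expected

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(n=st.integers(min_value=7, max_value=300), seed=st.integers(0, 2**31 - 1))
    def test_disjoint_and_exhaustive(self, n, seed):
        try:
            parts = split_dataset(frame_of(n), (0.80, 0.15, 0.05), seed=seed)
        except ValueError:
            # rounding left a partition empty at this n; the rejection is the contract
            return
        idx = np.concatenate([p.index.to_numpy() for p in parts])
        assert len(idx) == n and len(set(idx)) == n

    def test_same_seed_same_membership(self):
        a = split_dataset(frame_of(100), seed=5)
        b = split_dataset(frame_of(100), seed=5)
        for pa, pb in zip(a, b):
            assert pa.index.tolist() == pb.index.tolist()

    def test_empty_partition_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            split_dataset(frame_of(5), (0.8, 0.15, 0.05), seed=0)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            split_dataset(frame_of(100), (0.5, 0.2, 0.2), seed=0)


class TestBalance:
    def frame(self, n_pos, n_neg, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {"A": rng.uniform(size=n_pos + n_neg), "HOB": [1] * n_pos + [0] * n_neg}
        )

    def test_parity(self):
        out = balance_classes(self.frame(10, 90), "HOB", seed=0)
        assert (out["HOB"] == 1).sum() == (out["HOB"] == 0).sum() == 90

    def test_already_balanced_unchanged(self):
        t = self.frame(20, 20)
        pd.testing.assert_frame_equal(balance_classes(t, "HOB", seed=0), t)

    def test_single_minority_row_duplicated(self):
        t = self.frame(1, 5)
        out = balance_classes(t, "HOB", seed=3)
        pos = out[out["HOB"] == 1]
        assert len(pos) == 5 and pos["A"].nunique() == 1

    def test_deterministic(self):
        a = balance_classes(self.frame(3, 11), "HOB", seed=7)
        b = balance_classes(self.frame(3, 11), "HOB", seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_input_not_mutated(self):
        t = self.frame(5, 15)
        before = t.copy()
        balance_classes(t, "HOB", seed=0)
        pd.testing.assert_frame_equal(t, before)

    def test_absent_class_rejected(self):
        with pytest.raises(ValueError):
            balance_classes(self.frame(0, 10), "HOB", seed=0)


class TestBackbone:
    def test_regression_output_finite_scalar(self):
        model = build_backbone(BackboneSpec.small(20), seed=0)
        out = model(np.random.default_rng(0).uniform(size=(5, 20)))
        assert out.shape == (5, 1) and np.isfinite(out).all()

    def test_binary_output_in_unit_interval(self):
        model = build_backbone(BackboneSpec.small(20, "binary"), seed=0)
        out = model(np.random.default_rng(0).uniform(size=(64, 20)))
        assert ((out > 0) & (out < 1)).all()

    def test_default_spec_under_parameter_budget(self):
        model = build_backbone(BackboneSpec(), seed=0)
        assert model.n_parameters() < 2_000_000

    def test_input_length_checked(self):
        model = build_backbone(BackboneSpec.small(20), seed=0)
        with pytest.raises(ValueError, match="length"):
            model(np.zeros((2, 21)))


class TestTraining:
    def linear_problem(self, n=200, d=12, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.uniform(size=(n, d))
        w = rng.uniform(-1, 1, size=d)
        return X, 5 + X @ w, w

    def test_regressor_beats_mean_baseline(self):
        """On a noise-free linear target the net clearly beats label variance."""
        X, y, w = self.linear_problem()
        model = ActivityRegressor(
            spec=BackboneSpec.small(12), epochs=20, lr=3e-3, seed=0
        ).fit(X, y)
        rng = np.random.default_rng(1)
        Xv = rng.uniform(size=(80, 12))
        yv = 5 + Xv @ w
        assert np.mean((model.predict(Xv) - yv) ** 2) < yv.var()

    def test_zero_epochs_returns_untrained(self):
        X, y, _ = self.linear_problem(n=30)
        model = ActivityRegressor(spec=BackboneSpec.small(12), epochs=0, seed=0).fit(X, y)
        assert model.loss_trace_ == []
        assert np.isfinite(model.predict(X)).all()

    def test_training_reduces_loss(self):
        X, y, _ = self.linear_problem()
        model = ActivityRegressor(spec=BackboneSpec.small(12), epochs=8, lr=3e-3, seed=0).fit(X, y)
        assert model.loss_trace_[-1] <= model.loss_trace_[0]

    def test_fixed_seed_reproduces_final_loss(self):
        X, y, _ = self.linear_problem(n=60)
        runs = [
            ActivityRegressor(spec=BackboneSpec.small(12), epochs=3, seed=4).fit(X, y).loss_trace_
            for _ in range(2)
        ]
        assert runs[0] == runs[1]

    def test_classifier_separable_accuracy(self):
        """A margin-separated linear property is classified almost perfectly."""
        rng = np.random.default_rng(0)
        X = rng.uniform(size=(800, 12))
        w = rng.uniform(-1, 1, size=12)
        s = X @ w
        thr, sd = np.median(s), s.std()
        keep = np.abs(s - thr) > 0.5 * sd
        Xk, yk = X[keep], (s[keep] > thr).astype(int)
        ntr = 300
        model = AdmetClassifier(
            spec=BackboneSpec.small(12, "binary"), epochs=40, lr=1e-2, seed=0
        ).fit(Xk[:ntr], yk[:ntr])
        acc = (model.predict(Xk[ntr:]) == yk[ntr:]).mean()
        assert acc > 0.95

    def test_classifier_probability_range_and_threshold(self):
        X, y, w = self.linear_problem(n=60)
        yb = (y > np.median(y)).astype(int)
        model = AdmetClassifier(spec=BackboneSpec.small(12, "binary"), epochs=2, seed=0).fit(X, yb)
        proba = model.predict_proba(X)
        assert proba.shape == (60, 2)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)
        np.testing.assert_array_equal(model.predict(X), (proba[:, 1] >= 0.5).astype(int))

    def test_non_binary_labels_rejected(self):
        X, y, _ = self.linear_problem(n=20)
        with pytest.raises(ValueError, match="binary"):
            AdmetClassifier(spec=BackboneSpec.small(12, "binary"), epochs=1).fit(X, y)


class TestRegressionMetrics:
    def test_perfect_prediction(self):
        m = evaluate_regression([1.0, 2.0], [1.0, 2.0])
        assert (m.MSE, m.MAPE, m.MAE) == (0.0, 0.0, 0.0)

    def test_two_point_example(self):
        m = evaluate_regression([3.0, 5.0], [4.0, 5.0])
        assert m.MSE == pytest.approx(0.5)
        assert m.MAPE == pytest.approx(0.125)
        assert m.MAE == pytest.approx(0.5)

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(0)
        pred, y = rng.normal(size=50), rng.normal(size=50)
        m = evaluate_regression(pred, y)
        assert m.MSE == pytest.approx(np.mean((pred - y) ** 2), abs=1e-12)
        assert m.MAE == pytest.approx(np.mean(np.abs(pred - y)), abs=1e-12)
        nz = y != 0
        assert m.MAPE == pytest.approx(np.mean(np.abs((pred[nz] - y[nz]) / y[nz])), abs=1e-12)

    def test_zero_labels_excluded_from_mape(self):
        m = evaluate_regression([1.0, 2.0, 3.0], [0.0, 2.0, 3.0])
        assert m.n_zero_labels_excluded == 1
        assert m.MAPE == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            evaluate_regression([], [])


class TestClassificationMetrics:
    def test_confusion_example(self):
        # TP=3 FP=1 FN=2 TN=4
        true = [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]
        pred = [1, 1, 1, 0, 0, 1, 0, 0, 0, 0]
        m = evaluate_classification(pred, true)
        assert m.accuracy == pytest.approx(0.7)
        assert m.precision == pytest.approx(0.75)
        assert m.recall == pytest.approx(0.6)
        assert m.f1 == pytest.approx(2 * 0.75 * 0.6 / 1.35)

    def test_perfect_and_degenerate(self):
        m = evaluate_classification([1, 0, 1], [1, 0, 1])
        assert (m.accuracy, m.precision, m.recall, m.f1) == (1.0, 1.0, 1.0, 1.0)
        m = evaluate_classification([0, 0, 0], [1, 0, 1])
        assert m.recall == 0.0 and m.precision == 0.0 and m.f1 == 0.0

    def test_matches_sklearn_on_random_vectors(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            t = rng.integers(0, 2, 30)
            p = rng.integers(0, 2, 30)
            m = evaluate_classification(p, t)
            assert m.accuracy == pytest.approx(skm.accuracy_score(t, p))
            assert m.precision == pytest.approx(skm.precision_score(t, p, zero_division=0))
            assert m.recall == pytest.approx(skm.recall_score(t, p, zero_division=0))
            assert m.f1 == pytest.approx(skm.f1_score(t, p, zero_division=0))
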