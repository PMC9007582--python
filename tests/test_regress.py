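"""Tests for the linear calibration and its leave-one-out validation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import LeaveOneOut, cross_val_predict

from ringblot import (
    LabeledDataset,
    compute_metrics,
    fit_linear,
    jitter_labels,
    loo_predict,
    loo_report,
)


def _ols_normal_equations(X, y):
    """Closed-form OLS oracle: solve the normal equations on [X | 1]."""
    A = np.column_stack([X, np.ones(len(y))])
    theta = np.linalg.solve(A.T @ A, A.T @ y)
    return theta[:-1], theta[-1]


def _loo_oracle(X, y):
    """Materialize every leave-one-out submodel explicitly with numpy."""
    n = len(y)
    preds = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        w, b = _ols_normal_equations(X[keep], y[keep])
        preds[i] = X[i] @ w + b
    return preds


class TestJitterLabels:
    def test_zero_fraction_leaves_labels_unchanged(self, rng):
        y = np.array([0.0, 0.5, 10.0])
        assert np.array_equal(jitter_labels(y, 0.0, rng), y)

    def test_five_percent_tweak_stays_within_bounds(self, rng):
        y = np.full(200, 10.0)
        out = jitter_labels(y, 0.05, rng)
        assert np.all(out >= 9.5) and np.all(out <= 10.5)
        assert not np.allclose(out, y)

    def test_blank_label_stays_zero(self, rng):
        out = jitter_labels(np.array([0.0, 1.0]), 0.5, rng)
        assert out[0] == 0.0

    def test_negative_fraction_rejected(self, rng):
        with pytest.raises(ValueError):
            jitter_labels(np.ones(3), -0.1, rng)

    @given(fraction=st.floats(0.0, 0.5), seed=st.integers(0, 1000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_tweak_bounded_and_deterministic(self, fraction, seed):
        y = np.array([0.0, 0.1, 1.0, 10.0])
        a = jitter_labels(y, fraction, np.random.default_rng(seed))
        b = jitter_labels(y, fraction, np.random.default_rng(seed))
        assert np.array_equal(a, b)
        assert np.all(np.abs(a - y) <= fraction * y + 1e-12)


class TestFitLinear:
    def test_exactly_linear_labels_are_interpolated(self, rng):
        X = rng.random((20, 6))
        w_true = np.array([3.0, -1.0, 0.5, 2.0, 0.0, -4.0])
        y = X @ w_true + 1.7
        model = fit_linear(X, y)
        assert np.allclose(model.predict(X), y, atol=1e-9)
        assert np.allclose(model.coefficients, w_true, atol=1e-8)
        assert model.intercept == pytest.approx(1.7, abs=1e-8)

    def test_one_dimensional_toy_closed_form(self):
        X = np.array([[0.0], [1.0], [2.0]])
        y = np.array([0.0, 2.0, 4.0])
        model = fit_linear(X, y)
        assert model.coefficients[0] == pytest.approx(2.0)
        assert model.intercept == pytest.approx(0.0, abs=1e-12)

    def test_constant_labels_yield_zero_coefficients(self, rng):
        X = rng.random((15, 4))
        y = np.full(15, 3.3)
        model = fit_linear(X, y)
        assert np.allclose(model.coefficients, 0.0, atol=1e-10)
        assert model.intercept == pytest.approx(3.3)

    def test_matches_normal_equation_oracle(self, rng):
        X = rng.random((30, 6))
        y = rng.random(30) * 10
        model = fit_linear(X, y)
        w, b = _ols_normal_equations(X, y)
        assert np.allclose(model.coefficients, w, atol=1e-8)
        assert model.intercept == pytest.approx(b, abs=1e-8)

    def test_non_finite_inputs_rejected(self):
        X = np.ones((10, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            fit_linear(X, np.ones(10))

    def test_too_few_instances_rejected(self, rng):
        with pytest.raises(ValueError, match="instances"):
            fit_linear(rng.random((7, 6)), np.ones(7))


class TestLeaveOneOut:
    def test_noiseless_linear_data_predicted_exactly(self, rng):
        X = rng.random((12, 3))
        y = X @ np.array([1.0, 2.0, 3.0]) + 0.5
        ds = LabeledDataset(features=X, labels=y)
        preds, train_maes = loo_predict(ds)
        assert np.allclose(preds, y, atol=1e-9)
        assert np.allclose(train_maes, 0.0, atol=1e-9)

    def test_matches_explicit_fold_by_fold_oracle(self, rng):
        X = rng.random((10, 2))
        y = X @ np.array([2.0, 1.0]) + 0.3 + 0.1 * rng.standard_normal(10)
        ds = LabeledDataset(features=X, labels=y)
        preds, _ = loo_predict(ds)
        assert np.allclose(preds, _loo_oracle(X, y), atol=1e-10)

    def test_matches_sklearn_cross_val_predict(self, rng):
        X = rng.random((14, 4))
        y = rng.random(14) * 5
        ds = LabeledDataset(features=X, labels=y)
        preds, _ = loo_predict(ds)
        ref = cross_val_predict(LinearRegression(), X, y, cv=LeaveOneOut())
        assert np.allclose(preds, ref, atol=1e-10)

    def test_predictions_invariant_to_instance_order(self, rng):
        X = rng.random((11, 3))
        y = rng.random(11)
        perm = rng.permutation(11)
        preds, _ = loo_predict(LabeledDataset(features=X, labels=y))
        preds_p, _ = loo_predict(LabeledDataset(features=X[perm], labels=y[perm]))
        assert np.allclose(preds[perm], preds_p, atol=1e-12)

    def test_clean_prediction_isolated_from_own_label(self, rng):
        X = rng.random((12, 3))
        y = rng.random(12)
        i = 4
        preds_a, _ = loo_predict(LabeledDataset(features=X, labels=y))
        y2 = y.copy()
        y2[i] = 99.0  # corrupt the held-out label
        preds_b, _ = loo_predict(LabeledDataset(features=X, labels=y2))
        assert preds_a[i] == preds_b[i]  # fold i never saw label i
        others = np.arange(12) != i
        assert not np.allclose(preds_a[others], preds_b[others])

    def test_too_small_dataset_rejected(self, rng):
        X = rng.random((8, 6))
        with pytest.raises(ValueError, match="too small"):
            loo_predict(LabeledDataset(features=X, labels=np.ones(8)))

    def test_leave_pair_out_holds_replicates_together(self, rng):
        X = rng.random((20, 3))
        labels = np.repeat(np.linspace(1, 10, 10), 2)
        ds = LabeledDataset(features=X, labels=labels)
        report = loo_report(ds, leave_pair_out=True)
        assert report.n_folds == 10
        # twin isolation: corrupting one twin's features must not move the
        # other twin's prediction through the shared fold
        X2 = X.copy()
        X2[0] += 10.0
        preds_a, _ = loo_predict(ds, leave_pair_out=True)
        preds_b, _ = loo_predict(
            LabeledDataset(features=X2, labels=labels), leave_pair_out=True
        )
        # instance 1 shares instance 0's fold, so its model is unchanged
        assert preds_a[1] == preds_b[1]


class TestMetrics:
    def test_perfect_predictions_zero_errors(self):
        y = np.array([0.1, 0.5, 3.0, 9.0])
        m = compute_metrics(y, y)
        assert m.mae_overall == 0 and m.mae_low_range == 0
        assert m.mean_relative_error_high == 0

    def test_hand_arithmetic_example(self):
        m = compute_metrics(np.array([0.7, 3.0]), np.array([0.5, 4.0]))
        assert m.mae_overall == pytest.approx(0.6)
        assert m.mae_low_range == pytest.approx(0.2)
        assert m.mean_relative_error_high == pytest.approx(0.25)

    def test_empty_high_subset_is_undefined_not_zero(self):
        m = compute_metrics(np.array([0.2, 0.9]), np.array([0.3, 1.0]))
        assert m.mean_relative_error_high is None
        assert m.n_high == 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(np.ones(3), np.ones(4))

    def test_mae_decomposes_over_label_partition(self, rng):
        labels = rng.random(40) * 10
        preds = labels + rng.standard_normal(40)
        cut = 3.0
        m_all = compute_metrics(preds, labels)
        lo, hi = labels <= cut, labels > cut
        mae_lo = np.abs(preds[lo] - labels[lo]).mean()
        mae_hi = np.abs(preds[hi] - labels[hi]).mean()
        recomposed = (lo.sum() * mae_lo + hi.sum() * mae_hi) / 40
        assert m_all.mae_overall == pytest.approx(recomposed, abs=1e-12)


class TestReport:
    def test_generalization_gap_definition(self, rng):
        X = rng.random((15, 3))
        y = X @ np.array([1.0, -2.0, 0.5]) + 5 + 0.3 * rng.standard_normal(15)
        report = loo_report(LabeledDataset(features=X, labels=y))
        gap = (report.mae_overall - report.mean_train_mae) / report.mae_overall
        assert report.generalization_gap == pytest.approx(gap)

    def test_metrics_against_jittered_labels(self, rng):
        X = rng.random((12, 3))
        y = np.linspace(1, 10, 12)
        yj = jitter_labels(y, 0.05, rng)
        ds = LabeledDataset(features=X, labels=y, jittered_labels=yj)
        r_true = loo_report(ds, metrics_against="true")
        r_jit = loo_report(ds, metrics_against="jittered")
        # same fitted models, different reference labels for the metrics
        assert np.array_equal(r_true.clean_predictions, r_jit.clean_predictions)
        assert r_true.mae_overall != r_jit.mae_overall

    def test_clip_negative_flag(self, rng):
        X = rng.random((12, 3))
        y = rng.random(12) * 0.1
        r_raw = loo_report(LabeledDataset(features=X, labels=y))
        r_clip = loo_report(LabeledDataset(features=X, labels=y), clip_negative=True)
        assert np.all(r_clip.clean_predictions >= 0)
        if np.any(r_raw.clean_predictions < 0):
            assert r_clip.mae_overall != r_raw.mae_overall


class TestNoisyRecovery:
    """Statistical behaviour of LOO on y = Xw + b + sigma * z."""

    # positive weights keep y = Xw + b away from zero for moderate noise
    W = np.array([2.0, 1.0, 0.5, 1.5, 0.5, 3.0])
    B = 1.0

    def _design(self, seed, n=36):
        rng = np.random.default_rng(seed)
        X = rng.random((n, 6))
        z = rng.standard_normal(n)
        return X, z

    def test_loo_mae_scales_linearly_with_noise_sd(self):
        # the same noise realization is rescaled across levels; LOO errors
        # are linear in the label vector and the noiseless part is predicted
        # exactly, so the MAE is exactly proportional to sigma
        X, z = self._design(0)
        sigmas = [0.05, 0.1, 0.2]
        maes = []
        for s in sigmas:
            y = X @ self.W + self.B + s * z
            assert np.all(y >= 0)
            preds, _ = loo_predict(LabeledDataset(features=X, labels=y))
            maes.append(np.abs(preds - y).mean())
        assert maes[1] / maes[0] == pytest.approx(2.0, rel=1e-9)
        assert maes[2] / maes[1] == pytest.approx(2.0, rel=1e-9)

    def test_coefficients_converge_as_noise_vanishes(self):
        X, z = self._design(1)
        errs = []
        for s in [0.2, 0.02, 0.002]:
            y = X @ self.W + self.B + s * z
            model = fit_linear(X, y)
            errs.append(np.max(np.abs(model.coefficients - self.W)))
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < 0.01

    def test_train_mae_below_test_mae_in_every_replicate(self):
        wins = 0
        for rep in range(20):
            X, z = self._design(100 + rep)
            y = X @ self.W + self.B + 0.5 * z
            y = np.maximum(y, 0.0)  # labels are concentrations, >= 0
            report = loo_report(LabeledDataset(features=X, labels=y))
            wins += report.mean_train_mae < report.mae_overall
        assert wins == 20
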