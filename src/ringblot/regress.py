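"""Linear calibration of ring-profile features with leave-one-out validation.

The concentration readout is deliberately the simplest supervised model —
ordinary least squares with an intercept on the ring-profile features.
With only a few dozen labelled spots a full held-out split is wasteful, so
validation is leave-one-out (K-fold with K = n): every instance receives a
"clean" prediction from a model fitted on all the others, and each fold
also reports its mean absolute train residual so the generalization gap
can be assessed.

Metrics follow the assay's reporting conventions: overall MAE in ppm, MAE
restricted to the low range (labels <= 1 ppm, the detection-limit regime),
and mean relative error in the high range (labels > 2 ppm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LinearRegression

__all__ = [
    "LabeledDataset",
    "LinearModel",
    "RegressionMetrics",
    "LOOReport",
    "jitter_labels",
    "fit_linear",
    "loo_predict",
    "compute_metrics",
    "loo_report",
]


@dataclass(frozen=True, eq=False)
class LabeledDataset:
    """Feature matrix plus concentration labels for the regression stage.

    ``jittered_labels``, when present, are the labels after the small
    multiplicative tweak emulating pipetting uncertainty; they are used for
    *fitting* while metrics default to the original (true) labels.
    """

    features: np.ndarray
    labels: np.ndarray
    jittered_labels: np.ndarray | None = None
    instance_ids: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        X = np.asarray(self.features, dtype=float)
        y = np.asarray(self.labels, dtype=float)
        if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.shape[0]:
            raise ValueError("features must be (n, p) and labels (n,)")
        if np.any(y < 0):
            raise ValueError("labels must be non-negative")
        object.__setattr__(self, "features", X)
        object.__setattr__(self, "labels", y)
        if self.jittered_labels is not None:
            yj = np.asarray(self.jittered_labels, dtype=float)
            if yj.shape != y.shape:
                raise ValueError("jittered_labels must match labels in shape")
            object.__setattr__(self, "jittered_labels", yj)

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def fit_labels(self) -> np.ndarray:
        """Labels used for model fitting (jittered when available)."""
        return self.labels if self.jittered_labels is None else self.jittered_labels


@dataclass(frozen=True, eq=False)
class LinearModel:
    """An affine concentration predictor: ppm = features . coefficients + intercept."""

    coefficients: np.ndarray
    intercept: float

    def predict(self, features: np.ndarray) -> np.ndarray:
        X = np.asarray(features, dtype=float)
        return X @ self.coefficients + self.intercept


def jitter_labels(
    labels: np.ndarray, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Multiply each label by (1 + u), u uniform on [-fraction, +fraction].

    Zero labels remain exactly zero (the tweak is multiplicative), matching
    a pipetting-uncertainty model where the blank carries no analyte.
    """
    if fraction < 0:
        raise ValueError(f"jitter fraction must be >= 0, got {fraction}")
    y = np.asarray(labels, dtype=float)
    u = rng.uniform(-fraction, fraction, size=y.shape)
    return y * (1.0 + u)


def fit_linear(features: np.ndarray, labels: np.ndarray) -> LinearModel:
    """Ordinary least squares with intercept; minimum-norm under rank deficiency."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("features and labels must be finite")
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.shape[0]:
        raise ValueError("features must be (n, p) with matching labels (n,)")
    n, p = X.shape
    if n < p + 2:
        raise ValueError(
            f"need at least p + 2 = {p + 2} instances to fit {p + 1} parameters, got {n}"
        )
    reg = LinearRegression().fit(X, y)
    return LinearModel(coefficients=np.asarray(reg.coef_, dtype=float), intercept=float(reg.intercept_))


def _fold_groups(dataset: LabeledDataset, pair_on_labels: bool) -> list[np.ndarray]:
    """Test-index groups: singletons for LOO, label-sharing groups for leave-pair-out."""
    n = dataset.n
    if not pair_on_labels:
        return [np.array([i]) for i in range(n)]
    groups: dict[float, list[int]] = {}
    for i, lab in enumerate(dataset.labels):
        groups.setdefault(float(lab), []).append(i)
    return [np.array(idx) for idx in groups.values()]


def loo_predict(
    dataset: LabeledDataset, leave_pair_out: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Clean predictions and per-fold train MAEs under leave-one-out.

    For each fold the model is fitted on all other instances (using the
    jittered labels when present) and predicts the held-out instance(s);
    the fold's mean absolute train residual is recorded against the same
    fitting labels.  With ``leave_pair_out`` replicates sharing a label are
    held out together, avoiding twin leakage between duplicates.

    Returns ``(predictions, train_maes)``, both of length n; instances in
    the same fold share the fold's train MAE.  Predictions do not depend on
    instance ordering.
    """
    X, y_fit = dataset.features, dataset.fit_labels
    n, p = X.shape
    folds = _fold_groups(dataset, leave_pair_out)
    max_test = max(len(f) for f in folds)
    if n - max_test < p + 2:
        raise ValueError(
            f"leave-one-out needs every fold to retain >= p + 2 = {p + 2} "
            f"training instances; n = {n} is too small"
        )
    predictions = np.empty(n)
    train_maes = np.empty(n)
    for test_idx in folds:
        train = np.ones(n, dtype=bool)
        train[test_idx] = False
        model = fit_linear(X[train], y_fit[train])
        predictions[test_idx] = model.predict(X[test_idx])
        resid = model.predict(X[train]) - y_fit[train]
        train_maes[test_idx] = float(np.mean(np.abs(resid)))
    return predictions, train_maes


@dataclass(frozen=True)
class RegressionMetrics:
    """The metric suite over clean predictions.

    Subset metrics are ``None`` (undefined) when their subset is empty,
    never silently zero.
    """

    mae_overall: float
    mae_low_range: float | None
    mean_relative_error_high: float | None
    n_total: int
    n_low: int
    n_high: int
    low_cutoff: float
    high_cutoff: float


def compute_metrics(
    predictions: np.ndarray,
    labels: np.ndarray,
    low_cutoff: float = 1.0,
    high_cutoff: float = 2.0,
) -> RegressionMetrics:
    """MAE overall, MAE on labels <= low_cutoff, mean |rel. error| on labels > high_cutoff."""
    pred = np.asarray(predictions, dtype=float)
    lab = np.asarray(labels, dtype=float)
    if pred.shape != lab.shape or pred.ndim != 1:
        raise ValueError("predictions and labels must be 1-D with equal length")
    if np.any(lab < 0):
        raise ValueError("labels must be non-negative")
    err = np.abs(pred - lab)
    low = lab <= low_cutoff
    high = lab > high_cutoff
    return RegressionMetrics(
        mae_overall=float(err.mean()),
        mae_low_range=float(err[low].mean()) if low.any() else None,
        mean_relative_error_high=(
            float((err[high] / lab[high]).mean()) if high.any() else None
        ),
        n_total=len(lab),
        n_low=int(low.sum()),
        n_high=int(high.sum()),
        low_cutoff=low_cutoff,
        high_cutoff=high_cutoff,
    )


@dataclass(frozen=True, eq=False)
class LOOReport:
    """Clean predictions, per-fold train errors, and the full metric suite."""

    instance_ids: tuple[int, ...]
    labels: np.ndarray
    jittered_labels: np.ndarray | None
    clean_predictions: np.ndarray
    per_fold_train_mae: np.ndarray
    metrics: RegressionMetrics
    mean_train_mae: float
    generalization_gap: float | None
    n_folds: int
    metrics_against: str

    @property
    def mae_overall(self) -> float:
        return self.metrics.mae_overall

    @property
    def mae_low_range(self) -> float | None:
        return self.metrics.mae_low_range

    @property
    def mean_relative_error_high(self) -> float | None:
        return self.metrics.mean_relative_error_high

    def to_dict(self) -> dict:
        return {
            "n_instances": int(len(self.labels)),
            "n_folds": int(self.n_folds),
            "metrics_against": self.metrics_against,
            "mae_overall_ppm": self.mae_overall,
            "mae_low_range_ppm": self.mae_low_range,
            "mean_relative_error_high": self.mean_relative_error_high,
            "mean_train_mae_ppm": self.mean_train_mae,
            "generalization_gap": self.generalization_gap,
            "low_cutoff_ppm": self.metrics.low_cutoff,
            "high_cutoff_ppm": self.metrics.high_cutoff,
            "instance_ids": [int(i) for i in self.instance_ids],
            "true_ppm": [float(v) for v in self.labels],
            "jittered_ppm": (
                None
                if self.jittered_labels is None
                else [float(v) for v in self.jittered_labels]
            ),
            "predicted_ppm": [float(v) for v in self.clean_predictions],
            "fold_train_mae_ppm": [float(v) for v in self.per_fold_train_mae],
        }


def loo_report(
    dataset: LabeledDataset,
    low_cutoff: float = 1.0,
    high_cutoff: float = 2.0,
    metrics_against: str = "true",
    leave_pair_out: bool = False,
    clip_negative: bool = False,
) -> LOOReport:
    """Run leave-one-out validation and assemble the full report.

    ``metrics_against`` selects the reference labels for the error metrics:
    ``'true'`` (default, the original concentrations) or ``'jittered'``.
    ``clip_negative`` optionally clamps clean predictions at zero before
    metrics are computed; the default reports raw predictions.
    """
    if metrics_against not in ("true", "jittered"):
        raise ValueError("metrics_against must be 'true' or 'jittered'")
    predictions, train_maes = loo_predict(dataset, leave_pair_out=leave_pair_out)
    if clip_negative:
        predictions = np.maximum(predictions, 0.0)
    ref = (
        dataset.labels
        if metrics_against == "true" or dataset.jittered_labels is None
        else dataset.jittered_labels
    )
    metrics = compute_metrics(predictions, ref, low_cutoff, high_cutoff)
    n_folds = len(_fold_groups(dataset, leave_pair_out))
    # each fold contributes one train MAE; average over folds, not instances
    fold_maes = (
        train_maes
        if not leave_pair_out
        else np.array([train_maes[f[0]] for f in _fold_groups(dataset, True)])
    )
    mean_train = float(np.mean(fold_maes))
    gap = (
        (metrics.mae_overall - mean_train) / metrics.mae_overall
        if metrics.mae_overall > 0
        else None
    )
    ids = dataset.instance_ids or tuple(range(dataset.n))
    return LOOReport(
        instance_ids=tuple(ids),
        labels=dataset.labels,
        jittered_labels=dataset.jittered_labels,
        clean_predictions=predictions,
        per_fold_train_mae=train_maes,
        metrics=metrics,
        mean_train_mae=mean_train,
        generalization_gap=gap,
        n_folds=n_folds,
        metrics_against=metrics_against,
    )
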