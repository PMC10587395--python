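"""Multi-class Gaussian Naive Bayes classification.

Each class is modeled by independent per-feature Gaussians; prediction
is the argmax over classes of log prior plus summed per-feature log
densities.  Ties break toward the earlier class in the model's ordered
label set.  Per-feature variances are floored at
``1e-9 x pooled variance of that feature`` (plus a tiny absolute floor)
so degenerate constant voxels cannot produce infinite densities.

Decoding accuracy is pooled — the ratio of correct predictions to total
predictions regardless of class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InsufficientDataError

VAR_FLOOR_REL = 1e-9
VAR_FLOOR_ABS = 1e-12


def variance_floor(X: np.ndarray) -> np.ndarray:
    """Per-feature variance floor from the pooled training variance."""
    pooled = X.var(axis=0)
    return VAR_FLOOR_REL * pooled + VAR_FLOOR_ABS


@dataclass
class GNBModel:
    """Fitted per-class Gaussian parameters."""

    class_labels: np.ndarray
    means: np.ndarray  # (classes, features)
    variances: np.ndarray  # (classes, features), floored
    log_priors: np.ndarray  # (classes,)

    @property
    def n_features(self) -> int:
        return self.means.shape[1]


def gnb_fit(X: np.ndarray, y, class_order=None) -> GNBModel:
    """Fit class means, (MLE) variances and empirical priors.

    ``class_order`` fixes the ordered label set; by default labels are
    sorted.  Every class must contribute at least 2 trials.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if class_order is None:
        classes = np.unique(y)
    else:
        classes = np.asarray(class_order)
    if len(classes) < 2:
        raise InsufficientDataError("need at least 2 classes")
    floor = variance_floor(X)
    means = np.empty((len(classes), X.shape[1]))
    variances = np.empty_like(means)
    priors = np.empty(len(classes))
    for k, c in enumerate(classes):
        rows = X[y == c]
        if rows.shape[0] < 2:
            raise InsufficientDataError(f"class {c!r} has fewer than 2 trials")
        means[k] = rows.mean(axis=0)
        variances[k] = np.maximum(rows.var(axis=0), floor)
        priors[k] = rows.shape[0] / X.shape[0]
    return GNBModel(
        class_labels=classes,
        means=means,
        variances=variances,
        log_priors=np.log(priors),
    )


def gnb_log_posterior(model: GNBModel, X: np.ndarray) -> np.ndarray:
    """Unnormalized log posterior, (trials, classes)."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.n_features:
        raise InsufficientDataError("feature count does not match model")
    # (t, 1, f) - (1, k, f)
    diff = X[:, None, :] - model.means[None, :, :]
    log_dens = -0.5 * (
        np.log(2.0 * np.pi * model.variances)[None, :, :]
        + diff**2 / model.variances[None, :, :]
    ).sum(axis=2)
    return log_dens + model.log_priors[None, :]


def gnb_predict(model: GNBModel, X: np.ndarray):
    """Predicted labels and log posteriors; ties go to the earlier class."""
    logp = gnb_log_posterior(model, X)
    return model.class_labels[np.argmax(logp, axis=1)], logp


def accuracy(predicted, actual) -> float:
    """Pooled proportion correct (not class-balanced)."""
    predicted = np.asarray(predicted)
    actual = np.asarray(actual)
    if predicted.size == 0 or predicted.shape != actual.shape:
        raise InsufficientDataError("empty or mismatched prediction arrays")
    return float(np.mean(predicted == actual))


def leave_one_run_out_folds(runs) -> list[tuple[np.ndarray, np.ndarray]]:
    """One (train_idx, test_idx) pair per distinct run.

    Every trial is tested exactly once.  Fold accuracies are averaged
    with equal weights downstream (folds are equal-sized by design).
    """
    runs = np.asarray(runs)
    unique = np.unique(runs)
    if len(unique) < 2:
        raise InsufficientDataError(
            "only one run among selected trials; use the single-split (cross-modal) path"
        )
    folds = []
    idx = np.arange(len(runs))
    for r in unique:
        test = idx[runs == r]
        train = idx[runs != r]
        folds.append((train, test))
    return folds
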