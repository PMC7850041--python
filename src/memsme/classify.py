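"""Penalized logistic classification of subsequent recall.

Features are session-normalized log Morlet power over the full item
encoding epoch (0-1366 ms) at eight frequencies log-spaced between 3
and 180 Hz, one column per frequency x channel.  The model is an
L2-penalized logistic regression with inverse-regularization C =
2.4e-4 and minority-class observations weighted in inverse proportion
to class frequency.  Performance is the AUC of pooled out-of-fold
predicted probabilities under leave-one-session-out (multi-session
subjects) or leave-one-list-out (single-session subjects)
cross-validation, with significance from a label-permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.utils.validation import check_is_fitted, check_X_y

from .datatypes import EpochTensor, SchemaError
from .spectral import encoding_power_features, morlet_power

__all__ = [
    "CLASSIFIER_FREQS",
    "CLASSIFIER_WINDOW",
    "DEFAULT_C",
    "RecallClassifier",
    "ClassifierResult",
    "build_feature_matrix",
    "cross_validated_auc",
    "auc_permutation_pvalue",
]

#: 8 wavelet frequencies log-spaced on [3, 180] Hz.
CLASSIFIER_FREQS = np.logspace(np.log10(3.0), np.log10(180.0), 8)
CLASSIFIER_WINDOW = (0.0, 1.366)
DEFAULT_C = 2.4e-4


class RecallClassifier(BaseEstimator, ClassifierMixin):
    """L2 logistic regression for recalled/not-recalled labels.

    Parameters
    ----------
    C : float
        Inverse regularization strength (smaller = stronger penalty).
    class_weight : 'balanced' or None
        'balanced' weights each observation by ``n_total / (2 * n_class)``.
    zscore_features : bool
        Kept for the feature pipeline; fitting itself assumes features
        are already standardized.
    """

    def __init__(self, C: float = DEFAULT_C, class_weight: str | None = "balanced",
                 max_iter: int = 1000):
        self.C = C
        self.class_weight = class_weight
        self.max_iter = max_iter

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        if len(np.unique(y)) < 2:
            raise ValueError("both recall classes must be present for fitting")
        self.model_ = LogisticRegression(
            C=self.C,
            class_weight=self.class_weight,
            solver="liblinear",
            max_iter=self.max_iter,
        )
        self.model_.fit(X, y)
        self.coef_ = self.model_.coef_
        self.intercept_ = self.model_.intercept_
        self.classes_ = self.model_.classes_
        return self

    def decision_function(self, X):
        check_is_fitted(self, "model_")
        return self.model_.decision_function(X)

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict_proba(X)

    def predict(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict(X)


@dataclass
class ClassifierResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    fold_scheme: str
    probs: np.ndarray = field(repr=False, default=None)
    C: float = DEFAULT_C
    perm_p: float | None = None


def build_feature_matrix(
    epochs: EpochTensor,
    electrodes: pd.DataFrame,
    events: pd.DataFrame,
    freqs: np.ndarray = CLASSIFIER_FREQS,
    window: tuple = CLASSIFIER_WINDOW,
    zscore: bool = True,
) -> np.ndarray:
    """Items x (freqs x channels) spectral feature matrix.

    Log Morlet power averaged over the encoding window, z-scored over
    items within session per feature (disable with ``zscore=False`` to
    keep raw windowed log power).
    """
    if len(events) != epochs.n_items:
        raise SchemaError("events/epochs item mismatch")
    missing = set(electrodes.loc[~electrodes["excluded"], "channel"]) - set(epochs.channels)
    if missing:
        raise SchemaError(f"channels missing from epochs: {sorted(missing)}")
    power, times = morlet_power(epochs, np.asarray(freqs, float))
    if zscore:
        feats = encoding_power_features(
            power, times, events["session"].to_numpy(), window=window
        )
    else:
        dt = np.median(np.diff(times))
        mask = (times >= window[0] - dt / 2) & (times <= window[1] + dt / 2)
        feats = np.log(np.clip(power[..., mask], 1e-300, None)).mean(axis=-1)
    return feats.reshape(feats.shape[0], -1)


def _fold_labels(sessions: np.ndarray, lists: np.ndarray) -> tuple[np.ndarray, str]:
    sessions = np.asarray(sessions)
    lists = np.asarray(lists)
    if len(np.unique(sessions)) >= 2:
        return sessions, "leave-one-session-out"
    combo = np.array([f"{s}/{l}" for s, l in zip(sessions, lists)])
    if len(np.unique(combo)) < 2:
        raise SchemaError("need >= 2 sessions or >= 2 lists for cross-validation")
    return combo, "leave-one-list-out"


def cross_validated_auc(
    X: np.ndarray,
    y: np.ndarray,
    sessions: np.ndarray,
    lists: np.ndarray,
    C: float = DEFAULT_C,
) -> ClassifierResult:
    """Leave-one-session-out (or -list-out) cross-validated AUC.

    Out-of-fold predicted probabilities are pooled across folds; the
    ROC is a threshold sweep over the pooled probabilities and the AUC
    its trapezoidal area.  Folds whose training data contain a single
    class are skipped (their items drop from the pooled evaluation).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    folds, scheme = _fold_labels(sessions, lists)
    probs = np.full(len(y), np.nan)
    for f in np.unique(folds):
        test = folds == f
        train = ~test
        if len(np.unique(y[train])) < 2:
            continue
        clf = RecallClassifier(C=C).fit(X[train], y[train])
        probs[test] = clf.predict_proba(X[test])[:, list(clf.classes_).index(1)]
    ok = np.isfinite(probs)
    if len(np.unique(y[ok])) < 2:
        raise SchemaError("pooled out-of-fold predictions cover a single class")
    fpr, tpr, _ = roc_curve(y[ok], probs[ok])
    return ClassifierResult(
        auc=float(_trapezoid_auc(fpr, tpr)),
        fpr=fpr,
        tpr=tpr,
        fold_scheme=scheme,
        probs=probs,
        C=C,
    )


def auc_permutation_pvalue(
    X: np.ndarray,
    y: np.ndarray,
    sessions: np.ndarray,
    lists: np.ndarray,
    n_perm: int = 1000,
    rng_seed: int = 0,
    C: float = DEFAULT_C,
) -> tuple[float, np.ndarray]:
    """Permutation p-value for the cross-validated AUC.

    Recalled labels are randomly permuted across items (fold structure
    fixed) and the full cross-validation repeated per shuffle;
    ``p = (1 + #{null AUC >= observed}) / (n_perm + 1)``.
    """
    import warnings

    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a coarse permutation p-value")
    observed = cross_validated_auc(X, y, sessions, lists, C=C).auc
    rng = np.random.default_rng(rng_seed)
    null = np.empty(n_perm)
    y = np.asarray(y, dtype=int)
    for j in range(n_perm):
        y_perm = rng.permutation(y)
        try:
            null[j] = cross_validated_auc(X, y_perm, sessions, lists, C=C).auc
        except SchemaError:
            null[j] = np.nan
    null = null[np.isfinite(null)]
    p = (1.0 + np.sum(null >= observed)) / (len(null) + 1.0)
    return float(p), null
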