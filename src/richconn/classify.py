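"""SVM classification of network features under leave-one-out cross-validation.

The pipeline mirrors common neuroimaging practice: a two-sample t-test filter
selects discriminative features, min-max scaling maps each feature to [0, 1],
and an RBF-kernel SVM is trained. All three steps are fit strictly inside
each LOOCV training fold and then applied to the held-out subject, so no
statistic ever sees the test subject (no information leakage). Performance is
summarized as accuracy, sensitivity, specificity, and the ROC/AUC computed
from continuous decision values; significance of the accuracy is assessed by
label-permutation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as skmetrics
from sklearn.svm import SVC

__all__ = [
    "FeatureMatrix",
    "ClassificationReport",
    "tfilter_features",
    "minmax_scale",
    "loocv_svm",
    "permutation_significance",
]


@dataclass
class FeatureMatrix:
    """Subjects x features with names and binary group labels."""

    X: np.ndarray
    feature_names: list[str]
    labels: np.ndarray  # string or int labels, exactly 2 classes for SVM

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (subjects x features)")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length mismatch")
        if self.X.shape[0] != len(self.labels):
            raise ValueError("labels length mismatch")
        if np.isnan(self.X).any():
            raise ValueError("feature matrix contains missing values")


@dataclass
class ClassificationReport:
    accuracy: float
    sensitivity: float
    specificity: float
    roc_points: np.ndarray  # (FPR, TPR) rows
    auc: float
    p_perm: float | None
    config: dict = field(default_factory=dict)
    predictions: np.ndarray | None = None
    decision_values: np.ndarray | None = None

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "p_perm": self.p_perm,
            "config": self.config,
        }


def tfilter_features(
    X: np.ndarray, labels: np.ndarray, alpha: float = 0.05
) -> np.ndarray:
    """Indices of features whose two-sample t-test p < alpha.

    Intended to run on a training fold only. If nothing survives, the single
    feature with the largest |t| is kept (with a warning) so the downstream
    classifier always has input.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("t-filter requires exactly 2 classes")
    a = X[labels == classes[0]]
    b = X[labels == classes[1]]
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=0)
    p = np.where(np.isfinite(p), p, 1.0)
    keep = np.flatnonzero(p < alpha)
    if keep.size == 0:
        warnings.warn("no feature passed the t-filter; keeping top-1 by |t|")
        t = np.where(np.isfinite(t), np.abs(t), 0.0)
        keep = np.array([int(np.argmax(t))])
    return keep


def minmax_scale(
    X_train: np.ndarray, X_apply: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None]:
    """Per-feature (x - min) / (max - min) using training-fold statistics.

    Constant features map to 0. Values outside the training range (in
    ``X_apply``) are clipped into [0, 1].
    """
    lo = X_train.min(axis=0)
    hi = X_train.max(axis=0)
    span = hi - lo
    const = span == 0
    if const.any():
        warnings.warn(f"{int(const.sum())} constant feature(s) scaled to 0")
    span = np.where(const, 1.0, span)
    scaled_train = np.clip((X_train - lo) / span, 0.0, 1.0)
    scaled_train[:, const] = 0.0
    if X_apply is None:
        return scaled_train, None
    scaled_apply = np.clip((np.atleast_2d(X_apply) - lo) / span, 0.0, 1.0)
    scaled_apply[:, const] = 0.0
    return scaled_train, scaled_apply


def _fit_predict_fold(
    X: np.ndarray,
    y01: np.ndarray,
    test: int,
    alpha: float,
    C: float,
    gamma: "float | str",
    use_tfilter: bool,
) -> tuple[int, float]:
    train = np.arange(len(y01)) != test
    Xtr, ytr = X[train], y01[train]
    if len(np.unique(ytr)) < 2:
        raise ValueError("a class is absent from a training fold")
    if use_tfilter:
        keep = tfilter_features(Xtr, ytr, alpha)
    else:
        keep = np.arange(X.shape[1])
    Xtr_s, Xte_s = minmax_scale(Xtr[:, keep], X[test : test + 1, keep])
    clf = SVC(kernel="rbf", C=C, gamma=gamma)
    clf.fit(Xtr_s, ytr)
    pred = int(clf.predict(Xte_s)[0])
    dec = float(clf.decision_function(Xte_s)[0])
    return pred, dec


def loocv_svm(
    fm: FeatureMatrix,
    C: float = 1.0,
    gamma: "float | str" = "scale",
    tfilter_alpha: float = 0.05,
    use_tfilter: bool = True,
    global_tfilter: bool = False,
    positive_class=None,
    compute_permutation_p: int = 0,
    seed: int = 0,
) -> ClassificationReport:
    """Leave-one-out SVM with per-fold t-filtering and min-max scaling.

    ``gamma='scale'`` (default) is 1/(n_features * Var(X)) on the selected,
    scaled features of each fold; the variance term keeps the RBF kernel
    informative when many near-collinear edge features are supplied, where a
    bare 1/n_features collapses it toward a constant. ``gamma='auto'``
    (1/n_features) is available for strict LibSVM-default behavior.
    Sensitivity is the recall of ``positive_class`` (default: the
    lexicographically larger label, e.g. the patient group); specificity the
    recall of the other class. AUC integrates the ROC built from the per-fold
    continuous decision values.

    ``global_tfilter=True`` fits the t-filter once on ALL subjects before
    cross-validation. This LEAKS the held-out subject into feature selection
    and optimistically biases performance (selection bias); it exists only
    for compatibility with historical single-pass workflows and must not be
    used for reported results.
    """
    classes = np.unique(fm.labels)
    if len(classes) != 2:
        raise ValueError("LOOCV SVM is pairwise; need exactly 2 classes")
    if positive_class is None:
        positive_class = classes[-1]
    y01 = (fm.labels == positive_class).astype(int)
    n = len(y01)
    if min(y01.sum(), n - y01.sum()) < 2:
        raise ValueError("need at least 2 subjects per class")
    X = fm.X
    if global_tfilter and use_tfilter:
        keep = tfilter_features(X, y01, tfilter_alpha)  # leaky by design
        X = X[:, keep]
        use_tfilter = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=UserWarning)
        preds = np.empty(n, dtype=int)
        decs = np.empty(n)
        for i in range(n):
            preds[i], decs[i] = _fit_predict_fold(
                X, y01, i, tfilter_alpha, C, gamma, use_tfilter
            )
    acc = float((preds == y01).mean())
    pos, neg = y01 == 1, y01 == 0
    sens = float((preds[pos] == 1).mean())
    spec = float((preds[neg] == 0).mean())
    fpr, tpr, _ = skmetrics.roc_curve(y01, decs)
    auc = float(skmetrics.auc(fpr, tpr))
    config = {
        "kernel": "rbf",
        "C": C,
        "gamma": gamma,
        "tfilter_alpha": tfilter_alpha if use_tfilter else None,
        "positive_class": str(positive_class),
        "seed": seed,
    }
    report = ClassificationReport(
        acc, sens, spec, np.column_stack([fpr, tpr]), auc, None, config, preds, decs
    )
    if compute_permutation_p:
        report.p_perm = permutation_significance(
            fm,
            observed_accuracy=acc,
            n_perm=compute_permutation_p,
            seed=seed,
            C=C,
            gamma=gamma,
            tfilter_alpha=tfilter_alpha,
            use_tfilter=use_tfilter,
            positive_class=positive_class,
        )
    return report


def permutation_significance(
    fm: FeatureMatrix,
    observed_accuracy: float | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    **svm_kwargs,
) -> float:
    """Label-permutation p-value for LOOCV accuracy.

    p = (1 + #{permuted accuracy >= observed}) / (1 + n_perm). The whole
    pipeline (filter, scale, fit) is re-run on every permuted label vector.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if observed_accuracy is None:
        observed_accuracy = loocv_svm(fm, **svm_kwargs).accuracy
    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(n_perm):
        perm = FeatureMatrix(
            fm.X, fm.feature_names, rng.permutation(fm.labels)
        )
        try:
            acc = loocv_svm(perm, **svm_kwargs).accuracy
        except ValueError:  # degenerate permutation (class absent in a fold)
            continue
        if acc >= observed_accuracy - 1e-12:
            b += 1
    return (1 + b) / (1 + n_perm)
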