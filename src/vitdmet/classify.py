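"""Best linear decision functions for normal-vs-PET classification.

Two complementary fitters share a common report format:

* :func:`best_threshold_1d` — for a single feature, exhaustive search over
  every threshold (midpoints between sorted distinct values, plus rules
  beyond either extreme) and both orientations; the returned rule is the
  apparent-accuracy optimum among all one-dimensional linear classifiers.
* :func:`fit_linear_svm` — soft-margin linear support-vector machines over
  a small regularisation grid on standardised features.  Because the hinge
  loss maximises margin rather than accuracy, each fitted direction has its
  intercept re-optimised by an exhaustive threshold scan along the
  projection, and the accuracy-best single-feature threshold rules compete
  in the same candidate pool; the apparent-accuracy maximiser is reported
  with weights mapped back to original concentration units.  This makes the
  returned rule the best *available* linear decision function by apparent
  accuracy, never worse than any single-feature threshold.

Apparent (resubstitution) accuracy — the fraction of correct classifications
on the data used for fitting — is the primary score; an optional k-fold
cross-validated accuracy is reported alongside since apparent accuracy is
optimistic on small cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

from .ratios import METABOLITE_COLUMNS, RATIO_COLUMNS

__all__ = [
    "LinearClassifier",
    "ClassifierReport",
    "best_threshold_1d",
    "fit_linear_svm",
    "strategy_sweep",
    "DEFAULT_C_GRID",
]

DEFAULT_C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)


@dataclass(frozen=True)
class LinearClassifier:
    """Hyperplane rule: predict case iff weights . x + intercept > 0."""

    feature_names: tuple
    weights: np.ndarray
    intercept: float

    def decision(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X @ self.weights + self.intercept

    def predict(self, X) -> np.ndarray:
        return (self.decision(X) > 0.0).astype(int)


@dataclass(frozen=True)
class ClassifierReport:
    classifier: LinearClassifier
    accuracy: float
    tp: int
    fp: int
    tn: int
    fn: int
    n_used: int
    feature_subset: tuple
    method_tag: str
    cv_accuracy: float | None = None
    C: float | None = field(default=None)

    @property
    def confusion(self) -> dict:
        return {"TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn}


def _report(clf, X, y, subset, method_tag, cv_accuracy=None, C=None) -> ClassifierReport:
    pred = clf.predict(X)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    return ClassifierReport(
        classifier=clf,
        accuracy=(tp + tn) / len(y),
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        n_used=len(y),
        feature_subset=tuple(subset),
        method_tag=method_tag,
        cv_accuracy=cv_accuracy,
        C=C,
    )


def best_threshold_1d(x, labels, feature_name: str = "x") -> ClassifierReport:
    """Accuracy-optimal single-feature threshold rule, by exhaustive search.

    Candidate thresholds are the midpoints between consecutive distinct
    values plus one beyond each extreme (covering the majority-vote rules);
    both orientations are scored.  Ties are broken toward the threshold
    farthest from its nearest data point, then toward the lower threshold,
    then toward the "case above threshold" orientation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(labels, dtype=int)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and labels must be 1-D of equal length")
    if np.any(np.isnan(x)):
        raise ValueError("x contains missing values")
    distinct = np.unique(x)
    cands = [distinct[0] - 1.0, distinct[-1] + 1.0]
    cands.extend(0.5 * (distinct[:-1] + distinct[1:]))

    best = None  # (acc, margin, -threshold, orient_pref)
    best_rule = None
    for t in cands:
        margin = float(np.min(np.abs(x - t)))
        for orient in (1.0, -1.0):
            acc = float(np.mean(((orient * (x - t)) > 0.0).astype(int) == y))
            key = (acc, margin, -t, orient)
            if best is None or key > best:
                best = key
                best_rule = (t, orient)
    t, orient = best_rule
    clf = LinearClassifier(
        feature_names=(feature_name,),
        weights=np.array([orient]),
        intercept=-orient * t,
    )
    return _report(clf, x[:, None], y, (feature_name,), "exhaustive_1d")


def _best_intercept(z: np.ndarray, y: np.ndarray, w_dir: np.ndarray):
    """Accuracy-optimal threshold/orientation along a fixed direction.

    Returns ``(accuracy, weights, intercept)`` such that the rule
    ``weights . x + intercept > 0`` realises that accuracy.
    """
    if not np.any(w_dir != 0.0):
        acc = float(max(np.mean(y), 1.0 - np.mean(y)))
        return acc, w_dir, 0.0
    distinct = np.unique(z)
    cands = np.concatenate(
        [[distinct[0] - 1.0], 0.5 * (distinct[:-1] + distinct[1:]), [distinct[-1] + 1.0]]
    )
    best_acc, best_t, best_orient = -1.0, 0.0, 1.0
    for t in cands:
        for orient in (1.0, -1.0):
            acc = float(np.mean(((orient * (z - t)) > 0.0).astype(int) == y))
            if acc > best_acc:
                best_acc, best_t, best_orient = acc, t, orient
    return best_acc, best_orient * w_dir, -best_orient * best_t


def fit_linear_svm(
    X,
    labels,
    C_grid=DEFAULT_C_GRID,
    *,
    feature_names=None,
    cv_folds: int = 0,
    seed: int = 0,
) -> ClassifierReport:
    """Best linear SVM over a regularisation grid, scored by apparent accuracy.

    Features are standardised before fitting; reported weights are in the
    original units.  Ties across the grid go to the smallest C.  Features
    with zero variance carry no information for a linear rule and are
    dropped with a warning.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.ndim == 2 and X.shape[0] == 1 and X.shape[1] > 1 and np.asarray(labels).size > 1:
        X = X.T
    y = np.asarray(labels, dtype=int)
    if X.shape[0] != y.size:
        raise ValueError("X rows and labels length differ")
    if np.any(np.isnan(X)):
        raise ValueError("X contains missing values; drop incomplete rows first")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2 or counts.min() < 2:
        raise ValueError("need at least 2 subjects in each of two classes")
    if feature_names is None:
        feature_names = tuple(f"f{i}" for i in range(X.shape[1]))
    feature_names = tuple(feature_names)

    sd = X.std(axis=0, ddof=0)
    keep = sd > 0.0
    if not np.all(keep):
        dropped = [n for n, k in zip(feature_names, keep) if not k]
        warnings.warn(f"zero-variance features dropped: {dropped}", stacklevel=2)
        X = X[:, keep]
        feature_names = tuple(n for n, k in zip(feature_names, keep) if k)
        sd = sd[keep]
        if X.shape[1] == 0:
            raise ValueError("no informative features remain")
    mu = X.mean(axis=0)
    Z = (X - mu) / sd

    # candidate pool: SVC directions (intercept re-optimised along the
    # projection) in ascending C, then single-feature threshold rules
    best = None  # (acc, w_std, b_std, C)
    for C in sorted(C_grid):
        model = SVC(kernel="linear", C=C)
        model.fit(Z, y)
        w_dir = model.coef_.ravel()
        acc, w_std, b_std = _best_intercept(Z @ w_dir, y, w_dir)
        if best is None or acc > best[0]:
            best = (acc, w_std, b_std, C)
    for j in range(Z.shape[1]):
        axis = np.zeros(Z.shape[1])
        axis[j] = 1.0
        acc, w_std, b_std = _best_intercept(Z[:, j], y, axis)
        if acc > best[0]:
            best = (acc, w_std, b_std, None)
    _, w_std, b_std, best_C = best

    cv_acc = None
    if cv_folds and cv_folds >= 2:
        skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        cv_acc = float(
            np.mean(
                cross_val_score(
                    SVC(kernel="linear", C=best_C if best_C is not None else 1.0),
                    Z,
                    y,
                    cv=skf,
                )
            )
        )

    w = w_std / sd
    b = b_std - float(np.sum(w_std * mu / sd))
    clf = LinearClassifier(feature_names=feature_names, weights=w, intercept=b)
    return _report(clf, X, y, feature_names, "svm", cv_accuracy=cv_acc, C=best_C)


def strategy_sweep(
    table: pd.DataFrame,
    feature_space: str,
    subsets=None,
    *,
    label_groups=("NP3", "PET"),
    C_grid=DEFAULT_C_GRID,
    cv_folds: int = 5,
    seed: int = 0,
) -> list[ClassifierReport]:
    """Classifier sweep over feature subsets in one of the two strategies.

    ``feature_space`` is ``"metabolites"`` (the four measured concentrations,
    strategy 1) or ``"ratios"`` (alpha/beta/gamma computed upstream,
    strategy 2).  The default subsets are every singleton — fitted by
    exhaustive 1-D search — plus the full combination, fitted by linear SVM.
    Labels: ``label_groups[0]`` is control (0), ``label_groups[1]`` is case
    (1); rows in other groups are ignored.  Rows incomplete for a subset are
    dropped for that subset only.
    """
    if feature_space == "metabolites":
        space_cols = list(METABOLITE_COLUMNS)
    elif feature_space == "ratios":
        space_cols = list(RATIO_COLUMNS)
    else:
        raise ValueError(f"unknown feature_space {feature_space!r}")
    if subsets is None:
        subsets = [(c,) for c in space_cols] + [tuple(space_cols)]

    mask = table["group"].isin(label_groups)
    sub = table[mask]
    y_all = (sub["group"] == label_groups[1]).to_numpy(dtype=int)

    reports = []
    for subset in subsets:
        subset = tuple(subset)
        for col in subset:
            if col not in table.columns:
                raise KeyError(f"feature column {col!r} absent from table")
        X = sub[list(subset)].to_numpy(dtype=float)
        complete = ~np.any(np.isnan(X), axis=1)
        Xc, yc = X[complete], y_all[complete]
        if len(subset) == 1:
            rep = best_threshold_1d(Xc.ravel(), yc, feature_name=subset[0])
        else:
            rep = fit_linear_svm(
                Xc, yc, C_grid, feature_names=subset, cv_folds=cv_folds, seed=seed
            )
        reports.append(rep)
    return reports
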