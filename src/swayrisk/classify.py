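"""Splitting, normalization, imbalance-aware classification, and metrics.

Fall-risk labels are minority classes (roughly a quarter to a third of
a community cohort), so the primary classifiers are resampling
ensembles that counter majority-class bias:

Easy Ensemble
    Nine AdaBoost learners, each boosted over Complement Naive Bayes
    and trained on an independent balanced undersample of the majority
    class; class scores are averaged.
Balanced Bagging
    Nine Complement Naive Bayes learners, each fitted on a balanced
    bootstrap resample, with feature subsets drawn with replacement.
Complement Naive Bayes
    The plain imbalance-robust NB variant (additive smoothing 1.0).

Traditional comparators (RBF SVM, decision tree, MLP) are provided for
the recall/specificity contrast.  Both ensembles are scikit-learn
compatible estimators implemented here.

Feature tables are split 50/20/30 (train/validation/test), stratified
on the active label with largest-remainder rounding, and min-max
normalized to [0, 1] with statistics fitted on the training split only
(out-of-range values in other splits are clipped).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import AdaBoostClassifier
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve
from sklearn.naive_bayes import ComplementNB
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

from .features import PERSONAL_COLUMNS, posturographic_columns

CLASSIFIER_NAMES = (
    "easy_ensemble",
    "balanced_bagging",
    "complement_nb",
    "svm",
    "decision_tree",
    "mlp",
)

SELECTION_NAMES = ("none", "SMA", "HHO", "ABC", "MI", "F-value")


# --------------------------------------------------------------------------
# splitting


@dataclass(frozen=True)
class SplitSpec:
    fractions: tuple[float, float, float] = (0.50, 0.20, 0.30)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if any(f <= 0 for f in self.fractions):
            raise ValueError("split fractions must be positive")


def _largest_remainder(n: int, fractions: Sequence[float]) -> list[int]:
    """Integer split sizes; ties in remainders favour the later split."""
    ideal = [n * f for f in fractions]
    sizes = [int(np.floor(x)) for x in ideal]
    leftover = n - sum(sizes)
    order = sorted(
        range(len(fractions)),
        key=lambda i: (ideal[i] - sizes[i], i),
        reverse=True,
    )
    for i in order[:leftover]:
        sizes[i] += 1
    return sizes


def split_dataset(
    y: np.ndarray, spec: SplitSpec = SplitSpec()
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stratified train/validation/test indices under the split spec.

    Within each class, members are shuffled (seeded) and allotted to the
    three splits by largest-remainder rounding of the class size.
    """
    y = np.asarray(y, int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if counts.min() < 3:
        raise ValueError("every class needs at least 3 members to stratify")
    rng = np.random.default_rng(spec.seed)
    parts: list[list[np.ndarray]] = [[], [], []]
    for c in classes:
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        sizes = _largest_remainder(len(idx), spec.fractions)
        start = 0
        for s, size in enumerate(sizes):
            parts[s].append(idx[start : start + size])
            start += size
    return tuple(np.sort(np.concatenate(p)) for p in parts)  # type: ignore[return-value]


def fit_minmax(X_train: np.ndarray | pd.DataFrame) -> MinMaxScaler:
    """Min-max scaler fitted on the training split only; transforms clip to [0, 1].

    Constant columns map to 0 for every value.
    """
    scaler = MinMaxScaler(clip=True)
    scaler.fit(np.asarray(X_train, float))
    return scaler


# --------------------------------------------------------------------------
# imbalance-aware ensembles


def _balanced_undersample(
    y: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Indices keeping all minority samples and an equal-size random
    subset of the majority class."""
    classes, counts = np.unique(y, return_counts=True)
    minority = classes[np.argmin(counts)]
    n_min = counts.min()
    keep = [np.flatnonzero(y == minority)]
    for c in classes:
        if c == minority:
            continue
        idx = np.flatnonzero(y == c)
        keep.append(rng.choice(idx, size=n_min, replace=False))
    return np.concatenate(keep)


class EasyEnsembleClassifier(ClassifierMixin, BaseEstimator):
    """Ensemble of AdaBoost(Complement NB) learners on balanced undersamples.

    If boosting cannot be fit on a resample (the base learner scores
    worse than random on it, which Complement NB can on proportion-flat
    data), that member falls back to the plain base classifier.
    """

    def __init__(
        self,
        n_estimators: int = 9,
        n_boost: int = 10,
        alpha: float = 1.0,
        random_state: int = 0,
    ):
        self.n_estimators = n_estimators
        self.n_boost = n_boost
        self.alpha = alpha
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y, int)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need two classes")
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        rng = np.random.default_rng(self.random_state)
        self.estimators_ = []
        for k in range(self.n_estimators):
            idx = _balanced_undersample(y, rng)
            booster = AdaBoostClassifier(
                estimator=ComplementNB(alpha=self.alpha),
                n_estimators=self.n_boost,
                random_state=int(rng.integers(2**31)),
            )
            try:
                booster.fit(X[idx], y[idx])
                self.estimators_.append(booster)
            except ValueError:
                member = ComplementNB(alpha=self.alpha)
                member.fit(X[idx], y[idx])
                self.estimators_.append(member)
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "estimators_")
        X = np.asarray(X, float)
        probas = [est.predict_proba(X) for est in self.estimators_]
        return np.mean(probas, axis=0)

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[(proba[:, 1] >= 0.5).astype(int)]


class BalancedBaggingClassifier(ClassifierMixin, BaseEstimator):
    """Bagged Complement NB on balanced bootstrap resamples.

    Each of the ``n_estimators`` learners sees a balanced undersample of
    the training data, bootstrapped with replacement, and (optionally) a
    feature subset drawn with replacement.
    """

    def __init__(
        self,
        n_estimators: int = 9,
        alpha: float = 1.0,
        bootstrap: bool = True,
        bootstrap_features: bool = True,
        random_state: int = 0,
    ):
        self.n_estimators = n_estimators
        self.alpha = alpha
        self.bootstrap = bootstrap
        self.bootstrap_features = bootstrap_features
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y, int)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need two classes")
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        rng = np.random.default_rng(self.random_state)
        n_features = X.shape[1]
        self.estimators_ = []
        self.estimator_features_ = []
        for k in range(self.n_estimators):
            idx = _balanced_undersample(y, rng)
            if self.bootstrap:
                idx = rng.choice(idx, size=len(idx), replace=True)
                # a bootstrap can lose a class on tiny data; redraw a few times
                for _ in range(10):
                    if len(np.unique(y[idx])) == 2:
                        break
                    idx = rng.choice(
                        _balanced_undersample(y, rng), size=len(idx), replace=True
                    )
            feats = (
                rng.choice(n_features, size=n_features, replace=True)
                if self.bootstrap_features
                else np.arange(n_features)
            )
            est = ComplementNB(alpha=self.alpha)
            est.fit(X[np.ix_(idx, feats)], y[idx])
            self.estimators_.append(est)
            self.estimator_features_.append(feats)
        self.n_features_in_ = n_features
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "estimators_")
        X = np.asarray(X, float)
        probas = [
            est.predict_proba(X[:, feats])
            for est, feats in zip(self.estimators_, self.estimator_features_)
        ]
        return np.mean(probas, axis=0)

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[(proba[:, 1] >= 0.5).astype(int)]


@dataclass(frozen=True)
class ClassifierSpec:
    """Named classifier with the hyperparameters used throughout."""

    name: str = "complement_nb"
    n_estimators: int = 9
    alpha: float = 1.0
    bootstrap_features: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in CLASSIFIER_NAMES:
            raise ValueError(f"unknown classifier {self.name!r}")
        if self.n_estimators < 1:
            raise ValueError("ensemble sizes must be >= 1")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")


def make_classifier(spec: ClassifierSpec):
    """Instantiate the estimator for a classifier spec."""
    if spec.name == "easy_ensemble":
        return EasyEnsembleClassifier(
            n_estimators=spec.n_estimators, alpha=spec.alpha, random_state=spec.seed
        )
    if spec.name == "balanced_bagging":
        return BalancedBaggingClassifier(
            n_estimators=spec.n_estimators,
            alpha=spec.alpha,
            bootstrap_features=spec.bootstrap_features,
            random_state=spec.seed,
        )
    if spec.name == "complement_nb":
        return ComplementNB(alpha=spec.alpha)
    # traditional comparators, common defaults
    if spec.name == "svm":
        return SVC(kernel="rbf", C=1.0, probability=True, random_state=spec.seed)
    if spec.name == "decision_tree":
        return DecisionTreeClassifier(random_state=spec.seed)
    if spec.name == "mlp":
        return MLPClassifier(
            hidden_layer_sizes=(100,), max_iter=500, random_state=spec.seed
        )
    raise ValueError(spec.name)


def fit_classifier(spec: ClassifierSpec, X, y):
    """Fit the named classifier; every returned model exposes predict_proba."""
    y = np.asarray(y, int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    model = make_classifier(spec)
    model.fit(np.asarray(X, float), y)
    return model


# --------------------------------------------------------------------------
# metrics


@dataclass
class EvalMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    gm: float
    auc: float
    roc_points: list[tuple[float, float]] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "gm": self.gm,
            "auc": self.auc,
        }


def metrics_from_counts(
    tp: int, fp: int, tn: int, fn: int, auc: float = float("nan"),
    roc_points: list | None = None,
) -> EvalMetrics:
    """Derive accuracy/sensitivity/specificity/GM from a confusion matrix."""
    total = tp + fp + tn + fn
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    return EvalMetrics(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        accuracy=(tp + tn) / total if total else 0.0,
        sensitivity=sens,
        specificity=spec,
        gm=float(np.sqrt(sens * spec)),
        auc=auc,
        roc_points=roc_points or [],
    )


def evaluate(model, X, y) -> EvalMetrics:
    """Confusion counts at the 0.5 score threshold plus ROC AUC."""
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined: evaluation labels contain a single class")
    scores = model.predict_proba(X)[:, 1]
    y_hat = (scores >= 0.5).astype(int)
    tp = int(np.sum((y == 1) & (y_hat == 1)))
    fp = int(np.sum((y == 0) & (y_hat == 1)))
    tn = int(np.sum((y == 0) & (y_hat == 0)))
    fn = int(np.sum((y == 1) & (y_hat == 0)))
    fpr, tpr, _ = roc_curve(y, scores)
    return metrics_from_counts(
        tp, fp, tn, fn, auc=float(_auc(fpr, tpr)),
        roc_points=list(zip(fpr.tolist(), tpr.tolist())),
    )


# --------------------------------------------------------------------------
# end-to-end grid


def run_grid(
    table: pd.DataFrame,
    criteria: Sequence[str] = ("criteria_I", "criteria_II"),
    selections: Sequence[str] = ("none", "SMA", "HHO", "ABC"),
    classifiers: Sequence[str] = ("balanced_bagging", "complement_nb", "easy_ensemble"),
    split: SplitSpec = SplitSpec(),
    population: int = 100,
    epochs: int = 100,
    filter_k: int = 30,
    seed: int = 0,
    include_personal: bool = True,
) -> pd.DataFrame:
    """Evaluate every (criterion, selection, classifier) combination.

    For each criterion the table is split 50/20/30 stratified on that
    label; min-max normalization and feature selection are fitted on the
    training split only; metrics are reported on the test split.  Returns
    one row per combination with confusion counts, metrics, the selected
    feature count, and ROC points serialized as JSON.
    """
    from .selection import select_features

    posturo = [c for c in posturographic_columns() if c in table.columns]
    personal = [c for c in PERSONAL_COLUMNS if c in table.columns]
    rows = []
    for criterion in criteria:
        if criterion not in table.columns:
            raise ValueError(f"criterion column {criterion!r} missing from table")
        y = table[criterion].to_numpy(int)
        train_idx, val_idx, test_idx = split_dataset(
            y, SplitSpec(split.fractions, seed=seed)
        )

        scaler_p = fit_minmax(table.iloc[train_idx][posturo])
        Xp = {
            "train": scaler_p.transform(table.iloc[train_idx][posturo]),
            "test": scaler_p.transform(table.iloc[test_idx][posturo]),
        }
        if include_personal and personal:
            scaler_m = fit_minmax(table.iloc[train_idx][personal])
            Xm = {
                "train": scaler_m.transform(table.iloc[train_idx][personal]),
                "test": scaler_m.transform(table.iloc[test_idx][personal]),
            }
        else:
            Xm = None
        y_train, y_test = y[train_idx], y[test_idx]

        for selection in selections:
            if selection == "none":
                mask = np.ones(len(posturo), bool)
            else:
                res = select_features(
                    pd.DataFrame(Xp["train"], columns=posturo),
                    y_train,
                    algorithm=selection,
                    population=population,
                    epochs=epochs,
                    k=filter_k,
                    random_state=seed,
                    X_extra=None if Xm is None else Xm["train"],
                )
                mask = res.mask
            for clf_name in classifiers:
                X_train = Xp["train"][:, mask]
                X_test = Xp["test"][:, mask]
                if Xm is not None:
                    X_train = np.hstack([X_train, Xm["train"]])
                    X_test = np.hstack([X_test, Xm["test"]])
                model = fit_classifier(
                    ClassifierSpec(name=clf_name, seed=seed), X_train, y_train
                )
                m = evaluate(model, X_test, y_test)
                rows.append(
                    {
                        "criterion": criterion,
                        "selection": selection,
                        "classifier": clf_name,
                        "accuracy": m.accuracy,
                        "recall": m.sensitivity,
                        "specificity": m.specificity,
                        "gm": m.gm,
                        "auc": m.auc,
                        "tp": m.tp,
                        "fp": m.fp,
                        "tn": m.tn,
                        "fn": m.fn,
                        "n_selected": int(mask.sum()),
                        "seed": seed,
                        "roc_points": json.dumps(m.roc_points),
                    }
                )
    return pd.DataFrame(rows)
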