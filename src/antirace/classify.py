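"""Classification harness for staging subjects from behavioral or model
features.

Binary discrimination uses L2-regularized logistic regression.  The outer
loop is a repeated stratified shuffle split (default 200 repeats, 20% held
out); within each training split the regularization strength is selected by
10-fold stratified cross-validation over a fixed logarithmic grid.  Test
performance is summarized as the mean and SD of the held-out AUC, which is
insensitive to the unequal class sizes typical of clinical cohorts.
Multiclass staging uses a random forest under the same outer protocol,
reporting held-out accuracy and the pooled confusion matrix.

Features are z-scored with training-split statistics only, so no test
information leaks into the scaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegressionCV
from sklearn.metrics import confusion_matrix, roc_auc_score
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

#: 13 logarithmically spaced inverse regularization strengths.
C_GRID = np.logspace(-3, 3, 13)

MIN_PER_CLASS = 20


@dataclass
class FeatureSet:
    """Named per-subject feature matrix with aligned labels."""

    name: str
    X: pd.DataFrame
    y: np.ndarray
    subject_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        if len(self.X) != len(self.y):
            raise ValueError("features and labels must be aligned")
        if self.X.isna().any().any():
            raise ValueError(f"feature set {self.name!r} contains missing values")


@dataclass
class ClassifierReport:
    """Held-out performance over the outer repeats."""

    name: str
    scores: np.ndarray  # per-repeat AUC (binary) or accuracy (multiclass)
    n_repeats: int
    seed: int
    metric: str = "auc"
    confusion: np.ndarray | None = None  # pooled true x predicted counts
    classes: np.ndarray | None = None

    @property
    def mean(self) -> float:
        return float(np.mean(self.scores))

    @property
    def sd(self) -> float:
        return float(np.std(self.scores, ddof=1))


def _check_classes(y: np.ndarray, name: str) -> None:
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < MIN_PER_CLASS:
        warnings.warn(
            f"{name}: smallest class has {counts.min()} subjects "
            f"(< {MIN_PER_CLASS}); estimates will be unstable",
            stacklevel=3,
        )


def _binary_model(seed: int, n_inner_folds: int) -> Pipeline:
    return Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "logit",
                LogisticRegressionCV(
                    Cs=C_GRID,
                    cv=StratifiedKFold(n_inner_folds, shuffle=True, random_state=seed),
                    penalty="l2",
                    max_iter=5000,
                ),
            ),
        ]
    )


def _outer_splits(y: np.ndarray, n_repeats: int, test_size: float, seed: int):
    splitter = StratifiedShuffleSplit(
        n_splits=n_repeats, test_size=test_size, random_state=seed
    )
    return list(splitter.split(np.zeros_like(y, dtype=float).reshape(-1, 1), y))


def evaluate_binary(
    features: FeatureSet,
    n_repeats: int = 200,
    test_size: float = 0.2,
    n_inner_folds: int = 10,
    seed: int = 0,
    splits=None,
) -> ClassifierReport:
    """Held-out AUC of L2 logistic regression over repeated shuffle splits."""
    X = features.X.to_numpy(dtype=float)
    y = np.asarray(features.y)
    if len(np.unique(y)) != 2:
        raise ValueError("evaluate_binary needs exactly two classes")
    _check_classes(y, features.name)
    if splits is None:
        splits = _outer_splits(y, n_repeats, test_size, seed)
    aucs = np.empty(len(splits))
    for i, (tr, te) in enumerate(splits):
        model = _binary_model(seed + i, n_inner_folds)
        model.fit(X[tr], y[tr])
        score = model.predict_proba(X[te])[:, list(model.classes_).index(np.unique(y)[1])]
        aucs[i] = roc_auc_score(y[te] == np.unique(y)[1], score)
    return ClassifierReport(
        name=features.name, scores=aucs, n_repeats=len(splits), seed=seed, metric="auc"
    )


def evaluate_multiclass(
    features: FeatureSet,
    n_repeats: int = 200,
    test_size: float = 0.2,
    n_trees: int = 500,
    seed: int = 0,
    splits=None,
) -> ClassifierReport:
    """Held-out accuracy + pooled confusion matrix of a random forest."""
    X = features.X.to_numpy(dtype=float)
    y = np.asarray(features.y)
    classes = np.unique(y)
    if len(classes) < 3:
        raise ValueError("evaluate_multiclass needs at least three classes")
    _check_classes(y, features.name)
    if splits is None:
        splits = _outer_splits(y, n_repeats, test_size, seed)
    accs = np.empty(len(splits))
    pooled = np.zeros((len(classes), len(classes)), dtype=int)
    for i, (tr, te) in enumerate(splits):
        clf = RandomForestClassifier(
            n_estimators=n_trees, max_features="sqrt", random_state=seed + i
        )
        clf.fit(X[tr], y[tr])
        pred = clf.predict(X[te])
        accs[i] = float(np.mean(pred == y[te]))
        pooled += confusion_matrix(y[te], pred, labels=classes)
    return ClassifierReport(
        name=features.name,
        scores=accs,
        n_repeats=len(splits),
        seed=seed,
        metric="accuracy",
        confusion=pooled,
        classes=classes,
    )


@dataclass
class FeatureComparison:
    """Per-set AUC summary on shared splits plus paired tests vs the first set."""

    table: pd.DataFrame  # one row per feature set
    per_split: pd.DataFrame  # split x feature-set AUC matrix
    paired_pvalues: dict = field(default_factory=dict)  # (name_a, name_b) -> p


def compare_feature_sets(
    feature_sets,
    n_repeats: int = 200,
    test_size: float = 0.2,
    n_inner_folds: int = 10,
    seed: int = 0,
) -> FeatureComparison:
    """Evaluate several feature sets on identical outer splits.

    All sets must describe the same subjects in the same order (labels must
    match exactly).  AUC differences are assessed with a paired two-sided t
    test on the per-split AUCs.
    """
    feature_sets = list(feature_sets)
    y0 = np.asarray(feature_sets[0].y)
    for fs in feature_sets[1:]:
        if len(fs.y) != len(y0) or np.any(np.asarray(fs.y) != y0):
            raise ValueError("feature sets must share the same subjects and labels")
    splits = _outer_splits(y0, n_repeats, test_size, seed)
    per_split = {}
    for fs in feature_sets:
        rep = evaluate_binary(
            fs, n_inner_folds=n_inner_folds, seed=seed, splits=splits
        )
        per_split[fs.name] = rep.scores
    per_split = pd.DataFrame(per_split)
    table = pd.DataFrame(
        {
            "feature_set": per_split.columns,
            "mean_auc": per_split.mean().to_numpy(),
            "sd_auc": per_split.std(ddof=1).to_numpy(),
        }
    )
    pvals = {}
    names = list(per_split.columns)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            diff = per_split[a] - per_split[b]
            if np.allclose(diff, 0):
                pvals[(a, b)] = 1.0
            else:
                pvals[(a, b)] = float(sps.ttest_rel(per_split[a], per_split[b]).pvalue)
    return FeatureComparison(table=table, per_split=per_split, paired_pvalues=pvals)
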