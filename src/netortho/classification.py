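"""Classifier training, cross-validated AUC, and average-rank comparison.

Five methods are compared: AdaBoosted decision trees, Gaussian Naive Bayes,
an SVM with calibrated probabilities, logistic regression, and an ensemble
whose predicted probability is the unweighted mean of the other four.
Performance is the area under the ROC curve (reported in percent) of pooled
out-of-fold scores from stratified 10-fold cross-validation; methods are
compared across datasets by their average rank (rank 1 = best AUC within a
dataset, ties averaged).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import AdaBoostClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import FEATURE_COLUMNS, LABEL_POSITIVE

__all__ = [
    "ALGORITHMS",
    "EvaluationReport",
    "build_model",
    "train_classifier",
    "auc",
    "cross_validate",
    "average_rank",
    "evaluate_methods",
    "save_model",
    "load_model",
]

ALGORITHMS = ("boosted_tree", "naive_bayes", "svm", "logistic", "ensemble")

# Hyperparameters of the member classifiers (recorded in model metadata).
BOOST_DEPTH = 3
BOOST_ROUNDS = 50


class MeanProbabilityEnsemble(BaseEstimator, ClassifierMixin):
    """Ensemble whose positive-class probability is the unweighted mean of its
    member classifiers' probabilities."""

    def __init__(self, members=None, seed: int = 0):
        self.members = members
        self.seed = seed

    def fit(self, X, y):
        members = self.members or [
            _bare_classifier(name, self.seed)
            for name in ("boosted_tree", "naive_bayes", "svm", "logistic")
        ]
        self.members_ = [clone(m).fit(X, y) for m in members]
        self.classes_ = self.members_[0].classes_
        return self

    def predict_proba(self, X):
        probs = [m.predict_proba(X) for m in self.members_]
        return np.mean(probs, axis=0)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def _bare_classifier(algorithm: str, seed: int):
    if algorithm == "boosted_tree":
        return AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=BOOST_DEPTH, random_state=seed),
            n_estimators=BOOST_ROUNDS,
            random_state=seed,
        )
    if algorithm == "naive_bayes":
        return GaussianNB()
    if algorithm == "svm":
        # Platt-sigmoid calibration on internal 3-fold CV so the ensemble can
        # average calibrated probabilities.
        return CalibratedClassifierCV(
            SVC(kernel="rbf", random_state=seed), method="sigmoid", cv=3, ensemble=False
        )
    if algorithm == "logistic":
        return LogisticRegression(max_iter=1000)
    if algorithm == "ensemble":
        return MeanProbabilityEnsemble(seed=seed)
    raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")


def build_model(algorithm: str, seed: int = 0) -> Pipeline:
    """Untrained model: z-score standardization then the chosen classifier.

    Standardization is part of the pipeline, so under cross-validation it is
    fit on training folds only.
    """
    return Pipeline(
        [("scale", StandardScaler()), ("clf", _bare_classifier(algorithm, seed))]
    )


def _xy(
    table: pd.DataFrame, features: tuple[str, ...] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    cols = list(features) if features else FEATURE_COLUMNS
    X = table[cols].to_numpy(dtype=float)
    y = (table["label"] == LABEL_POSITIVE).to_numpy(dtype=int)
    return X, y


def train_classifier(
    table: pd.DataFrame,
    algorithm: str,
    seed: int = 0,
    features: tuple[str, ...] | None = None,
) -> Pipeline:
    """Fit a model on a labeled feature table (needs both classes present)."""
    X, y = _xy(table, features)
    if len(np.unique(y)) < 2:
        raise ValueError("training table contains a single class")
    model = build_model(algorithm, seed)
    model.fit(X, y)
    return model


def auc(scores, labels) -> float:
    """Area under the ROC curve, in percent, by the Mann–Whitney statistic:
    100 * [P(score_pos > score_neg) + 0.5 * P(equal)]."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if labels.dtype != bool:
        labels = labels.astype(int).astype(bool) if labels.dtype.kind in "biuf" else (
            labels == LABEL_POSITIVE
        )
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: labels contain a single class")
    ranks = stats.rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2
    return float(100.0 * u / (n_pos * n_neg))


def cross_validate(
    table: pd.DataFrame,
    algorithm: str,
    folds: int = 10,
    seed: int = 0,
    features: tuple[str, ...] | None = None,
) -> float:
    """Pooled out-of-fold AUC (percent) from stratified k-fold CV.

    Fold assignment is deterministic given ``seed``.  Raises when the rarer
    class has fewer members than folds (advise reducing ``folds``).
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    X, y = _xy(table, features)
    counts = np.bincount(y, minlength=2)
    if counts.min() == 0:
        raise ValueError("cross-validation needs both classes present")
    if counts.min() < folds:
        raise ValueError(
            f"rarer class has {counts.min()} members < {folds} folds; "
            "use fewer folds"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    oof = np.empty(len(y), dtype=float)
    for train_idx, test_idx in skf.split(X, y):
        model = build_model(algorithm, seed)
        model.fit(X[train_idx], y[train_idx])
        proba = model.predict_proba(X[test_idx])
        pos_col = int(np.flatnonzero(model.classes_ == 1)[0])
        oof[test_idx] = proba[:, pos_col]
    return auc(oof, y.astype(bool))


def average_rank(auc_grid: pd.DataFrame) -> pd.Series:
    """Average rank of each method (column) over datasets (rows).

    Within each dataset methods are ranked by descending AUC; ties receive
    the average of the tied ranks.
    """
    ranks = auc_grid.rank(axis=1, ascending=False, method="average")
    return ranks.mean(axis=0)


@dataclass
class EvaluationReport:
    """Cross-validated AUCs (percent) per dataset and method, plus average ranks."""

    aucs: pd.DataFrame  # rows: datasets, columns: methods
    average_ranks: pd.Series = field(init=False)

    def __post_init__(self):
        self.average_ranks = average_rank(self.aucs)

    def to_tsv(self, path) -> None:
        out = self.aucs.copy()
        out.loc["Average Rank"] = self.average_ranks
        out.to_csv(path, sep="\t", index_label="dataset", float_format="%.4f")


def evaluate_methods(
    tables: dict[str, pd.DataFrame],
    algorithms: tuple[str, ...] = ALGORITHMS,
    folds: int = 10,
    seed: int = 0,
    features: tuple[str, ...] | None = None,
) -> EvaluationReport:
    """Cross-validate every method on every dataset and rank them."""
    grid = pd.DataFrame(
        {
            algo: {
                name: cross_validate(tbl, algo, folds=folds, seed=seed, features=features)
                for name, tbl in tables.items()
            }
            for algo in algorithms
        }
    )
    return EvaluationReport(aucs=grid.loc[list(tables)])


def save_model(model, path, metadata: dict) -> None:
    """Persist a fitted model with a JSON metadata sidecar (<path>.json)."""
    joblib.dump(model, path)
    with open(f"{path}.json", "wt", encoding="utf-8") as handle:
        json.dump(metadata, handle, indent=2, sort_keys=True)


def load_model(path):
    return joblib.load(path)
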