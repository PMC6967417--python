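"""Classifier benchmarking: repeated stratified cross-validation, the
standard binary classification metrics, and ranking of unlabeled pairs.

The protocol is "repeats x folds" cross-validation (default 10 x 5):
``repeats`` independent stratified fold assignments, each scored on its
held-out folds, with metrics averaged over all repeats*folds records.
Classifiers are scikit-learn estimators selected by short spec names
("gbdt", "rf", "dnn") with hyperparameters pinned in CLASSIFIER_CONFIG.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .featurize import PairFeatures

__all__ = [
    "CVProtocol",
    "EvalReport",
    "CLASSIFIER_CONFIG",
    "make_classifier",
    "auc",
    "threshold_metrics",
    "run_cv",
    "train_full_and_score",
    "rank_unlabeled",
]

METRICS = ("auc", "accuracy", "precision", "recall", "f1")

# Pinned hyperparameters, echoed into every report.
CLASSIFIER_CONFIG: dict[str, dict] = {
    "gbdt": {"max_iter": 100, "learning_rate": 0.1, "max_leaf_nodes": 31},
    "rf": {"n_estimators": 100, "n_jobs": 1},
    "dnn": {
        "hidden_layer_sizes": (128, 64),
        "activation": "relu",
        "early_stopping": True,
        "validation_fraction": 0.1,
        "max_iter": 300,
    },
}


@dataclass(frozen=True)
class CVProtocol:
    folds: int = 5
    repeats: int = 10
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2 or self.repeats < 1:
            raise ValueError("need folds >= 2 and repeats >= 1")


@dataclass
class EvalReport:
    """Per-fold metric records plus aggregates for one (features, classifier) cell."""

    records: pd.DataFrame  # columns: repeat, fold, auc, accuracy, precision, recall, f1
    classifier: str
    combo: str
    config: dict = field(default_factory=dict)

    def summary(self) -> dict[str, dict[str, float]]:
        return {
            m: {
                "mean": float(self.records[m].mean()),
                "sd": float(self.records[m].std(ddof=1)),
            }
            for m in METRICS
        }

    def mean(self, metric: str) -> float:
        return float(self.records[metric].mean())


def make_classifier(spec: str, seed: int = 0):
    """Instantiate a pinned scikit-learn classifier by short name."""
    if spec == "gbdt":
        from sklearn.ensemble import HistGradientBoostingClassifier

        return HistGradientBoostingClassifier(
            random_state=seed, **CLASSIFIER_CONFIG["gbdt"]
        )
    if spec == "rf":
        from sklearn.ensemble import RandomForestClassifier

        return RandomForestClassifier(random_state=seed, **CLASSIFIER_CONFIG["rf"])
    if spec == "dnn":
        from sklearn.neural_network import MLPClassifier

        return MLPClassifier(random_state=seed, **CLASSIFIER_CONFIG["dnn"])
    raise ValueError(f"unknown classifier spec {spec!r}; expected gbdt, rf or dnn")


def auc(scores, labels) -> float:
    """Area under the ROC curve via the tie-aware rank statistic.

    Equals the probability that a uniformly chosen positive outscores a
    uniformly chosen negative, with ties credited one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)
    return float(
        (ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    )


def threshold_metrics(scores, labels, threshold: float = 0.5) -> dict[str, float]:
    """Accuracy, precision, recall and F1 at a fixed score threshold.

    A score >= threshold predicts positive.  With no predicted positives,
    precision is reported as 0 with a warning (and F1 follows).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("threshold metrics need both classes present")
    pred = scores >= threshold
    actual = labels == 1
    tp = int(np.sum(pred & actual))
    fp = int(np.sum(pred & ~actual))
    fn = int(np.sum(~pred & actual))
    tn = int(np.sum(~pred & ~actual))
    accuracy = (tp + tn) / len(labels)
    if tp + fp == 0:
        warnings.warn("no predicted positives; precision set to 0", stacklevel=2)
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return {
        "accuracy": accuracy,
        "precision": precision,
        "recall": recall,
        "f1": f1,
    }


def _positive_probabilities(clf, X) -> np.ndarray:
    proba = clf.predict_proba(X)
    return proba[:, list(clf.classes_).index(1)]


def run_cv(
    features: PairFeatures | np.ndarray,
    labels,
    classifier_spec: str = "gbdt",
    protocol: CVProtocol | None = None,
) -> EvalReport:
    """Repeated stratified k-fold evaluation of one classifier.

    Repeat r shuffles fold assignment with seed ``protocol.seed + r``; each
    fold is scored with AUC plus the threshold metrics, giving
    repeats*folds records.
    """
    protocol = protocol or CVProtocol()
    if isinstance(features, PairFeatures):
        X, combo = features.matrix, features.combo
    else:
        X, combo = np.asarray(features, dtype=float), "features"
    y = np.asarray(labels)
    counts = np.bincount(y.astype(int), minlength=2)
    if counts.min() < protocol.folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples; cannot stratify into "
            f"{protocol.folds} folds"
        )
    rows = []
    for r in range(protocol.repeats):
        splitter = StratifiedKFold(
            n_splits=protocol.folds, shuffle=True, random_state=protocol.seed + r
        )
        for f, (train_idx, test_idx) in enumerate(splitter.split(X, y)):
            clf = make_classifier(classifier_spec, seed=protocol.seed + r)
            clf.fit(X[train_idx], y[train_idx])
            scores = _positive_probabilities(clf, X[test_idx])
            rec = {"repeat": r, "fold": f, "auc": auc(scores, y[test_idx])}
            rec.update(threshold_metrics(scores, y[test_idx]))
            rows.append(rec)
    return EvalReport(
        records=pd.DataFrame(rows),
        classifier=classifier_spec,
        combo=combo,
        config=dict(CLASSIFIER_CONFIG[classifier_spec]),
    )


def train_full_and_score(
    features_train,
    labels_train,
    features_score,
    classifier_spec: str = "gbdt",
    seed: int = 0,
) -> np.ndarray:
    """Fit once on the full training set and score new rows.

    Returns the predicted probability of the positive class for every
    scoring row, in [0, 1].
    """
    X_train = (
        features_train.matrix
        if isinstance(features_train, PairFeatures)
        else np.asarray(features_train, dtype=float)
    )
    X_score = (
        features_score.matrix
        if isinstance(features_score, PairFeatures)
        else np.asarray(features_score, dtype=float)
    )
    y = np.asarray(labels_train)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels must contain both classes")
    if X_score.shape[1] != X_train.shape[1]:
        raise ValueError(
            f"feature-dimension mismatch: trained on {X_train.shape[1]} columns, "
            f"scoring rows have {X_score.shape[1]}"
        )
    clf = make_classifier(classifier_spec, seed=seed)
    clf.fit(X_train, y)
    return _positive_probabilities(clf, X_score)


def rank_unlabeled(
    probabilities,
    pair_ids: list[tuple[str, str]],
    top_n: int,
) -> list[tuple[tuple[str, str], float]]:
    """The top_n pairs by descending probability.

    Ties are broken by (drug_id, target_id) lexicographic order so the
    ranking is deterministic.
    """
    if len(pair_ids) < top_n:
        raise ValueError("fewer pairs than requested top_n")
    probabilities = np.asarray(probabilities, dtype=float)
    order = sorted(
        range(len(pair_ids)), key=lambda i: (-probabilities[i], pair_ids[i])
    )
    return [(pair_ids[i], float(probabilities[i])) for i in order[:top_n]]
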