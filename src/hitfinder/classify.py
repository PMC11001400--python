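"""Hit/miss classification on region-count descriptors.

Four classical supervised models are supported with the defaults used for
this pipeline: a multilayer perceptron (four hidden layers of 50/30/20/20
logistic units, SGD, L2 term 1e-5), an RBF support vector machine (C = 10),
a random forest (Gini impurity, depth <= 30, 100 trees) and Gaussian naive
Bayes (var_smoothing 1e-9).  Evaluation reports precision, recall, F1 and
accuracy as percentages from the TP/TN/FP/FN tally, plus a cross-data-set
protocol that trains on one named corpus and tests on another.

The estimators themselves come from scikit-learn; the metric arithmetic and
the evaluation protocol are implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, Sequence, Tuple

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "ClassifierSpec",
    "TrainedClassifier",
    "ConfusionCounts",
    "ClassificationMetrics",
    "DEFAULT_HYPERPARAMS",
    "train",
    "predict",
    "confusion",
    "metrics",
    "evaluate",
    "cross_dataset_eval",
    "tune_hyperparameters",
    "save_model",
    "load_model",
]

DEFAULT_HYPERPARAMS: Dict[str, Dict] = {
    "mlp": {
        "hidden_layer_sizes": (50, 30, 20, 20),
        "activation": "logistic",
        "solver": "sgd",
        "alpha": 1e-5,
        "learning_rate": "constant",
        # step size and stopping are open choices: a four-layer logistic
        # stack on raw count features starts on a flat loss plateau, so a
        # larger constant step is used and the full epoch budget always
        # runs (n_iter_no_change matches max_iter so plateau epochs are
        # never mistaken for convergence)
        "learning_rate_init": 0.1,
        "tol": 0.0,
        "max_iter": 1000,
        "n_iter_no_change": 1000,
        "early_stopping": False,
    },
    "svm": {"C": 10.0, "kernel": "rbf"},
    "rf": {"criterion": "gini", "max_depth": 30, "n_estimators": 100},
    "nb": {"var_smoothing": 1e-9},
}


@dataclass(frozen=True)
class ClassifierSpec:
    """Which model to fit and with which hyperparameters.

    ``hyperparams`` overrides the kind's defaults key by key.  ``scale``
    inserts a standardization step before the model (off by default: raw
    region counts are already small and commensurate).
    """

    kind: str = "mlp"
    hyperparams: Mapping = field(default_factory=dict)
    random_seed: int = 0
    scale: bool = False

    def __post_init__(self) -> None:
        if self.kind not in DEFAULT_HYPERPARAMS:
            raise ValueError(
                f"unknown classifier kind {self.kind!r}; "
                f"choose from {sorted(DEFAULT_HYPERPARAMS)}"
            )

    def resolved_hyperparams(self) -> Dict:
        hp = dict(DEFAULT_HYPERPARAMS[self.kind])
        hp.update(self.hyperparams)
        return hp


def _build_estimator(spec: ClassifierSpec):
    hp = spec.resolved_hyperparams()
    if spec.kind == "mlp":
        return MLPClassifier(random_state=spec.random_seed, **hp)
    if spec.kind == "svm":
        return SVC(random_state=spec.random_seed, **hp)
    if spec.kind == "rf":
        return RandomForestClassifier(random_state=spec.random_seed, **hp)
    return GaussianNB(**hp)


@dataclass
class TrainedClassifier:
    """A fitted model together with the spec that produced it."""

    spec: ClassifierSpec
    estimator: object
    scaler: object | None
    n_features: int
    classes: Tuple

    def predict(self, features: np.ndarray) -> np.ndarray:
        return predict(self, features)


def train(
    features: np.ndarray, labels: Sequence, spec: ClassifierSpec | None = None
) -> TrainedClassifier:
    """Fit one classifier; reproducible for a fixed ``spec.random_seed``."""
    spec = spec or ClassifierSpec()
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D (N, n) matrix")
    if len(X) != len(y):
        raise ValueError(
            f"feature rows ({len(X)}) and labels ({len(y)}) disagree"
        )
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training data must contain at least two classes")
    scaler = None
    if spec.scale:
        scaler = StandardScaler().fit(X)
        X = scaler.transform(X)
    estimator = _build_estimator(spec)
    with warnings.catch_warnings():
        # the MLP runs its full epoch budget by design (tol=0), which
        # sklearn reports as non-convergence
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        estimator.fit(X, y)
    return TrainedClassifier(
        spec=spec,
        estimator=estimator,
        scaler=scaler,
        n_features=X.shape[1],
        classes=tuple(classes.tolist()),
    )


def predict(model: TrainedClassifier, features: np.ndarray) -> np.ndarray:
    X = np.asarray(features, dtype=np.float64)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature width {X.shape[1]} does not match the trained "
            f"width {model.n_features}"
        )
    if model.scaler is not None:
        X = model.scaler.transform(X)
    return model.estimator.predict(X)


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion tally; TP+TN+FP+FN equals the number of samples."""

    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def confusion(
    y_true: Sequence, y_pred: Sequence, positive_label="hit"
) -> ConfusionCounts:
    """2x2 tally with ``positive_label`` (default 'hit') as positive."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred lengths differ")
    tpos = y_true == positive_label
    ppos = y_pred == positive_label
    return ConfusionCounts(
        TP=int(np.sum(tpos & ppos)),
        TN=int(np.sum(~tpos & ~ppos)),
        FP=int(np.sum(~tpos & ppos)),
        FN=int(np.sum(tpos & ~ppos)),
    )


@dataclass(frozen=True)
class ClassificationMetrics:
    """Precision, recall, F1 and accuracy as percentages in [0, 100]."""

    f1: float
    precision: float
    recall: float
    accuracy: float


def _safe_div(num: float, den: float) -> float:
    # 0-by-convention on degenerate denominators (e.g. no predicted positives)
    return num / den if den > 0 else 0.0


def metrics(counts: ConfusionCounts) -> ClassificationMetrics:
    """precision = TP/(TP+FP), recall = TP/(TP+FN),
    F1 = 2PR/(P+R), accuracy = (TP+TN)/total, all x100."""
    if counts.total == 0:
        raise ValueError("cannot compute metrics from all-zero counts")
    precision = _safe_div(counts.TP, counts.TP + counts.FP)
    recall = _safe_div(counts.TP, counts.TP + counts.FN)
    f1 = _safe_div(2 * precision * recall, precision + recall)
    accuracy = (counts.TP + counts.TN) / counts.total
    return ClassificationMetrics(
        f1=100.0 * f1,
        precision=100.0 * precision,
        recall=100.0 * recall,
        accuracy=100.0 * accuracy,
    )


def evaluate(
    y_true: Sequence, y_pred: Sequence, positive_label="hit"
) -> ClassificationMetrics:
    """Metrics for predictions.

    Binary labels use ``positive_label`` as the positive class; with more
    than two classes the one-vs-rest metrics are macro-averaged and accuracy
    is the plain fraction correct.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    labels = np.unique(np.concatenate([y_true, y_pred]))
    if len(labels) <= 2:
        return metrics(confusion(y_true, y_pred, positive_label))
    per_class = [metrics(confusion(y_true, y_pred, lab)) for lab in labels]
    return ClassificationMetrics(
        f1=float(np.mean([m.f1 for m in per_class])),
        precision=float(np.mean([m.precision for m in per_class])),
        recall=float(np.mean([m.recall for m in per_class])),
        accuracy=100.0 * float(np.mean(y_true == y_pred)),
    )


def cross_dataset_eval(
    datasets: Mapping[str, Tuple[np.ndarray, Sequence]],
    spec: ClassifierSpec | None = None,
    holdout_fraction: float = 0.2,
) -> pd.DataFrame:
    """Train-on-one / test-on-another accuracy matrix over named corpora.

    Off-diagonal (train, test) cells train on the full train corpus and
    report accuracy (%) on the full test corpus.  Diagonal cells use a
    stratified held-out split of the same corpus (default 80/20, seeded by
    ``spec.random_seed``) so they measure generalization, not memorization.
    """
    spec = spec or ClassifierSpec()
    if len(datasets) < 2:
        raise ValueError("cross-data-set evaluation needs >= 2 named sets")
    names = list(datasets)
    widths = {np.asarray(X).shape[1] for X, _ in datasets.values()}
    if len(widths) != 1:
        raise ValueError(f"incompatible feature widths: {sorted(widths)}")
    table = pd.DataFrame(index=names, columns=names, dtype=float)
    for train_name in names:
        X_tr, y_tr = datasets[train_name]
        model = train(np.asarray(X_tr), y_tr, spec)
        for test_name in names:
            if test_name == train_name:
                X_a, X_b, y_a, y_b = train_test_split(
                    np.asarray(X_tr),
                    np.asarray(y_tr),
                    test_size=holdout_fraction,
                    stratify=np.asarray(y_tr),
                    random_state=spec.random_seed,
                )
                held_model = train(X_a, y_a, spec)
                acc = float(np.mean(predict(held_model, X_b) == y_b))
            else:
                X_te, y_te = datasets[test_name]
                acc = float(
                    np.mean(predict(model, np.asarray(X_te)) == np.asarray(y_te))
                )
            table.loc[train_name, test_name] = 100.0 * acc
    return table


def tune_hyperparameters(
    features: np.ndarray,
    labels: Sequence,
    grid: Sequence[ClassifierSpec],
    cv_folds: int = 5,
    seed: int = 0,
) -> ClassifierSpec:
    """Exhaustive grid search with stratified CV; best mean accuracy wins.

    ``grid`` is an explicit list of candidate specs (possibly of different
    kinds); ties break in favour of the earlier entry.
    """
    if not grid:
        raise ValueError("grid must be non-empty")
    if cv_folds < 2:
        raise ValueError("cv_folds must be >= 2")
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < cv_folds:
        raise ValueError(
            f"minority class has {counts.min()} samples; cannot build "
            f"{cv_folds} stratified folds"
        )
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    best_spec = None
    best_score = -np.inf
    for spec in grid:
        spec = replace(spec, random_seed=seed)
        scores = []
        for train_idx, test_idx in cv.split(X, y):
            model = train(X[train_idx], y[train_idx], spec)
            scores.append(
                float(np.mean(predict(model, X[test_idx]) == y[test_idx]))
            )
        score = float(np.mean(scores))
        if score > best_score:  # strict: ties keep the earlier spec
            best_score = score
            best_spec = spec
    return best_spec


_MODEL_FORMAT_VERSION = 1


def save_model(model: TrainedClassifier, path) -> None:
    """Serialize spec + fitted weights to a versioned joblib file."""
    joblib.dump(
        {
            "format_version": _MODEL_FORMAT_VERSION,
            "spec": model.spec,
            "estimator": model.estimator,
            "scaler": model.scaler,
            "n_features": model.n_features,
            "classes": model.classes,
        },
        path,
    )


def load_model(path) -> TrainedClassifier:
    payload = joblib.load(path)
    version = payload.get("format_version")
    if version != _MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model file version: {version}")
    return TrainedClassifier(
        spec=payload["spec"],
        estimator=payload["estimator"],
        scaler=payload["scaler"],
        n_features=payload["n_features"],
        classes=payload["classes"],
    )


def metrics_table(results: Mapping[str, ClassificationMetrics]) -> pd.DataFrame:
    """Rows = classifier kinds, columns = F1/Precision/Recall/Accuracy (%)."""
    return pd.DataFrame(
        {
            name: {
                "F1": m.f1,
                "Precision": m.precision,
                "Recall": m.recall,
                "Accuracy": m.accuracy,
            }
            for name, m in results.items()
        }
    ).T[["F1", "Precision", "Recall", "Accuracy"]]
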