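"""Binary classifiers over sequence feature vectors.

The primary model is an RBF-kernel support vector machine tuned by grid
search; kNN, random forest, Gaussian naive Bayes, and an RBF-network
stand-in (all training points as centers, regularized least-squares output
weights) are provided for the classifier comparison. The RBF network is a
generic re-implementation of the radial-basis-function network family, not
the published QuickRBF binary, and is labeled as a stand-in in reports.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

ARCHIVE_FORMAT_VERSION = 1

FAMILIES = ("svm", "knn", "random_forest", "naive_bayes", "rbf_network")

#: Default log2 grids for the SVM search: C in 2^-5..2^15, gamma in 2^-15..2^3,
#: both stepping by x4.
DEFAULT_C_GRID = tuple(2.0**e for e in range(-5, 16, 2))
DEFAULT_GAMMA_GRID = tuple(2.0**e for e in range(-15, 4, 2))


@dataclass(frozen=True)
class ClassifierSpec:
    family: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown classifier family {self.family!r}; choose from {FAMILIES}")


class RBFNetwork:
    """Radial-basis-function network: every training point is a center.

    The design matrix is the RBF kernel between inputs and centers; output
    weights solve a ridge-regularized least-squares problem against +/-1
    targets. Scores are the network output; the decision threshold is 0.
    """

    def __init__(self, gamma: float | None = None, alpha: float = 1e-3):
        self.gamma = gamma
        self.alpha = alpha

    def _kernel(self, X: np.ndarray) -> np.ndarray:
        sq = ((X[:, None, :] - self.centers_[None, :, :]) ** 2).sum(-1)
        return np.exp(-self.gamma_ * sq)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RBFNetwork":
        self.centers_ = np.asarray(X, dtype=np.float64)
        var = self.centers_.var()
        self.gamma_ = self.gamma if self.gamma is not None else 1.0 / (
            X.shape[1] * var if var > 0 else X.shape[1]
        )
        K = self._kernel(self.centers_)
        t = np.where(np.asarray(y) == 1, 1.0, -1.0)
        self.weights_ = np.linalg.solve(
            K.T @ K + self.alpha * np.eye(K.shape[1]), K.T @ t
        )
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return self._kernel(np.asarray(X, dtype=np.float64)) @ self.weights_

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.decision_function(X) > 0).astype(int)


def _build_estimator(spec: ClassifierSpec):
    hp = dict(spec.hyperparameters)
    if spec.family == "svm":
        # Feature coordinates (count x scalar) live on very different scales,
        # so the RBF kernel sees a per-feature standardizer fit on training
        # data; hyperparameters refer to the SVC step.
        standardize = hp.pop("standardize", True)
        svc = SVC(
            kernel=hp.pop("kernel", "rbf"),
            C=hp.pop("C", 1.0),
            gamma=hp.pop("gamma", "scale"),
            random_state=spec.seed,
            **hp,
        )
        return make_pipeline(StandardScaler(), svc) if standardize else svc
    if spec.family == "knn":
        return KNeighborsClassifier(n_neighbors=hp.pop("n_neighbors", 5), **hp)
    if spec.family == "random_forest":
        return RandomForestClassifier(
            n_estimators=hp.pop("n_estimators", 100),
            random_state=spec.seed,
            n_jobs=1,
            **hp,
        )
    if spec.family == "naive_bayes":
        return GaussianNB(**hp)
    if spec.family == "rbf_network":
        return RBFNetwork(gamma=hp.pop("gamma", None), alpha=hp.pop("alpha", 1e-3))
    raise AssertionError(spec.family)


@dataclass
class TrainedModel:
    spec: ClassifierSpec
    estimator: object
    n_features: int
    manifest: tuple[str, ...] | None = None


def train_classifier(
    features: np.ndarray, labels: np.ndarray, spec: ClassifierSpec,
    manifest: tuple[str, ...] | None = None,
) -> TrainedModel:
    """Fit one classifier; deterministic given the spec's seed (single thread)."""
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains non-finite values")
    est = _build_estimator(spec).fit(X, y)
    return TrainedModel(spec, est, X.shape[1], manifest)


def predict_scores(model: TrainedModel, features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Real-valued positive-class scores and binary predictions.

    SVM and the RBF network score with the signed decision value (threshold
    0); probabilistic families score with the positive-class probability
    (threshold 0.5). Predicted label is positive iff the score exceeds the
    family's threshold.
    """
    X = np.asarray(features, dtype=np.float64)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.n_features:
        raise ValueError(f"feature length {X.shape[1]} != trained manifest length {model.n_features}")
    est = model.estimator
    if hasattr(est, "decision_function"):
        scores = np.asarray(est.decision_function(X), dtype=np.float64)
        preds = (scores > 0).astype(int)
    else:
        scores = np.asarray(est.predict_proba(X), dtype=np.float64)[
            :, list(est.classes_).index(1)
        ]
        preds = (scores > 0.5).astype(int)
    return scores, preds


def tune_svm(
    features: np.ndarray,
    labels: np.ndarray,
    c_grid: tuple[float, ...] = DEFAULT_C_GRID,
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID,
    inner_k: int = 3,
    seed: int = 0,
) -> ClassifierSpec:
    """Grid-search (C, gamma) by mean inner-CV AUC.

    Ties break toward smaller C, then smaller gamma, so results do not depend
    on grid iteration order.
    """
    if inner_k < 2:
        raise ValueError("inner_k must be >= 2")
    if not c_grid or not gamma_grid:
        raise ValueError("empty hyperparameter grid")
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    skf = StratifiedKFold(n_splits=inner_k, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    best: tuple[float, float, float] | None = None  # (auc, -C, -gamma) maximized
    best_point = (c_grid[0], gamma_grid[0])
    for C, gamma in itertools.product(sorted(c_grid), sorted(gamma_grid)):
        aucs = []
        for tr, te in folds:
            if len(np.unique(y[te])) < 2 or len(np.unique(y[tr])) < 2:
                continue
            est = make_pipeline(StandardScaler(), SVC(kernel="rbf", C=C, gamma=gamma))
            est.fit(X[tr], y[tr])
            aucs.append(roc_auc_score(y[te], est.decision_function(X[te])))
        mean_auc = float(np.mean(aucs)) if aucs else 0.0
        key = (mean_auc, -C, -gamma)
        if best is None or key > best:
            best = key
            best_point = (C, gamma)
    return ClassifierSpec("svm", {"C": best_point[0], "gamma": best_point[1]}, seed)


def save_trained(model: TrainedModel, path: str | Path) -> None:
    joblib.dump(
        {"format_version": ARCHIVE_FORMAT_VERSION, "spec": model.spec,
         "estimator": model.estimator, "n_features": model.n_features,
         "manifest": model.manifest},
        path,
    )


def load_trained(path: str | Path) -> TrainedModel:
    blob = joblib.load(path)
    if blob.get("format_version") != ARCHIVE_FORMAT_VERSION:
        raise ValueError(f"unsupported model archive version {blob.get('format_version')}")
    return TrainedModel(blob["spec"], blob["estimator"], blob["n_features"], blob["manifest"])
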