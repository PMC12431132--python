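"""SVM classification heads on CNN features, and the hybrid estimator.

The head standardizes features (training-set mean/s.d. per dimension)
and fits a soft-margin SVM; the gamma convention is
k(x, x') = exp(-gamma * ||x - x'||^2), so the printed gamma = 0.4 plugs
in directly.  Labels follow the sign of the decision function
(positive = drowsy); points exactly on the boundary go to class 0.
Hyperparameters can be grid-searched by stratified k-fold accuracy with
ties broken toward smaller C, then smaller gamma.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .models import ConvNetClassifier

KERNELS = ("linear", "poly", "rbf", "sigmoid")
_KERNEL_ALIASES = {"polynomial": "poly"}

DEFAULT_GRID = {
    "C": [0.01, 0.1, 1.0, 10.0, 100.0],
    "gamma": [0.05, 0.1, 0.2, 0.4, 0.8, 1.6],
    "degree": [2, 3, 4],
}


@dataclass(frozen=True)
class SVMConfig:
    """Kernel and regularization of the SVM head."""

    kernel: str = "rbf"
    C: float = 1.0
    gamma: float = 0.4
    degree: int = 3

    def __post_init__(self):
        kernel = _KERNEL_ALIASES.get(self.kernel, self.kernel)
        object.__setattr__(self, "kernel", kernel)
        if kernel not in KERNELS:
            raise ValueError(f"kernel must be one of {KERNELS}, got {kernel!r}")
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.degree < 2:
            raise ValueError("degree must be >= 2")


@dataclass
class TrainedSVM:
    """A fitted head: standardization parameters plus the SVC."""

    config: SVMConfig
    scaler: StandardScaler
    svc: SVC

    @property
    def support_vectors(self) -> np.ndarray:
        return self.svc.support_vectors_

    @property
    def dual_coef(self) -> np.ndarray:
        return self.svc.dual_coef_

    @property
    def bias(self) -> float:
        return float(self.svc.intercept_[0])

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = _check_features(X)
        return self.svc.decision_function(self.scaler.transform(X))


def _check_features(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, float)
    if X.ndim != 2:
        raise ValueError("features must be 2-D (n_samples, n_features)")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    return X


def _make_svc(config: SVMConfig) -> SVC:
    return SVC(kernel=config.kernel, C=config.C, gamma=config.gamma,
               degree=config.degree, coef0=0.0)


def fit_svm(features: np.ndarray, labels: np.ndarray,
            config: SVMConfig = SVMConfig()) -> TrainedSVM:
    """Standardize features and fit the soft-margin SVM."""
    X = _check_features(features)
    y = np.asarray(labels).ravel()
    if np.unique(y).size < 2:
        raise ValueError("need samples of both classes")
    scaler = StandardScaler().fit(X)
    svc = _make_svc(config).fit(scaler.transform(X), y)
    return TrainedSVM(config=config, scaler=scaler, svc=svc)


def predict(svm: TrainedSVM, features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Labels and continuous scores (signed distance to the hyperplane).

    Positive score -> drowsy (1); a score of exactly 0 goes to class 0.
    """
    scores = svm.decision_function(features)
    return (scores > 0).astype(int), scores


def grid_search(
    features: np.ndarray,
    labels: np.ndarray,
    kernel: str = "rbf",
    grid: dict | None = None,
    k: int = 5,
    seed: int = 0,
) -> tuple[SVMConfig, pd.DataFrame]:
    """Pick the best config by stratified k-fold CV accuracy.

    Returns the winning :class:`SVMConfig` and a table with one row per
    grid cell and one column per fold.  Ties break toward smaller C,
    then smaller gamma.
    """
    X = _check_features(features)
    y = np.asarray(labels).ravel()
    grid = dict(DEFAULT_GRID, **(grid or {}))
    kernel = _KERNEL_ALIASES.get(kernel, kernel)
    cs = grid["C"]
    gammas = grid["gamma"] if kernel in ("rbf", "poly", "sigmoid") else [0.4]
    degrees = grid["degree"] if kernel == "poly" else [3]
    configs = [
        SVMConfig(kernel=kernel, C=c, gamma=g, degree=d)
        for c in cs for g in gammas for d in degrees
    ]
    if not configs:
        raise ValueError("empty grid")
    minority = np.bincount(pd.factorize(y)[0]).min()
    if k > minority:
        raise ValueError(f"{k}-fold CV infeasible with minority class of {minority}")
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(cv.split(X, y))
    rows = []
    for cfg in configs:
        accs = []
        for tr, te in folds:
            scaler = StandardScaler().fit(X[tr])
            svc = _make_svc(cfg).fit(scaler.transform(X[tr]), y[tr])
            accs.append(float(np.mean(svc.predict(scaler.transform(X[te])) == y[te])))
        rows.append(accs)
    table = pd.DataFrame(
        rows, columns=[f"fold{i}" for i in range(k)],
        index=pd.MultiIndex.from_tuples(
            [(c.C, c.gamma, c.degree) for c in configs], names=["C", "gamma", "degree"]
        ),
    )
    means = table.mean(axis=1).to_numpy()
    order = sorted(
        range(len(configs)),
        key=lambda i: (-means[i], configs[i].C, configs[i].gamma, configs[i].degree),
    )
    return configs[order[0]], table


class HybridCNNSVM(BaseEstimator, ClassifierMixin):
    """The full hybrid classifier: CNN feature extractor + SVM head.

    ``fit`` trains the CNN end-to-end on the images, extracts the 128-d
    penultimate features, then fits the standardized SVM on them
    (optionally grid-searching C/gamma by stratified CV).
    """

    def __init__(self, cnn: ConvNetClassifier | None = None,
                 kernel: str = "rbf", C: float = 1.0, gamma: float = 0.4,
                 degree: int = 3, search: bool = False, cv_folds: int = 5,
                 random_state: int = 0):
        self.cnn = cnn
        self.kernel = kernel
        self.C = C
        self.gamma = gamma
        self.degree = degree
        self.search = search
        self.cv_folds = cv_folds
        self.random_state = random_state

    def fit(self, X, y):
        y = np.asarray(y).ravel()
        self.cnn_ = clone(self.cnn) if self.cnn is not None else ConvNetClassifier(
            random_state=self.random_state)
        self.cnn_.fit(X, y)
        feats = self.cnn_.transform(X)
        if self.search:
            config, self.cv_table_ = grid_search(
                feats, y, kernel=self.kernel, k=self.cv_folds, seed=self.random_state)
        else:
            config = SVMConfig(kernel=self.kernel, C=self.C, gamma=self.gamma,
                               degree=self.degree)
        self.svm_ = fit_svm(feats, y, config)
        self.config_ = self.svm_.config
        self.classes_ = np.unique(y)
        return self

    def decision_function(self, X):
        return self.svm_.decision_function(self.cnn_.transform(X))

    def predict(self, X):
        labels, _ = predict(self.svm_, self.cnn_.transform(X))
        return self.classes_[labels]

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.input_tags.two_d_array = False
        return tags
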