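"""Train target-specific activity classifiers on standardized fingerprints.

:class:`PadifClassifier` is a scikit-learn estimator wrapping the training
protocol used throughout the workflow: z-score feature standardization
(statistics fitted on training data only), optional ADASYN oversampling of
the minority class on the training folds, stratified k-fold
cross-validation over a small per-family hyperparameter grid with mean
fold F1 as the selection metric, and a final refit on the full training
set.  Four model families are supported: random forest (``rf``), RBF
support-vector machine (``svm``), gradient-boosted trees (``xgb``) and a
multilayer perceptron (``mlp``, with early stopping on a validation
split).

ADASYN (adaptive synthetic sampling) is implemented here directly:
synthetic minority points are interpolated between minority samples and
their minority nearest neighbours, with per-sample generation counts
proportional to the local majority density, so harder regions of the
minority manifold receive more synthetic support.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import joblib
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import f1_score
from sklearn.model_selection import ParameterGrid, StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.neighbors import NearestNeighbors
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted, check_X_y, check_array
from xgboost import XGBClassifier

from .errors import LayoutError, ParameterError

__all__ = [
    "MODEL_FAMILIES",
    "DEFAULT_GRIDS",
    "adasyn_oversample",
    "TrainConfig",
    "PadifClassifier",
    "fit",
    "predict_scores",
    "save_model",
    "load_model",
    "training_report",
]

MODEL_FAMILIES = ("rf", "svm", "xgb", "mlp")

#: Small fixed hyperparameter grids per family.  The training protocol
#: delegates breadth to the selection metric, not to large grids; the
#: grids are config, not claims.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "rf": {"n_estimators": [100, 300], "max_features": ["sqrt"]},
    "svm": {"C": [1.0, 10.0], "gamma": ["scale"]},
    "xgb": {"n_estimators": [200], "max_depth": [3, 6], "learning_rate": [0.1]},
    "mlp": {"hidden_layer_sizes": [(64,), (128,)], "alpha": [1e-4]},
}

MODEL_FORMAT_VERSION = 1


def adasyn_oversample(
    X: np.ndarray,
    y: np.ndarray,
    n_neighbors: int = 5,
    random_state: int | None = None,
    balance_ratio: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Adaptive synthetic oversampling of the minority class.

    For each minority sample, the fraction of majority points among its
    ``n_neighbors`` nearest neighbours (over all samples) weights how many
    synthetic points are generated there; synthetic points interpolate
    uniformly between the sample and a random minority neighbour.  Enough
    points are generated to bring the minority count to ``balance_ratio``
    times the majority count.  When the classes are perfectly separated
    (all density weights zero) the weights fall back to uniform.  If the
    minority class has fewer than ``n_neighbors + 1`` members the data is
    returned unchanged with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ParameterError(f"ADASYN requires 2 classes, got {classes.size}")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    n_new = int(round(balance_ratio * n_maj - n_min))
    if n_new <= 0:
        return X, y
    if n_min <= n_neighbors:
        warnings.warn(
            f"ADASYN infeasible (minority {n_min} <= {n_neighbors} neighbours); "
            "returning data unchanged",
            stacklevel=2,
        )
        return X, y
    rng = np.random.default_rng(random_state)
    X_min = X[y == minority]

    nn_all = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(X)
    _, idx = nn_all.kneighbors(X_min)
    # drop self-neighbour (first column) and measure local majority density
    ratios = np.array([np.mean(y[row[1:]] != minority) for row in idx])
    if ratios.sum() == 0.0:
        weights = np.full(len(X_min), 1.0 / len(X_min))
    else:
        weights = ratios / ratios.sum()

    # largest-remainder allocation so counts sum exactly to n_new
    raw = weights * n_new
    alloc = np.floor(raw).astype(int)
    rem = n_new - alloc.sum()
    if rem > 0:
        alloc[np.argsort(-(raw - alloc), kind="stable")[:rem]] += 1

    k_min = min(n_neighbors, len(X_min) - 1)
    nn_min = NearestNeighbors(n_neighbors=k_min + 1).fit(X_min)
    _, idx_min = nn_min.kneighbors(X_min)
    synth = []
    for i, g in enumerate(alloc):
        for _ in range(g):
            j = idx_min[i][1 + rng.integers(k_min)]
            lam = rng.random()
            synth.append(X_min[i] + lam * (X_min[j] - X_min[i]))
    X_out = np.vstack([X, np.asarray(synth)])
    y_out = np.concatenate([y, np.full(len(synth), minority, dtype=y.dtype)])
    return X_out, y_out


@dataclass
class TrainConfig:
    """Training protocol knobs (defaults mirror the workflow protocol)."""

    model_family: str = "rf"
    n_folds: int = 10
    seed: int = 0
    oversample: bool = True
    adasyn_neighbors: int = 5
    early_stopping: bool = True
    param_grid: dict[str, list] | None = None

    def __post_init__(self) -> None:
        if self.model_family not in MODEL_FAMILIES:
            raise ParameterError(f"unknown model family {self.model_family!r}")
        if self.n_folds < 2:
            raise ParameterError("n_folds must be >= 2")


def _make_estimator(family: str, params: dict, seed: int, early_stopping: bool):
    if family == "rf":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if family == "svm":
        # Platt-scaled probabilities via explicit CV calibration; deterministic
        # (unshuffled stratified folds), and keeps the [0, 1] score contract
        return CalibratedClassifierCV(
            SVC(kernel="rbf", **params), method="sigmoid", cv=3, ensemble=False
        )
    if family == "xgb":
        return XGBClassifier(
            random_state=seed,
            n_jobs=1,
            eval_metric="logloss",
            tree_method="hist",
            verbosity=0,
            **params,
        )
    if family == "mlp":
        return MLPClassifier(
            random_state=seed,
            max_iter=300,
            early_stopping=early_stopping,
            validation_fraction=0.1,
            n_iter_no_change=10,
            **params,
        )
    raise ParameterError(f"unknown model family {family!r}")


class PadifClassifier(ClassifierMixin, BaseEstimator):
    """Activity classifier on standardized fingerprint vectors.

    Parameters
    ----------
    model_family : {"rf", "svm", "xgb", "mlp"}
        Estimator family.
    n_folds : int
        Stratified CV folds for hyperparameter selection (default 10).
    oversample : bool
        Apply ADASYN to the training folds (and the final training set).
    adasyn_neighbors : int
        Neighbour count for ADASYN (default 5).
    early_stopping : bool
        Early stopping for the MLP (ignored by other families).
    param_grid : dict, optional
        Hyperparameter grid; defaults to :data:`DEFAULT_GRIDS` per family.
    random_state : int, optional
        Seed for folds, oversampling and the estimator.

    Attributes
    ----------
    scaler_ : StandardScaler fitted on the training set only.
    estimator_ : the refitted winning estimator.
    best_params_ : chosen hyperparameters.
    cv_results_ : per-candidate mean and fold-wise F1.
    classes_ : class labels (the larger label is the "active" score target).
    """

    def __init__(
        self,
        model_family: str = "rf",
        n_folds: int = 10,
        oversample: bool = True,
        adasyn_neighbors: int = 5,
        early_stopping: bool = True,
        param_grid: dict[str, list] | None = None,
        random_state: int | None = None,
    ):
        self.model_family = model_family
        self.n_folds = n_folds
        self.oversample = oversample
        self.adasyn_neighbors = adasyn_neighbors
        self.early_stopping = early_stopping
        self.param_grid = param_grid
        self.random_state = random_state

    def _resample(self, X, y, seed):
        if not self.oversample:
            return X, y
        return adasyn_oversample(
            X, y, n_neighbors=self.adasyn_neighbors, random_state=seed
        )

    def fit(self, X: np.ndarray, y: np.ndarray) -> "PadifClassifier":
        X, y = check_X_y(X, y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ParameterError(
                f"training data must contain both classes, found {self.classes_.size}"
            )
        if self.model_family not in MODEL_FAMILIES:
            raise ParameterError(f"unknown model family {self.model_family!r}")
        seed = 0 if self.random_state is None else int(self.random_state)
        grid = list(ParameterGrid(self.param_grid or DEFAULT_GRIDS[self.model_family]))
        n_folds = min(self.n_folds, int(np.unique(y, return_counts=True)[1].min()))
        if n_folds < 2:
            raise ParameterError("too few samples in the minority class for CV")
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        folds = list(skf.split(X, y))

        cv_results = []
        for params in grid:
            fold_scores = []
            for k, (tr, va) in enumerate(folds):
                scaler = StandardScaler().fit(X[tr])
                X_tr, y_tr = self._resample(scaler.transform(X[tr]), y[tr], seed + k)
                est = _make_estimator(self.model_family, params, seed, self.early_stopping)
                est.fit(X_tr, y_tr)
                pred = est.predict(scaler.transform(X[va]))
                fold_scores.append(f1_score(y[va], pred, zero_division=0))
            cv_results.append(
                {"params": params, "fold_f1": fold_scores, "mean_f1": float(np.mean(fold_scores))}
            )
        best = max(range(len(grid)), key=lambda i: (cv_results[i]["mean_f1"], -i))
        self.best_params_ = grid[best]
        self.cv_results_ = cv_results
        self.n_folds_ = n_folds

        self.scaler_ = StandardScaler().fit(X)
        X_fit, y_fit = self._resample(self.scaler_.transform(X), y, seed)
        self.estimator_ = _make_estimator(
            self.model_family, self.best_params_, seed, self.early_stopping
        )
        self.estimator_.fit(X_fit, y_fit)
        self.n_features_in_ = X.shape[1]
        return self

    def _check_vectors(self, X):
        check_is_fitted(self, "estimator_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise LayoutError(
                f"vector length {X.shape[1]} does not match the training layout "
                f"({self.n_features_in_})"
            )
        return X

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = self._check_vectors(X)
        return self.estimator_.predict_proba(self.scaler_.transform(X))

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        """Score in [0, 1] for the active (larger-label) class."""
        return self.predict_proba(X)[:, -1]

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = self._check_vectors(X)
        return self.estimator_.predict(self.scaler_.transform(X))


# ---------------------------------------------------------------------------
# thin functional wrappers


def fit(X: np.ndarray, y: np.ndarray, config: TrainConfig | None = None) -> PadifClassifier:
    """Train one classifier under a :class:`TrainConfig`."""
    cfg = config or TrainConfig()
    return PadifClassifier(
        model_family=cfg.model_family,
        n_folds=cfg.n_folds,
        oversample=cfg.oversample,
        adasyn_neighbors=cfg.adasyn_neighbors,
        early_stopping=cfg.early_stopping,
        param_grid=cfg.param_grid,
        random_state=cfg.seed,
    ).fit(X, y)


def predict_scores(model: PadifClassifier, X: np.ndarray) -> np.ndarray:
    return model.predict_scores(X)


def save_model(path: str | Path, model: PadifClassifier) -> None:
    """Serialize a fitted model with a format-version header."""
    check_is_fitted(model, "estimator_")
    joblib.dump({"format_version": MODEL_FORMAT_VERSION, "model": model}, path)


def load_model(path: str | Path) -> PadifClassifier:
    blob = joblib.load(path)
    if not isinstance(blob, dict) or blob.get("format_version") != MODEL_FORMAT_VERSION:
        raise ParameterError(f"{path}: not a recognized model artifact")
    return blob["model"]


def training_report(model: PadifClassifier) -> dict[str, Any]:
    """JSON-serializable summary of a fitted model's training run."""
    check_is_fitted(model, "estimator_")
    return {
        "model_family": model.model_family,
        "n_folds": model.n_folds_,
        "seed": model.random_state,
        "oversample": model.oversample,
        "best_params": {k: (list(v) if isinstance(v, tuple) else v)
                        for k, v in model.best_params_.items()},
        "cv_results": [
            {
                "params": {k: (list(v) if isinstance(v, tuple) else v)
                           for k, v in r["params"].items()},
                "fold_f1": [round(float(s), 6) for s in r["fold_f1"]],
                "mean_f1": round(r["mean_f1"], 6),
            }
            for r in model.cv_results_
        ],
    }
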