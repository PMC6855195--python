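"""Multi-layer-perceptron density surrogate.

A feed-forward regressor (default two hidden layers of 100 units) trained on
standardized descriptors; the target is standardized internally for
optimizer stability and predictions are returned on the original scale.
Hyperparameters are selected by exhaustive grid search over activation,
L2 regularization strength, solver and learning-rate schedule, scored by
k-fold cross-validated squared-Pearson R2 on the training split.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPRegressor

__all__ = [
    "HyperGrid",
    "ModelSpec",
    "TrainedModel",
    "split_dataset",
    "grid_search",
    "train",
    "predict",
    "save_model",
    "load_model",
]

_BUNDLE_VERSION = "1"


@dataclass
class HyperGrid:
    """Exhaustive hyperparameter search space (4 x 5 x 2 x 3 = 120 combos
    with the defaults)."""

    activations: tuple[str, ...] = ("identity", "tanh", "relu", "logistic")
    l2_alphas: tuple[float, ...] = (0.1, 0.01, 0.001, 0.0001, 0.00001)
    solvers: tuple[str, ...] = ("sgd", "adam")
    lr_schedules: tuple[str, ...] = ("constant", "invscaling", "adaptive")

    def __post_init__(self) -> None:
        for name in ("activations", "l2_alphas", "solvers", "lr_schedules"):
            if not getattr(self, name):
                raise ValueError(f"{name} must be non-empty")

    def combinations(self):
        """Iterate (activation, alpha, solver, lr_schedule) in grid order."""
        return itertools.product(self.activations, self.l2_alphas,
                                 self.solvers, self.lr_schedules)

    def __len__(self) -> int:
        return (len(self.activations) * len(self.l2_alphas)
                * len(self.solvers) * len(self.lr_schedules))


@dataclass
class ModelSpec:
    """One fully specified model configuration.

    The defaults are the grid-search winner: relu activation, adam solver,
    adaptive learning rate, L2 alpha 1e-4, two hidden layers of 100 units.
    ``max_iter``/``tol``/``n_iter_no_change`` are generous convergence
    settings exposed for tuning.
    """

    hidden_layers: tuple[int, ...] = (100, 100)
    activation: str = "relu"
    l2_alpha: float = 0.0001
    solver: str = "adam"
    lr_schedule: str = "adaptive"
    seed: int = 0
    max_iter: int = 600
    tol: float = 1e-6
    n_iter_no_change: int = 30

    def __post_init__(self) -> None:
        if any(h < 1 for h in self.hidden_layers):
            raise ValueError("hidden layer sizes must be >= 1")

    def build(self) -> MLPRegressor:
        return MLPRegressor(hidden_layer_sizes=tuple(self.hidden_layers),
                            activation=self.activation,
                            alpha=self.l2_alpha,
                            solver=self.solver,
                            learning_rate=self.lr_schedule,
                            random_state=self.seed,
                            max_iter=self.max_iter,
                            tol=self.tol,
                            n_iter_no_change=self.n_iter_no_change)


@dataclass
class TrainedModel:
    """Fitted regressor bundled with its scaler statistics and feature names.

    Prediction is defined only for inputs whose columns match
    ``feature_names`` exactly (same names, same order); a mismatch raises
    rather than silently mispredicting.
    """

    regressor: MLPRegressor
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float
    feature_names: list[str] | None
    spec: ModelSpec
    n_train: int

    def predict(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            if self.feature_names is not None and list(X.columns) != self.feature_names:
                raise ValueError("feature columns do not match the trained model")
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            X = X.reshape(-1, len(self.x_mean)) if X.size else X.reshape(0, len(self.x_mean))
        if X.shape[0] == 0:
            return np.empty(0)
        if X.shape[1] != len(self.x_mean):
            raise ValueError(
                f"expected {len(self.x_mean)} features, got {X.shape[1]}")
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite feature values")
        z = (X - self.x_mean) / self.x_sd
        out = self.regressor.predict(z)
        return out * self.y_sd + self.y_mean


def split_dataset(n: int, train_frac: float = 0.8,
                  seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive random train/test index split,
    ``|train| = round(train_frac * n)``, reproducible under ``seed``."""
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    if not (0 < train_frac < 1):
        raise ValueError("train_frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(train_frac * n))
    n_train = min(max(n_train, 1), n - 1)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def _validate_xy(X, y) -> tuple[np.ndarray, np.ndarray, list[str] | None]:
    names = list(X.columns) if isinstance(X, pd.DataFrame) else None
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != len(y):
        raise ValueError("X must be 2-D with one row per target value")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("non-finite values in X or y")
    return X, y, names


def train(X, y, spec: ModelSpec | None = None) -> TrainedModel:
    """Fit the surrogate: standardize features and target on the training
    rows, then fit the MLP.  Reproducible given ``spec.seed``."""
    if spec is None:
        spec = ModelSpec()
    X, y, names = _validate_xy(X, y)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows to train")
    x_mean = X.mean(axis=0)
    x_sd = X.std(axis=0)
    x_sd[x_sd == 0] = 1.0  # constant features pass through as zeros
    y_mean = float(y.mean())
    y_sd = float(y.std()) or 1.0
    reg = spec.build()
    reg.fit((X - x_mean) / x_sd, (y - y_mean) / y_sd)
    return TrainedModel(regressor=reg, x_mean=x_mean, x_sd=x_sd,
                        y_mean=y_mean, y_sd=y_sd, feature_names=names,
                        spec=spec, n_train=X.shape[0])


def predict(model: TrainedModel, X) -> np.ndarray:
    """Bulk inference; one finite value per row (source = surrogate)."""
    return model.predict(X)


def _cv_r2(X, y, spec: ModelSpec, cv_folds: int, seed: int) -> float:
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    scores = []
    for tr, te in kf.split(X):
        model = train(X[tr], y[tr], spec)
        pred = model.predict(X[te])
        if np.var(pred) == 0 or np.var(y[te]) == 0:
            scores.append(0.0)
            continue
        rho = np.corrcoef(pred, y[te])[0, 1]
        scores.append(float(rho * rho))
    return float(np.mean(scores))


def grid_search(X, y, grid: HyperGrid | None = None, cv_folds: int = 5,
                seed: int = 0,
                base_spec: ModelSpec | None = None) -> ModelSpec:
    """Exhaustively score every grid combination by ``cv_folds``-fold
    cross-validated R2 and return the best spec (ties by grid order)."""
    if grid is None:
        grid = HyperGrid()
    if cv_folds < 2:
        raise ValueError("cv_folds must be >= 2")
    X, y, _ = _validate_xy(X, y)
    if np.var(y) == 0:
        raise ValueError("degenerate target: zero variance")
    if base_spec is None:
        base_spec = ModelSpec(seed=seed)
    best_spec, best_score = None, -np.inf
    for activation, alpha, solver, lr in grid.combinations():
        spec = ModelSpec(hidden_layers=base_spec.hidden_layers,
                         activation=activation, l2_alpha=alpha,
                         solver=solver, lr_schedule=lr, seed=seed,
                         max_iter=base_spec.max_iter, tol=base_spec.tol,
                         n_iter_no_change=base_spec.n_iter_no_change)
        if len(grid) == 1:
            return spec  # nothing to compare
        score = _cv_r2(X, y, spec, cv_folds, seed)
        if score > best_score:
            best_spec, best_score = spec, score
    return best_spec


def save_model(model: TrainedModel, path) -> None:
    joblib.dump({"version": _BUNDLE_VERSION, "model": model}, path)


def load_model(path) -> TrainedModel:
    bundle = joblib.load(path)
    if bundle.get("version") != _BUNDLE_VERSION:
        raise ValueError(f"unsupported model bundle version: {bundle.get('version')!r}")
    return bundle["model"]
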