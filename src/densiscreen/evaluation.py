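"""Regression metric suite, linear calibration, and the bootstrap
learning-curve protocol.

Conventions (stated in every report):

* error sign: ``e_i = pred_i - ref_i``;
* percentage metrics divide ``e_i`` by ``ref_i`` and are reported in %;
* ``r2`` is the squared Pearson correlation (so it coexists with a
  non-trivial regression slope);
* ``slope`` / ``offset`` come from ordinary least squares of the *reference
  on the prediction* — the one convention under which a least-squares
  calibrated predictor reports exactly slope 1 / offset 0 on noise-free data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, asdict, field

import numpy as np

from .surrogate import ModelSpec, train

logger = logging.getLogger(__name__)

__all__ = [
    "RegressionReport",
    "regression_report",
    "calibrate_linear",
    "LearningCurvePoint",
    "learning_curve",
    "DEFAULT_FRACTIONS",
]

#: Default learning-curve grid: 0.05% up to the full data set.
DEFAULT_FRACTIONS = (0.0005, 0.001, 0.002, 0.005, 0.01, 0.02, 0.05,
                     0.1, 0.2, 0.5, 0.8, 1.0)


@dataclass
class RegressionReport:
    """The eleven-statistic error report.

    Errors (mae, rmse, me, maxae, offset) share the unit of the inputs
    (kg m^-3 for densities); percentage metrics are in %.
    """

    r2: float
    slope: float
    offset: float
    mae: float
    mape: float
    rmse: float
    rmspe: float
    me: float
    mpe: float
    maxae: float
    maxape: float
    n: int = 0
    convention: str = "e = pred - ref; slope/offset from OLS of ref on pred; r2 = squared Pearson"

    def to_dict(self) -> dict:
        return asdict(self)


def _as_1d(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite values")
    return arr


def regression_report(pred, ref) -> RegressionReport:
    """Compute the full metric suite for predictions against a reference."""
    p, r = _as_1d(pred), _as_1d(ref)
    if len(p) != len(r):
        raise ValueError("pred and ref must have equal length")
    if len(p) < 2:
        raise ValueError("need at least 2 points")
    if np.any(r == 0):
        raise ValueError("reference contains zeros; percentage metrics undefined")
    if np.var(r) == 0:
        raise ValueError("constant reference; r2 undefined")
    e = p - r
    pe = 100.0 * e / r
    if np.var(p) == 0:
        raise ValueError("constant prediction; slope undefined")
    rho = np.corrcoef(p, r)[0, 1]
    slope = float(np.cov(p, r, ddof=1)[0, 1] / np.var(p, ddof=1))
    offset = float(r.mean() - slope * p.mean())
    return RegressionReport(
        r2=float(rho * rho),
        slope=slope,
        offset=offset,
        mae=float(np.mean(np.abs(e))),
        mape=float(np.mean(np.abs(pe))),
        rmse=float(np.sqrt(np.mean(e ** 2))),
        rmspe=float(np.sqrt(np.mean(pe ** 2))),
        me=float(np.mean(e)),
        mpe=float(np.mean(pe)),
        maxae=float(np.max(np.abs(e))),
        maxape=float(np.max(np.abs(pe))),
        n=len(p),
    )


def calibrate_linear(raw, ref) -> tuple[float, float, np.ndarray]:
    """Fit ``raw = slope * ref + offset`` by least squares and invert it.

    Returns ``(slope_fit, offset_fit, corrected)`` with
    ``corrected = (raw - offset_fit) / slope_fit``.  On noise-free linearly
    biased data the fit recovers the injected bias exactly and the corrected
    values equal the reference to machine precision.
    """
    x, y = _as_1d(ref), _as_1d(raw)
    if len(x) != len(y):
        raise ValueError("raw and ref must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points for calibration")
    if np.var(y) == 0:
        raise ValueError("constant raw values; calibration undefined")
    if np.var(x) == 0:
        raise ValueError("constant reference; calibration undefined")
    slope_fit = float(np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1))
    offset_fit = float(y.mean() - slope_fit * x.mean())
    if slope_fit == 0:
        raise ValueError("zero fitted slope; cannot invert calibration")
    corrected = (y - offset_fit) / slope_fit
    return slope_fit, offset_fit, corrected


@dataclass
class LearningCurvePoint:
    """Aggregated train/test accuracy at one training-set fraction."""

    fraction: float
    n_train: int
    mean_test_r2: float
    sd_test_r2: float
    mean_train_r2: float
    sd_train_r2: float
    n_reps: int
    train_only: bool = False  # fraction 1.0: test R2 computed on training data

    def to_dict(self) -> dict:
        return asdict(self)


def _pearson_r2(a: np.ndarray, b: np.ndarray) -> float:
    if np.var(a) == 0 or np.var(b) == 0:
        return 0.0
    rho = np.corrcoef(a, b)[0, 1]
    return float(rho * rho)


def learning_curve(X, y, fractions=DEFAULT_FRACTIONS, n_reps: int = 50,
                   seed: int = 0,
                   spec: ModelSpec | None = None) -> list[LearningCurvePoint]:
    """Bootstrap learning curve over training-set fractions.

    For each fraction and each of ``n_reps`` independent repetitions, a
    training set of ``round(fraction * n)`` rows is drawn without replacement
    (so the remainder is a valid test set), a fresh model is trained with
    ``spec``, and train/test squared-Pearson R2 are recorded.  Repetitions
    are independent re-draws; mean and sd are aggregated per fraction.
    Fraction 1.0 trains on everything and evaluates on the training rows
    only, flagged ``train_only``.
    """
    X = np.asarray(X, dtype=float)
    y = _as_1d(y)
    n = len(y)
    if X.shape[0] != n:
        raise ValueError("X and y row counts differ")
    if spec is None:
        spec = ModelSpec()
    master = np.random.default_rng(seed)
    points: list[LearningCurvePoint] = []
    for frac in fractions:
        n_train = int(round(frac * n))
        if n_train < 2:
            logger.warning("fraction %g yields %d training rows; skipped",
                           frac, n_train)
            continue
        train_only = n_train >= n
        n_train = min(n_train, n)
        train_r2s, test_r2s = [], []
        for rep in range(n_reps):
            rep_seed = int(master.integers(0, 2**31 - 1))
            rng = np.random.default_rng(rep_seed)
            idx = rng.choice(n, size=n_train, replace=False)
            mask = np.zeros(n, dtype=bool)
            mask[idx] = True
            model = train(X[mask], y[mask],
                          ModelSpec(**{**spec.__dict__, "seed": rep_seed}))
            pred_train = model.predict(X[mask])
            train_r2s.append(_pearson_r2(pred_train, y[mask]))
            if train_only:
                test_r2s.append(train_r2s[-1])
            else:
                pred_test = model.predict(X[~mask])
                test_r2s.append(_pearson_r2(pred_test, y[~mask]))
        points.append(LearningCurvePoint(
            fraction=frac, n_train=n_train,
            mean_test_r2=float(np.mean(test_r2s)),
            sd_test_r2=float(np.std(test_r2s, ddof=1)) if n_reps > 1 else 0.0,
            mean_train_r2=float(np.mean(train_r2s)),
            sd_train_r2=float(np.std(train_r2s, ddof=1)) if n_reps > 1 else 0.0,
            n_reps=n_reps, train_only=train_only))
    return points
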