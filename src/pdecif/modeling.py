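"""Gradient-boosted-tree scoring functions with resampled grid search.

The learner is XGBoost regression; three hyperparameters are tuned by
exhaustive grid search — boosting rounds, maximum tree depth and learning
rate — with every other learner setting pinned explicitly (see
``FIXED_LEARNER_PARAMS``).  Candidate settings are scored on training data
only, under one of three resampling schemes performed once without
repetition: a 70-30 train-validation split, 5-fold CV or 10-fold CV.  The
winner is the lowest mean validation RMSE (ties: fewer rounds, then
shallower trees, then lower learning rate); the final model is refit on the
full training set and reported as Pearson R and RMSE (pK units) on the
untouched test set.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted
from xgboost import XGBRegressor

logger = logging.getLogger(__name__)

DEFAULT_ROUNDS = (500, 1000, 1500, 2000)
DEFAULT_MAX_DEPTH = (2, 4, 6, 8)
DEFAULT_LEARNING_RATE = (0.001, 0.01, 0.1, 0.2, 0.3)

#: Non-searched learner settings, frozen so runs are implementation-stable.
FIXED_LEARNER_PARAMS: dict = {
    "objective": "reg:squarederror",
    "tree_method": "hist",
    "subsample": 1.0,
    "colsample_bytree": 1.0,
    "min_child_weight": 1,
    "reg_lambda": 1.0,
    "reg_alpha": 0.0,
    "gamma": 0.0,
    "n_jobs": 1,
    "verbosity": 0,
}


@dataclass(frozen=True)
class HyperparameterGrid:
    """Search grid over boosting rounds, tree depth and learning rate."""

    rounds: tuple[int, ...] = DEFAULT_ROUNDS
    max_depth: tuple[int, ...] = DEFAULT_MAX_DEPTH
    learning_rate: tuple[float, ...] = DEFAULT_LEARNING_RATE

    def __post_init__(self) -> None:
        if not (self.rounds and self.max_depth and self.learning_rate):
            raise ValueError("all grid axes must be non-empty")

    def combinations(self) -> list[dict]:
        """All grid points, in tie-break order (rounds, depth, rate)."""
        return [
            {"rounds": r, "max_depth": d, "learning_rate": lr}
            for r, d, lr in product(
                sorted(self.rounds), sorted(self.max_depth), sorted(self.learning_rate)
            )
        ]

    def __len__(self) -> int:
        return len(self.rounds) * len(self.max_depth) * len(self.learning_rate)


@dataclass(frozen=True)
class ResamplingSpec:
    """How hyperparameter candidates are scored: one 70-30 split or k-fold CV.

    Performed once, without repetition; a single seed drives the shuffling.
    """

    kind: str = "split"  # "split" or "kfold"
    holdout_fraction: float = 0.30
    k: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("split", "kfold"):
            raise ValueError(f"kind must be 'split' or 'kfold', got {self.kind!r}")
        if not 0 < self.holdout_fraction < 1:
            raise ValueError("holdout fraction must be in (0, 1)")
        if self.kind == "kfold" and self.k < 2:
            raise ValueError("k must be >= 2")


@dataclass(frozen=True)
class ModelMetrics:
    """Pearson correlation and root-mean-square error on a held-out set."""

    pearson_r: float
    rmse: float
    pearson_defined: bool = True


def make_resamples(n_samples: int, spec: ResamplingSpec) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic (train, validation) index pairs for a resampling spec.

    The split kind yields one pair with ceil((1 - holdout) * n) training
    samples; k-fold yields k pairs whose validation blocks partition the set.
    """
    if n_samples < 10:
        raise ValueError(f"need at least 10 samples, got {n_samples}")
    if spec.kind == "split":
        rng = np.random.RandomState(spec.seed)
        order = rng.permutation(n_samples)
        n_train = int(math.ceil((1.0 - spec.holdout_fraction) * n_samples))
        return [(np.sort(order[:n_train]), np.sort(order[n_train:]))]
    if spec.k > n_samples:
        raise ValueError(f"k={spec.k} exceeds n_samples={n_samples}")
    folds = KFold(n_splits=spec.k, shuffle=True, random_state=spec.seed)
    return [(tr, va) for tr, va in folds.split(np.arange(n_samples))]


def _make_learner(params: dict, seed: int) -> XGBRegressor:
    return XGBRegressor(
        n_estimators=int(params["rounds"]),
        max_depth=int(params["max_depth"]),
        learning_rate=float(params["learning_rate"]),
        random_state=seed,
        **FIXED_LEARNER_PARAMS,
    )


def evaluate_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> ModelMetrics:
    """Pearson R (flagged undefined for constant inputs) and RMSE."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1 or y_true.size < 3:
        raise ValueError("predictions and labels must be 1-D, equal length >= 3")
    rmse = float(np.sqrt(np.mean((y_true - y_pred) ** 2)))
    if np.std(y_pred) == 0 or np.std(y_true) == 0:
        return ModelMetrics(pearson_r=float("nan"), rmse=rmse, pearson_defined=False)
    r = float(stats.pearsonr(y_true, y_pred).statistic)
    return ModelMetrics(pearson_r=r, rmse=rmse)


def grid_search(
    X,
    y,
    grid: HyperparameterGrid | None = None,
    spec: ResamplingSpec | None = None,
) -> tuple[dict, pd.DataFrame]:
    """Exhaustively score every grid point under the resampling spec.

    Returns the winning parameters (lowest mean validation RMSE; ties broken
    by fewer rounds, then shallower depth, then lower learning rate — the
    order in which ``combinations()`` enumerates) and the full results table
    with per-point mean validation R and RMSE.
    """
    grid = grid if grid is not None else HyperparameterGrid()
    spec = spec if spec is not None else ResamplingSpec()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.std(y) == 0:
        raise ValueError("degenerate target: zero variance")
    resamples = make_resamples(len(y), spec)
    records = []
    for params in grid.combinations():
        fold_rmse, fold_r = [], []
        for train_idx, valid_idx in resamples:
            learner = _make_learner(params, spec.seed)
            learner.fit(X[train_idx], y[train_idx])
            metrics = evaluate_predictions(y[valid_idx], learner.predict(X[valid_idx]))
            fold_rmse.append(metrics.rmse)
            fold_r.append(metrics.pearson_r)
        records.append(
            {
                **params,
                "mean_valid_rmse": float(np.mean(fold_rmse)),
                "mean_valid_r": float(np.mean(fold_r)),
            }
        )
    results = pd.DataFrame.from_records(records)
    best_pos = int(results["mean_valid_rmse"].to_numpy().argmin())  # first minimum
    best = {k: records[best_pos][k] for k in ("rounds", "max_depth", "learning_rate")}
    return best, results


def train_final_and_evaluate(
    X_train, y_train, best_params: dict, X_test, y_test, seed: int = 0
) -> ModelMetrics:
    """Refit on the full training set with the winning parameters; score test."""
    learner = _make_learner(best_params, seed)
    learner.fit(np.asarray(X_train, dtype=float), np.asarray(y_train, dtype=float))
    return evaluate_predictions(
        np.asarray(y_test, dtype=float), learner.predict(np.asarray(X_test, dtype=float))
    )


class GradientBoostedScorer(BaseEstimator, RegressorMixin):
    """Scoring-function regressor with built-in resampled grid search.

    ``fit`` runs the grid search on the training data under the configured
    resampling scheme, then refits the winning model on all of it.  Fitted
    attributes: ``best_params_``, ``cv_results_``, ``model_``.
    """

    def __init__(
        self,
        rounds: tuple[int, ...] = DEFAULT_ROUNDS,
        max_depth: tuple[int, ...] = DEFAULT_MAX_DEPTH,
        learning_rate: tuple[float, ...] = DEFAULT_LEARNING_RATE,
        resampling: str = "split",
        k: int = 5,
        seed: int = 0,
    ):
        self.rounds = rounds
        self.max_depth = max_depth
        self.learning_rate = learning_rate
        self.resampling = resampling
        self.k = k
        self.seed = seed

    def _grid(self) -> HyperparameterGrid:
        return HyperparameterGrid(
            rounds=tuple(self.rounds),
            max_depth=tuple(self.max_depth),
            learning_rate=tuple(self.learning_rate),
        )

    def _spec(self) -> ResamplingSpec:
        if self.resampling == "split":
            return ResamplingSpec(kind="split", seed=self.seed)
        return ResamplingSpec(kind="kfold", k=self.k, seed=self.seed)

    def fit(self, X, y) -> "GradientBoostedScorer":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        self.best_params_, self.cv_results_ = grid_search(X, y, self._grid(), self._spec())
        self.model_ = _make_learner(self.best_params_, self.seed)
        self.model_.fit(X, y)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        return self.model_.predict(np.asarray(X, dtype=float))

    def evaluate(self, X_test, y_test) -> ModelMetrics:
        """Pearson R and RMSE of the refit model on a held-out set."""
        return evaluate_predictions(np.asarray(y_test, dtype=float), self.predict(X_test))
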