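"""Boruta all-relevant feature selection with a random-forest backend.

Each run appends a shuffled "shadow" copy of every original feature to the
design matrix, fits a random-forest regressor, and records a *hit* for each
real feature whose importance exceeds the maximum importance among the
shadows.  After every run a two-sided binomial test against the p = 0.5
null, Bonferroni-corrected over the full feature count, promotes features
with significantly many hits to *confirmed* and demotes features with
significantly few to *rejected*.  The loop stops when everything is
decided or after ``max_runs`` runs; what remains is reported *tentative*,
never force-resolved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestRegressor
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

CONFIRMED = "confirmed"
REJECTED = "rejected"
TENTATIVE = "tentative"


@dataclass(frozen=True)
class BorutaConfig:
    """Knobs of the Boruta loop.

    ``max_runs`` bounds the number of forest fits (default 500), ``alpha``
    is the significance level of the binomial decision test (default 0.01),
    and ``n_trees`` the forest size per run.
    """

    max_runs: int = 500
    alpha: float = 0.01
    n_trees: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_runs < 1:
            raise ValueError("max_runs must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class BorutaResult:
    """Per-feature outcome of a Boruta run."""

    statuses: pd.Series  # confirmed / rejected / tentative per feature
    hits: pd.Series  # shadow-beating counts per feature
    mean_importances: pd.Series
    n_runs: int
    decision_runs: pd.Series | None = None  # run at which each decision fell (0 = none)

    def features(self, status: str) -> list[str]:
        return list(self.statuses.index[self.statuses == status])

    @property
    def confirmed(self) -> list[str]:
        return self.features(CONFIRMED)

    @property
    def rejected(self) -> list[str]:
        return self.features(REJECTED)

    @property
    def tentative(self) -> list[str]:
        return self.features(TENTATIVE)


def boruta_select(X, y, config: BorutaConfig | None = None) -> BorutaResult:
    """Run the Boruta loop on a feature matrix and regression target."""
    config = config if config is not None else BorutaConfig()
    frame = pd.DataFrame(X)
    names = [str(c) for c in frame.columns]
    Xv = frame.to_numpy(dtype=float)
    yv = np.asarray(y, dtype=float)
    n, p = Xv.shape
    if n < 5:
        raise ValueError(f"need at least 5 samples, got {n}")
    if not (np.all(np.isfinite(Xv)) and np.all(np.isfinite(yv))):
        raise ValueError("X and y must be finite")

    rng = np.random.RandomState(config.seed)
    status = np.array([TENTATIVE] * p, dtype=object)
    hits = np.zeros(p, dtype=int)
    decision_run = np.zeros(p, dtype=int)  # 0 = still tentative at the end
    importance_sum = np.zeros(p, dtype=float)
    n_runs = 0

    for run in range(config.max_runs):
        undecided = status == TENTATIVE
        if not undecided.any():
            break
        # Rejected features leave the model; confirmed ones stay in it but
        # are no longer tested.  Shadows are fresh shuffles of *all* original
        # features every run, so the max-shadow bar keeps reflecting the
        # original null spread even after most features are rejected.
        model_mask = status != REJECTED
        model_idx = np.flatnonzero(model_mask)
        undecided_idx = np.flatnonzero(undecided)
        shadows = Xv.copy()
        for j in range(shadows.shape[1]):
            rng.shuffle(shadows[:, j])
        design = np.hstack([Xv[:, model_idx], shadows])
        forest = RandomForestRegressor(
            n_estimators=config.n_trees,
            random_state=rng.randint(0, 2**31 - 1),
            n_jobs=1,
        )
        forest.fit(design, yv)
        importances = forest.feature_importances_
        real_imp = importances[: len(model_idx)]
        shadow_max = importances[len(model_idx) :].max()
        importance_sum[model_idx] += real_imp
        n_runs = run + 1

        position = {fi: k for k, fi in enumerate(model_idx)}
        for fi in undecided_idx:
            if real_imp[position[fi]] > shadow_max:
                hits[fi] += 1

        # Bonferroni over the full feature count, held constant across runs.
        for fi in undecided_idx:
            test = stats.binomtest(int(hits[fi]), n_runs, p=0.5, alternative="two-sided")
            if test.pvalue * p < config.alpha:
                status[fi] = CONFIRMED if hits[fi] > n_runs / 2 else REJECTED
                decision_run[fi] = n_runs

    mean_imp = np.where(n_runs > 0, importance_sum / max(n_runs, 1), 0.0)
    logger.info(
        "boruta: %d runs, %d confirmed / %d rejected / %d tentative of %d features",
        n_runs,
        int((status == CONFIRMED).sum()),
        int((status == REJECTED).sum()),
        int((status == TENTATIVE).sum()),
        p,
    )
    return BorutaResult(
        statuses=pd.Series(status, index=names),
        hits=pd.Series(hits, index=names),
        mean_importances=pd.Series(mean_imp, index=names),
        n_runs=n_runs,
        decision_runs=pd.Series(decision_run, index=names),
    )


class BorutaSelector(SelectorMixin, BaseEstimator):
    """sklearn-style selector keeping the Boruta-confirmed features.

    ``fit`` exposes ``result_`` (full statuses/hits) and ``support_``; the
    ``transform`` inherited from :class:`SelectorMixin` projects onto the
    confirmed features.  ``keep_tentative=True`` additionally retains
    features left undecided at ``max_runs``.
    """

    def __init__(
        self,
        max_runs: int = 500,
        alpha: float = 0.01,
        n_trees: int = 500,
        seed: int = 0,
        keep_tentative: bool = False,
    ):
        self.max_runs = max_runs
        self.alpha = alpha
        self.n_trees = n_trees
        self.seed = seed
        self.keep_tentative = keep_tentative

    def fit(self, X, y) -> "BorutaSelector":
        frame = pd.DataFrame(X)
        self.result_ = boruta_select(
            frame,
            y,
            BorutaConfig(
                max_runs=self.max_runs, alpha=self.alpha, n_trees=self.n_trees, seed=self.seed
            ),
        )
        keep = {CONFIRMED, TENTATIVE} if self.keep_tentative else {CONFIRMED}
        self.support_ = self.result_.statuses.isin(keep).to_numpy()
        self.n_features_in_ = frame.shape[1]
        self.feature_names_in_ = np.asarray([str(c) for c in frame.columns], dtype=object)
        return self

    def _get_support_mask(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_
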