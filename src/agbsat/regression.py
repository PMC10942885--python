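"""Random-forest regression of biomass on spectral features.

Implements the evaluation protocol used throughout the package: a
regression forest (ntree trees, mtry = floor(sqrt(p)) candidate
predictors per split), out-of-bag (OOB) permutation importance in the
%IncMSE style, backward feature elimination driven by that importance
with 10-fold cross-validated RMSE per model size, a top-k "optimal"
model, and pooled out-of-fold R2 / RMSE averaged over repeated runs.

OOB permutation importance: for every tree, predictions on its own
out-of-bag samples are compared before and after permuting one feature;
the mean MSE increase across trees, expressed as a percentage of the
OOB MSE, is the feature's importance.  sklearn's forest is the tree
engine; the OOB bookkeeping is done here since sklearn only offers
permutation importance on a fixed validation set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.ensemble._forest import (
    _generate_unsampled_indices,
    _get_n_samples_bootstrap,
)
from sklearn.model_selection import KFold

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelConfig:
    """Forest and evaluation settings.

    ``mtry`` defaults to floor(sqrt(p)) at fit time when left None.
    """

    ntree: int = 1000
    mtry: int | None = None
    n_repeats: int = 100
    train_fraction: float = 0.70
    cv_folds: int = 10
    top_k: int = 3
    base_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be at least 2")
        if self.ntree < 1 or self.n_repeats < 1 or self.top_k < 1:
            raise ValueError("ntree, n_repeats, top_k must be positive")

    def resolved_mtry(self, p: int) -> int:
        if self.mtry is not None:
            return min(self.mtry, p)
        return max(1, int(np.floor(np.sqrt(p))))


@dataclass
class FitResult:
    model: RandomForestRegressor
    importance: pd.Series  # %IncMSE per feature
    oob_mse: float


@dataclass
class EliminationStep:
    variables: list[str]
    cv_rmse: float
    importance: pd.Series


@dataclass
class EliminationTrace:
    steps: list[EliminationStep]

    @property
    def selected(self) -> EliminationStep:
        """Step minimizing CV RMSE; ties resolved toward the smaller set."""
        return min(self.steps, key=lambda s: (s.cv_rmse, len(s.variables)))


@dataclass
class EvaluationResult:
    """Reporting surface for one (variable group, enhancement variant)."""

    group: str
    variant: str
    r2: float
    rmse: float
    importance: pd.Series
    selected: list[str] = field(default_factory=list)
    predictions: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.rmse < 0:
            raise ValueError("RMSE cannot be negative")
        if self.r2 > 1 + 1e-12:
            raise ValueError("R2 cannot exceed 1")


def rmse(pred, obs) -> float:
    """Root mean squared prediction error, in the units of ``obs``."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.size == 0:
        raise ValueError("pred and obs must be equal-length and non-empty")
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def r_squared(pred, obs) -> float:
    """1 - SSE/SST; undefined (error) when obs has zero variance."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.size < 2:
        raise ValueError("pred and obs must be equal-length, length >= 2")
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0:
        raise ValueError("R2 undefined: observations have zero variance")
    return 1.0 - float(np.sum((obs - pred) ** 2)) / sst


def split(index, train_fraction: float = 0.70, seed: int = 0):
    """Seeded 70/30-style shuffle split; train size = floor(fraction * n)."""
    ids = np.asarray(index)
    n = len(ids)
    n_train = int(np.floor(train_fraction * n))
    if n < 2 or n_train < 1 or n_train >= n:
        raise ValueError(f"degenerate split sizes for n={n}")
    perm = np.random.default_rng(seed).permutation(n)
    return ids[perm[:n_train]], ids[perm[n_train:]]


def _as_xy(X, y) -> tuple[pd.DataFrame, np.ndarray]:
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    if X.isna().any().any() or not np.all(np.isfinite(y)):
        raise ValueError("features and response must be finite, no missing cells")
    if X.shape[1] == 0:
        raise ValueError("no features")
    if X.shape[0] != len(y):
        raise ValueError("feature rows must match response length")
    return X, y


def _make_forest(p: int, config: ModelConfig, seed: int) -> RandomForestRegressor:
    return RandomForestRegressor(
        n_estimators=config.ntree,
        max_features=config.resolved_mtry(p),
        bootstrap=True,
        random_state=int(seed) % (2**31),
        n_jobs=1,
    )


def _oob_importance(
    forest: RandomForestRegressor,
    Xv: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    """Per-feature %IncMSE from OOB permutation, and the OOB MSE."""
    n, p = Xv.shape
    try:
        nb = _get_n_samples_bootstrap(n, forest.max_samples, None)
    except TypeError:  # older sklearn without the sample_weight argument
        nb = _get_n_samples_bootstrap(n, forest.max_samples)
    delta = np.zeros(p)
    used = 0
    base_mses = []
    for tree in forest.estimators_:
        try:
            oob = _generate_unsampled_indices(tree.random_state, n, nb, None)
        except TypeError:
            oob = _generate_unsampled_indices(tree.random_state, n, nb)
        if len(oob) < 2:
            continue
        Xo = Xv[oob]
        yo = y[oob]
        k = len(oob)
        base = float(np.mean((yo - tree.predict(Xo)) ** 2))
        stacked = np.repeat(Xo[None, :, :], p, axis=0)
        for j in range(p):
            stacked[j, :, j] = Xo[rng.permutation(k), j]
        preds = tree.predict(stacked.reshape(p * k, p)).reshape(p, k)
        delta += np.mean((yo[None, :] - preds) ** 2, axis=1) - base
        base_mses.append(base)
        used += 1
    if used == 0:
        raise ValueError("no tree had enough OOB samples for importance")
    oob_mse = float(np.mean(base_mses))
    imp = 100.0 * (delta / used) / max(oob_mse, 1e-12)
    return imp, oob_mse


def fit_forest(X, y, config: ModelConfig, seed: int = 0) -> FitResult:
    """Fit the forest and compute OOB permutation importance."""
    X, y = _as_xy(X, y)
    forest = _make_forest(X.shape[1], config, seed)
    Xv = X.to_numpy(dtype=float)
    forest.fit(Xv, y)
    rng = np.random.default_rng(seed + 1)
    imp, oob_mse = _oob_importance(forest, Xv, y, rng)
    return FitResult(
        forest, pd.Series(imp, index=X.columns, name="pct_inc_mse"), oob_mse
    )


def cv_predict(X, y, config: ModelConfig, seed: int = 0) -> pd.Series:
    """Pooled out-of-fold predictions from seeded k-fold CV."""
    X, y = _as_xy(X, y)
    kf = KFold(
        n_splits=min(config.cv_folds, len(y)),
        shuffle=True,
        random_state=int(seed) % (2**31),
    )
    pred = np.empty(len(y))
    Xv = X.to_numpy(dtype=float)
    for f, (tr, te) in enumerate(kf.split(Xv)):
        forest = _make_forest(X.shape[1], config, seed * 1009 + f)
        forest.fit(Xv[tr], y[tr])
        pred[te] = forest.predict(Xv[te])
    return pd.Series(pred, index=X.index, name="cv_prediction")


def cv_metrics(X, y, config: ModelConfig, seed: int = 0):
    """(R2, RMSE, pooled predictions) from one seeded k-fold CV pass."""
    pred = cv_predict(X, y, config, seed)
    y = np.asarray(y, dtype=float)
    return r_squared(pred.to_numpy(), y), rmse(pred.to_numpy(), y), pred


def backward_eliminate(
    X, y, config: ModelConfig, seed: int = 0
) -> EliminationTrace:
    """Iteratively drop the least important variable, tracking CV RMSE.

    Each round refits the forest on the surviving variables, records the
    10-fold CV RMSE at that size, then removes the variable with the
    lowest OOB importance.  The trace has one step per size from p down
    to 1; ``trace.selected`` is the CV-RMSE argmin (ties -> smaller set).
    """
    X, y = _as_xy(X, y)
    if X.shape[1] < 2:
        raise ValueError("backward elimination needs at least 2 features")
    cols = list(X.columns)
    steps: list[EliminationStep] = []
    round_no = 0
    while cols:
        fit = fit_forest(X[cols], y, config, seed=seed + 7919 * round_no)
        _, cv_rmse, _ = cv_metrics(
            X[cols], y, config, seed=seed + 7919 * round_no + 1
        )
        steps.append(EliminationStep(cols.copy(), cv_rmse, fit.importance))
        if len(cols) == 1:
            break
        cols.remove(fit.importance.idxmin())
        round_no += 1
    return EliminationTrace(steps)


def mean_importance(X, y, config: ModelConfig) -> pd.Series:
    """OOB importance averaged over ``n_repeats`` seeded refits."""
    X, y = _as_xy(X, y)
    total = None
    for r in range(config.n_repeats):
        fit = fit_forest(X, y, config, seed=config.base_seed + 104729 * r)
        total = fit.importance if total is None else total + fit.importance
    return total / config.n_repeats


def evaluate_group(
    X, y, config: ModelConfig, group: str = "", variant: str = ""
) -> EvaluationResult:
    """Repeated k-fold CV of a fixed feature set; metrics averaged over
    repeats, predictions pooled and averaged."""
    X, y = _as_xy(X, y)
    r2s, rmses, preds = [], [], []
    imp = None
    for r in range(config.n_repeats):
        s = config.base_seed + 104729 * r
        r2, rm, pred = cv_metrics(X, y, config, seed=s)
        fit = fit_forest(X, y, config, seed=s)
        imp = fit.importance if imp is None else imp + fit.importance
        r2s.append(r2)
        rmses.append(rm)
        preds.append(pred)
    return EvaluationResult(
        group=group,
        variant=variant,
        r2=float(np.mean(r2s)),
        rmse=float(np.mean(rmses)),
        importance=imp / config.n_repeats,
        selected=list(X.columns),
        predictions=sum(preds) / len(preds),
    )


def evaluate_optimal(
    X, y, config: ModelConfig, group: str = "optimal", variant: str = ""
) -> EvaluationResult:
    """Top-k model: rank by mean OOB importance over repeats, keep the
    ``top_k`` best, then evaluate that restricted set by repeated CV."""
    X, y = _as_xy(X, y)
    if X.shape[1] < config.top_k:
        raise ValueError("need at least top_k features")
    imp = mean_importance(X, y, config)
    top = list(imp.sort_values(ascending=False).index[: config.top_k])
    result = evaluate_group(X[top], y, config, group=group, variant=variant)
    result.importance = imp
    result.selected = top
    return result
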