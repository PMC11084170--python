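"""Age-prediction clocks: random forests on heterogeneity scores, LASSO on
window methylation, and recursive feature elimination.

Feature matrices are oriented loci/windows x samples (rows are features),
matching the score assembler; they are transposed internally for sklearn.
Test samples never influence imputation, hyperparameter selection, or
fitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import GridSearchCV, KFold, cross_val_predict

__all__ = [
    "ClockModel",
    "ClockEvaluation",
    "ClockFit",
    "DEFAULT_RF_GRID",
    "split_train_test",
    "evaluate_clock",
    "fit_wsh_rf_clock",
    "fit_region_lasso_clock",
    "rfe_curve",
]

logger = logging.getLogger(__name__)

DEFAULT_RF_GRID: dict[str, list] = {
    "n_estimators": [200, 500],
    "max_depth": [None, 5, 10],
    "min_samples_leaf": [1, 3, 5],
}

DEFAULT_LASSO_ALPHAS = np.logspace(-4, 1, 60)


@dataclass
class ClockModel:
    """A fitted age predictor with its features and provenance."""

    family: str  # "RF" | "LASSO"
    features: list[str]
    hyperparameters: dict
    train_samples: list[str]
    seed: int
    coefficients: Optional[dict[str, float]] = None  # LASSO
    intercept: Optional[float] = None
    importances: Optional[dict[str, float]] = None  # RF
    estimator: object = field(default=None, repr=False)
    imputation: Optional[dict[str, float]] = None

    @property
    def n_nonzero(self) -> Optional[int]:
        if self.coefficients is None:
            return None
        return int(sum(1 for v in self.coefficients.values() if v != 0.0))

    def to_dict(self) -> dict:
        out = {
            "family": self.family,
            "features": self.features,
            "hyperparameters": {k: (None if v is None else v) for k, v in self.hyperparameters.items()},
            "train_samples": self.train_samples,
            "seed": self.seed,
        }
        if self.coefficients is not None:
            out["coefficients"] = self.coefficients
            out["intercept"] = self.intercept
            out["n_nonzero"] = self.n_nonzero
        if self.importances is not None:
            out["importances"] = self.importances
        return out


@dataclass
class ClockEvaluation:
    """R^2 / MAE of predictions against true ages (years)."""

    r2: float
    mae: float
    r2_correlation: float  # squared Pearson correlation, reported alongside
    true_ages: list[float]
    predicted_ages: list[float]
    sample_ids: list[str] = field(default_factory=list)

    def to_dict(self, include_predictions: bool = True) -> dict:
        out = {"r2": self.r2, "mae": self.mae, "r2_correlation": self.r2_correlation}
        if include_predictions:
            out["sample_ids"] = self.sample_ids
            out["true_ages"] = self.true_ages
            out["predicted_ages"] = self.predicted_ages
        return out


@dataclass
class ClockFit:
    """Bundle returned by the fit_* functions."""

    model: ClockModel
    cv_evaluation: ClockEvaluation
    test_evaluation: ClockEvaluation
    train_evaluation: Optional[ClockEvaluation] = None

    def __iter__(self):
        return iter((self.model, self.cv_evaluation, self.test_evaluation))


def split_train_test(
    sample_ids: Sequence[str], fraction: float = 0.8, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Deterministic disjoint+exhaustive split; ``fraction`` goes to train."""
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    ids = list(sample_ids)
    if len(ids) < 5:
        raise ValueError("need at least 5 samples to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n_train = int(round(len(ids) * fraction))
    n_train = min(max(n_train, 1), len(ids) - 1)
    train = sorted(ids[i] for i in order[:n_train])
    test = sorted(ids[i] for i in order[n_train:])
    return train, test


def evaluate_clock(
    true_ages: Sequence[float],
    predicted_ages: Sequence[float],
    sample_ids: Optional[Sequence[str]] = None,
) -> ClockEvaluation:
    """Coefficient of determination and mean absolute error in years."""
    y = np.asarray(true_ages, dtype=float)
    yhat = np.asarray(predicted_ages, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError("true and predicted ages must be equal-length 1-D")
    if y.size < 2:
        raise ValueError("need >= 2 samples to evaluate")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("true ages have zero variance; R^2 undefined")
    ss_res = float(np.sum((y - yhat) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    mae = float(np.mean(np.abs(y - yhat)))
    if np.std(yhat) > 0:
        r2_corr = float(np.corrcoef(y, yhat)[0, 1] ** 2)
    else:
        r2_corr = 0.0
    return ClockEvaluation(
        r2=float(r2),
        mae=mae,
        r2_correlation=r2_corr,
        true_ages=y.tolist(),
        predicted_ages=yhat.tolist(),
        sample_ids=list(sample_ids) if sample_ids is not None else [],
    )


def _design(
    matrix: pd.DataFrame,
    ages: pd.Series,
    train: list[str],
    test: list[str],
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray, np.ndarray, dict[str, float]]:
    """Transpose to samples x features and impute NAs with train-only medians."""
    X = matrix.T
    X_train = X.loc[train].copy()
    X_test = X.loc[test].copy()
    medians = X_train.median(axis=0, skipna=True)
    usable = medians.notna()
    if not usable.all():
        dropped = medians.index[~usable].tolist()
        logger.info("dropping %d features with no training data", len(dropped))
        X_train = X_train.loc[:, usable]
        X_test = X_test.loc[:, usable]
        medians = medians[usable]
    X_train = X_train.fillna(medians)
    X_test = X_test.fillna(medians)
    y_train = ages.reindex(train).to_numpy(dtype=float)
    y_test = ages.reindex(test).to_numpy(dtype=float)
    return X_train, X_test, y_train, y_test, medians.to_dict()


def fit_wsh_rf_clock(
    matrix: pd.DataFrame,
    ages: pd.Series,
    seed: int = 0,
    test_fraction_train: float = 0.8,
    param_grid: Optional[dict] = None,
    cv_folds: int = 5,
    stability_iterations: int = 5,
    stability_folds: int = 10,
    split: Optional[tuple[list[str], list[str]]] = None,
) -> ClockFit:
    """Random-forest clock on a heterogeneity-score feature matrix.

    Hyperparameters are grid-searched by ``cv_folds``-fold CV on the train
    split (scoring MAE); stability is estimated by ``stability_iterations``
    rounds of ``stability_folds``-fold CV with the winning hyperparameters;
    the final model is refit on the full train split and evaluated on the
    untouched test split.
    """
    if matrix.shape[0] < 2:
        raise ValueError(
            "fewer than 2 features; relax the correlation threshold to admit more loci"
        )
    train, test = split if split is not None else split_train_test(
        matrix.columns, test_fraction_train, seed
    )
    X_train, X_test, y_train, y_test, medians = _design(matrix, ages, train, test)
    grid = param_grid if param_grid is not None else DEFAULT_RF_GRID

    search = GridSearchCV(
        RandomForestRegressor(random_state=seed),
        grid,
        cv=KFold(cv_folds, shuffle=True, random_state=seed),
        scoring="neg_mean_absolute_error",
        n_jobs=None,
    )
    search.fit(X_train, y_train)
    best_params = search.best_params_

    # stability: repeated K-fold CV with the winning hyperparameters
    cv_r2, cv_mae, cv_r2c = [], [], []
    pred_accum = np.zeros(len(train))
    for it in range(stability_iterations):
        est = RandomForestRegressor(random_state=seed + it, **best_params)
        folds = KFold(stability_folds, shuffle=True, random_state=seed + it)
        preds = cross_val_predict(est, X_train, y_train, cv=folds)
        ev = evaluate_clock(y_train, preds, train)
        cv_r2.append(ev.r2)
        cv_mae.append(ev.mae)
        cv_r2c.append(ev.r2_correlation)
        pred_accum += preds
    cv_eval = ClockEvaluation(
        r2=float(np.mean(cv_r2)),
        mae=float(np.mean(cv_mae)),
        r2_correlation=float(np.mean(cv_r2c)),
        true_ages=y_train.tolist(),
        predicted_ages=(pred_accum / stability_iterations).tolist(),
        sample_ids=list(train),
    )

    final = RandomForestRegressor(random_state=seed, **best_params)
    final.fit(X_train, y_train)
    test_eval = evaluate_clock(y_test, final.predict(X_test), test)
    train_eval = evaluate_clock(y_train, final.predict(X_train), train)

    model = ClockModel(
        family="RF",
        features=list(X_train.columns),
        hyperparameters=best_params,
        train_samples=list(train),
        seed=seed,
        importances=dict(zip(X_train.columns, final.feature_importances_.tolist())),
        estimator=final,
        imputation=medians,
    )
    return ClockFit(model, cv_eval, test_eval, train_eval)


def fit_region_lasso_clock(
    matrix: pd.DataFrame,
    ages: pd.Series,
    seed: int = 0,
    test_fraction_train: float = 0.8,
    alphas: Optional[np.ndarray] = None,
    cv_folds: int = 10,
    split: Optional[tuple[list[str], list[str]]] = None,
) -> ClockFit:
    """LASSO clock on a window-methylation feature matrix.

    The alpha is chosen on a log-spaced grid by ``cv_folds``-fold CV on the
    train split, the model is refit on the full train split, and the count
    of non-zero coefficients is reported.
    """
    if matrix.shape[0] < 1:
        raise ValueError("no features in matrix")
    train, test = split if split is not None else split_train_test(
        matrix.columns, test_fraction_train, seed
    )
    X_train, X_test, y_train, y_test, medians = _design(matrix, ages, train, test)
    alpha_grid = np.asarray(alphas if alphas is not None else DEFAULT_LASSO_ALPHAS, dtype=float)

    folds = KFold(cv_folds, shuffle=True, random_state=seed)
    search = LassoCV(alphas=alpha_grid, cv=folds, max_iter=200_000, random_state=seed)
    search.fit(X_train, y_train)
    best_alpha = float(search.alpha_)

    final = Lasso(alpha=best_alpha, max_iter=200_000)
    final.fit(X_train, y_train)
    if not np.any(final.coef_ != 0.0):
        raise ValueError(
            "all coefficients zero at every alpha; extend the alpha grid downwards"
        )

    cv_preds = cross_val_predict(Lasso(alpha=best_alpha, max_iter=200_000), X_train, y_train, cv=folds)
    cv_eval = evaluate_clock(y_train, cv_preds, train)
    test_eval = evaluate_clock(y_test, final.predict(X_test), test)
    train_eval = evaluate_clock(y_train, final.predict(X_train), train)

    model = ClockModel(
        family="LASSO",
        features=list(X_train.columns),
        hyperparameters={"alpha": best_alpha},
        train_samples=list(train),
        seed=seed,
        coefficients=dict(zip(X_train.columns, final.coef_.tolist())),
        intercept=float(final.intercept_),
        estimator=final,
        imputation=medians,
    )
    return ClockFit(model, cv_eval, test_eval, train_eval)


def _make_estimator(family: str, hyperparameters: dict, seed: int):
    if family == "LASSO":
        return Lasso(alpha=hyperparameters.get("alpha", 0.01), max_iter=200_000)
    if family == "RF":
        params = {k: v for k, v in hyperparameters.items() if k != "alpha"}
        return RandomForestRegressor(random_state=seed, **params)
    raise ValueError(f"unknown family {family!r}")


def _feature_ranks(estimator) -> np.ndarray:
    if hasattr(estimator, "coef_"):
        return np.abs(np.asarray(estimator.coef_, dtype=float))
    return np.asarray(estimator.feature_importances_, dtype=float)


def rfe_curve(
    matrix: pd.DataFrame,
    ages: pd.Series,
    features: Optional[Sequence[str]] = None,
    family: str = "LASSO",
    hyperparameters: Optional[dict] = None,
    seed: int = 0,
    tol: float = 0.05,
    split: Optional[tuple[list[str], list[str]]] = None,
    test_fraction_train: float = 0.8,
) -> tuple[pd.DataFrame, list[str]]:
    """Recursive feature elimination with per-step test evaluation.

    Starting from ``features`` (default: all matrix rows) the least
    important feature (smallest refit |coefficient| or importance) is
    removed one at a time, retraining on the fixed train split and
    evaluating on the fixed test split at every size k down to 1. The
    minimal set is the smallest k whose test MAE is at most (1 + tol)
    times the full-model test MAE.

    Returns (curve frame with one row per k, minimal feature list).
    """
    current = list(features) if features is not None else list(matrix.index)
    if not current:
        raise ValueError("empty starting feature set")
    missing = [f for f in current if f not in matrix.index]
    if missing:
        raise ValueError(f"features absent from matrix: {missing[:5]}")
    hyperparameters = dict(hyperparameters or {})
    train, test = split if split is not None else split_train_test(
        matrix.columns, test_fraction_train, seed
    )
    rows = []
    sets: dict[int, list[str]] = {}
    while current:
        sub = matrix.loc[current]
        X_train, X_test, y_train, y_test, _ = _design(sub, ages, train, test)
        est = _make_estimator(family, hyperparameters, seed)
        est.fit(X_train, y_train)
        ev = evaluate_clock(y_test, est.predict(X_test), test)
        rows.append(
            {"k": len(current), "test_r2": ev.r2, "test_mae": ev.mae, "features": ",".join(current)}
        )
        sets[len(current)] = list(current)
        if len(current) == 1:
            break
        ranks = _feature_ranks(est)
        drop_idx = int(np.argmin(ranks))
        current.pop(drop_idx)
    curve = pd.DataFrame(rows).sort_values("k").reset_index(drop=True)
    full_mae = float(curve.loc[curve["k"].idxmax(), "test_mae"])
    threshold = (1.0 + tol) * full_mae
    eligible = curve[curve["test_mae"] <= threshold]
    minimal_k = int(eligible["k"].min())
    return curve, sets[minimal_k]
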