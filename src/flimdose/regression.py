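"""Regression model suite and evaluation protocol.

Four standard regressors — ordinary least squares (``Lin``), ridge
(``Rid``), random forest (``For``) and gradient-boosted trees (``GBR``) —
evaluated with a seeded repeated stratified K-fold protocol: the data are
split 80/20 into a cross-validation pool and a held-out test set, the
pool is cut into K folds stratified on the binned continuous target, and
the fold scoring (R² and MAE) is repeated with reshuffling.  Predictions
are clipped at zero, since concentrations, exposure times and dosages are
physically non-negative.  Feature relevance is read off the forest's
Gini importances (mean decrease in impurity, normalized to sum to one).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import LinearRegression, Ridge
from sklearn.metrics import mean_absolute_error, r2_score
from sklearn.model_selection import RepeatedKFold, RepeatedStratifiedKFold

from .dataset import DecayDataset, _bin_target, filter_records, stratified_split_indices
from .features import FeatureTable, build_feature_table

logger = logging.getLogger(__name__)

MODEL_NAMES = ("Lin", "Rid", "For", "GBR")


@dataclass(frozen=True)
class ModelSpec:
    """One regressor choice: registry name, hyperparameter overrides, seed."""

    name: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 1

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model '{self.name}'; valid names: {MODEL_NAMES}")


@dataclass
class CVResult:
    """Cross-validation score bundle: means/stds and per-fold detail."""

    r2_mean: float
    r2_std: float
    mae_mean: float
    mae_std: float
    per_fold: list[tuple[int, int, float, float]]  # (repeat, fold, r2, mae)
    n_splits: int
    n_repeats: int


@dataclass
class EvalResult:
    """Held-out-test scores and the (actual, predicted) pairs behind them."""

    r2: float
    mae: float
    pairs: list[tuple[float, float]]


@dataclass
class ImportanceReport:
    """Gini importances sorted descending; ``ranked`` truncated for display,
    ``full`` keeps every feature."""

    ranked: list[tuple[str, float]]
    full: list[tuple[str, float]]

    def top_features(self) -> list[str]:
        return [name for name, _ in self.ranked]


def make_model(spec: ModelSpec):
    """Instantiate the scikit-learn regressor for a :class:`ModelSpec`.

    Conventional defaults throughout (ridge penalty 1.0, 100 trees,
    boosting defaults); every randomized component is seeded from
    ``spec.seed``.
    """
    hp = dict(spec.hyperparameters)
    if spec.name == "Lin":
        return LinearRegression(**hp)
    if spec.name == "Rid":
        hp.setdefault("alpha", 1.0)
        return Ridge(**hp)
    if spec.name == "For":
        hp.setdefault("n_estimators", 100)
        hp.setdefault("random_state", spec.seed)
        return RandomForestRegressor(**hp)
    if spec.name == "GBR":
        hp.setdefault("random_state", spec.seed)
        return GradientBoostingRegressor(**hp)
    raise ValueError(f"unknown model '{spec.name}'; valid names: {MODEL_NAMES}")


def clip_nonnegative(predictions: np.ndarray) -> np.ndarray:
    """Elementwise ``max(0, ·)`` — targets are physically non-negative."""
    return np.maximum(np.asarray(predictions, dtype=float), 0.0)


def _quiet_fit(model, X: np.ndarray, y: np.ndarray) -> None:
    """Fit, silencing the conditioning warning raw interaction columns
    (spanning many orders of magnitude) trigger in the ridge solver."""
    from scipy.linalg import LinAlgWarning

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", LinAlgWarning)
        model.fit(X, y)


def _score(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float]:
    """(R², MAE); R² is NaN-flagged when the true values have zero variance."""
    mae = float(mean_absolute_error(y_true, y_pred))
    if np.ptp(y_true) == 0:
        return float("nan"), mae
    return float(r2_score(y_true, y_pred)), mae


def repeated_stratified_cv(
    table: FeatureTable,
    spec: ModelSpec,
    n_splits: int = 5,
    n_repeats: int = 10,
    seed: int = 1,
    rows: Sequence[int] | None = None,
    n_bins: int = 5,
) -> CVResult:
    """Repeated stratified K-fold cross-validation of one model.

    Strata come from the binned target (distinct values when ≤ 10 of them,
    else quantile bins).  ``rows`` restricts the pool (e.g. to the 80%
    training share).  Fully reproducible from ``seed``.
    """
    if table.target is None:
        raise ValueError("feature table has no target")
    rows = np.arange(table.n_rows) if rows is None else np.asarray(rows)
    if len(rows) < n_splits:
        raise ValueError(f"{len(rows)} rows < {n_splits} folds")
    X = table.values[rows]
    y = table.target[rows]
    strata = _bin_target(y, n_bins)
    _, counts = np.unique(strata, return_counts=True)
    if counts.min() < n_splits:
        warnings.warn(
            "a stratum is smaller than n_splits; falling back to unstratified K-fold",
            stacklevel=2,
        )
        splitter = RepeatedKFold(n_splits=n_splits, n_repeats=n_repeats, random_state=seed)
        split_iter = splitter.split(X)
    else:
        splitter = RepeatedStratifiedKFold(
            n_splits=n_splits, n_repeats=n_repeats, random_state=seed
        )
        split_iter = splitter.split(X, strata)

    per_fold: list[tuple[int, int, float, float]] = []
    for k, (tr, va) in enumerate(split_iter):
        model = make_model(spec)
        _quiet_fit(model, X[tr], y[tr])
        pred = clip_nonnegative(model.predict(X[va]))
        r2, mae = _score(y[va], pred)
        per_fold.append((k // n_splits, k % n_splits, r2, mae))

    r2s = np.array([f[2] for f in per_fold])
    maes = np.array([f[3] for f in per_fold])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN degenerate targets
        return CVResult(
            r2_mean=float(np.nanmean(r2s)),
            r2_std=float(np.nanstd(r2s)),
            mae_mean=float(maes.mean()),
            mae_std=float(maes.std()),
            per_fold=per_fold,
            n_splits=n_splits,
            n_repeats=n_repeats,
        )


def evaluate_test(
    model,
    table: FeatureTable,
    train_idx: Sequence[int],
    test_idx: Sequence[int],
) -> EvalResult:
    """Fit on the train rows, predict (clipped) on the held-out test rows."""
    train_idx = np.asarray(train_idx)
    test_idx = np.asarray(test_idx)
    if np.intersect1d(train_idx, test_idx).size:
        raise ValueError("train and test indices overlap")
    if table.target is None:
        raise ValueError("feature table has no target")
    X, y = table.values, table.target
    _quiet_fit(model, X[train_idx], y[train_idx])
    pred = clip_nonnegative(model.predict(X[test_idx]))
    r2, mae = _score(y[test_idx], pred)
    return EvalResult(r2=r2, mae=mae, pairs=list(zip(y[test_idx].tolist(), pred.tolist())))


def gini_importances(
    forest, column_names: Sequence[str], top_k: int = 8
) -> ImportanceReport:
    """Mean-decrease-in-impurity importances of a fitted forest, sum-normalized."""
    if not hasattr(forest, "feature_importances_"):
        raise ValueError("model does not expose feature importances (unfitted?)")
    imp = np.asarray(forest.feature_importances_, dtype=float)
    total = imp.sum()
    if total > 0:
        imp = imp / total
    order = np.argsort(imp)[::-1]
    full = [(column_names[i], float(imp[i])) for i in order]
    return ImportanceReport(ranked=full[:top_k], full=full)


def _experiment_rows(
    table: FeatureTable,
    specs: Sequence[ModelSpec],
    seed: int,
    n_splits: int,
    n_repeats: int,
) -> tuple[pd.DataFrame, dict[str, object]]:
    train_idx, test_idx = stratified_split_indices(table.target, test_fraction=0.2, seed=seed)
    rows = []
    fitted: dict[str, object] = {"train_idx": train_idx, "test_idx": test_idx}
    for spec in specs:
        cv = repeated_stratified_cv(
            table, spec, n_splits=n_splits, n_repeats=n_repeats, seed=seed, rows=train_idx
        )
        ev = evaluate_test(make_model(spec), table, train_idx, test_idx)
        fitted[spec.name] = ev
        rows.append(
            {
                "model": spec.name,
                "r2_mean": cv.r2_mean,
                "r2_std": cv.r2_std,
                "mae_mean": cv.mae_mean,
                "mae_std": cv.mae_std,
                "test_r2": ev.r2,
                "test_mae": ev.mae,
            }
        )
    return pd.DataFrame(rows), fitted


def run_fixed_label_experiment(
    ds: DecayDataset,
    fixed: str,
    fixed_value: float,
    specs: Sequence[ModelSpec] | None = None,
    seed: int = 1,
    n_splits: int = 5,
    n_repeats: int = 10,
    include_interactions: bool = True,
) -> pd.DataFrame:
    """Score the models on the subset where one label is held fixed.

    ``fixed`` is ``"concentration"`` or ``"exposure"``; the other label is
    the regression target.  Returns one score row per model (CV mean/std
    and held-out-test R²/MAE).
    """
    if fixed not in ("concentration", "exposure"):
        raise ValueError("fixed must be 'concentration' or 'exposure'")
    specs = [ModelSpec(n, seed=seed) for n in MODEL_NAMES] if specs is None else list(specs)
    if fixed == "concentration":
        sub = filter_records(ds, lambda s, c, e: c == fixed_value)
        target = "exposure"
    else:
        sub = filter_records(ds, lambda s, c, e: e == fixed_value)
        target = "concentration"
    if len(sub) == 0:
        raise ValueError(f"no records with {fixed} == {fixed_value}")
    table = build_feature_table(sub, target_name=target,
                                include_interactions=include_interactions)
    scores, _ = _experiment_rows(table, specs, seed, n_splits, n_repeats)
    scores.insert(0, "fixed_value", fixed_value)
    scores.insert(0, "fixed", fixed)
    return scores


def run_dosage_experiment(
    ds: DecayDataset,
    specs: Sequence[ModelSpec] | None = None,
    seed: int = 1,
    n_splits: int = 5,
    n_repeats: int = 10,
    include_interactions: bool = True,
    top_k: int = 8,
) -> tuple[pd.DataFrame, ImportanceReport, dict]:
    """Score the models on dosage (concentration × exposure) over the full set.

    Returns the score table, the forest's Gini importance report, and a
    detail dict with the split indices and per-model :class:`EvalResult`.
    """
    if len(ds) == 0:
        raise ValueError("dataset is empty")
    specs = [ModelSpec(n, seed=seed) for n in MODEL_NAMES] if specs is None else list(specs)
    table = build_feature_table(ds, target_name="dosage",
                                include_interactions=include_interactions)
    scores, detail = _experiment_rows(table, specs, seed, n_splits, n_repeats)

    forest = make_model(ModelSpec("For", seed=seed))
    forest.fit(table.values[detail["train_idx"]], table.target[detail["train_idx"]])
    report = gini_importances(forest, table.column_names, top_k=top_k)
    detail["table"] = table
    return scores, report, detail
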