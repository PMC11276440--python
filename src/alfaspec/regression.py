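"""Calibration models: PLS regression (NIPALS) and random-forest regression.

PLSR is implemented as single-response NIPALS with mean-centering and
component-wise deflation; for one response the weight vector per component
is ``X'y`` normalised, so the algorithm is direct (no inner iteration) and
fully deterministic.  The coefficient vector in original variable space is
``B = W (P'W)^{-1} q``, and predictions from ``B`` agree with sequential
score projection to floating tolerance.

Random-forest regression delegates tree construction to
:class:`sklearn.ensemble.RandomForestRegressor` (bootstrap rows, fresh
``floor(sqrt(p))`` feature subset per split, variance-reduction splits,
impurity-based importances normalised to one); hyperparameter defaults and
the exhaustive K-fold grid search with parsimony tie-breaking live here.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
from sklearn.ensemble import RandomForestRegressor


# ---------------------------------------------------------------------------
# K-fold helper (seeded shuffle then contiguous blocks)
# ---------------------------------------------------------------------------

def kfold_indices(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Validation-index blocks for K-fold CV: seeded shuffle, contiguous split."""
    if not (2 <= k <= n):
        raise ValueError(f"need 2 <= K <= n, got K={k}, n={n}")
    order = np.random.default_rng(seed).permutation(n)
    return [np.sort(f) for f in np.array_split(order, k)]


# ---------------------------------------------------------------------------
# PLSR
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PLSRModel:
    n_components: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray  # p x A
    loadings: np.ndarray  # p x A
    y_loadings: np.ndarray  # A
    coef: np.ndarray  # p, original (centered) variable space

    @property
    def n_features(self) -> int:
        return int(self.x_mean.size)


def plsr_fit(X: np.ndarray, y: np.ndarray, n_components: int) -> PLSRModel:
    """Fit single-response PLSR by NIPALS.

    Zero-variance columns get zero weight; if the residual covariance
    vanishes early (perfect fit), later components are zero vectors so the
    requested ``n_components`` keeps its contract.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be n x p with len(y) == n")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values are not supported")
    n, p = X.shape
    a_max = min(n - 1, p)
    if not (1 <= n_components <= a_max):
        raise ValueError(
            f"n_components must be in [1, {a_max}] for n={n}, p={p}"
        )
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    E = X - x_mean
    f = y - y_mean
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    eps = np.finfo(float).eps
    scale = max(np.linalg.norm(E), 1.0)
    for a in range(n_components):
        w = E.T @ f
        norm_w = np.linalg.norm(w)
        if norm_w <= eps * 100 * scale * max(np.linalg.norm(f), eps):
            break  # nothing left to model; remaining components stay zero
        w /= norm_w
        t = E @ w
        tt = float(t @ t)
        if tt <= eps:
            break
        p_a = (E.T @ t) / tt
        q_a = float(f @ t) / tt
        E = E - np.outer(t, p_a)
        f = f - q_a * t
        W[:, a] = w
        P[:, a] = p_a
        q[a] = q_a
    # B = W (P'W)^{-1} q, restricted to the components actually extracted
    used = np.flatnonzero(np.any(W != 0, axis=0))
    if used.size:
        Wu, Pu, qu = W[:, used], P[:, used], q[used]
        coef = Wu @ np.linalg.solve(Pu.T @ Wu, qu)
    else:
        coef = np.zeros(p)
    return PLSRModel(
        n_components=n_components,
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        loadings=P,
        y_loadings=q,
        coef=coef,
    )


def plsr_predict(model: PLSRModel, X_new: np.ndarray) -> np.ndarray:
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new[None, :]
    if X_new.shape[1] != model.n_features:
        raise ValueError(
            f"X_new has {X_new.shape[1]} columns, model expects {model.n_features}"
        )
    return (X_new - model.x_mean) @ model.coef + model.y_mean


def plsr_predict_sequential(model: PLSRModel, X_new: np.ndarray) -> np.ndarray:
    """Prediction via component-wise score projection (internal cross-check)."""
    X_new = np.asarray(X_new, dtype=float)
    E = X_new - model.x_mean
    yhat = np.full(X_new.shape[0], model.y_mean)
    for a in range(model.n_components):
        w = model.weights[:, a]
        if not np.any(w):
            continue
        t = E @ w
        yhat += model.y_loadings[a] * t
        E = E - np.outer(t, model.loadings[:, a])
    return yhat


def select_components_kfold(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    a_max: int | None = None,
    seed: int = 0,
) -> tuple[int, np.ndarray]:
    """Choose the PLSR component count by pooled K-fold RMSECV.

    Returns ``(A*, curve)`` where ``curve[a-1]`` is the CV RMSE with ``a``
    components and ``A*`` is the argmin (smallest ``a`` on ties).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    folds = kfold_indices(n, k, seed)
    limit = min(min(n - f.size for f in folds) - 1, p)
    if a_max is None:
        a_max = limit
    a_max = min(a_max, limit)
    if a_max < 1:
        raise ValueError("no admissible component count for these folds")
    sq = np.zeros(a_max)
    for fold in folds:
        train = np.setdiff1d(np.arange(n), fold)
        model = plsr_fit(X[train], y[train], a_max)
        E = X[fold] - model.x_mean
        yhat = np.full(fold.size, model.y_mean)
        for a in range(a_max):
            w = model.weights[:, a]
            if np.any(w):
                t = E @ w
                yhat = yhat + model.y_loadings[a] * t
                E = E - np.outer(t, model.loadings[:, a])
            sq[a] += float(np.sum((y[fold] - yhat) ** 2))
    curve = np.sqrt(sq / n)
    best = int(np.argmin(curve)) + 1  # argmin returns first (smallest A) on ties
    return best, curve


# ---------------------------------------------------------------------------
# Random-forest regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RFRHyperparams:
    """Forest settings; defaults follow common small-sample FTIR practice."""

    n_trees: int = 15
    max_depth: int | None = 10
    min_split: int = 2
    min_leaf: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1 or self.min_split < 2 or self.min_leaf < 1:
            raise ValueError("invalid forest hyperparameters")
        if self.max_depth is not None and self.max_depth < 1:
            raise ValueError("max_depth must be >= 1 or None")


@dataclass(frozen=True)
class RFRModel:
    estimator: RandomForestRegressor
    hyperparams: RFRHyperparams
    importances: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def n_features(self) -> int:
        return int(self.estimator.n_features_in_)


def rfr_fit(X: np.ndarray, y: np.ndarray, hyperparams: RFRHyperparams | None = None) -> RFRModel:
    """Fit the bootstrap tree ensemble; feature subsets are floor(sqrt(p))."""
    if hyperparams is None:
        hyperparams = RFRHyperparams()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.size == 0 or X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a non-empty X with at least 2 rows")
    est = RandomForestRegressor(
        n_estimators=hyperparams.n_trees,
        max_depth=hyperparams.max_depth,
        min_samples_split=hyperparams.min_split,
        min_samples_leaf=hyperparams.min_leaf,
        max_features="sqrt",
        bootstrap=True,
        random_state=int(hyperparams.seed),
    )
    est.fit(X, y)
    return RFRModel(
        estimator=est,
        hyperparams=hyperparams,
        importances=np.asarray(est.feature_importances_, dtype=float),
    )


def rfr_predict(model: RFRModel, X_new: np.ndarray) -> np.ndarray:
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new[None, :]
    if X_new.shape[1] != model.n_features:
        raise ValueError(
            f"X_new has {X_new.shape[1]} columns, model expects {model.n_features}"
        )
    return model.estimator.predict(X_new)


DEFAULT_RFR_GRID: Mapping[str, Sequence[Any]] = {
    "n_trees": (15, 50, 100),
    "max_depth": (5, 10, None),
    "min_leaf": (1, 2),
    "min_split": (2, 4),
}


def rfr_grid_search(
    X: np.ndarray,
    y: np.ndarray,
    grid: Mapping[str, Sequence[Any]] | None = None,
    k: int = 5,
    seed: int = 0,
) -> tuple[RFRHyperparams, list[dict[str, Any]]]:
    """Exhaustive K-fold CV over a forest hyperparameter grid.

    Ties on CV RMSE go to fewer trees, then shallower depth (``None`` =
    unbounded counts as deepest), then smaller leaf/split settings.
    """
    if grid is None:
        grid = DEFAULT_RFR_GRID
    keys = list(grid)
    combos = [dict(zip(keys, vals)) for vals in itertools.product(*(grid[k_] for k_ in keys))]
    if not combos:
        raise ValueError("empty hyperparameter grid")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    folds = kfold_indices(n, k, seed)
    table: list[dict[str, Any]] = []
    for combo in combos:
        hp = RFRHyperparams(seed=seed, **combo)
        sq = 0.0
        for fold in folds:
            train = np.setdiff1d(np.arange(n), fold)
            model = rfr_fit(X[train], y[train], hp)
            pred = rfr_predict(model, X[fold])
            sq += float(np.sum((y[fold] - pred) ** 2))
        row = dict(combo)
        row["cv_rmse"] = float(np.sqrt(sq / n))
        table.append(row)

    def sort_key(row: dict[str, Any]):
        depth = row.get("max_depth", 10)
        return (
            row["cv_rmse"],
            row.get("n_trees", 0),
            np.inf if depth is None else depth,
            row.get("min_leaf", 0),
            row.get("min_split", 0),
        )

    best = min(table, key=sort_key)
    best_params = {k_: v for k_, v in best.items() if k_ != "cv_rmse"}
    return RFRHyperparams(seed=seed, **best_params), table
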