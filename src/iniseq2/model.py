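"""Statistical modelling of origin efficiency from genomic features.

Predictor screening (pairwise correlation and linear-dependency filters),
correlation clustering for heatmap ordering, PCA of the standardized
predictors, RBF-kernel support-vector regression of efficiency with
cross-validated tuning of (sigma, C), and permutation feature importance.

The RBF kernel uses the kernlab/caret convention
``k(x, y) = exp(-sigma * ||x - y||^2)`` (scikit-learn's ``gamma`` equals
``sigma``).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from scipy.stats import pearsonr
from sklearn.model_selection import GridSearchCV, KFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

logger = logging.getLogger(__name__)

RESPONSE = "efficiency"


def _predictor_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c != RESPONSE]


def screen_predictors(
    table: pd.DataFrame, max_abs_cor: float = 0.85, rank_tol: float = 1e-8
) -> list[str]:
    """Drop constant, highly correlated and linearly dependent predictors.

    Of any pair with |Pearson r| > ``max_abs_cor`` the later column (in table
    order) is dropped; exact linear combinations are then removed by a rank
    test on the standardized matrix. Order-stable and idempotent.
    """
    cols = _predictor_columns(table)
    if len(cols) < 2:
        raise ValueError("need at least two predictors to screen")
    kept: list[str] = []
    for c in cols:
        x = table[c].to_numpy(dtype=float)
        if np.nanstd(x) == 0:
            logger.warning("dropping constant predictor %r", c)
            continue
        kept.append(c)
    corr = table[kept].corr().abs().to_numpy()
    retained_idx: list[int] = []
    for j in range(len(kept)):
        if all(corr[j, i] <= max_abs_cor for i in retained_idx):
            retained_idx.append(j)
    retained = [kept[j] for j in retained_idx]
    # linear-dependency screen: keep a column only if it raises the rank
    X = table[retained].to_numpy(dtype=float)
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    final: list[str] = []
    basis: list[np.ndarray] = []
    for j, c in enumerate(retained):
        cand = np.column_stack(basis + [X[:, j]])
        if np.linalg.matrix_rank(cand, tol=rank_tol * max(cand.shape)) == len(basis) + 1:
            basis.append(X[:, j])
            final.append(c)
        else:
            logger.warning("dropping linearly dependent predictor %r", c)
    return final


def correlation_cluster(table: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Pearson correlation matrix over complete rows plus a single-linkage order.

    Features are ordered by single-linkage clustering of Manhattan distances
    between the rows of the correlation matrix (heatmap ordering).
    """
    cols = _predictor_columns(table)
    if len(cols) < 2:
        raise ValueError("need at least two predictors")
    complete = table[cols].dropna()
    if len(complete) < 3:
        raise ValueError("fewer than three complete observations")
    corr = complete.corr()
    if len(cols) == 2:
        order = cols
    else:
        Z = linkage(pdist(corr.to_numpy(), metric="cityblock"), method="single")
        order = [cols[i] for i in leaves_list(Z)]
    return corr, order


@dataclass
class PCAResult:
    eigenvalues: np.ndarray
    eigenvectors: pd.DataFrame  # columns PC1.., rows = features
    scores: pd.DataFrame  # per-origin principal component scores


def run_pca(table: pd.DataFrame) -> PCAResult:
    """PCA of the centered and scaled predictor matrix (efficiency excluded)."""
    cols = _predictor_columns(table)
    X = table[cols].to_numpy(dtype=float)
    n, p = X.shape
    if p > n:
        raise ValueError(f"more predictors ({p}) than observations ({n})")
    Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    u, s, vt = np.linalg.svd(Xs / np.sqrt(n - 1), full_matrices=False)
    eigenvalues = s**2
    pcs = [f"PC{i + 1}" for i in range(p)]
    eigenvectors = pd.DataFrame(vt.T, index=cols, columns=pcs)
    scores = pd.DataFrame(Xs @ vt.T, index=table.index, columns=pcs)
    return PCAResult(eigenvalues, eigenvectors, scores)


@dataclass
class ModelSpec:
    """Configuration of the efficiency regression.

    ``sigma_grid=None`` uses the median pairwise-distance heuristic scaled by
    {0.25, 0.5, 1, 2, 4}; ``c_grid=None`` uses powers of 2 from 2^-2 to 2^8.
    Model selection is by cross-validated RMSE. ``epsilon`` is the SVR
    insensitivity tube, sized for a response on the [0, 1] efficiency scale.
    """

    train_fraction: float = 0.7
    cv_folds: int = 10
    sigma_grid: np.ndarray | None = None
    c_grid: np.ndarray | None = None
    epsilon: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.sigma_grid is not None and len(self.sigma_grid) == 0:
            raise ValueError("sigma grid must be non-empty")
        if self.c_grid is not None and len(self.c_grid) == 0:
            raise ValueError("C grid must be non-empty")


@dataclass
class ModelResult:
    sigma: float
    C: float
    train_correlation: float
    test_correlation: float
    cv_rmse: float
    pipeline: Pipeline
    feature_names: list[str]
    X_test: np.ndarray
    y_test: np.ndarray


def _median_heuristic_sigma(X: np.ndarray, rng: np.random.Generator, cap: int = 500) -> float:
    """kernlab-style sigma from the median pairwise squared distance."""
    if X.shape[0] > cap:
        X = X[rng.choice(X.shape[0], size=cap, replace=False)]
    d2 = pdist(X, metric="sqeuclidean")
    med = float(np.median(d2))
    if med == 0:
        med = 1.0
    return 1.0 / (2.0 * med)


def fit_efficiency_model(table: pd.DataFrame, spec: ModelSpec = ModelSpec()) -> ModelResult:
    """Tune and fit an RBF-SVR of efficiency on the predictors.

    Seeded 70/30 split; (sigma, C) tuned by k-fold cross-validated RMSE on the
    training set; the winner is refit on the full training set and evaluated
    as the Pearson correlation between predicted and observed efficiency on
    both splits.
    """
    cols = _predictor_columns(table)
    y = table[RESPONSE].to_numpy(dtype=float)
    if np.std(y) == 0:
        raise ValueError("degenerate (constant) efficiency response")
    X = table[cols].to_numpy(dtype=float)
    X_train, X_test, y_train, y_test = train_test_split(
        X, y, train_size=spec.train_fraction, random_state=spec.seed
    )
    rng = np.random.default_rng(spec.seed)
    scaler = StandardScaler().fit(X_train)
    if spec.sigma_grid is None:
        sigma0 = _median_heuristic_sigma(scaler.transform(X_train), rng)
        sigmas = sigma0 * np.array([0.25, 0.5, 1.0, 2.0, 4.0])
    else:
        sigmas = np.asarray(spec.sigma_grid, dtype=float)
    cs = (2.0 ** np.arange(-2, 9) if spec.c_grid is None
          else np.asarray(spec.c_grid, dtype=float))
    pipe = Pipeline(
        [("scale", StandardScaler()), ("svr", SVR(kernel="rbf", epsilon=spec.epsilon))]
    )
    search = GridSearchCV(
        pipe,
        {"svr__gamma": sigmas, "svr__C": cs},
        scoring="neg_root_mean_squared_error",
        cv=KFold(spec.cv_folds, shuffle=True, random_state=spec.seed),
        n_jobs=None,
        refit=True,
    )
    search.fit(X_train, y_train)
    best = search.best_estimator_
    train_r = pearsonr(best.predict(X_train), y_train).statistic
    test_r = pearsonr(best.predict(X_test), y_test).statistic
    return ModelResult(
        sigma=float(search.best_params_["svr__gamma"]),
        C=float(search.best_params_["svr__C"]),
        train_correlation=float(train_r),
        test_correlation=float(test_r),
        cv_rmse=float(-search.best_score_),
        pipeline=best,
        feature_names=cols,
        X_test=X_test,
        y_test=y_test,
    )


def predictor_importance(
    result: ModelResult, seed: int = 0, n_repeats: int = 20
) -> pd.Series:
    """Permutation importance: mean increase in test RMSE when a feature is shuffled.

    Averaged over ``n_repeats`` shuffles per feature and floored at 0.
    """
    rng = np.random.default_rng(seed)
    X, y = result.X_test, result.y_test
    base_rmse = float(np.sqrt(np.mean((result.pipeline.predict(X) - y) ** 2)))
    importances = {}
    for j, name in enumerate(result.feature_names):
        deltas = np.empty(n_repeats)
        Xp = X.copy()
        for r in range(n_repeats):
            Xp[:, j] = rng.permutation(X[:, j])
            rmse = float(np.sqrt(np.mean((result.pipeline.predict(Xp) - y) ** 2)))
            deltas[r] = rmse - base_rmse
        importances[name] = max(float(deltas.mean()), 0.0)
    return pd.Series(importances).sort_values(ascending=False)
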