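"""Prediction of symptom severity and cognitive scores from oscillatory
features with nested cross-validation.

Severity (low / moderate / high) is classified with a linear discriminant
using a diagonal shared covariance matrix; cognitive scores are regressed
with Lasso.  Both use 10-fold outer cross-validation with an inner 5-fold
grid search, so standardization and hyper-parameter selection never see
the held-out fold.  Classification chance levels come from the exact
cumulative binomial distribution.
"""
from __future__ import annotations

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import Lasso
from sklearn.model_selection import GridSearchCV, KFold, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from .containers import PredictionResult

SHRINKAGE_GRID = tuple(np.round(np.linspace(0.0, 1.0, 11), 2))


class DiagonalLDA(BaseEstimator, ClassifierMixin):
    """Linear discriminant with a shared diagonal covariance matrix.

    Per-feature variances are pooled across classes; ``shrinkage`` blends
    them toward their mean, regularizing ill-conditioned feature scales:
    ``var_s = (1 - shrinkage) * var + shrinkage * mean(var)``.
    """

    def __init__(self, shrinkage: float = 0.0):
        self.shrinkage = shrinkage

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self.means_ = np.array([X[y == c].mean(axis=0) for c in self.classes_])
        resid = X - self.means_[np.searchsorted(self.classes_, y)]
        pooled = resid.var(axis=0, ddof=len(self.classes_))
        pooled = np.maximum(pooled, 1e-12)
        var = (1 - self.shrinkage) * pooled + self.shrinkage * pooled.mean()
        self.var_ = np.maximum(var, 1e-12)
        self.priors_ = np.array([np.mean(y == c) for c in self.classes_])
        return self

    def _scores(self, X):
        X = np.asarray(X, dtype=float)
        d2 = (
            ((X[:, None, :] - self.means_[None, :, :]) ** 2) / self.var_[None, None, :]
        ).sum(axis=-1)
        return -0.5 * d2 + np.log(self.priors_)[None, :]

    def predict(self, X):
        check_is_fitted(self, "means_")
        return self.classes_[np.argmax(self._scores(X), axis=1)]


def chance_threshold(n: int, n_classes: int, alpha: float = 0.05) -> float:
    """Empirical chance level (%) from the cumulative binomial distribution.

    Smallest accuracy k/n whose upper-tail probability under random
    guessing (p = 1/n_classes) falls below ``alpha``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    k = np.arange(n + 1)
    tail = stats.binom.sf(k - 1, n, 1.0 / n_classes)  # P(X >= k)
    passing = k[tail < alpha]
    k_min = int(passing[0]) if len(passing) else n + 1
    return 100.0 * min(k_min, n) / n if k_min <= n else 100.0


def _stratified_outer(y: np.ndarray, n_outer: int, seed: int) -> StratifiedKFold:
    """Outer folds, shrunk if a class is too small to stratify 10 ways."""
    _, counts = np.unique(y, return_counts=True)
    n_splits = int(min(n_outer, counts.min()))
    if n_splits < 2:
        raise ValueError("every class needs >= 2 members")
    return StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)


def lda_nested_cv(
    X: np.ndarray,
    y: np.ndarray,
    n_outer: int = 10,
    n_inner: int = 5,
    shrinkage_grid: tuple[float, ...] = SHRINKAGE_GRID,
    seed: int = 0,
    alpha: float = 0.05,
) -> PredictionResult:
    """Nested-CV severity classification with the diagonal-covariance LDA.

    Outer folds are stratified; the inner 5-fold grid search selects the
    shrinkage strength.  The metric is pooled outer-fold accuracy (the
    fraction of all held-out participants classified correctly), reported
    in percent together with the binomial chance threshold.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain missing values")
    outer = _stratified_outer(y, n_outer, seed)
    fold_acc, correct, total = [], 0, 0
    for train, test in outer.split(X, y):
        inner = StratifiedKFold(
            n_splits=min(n_inner, np.bincount(np.unique(y[train], return_inverse=True)[1]).min()),
            shuffle=True,
            random_state=seed,
        )
        search = GridSearchCV(
            DiagonalLDA(), {"shrinkage": list(shrinkage_grid)}, cv=inner
        )
        search.fit(X[train], y[train])
        pred = search.predict(X[test])
        fold_acc.append(float(np.mean(pred == y[test])))
        correct += int(np.sum(pred == y[test]))
        total += len(test)
    accuracy = 100.0 * correct / total
    return PredictionResult(
        task="severity-3-class",
        fold_metric=np.array(fold_acc),
        metric=accuracy,
        chance_threshold=chance_threshold(total, len(np.unique(y)), alpha),
    )


def lasso_nested_cv(
    X: np.ndarray,
    y: np.ndarray,
    n_outer: int = 10,
    n_inner: int = 5,
    n_alphas: int = 30,
    seed: int = 0,
    feature_names: list[str] | None = None,
) -> PredictionResult:
    """Nested-CV Lasso regression of a cognitive score on features.

    Standardization and the 30-point log-spaced penalty grid (anchored at
    the training fold's null-model penalty) live strictly inside each
    training fold.  The reported metric is the mean held-out R^2 over the
    outer folds; the displayed model comes from a whole-data refit after
    the cross-validated assessment.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.std(y) == 0:
        raise ValueError("target is constant")
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain missing values")

    def alpha_grid(Xt: np.ndarray, yt: np.ndarray) -> np.ndarray:
        Xs = (Xt - Xt.mean(0)) / np.maximum(Xt.std(0), 1e-12)
        yc = yt - yt.mean()
        a_max = np.max(np.abs(Xs.T @ yc)) / len(yt)
        a_max = max(a_max, 1e-6)
        return np.logspace(np.log10(a_max), np.log10(a_max * 1e-3), n_alphas)

    def fit_search(Xt: np.ndarray, yt: np.ndarray) -> GridSearchCV:
        pipe = Pipeline(
            [("scale", StandardScaler()), ("lasso", Lasso(max_iter=50000))]
        )
        search = GridSearchCV(
            pipe,
            {"lasso__alpha": alpha_grid(Xt, yt)},
            cv=KFold(n_splits=n_inner, shuffle=True, random_state=seed),
            scoring="neg_mean_squared_error",
        )
        return search.fit(Xt, yt)

    outer = KFold(n_splits=min(n_outer, len(y)), shuffle=True, random_state=seed)
    r2 = []
    for train, test in outer.split(X):
        search = fit_search(X[train], y[train])
        pred = search.predict(X[test])
        ss_res = np.sum((y[test] - pred) ** 2)
        ss_tot = np.sum((y[test] - np.mean(y[test])) ** 2)
        r2.append(1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0)
    r2 = np.array(r2)

    final = fit_search(X, y)
    scaler: StandardScaler = final.best_estimator_.named_steps["scale"]
    lasso: Lasso = final.best_estimator_.named_steps["lasso"]
    # express the standardized fit on the original feature scale
    w = lasso.coef_ / scaler.scale_
    intercept = float(lasso.intercept_ - np.sum(scaler.mean_ * w))
    names = feature_names or [f"x{i}" for i in range(X.shape[1])]
    coefficients = dict(zip(names, map(float, w)))
    coefficients["intercept"] = intercept
    return PredictionResult(
        task="score-regression",
        fold_metric=r2,
        metric=float(r2.mean()),
        coefficients=coefficients,
        feature_names=names,
    )


def pac_cluster_features(comodulograms: list) -> np.ndarray:
    """Feature matrix (max MI, f_p at max, f_a at max) per participant.

    Each element of ``comodulograms`` is one participant's Comodulogram
    for a given electrode cluster; the features are the raw-MI grid
    maximum and its grid coordinates.
    """
    rows = []
    for c in comodulograms:
        i, j = np.unravel_index(np.nanargmax(c.mi), c.mi.shape)
        rows.append([c.mi[i, j], c.phase_freqs[i], c.amp_freqs[j]])
    return np.asarray(rows, dtype=float)
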