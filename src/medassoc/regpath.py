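"""Shared L1 regularization-path machinery: penalty grids, cross-validated
deviance, the one-standard-error rule and per-feature drop-out penalties.

The penalty is parameterized as lambda in the per-observation objective
(1/n) * deviance/2 + lambda * ||beta||_1, which maps to scikit-learn's
``C = 1 / (n * lambda)``.  The grid runs from the data-derived null penalty
(smallest lambda at which every coefficient is zero) down by a configurable
ratio, log-spaced.  The intercept is never penalized (liblinear's implicit
intercept penalty is neutralized with a large ``intercept_scaling``).

Both the binary and the multinomial pipelines reuse this module so one tested
code path implements the 1-SE rule everywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .errors import ConvergenceError

DEFAULT_GRID_SIZE = 100
DEFAULT_MIN_RATIO = 1e-4
NONZERO_TOL = 1e-8


@dataclass
class CvPath:
    """Cross-validation summary along a decreasing penalty grid."""

    lambdas: np.ndarray  # decreasing
    mean_deviance: np.ndarray  # mean out-of-fold per-observation deviance
    se_deviance: np.ndarray
    lambda_star: float
    index_star: int
    index_min: int

    @property
    def lambda_min_deviance(self) -> float:
        return float(self.lambdas[self.index_min])


def make_lambda_grid(
    lambda_max: float, size: int = DEFAULT_GRID_SIZE, min_ratio: float = DEFAULT_MIN_RATIO
) -> np.ndarray:
    if lambda_max <= 0:
        raise ValueError("lambda_max must be positive")
    return np.geomspace(lambda_max, lambda_max * min_ratio, size)


def choose_one_se(
    lambdas: np.ndarray, mean_dev: np.ndarray, se_dev: np.ndarray
) -> tuple[int, int]:
    """Largest penalty whose mean CV deviance is within one SE of the minimum.

    Returns ``(index_star, index_min)`` into the decreasing grid.  By
    construction ``lambdas[index_star] >= lambdas[index_min]``.
    """
    index_min = int(np.argmin(mean_dev))
    threshold = mean_dev[index_min] + se_dev[index_min]
    candidates = np.flatnonzero(mean_dev <= threshold)
    index_star = int(candidates.min())  # grid is decreasing: smallest index = largest penalty
    assert lambdas[index_star] >= lambdas[index_min]
    return index_star, index_min


def _column_scales(X: sp.spmatrix) -> np.ndarray:
    mean = np.asarray(X.mean(axis=0)).ravel()
    meansq = np.asarray(X.multiply(X).mean(axis=0)).ravel()
    sd = np.sqrt(np.maximum(meansq - mean**2, 0.0))
    sd[sd == 0] = 1.0
    return sd


def _maybe_standardize(X: sp.spmatrix, standardize: bool) -> tuple[sp.csr_matrix, np.ndarray]:
    X = sp.csr_matrix(X, dtype=np.float64)
    if not standardize:
        return X, np.ones(X.shape[1])
    scales = _column_scales(X)
    return (X @ sp.diags(1.0 / scales)).tocsr(), scales


def binary_lambda_max(X: sp.spmatrix, y: np.ndarray, standardize: bool = False) -> float:
    """Smallest penalty at which the L1 logistic solution is all-zero."""
    Xs, _ = _maybe_standardize(X, standardize)
    resid = y - y.mean()
    return float(np.max(np.abs(Xs.T @ resid)) / len(y))


def multinomial_lambda_max(X: sp.spmatrix, y: np.ndarray, standardize: bool = False) -> float:
    Xs, _ = _maybe_standardize(X, standardize)
    classes = np.unique(y)
    n = len(y)
    grad = 0.0
    for c in classes:
        ind = (y == c).astype(float)
        grad = max(grad, float(np.max(np.abs(Xs.T @ (ind - ind.mean()))) / n))
    return grad


def _kkt_satisfied(
    clf: LogisticRegression, X: sp.spmatrix, y: np.ndarray, lam: float, slack: float = 0.05
) -> bool:
    """First-order optimality of the L1 solution, with relative slack.

    For zero coefficients the score must satisfy |g_jc| <= lam; for nonzero
    ones g_jc + lam * sign(w_jc) must vanish.  Used to accept fits where the
    solver's iteration cap fired while oscillating at a coefficient's entry
    threshold (the solution there is optimal to within numerical noise).
    """
    n = X.shape[0]
    prob = clf.predict_proba(X)
    Y = (y[:, None] == clf.classes_[None, :]).astype(float)
    resid = prob - Y  # n x K
    if clf.coef_.shape[0] == 1:  # binary parameterization: positive class only
        resid = resid[:, [1]]
    grad = np.asarray(X.T @ resid).T / n  # matches clf.coef_ shape
    w = clf.coef_
    tol = slack * lam
    zero = np.abs(w) <= NONZERO_TOL
    if np.any(np.abs(grad[zero]) > lam + tol):
        return False
    return not np.any(np.abs(grad[~zero] + lam * np.sign(w[~zero])) > tol)


def _check_converged(
    clf: LogisticRegression,
    lam: float,
    X: sp.spmatrix | None = None,
    y: np.ndarray | None = None,
) -> None:
    n_iter = int(np.max(clf.n_iter_))
    if n_iter < clf.max_iter:
        return
    if X is not None and _kkt_satisfied(clf, X, y, lam):
        return
    raise ConvergenceError(f"L1 fit did not converge at penalty {lam:.6g}")


def fit_binary_path(
    X: sp.spmatrix, y: np.ndarray, lambdas: np.ndarray, standardize: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Coefficients (len(lambdas) x p, original scale) and intercepts along the path."""
    Xs, scales = _maybe_standardize(X, standardize)
    n = len(y)
    coefs = np.zeros((len(lambdas), Xs.shape[1]))
    intercepts = np.zeros(len(lambdas))
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        for i, lam in enumerate(lambdas):
            clf = LogisticRegression(
                l1_ratio=1.0,
                solver="liblinear",
                C=1.0 / (n * lam),
                intercept_scaling=100.0,
                tol=1e-6,
                max_iter=10000,
            )
            try:
                clf.fit(Xs, y)
            except ConvergenceWarning as exc:  # pragma: no cover - defensive
                raise ConvergenceError(f"L1 fit did not converge at penalty {lam:.6g}") from exc
            _check_converged(clf, lam)
            coefs[i] = clf.coef_.ravel() / scales
            intercepts[i] = clf.intercept_[0]
    return coefs, intercepts


def binary_deviance(y: np.ndarray, prob: np.ndarray) -> np.ndarray:
    eps = 1e-12
    p = np.clip(prob, eps, 1 - eps)
    return -2.0 * (y * np.log(p) + (1 - y) * np.log(1 - p))


def cv_binary_path(
    X: sp.spmatrix,
    y: np.ndarray,
    lambdas: np.ndarray,
    n_folds: int = 5,
    seed: int = 0,
    standardize: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-penalty mean and standard error of out-of-fold per-observation deviance.

    Folds are stratified by label; the SE is the usual sd-of-fold-means over
    sqrt(n_folds).
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_means = np.zeros((n_folds, len(lambdas)))
    X = sp.csr_matrix(X, dtype=np.float64)
    for k, (train, test) in enumerate(skf.split(X, y)):
        coefs, intercepts = fit_binary_path(X[train], y[train], lambdas, standardize)
        eta = X[test] @ coefs.T + intercepts  # n_test x n_lambda
        prob = 1.0 / (1.0 + np.exp(-eta))
        dev = binary_deviance(y[test][:, None], prob)
        fold_means[k] = dev.mean(axis=0)
    mean = fold_means.mean(axis=0)
    se = fold_means.std(axis=0, ddof=1) / np.sqrt(n_folds)
    return mean, se


def dropout_penalties(lambdas: np.ndarray, coef_path: np.ndarray) -> np.ndarray:
    """Largest penalty at which each feature's coefficient is nonzero (0 if never).

    ``coef_path`` has shape (n_lambda, p) or (n_lambda, K, p); any class
    counts for the multinomial case.
    """
    nz = np.abs(coef_path) > NONZERO_TOL
    if nz.ndim == 3:
        nz = nz.any(axis=1)
    out = np.zeros(nz.shape[1])
    for j in range(nz.shape[1]):
        hits = np.flatnonzero(nz[:, j])
        if hits.size:
            out[j] = lambdas[hits.min()]
    return out


def _multinomial_estimator(C: float) -> LogisticRegression:
    return LogisticRegression(
        l1_ratio=1.0,
        solver="saga",
        C=C,
        warm_start=True,
        tol=1e-5,
        max_iter=1000,  # stalls at a coefficient entry threshold are accepted via the KKT check
        random_state=0,  # saga shuffles samples; fix for reproducibility
    )


def _symmetric_coefs(
    clf: LogisticRegression, classes: np.ndarray, scales: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Coefficients in the symmetric (zero-mean across classes) parameterization.

    scikit-learn fits the binary parameterization when K = 2; that solution is
    converted to (-w/2, +w/2), which carries the same L1 cost for any pairwise
    difference, so path and CV choices are unaffected.
    """
    if len(classes) == 2:
        w = clf.coef_.ravel() / scales
        b = clf.intercept_[0]
        coefs = np.vstack([-w / 2.0, w / 2.0])
        intercepts = np.array([-b / 2.0, b / 2.0])
    else:
        coefs = clf.coef_ / scales
        intercepts = clf.intercept_.copy()
    coefs = coefs - coefs.mean(axis=0, keepdims=True)
    intercepts = intercepts - intercepts.mean()
    return coefs, intercepts


def _refine_intercepts(eta: np.ndarray, y_idx: np.ndarray, b0: np.ndarray) -> np.ndarray:
    """Exact unpenalized intercepts given fixed coefficients.

    saga's stopping rule can leave intercepts unconverged at strong penalties
    (it may quit after one epoch when all weights are tiny), which would distort
    the CV deviance at the top of the path; this solves the small convex
    problem max_b sum_i log softmax(eta_i + b)_{y_i} directly.
    """
    from scipy.optimize import minimize

    n, K = eta.shape
    onehot_counts = np.bincount(y_idx, minlength=K).astype(float)

    def neg_ll(b):
        z = eta + b
        z -= z.max(axis=1, keepdims=True)
        logsumexp = np.log(np.exp(z).sum(axis=1))
        ll = z[np.arange(n), y_idx].sum() - logsumexp.sum()
        p = np.exp(z)
        p /= p.sum(axis=1, keepdims=True)
        grad = -(onehot_counts - p.sum(axis=0))
        return -ll, grad

    res = minimize(neg_ll, b0, jac=True, method="L-BFGS-B", options={"maxiter": 200})
    b = res.x
    return b - b.mean()


def fit_multinomial_path(
    X: sp.spmatrix,
    y: np.ndarray,
    lambdas: np.ndarray,
    standardize: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Symmetric-parameterization coefficient path for the multinomial model.

    Returns ``(classes, coefs, intercepts)`` with ``coefs`` of shape
    (n_lambda, K, p) and ``intercepts`` of shape (n_lambda, K); warm-started
    along the decreasing penalty grid.
    """
    Xs, scales = _maybe_standardize(X, standardize)
    n = len(y)
    classes = np.unique(y)
    clf = _multinomial_estimator(C=1.0)
    coefs = np.zeros((len(lambdas), len(classes), Xs.shape[1]))
    intercepts = np.zeros((len(lambdas), len(classes)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for i, lam in enumerate(lambdas):
            clf.set_params(C=1.0 / (n * lam))
            clf.fit(Xs, y)
            _check_converged(clf, lam, Xs, y)
            coefs[i], intercepts[i] = _symmetric_coefs(clf, classes, scales)
            eta = np.asarray(X @ coefs[i].T)
            y_idx = np.searchsorted(classes, y)
            intercepts[i] = _refine_intercepts(eta, y_idx, intercepts[i])
    return classes, coefs, intercepts


def multinomial_deviance(y: np.ndarray, classes: np.ndarray, prob: np.ndarray) -> np.ndarray:
    eps = 1e-12
    idx = np.searchsorted(classes, y)
    p = np.clip(prob[np.arange(len(y)), idx], eps, 1.0)
    return -2.0 * np.log(p)


def cv_multinomial_path(
    X: sp.spmatrix,
    y: np.ndarray,
    lambdas: np.ndarray,
    n_folds: int = 5,
    seed: int = 0,
    standardize: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_means = np.zeros((n_folds, len(lambdas)))
    X = sp.csr_matrix(X, dtype=np.float64)
    for k, (train, test) in enumerate(skf.split(X, y)):
        classes, coefs, intercepts = fit_multinomial_path(X[train], y[train], lambdas, standardize)
        for i in range(len(lambdas)):
            eta = X[test] @ coefs[i].T + intercepts[i]
            eta -= eta.max(axis=1, keepdims=True)
            prob = np.exp(eta)
            prob /= prob.sum(axis=1, keepdims=True)
            fold_means[k, i] = multinomial_deviance(y[test], classes, prob).mean()
    mean = fold_means.mean(axis=0)
    se = fold_means.std(axis=0, ddof=1) / np.sqrt(n_folds)
    return mean, se
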