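"""Association pipeline: correlation screen, L1-penalized selection with the
one-standard-error rule, unpenalized refit with Wald inference, and
Benjamini-Hochberg adjustment.

The model is a main-effects logistic regression of case/control status on
binary condition/medication indicators,

    Pr(Y = 1 | X = x) = exp(b0 + b'x) / (1 + exp(b0 + b'x)),

so each coefficient is the log of the odds ratio for the corresponding concept
adjusted for every other selected concept.  Selection happens on the same data
used for the final fit, so the reported p-values inherit the usual
post-selection optimism; they are intended for ranking, not as calibrated
error rates (the FDR adjustment is applied to them as-is, as a filtering
device).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import statsmodels.api as sm
from scipy import stats

from .cohort import CaseControlDataset
from .errors import SeparationError
from . import regpath

logger = logging.getLogger(__name__)


@dataclass
class ScreenResult:
    """Outcome of the marginal correlation screen."""

    retained: list[str]
    stats: pd.DataFrame  # concept_id, kind, r, p_value, retained flag
    duplicate_groups: list[list[str]] = field(default_factory=list)


@dataclass
class SelectedSet:
    """Concepts surviving the L1 path at the 1-SE penalty."""

    concepts: list[str]
    lambdas: np.ndarray
    lambda_star: float
    cv_mean_deviance: np.ndarray
    cv_se_deviance: np.ndarray
    dropout_penalty: pd.Series  # indexed by screened concept id
    coefficients: pd.Series  # penalized coefficients at lambda_star


def screen_features(ds: CaseControlDataset, alpha: float = 0.05) -> ScreenResult:
    """Retain concepts whose point-biserial correlation with the labels has
    two-sided p < alpha; collapse perfectly correlated duplicate columns.

    The p-value comes from t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees of
    freedom.  Zero-variance columns are dropped before testing.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    n = len(ds.y)
    if n < 4:
        raise ValueError("need at least 4 patients for the correlation screen")
    if ds.n_cases < 2 or ds.n_controls < 2:
        raise ValueError("need >= 2 patients in each label group")

    X = sp.csc_matrix(ds.X, dtype=np.float64)
    y = ds.y.astype(np.float64)
    col_sum = np.asarray(X.sum(axis=0)).ravel()
    nonconstant = (col_sum > 0) & (col_sum < n)

    # duplicate groups among non-constant columns: identical 0/1 patterns
    groups: dict[bytes, list[int]] = {}
    for j in np.flatnonzero(nonconstant):
        key = X.indices[X.indptr[j] : X.indptr[j + 1]].tobytes()
        groups.setdefault(key, []).append(j)
    representative = np.zeros(X.shape[1], dtype=bool)
    duplicate_groups = []
    ids = ds.columns["concept_id"].to_numpy()
    for members in groups.values():
        representative[members[0]] = True
        if len(members) > 1:
            duplicate_groups.append([ids[j] for j in members])

    xy = np.asarray(X.T @ y).ravel()
    sy = y.sum()
    num = n * xy - col_sum * sy
    den = np.sqrt((n * col_sum - col_sum**2) * (n * sy - sy**2))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / den, 0.0)
        r = np.clip(r, -1.0, 1.0)
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 0.0))
    p = np.where(np.isinf(t) | (np.abs(r) == 1.0), 0.0, 2.0 * stats.t.sf(np.abs(t), n - 2))

    retained_mask = nonconstant & representative & (p < alpha)
    table = pd.DataFrame(
        {
            "concept_id": ids,
            "kind": ds.columns["kind"].to_numpy(),
            "r": r,
            "p_value": p,
            "retained": retained_mask,
        }
    )
    retained = [ids[j] for j in np.flatnonzero(retained_mask)]
    logger.info(
        "screen: %d of %d concepts retained at alpha=%g (%d duplicate groups)",
        len(retained), X.shape[1], alpha, len(duplicate_groups),
    )
    return ScreenResult(retained=retained, stats=table, duplicate_groups=duplicate_groups)


def lasso_select(
    ds: CaseControlDataset,
    screened: ScreenResult,
    n_folds: int = 5,
    seed: int = 0,
    grid_size: int = regpath.DEFAULT_GRID_SIZE,
    min_ratio: float = regpath.DEFAULT_MIN_RATIO,
    standardize: bool = False,
    lambdas: np.ndarray | None = None,
) -> SelectedSet:
    """L1-penalized logistic selection under stratified K-fold CV and the 1-SE rule."""
    if not screened.retained:
        raise ValueError("screened set is empty")
    cols = [ds.column_index(c) for c in screened.retained]
    X = sp.csc_matrix(ds.X, dtype=np.float64)[:, cols].tocsr()
    y = np.asarray(ds.y, dtype=np.int64)

    if lambdas is None:
        lam_max = regpath.binary_lambda_max(X, y, standardize)
        lambdas = regpath.make_lambda_grid(lam_max, grid_size, min_ratio)
    lambdas = np.asarray(lambdas, dtype=float)

    mean_dev, se_dev = regpath.cv_binary_path(X, y, lambdas, n_folds, seed, standardize)
    i_star, i_min = regpath.choose_one_se(lambdas, mean_dev, se_dev)
    lambda_star = float(lambdas[i_star])

    coef_path, _ = regpath.fit_binary_path(X, y, lambdas, standardize)
    dropout = regpath.dropout_penalties(lambdas, coef_path)
    beta_star = coef_path[i_star]
    nonzero = np.abs(beta_star) > regpath.NONZERO_TOL
    concepts = [c for c, nz in zip(screened.retained, nonzero) if nz]
    logger.info(
        "lasso: lambda*=%.4g (min-deviance lambda=%.4g), %d of %d concepts selected",
        lambda_star, lambdas[i_min], len(concepts), len(screened.retained),
    )
    return SelectedSet(
        concepts=concepts,
        lambdas=lambdas,
        lambda_star=lambda_star,
        cv_mean_deviance=mean_dev,
        cv_se_deviance=se_dev,
        dropout_penalty=pd.Series(dropout, index=screened.retained),
        coefficients=pd.Series(beta_star, index=screened.retained),
    )


def _separation_flags(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Flag binary columns whose 2x2 table against the labels has a zero cell."""
    flags = np.zeros(X.shape[1], dtype=bool)
    for j in range(X.shape[1]):
        x = X[:, j]
        a = np.sum((x == 1) & (y == 1))
        b = np.sum((x == 1) & (y == 0))
        c = np.sum((x == 0) & (y == 1))
        d = np.sum((x == 0) & (y == 0))
        flags[j] = min(a, b, c, d) == 0
    return flags


def fit_final_logistic(ds: CaseControlDataset, selected: SelectedSet) -> pd.DataFrame:
    """Unpenalized ML refit on the selected concepts; the machine twin of a
    ranked adjusted-odds-ratio table.

    Columns: concept_id, kind, coef, adjusted_or, p_value, p_adjusted, rank,
    separation_flag; sorted by p ascending with ties broken by odds ratio
    descending.  Quasi-separated columns (zero cell against the labels) are
    flagged rather than silently reported; an error is raised only when even
    the fallback optimizer cannot produce finite estimates.
    """
    if not selected.concepts:
        raise ValueError("selected set is empty")
    cols = [ds.column_index(c) for c in selected.concepts]
    X = np.asarray(ds.X.todense(), dtype=np.float64)[:, cols]
    y = np.asarray(ds.y, dtype=np.float64)
    flags = _separation_flags(X, y)
    design = sm.add_constant(X, has_constant="add")

    model = sm.Logit(y, design)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(method="newton", maxiter=200, disp=0)
    except Exception:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(method="lbfgs", maxiter=500, disp=0)
    params = np.asarray(res.params)[1:]
    bse = np.asarray(res.bse)[1:]
    if not (np.all(np.isfinite(params)) and np.all(np.isfinite(bse))):
        offenders = [c for c, f in zip(selected.concepts, flags) if f]
        raise SeparationError(
            f"perfect separation: logistic MLE undefined (offending columns: {offenders})"
        )

    z = np.divide(params, bse, out=np.full_like(params, np.inf), where=bse > 0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    kind = ds.columns["kind"].to_numpy()[cols]
    table = pd.DataFrame(
        {
            "concept_id": selected.concepts,
            "kind": kind,
            "coef": params,
            "se": bse,
            "adjusted_or": np.exp(params),
            "p_value": p,
            "separation_flag": flags,
        }
    )
    _, p_adj = adjust_fdr(table["p_value"].to_numpy())
    table["p_adjusted"] = p_adj
    table = table.sort_values(
        ["p_value", "adjusted_or"], ascending=[True, False], kind="mergesort"
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table[
        ["concept_id", "kind", "coef", "se", "adjusted_or", "p_value", "p_adjusted",
         "rank", "separation_flag"]
    ]


def adjust_fdr(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: reject the largest k with p_(k) <= k*q/m.

    Returns ``(reject, p_adjusted)`` aligned with the input; adjusted p-values
    are min over j >= rank of m * p_(j) / j, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    adj = np.minimum.accumulate((m * ranked / np.arange(1, m + 1))[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    p_adjusted = np.empty(m)
    p_adjusted[order] = adj
    passing = np.flatnonzero(ranked <= np.arange(1, m + 1) * q / m)
    reject = np.zeros(m, dtype=bool)
    if passing.size:
        reject[order[: passing.max() + 1]] = True
    return reject, p_adjusted
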