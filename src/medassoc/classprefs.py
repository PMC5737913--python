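"""Drug-class preference modelling: which comorbidities tilt the choice among
the drug classes used to treat the index condition.

The model is an L1-penalized multinomial logit of the class outcome C on
binary comorbidity indicators x,

    Pr(C = c | X = x) = exp(b0c + bc'x) / sum_k exp(b0k + bk'x),

fitted along a penalty path with the same cross-validated one-standard-error
rule as the binary pipeline.  Per-class coefficients are only identified up to
a per-feature constant; coefficients are reported in the symmetric
parameterization (zero mean across classes per feature) and every interpreted
quantity depends on them only through pairwise differences:
exp(b_a,j - b_ref,j) is the factor by which comorbidity j multiplies the odds
of class a over the reference class.

No p-values are computed for this model; comorbidities are ranked by their
drop-out penalty — the largest penalty at which the comorbidity still carries
a nonzero coefficient for any class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .cohort import ClassChoiceDataset
from . import regpath

logger = logging.getLogger(__name__)


@dataclass
class MulticlassScreenResult:
    retained: list[str]
    stats: pd.DataFrame  # concept_id, chi2, p_value, retained


@dataclass
class ClassPreferenceModel:
    """Fitted (or externally supplied) multinomial class-preference coefficients."""

    classes: tuple[str, ...]
    features: tuple[str, ...]
    intercepts: np.ndarray  # (K,)
    coefficients: np.ndarray  # (K, p), zero mean across classes per feature
    dropout_penalty: np.ndarray | None = None  # (p,)
    lambda_star: float | None = None
    percent_of_patients: np.ndarray | None = None  # (p,)
    parameterization: str = "symmetric_zero_mean"

    def _class_index(self, label: str) -> int:
        try:
            return self.classes.index(label)
        except ValueError:
            raise ValueError(f"unknown class {label!r}") from None

    def _feature_index(self, comorbidity: str) -> int:
        try:
            return self.features.index(comorbidity)
        except ValueError:
            raise ValueError(f"unknown comorbidity {comorbidity!r}") from None

    def predict_proba(self, X: sp.spmatrix | np.ndarray) -> np.ndarray:
        eta = np.asarray(X @ self.coefficients.T) + self.intercepts
        eta -= eta.max(axis=1, keepdims=True)
        prob = np.exp(eta)
        return prob / prob.sum(axis=1, keepdims=True)

    @classmethod
    def from_coefficients(
        cls,
        classes: tuple[str, ...] | list[str],
        features: tuple[str, ...] | list[str],
        coefficients: np.ndarray,
        intercepts: np.ndarray | None = None,
    ) -> "ClassPreferenceModel":
        """Wrap an externally reported per-class coefficient table.

        The coefficients are re-centered per feature; pairwise differences —
        the only identified quantities — are unchanged by this.
        """
        coef = np.asarray(coefficients, dtype=float)
        if coef.shape != (len(classes), len(features)):
            raise ValueError("coefficient matrix must be K x p")
        coef = coef - coef.mean(axis=0, keepdims=True)
        if intercepts is None:
            intercepts = np.zeros(len(classes))
        return cls(
            classes=tuple(classes),
            features=tuple(features),
            intercepts=np.asarray(intercepts, dtype=float),
            coefficients=coef,
        )


def screen_multiclass(ds: ClassChoiceDataset, alpha: float = 0.05) -> MulticlassScreenResult:
    """Chi-square screen of each comorbidity's K x 2 table against the outcome."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    classes = np.unique(ds.outcome)
    if len(classes) < 2:
        raise ValueError("need at least 2 outcome classes")
    counts = pd.Series(ds.outcome).value_counts()
    empty = [c for c in ds.classes if counts.get(c, 0) == 0]
    if empty:
        raise ValueError(f"classes with zero patients: {empty}")

    X = sp.csc_matrix(ds.X, dtype=np.float64)
    n = X.shape[0]
    ids = ds.columns["concept_id"].to_numpy()
    chi2 = np.full(X.shape[1], np.nan)
    p = np.full(X.shape[1], np.nan)
    retained = np.zeros(X.shape[1], dtype=bool)
    class_ind = {c: (ds.outcome == c) for c in classes}
    for j in range(X.shape[1]):
        x = np.asarray(X[:, j].todense()).ravel() > 0
        npos = int(x.sum())
        if npos == 0 or npos == n:
            continue  # zero-variance column
        table = np.array([[np.sum(ind & x), np.sum(ind & ~x)] for ind in class_ind.values()])
        res = stats.chi2_contingency(table, correction=False)
        chi2[j], p[j] = res.statistic, res.pvalue
        retained[j] = p[j] < alpha
    table_out = pd.DataFrame(
        {"concept_id": ids, "chi2": chi2, "p_value": p, "retained": retained}
    )
    retained_ids = [ids[j] for j in np.flatnonzero(retained)]
    logger.info("multiclass screen: %d of %d comorbidities retained", len(retained_ids), len(ids))
    return MulticlassScreenResult(retained=retained_ids, stats=table_out)


def fit_multinomial_lasso(
    ds: ClassChoiceDataset,
    retained: list[str],
    n_folds: int = 5,
    seed: int = 0,
    grid_size: int = regpath.DEFAULT_GRID_SIZE,
    min_ratio: float = regpath.DEFAULT_MIN_RATIO,
    standardize: bool = False,
    lambdas: np.ndarray | None = None,
) -> ClassPreferenceModel:
    """L1 multinomial fit at the cross-validated 1-SE penalty.

    Records per-comorbidity drop-out penalties from the full-data path; no
    p-values are computed for this model.
    """
    if not retained:
        raise ValueError("retained comorbidity set is empty")
    ids = list(ds.columns["concept_id"])
    cols = [ids.index(c) for c in retained]
    X = sp.csc_matrix(ds.X, dtype=np.float64)[:, cols].tocsr()
    y = np.asarray(ds.outcome)

    if lambdas is None:
        lam_max = regpath.multinomial_lambda_max(X, y, standardize)
        lambdas = regpath.make_lambda_grid(lam_max, grid_size, min_ratio)
    lambdas = np.asarray(lambdas, dtype=float)

    mean_dev, se_dev = regpath.cv_multinomial_path(X, y, lambdas, n_folds, seed, standardize)
    i_star, _ = regpath.choose_one_se(lambdas, mean_dev, se_dev)
    lambda_star = float(lambdas[i_star])

    classes, coef_path, intercept_path = regpath.fit_multinomial_path(X, y, lambdas, standardize)
    dropout = regpath.dropout_penalties(lambdas, coef_path)
    percent = np.asarray(X.mean(axis=0)).ravel() * 100.0
    logger.info("multinomial lasso: lambda*=%.4g over %d classes", lambda_star, len(classes))
    return ClassPreferenceModel(
        classes=tuple(str(c) for c in classes),
        features=tuple(retained),
        intercepts=intercept_path[i_star],
        coefficients=coef_path[i_star],
        dropout_penalty=dropout,
        lambda_star=lambda_star,
        percent_of_patients=percent,
    )


def interpret_pair(
    model: ClassPreferenceModel, comorbidity: str, class_a: str, class_ref: str
) -> float:
    """Factor by which the comorbidity multiplies the odds of ``class_a`` being
    prescribed rather than ``class_ref``: exp(b_a - b_ref) for that comorbidity."""
    j = model._feature_index(comorbidity)
    ia = model._class_index(class_a)
    ir = model._class_index(class_ref)
    return float(np.exp(model.coefficients[ia, j] - model.coefficients[ir, j]))


def rank_comorbidities(model: ClassPreferenceModel, top_n: int) -> pd.DataFrame:
    """Comorbidities ordered by drop-out penalty (descending): one row per
    comorbidity, one coefficient column per class, plus the percent of the
    analysis population carrying the comorbidity."""
    if top_n <= 0:
        raise ValueError("top_n must be positive")
    if model.dropout_penalty is None:
        raise ValueError("model carries no drop-out penalties (not fitted on data)")
    data = {"comorbidity": list(model.features)}
    for i, cls in enumerate(model.classes):
        data[cls] = model.coefficients[i]
    data["percent_of_patients"] = (
        model.percent_of_patients
        if model.percent_of_patients is not None
        else np.full(len(model.features), np.nan)
    )
    data["dropout_penalty"] = model.dropout_penalty
    table = pd.DataFrame(data)
    table = table.sort_values(
        ["dropout_penalty", "comorbidity"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return table.head(top_n)
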