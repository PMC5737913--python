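"""Association pipeline: screening against an exact permutation oracle, LASSO
selection behavior on known signal/null data, the unpenalized refit against
the 2x2 cross-product oracle, and Benjamini-Hochberg against brute force."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from medassoc import (
    adjust_fdr,
    fit_final_logistic,
    lasso_select,
    screen_features,
)
from medassoc.regpath import binary_lambda_max
from conftest import dataset_from_table, make_case_control


def simulate_logistic(seed, n, betas, prevalence=0.3, intercept=-1.0):
    rng = np.random.default_rng(seed)
    p = len(betas)
    X = (rng.random((n, p)) < prevalence).astype(float)
    eta = intercept + X @ np.asarray(betas)
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    return make_case_control(y, X)


class TestScreen:
    def test_label_identical_column_retained_with_zero_p(self):
        y = np.array([1, 1, 1, 0, 0, 0] * 3)
        X = np.column_stack([y, 1 - y[::-1]])
        ds = make_case_control(y, X, names=["same_as_label", "other"])
        res = screen_features(ds, alpha=0.01)
        row = res.stats.set_index("concept_id").loc["same_as_label"]
        assert row["r"] == pytest.approx(1.0)
        assert row["p_value"] == 0.0
        assert "same_as_label" in res.retained

    def test_constant_column_dropped_before_testing(self):
        y = np.array([1, 1, 0, 0, 1, 0])
        X = np.column_stack([np.ones(6), y])
        ds = make_case_control(y, X, names=["always_on", "signal"])
        res = screen_features(ds, alpha=0.05)
        assert "always_on" not in res.retained
        assert not res.stats.set_index("concept_id").loc["always_on", "retained"]

    def test_duplicate_columns_keep_one_representative(self):
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        x = np.array([1, 1, 1, 0, 0, 0, 0, 0], dtype=float)
        X = np.column_stack([x, x, 1 - x])
        ds = make_case_control(y, X, names=["a", "b", "flip"])
        res = screen_features(ds, alpha=0.5)
        assert ["a", "b"] in res.duplicate_groups
        assert ("a" in res.retained) and ("b" not in res.retained)

    def test_p_value_matches_exact_permutation_oracle(self):
        """n=12, point-biserial t-test vs the exact permutation distribution of
        |r| over all label placements."""
        y = np.array([1] * 6 + [0] * 6)
        x = np.array([1, 1, 1, 1, 0, 0, 0, 1, 0, 0, 0, 0], dtype=float)
        ds = make_case_control(y, np.column_stack([x]), names=["med"])
        p_t = screen_features(ds, alpha=0.999).stats["p_value"].iloc[0]

        def corr(labels):
            return abs(np.corrcoef(labels, x)[0, 1])

        r_obs = corr(y)
        beyond = ties = total = 0
        for ones in itertools.combinations(range(12), 6):
            labels = np.zeros(12)
            labels[list(ones)] = 1
            total += 1
            r = corr(labels)
            if r > r_obs + 1e-12:
                beyond += 1
            elif r >= r_obs - 1e-12:
                ties += 1
        # mid-p: half weight on the tie atom, the standard continuity
        # correction when comparing a discrete null to a continuous one
        p_perm = (beyond + 0.5 * ties) / total
        assert abs(p_t - p_perm) < 0.06

    def test_too_few_patients_error(self):
        ds = make_case_control(np.array([1, 0]), np.array([[1.0], [0.0]]))
        with pytest.raises(ValueError):
            screen_features(ds, alpha=0.05)


class TestLassoSelect:
    def test_penalty_above_maximum_selects_nothing(self):
        ds = simulate_logistic(0, 500, [1.5, 0.0])
        screened = screen_features(ds, alpha=0.999)
        lam_max = binary_lambda_max(ds.X, ds.y)
        sel = lasso_select(ds, screened, lambdas=np.array([lam_max * 2, lam_max * 1.5]))
        assert sel.concepts == []

    def test_strong_covariate_selected_among_noise(self):
        ds = simulate_logistic(7, 2000, [2.0] + [0.0] * 20)
        screened = screen_features(ds, alpha=0.999)
        sel = lasso_select(ds, screened, n_folds=5, seed=7)
        assert "c000" in sel.concepts

    def test_null_simulation_selects_almost_nothing(self):
        good = 0
        for seed in range(10):
            ds = simulate_logistic(100 + seed, 2000, [0.0] * 20, intercept=-0.4)
            screened = screen_features(ds, alpha=0.999)
            sel = lasso_select(ds, screened, n_folds=5, seed=seed)
            if len(sel.concepts) <= 2:
                good += 1
        assert good >= 8

    def test_one_se_penalty_dominates_minimizer(self):
        for seed in (0, 1):
            ds = simulate_logistic(seed, 1500, [1.0, 0.5, 0.0, 0.0])
            screened = screen_features(ds, alpha=0.999)
            sel = lasso_select(ds, screened, n_folds=5, seed=seed)
            i_min = int(np.argmin(sel.cv_mean_deviance))
            assert sel.lambda_star >= sel.lambdas[i_min]

    def test_selection_nested_in_screen(self):
        ds = simulate_logistic(3, 1500, [1.5, 1.0, 0.0, 0.0, 0.0])
        screened = screen_features(ds, alpha=0.05)
        sel = lasso_select(ds, screened, n_folds=5, seed=3)
        assert set(sel.concepts) <= set(screened.retained)

    def test_dropout_order_invariant_to_column_permutation(self):
        ds = simulate_logistic(11, 1500, [1.5, 0.8, 0.3, 0.0])
        screened = screen_features(ds, alpha=0.999)
        sel = lasso_select(ds, screened, n_folds=5, seed=11)
        perm = [2, 0, 3, 1]
        Xp = np.asarray(ds.X.todense())[:, perm]
        names = [f"c{j:03d}" for j in perm]
        dsp = make_case_control(ds.y, Xp, names=names)
        selp = lasso_select(dsp, screen_features(dsp, alpha=0.999), n_folds=5, seed=11)
        for name in names:
            assert sel.dropout_penalty[name] == pytest.approx(
                selp.dropout_penalty[name], rel=1e-9
            )


class TestFinalFit:
    def test_single_covariate_or_equals_cross_product(self):
        ds = dataset_from_table(a=20, b=10, c=30, d=60)
        screened = screen_features(ds, alpha=0.999)
        sel = lasso_select(ds, screened, n_folds=5, seed=0)
        # force the single covariate through regardless of the CV choice
        sel.concepts = ["exposure"]
        table = fit_final_logistic(ds, sel)
        assert table["adjusted_or"].iloc[0] == pytest.approx(4.0, abs=1e-6)

    def test_label_copy_covariate_flagged_not_fatal(self):
        y = np.array([1] * 20 + [0] * 30)
        rng = np.random.default_rng(0)
        X = np.column_stack([y.astype(float), (rng.random(50) < 0.4).astype(float)])
        ds = make_case_control(y, X, names=["copy_of_label", "benign"])
        sel = lasso_select(ds, screen_features(ds, alpha=0.999), n_folds=5, seed=0)
        sel.concepts = ["copy_of_label", "benign"]
        table = fit_final_logistic(ds, sel).set_index("concept_id")
        assert bool(table.loc["copy_of_label", "separation_flag"])
        assert not bool(table.loc["benign", "separation_flag"])

    def test_table_sorted_by_p_then_or_descending(self):
        ds = simulate_logistic(5, 3000, [1.5, 1.0, 0.5])
        sel = lasso_select(ds, screen_features(ds, alpha=0.999), n_folds=5, seed=5)
        sel.concepts = ["c000", "c001", "c002"]
        table = fit_final_logistic(ds, sel)
        p = table["p_value"].to_numpy()
        assert (np.diff(p) >= 0).all()
        assert list(table["rank"]) == list(range(1, len(table) + 1))
        assert (table["p_adjusted"] >= table["p_value"] - 1e-15).all()


def bh_oracle(p, q):
    """Check every cutoff k directly: reject the largest k with p_(k) <= kq/m."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    best_k = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            best_k = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:best_k]] = True
    return reject


class TestBenjaminiHochberg:
    def test_stepup_rejects_all_when_all_small(self):
        reject, adj = adjust_fdr(np.array([0.01, 0.02, 0.03, 0.04]), q=0.05)
        assert reject.all()
        assert (adj <= 0.05).all()

    def test_no_rejections_at_p_one(self):
        reject, adj = adjust_fdr(np.ones(5), q=0.05)
        assert not reject.any()
        assert (adj == 1.0).all()

    def test_matches_bruteforce_oracle_on_random_vectors(self):
        rng = np.random.default_rng(2024)
        for _ in range(300):
            m = int(rng.integers(1, 11))
            p = np.round(rng.random(m), 3)
            q = float(rng.choice([0.01, 0.05, 0.1, 0.25]))
            reject, _ = adjust_fdr(p, q)
            np.testing.assert_array_equal(reject, bh_oracle(p, q))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        p=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=10),
        q1=st.floats(0.01, 0.4),
        q2=st.floats(0.01, 0.4),
    )
    def test_rejection_set_monotone_in_q(self, p, q1, q2):
        lo, hi = sorted([q1, q2])
        r_lo, _ = adjust_fdr(np.array(p), lo)
        r_hi, _ = adjust_fdr(np.array(p), hi)
        assert set(np.flatnonzero(r_lo)) <= set(np.flatnonzero(r_hi))

    def test_adjusted_p_reproduces_rejections(self):
        rng = np.random.default_rng(7)
        p = rng.random(8)
        for q in (0.05, 0.2):
            reject, adj = adjust_fdr(p, q)
            np.testing.assert_array_equal(reject, adj <= q)

    def test_empty_input(self):
        reject, adj = adjust_fdr(np.array([]))
        assert reject.size == 0 and adj.size == 0
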