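"""Class-preference model: chi-square screen against the textbook formula,
identifiability discipline of the symmetric parameterization, pairwise
interpretation, and ranking by drop-out penalty."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from medassoc import (
    ClassChoiceDataset,
    ClassPreferenceModel,
    build_class_choice,
    fit_multinomial_lasso,
    generate_population,
    interpret_pair,
    rank_comorbidities,
    screen_multiclass,
)
from medassoc.regpath import multinomial_lambda_max
from conftest import classpref_config


def make_class_choice(outcome, X, names=None, classes=None):
    X = np.asarray(X, dtype=float)
    outcome = np.asarray(outcome, dtype=object)
    if names is None:
        names = [f"com{j}" for j in range(X.shape[1])]
    return ClassChoiceDataset(
        patient_ids=np.arange(len(outcome)),
        outcome=outcome,
        X=sp.csr_matrix(X),
        columns=pd.DataFrame({"concept_id": names, "kind": ["condition"] * X.shape[1]}),
        selected_visits=np.zeros(len(outcome), dtype=np.int64),
        classes=tuple(classes or sorted(set(outcome))),
        index_condition="index",
    )


def fitted_classpref_dataset(seed, shift=1.0, n=10000):
    cfg = classpref_config(seed, shift=shift, n_patients=n)
    mentions, _ = generate_population(cfg)
    return build_class_choice(mentions, "hypertension", cfg.class_map, seed=seed)


class TestScreen:
    def test_chi_square_matches_textbook_formula(self):
        # 3 classes x comorbidity present/absent, hand-built counts
        outcome = np.repeat(["a", "b", "c"], [40, 40, 40])
        x = np.concatenate([np.ones(30), np.zeros(10),   # class a: 30 with
                            np.ones(20), np.zeros(20),   # class b: 20 with
                            np.ones(10), np.zeros(30)])  # class c: 10 with
        ds = make_class_choice(outcome, x.reshape(-1, 1))
        observed = np.array([[30, 10], [20, 20], [10, 30]], dtype=float)
        expected = observed.sum(1, keepdims=True) * observed.sum(0) / observed.sum()
        chi2_hand = ((observed - expected) ** 2 / expected).sum()
        res = screen_multiclass(ds, alpha=0.05)
        assert res.stats["chi2"].iloc[0] == pytest.approx(chi2_hand)
        assert res.retained == ["com0"]

    def test_absent_comorbidity_dropped(self):
        outcome = np.array(["a", "b"] * 10, dtype=object)
        X = np.zeros((20, 1))
        res = screen_multiclass(make_class_choice(outcome, X), alpha=0.05)
        assert res.retained == []

    def test_perfect_determiner_retained(self):
        outcome = np.array(["a"] * 20 + ["b"] * 20, dtype=object)
        x = np.array([1.0] * 20 + [0.0] * 20)
        res = screen_multiclass(make_class_choice(outcome, x.reshape(-1, 1)), alpha=0.001)
        assert res.retained == ["com0"]

    def test_empty_class_errors(self):
        outcome = np.array(["a"] * 10, dtype=object)
        ds = make_class_choice(outcome, np.ones((10, 1)), classes=["a", "b"])
        with pytest.raises(ValueError):
            screen_multiclass(ds, alpha=0.05)


class TestFit:
    def test_max_penalty_gives_intercept_only_marginals(self):
        ds = fitted_classpref_dataset(seed=21, n=2000)
        lam_max = multinomial_lambda_max(ds.X, ds.outcome)
        model = fit_multinomial_lasso(
            ds, ["diabetes"], n_folds=3, seed=0,
            lambdas=np.array([lam_max * 1.5, lam_max * 1.2]),
        )
        assert np.abs(model.coefficients).max() < 1e-6
        probs = np.exp(model.intercepts) / np.exp(model.intercepts).sum()
        marginals = np.array([(ds.outcome == c).mean() for c in model.classes])
        np.testing.assert_allclose(probs, marginals, atol=1e-3)

    def test_positive_shift_recovered_with_positive_difference(self):
        ds = fitted_classpref_dataset(seed=33, n=4000)
        model = fit_multinomial_lasso(ds, ["diabetes"], n_folds=5, seed=33)
        assert interpret_pair(model, "diabetes", "class_a", "class_b") > 1.0

    def test_fitted_probabilities_normalize(self):
        ds = fitted_classpref_dataset(seed=8, n=2000)
        model = fit_multinomial_lasso(ds, ["diabetes"], n_folds=3, seed=8)
        probs = model.predict_proba(ds.X)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-10)

    def test_percent_of_patients_matches_dataset(self):
        ds = fitted_classpref_dataset(seed=5, n=2000)
        model = fit_multinomial_lasso(ds, ["diabetes"], n_folds=3, seed=5)
        prev = np.asarray(ds.X.todense())[:, 0].mean() * 100
        assert model.percent_of_patients[0] == pytest.approx(prev)


class TestInterpretation:
    def test_published_style_coefficient_pair(self):
        """Subtracting the reference-class coefficient and exponentiating:
        0.018 - (-0.043) = 0.061, whose exponential rounds to 1.06."""
        model = ClassPreferenceModel.from_coefficients(
            classes=["a2_blocker", "beta_blocker"],
            features=["asthma"],
            coefficients=np.array([[0.018], [-0.043]]),
        )
        factor = interpret_pair(model, "asthma", "a2_blocker", "beta_blocker")
        assert np.log(factor) == pytest.approx(0.061)
        assert round(factor, 2) == 1.06

    def test_identity_pair_is_one(self):
        model = ClassPreferenceModel.from_coefficients(
            ["a", "b"], ["x"], np.array([[0.5], [-0.2]])
        )
        assert interpret_pair(model, "x", "a", "a") == 1.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(coef=arrays(np.float64, (3, 2), elements=st.floats(-2, 2)))
    def test_reciprocity(self, coef):
        model = ClassPreferenceModel.from_coefficients(["a", "b", "c"], ["x", "y"], coef)
        ab = interpret_pair(model, "x", "a", "b")
        ba = interpret_pair(model, "x", "b", "a")
        assert ab * ba == pytest.approx(1.0)

    def test_per_feature_shift_leaves_interpretation_unchanged(self):
        coef = np.array([[0.3, -0.1], [-0.2, 0.4], [0.1, 0.0]])
        base = ClassPreferenceModel.from_coefficients(["a", "b", "c"], ["x", "y"], coef)
        shifted = ClassPreferenceModel.from_coefficients(
            ["a", "b", "c"], ["x", "y"], coef + np.array([[5.0, -3.0]])
        )
        for f in ("x", "y"):
            for ca in ("a", "b", "c"):
                assert interpret_pair(base, f, ca, "c") == pytest.approx(
                    interpret_pair(shifted, f, ca, "c")
                )

    def test_unknown_names_error(self):
        model = ClassPreferenceModel.from_coefficients(["a", "b"], ["x"], np.zeros((2, 1)))
        with pytest.raises(ValueError):
            interpret_pair(model, "x", "a", "zzz")
        with pytest.raises(ValueError):
            interpret_pair(model, "unknown", "a", "b")


class TestRanking:
    def _model(self, dropout):
        p = len(dropout)
        return ClassPreferenceModel(
            classes=("a", "b"),
            features=tuple(f"com{j}" for j in range(p)),
            intercepts=np.zeros(2),
            coefficients=np.zeros((2, p)),
            dropout_penalty=np.asarray(dropout, dtype=float),
            percent_of_patients=np.full(p, 10.0),
        )

    def test_sorted_by_dropout_descending(self):
        table = rank_comorbidities(self._model([0.01, 0.1]), top_n=5)
        assert list(table["comorbidity"]) == ["com1", "com0"]

    def test_single_comorbidity_first(self):
        table = rank_comorbidities(self._model([0.2]), top_n=1)
        assert list(table["comorbidity"]) == ["com0"]

    def test_top_n_validation(self):
        with pytest.raises(ValueError):
            rank_comorbidities(self._model([0.1]), top_n=0)

    def test_ranking_invariant_to_feature_order(self):
        """Fitting with permuted comorbidity columns must give the same
        ranked ordering."""
        rng = np.random.default_rng(0)
        n = 3000
        X = (rng.random((n, 3)) < [0.4, 0.3, 0.2]).astype(float)
        eta_a = 1.2 * X[:, 0] - 0.8 * X[:, 1]
        pa = 1 / (1 + np.exp(-eta_a))
        outcome = np.where(rng.random(n) < pa, "a", "b")
        names = ["com_x", "com_y", "com_z"]
        ds1 = make_class_choice(outcome, X, names=names)
        perm = [2, 0, 1]
        ds2 = make_class_choice(outcome, X[:, perm], names=[names[i] for i in perm])
        m1 = fit_multinomial_lasso(ds1, names, n_folds=3, seed=4)
        m2 = fit_multinomial_lasso(ds2, [names[i] for i in perm], n_folds=3, seed=4)
        t1 = rank_comorbidities(m1, 3)
        t2 = rank_comorbidities(m2, 3)
        assert list(t1["comorbidity"]) == list(t2["comorbidity"])
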