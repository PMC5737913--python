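"""Shared fixtures: hand-built mention tables, direct dataset constructors and
the standard confounded study configuration used by the end-to-end checks."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from medassoc import CaseControlDataset, MentionTable, SimConfig


def mention_frame(rows: list[tuple[int, int, str, str]]) -> MentionTable:
    return MentionTable(
        pd.DataFrame(rows, columns=["patient_id", "visit_id", "kind", "concept_id"])
    )


@pytest.fixture
def four_patient_mentions() -> MentionTable:
    """Two cases, two controls, one visit each — selection is deterministic."""
    return mention_frame(
        [
            (1, 0, "condition", "hypertension"),
            (1, 0, "condition", "diabetes"),
            (1, 0, "medication", "med_x"),
            (2, 0, "condition", "hypertension"),
            (2, 0, "medication", "med_y"),
            (3, 0, "condition", "diabetes"),
            (3, 0, "condition", "asthma"),
            (3, 0, "medication", "med_y"),
            (4, 0, "medication", "med_x"),
        ]
    )


@pytest.fixture
def multi_visit_mentions() -> MentionTable:
    """Cases and controls with several visits; the index condition is recorded
    at some visits only, so visit selection matters."""
    return mention_frame(
        [
            # patient 1: case, hypertension at visits 0 and 2 of 3
            (1, 0, "condition", "hypertension"),
            (1, 0, "medication", "med_x"),
            (1, 1, "condition", "diabetes"),
            (1, 2, "condition", "hypertension"),
            (1, 2, "condition", "diabetes"),
            # patient 2: case, every visit mentions hypertension
            (2, 0, "condition", "hypertension"),
            (2, 1, "condition", "hypertension"),
            (2, 1, "medication", "med_y"),
            # patient 3: control with 2 visits
            (3, 0, "condition", "asthma"),
            (3, 1, "medication", "med_x"),
            # patient 4: control with a single visit
            (4, 0, "medication", "med_y"),
        ]
    )


def make_case_control(
    y: np.ndarray, X: np.ndarray, kinds: list[str] | None = None,
    names: list[str] | None = None,
) -> CaseControlDataset:
    """Directly assemble a case/control dataset from dense arrays."""
    X = np.asarray(X, dtype=np.float64)
    n, p = X.shape
    if names is None:
        names = [f"c{j:03d}" for j in range(p)]
    if kinds is None:
        kinds = ["medication"] * p
    return CaseControlDataset(
        patient_ids=np.arange(n),
        y=np.asarray(y, dtype=np.int8),
        X=sp.csr_matrix(X),
        columns=pd.DataFrame({"concept_id": names, "kind": kinds}),
        selected_visits=np.zeros(n, dtype=np.int64),
        index_condition="index",
    )


def dataset_from_table(a: int, b: int, c: int, d: int) -> CaseControlDataset:
    """Single-covariate dataset whose implied 2x2 table is (a, b, c, d)."""
    y = np.concatenate([np.ones(a + c), np.zeros(b + d)])
    x = np.concatenate([np.ones(a), np.zeros(c), np.ones(b), np.zeros(d)])
    return make_case_control(y, x.reshape(-1, 1), names=["exposure"])


def confounded_config(seed: int, n_patients: int = 20000) -> SimConfig:
    """The standard confounded study: five true index-condition treatments,
    three confounder-only medications (treating comorbidities that co-occur
    with the index condition), and fifty background medications."""
    true_meds = [(f"ht_med_{i}", "hypertension", q)
                 for i, q in enumerate([0.8, 0.75, 0.7, 0.65, 0.6], start=1)]
    conf_meds = [("conf_med_1", "ckd", 0.7), ("conf_med_2", "afib", 0.7),
                 ("conf_med_3", "ckd", 0.5)]
    background = [(m, 0.02) for m, _, _ in true_meds + conf_meds]
    noise = [(f"noise_med_{i:02d}", 0.03) for i in range(50)]
    return SimConfig(
        n_patients=n_patients,
        conditions=[
            ("hypertension", 0.35),
            ("ckd", 0.10),
            ("afib", 0.08),
            ("diabetes", 0.25),
            ("asthma", 0.12),
            ("back_pain", 0.20),
        ],
        comorbidity_links=[
            ("hypertension", "ckd", 4.0),
            ("hypertension", "afib", 3.0),
            ("hypertension", "diabetes", 2.0),
        ],
        treatments=true_meds + conf_meds,
        noise_meds=background + noise,
        visit_count_mean=4.0,
        visit_count_dispersion=1.0,
        recording_prob=0.7,
        index_condition="hypertension",
        seed=seed,
    )


def classpref_config(seed: int, shift: float = 1.0, n_patients: int = 10000) -> SimConfig:
    """Two drug classes for the index condition; one comorbidity (diabetes,
    prevalence 0.4) shifts the class-A log-odds by ``shift``."""
    return SimConfig(
        n_patients=n_patients,
        conditions=[("hypertension", 1.0), ("diabetes", 0.4)],
        treatments=[("med_a", "hypertension", 0.99), ("med_b", "hypertension", 0.99)],
        class_map={"med_a": "class_a", "med_b": "class_b"},
        class_preference_effects=[("diabetes", "class_a", shift)],
        visit_count_mean=1.0,
        recording_prob=1.0,
        index_condition="hypertension",
        seed=seed,
    )
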