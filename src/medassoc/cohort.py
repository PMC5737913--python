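"""Case/control and class-choice dataset construction from mention tables.

The first step of the association procedure: cases are patients that have ever
had the index condition, controls are everyone else.  Each patient contributes
a single visit — for cases a uniformly random visit at which the index
condition was recorded, for controls a uniformly random visit — and the binary
feature vector is the set of concepts mentioned at that visit, minus the index
condition itself (it is already captured by the label).

For the drug-class comparison the population is restricted to patients with at
least one visit co-mentioning the index condition and a medication of one of
the classes of interest; the outcome is drawn uniformly among the distinct
classes mentioned at the selected visit, and only condition mentions enter the
feature matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import CohortError
from .simulate import KIND_CONDITION, KIND_MEDICATION, MentionTable, select_index_visits

logger = logging.getLogger(__name__)


@dataclass
class CaseControlDataset:
    """One row per patient: 0/1 label and binary concept features at the selected visit."""

    patient_ids: np.ndarray
    y: np.ndarray
    X: sp.csr_matrix
    columns: pd.DataFrame  # concept_id, kind
    selected_visits: np.ndarray
    index_condition: str

    @property
    def n_cases(self) -> int:
        return int(self.y.sum())

    @property
    def n_controls(self) -> int:
        return int(len(self.y) - self.y.sum())

    def column_index(self, concept: str) -> int:
        hits = np.flatnonzero(self.columns["concept_id"].to_numpy() == concept)
        if hits.size == 0:
            raise KeyError(f"unknown concept {concept!r}")
        return int(hits[0])


@dataclass
class ClassChoiceDataset:
    """One row per qualifying patient: drug-class outcome and comorbidity features."""

    patient_ids: np.ndarray
    outcome: np.ndarray  # class label per patient
    X: sp.csr_matrix
    columns: pd.DataFrame  # concept_id (conditions only)
    selected_visits: np.ndarray
    classes: tuple[str, ...]
    index_condition: str


def _feature_matrix(
    rows: pd.DataFrame, patient_ids: np.ndarray
) -> tuple[sp.csr_matrix, pd.DataFrame]:
    """Binary patients x concepts matrix from long-format mention rows."""
    vocab = (
        rows[["concept_id", "kind"]]
        .drop_duplicates()
        .sort_values(["concept_id", "kind"])
        .reset_index(drop=True)
    )
    col_of = {c: i for i, c in enumerate(vocab["concept_id"])}
    row_of = {p: i for i, p in enumerate(patient_ids)}
    i = rows["patient_id"].map(row_of).to_numpy()
    j = rows["concept_id"].map(col_of).to_numpy()
    X = sp.coo_matrix(
        (np.ones(len(rows)), (i, j)), shape=(len(patient_ids), len(vocab))
    ).tocsr()
    X.data = np.minimum(X.data, 1.0)
    return X, vocab


def build_case_control(
    mentions: MentionTable,
    index_condition: str,
    seed: int = 0,
    feature_window: str = "visit",
) -> CaseControlDataset:
    """Construct the one-visit-per-patient binary case/control dataset.

    ``feature_window='visit'`` (default) takes features from the selected visit
    only; ``'history'`` takes the union of all visits.
    """
    if feature_window not in ("visit", "history"):
        raise ValueError("feature_window must be 'visit' or 'history'")
    selection = select_index_visits(mentions, index_condition, seed)
    n_cases = int(selection["is_case"].sum())
    if n_cases == 0 or n_cases == len(selection):
        raise CohortError(
            f"degenerate design: {n_cases} cases out of {len(selection)} patients"
        )

    frame = mentions.frame
    if feature_window == "visit":
        rows = frame.merge(
            selection.rename(columns={"selected_visit": "visit_id"})[
                ["patient_id", "visit_id"]
            ],
            on=["patient_id", "visit_id"],
        )
    else:
        rows = frame
    rows = rows[rows["concept_id"] != index_condition]
    rows = rows[["patient_id", "concept_id", "kind"]].drop_duplicates()

    patient_ids = selection["patient_id"].to_numpy()
    X, vocab = _feature_matrix(rows, patient_ids)
    n_vocab_total = mentions.vocabulary().shape[0]
    dropped = n_vocab_total - 1 - len(vocab)  # -1: the index condition itself
    if dropped > 0:
        logger.info("dropped %d concepts absent after visit selection", dropped)

    return CaseControlDataset(
        patient_ids=patient_ids,
        y=selection["is_case"].to_numpy().astype(np.int8),
        X=X,
        columns=vocab,
        selected_visits=selection["selected_visit"].to_numpy(),
        index_condition=index_condition,
    )


def build_class_choice(
    mentions: MentionTable,
    index_condition: str,
    class_map: Mapping[str, str],
    seed: int = 0,
) -> ClassChoiceDataset:
    """Construct the restricted dataset for the drug-class preference analysis.

    A patient qualifies with >= 1 visit where the index condition and at least
    one class-mapped medication are both recorded.  The visit is chosen
    uniformly among qualifying visits; the outcome uniformly among the distinct
    classes mentioned at that visit (class multiplicity upstream is preserved —
    deduplication happens only at the draw itself).
    """
    if not class_map:
        raise ValueError("class_map must be non-empty")
    frame = mentions.frame
    index_visits = frame.loc[
        (frame["concept_id"] == index_condition) & (frame["kind"] == KIND_CONDITION),
        ["patient_id", "visit_id"],
    ].drop_duplicates()
    med_rows = frame[
        (frame["kind"] == KIND_MEDICATION) & frame["concept_id"].isin(class_map.keys())
    ].copy()
    med_rows["drug_class"] = med_rows["concept_id"].map(class_map)
    qualifying = index_visits.merge(
        med_rows[["patient_id", "visit_id"]].drop_duplicates(),
        on=["patient_id", "visit_id"],
    ).sort_values(["patient_id", "visit_id"], kind="mergesort")
    if qualifying.empty:
        raise CohortError("no patient has a visit co-mentioning the index condition and a mapped medication")

    rng = np.random.default_rng(seed)
    sizes = qualifying.groupby("patient_id", sort=True).size()
    offsets = np.concatenate([[0], np.cumsum(sizes.to_numpy())[:-1]])
    picks = offsets + np.floor(rng.random(len(sizes)) * sizes.to_numpy()).astype(np.int64)
    chosen = qualifying.iloc[picks].reset_index(drop=True)
    patient_ids = chosen["patient_id"].to_numpy()
    selected_visits = chosen["visit_id"].to_numpy()

    # distinct classes mentioned at each selected visit, then one uniform draw
    at_visit = med_rows.merge(chosen, on=["patient_id", "visit_id"])
    class_sets = (
        at_visit.groupby("patient_id")["drug_class"]
        .apply(lambda s: sorted(set(s)))
        .reindex(patient_ids)
    )
    outcome = np.array(
        [classes[int(rng.integers(len(classes)))] for classes in class_sets],
        dtype=object,
    )

    cond_rows = frame[
        (frame["kind"] == KIND_CONDITION) & (frame["concept_id"] != index_condition)
    ].merge(
        chosen.rename(columns={"visit_id": "visit_id"}), on=["patient_id", "visit_id"]
    )[["patient_id", "concept_id", "kind"]].drop_duplicates()
    X, vocab = _feature_matrix(cond_rows, patient_ids)

    return ClassChoiceDataset(
        patient_ids=patient_ids,
        outcome=outcome,
        X=X,
        columns=vocab,
        selected_visits=selected_visits,
        classes=tuple(sorted(set(class_map.values()))),
        index_condition=index_condition,
    )
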