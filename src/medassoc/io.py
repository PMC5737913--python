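"""Plain-text serialization of every pipeline artifact.

Mention tables, labels and column metadata are delimited text; the sparse
binary feature matrix is MatrixMarket coordinate format; configurations and
truth sets are YAML.  Writers produce stable column order and all formats
round-trip losslessly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from .cohort import CaseControlDataset, ClassChoiceDataset
from .simulate import MENTION_COLUMNS, MentionTable, SimConfig, TruthSet


def _p(prefix: Path, ext: str) -> Path:
    """`prefix + ext` without Path.with_suffix's dot stripping."""
    return prefix.parent / (prefix.name + ext)


def write_mentions(mentions: MentionTable, path: str | Path) -> None:
    mentions.frame.to_csv(path, index=False, columns=list(MENTION_COLUMNS))


def read_mentions(path: str | Path) -> MentionTable:
    frame = pd.read_csv(path, dtype={"patient_id": np.int64, "visit_id": np.int64,
                                     "kind": str, "concept_id": str})
    return MentionTable(frame)


def write_sim_config(config: SimConfig, path: str | Path) -> None:
    doc = {
        "n_patients": config.n_patients,
        "conditions": [list(c) for c in config.conditions],
        "comorbidity_links": [list(c) for c in config.comorbidity_links],
        "treatments": [list(t) for t in config.treatments],
        "noise_meds": [list(m) for m in config.noise_meds],
        "class_map": dict(config.class_map),
        "class_preference_effects": [list(e) for e in config.class_preference_effects],
        "visit_count_mean": config.visit_count_mean,
        "visit_count_dispersion": config.visit_count_dispersion,
        "recording_prob": config.recording_prob,
        "index_condition": config.index_condition,
        "seed": config.seed,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_sim_config(path: str | Path) -> SimConfig:
    doc = yaml.safe_load(Path(path).read_text())
    return sim_config_from_dict(doc)


def sim_config_from_dict(doc: dict) -> SimConfig:
    return SimConfig(
        n_patients=int(doc["n_patients"]),
        conditions=[tuple(c) for c in doc.get("conditions", [])],
        comorbidity_links=[tuple(c) for c in doc.get("comorbidity_links", [])],
        treatments=[tuple(t) for t in doc.get("treatments", [])],
        noise_meds=[tuple(m) for m in doc.get("noise_meds", [])],
        class_map=doc.get("class_map", {}) or {},
        class_preference_effects=[tuple(e) for e in doc.get("class_preference_effects", [])],
        visit_count_mean=float(doc.get("visit_count_mean", 5.0)),
        visit_count_dispersion=float(doc.get("visit_count_dispersion", 1.0)),
        recording_prob=float(doc.get("recording_prob", 1.0)),
        index_condition=doc.get("index_condition"),
        seed=int(doc.get("seed", 0)),
    )


def write_truth(truth: TruthSet, path: str | Path) -> None:
    doc = {
        "true_treatments": [list(p) for p in sorted(truth.true_treatments)],
        "confounded_meds": sorted(truth.confounded_meds),
        "class_effects": [list(e) for e in truth.class_effects],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_truth(path: str | Path) -> TruthSet:
    doc = yaml.safe_load(Path(path).read_text())
    return TruthSet(
        true_treatments=frozenset(tuple(p) for p in doc["true_treatments"]),
        confounded_meds=frozenset(doc["confounded_meds"]),
        class_effects=tuple(tuple(e) for e in doc["class_effects"]),
    )


def write_case_control(ds: CaseControlDataset, prefix: str | Path) -> None:
    prefix = Path(prefix)
    pd.DataFrame(
        {
            "patient_id": ds.patient_ids,
            "label": ds.y,
            "selected_visit": ds.selected_visits,
        }
    ).to_csv(_p(prefix, ".labels.csv"), index=False)
    scipy.io.mmwrite(str(_p(prefix, ".matrix.mtx")), sp.coo_matrix(ds.X))
    ds.columns.to_csv(_p(prefix, ".columns.csv"), index=False)
    _p(prefix, ".meta.yaml").write_text(
        yaml.safe_dump({"index_condition": ds.index_condition})
    )


def read_case_control(prefix: str | Path) -> CaseControlDataset:
    prefix = Path(prefix)
    labels = pd.read_csv(_p(prefix, ".labels.csv"))
    X = sp.csr_matrix(scipy.io.mmread(str(_p(prefix, ".matrix.mtx"))))
    columns = pd.read_csv(_p(prefix, ".columns.csv"), dtype=str)
    meta = yaml.safe_load(_p(prefix, ".meta.yaml").read_text())
    return CaseControlDataset(
        patient_ids=labels["patient_id"].to_numpy(),
        y=labels["label"].to_numpy().astype(np.int8),
        X=X,
        columns=columns,
        selected_visits=labels["selected_visit"].to_numpy(),
        index_condition=meta["index_condition"],
    )


def write_class_choice(ds: ClassChoiceDataset, prefix: str | Path) -> None:
    prefix = Path(prefix)
    pd.DataFrame(
        {
            "patient_id": ds.patient_ids,
            "outcome": ds.outcome,
            "selected_visit": ds.selected_visits,
        }
    ).to_csv(_p(prefix, ".outcomes.csv"), index=False)
    scipy.io.mmwrite(str(_p(prefix, ".matrix.mtx")), sp.coo_matrix(ds.X))
    ds.columns.to_csv(_p(prefix, ".columns.csv"), index=False)
    _p(prefix, ".meta.yaml").write_text(
        yaml.safe_dump(
            {"index_condition": ds.index_condition, "classes": list(ds.classes)}
        )
    )


def read_class_choice(prefix: str | Path) -> ClassChoiceDataset:
    prefix = Path(prefix)
    outcomes = pd.read_csv(_p(prefix, ".outcomes.csv"))
    X = sp.csr_matrix(scipy.io.mmread(str(_p(prefix, ".matrix.mtx"))))
    columns = pd.read_csv(_p(prefix, ".columns.csv"), dtype=str)
    meta = yaml.safe_load(_p(prefix, ".meta.yaml").read_text())
    return ClassChoiceDataset(
        patient_ids=outcomes["patient_id"].to_numpy(),
        outcome=outcomes["outcome"].to_numpy(dtype=object),
        X=X,
        columns=columns,
        selected_visits=outcomes["selected_visit"].to_numpy(),
        classes=tuple(meta["classes"]),
        index_condition=meta["index_condition"],
    )


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)
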