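"""Scoring of ranked association output against an indication reference and
against simulator ground truth.

The reference is a two-column (medication, condition) table emulating a
high-precision medication-indication knowledge base; precision@k asks what
fraction of the top-k ranked medications are known indications for the index
condition.  When simulator ground truth is available, recall of true
treatments and the number of confounder-only medications in the top k measure
whether confounding was actually removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .association import adjust_fdr
from .simulate import TruthSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReferenceSet:
    pairs: frozenset[tuple[str, str]]
    provenance: str = "unspecified"

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self.pairs


@dataclass
class EvaluationReport:
    k: int
    top_k: pd.DataFrame  # concept_id, in_reference
    precision_at_k: float
    n_discoveries: int
    in_reference_discoveries: int
    discovery_proportion: float | None  # None when there are no discoveries
    recall_at_k: float | None = None
    confounders_in_top_k: int | None = None


def load_reference(path: str | Path, provenance: str | None = None) -> ReferenceSet:
    """Read a `medication_id,condition_id` delimited file into a ReferenceSet."""
    path = Path(path)
    pairs: set[tuple[str, str]] = set()
    with path.open() as fh:
        header = fh.readline()
        if header.strip() and header.strip() != "medication_id,condition_id":
            raise ValueError(f"{path}:1: expected header 'medication_id,condition_id'")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 2 or not all(parts):
                raise ValueError(f"{path}:{lineno}: malformed row {line!r}")
            pairs.add((parts[0], parts[1]))
    logger.info("loaded %d reference pairs from %s", len(pairs), path)
    return ReferenceSet(pairs=frozenset(pairs), provenance=provenance or str(path))


def write_reference(ref: ReferenceSet, path: str | Path) -> None:
    frame = pd.DataFrame(sorted(ref.pairs), columns=["medication_id", "condition_id"])
    frame.to_csv(path, index=False)


def precision_at_k(
    ranked_meds: Sequence[str], ref: ReferenceSet, condition: str, k: int
) -> float:
    """Fraction of the top-k ranked medications listed for the condition."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(ranked_meds) < k:
        logger.warning("ranked list shorter than k=%d; evaluating at %d", k, len(ranked_meds))
        k = len(ranked_meds)
    if k == 0:
        return 0.0
    top = list(ranked_meds)[:k]
    return sum((m, condition) in ref for m in top) / k


def discovery_report(
    assoc: pd.DataFrame,
    ref: ReferenceSet,
    condition: str,
    q: float = 0.05,
    k: int = 30,
    truth: TruthSet | None = None,
) -> EvaluationReport:
    """Score a ranked association table (regression or tabulation output).

    Only medication rows count as discoveries (the protocol counts drugs, and
    the regression table may also contain conditions).  The FDR cut applies the
    BH step-up rule at level ``q`` to the medication p-values.  The in-reference
    discovery proportion is reported as None, never 0, when nothing passes.
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    meds = assoc[assoc["kind"] == "medication"] if "kind" in assoc.columns else assoc
    meds = meds.sort_values("rank") if "rank" in meds.columns else meds
    ranked = list(meds["concept_id"])

    k_eff = min(k, len(ranked)) if ranked else 0
    top = pd.DataFrame(
        {
            "concept_id": ranked[:k_eff],
            "in_reference": [(m, condition) in ref for m in ranked[:k_eff]],
        }
    )
    prec = precision_at_k(ranked, ref, condition, k) if ranked else 0.0

    reject, _ = adjust_fdr(meds["p_value"].to_numpy(), q)
    discovered = [m for m, rj in zip(ranked, reject) if rj]
    n_in_ref = sum((m, condition) in ref for m in discovered)
    proportion = n_in_ref / len(discovered) if discovered else None

    recall = confounders = None
    if truth is not None:
        recall, confounders = truth_recovery(ranked, truth, condition, k)
    return EvaluationReport(
        k=k,
        top_k=top,
        precision_at_k=prec,
        n_discoveries=len(discovered),
        in_reference_discoveries=n_in_ref,
        discovery_proportion=proportion,
        recall_at_k=recall,
        confounders_in_top_k=confounders,
    )


def truth_recovery(
    ranked_meds: Sequence[str], truth: TruthSet, condition: str, k: int
) -> tuple[float, int]:
    """(recall of true treatments in the top k, confounder-only meds in the top k)."""
    if truth is None:
        raise ValueError("truth set unavailable")
    true_meds = truth.true_meds(condition)
    top = set(list(ranked_meds)[:k])
    recall = len(top & true_meds) / len(true_meds) if true_meds else 0.0
    confounders = len(top & truth.confounded_meds)
    return recall, confounders


def reference_from_truth(truth: TruthSet, provenance: str = "simulator-truth") -> ReferenceSet:
    """Use the simulator's true treatment pairs as an indication reference."""
    return ReferenceSet(pairs=frozenset(truth.true_treatments), provenance=provenance)
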