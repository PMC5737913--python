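"""Naive tabulation baseline: per-medication 2x2 tables against case/control
status, Fisher's exact test and unadjusted (cross-product) odds ratios.

This is the comparator the regression pipeline is meant to beat: it adjusts
for nothing, so a medication treating a comorbidity of the index condition
shows a spurious marginal association.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CaseControlDataset


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 exposure-by-outcome counts.

    a: cases with the medication, b: controls with it,
    c: cases without, d: controls without.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass(frozen=True)
class FisherResult:
    odds_ratio: float  # cross-product a*d / (b*c); inf or 0 when a cross term is 0
    p_value: float
    degenerate: bool  # True when the odds ratio hit 0 or infinity


def tabulate(ds: CaseControlDataset, concept: str) -> ContingencyTable:
    """2x2 table of one concept column against the case/control labels."""
    j = ds.column_index(concept)
    x = np.asarray(ds.X[:, j].todense()).ravel() > 0
    y = ds.y.astype(bool)
    return ContingencyTable(
        a=int(np.sum(x & y)),
        b=int(np.sum(x & ~y)),
        c=int(np.sum(~x & y)),
        d=int(np.sum(~x & ~y)),
    )


def fisher_test(t: ContingencyTable) -> FisherResult:
    """Two-sided Fisher's exact test with the sample (cross-product) odds ratio.

    Two-sided p sums hypergeometric probabilities of all tables with the
    observed margins whose probability does not exceed the observed table's.
    """
    if t.total == 0:
        raise ValueError("empty contingency table")
    ad, bc = t.a * t.d, t.b * t.c
    if bc == 0:
        odds = np.inf if ad > 0 else np.nan
    else:
        odds = ad / bc
    _, p = stats.fisher_exact(t.as_array(), alternative="two-sided")
    return FisherResult(
        odds_ratio=float(odds), p_value=float(p), degenerate=bool(ad == 0 or bc == 0)
    )


def tabulate_all(ds: CaseControlDataset, kind: str | None = "medication") -> pd.DataFrame:
    """Fisher-tested 2x2 tables for every concept column (of the given kind)."""
    mask = np.ones(len(ds.columns), dtype=bool)
    if kind is not None:
        mask = ds.columns["kind"].to_numpy() == kind
    rows = []
    for j in np.flatnonzero(mask):
        concept = ds.columns["concept_id"].iloc[j]
        t = tabulate(ds, concept)
        res = fisher_test(t)
        rows.append(
            (concept, t.a, t.b, t.c, t.d, res.odds_ratio, res.p_value)
        )
    table = pd.DataFrame(
        rows, columns=["concept_id", "a", "b", "c", "d", "unadjusted_or", "p_value"]
    )
    return rank_tabulation(table)


def rank_tabulation(results: pd.DataFrame) -> pd.DataFrame:
    """Sort by p ascending, ties (including underflow-to-zero) broken by
    odds ratio descending; adds/refreshes the ``rank`` column."""
    if results.empty:
        raise ValueError("no tabulation results to rank")
    table = results.sort_values(
        ["p_value", "unadjusted_or"], ascending=[True, False], kind="mergesort"
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table
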