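"""Synthetic longitudinal EHR mention generator with known treatment structure.

Emulates the long-format output of an NLP/normalization pipeline over outpatient
notes: one row per (patient, visit, concept) where a concept is either a
condition or a medication identifier.  The generative model is deliberately
simple but carries the three structures the downstream statistics must be able
to tell apart:

* direct treatment links — a medication is prescribed, with a configurable
  probability, to patients carrying a specific condition;
* confounding — conditions co-occur via odds multipliers, so a medication
  treating a comorbidity acquires a spurious marginal association with the
  index condition;
* class preference — when several drug classes treat the index condition, the
  class actually chosen follows a multinomial logit whose log-odds are shifted
  by the patient's comorbidities.

Latent per-patient state (conditions held, medications taken) is then observed
through per-visit recording noise: each latent concept is independently
mentioned at each visit with probability ``recording_prob``.  Visit counts are
overdispersed (shifted negative binomial), since real outpatient visit counts
have sd larger than their mean.

Every patient has an independent RNG stream derived from (seed, patient index),
so the table is reproducible and edits to one configuration block perturb the
other draws minimally.  For a fixed configuration shape, each treatment link
consumes exactly one uniform per patient regardless of outcome, which makes
per-medication frequencies monotone in the prescribing probability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError

KIND_CONDITION = "condition"
KIND_MEDICATION = "medication"

MENTION_COLUMNS = ("patient_id", "visit_id", "kind", "concept_id")


@dataclass(frozen=True)
class SimConfig:
    """Generative configuration for one synthetic EHR population.

    Parameters
    ----------
    n_patients
        Number of patients to simulate.
    conditions
        ``(condition_id, marginal_prevalence)`` pairs, sampled in order.
    comorbidity_links
        ``(parent, child, odds_multiplier)`` triples: when the parent condition
        is present (and was sampled before the child), the child's prevalence
        odds are multiplied.
    treatments
        ``(medication_id, condition_id, prescribing_prob)`` triples.
    noise_meds
        ``(medication_id, background_prob)`` pairs — background mentions
        independent of any condition.  A medication may appear both here and in
        ``treatments`` (off-indication mentions).
    class_map
        medication id -> drug-class label, for the class-preference mechanism.
    class_preference_effects
        ``(comorbidity_id, class_label, log_odds_shift)`` triples applied to the
        class-choice logit when the comorbidity is present.
    visit_count_mean
        Mean number of visits per patient (>= 1); counts are
        1 + NegativeBinomial with mean ``visit_count_mean - 1``.
    visit_count_dispersion
        Negative-binomial size parameter r (smaller = more overdispersed).
    recording_prob
        Probability that a latent concept is mentioned at any given visit.
    index_condition
        The condition whose treatments define the ground truth; defaults to the
        first configured condition.
    seed
        Base seed for the per-patient RNG streams.
    """

    n_patients: int
    conditions: Sequence[tuple[str, float]]
    comorbidity_links: Sequence[tuple[str, str, float]] = ()
    treatments: Sequence[tuple[str, str, float]] = ()
    noise_meds: Sequence[tuple[str, float]] = ()
    class_map: Mapping[str, str] = field(default_factory=dict)
    class_preference_effects: Sequence[tuple[str, str, float]] = ()
    visit_count_mean: float = 5.0
    visit_count_dispersion: float = 1.0
    recording_prob: float = 1.0
    index_condition: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        # canonicalize sequences so configs compare equal regardless of
        # list/tuple provenance (e.g. after a YAML round trip)
        for name in ("conditions", "comorbidity_links", "treatments",
                     "noise_meds", "class_preference_effects"):
            value = tuple(tuple(item) for item in getattr(self, name))
            object.__setattr__(self, name, value)
        object.__setattr__(self, "class_map", dict(self.class_map))

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ConfigError("n_patients must be non-negative")
        cond_ids = [c for c, _ in self.conditions]
        if len(set(cond_ids)) != len(cond_ids):
            raise ConfigError("duplicate condition ids")
        for cid, prev in self.conditions:
            if not 0.0 <= prev <= 1.0:
                raise ConfigError(f"prevalence of {cid!r} outside [0, 1]")
        cond_set = set(cond_ids)
        for parent, child, mult in self.comorbidity_links:
            if parent not in cond_set or child not in cond_set:
                raise ConfigError(f"comorbidity link ({parent}, {child}) references unknown condition")
            if mult <= 0:
                raise ConfigError("odds multiplier must be > 0")
        for med, cond, prob in self.treatments:
            if cond not in cond_set:
                raise ConfigError(f"treatment {med!r} targets unknown condition {cond!r}")
            if not 0.0 <= prob <= 1.0:
                raise ConfigError(f"prescribing probability of {med!r} outside [0, 1]")
        for med, prob in self.noise_meds:
            if not 0.0 <= prob <= 1.0:
                raise ConfigError(f"background probability of {med!r} outside [0, 1]")
        classes = set(self.class_map.values())
        for comorbidity, label, _shift in self.class_preference_effects:
            if label not in classes:
                raise ConfigError(f"class preference references unknown class {label!r}")
            if comorbidity not in cond_set:
                raise ConfigError(f"class preference references unknown condition {comorbidity!r}")
        if self.visit_count_mean < 1:
            raise ConfigError("visit_count_mean must be >= 1")
        if self.visit_count_dispersion <= 0:
            raise ConfigError("visit_count_dispersion must be > 0")
        if not 0.0 < self.recording_prob <= 1.0:
            raise ConfigError("recording_prob must be in (0, 1]")
        if self.index_condition is not None and self.index_condition not in cond_set:
            raise ConfigError(f"index_condition {self.index_condition!r} not configured")

    @property
    def resolved_index_condition(self) -> str | None:
        if self.index_condition is not None:
            return self.index_condition
        return self.conditions[0][0] if self.conditions else None


@dataclass
class MentionTable:
    """Long-format (patient, visit, kind, concept) mention records."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in MENTION_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"mention table missing columns {missing}")
        self.frame = self.frame.loc[:, list(MENTION_COLUMNS)].reset_index(drop=True)

    @property
    def empty(self) -> bool:
        return self.frame.empty

    def patients(self) -> np.ndarray:
        return np.sort(self.frame["patient_id"].unique())

    def vocabulary(self) -> pd.DataFrame:
        """Distinct (concept_id, kind) pairs present in the table."""
        return (
            self.frame[["concept_id", "kind"]]
            .drop_duplicates()
            .sort_values("concept_id")
            .reset_index(drop=True)
        )


@dataclass(frozen=True)
class TruthSet:
    """Simulator ground truth, relative to the configured index condition."""

    true_treatments: frozenset[tuple[str, str]]
    confounded_meds: frozenset[str]
    class_effects: tuple[tuple[str, str, float], ...]

    def true_meds(self, condition: str) -> frozenset[str]:
        return frozenset(m for m, c in self.true_treatments if c == condition)


def _patient_rng(seed: int, patient: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(patient,)))


def generate_population(config: SimConfig) -> tuple[MentionTable, TruthSet]:
    """Draw a full synthetic population; deterministic given ``config.seed``."""
    config.validate()
    index = config.resolved_index_condition

    cond_order = [c for c, _ in config.conditions]
    prev = dict(config.conditions)
    cond_pos = {c: i for i, c in enumerate(cond_order)}
    # links applying to a child, restricted to parents sampled earlier
    links_by_child: dict[str, list[tuple[str, float]]] = {}
    for parent, child, mult in config.comorbidity_links:
        if cond_pos[parent] < cond_pos[child]:
            links_by_child.setdefault(child, []).append((parent, mult))

    plain_treatments: list[tuple[str, str, float]] = []
    class_groups: dict[str, dict[str, list[tuple[str, float]]]] = {}
    for med, cond, prob in config.treatments:
        label = config.class_map.get(med)
        if label is None:
            plain_treatments.append((med, cond, prob))
        else:
            class_groups.setdefault(cond, {}).setdefault(label, []).append((med, prob))

    shift = {(c, k): s for c, k, s in config.class_preference_effects}

    mu = config.visit_count_mean - 1.0
    r = config.visit_count_dispersion

    pid_col: list[np.ndarray] = []
    visit_col: list[np.ndarray] = []
    kind_col: list[np.ndarray] = []
    concept_col: list[np.ndarray] = []

    for pid in range(config.n_patients):
        rng = _patient_rng(config.seed, pid)

        present: dict[str, bool] = {}
        for cond in cond_order:
            p = prev[cond]
            mults = [m for parent, m in links_by_child.get(cond, ()) if present.get(parent)]
            if mults and 0.0 < p < 1.0:
                odds = p / (1.0 - p) * math.prod(mults)
                p = odds / (1.0 + odds)
            present[cond] = bool(rng.random() < p)

        meds: set[str] = set()
        for med, cond, prob in plain_treatments:
            u = rng.random()  # always drawn: keeps streams aligned across configs
            if present[cond] and u < prob:
                meds.add(med)
        for cond in cond_order:
            groups = class_groups.get(cond)
            if groups is None:
                continue
            qs = [q for cls in groups.values() for _, q in cls]
            p_any = 1.0 - math.prod(1.0 - q for q in qs)
            u_treat, u_class, u_med = rng.random(3)
            if not (present[cond] and u_treat < p_any):
                continue
            labels = sorted(groups)
            logw = np.array(
                [
                    math.log(sum(q for _, q in groups[k]))
                    + sum(shift.get((c, k), 0.0) for c in cond_order if present[c])
                    for k in labels
                ]
            )
            w = np.exp(logw - logw.max())
            cum = np.cumsum(w / w.sum())
            chosen = labels[int(np.searchsorted(cum, u_class, side="right"))]
            within = groups[chosen]
            wq = np.array([q for _, q in within], dtype=float)
            cumq = np.cumsum(wq / wq.sum())
            meds.add(within[int(np.searchsorted(cumq, u_med, side="right"))][0])
        for med, prob in config.noise_meds:
            u = rng.random()
            if u < prob:
                meds.add(med)

        n_visits = 1 + (int(rng.negative_binomial(r, r / (r + mu))) if mu > 0 else 0)

        latent_ids = [c for c in cond_order if present[c]] + sorted(meds)
        if not latent_ids:
            continue
        kinds = np.array(
            [KIND_CONDITION] * sum(present[c] for c in cond_order) + [KIND_MEDICATION] * len(meds)
        )
        ids = np.array(latent_ids)
        if config.recording_prob >= 1.0:
            rec = np.ones((n_visits, len(ids)), dtype=bool)
        else:
            rec = rng.random((n_visits, len(ids))) < config.recording_prob
        vi, ci = np.nonzero(rec)
        if vi.size:
            pid_col.append(np.full(vi.size, pid))
            visit_col.append(vi)
            kind_col.append(kinds[ci])
            concept_col.append(ids[ci])

    if pid_col:
        frame = pd.DataFrame(
            {
                "patient_id": np.concatenate(pid_col),
                "visit_id": np.concatenate(visit_col),
                "kind": np.concatenate(kind_col),
                "concept_id": np.concatenate(concept_col),
            }
        )
    else:
        frame = pd.DataFrame(
            {
                "patient_id": pd.Series(dtype=np.int64),
                "visit_id": pd.Series(dtype=np.int64),
                "kind": pd.Series(dtype=object),
                "concept_id": pd.Series(dtype=object),
            }
        )
    frame = frame.sort_values(["patient_id", "visit_id", "kind", "concept_id"]).reset_index(drop=True)

    true_pairs = frozenset(
        (med, cond) for med, cond, _ in config.treatments if cond == index
    )
    treated_conditions: dict[str, set[str]] = {}
    for med, cond, _ in config.treatments:
        treated_conditions.setdefault(med, set()).add(cond)
    confounded = frozenset(
        med for med, conds in treated_conditions.items() if index not in conds
    )
    truth = TruthSet(
        true_treatments=true_pairs,
        confounded_meds=confounded,
        class_effects=tuple(config.class_preference_effects),
    )
    return MentionTable(frame), truth


def select_index_visits(
    mentions: MentionTable, index_condition: str, seed: int, require_present: bool = True
) -> pd.DataFrame:
    """One-visit-per-patient selection rule shared by cohort building and summaries.

    Cases (patients with >= 1 visit mentioning the index condition) get a
    uniformly random visit among those mentioning it; controls get a uniformly
    random visit among all their visits.  Returns a frame with columns
    ``patient_id``, ``is_case``, ``selected_visit``, one row per patient,
    sorted by patient id.  Deterministic given ``seed``.
    """
    frame = mentions.frame
    if frame.empty:
        raise ValueError("empty mention table")
    med_ids = set(frame.loc[frame["kind"] == KIND_MEDICATION, "concept_id"].unique())
    if index_condition in med_ids:
        raise ValueError(f"{index_condition!r} is a medication, not a condition")
    cond_ids = set(frame.loc[frame["kind"] == KIND_CONDITION, "concept_id"].unique())
    if require_present and index_condition not in cond_ids:
        raise ValueError(f"index condition {index_condition!r} not in vocabulary")

    visits = frame[["patient_id", "visit_id"]].drop_duplicates()
    index_visits = frame.loc[
        (frame["concept_id"] == index_condition) & (frame["kind"] == KIND_CONDITION),
        ["patient_id", "visit_id"],
    ].drop_duplicates()
    case_ids = set(index_visits["patient_id"].unique())

    eligible = pd.concat(
        [
            index_visits,
            visits[~visits["patient_id"].isin(case_ids)],
        ]
    ).sort_values(["patient_id", "visit_id"], kind="mergesort")

    rng = np.random.default_rng(seed)
    sizes = eligible.groupby("patient_id", sort=True).size()
    offsets = np.concatenate([[0], np.cumsum(sizes.to_numpy())[:-1]])
    picks = offsets + np.floor(rng.random(len(sizes)) * sizes.to_numpy()).astype(np.int64)
    chosen = eligible.iloc[picks].reset_index(drop=True)
    chosen = chosen.rename(columns={"visit_id": "selected_visit"})
    chosen["is_case"] = chosen["patient_id"].isin(case_ids)
    return chosen[["patient_id", "is_case", "selected_visit"]]


def summarize(mentions: MentionTable, index_condition: str, seed: int = 0) -> pd.DataFrame:
    """Case/control summary table: counts, visits and unique concepts per patient.

    Mirrors the usual descriptive table for a case/control mention dataset:
    patient counts, mean (sd) visits, mean (sd) unique conditions/medications
    per patient over all visits and at the one selected visit.
    """
    selection = select_index_visits(mentions, index_condition, seed, require_present=False)
    frame = mentions.frame

    def _stats(sub: pd.DataFrame, sel: pd.DataFrame) -> dict[str, tuple[float, float | None]]:
        pts = sel["patient_id"]
        visits = sub[["patient_id", "visit_id"]].drop_duplicates().groupby("patient_id").size()
        visits = visits.reindex(pts, fill_value=0)

        def per_patient_unique(kind: str, selected_only: bool) -> pd.Series:
            rows = sub[sub["kind"] == kind]
            if selected_only:
                rows = rows.merge(
                    sel.rename(columns={"selected_visit": "visit_id"})[["patient_id", "visit_id"]],
                    on=["patient_id", "visit_id"],
                )
            counts = rows.groupby("patient_id")["concept_id"].nunique()
            return counts.reindex(pts, fill_value=0)

        out: dict[str, tuple[float, float | None]] = {
            "n_patients": (float(len(pts)), None),
            "visits_per_patient": (visits.mean(), visits.std()),
        }
        for kind, label in ((KIND_CONDITION, "conditions"), (KIND_MEDICATION, "medications")):
            allv = per_patient_unique(kind, selected_only=False)
            selv = per_patient_unique(kind, selected_only=True)
            out[f"unique_{label}_all_visits"] = (allv.mean(), allv.std())
            out[f"unique_{label}_selected_visit"] = (selv.mean(), selv.std())
        return out

    rows = []
    for is_case, label in ((True, "cases"), (False, "controls")):
        sel = selection[selection["is_case"] == is_case]
        sub = frame[frame["patient_id"].isin(sel["patient_id"])]
        stats = _stats(sub, sel) if len(sel) else {}
        rows.append((label, stats))

    statistics = [
        "n_patients",
        "visits_per_patient",
        "unique_conditions_all_visits",
        "unique_medications_all_visits",
        "unique_conditions_selected_visit",
        "unique_medications_selected_visit",
    ]
    data = {"statistic": statistics}
    for label, stats in rows:
        data[f"{label}_mean"] = [stats.get(s, (0.0, None))[0] for s in statistics]
        data[f"{label}_sd"] = [stats.get(s, (0.0, None))[1] for s in statistics]
    return pd.DataFrame(data)
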