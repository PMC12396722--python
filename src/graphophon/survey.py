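"""Forced-choice survey analysis.

Each participant sees a series of questions; in each, one phoneme pair is
shown with three candidate symbol pairs, one per systematicity type
(english / chinese / korean), and the participant picks the pair they feel
fits the sounds. A follow-up asks which symbol maps to which phoneme, and
the ``assignment_consistent`` flag records whether that follow-up matched
the material's L1→P1 orientation.

The analysis computes per-group preference proportions over the three
types, the rate of choosing the type *designated* for one's language group
(UK→english, CN→chinese, KR→korean), a Monte Carlo null distribution of
proportions under uniform random choice, tie-inclusive two-sided Monte
Carlo p-values, and a question-level preference correlation matrix.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .systematicity import MATERIAL_TYPES

__all__ = [
    "GROUPS",
    "DEFAULT_DESIGNATION",
    "ResponseSet",
    "NullDistribution",
    "preference_proportions",
    "intended_rate",
    "mapping_consistency_rate",
    "permutation_null",
    "permutation_p_value",
    "question_preference_matrix",
    "preference_correlation_matrix",
    "significance_stars",
]

GROUPS = ("UK", "CN", "KR")

# Which systematicity type each language group's own writing system exhibits.
DEFAULT_DESIGNATION = {"UK": "english", "CN": "chinese", "KR": "korean"}

_COLUMNS = ["participant_id", "group", "question_id", "chosen_type", "assignment_consistent"]


@dataclasses.dataclass
class ResponseSet:
    """Long-format forced-choice records, one row per participant × question."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"response table missing columns {missing}")
        bad_groups = set(df["group"]) - set(GROUPS)
        if bad_groups:
            raise ValueError(f"unknown groups {sorted(bad_groups)}; expected {GROUPS}")
        bad_types = set(df["chosen_type"]) - set(MATERIAL_TYPES)
        if bad_types:
            raise ValueError(f"unknown chosen_type values {sorted(bad_types)}")
        if df.duplicated(["participant_id", "question_id"]).any():
            raise ValueError("duplicate participant × question records")
        per_participant = df.groupby("participant_id")["question_id"].agg(frozenset)
        if per_participant.nunique() != 1:
            raise ValueError("question_ids must be identical (complete) for every participant")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def groups(self) -> list[str]:
        return [g for g in GROUPS if g in set(self.records["group"])]

    @property
    def question_ids(self) -> list[int]:
        return sorted(self.records["question_id"].unique())

    def group_records(self, group: str) -> pd.DataFrame:
        if group not in set(self.records["group"]):
            raise KeyError(f"group {group!r} not present")
        return self.records[self.records["group"] == group]

    @classmethod
    def from_csv(cls, path) -> "ResponseSet":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


def preference_proportions(r: ResponseSet, group: str) -> dict[str, float]:
    """Fraction of a group's choices falling on each systematicity type;
    sums to 1."""
    recs = r.group_records(group)
    counts = recs["chosen_type"].value_counts()
    n = len(recs)
    return {t: float(counts.get(t, 0)) / n for t in MATERIAL_TYPES}


def intended_rate(r: ResponseSet, designation: dict[str, str] | None = None) -> dict[str, float]:
    """Per group, the fraction of choices equal to the type designated for
    that group (defaults to each group's native-script type)."""
    designation = designation if designation is not None else DEFAULT_DESIGNATION
    out = {}
    for group in r.groups:
        if group not in designation:
            raise KeyError(f"no designated type for group {group!r}")
        recs = r.group_records(group)
        out[group] = float((recs["chosen_type"] == designation[group]).mean())
    return out


def mapping_consistency_rate(r: ResponseSet) -> float:
    """Fraction of follow-up symbol→phoneme assignments matching the
    material's L1→P1 orientation."""
    flags = r.records["assignment_consistent"]
    if flags.isna().any():
        raise ValueError("assignment_consistent has missing values")
    return float(flags.astype(bool).mean())


@dataclasses.dataclass
class NullDistribution:
    """Monte Carlo null: per replicate, the type proportions that result
    when every choice is uniform over the three types."""

    replicates: np.ndarray  # (reps, 3), columns in MATERIAL_TYPES order
    reps: int
    n_participants: int
    n_questions: int
    seed: int

    def column(self, chosen_type: str) -> np.ndarray:
        return self.replicates[:, MATERIAL_TYPES.index(chosen_type)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.replicates, columns=list(MATERIAL_TYPES))


def permutation_null(
    n_participants: int, n_questions: int = 10, reps: int = 10_000, seed: int = 0
) -> NullDistribution:
    """Simulate ``reps`` survey replicates of n_participants × n_questions
    i.i.d. uniform choices over the three types and record the resulting
    proportions."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    n = n_participants * n_questions
    counts = rng.multinomial(n, [1 / 3] * 3, size=reps)
    return NullDistribution(counts / n, reps, n_participants, n_questions, seed)


def permutation_p_value(null: NullDistribution, observed: float, chosen_type: str = "korean") -> float:
    """Two-sided Monte Carlo p: the (add-one smoothed, tie-inclusive)
    fraction of null replicates at least as far from 1/3 as the observed
    proportion."""
    dev = abs(observed - 1 / 3)
    null_dev = np.abs(null.column(chosen_type) - 1 / 3)
    extreme = int(np.count_nonzero(null_dev >= dev))
    return (extreme + 1) / (null.reps + 1)


def question_preference_matrix(
    r: ResponseSet, designation: dict[str, str] | None = None
) -> pd.DataFrame:
    """Per-question selection-pattern vectors: for each group, the
    proportion preferring each of the three types plus the proportion
    selecting the group's designated (intended) type — 4 vectors per group,
    indexed by a human-readable label, columns = question ids."""
    designation = designation if designation is not None else DEFAULT_DESIGNATION
    questions = r.question_ids
    rows = {}
    for group in r.groups:
        recs = r.group_records(group)
        per_q = recs.groupby("question_id")["chosen_type"]
        if sorted(per_q.groups) != questions:
            raise ValueError(f"group {group!r} missing questions")
        for t in MATERIAL_TYPES:
            vec = per_q.apply(lambda s, t=t: float((s == t).mean()))
            rows[f"{group} preferring {t.capitalize()}"] = vec.reindex(questions).to_numpy()
        intended = designation[group]
        vec = per_q.apply(lambda s: float((s == intended).mean()))
        rows[f"{group} selecting {intended.capitalize()} (intended)"] = vec.reindex(questions).to_numpy()
    return pd.DataFrame(rows, index=questions).T


def preference_correlation_matrix(vectors: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlation of the selection-pattern vectors.

    Returns (r matrix, p matrix); a cell involving a constant vector is NaN
    in both. Diagonal r = 1, p = 0.
    """
    if vectors.shape[1] < 3:
        raise ValueError("need at least 3 questions to correlate")
    labels = list(vectors.index)
    k = len(labels)
    r_mat = np.full((k, k), np.nan)
    p_mat = np.full((k, k), np.nan)
    arr = vectors.to_numpy(dtype=float)
    for i in range(k):
        r_mat[i, i], p_mat[i, i] = 1.0, 0.0
        for j in range(i + 1, k):
            if np.std(arr[i]) == 0 or np.std(arr[j]) == 0:
                continue
            r, p = stats.pearsonr(arr[i], arr[j])
            r_mat[i, j] = r_mat[j, i] = r
            p_mat[i, j] = p_mat[j, i] = p
    return (
        pd.DataFrame(r_mat, index=labels, columns=labels),
        pd.DataFrame(p_mat, index=labels, columns=labels),
    )


def significance_stars(p: float) -> str:
    """Conventional star coding: * p<.05, ** p<.01, *** p<.001."""
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""
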