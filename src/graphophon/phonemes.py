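"""Phoneme feature vectors and phonetic distance metrics.

Phonemes live in a numeric feature space (typically binary articulatory
features: voicing, nasality, place, manner, ...). Four pairwise distances
are provided — Euclidean, cosine, Jaccard, and feature-edit (Hamming) — and
a reference pairwise-distance table for the ten consonant pairs used in the
forced-choice study ships as a built-in fixture. The underlying feature
inventory behind that table is not public, so the fixture is the distance
table itself, not vectors; user-supplied feature tables are first-class.
"""

from __future__ import annotations

import dataclasses
import itertools
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PhonemeFeatureTable",
    "PhoneticDistanceTable",
    "euclidean_distance",
    "cosine_distance",
    "jaccard_distance",
    "feature_edit_distance",
    "reference_distance_table",
    "distance_table_from_features",
    "table1_correlations",
]


@dataclasses.dataclass
class PhonemeFeatureTable:
    """Ordered phoneme labels with one fixed-length numeric feature vector each."""

    phonemes: list[str]
    vectors: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if len(set(self.phonemes)) != len(self.phonemes):
            raise ValueError("phoneme labels must be unique")
        if len(self.phonemes) < 2:
            raise ValueError("need at least 2 phonemes")
        lengths = {len(np.atleast_1d(self.vectors[p])) for p in self.phonemes}
        if len(lengths) != 1:
            raise ValueError(f"feature vectors have inconsistent lengths {sorted(lengths)}")
        self.vectors = {p: np.asarray(self.vectors[p], dtype=float) for p in self.phonemes}

    @property
    def n_features(self) -> int:
        return len(self.vectors[self.phonemes[0]])

    def is_binary(self) -> bool:
        return all(np.isin(v, (0.0, 1.0)).all() for v in self.vectors.values())

    @classmethod
    def from_csv(cls, path: str | Path) -> "PhonemeFeatureTable":
        """First column = phoneme label, remaining columns numeric features."""
        df = pd.read_csv(path)
        labels = df.iloc[:, 0].astype(str).tolist()
        vecs = {lab: df.iloc[i, 1:].to_numpy(dtype=float) for i, lab in enumerate(labels)}
        return cls(labels, vecs)

    def to_csv(self, path: str | Path) -> None:
        rows = [{"phoneme": p, **{f"f{i}": v for i, v in enumerate(self.vectors[p])}} for p in self.phonemes]
        pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# pairwise metrics


def _check_lengths(u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1:
        raise ValueError(f"feature vectors must be 1-D and equal length; got {u.shape} vs {v.shape}")
    return u, v


def euclidean_distance(u, v) -> float:
    u, v = _check_lengths(u, v)
    return float(np.linalg.norm(u - v))


def cosine_distance(u, v) -> float:
    """1 − cos(u, v); requires both vectors non-zero. In [0, 1] for
    non-negative vectors."""
    u, v = _check_lengths(u, v)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine distance undefined for a zero vector")
    return float(1.0 - np.dot(u, v) / (nu * nv))


def jaccard_distance(u, v) -> float:
    """1 − |supp(u) ∩ supp(v)| / |supp(u) ∪ supp(v)| for binary vectors.

    Non-binary input is rejected rather than silently thresholded.
    """
    u, v = _check_lengths(u, v)
    if not (np.isin(u, (0.0, 1.0)).all() and np.isin(v, (0.0, 1.0)).all()):
        raise ValueError("jaccard distance requires binary feature vectors")
    union = np.count_nonzero((u == 1) | (v == 1))
    if union == 0:
        raise ValueError("jaccard distance undefined when both vectors are all-zero")
    inter = np.count_nonzero((u == 1) & (v == 1))
    return float(1.0 - inter / union)


def feature_edit_distance(u, v) -> int:
    """Number of feature positions in which the two vectors differ."""
    u, v = _check_lengths(u, v)
    return int(np.count_nonzero(u != v))


# ---------------------------------------------------------------------------
# distance tables

_METRIC_COLUMNS = ["euclidean", "cosine", "jaccard", "feature_edit"]

# Ten consonant pairs with their pairwise distances under the four metrics,
# spanning Euclidean 1 to 2.24 (the feature space's maximum) in an even
# spread — the stimulus-design input for the forced-choice study.
_REFERENCE_ROWS = [
    ("g", "s", 2.24, 1.00, 1.00, 5),
    ("h", "m", 2.24, 1.00, 1.00, 5),
    ("k", "s", 2.00, 1.00, 1.00, 4),
    ("p", "h", 2.00, 1.00, 1.00, 2),
    ("b", "k", 1.73, 0.59, 0.75, 3),
    ("p", "g", 1.73, 0.59, 0.75, 3),
    ("b", "m", 1.41, 0.33, 0.50, 2),
    ("h", "s", 1.41, 0.50, 0.67, 2),
    ("k", "g", 1.00, 0.18, 0.33, 1),
    ("p", "b", 1.00, 0.18, 0.33, 1),
]


@dataclasses.dataclass
class PhoneticDistanceTable:
    """Long-format pairwise phonetic distances under the four metrics.

    ``rows`` has columns phoneme_1, phoneme_2, euclidean, cosine, jaccard,
    feature_edit.
    """

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ["phoneme_1", "phoneme_2", *_METRIC_COLUMNS] if c not in self.rows.columns]
        if missing:
            raise ValueError(f"distance table missing columns {missing}")
        r = self.rows
        if (r[_METRIC_COLUMNS] < 0).any().any():
            raise ValueError("distances must be non-negative")
        if ((r["cosine"] > 1) | (r["jaccard"] > 1)).any():
            raise ValueError("cosine and jaccard distances must lie in [0, 1]")
        if not np.allclose(r["feature_edit"], np.round(r["feature_edit"])):
            raise ValueError("feature_edit must be integer-valued")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return list(zip(self.rows["phoneme_1"].astype(str), self.rows["phoneme_2"].astype(str)))

    def distances(self, metric: str = "euclidean") -> np.ndarray:
        if metric not in _METRIC_COLUMNS:
            raise ValueError(f"unknown phonetic metric {metric!r}")
        return self.rows[metric].to_numpy(dtype=float)

    def lookup(self, p1: str, p2: str, metric: str = "euclidean") -> float:
        r = self.rows
        hit = r[((r.phoneme_1 == p1) & (r.phoneme_2 == p2)) | ((r.phoneme_1 == p2) & (r.phoneme_2 == p1))]
        if hit.empty:
            raise KeyError(f"phoneme pair ({p1!r}, {p2!r}) not in distance table")
        return float(hit.iloc[0][metric])

    @classmethod
    def from_csv(cls, path: str | Path) -> "PhoneticDistanceTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.rows.to_csv(path, index=False)


def reference_distance_table() -> PhoneticDistanceTable:
    """The built-in ten-pair consonant distance table (see module docstring)."""
    return PhoneticDistanceTable(
        pd.DataFrame(_REFERENCE_ROWS, columns=["phoneme_1", "phoneme_2", *_METRIC_COLUMNS])
    )


def distance_table_from_features(table: PhonemeFeatureTable) -> PhoneticDistanceTable:
    """All-pairs distance table computed from a feature table. Jaccard is
    included only when the features are binary (NaN otherwise)."""
    binary = table.is_binary()
    rows = []
    for p1, p2 in itertools.combinations(table.phonemes, 2):
        u, v = table.vectors[p1], table.vectors[p2]
        rows.append(
            {
                "phoneme_1": p1,
                "phoneme_2": p2,
                "euclidean": euclidean_distance(u, v),
                "cosine": cosine_distance(u, v),
                "jaccard": jaccard_distance(u, v) if binary else np.nan,
                "feature_edit": feature_edit_distance(u, v),
            }
        )
    return PhoneticDistanceTable(pd.DataFrame(rows))


def table1_correlations(t: PhoneticDistanceTable, ndigits: int = 2) -> dict[str, float]:
    """Pearson r between the Euclidean column and each other metric column,
    rounded to ``ndigits`` (2 by default, matching how such tables are
    printed)."""
    if len(t) < 3:
        raise ValueError("need at least 3 rows to correlate")
    eu = t.distances("euclidean")
    out = {}
    for col in ("cosine", "jaccard", "feature_edit"):
        other = t.distances(col)
        if np.std(eu) == 0 or np.std(other) == 0:
            raise ValueError(f"correlation with {col!r} undefined: constant column")
        r, _ = stats.pearsonr(eu, other)
        out[f"euclidean_vs_{col}"] = round(float(r), ndigits)
    return out
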