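"""Scoring materials for grapho-phonemic systematicity.

A *material* is a set of matched (phoneme pair, symbol pair) items — ten in
the standard design — built so that the pairwise distances between the two
symbols of each item track the phonetic distances between the two phonemes
under one intended glyph metric (pixel count for the English-type material,
perimetric complexity for the Chinese-type, Hausdorff for the Korean-type).
Systematicity is the correlation, over items, between the phonetic distance
vector and the glyph distance vector. Cross-validation scores each material
under all three glyph metrics; a material is *exclusive* when it is
significant only under its intended metric.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .glyphs import METRICS, GlyphLibrary, glyph_distance
from .phonemes import PhoneticDistanceTable

__all__ = [
    "MATERIAL_TYPES",
    "TYPE_TO_METRIC",
    "METRIC_TO_TYPE",
    "Material",
    "SystematicityScore",
    "pair_distance_vectors",
    "score_systematicity",
    "score_material",
    "crossval_matrix",
    "exclusivity_check",
    "crossval_to_frame",
]

# Material type <-> the glyph metric its symbol pairs were optimized under.
MATERIAL_TYPES = ("english", "chinese", "korean")
TYPE_TO_METRIC = {"english": "pixel", "chinese": "pc", "korean": "hausdorff"}
METRIC_TO_TYPE = {v: k for k, v in TYPE_TO_METRIC.items()}


@dataclasses.dataclass
class Material:
    """Matched phoneme/symbol pairs, oriented so glyph L1 encodes phoneme P1
    and L2 encodes P2 in each item."""

    material_type: str
    pairs: list[tuple[str, str, str, str]]  # (phoneme_1, phoneme_2, glyph_L1, glyph_L2)
    intended_metric: str

    def __post_init__(self) -> None:
        if self.material_type not in MATERIAL_TYPES:
            raise ValueError(f"material_type must be one of {MATERIAL_TYPES}")
        if self.intended_metric not in METRICS:
            raise ValueError(f"intended_metric must be one of {METRICS}")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def glyph_ids(self) -> list[str]:
        return [g for (_, _, l1, l2) in self.pairs for g in (l1, l2)]

    def validate_standard(self) -> None:
        """Enforce the standard design: exactly 10 items over 20 distinct glyphs."""
        if len(self.pairs) != 10:
            raise ValueError(f"standard material needs 10 pairs, got {len(self.pairs)}")
        if len(set(self.glyph_ids)) != 20:
            raise ValueError("standard material needs 20 distinct glyphs")

    @classmethod
    def from_csv(cls, path: str | Path) -> "Material":
        df = pd.read_csv(path)
        if "pair_index" in df.columns:
            df = df.sort_values("pair_index")
        mtype = str(df["material_type"].iloc[0])
        pairs = [
            (str(r.phoneme_1), str(r.phoneme_2), str(r.glyph_L1), str(r.glyph_L2))
            for r in df.itertuples(index=False)
        ]
        return cls(mtype, pairs, TYPE_TO_METRIC[mtype])

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {
                "pair_index": i + 1,
                "phoneme_1": p1,
                "phoneme_2": p2,
                "glyph_L1": l1,
                "glyph_L2": l2,
                "material_type": self.material_type,
            }
            for i, (p1, p2, l1, l2) in enumerate(self.pairs)
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


@dataclasses.dataclass(frozen=True)
class SystematicityScore:
    """Pearson and Spearman correlation of the n paired distances."""

    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    n: int


def pair_distance_vectors(
    m: Material,
    pd_table: PhoneticDistanceTable,
    lib: GlyphLibrary,
    metric: str,
    phonetic_metric: str = "euclidean",
) -> tuple[np.ndarray, np.ndarray]:
    """Item-aligned (phonetic distances, glyph distances) vectors for a
    material, glyph distances under the named metric."""
    phon = np.array([pd_table.lookup(p1, p2, phonetic_metric) for (p1, p2, _, _) in m.pairs])
    glyph = np.array([glyph_distance(lib[l1], lib[l2], metric) for (_, _, l1, l2) in m.pairs])
    return phon, glyph


def score_systematicity(x: np.ndarray, y: np.ndarray) -> SystematicityScore:
    """Correlate two aligned distance vectors.

    Pearson r with a two-sided p from the t distribution on n−2 df, and
    Spearman rho (average ranks on ties) with its standard two-sided p.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("distance vectors must be 1-D and equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 paired distances")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: constant distance vector")
    pr, pp = stats.pearsonr(x, y)
    sr, sp = stats.spearmanr(x, y)
    return SystematicityScore(float(pr), float(pp), float(sr), float(sp), n)


def score_material(
    m: Material, pd_table: PhoneticDistanceTable, lib: GlyphLibrary, metric: str | None = None
) -> SystematicityScore:
    """Score a material under a glyph metric (its intended metric if None)."""
    metric = metric or m.intended_metric
    phon, glyph = pair_distance_vectors(m, pd_table, lib, metric)
    return score_systematicity(phon, glyph)


def crossval_matrix(
    materials: list[Material], pd_table: PhoneticDistanceTable, lib: GlyphLibrary
) -> dict[str, dict[str, SystematicityScore]]:
    """Score every material under every glyph metric.

    Returns ``{metric: {material_type: score}}`` — rows are metrics, columns
    materials, the diagonal being each material's intended-metric score.
    """
    if len({m.intended_metric for m in materials}) != len(materials):
        raise ValueError("materials must have distinct intended metrics")
    return {
        metric: {m.material_type: score_material(m, pd_table, lib, metric) for m in materials}
        for metric in METRICS
    }


def exclusivity_check(
    cv: dict[str, dict[str, SystematicityScore]], alpha: float = 0.05
) -> dict[str, dict]:
    """Per material: pass iff Pearson p < alpha under the intended metric and
    Pearson p >= alpha under both other metrics. Exclusivity is judged on
    Pearson only; Spearman is reported alongside but not gated."""
    out: dict[str, dict] = {}
    material_types = next(iter(cv.values())).keys()
    for mtype in material_types:
        intended = TYPE_TO_METRIC[mtype]
        reasons = []
        s_int = cv[intended][mtype]
        if not s_int.pearson_p < alpha:
            reasons.append(f"intended metric {intended}: pearson_p={s_int.pearson_p:.3g} >= alpha")
        for metric in METRICS:
            if metric == intended:
                continue
            s_off = cv[metric][mtype]
            if s_off.pearson_p < alpha:
                reasons.append(f"off metric {metric}: pearson_p={s_off.pearson_p:.3g} < alpha")
        out[mtype] = {"passed": not reasons, "reasons": reasons}
    return out


def crossval_to_frame(cv: dict[str, dict[str, SystematicityScore]]) -> pd.DataFrame:
    """Cross-validation grid as a tidy DataFrame (metric × material rows)."""
    rows = []
    for metric, by_mat in cv.items():
        for mtype, s in by_mat.items():
            rows.append(
                {
                    "metric": metric,
                    "material_type": mtype,
                    "pearson_r": s.pearson_r,
                    "pearson_p": s.pearson_p,
                    "spearman_rho": s.spearman_rho,
                    "spearman_p": s.spearman_p,
                    "n": s.n,
                }
            )
    return pd.DataFrame(rows)
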