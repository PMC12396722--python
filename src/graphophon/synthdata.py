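"""Synthetic inputs for every pipeline stage.

Real stimulus libraries for this kind of study are rasterized archaic
letterforms (Phoenician, Aramaic, Old Hungarian, Mkhedruli); the survey
data are forced-choice records from human participants. Neither is needed
here: this module generates structurally equivalent stand-ins.

Glyphs are *stroke/blob compositions*, not pixel noise, so the three shape
metrics stay partially decoupled the way they are for real letterforms:
total ink (stroke count, blob area) drives pixel count, boundary
jaggedness drives perimetric complexity, and the spatial placement of
components (a small "satellite" stroke away from the main body) drives the
Hausdorff distance. That decoupling is what makes *planted* libraries
possible: glyph pairs engineered so that their distances under one target
metric follow an affine map of a prescribed phonetic-distance vector while
the other two metrics carry no signal.

Simulated respondents draw each forced choice i.i.d. from a per-group
multinomial over the three systematicity types; an optional Dirichlet
overdispersion adds participant-level preference heterogeneity.

All generators are reproducible from their seed.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .glyphs import (
    GlyphLibrary,
    GlyphRaster,
    hausdorff_distance,
    perimetric_complexity,
)
from .phonemes import PhonemeFeatureTable
from .survey import GROUPS, ResponseSet
from .systematicity import METRIC_TO_TYPE, Material

__all__ = [
    "GlyphGenConfig",
    "ResponseGenConfig",
    "generate_glyph_library",
    "generate_feature_space",
    "plant_material_library",
    "simulate_responses",
]


# ---------------------------------------------------------------------------
# low-level raster primitives


def _grow_blob(
    rng: np.random.Generator,
    canvas: tuple[int, int],
    area: int,
    jaggedness: float,
    start: tuple[int, int],
    occupied: np.ndarray | None = None,
) -> np.ndarray:
    """Connected region of exactly ``area`` pixels grown from ``start``.

    ``jaggedness`` in [0, 1] biases growth: 0 prefers frontier cells with
    many ink neighbours (compact, low perimeter), 1 prefers cells with few
    (dendritic, high perimeter). Growth never enters ``occupied`` cells, so
    pixel budgets stay exact when several components share a canvas.
    """
    rows, cols = canvas
    grid = np.zeros(canvas, dtype=bool)
    blocked = occupied if occupied is not None else np.zeros(canvas, dtype=bool)
    r0 = min(max(start[0], 0), rows - 1)
    c0 = min(max(start[1], 0), cols - 1)
    if blocked[r0, c0]:  # nudge to a free cell nearby
        free = np.argwhere(~blocked)
        if len(free) == 0:
            raise ValueError("canvas full: cannot grow blob")
        d2 = ((free - (r0, c0)) ** 2).sum(axis=1)
        r0, c0 = free[int(np.argmin(d2))]
    grid[r0, c0] = True
    frontier: dict[tuple[int, int], int] = {}
    gamma = 2.5 * (1.0 - 2.0 * jaggedness)  # >0 compact, <0 dendritic

    def add_neighbours(r: int, c: int) -> None:
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < rows and 0 <= cc < cols and not grid[rr, cc] and not blocked[rr, cc]:
                frontier[(rr, cc)] = frontier.get((rr, cc), 0) + 1

    add_neighbours(r0, c0)
    while grid.sum() < area:
        if not frontier:
            raise ValueError(f"blob growth stuck at {int(grid.sum())} of {area} pixels")
        cells = list(frontier)
        w = np.exp(gamma * np.array([frontier[c] for c in cells], dtype=float))
        pick = cells[int(rng.choice(len(cells), p=w / w.sum()))]
        del frontier[pick]
        grid[pick] = True
        add_neighbours(*pick)
    return grid


def _grow_attached(
    rng: np.random.Generator,
    canvas: tuple[int, int],
    area: int,
    jaggedness: float,
    body: np.ndarray,
    max_tries: int = 30,
) -> np.ndarray:
    """Blob of exact ``area`` grown from a free cell bordering ``body``
    (dendritic bodies leave one-cell pockets where growth stalls, hence the
    retries over different border cells)."""
    border = np.zeros_like(body)
    border[1:, :] |= body[:-1, :]
    border[:-1, :] |= body[1:, :]
    border[:, 1:] |= body[:, :-1]
    border[:, :-1] |= body[:, 1:]
    candidates = np.argwhere(border & ~body)
    if len(candidates) == 0:
        raise ValueError("body has no free border cells")
    for _ in range(max_tries):
        start = candidates[int(rng.integers(len(candidates)))]
        try:
            return _grow_blob(rng, canvas, area, jaggedness, tuple(start), occupied=body)
        except ValueError:
            continue
    raise ValueError("could not grow an attached blob")


def _stamp(grid: np.ndarray, pattern: np.ndarray, top: int, left: int) -> None:
    """OR a small relative pattern into a grid at (top, left), clipped."""
    pr, pc = pattern.shape
    rows, cols = grid.shape
    r0, c0 = max(top, 0), max(left, 0)
    r1, c1 = min(top + pr, rows), min(left + pc, cols)
    if r1 <= r0 or c1 <= c0:
        return
    grid[r0:r1, c0:c1] |= pattern[r0 - top : r1 - top, c0 - left : c1 - left]


def _line_cells(r0: int, c0: int, r1: int, c1: int) -> list[tuple[int, int]]:
    """Bresenham line between two cells (inclusive)."""
    from skimage.draw import line

    rr, cc = line(r0, c0, r1, c1)
    return list(zip(rr.tolist(), cc.tolist()))


# ---------------------------------------------------------------------------
# generic stroke-composition library


@dataclasses.dataclass
class GlyphGenConfig:
    """Controls for the generic stroke-composition glyph generator.

    ``stroke_count_range`` spreads ink area; ``jagged_fraction`` mixes
    straight strokes with random-walk (jagged) strokes to spread perimetric
    complexity; stroke placement spreads Hausdorff distance. ``plant``
    optionally reserves the first glyphs for a *stroke ladder*: pairs
    (base_i, base_i + i extra disjoint strokes) whose pixel-count distance
    increases strictly with i.
    """

    n_glyphs: int = 40
    canvas: tuple[int, int] = (48, 48)
    stroke_count_range: tuple[int, int] = (1, 10)
    stroke_length: int = 12
    jagged_fraction: float = 0.5
    plant: dict | None = None  # e.g. {"kind": "stroke_ladder", "n_pairs": 10}
    seed: int = 0

    def __post_init__(self) -> None:
        if self.canvas[0] < 16 or self.canvas[1] < 16:
            raise ValueError("canvas must be at least 16×16")
        lo, hi = self.stroke_count_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid stroke_count_range")


def _random_stroke(
    rng: np.random.Generator, canvas: tuple[int, int], length: int, jagged: bool
) -> list[tuple[int, int]]:
    rows, cols = canvas
    r, c = int(rng.integers(1, rows - 1)), int(rng.integers(1, cols - 1))
    if jagged:
        cells = [(r, c)]
        for _ in range(length - 1):
            dr, dc = [(1, 0), (-1, 0), (0, 1), (0, -1)][int(rng.integers(4))]
            r = min(max(r + dr, 0), rows - 1)
            c = min(max(c + dc, 0), cols - 1)
            cells.append((r, c))
        return cells
    theta = rng.uniform(0, 2 * math.pi)
    r1 = min(max(int(round(r + (length - 1) * math.sin(theta))), 0), rows - 1)
    c1 = min(max(int(round(c + (length - 1) * math.cos(theta))), 0), cols - 1)
    return _line_cells(r, c, r1, c1)


def _stroke_glyph(
    rng: np.random.Generator, cfg: GlyphGenConfig, n_strokes: int
) -> np.ndarray:
    grid = np.zeros(cfg.canvas, dtype=bool)
    for _ in range(n_strokes):
        jagged = rng.random() < cfg.jagged_fraction
        for cell in _random_stroke(rng, cfg.canvas, cfg.stroke_length, jagged):
            grid[cell] = True
    if not grid.any():  # degenerate stroke collapsed to nothing; force one pixel
        grid[cfg.canvas[0] // 2, cfg.canvas[1] // 2] = True
    return grid


def _add_disjoint_strokes(
    rng: np.random.Generator, grid: np.ndarray, k: int, length: int, max_tries: int = 200
) -> np.ndarray:
    """Add k strokes of exactly ``length`` fresh pixels each (no overlap with
    existing ink), so the pixel count rises by exactly k·length."""
    out = grid.copy()
    rows, cols = out.shape
    for _ in range(k):
        for attempt in range(max_tries):
            horizontal = rng.random() < 0.5
            if horizontal:
                r = int(rng.integers(rows))
                c = int(rng.integers(cols - length))
                cells = [(r, c + i) for i in range(length)]
            else:
                r = int(rng.integers(rows - length))
                c = int(rng.integers(cols))
                cells = [(r + i, c) for i in range(length)]
            if all(not out[cell] for cell in cells):
                for cell in cells:
                    out[cell] = True
                break
        else:
            raise ValueError("canvas too crowded to place a disjoint stroke (plant infeasible)")
    return out


def generate_glyph_library(cfg: GlyphGenConfig) -> GlyphLibrary:
    """Random stroke-composition library; see :class:`GlyphGenConfig`."""
    rng = np.random.default_rng(cfg.seed)
    glyphs: list[GlyphRaster] = []
    if cfg.plant is not None:
        if cfg.plant.get("kind") != "stroke_ladder":
            raise ValueError(f"unknown plant kind {cfg.plant.get('kind')!r}")
        n_pairs = int(cfg.plant.get("n_pairs", 10))
        length = int(cfg.plant.get("stroke_pixels", cfg.stroke_length))
        if 2 * n_pairs > cfg.n_glyphs:
            raise ValueError("plant needs 2·n_pairs <= n_glyphs")
        max_extra = n_pairs * length
        if max_extra > cfg.canvas[0] * cfg.canvas[1] // 4:
            raise ValueError("stroke ladder exceeds canvas capacity (plant infeasible)")
        for i in range(1, n_pairs + 1):
            base = _stroke_glyph(rng, cfg, int(rng.integers(*cfg.stroke_count_range)) + 1)
            partner = _add_disjoint_strokes(rng, base, i, length)
            glyphs.append(GlyphRaster(f"plant{i:02d}a", base))
            glyphs.append(GlyphRaster(f"plant{i:02d}b", partner))
    lo, hi = cfg.stroke_count_range
    while len(glyphs) < cfg.n_glyphs:
        n_strokes = int(rng.integers(lo, hi + 1))
        glyphs.append(GlyphRaster(f"rand{len(glyphs):03d}", _stroke_glyph(rng, cfg, n_strokes)))
    return GlyphLibrary("synthetic", glyphs)


# ---------------------------------------------------------------------------
# feature space


def generate_feature_space(
    n_phonemes: int, n_features: int, density: float = 0.5, seed: int = 0, max_tries: int = 50
) -> PhonemeFeatureTable:
    """Random binary feature vectors (distinct across phonemes), for which
    Euclidean² = feature-edit holds identically."""
    if n_features < 2:
        raise ValueError("need at least 2 features")
    rng = np.random.default_rng(seed)
    labels = [f"p{i:02d}" for i in range(n_phonemes)]
    for _ in range(max_tries):
        mat = (rng.random((n_phonemes, n_features)) < density).astype(float)
        if len({tuple(row) for row in mat}) == n_phonemes and mat.any(axis=1).all():
            return PhonemeFeatureTable(labels, {lab: mat[i] for i, lab in enumerate(labels)})
    raise ValueError(
        f"could not draw {n_phonemes} distinct binary vectors "
        f"(n_features={n_features}, density={density}); space too degenerate"
    )


# ---------------------------------------------------------------------------
# planted material libraries


@dataclasses.dataclass
class PlantConfig:
    canvas: tuple[int, int] = (48, 48)
    n_decoys: int = 20
    seed: int = 0
    target_r_min: float = 0.95  # construction is retried below this
    off_p_min: float = 0.20  # minimum off-metric Pearson p at construction
    max_tries: int = 25


def _satellite_pattern(rng: np.random.Generator, area: int = 5) -> np.ndarray:
    size = 4
    blob = _grow_blob(rng, (size, size), area, jaggedness=0.2, start=(size // 2, size // 2))
    rs, cs = np.nonzero(blob)
    return blob[rs.min() : rs.max() + 1, cs.min() : cs.max() + 1]


def _body_with_satellite(
    rng: np.random.Generator, canvas: tuple[int, int], area: int, jaggedness: float
) -> np.ndarray:
    """Main blob plus a small satellite at a random offset; total ink exact."""
    rows, cols = canvas
    center = (rows // 2 + int(rng.integers(-3, 4)), cols // 2 + int(rng.integers(-3, 4)))
    sat_area = 5
    body = _grow_blob(rng, canvas, area - sat_area, jaggedness, center)
    for _ in range(20):  # a start pixel can land in a pocket too small to grow in
        theta = rng.uniform(0, 2 * math.pi)
        off = rng.uniform(6, 16)
        sr = int(round(center[0] + off * math.sin(theta)))
        sc = int(round(center[1] + off * math.cos(theta)))
        try:
            sat = _grow_blob(rng, canvas, sat_area, 0.2, (sr, sc), occupied=body)
        except ValueError:
            continue
        return body | sat
    raise ValueError("could not place satellite next to body")


def _plant_pixel_pairs(
    rng: np.random.Generator, phon: np.ndarray, canvas: tuple[int, int]
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Pairs whose ink-area difference is an affine map of the phonetic
    distances (exact up to rounding); satellites and jaggedness randomize
    the other metrics."""
    beta = 25.0
    pairs = []
    for d in phon:
        a_area = int(rng.integers(60, 91))
        b_area = a_area + int(round(beta * d))
        ja, jb = rng.uniform(0.1, 0.9), rng.uniform(0.1, 0.9)
        pairs.append(
            (
                _body_with_satellite(rng, canvas, a_area, ja),
                _body_with_satellite(rng, canvas, b_area, jb),
            )
        )
    return pairs


def _plant_pc_pairs(
    rng: np.random.Generator, phon: np.ndarray, canvas: tuple[int, int]
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Measure-and-match from a pool spread across jaggedness: pick glyph
    pairs whose perimetric-complexity gap best fits an affine map of the
    phonetic distances; areas are independently random so pixel count
    carries no signal."""
    pool_size = 120
    pool = []
    for _ in range(pool_size):
        area = int(rng.integers(80, 121))
        jag = rng.uniform(0.0, 1.0)
        grid = _body_with_satellite(rng, canvas, area, jag)
        pool.append((perimetric_complexity(GlyphRaster("tmp", grid)), grid))
    pcs = np.array([p[0] for p in pool])
    lo_gap = 0.05 * (pcs.max() - pcs.min())
    hi_gap = 0.75 * (pcs.max() - pcs.min())
    d_lo, d_hi = phon.min(), phon.max()
    targets = lo_gap + (phon - d_lo) / (d_hi - d_lo) * (hi_gap - lo_gap)
    used = np.zeros(pool_size, dtype=bool)
    pairs: list[tuple[np.ndarray, np.ndarray]] = [None] * len(phon)  # type: ignore[list-item]
    for idx in np.argsort(-targets):  # hardest (largest) gaps first
        best, best_err = None, np.inf
        for i in range(pool_size):
            if used[i]:
                continue
            for j in range(i + 1, pool_size):
                if used[j]:
                    continue
                err = abs(abs(pcs[i] - pcs[j]) - targets[idx])
                if err < best_err:
                    best, best_err = (i, j), err
        i, j = best  # pool >> pairs, so a free pair always exists
        used[i] = used[j] = True
        pairs[idx] = (pool[i][1], pool[j][1])
    return pairs


def _plant_hausdorff_pairs(
    rng: np.random.Generator, phon: np.ndarray, canvas: tuple[int, int]
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Pairs (body, body + edit + satellite-at-offset): the satellite offset
    is tuned by scan so the centroid-aligned Hausdorff distance follows an
    affine map of the phonetic distances; the small attached edit randomizes
    ink area."""
    rows, cols = canvas
    offsets = np.arange(3, 20)
    prepared = []
    for _ in phon:
        center = (rows // 2 + int(rng.integers(-2, 3)), cols // 2 + int(rng.integers(-2, 3)))
        area = int(rng.integers(70, 111))
        body = _grow_blob(rng, canvas, area, rng.uniform(0.1, 0.7), center)
        edit = _grow_attached(rng, canvas, int(rng.integers(4, 13)), 0.4, body)
        base = body | edit
        sat = _satellite_pattern(rng)
        theta = rng.uniform(0, 2 * math.pi)
        a = GlyphRaster("a", body)
        curve = []
        for o in offsets:
            b_grid = base.copy()
            _stamp(
                b_grid,
                sat,
                int(round(center[0] + o * math.sin(theta) - sat.shape[0] / 2)),
                int(round(center[1] + o * math.cos(theta) - sat.shape[1] / 2)),
            )
            curve.append(hausdorff_distance(a, GlyphRaster("b", b_grid)))
        prepared.append((body, base, sat, theta, center, np.array(curve)))
    # pick an affine target band reachable by every pair's offset curve
    lo_h = max(c[5].min() for c in prepared) + 0.3
    hi_h = min(c[5].max() for c in prepared) - 0.3
    if hi_h - lo_h < 2.0:
        raise ValueError("hausdorff plant infeasible on this canvas (offset range too narrow)")
    d_lo, d_hi = phon.min(), phon.max()
    targets = lo_h + (phon - d_lo) / (d_hi - d_lo) * (hi_h - lo_h)
    pairs = []
    for (body, base, sat, theta, center, curve), h in zip(prepared, targets):
        o = offsets[int(np.argmin(np.abs(curve - h)))]
        b_grid = base.copy()
        _stamp(
            b_grid,
            sat,
            int(round(center[0] + o * math.sin(theta) - sat.shape[0] / 2)),
            int(round(center[1] + o * math.cos(theta) - sat.shape[1] / 2)),
        )
        pairs.append((body, b_grid))
    return pairs


_PLANTERS = {
    "pixel": _plant_pixel_pairs,
    "pc": _plant_pc_pairs,
    "hausdorff": _plant_hausdorff_pairs,
}


def plant_material_library(
    phoneme_pairs: list[tuple[str, str]],
    phoneme_distances: np.ndarray,
    target_metric: str,
    cfg: PlantConfig | None = None,
) -> tuple[GlyphLibrary, Material]:
    """Library with a planted systematic material.

    Builds glyph pairs whose ``target_metric`` distances are an affine map of
    ``phoneme_distances`` (plus small construction noise), embeds them among
    ``n_decoys`` decoy glyphs of the same visual family, and returns the
    library together with the planted material. Construction is verified and
    retried until the planted material scores Pearson r >= ``target_r_min``
    under the target metric while both off metrics stay clearly
    non-significant (Pearson p >= ``off_p_min``).
    """
    from .phonemes import PhoneticDistanceTable  # local: avoid cycle at import time
    from .systematicity import score_material

    cfg = cfg or PlantConfig()
    phon = np.asarray(phoneme_distances, dtype=float)
    if len(phon) != len(phoneme_pairs):
        raise ValueError("phoneme_distances and phoneme_pairs must align")
    if (phon <= 0).any():
        raise ValueError("phonetic distances must be positive")
    if target_metric not in _PLANTERS:
        raise ValueError(f"unknown target metric {target_metric!r}")

    planter = _PLANTERS[target_metric]
    last_err: Exception | None = None
    for attempt in range(cfg.max_tries):
        rng = np.random.default_rng((cfg.seed, attempt))
        try:
            grid_pairs = planter(rng, phon, cfg.canvas)
        except ValueError as exc:
            last_err = exc
            continue
        glyphs = []
        mat_pairs = []
        for i, ((p1, p2), (ga, gb)) in enumerate(zip(phoneme_pairs, grid_pairs)):
            ida, idb = f"{target_metric}_p{i:02d}a", f"{target_metric}_p{i:02d}b"
            glyphs.append(GlyphRaster(ida, ga))
            glyphs.append(GlyphRaster(idb, gb))
            mat_pairs.append((p1, p2, ida, idb))
        for j in range(cfg.n_decoys):
            area = int(rng.integers(60, 130))
            grid = _body_with_satellite(rng, cfg.canvas, area, rng.uniform(0.0, 1.0))
            glyphs.append(GlyphRaster(f"{target_metric}_d{j:02d}", grid))
        lib = GlyphLibrary(f"planted_{target_metric}", glyphs)
        material = Material(METRIC_TO_TYPE[target_metric], mat_pairs, target_metric)

        pd_rows = pd.DataFrame(
            {
                "phoneme_1": [p for p, _ in phoneme_pairs],
                "phoneme_2": [q for _, q in phoneme_pairs],
                "euclidean": phon,
                "cosine": np.clip(phon / phon.max(), 0, 1),
                "jaccard": np.clip(phon / phon.max(), 0, 1),
                "feature_edit": np.round(phon**2),
            }
        )
        pd_table = PhoneticDistanceTable(pd_rows)
        s_target = score_material(material, pd_table, lib, target_metric)
        off_ok = True
        for m in _PLANTERS:
            if m == target_metric:
                continue
            if score_material(material, pd_table, lib, m).pearson_p < cfg.off_p_min:
                off_ok = False
        if s_target.pearson_r >= cfg.target_r_min and off_ok:
            return lib, material
    raise ValueError(
        f"plant_material_library: no acceptable construction in {cfg.max_tries} tries"
        + (f" (last error: {last_err})" if last_err else "")
    )


# ---------------------------------------------------------------------------
# simulated respondents


@dataclasses.dataclass
class ResponseGenConfig:
    """Simulated survey cohort.

    Defaults mirror the study's cohort sizes (271 UK, 308 CN, 266 KR;
    10 choice questions each) with chance-level preference weights — the
    null configuration. Planted preferences are expressed by overriding
    ``weights`` per group with a non-uniform triple over
    (english, chinese, korean).
    """

    n_per_group: dict[str, int] = dataclasses.field(
        default_factory=lambda: {"UK": 271, "CN": 308, "KR": 266}
    )
    n_questions: int = 10
    weights: dict[str, tuple[float, float, float]] = dataclasses.field(
        default_factory=lambda: {g: (1 / 3, 1 / 3, 1 / 3) for g in GROUPS}
    )
    assignment_accuracy: float = 0.8
    overdispersion: float = 0.0  # >0: per-participant Dirichlet jitter of the weights
    seed: int = 0

    def __post_init__(self) -> None:
        for g, w in self.weights.items():
            w = np.asarray(w, dtype=float)
            if w.shape != (3,) or (w < 0).any() or not np.isclose(w.sum(), 1.0):
                raise ValueError(f"weights for group {g!r} must be a probability triple")
        if not 0.0 <= self.assignment_accuracy <= 1.0:
            raise ValueError("assignment_accuracy must be in [0, 1]")
        if self.overdispersion < 0:
            raise ValueError("overdispersion must be >= 0")


def simulate_responses(cfg: ResponseGenConfig) -> ResponseSet:
    """Draw a full forced-choice response table from the generative model in
    :class:`ResponseGenConfig`."""
    from .systematicity import MATERIAL_TYPES

    rng = np.random.default_rng(cfg.seed)
    frames = []
    for group, n in cfg.n_per_group.items():
        if group not in cfg.weights:
            raise KeyError(f"no preference weights for group {group!r}")
        base_w = np.asarray(cfg.weights[group], dtype=float)
        if cfg.overdispersion > 0:
            kappa = 1.0 / cfg.overdispersion
            w_per = rng.dirichlet(base_w * kappa + 1e-9, size=n)
        else:
            w_per = np.tile(base_w, (n, 1))
        choices = np.empty((n, cfg.n_questions), dtype=int)
        for i in range(n):
            choices[i] = rng.choice(3, size=cfg.n_questions, p=w_per[i])
        consistent = rng.random((n, cfg.n_questions)) < cfg.assignment_accuracy
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": np.repeat([f"{group}_{i:04d}" for i in range(n)], cfg.n_questions),
                    "group": group,
                    "question_id": np.tile(np.arange(1, cfg.n_questions + 1), n),
                    "chosen_type": np.array(MATERIAL_TYPES)[choices.ravel()],
                    "assignment_consistent": consistent.ravel(),
                }
            )
        )
    return ResponseSet(pd.concat(frames, ignore_index=True))
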