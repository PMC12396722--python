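"""Stimulus-set design: accept-if-better search for systematic materials.

Given a glyph library and a set of phoneme pairs with known phonetic
distances, the optimizer assembles 10 symbol pairs (20 distinct glyphs)
whose pairwise glyph distances — under a chosen target metric — correlate
maximally with the phonetic distances. A candidate replaces the incumbent
only if its target-metric Pearson r strictly improves (ties keep the
incumbent, for reproducibility). Optionally, cross-metric exclusivity is
enforced so the designed material is significant *only* under its target
metric.

Two proposal moves are available:

* ``restart`` (default) — every candidate is a fresh independent random
  selection; acceptance then simply keeps the best random draw seen.
* ``swap`` — local hill climbing: perturb the incumbent by exchanging one
  glyph with an unused one, swapping glyphs between two symbol pairs, or
  swapping which phoneme pairs two symbol pairs serve. Converges far faster
  on libraries that actually contain a highly systematic subset.

With ``exclusivity_required``: in restart mode, non-exclusive candidates
are rejected outright; in swap mode the climb itself is on r (a local
search whose every step must already be exclusive could never leave a
random start), and the best exclusive candidate encountered is the one
returned. Either way, if no exclusive candidate is ever seen the result
carries ``exclusivity_ok=False`` and the best-so-far material.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

from .glyphs import METRICS, GlyphLibrary, pairwise_distance_matrix
from .phonemes import PhoneticDistanceTable
from .systematicity import (
    METRIC_TO_TYPE,
    Material,
    SystematicityScore,
    score_material,
)

__all__ = ["DesignConfig", "DesignResult", "propose_material", "optimize_material"]


@dataclasses.dataclass
class DesignConfig:
    target_metric: str
    off_metrics: tuple[str, ...] | None = None  # default: the other two metrics
    n_pairs: int = 10
    max_iterations: int = 5000
    alpha: float = 0.05
    seed: int = 0
    exclusivity_required: bool = False
    move: str = "restart"  # or "swap"

    def __post_init__(self) -> None:
        if self.target_metric not in METRICS:
            raise ValueError(f"target_metric must be one of {METRICS}")
        if self.off_metrics is None:
            self.off_metrics = tuple(m for m in METRICS if m != self.target_metric)
        if self.target_metric in self.off_metrics:
            raise ValueError("target_metric cannot appear in off_metrics")
        if self.n_pairs < 3:
            raise ValueError("n_pairs must be >= 3")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.move not in ("restart", "swap"):
            raise ValueError("move must be 'restart' or 'swap'")


@dataclasses.dataclass
class DesignResult:
    material: Material
    score: SystematicityScore
    trace: list[float]  # incumbent target-metric r per iteration, non-decreasing
    exclusivity_ok: bool
    n_iterations: int


def _pearson_r_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and two-sided t-distribution p, minimal-overhead version for
    the inner search loop."""
    n = len(x)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        return 0.0, 1.0
    r = float(np.clip((xc @ yc) / denom, -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return r, float(p)


def _random_selection(rng: np.random.Generator, n_glyphs: int, n_pairs: int) -> np.ndarray:
    idx = rng.choice(n_glyphs, size=2 * n_pairs, replace=False)
    return idx.reshape(n_pairs, 2)


def _selection_to_material(
    sel: np.ndarray, lib: GlyphLibrary, pd_table: PhoneticDistanceTable, target_metric: str
) -> Material:
    ids = lib.glyph_ids
    pairs = [
        (p1, p2, ids[int(a)], ids[int(b)])
        for (p1, p2), (a, b) in zip(pd_table.pairs, sel)
    ]
    return Material(METRIC_TO_TYPE[target_metric], pairs, target_metric)


def propose_material(
    lib: GlyphLibrary,
    pd_table: PhoneticDistanceTable,
    rng: np.random.Generator,
    target_metric: str = "pixel",
    n_pairs: int | None = None,
) -> Material:
    """One random candidate: 2·n_pairs distinct glyphs sampled without
    replacement, paired up, and matched to the phoneme pairs in random order
    with random L1/L2 orientation."""
    n_pairs = n_pairs if n_pairs is not None else len(pd_table)
    if len(lib) < 2 * n_pairs:
        raise ValueError(f"library has {len(lib)} glyphs; need at least {2 * n_pairs}")
    if n_pairs != len(pd_table):
        raise ValueError("n_pairs must match the number of phoneme pairs")
    sel = _random_selection(rng, len(lib), n_pairs)
    return _selection_to_material(sel, lib, pd_table, target_metric)


class _SearchSpace:
    """Precomputed pairwise distance matrices so the inner loop is pure
    array lookups."""

    def __init__(self, lib: GlyphLibrary, pd_table: PhoneticDistanceTable, metrics: tuple[str, ...]):
        self.lib = lib
        self.pd_table = pd_table
        self.phon = pd_table.distances("euclidean")
        self.dist = {m: pairwise_distance_matrix(lib, m).to_numpy() for m in metrics}

    def glyph_vector(self, sel: np.ndarray, metric: str) -> np.ndarray:
        return self.dist[metric][sel[:, 0], sel[:, 1]]

    def target_r(self, sel: np.ndarray, metric: str) -> float:
        return _pearson_r_p(self.phon, self.glyph_vector(sel, metric))[0]

    def exclusive(self, sel: np.ndarray, target: str, off: tuple[str, ...], alpha: float) -> bool:
        _, p = _pearson_r_p(self.phon, self.glyph_vector(sel, target))
        if not p < alpha:
            return False
        for m in off:
            _, p_off = _pearson_r_p(self.phon, self.glyph_vector(sel, m))
            if p_off < alpha:
                return False
        return True


def _swap_move(sel: np.ndarray, rng: np.random.Generator, n_glyphs: int) -> np.ndarray:
    """Perturb a selection: replace one glyph with an unused one, exchange
    glyphs between two symbol pairs, or swap two pairs' phoneme slots."""
    new = sel.copy()
    n_pairs = sel.shape[0]
    kind = rng.integers(3)
    if kind == 0:  # bring in an unused glyph
        used = set(sel.ravel().tolist())
        unused = [g for g in range(n_glyphs) if g not in used]
        if unused:
            i, j = rng.integers(n_pairs), rng.integers(2)
            new[i, j] = unused[rng.integers(len(unused))]
            return new
        kind = 1
    if kind == 1:  # exchange glyphs between two pairs
        i, k = rng.choice(n_pairs, size=2, replace=False)
        j, l = rng.integers(2), rng.integers(2)
        new[i, j], new[k, l] = new[k, l], new[i, j]
        return new
    # swap which phoneme slots two symbol pairs serve
    i, k = rng.choice(n_pairs, size=2, replace=False)
    new[[i, k]] = new[[k, i]]
    return new


def optimize_material(
    lib: GlyphLibrary, pd_table: PhoneticDistanceTable, cfg: DesignConfig
) -> DesignResult:
    """Accept-if-better search for a maximally systematic material.

    Fully reproducible from ``cfg.seed``; the returned trace of incumbent
    target-metric r values is non-decreasing, and the returned score is
    recomputed from scratch on the final material.
    """
    n_pairs = cfg.n_pairs
    if n_pairs != len(pd_table):
        raise ValueError("cfg.n_pairs must match the number of phoneme pairs in pd_table")
    if len(lib) < 2 * n_pairs:
        raise ValueError(f"library has {len(lib)} glyphs; need at least {2 * n_pairs}")
    rng = np.random.default_rng(cfg.seed)
    space = _SearchSpace(lib, pd_table, (cfg.target_metric, *cfg.off_metrics))

    incumbent = _random_selection(rng, len(lib), n_pairs)
    inc_r = space.target_r(incumbent, cfg.target_metric)
    best_excl: np.ndarray | None = None
    best_excl_r = -np.inf

    def note_exclusive(sel: np.ndarray, r: float) -> None:
        nonlocal best_excl, best_excl_r
        if r > best_excl_r and space.exclusive(sel, cfg.target_metric, cfg.off_metrics, cfg.alpha):
            best_excl, best_excl_r = sel.copy(), r

    if cfg.exclusivity_required:
        note_exclusive(incumbent, inc_r)

    trace = [inc_r]
    for _ in range(cfg.max_iterations):
        if cfg.move == "restart":
            cand = _random_selection(rng, len(lib), n_pairs)
        else:
            cand = _swap_move(incumbent, rng, len(lib))
        cand_r = space.target_r(cand, cfg.target_metric)
        if cand_r > inc_r:
            if cfg.exclusivity_required and cfg.move == "restart":
                # literal accept rule: a non-exclusive candidate never replaces
                if space.exclusive(cand, cfg.target_metric, cfg.off_metrics, cfg.alpha):
                    incumbent, inc_r = cand, cand_r
                    best_excl, best_excl_r = cand.copy(), cand_r
            else:
                incumbent, inc_r = cand, cand_r
                if cfg.exclusivity_required:
                    note_exclusive(cand, cand_r)
        trace.append(inc_r)

    exclusivity_ok = True
    final_sel = incumbent
    if cfg.exclusivity_required:
        if best_excl is not None:
            final_sel = best_excl
        else:
            exclusivity_ok = False

    material = _selection_to_material(final_sel, lib, pd_table, cfg.target_metric)
    try:
        score = score_material(material, pd_table, lib, cfg.target_metric)
    except ValueError:
        # degenerate library: the selection's distance vector is constant, so
        # the correlation is undefined — report NaN r with p = 1
        score = SystematicityScore(float("nan"), 1.0, float("nan"), 1.0, n_pairs)
    return DesignResult(material, score, trace, exclusivity_ok, cfg.max_iterations)
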