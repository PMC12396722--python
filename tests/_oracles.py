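"""Independent brute-force / textbook-formula oracles used by the tests.

Deliberately naive implementations, kept separate from the package code
paths they check.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import special


def hausdorff_brute_force(points_a: np.ndarray, points_b: np.ndarray) -> float:
    """O(|A||B|) double loop over both directed distances."""
    def directed(src, dst):
        worst = 0.0
        for p in src:
            best = math.inf
            for q in dst:
                d = math.dist(p, q)
                if d < best:
                    best = d
            if best > worst:
                worst = best
        return worst

    return max(directed(points_a, points_b), directed(points_b, points_a))


def pearson_textbook(x, y) -> tuple[float, float]:
    """r from the raw-sums formula; two-sided p from the t distribution."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    num = n * (x * y).sum() - sx * sy
    den = math.sqrt(n * (x * x).sum() - sx * sx) * math.sqrt(n * (y * y).sum() - sy * sy)
    r = num / den
    t = r * math.sqrt((n - 2) / (1 - r * r))
    p = 2 * special.stdtr(n - 2, -abs(t))
    return r, p


def average_ranks(x) -> np.ndarray:
    """Ranks 1..n with ties receiving the average of their positions."""
    x = np.asarray(x, float)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x))
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def spearman_textbook(x, y) -> tuple[float, float]:
    """rho = Pearson on average ranks; two-sided t-distribution p."""
    return pearson_textbook(average_ranks(x), average_ranks(y))
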