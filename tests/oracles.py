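"""Independent reference implementations used only by the test suite.

These are deliberately naive - exhaustive enumeration, dense random
sampling, direct term-by-term formulas - and share no code with the package
paths they validate.
"""

from __future__ import annotations

import math

import numpy as np


def brute_force_global_alignment_score(
    a: str, b: str, score_fn, gap_open: float, gap_extend: float
) -> float:
    """Optimal global alignment score by exhaustive enumeration.

    Enumerates every monotone path through the alignment grid and scores it
    directly: substitution scores for residue-residue columns, and
    ``gap_open + (L - 1) * gap_extend`` for every maximal gap run of length
    ``L``.  Exponential in sequence length; intended for lengths <= 6.
    """
    best = -math.inf

    def recurse(i: int, j: int, score: float, last_move: str) -> None:
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            recurse(i + 1, j + 1, score + score_fn(a[i], b[j]), "M")
        if i < len(a):  # gap in b
            cost = gap_extend if last_move == "X" else gap_open
            recurse(i + 1, j, score - cost, "X")
        if j < len(b):  # gap in a
            cost = gap_extend if last_move == "Y" else gap_open
            recurse(i, j + 1, score - cost, "Y")

    recurse(0, 0, 0.0, "start")
    return best


def dense_sampling_sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float,
    n_points: int = 100_000,
    seed: int = 0,
) -> np.ndarray:
    """Per-atom SASA by dense uniform random sampling on each atom's
    probe-expanded sphere (Monte Carlo surface integration)."""
    rng = np.random.default_rng(seed)
    expanded = radii + probe
    out = np.empty(len(coords))
    for i in range(len(coords)):
        v = rng.normal(size=(n_points, 3))
        v /= np.linalg.norm(v, axis=1)[:, None]
        pts = coords[i] + expanded[i] * v
        free = np.ones(n_points, bool)
        for j in range(len(coords)):
            if j == i:
                continue
            d = np.linalg.norm(pts - coords[j], axis=1)
            free &= d >= expanded[j]
        out[i] = 4.0 * np.pi * expanded[i] ** 2 * free.mean()
    return out


def direct_sum_potential(
    charge_positions, charge_values, points, bjerrum: float, kappa: float
):
    """Screened-Coulomb potential by an explicit double loop."""
    out = []
    for p in points:
        total = 0.0
        for pos, q in zip(charge_positions, charge_values):
            d = math.dist(p, pos)
            total += q * math.exp(-kappa * d) / d
        out.append(bjerrum * total)
    return np.array(out)


def pearson_by_hand(x, y) -> float:
    """Pearson correlation from its definition."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    dx = x - x.mean()
    dy = y - y.mean()
    return float((dx * dy).sum() / math.sqrt((dx**2).sum() * (dy**2).sum()))
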