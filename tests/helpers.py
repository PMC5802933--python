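"""Independent oracles for the change-point tests.

Everything here recomputes costs and optima from first principles
(direct formulas + exhaustive enumeration) without touching the package's
search code, so it can serve as a cross-check for PELT / segment
neighborhood / binary segmentation.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

VAR_FLOOR = 1e-12


def naive_segment_cost(x: np.ndarray, i: int, j: int, change_type: str) -> float:
    """Gaussian segment cost for positions i..j (1-based, inclusive)."""
    seg = np.asarray(x, dtype=float)[i - 1 : j]
    m = len(seg)
    if change_type == "mean":
        return float(((seg - seg.mean()) ** 2).sum())
    if change_type == "variance":
        mu = float(np.mean(x))
        v = float(((seg - mu) ** 2).mean())
        return m * math.log(max(v, VAR_FLOOR))
    v = float(seg.var())
    return m * (math.log(2 * math.pi) + math.log(max(v, VAR_FLOOR)) + 1.0)


def min_seg_len(change_type: str) -> int:
    return 1 if change_type == "mean" else 2


def brute_force_optimum(
    x: np.ndarray, change_type: str, penalty: float
) -> tuple[float, tuple[int, ...]]:
    """Exhaustively minimize sum(segment costs) + penalty * n_changepoints.

    Enumerates all 2^(n-1) placements of change points (1-based last
    positions), skipping those violating the minimum segment length.
    Returns (optimal penalized cost, optimal change points); ties resolve
    to the fewest change points, then lexicographically smallest indices.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    msl = min_seg_len(change_type)
    pair_cost = {}
    for i in range(1, n + 1):
        for j in range(i + msl - 1, n + 1):
            pair_cost[(i, j)] = naive_segment_cost(x, i, j, change_type)
    best_cost = math.inf
    best_cpts: tuple[int, ...] = ()
    for k in range(0, n):
        for cpts in itertools.combinations(range(1, n), k):
            bounds = [0, *cpts, n]
            lengths = np.diff(bounds)
            if (lengths < msl).any():
                continue
            total = penalty * k
            for a, b in zip(bounds[:-1], bounds[1:]):
                total += pair_cost[(a + 1, b)]
            if total < best_cost - 1e-12:
                best_cost = total
                best_cpts = cpts
    return best_cost, best_cpts
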