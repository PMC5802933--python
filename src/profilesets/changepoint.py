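"""Univariate change-point detection on the ranked profile-statistic series.

Four search methods are exposed -- AMOC (at most one change), binary
segmentation, PELT (pruned exact linear time) and segment neighborhood --
over three Gaussian change types:

``mean``
    change in mean with fixed variance; segment cost is the residual sum
    of squares around the segment mean.
``variance``
    change in variance with the mean fixed at the global series mean;
    segment cost is ``m * log(sigma2)`` with ``sigma2`` the mean squared
    deviation from the global mean.
``both``
    change in mean and variance; segment cost is the Gaussian
    -2 log-likelihood ``m * (log(2*pi) + log(sigma2) + 1)`` with the
    segment's own MLE mean and variance.

Variance estimates are floored at 1e-12 so costs stay finite on constant
segments.  All searches are deterministic; equal-cost splits resolve
toward the smaller index.  A segmentation is penalized linearly:
``total = sum(segment costs) + penalty * (number of change points)``.
PELT and segment neighborhood both return the exact penalized optimum
(segment neighborhood subject to its ``max_cpts`` bound); binary
segmentation is the usual greedy approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

CHANGE_TYPES = ("mean", "variance", "both")
METHODS = ("AMOC", "BinSeg", "PELT", "SegNeigh")
#: alternate spelling accepted in configs
METHOD_ALIASES = {"SEQNEIGH": "SegNeigh"}

VAR_FLOOR = 1e-12
LOG_2PI = math.log(2.0 * math.pi)

#: minimum segment length per change type (variance needs >= 2 points)
MIN_SEG_LEN = {"mean": 1, "variance": 2, "both": 2}


class ChangePointError(ValueError):
    """Raised for invalid change-point settings or series."""


def normalize_method(name: str) -> str:
    key = name.strip().upper()
    key = METHOD_ALIASES.get(key, key).upper()
    for m in METHODS:
        if key == m.upper():
            return m
    raise ChangePointError(
        f"unknown change-point method {name!r}; choose from {METHODS} "
        f"(or 'SeqNeigh')"
    )


def default_penalty(n: int, change_type: str) -> float:
    """MBIC-style default: 3*log(n) for mean/variance, 4*log(n) for both."""
    k = 4.0 if change_type == "both" else 3.0
    return k * math.log(n)


@dataclass(frozen=True)
class ChangePointSettings:
    """User-facing change-point configuration.

    ``penalty=None`` selects the default ``k*log(n)`` penalty at detection
    time (k = 3 for mean/variance changes, 4 for joint changes).
    ``max_cpts`` bounds BinSeg and SegNeigh only.
    """

    change_type: str = "both"
    method: str = "BinSeg"
    penalty: float | None = None
    max_cpts: int = 20

    def __post_init__(self) -> None:
        if self.change_type not in CHANGE_TYPES:
            raise ChangePointError(
                f"change_type must be one of {CHANGE_TYPES}, "
                f"got {self.change_type!r}"
            )
        object.__setattr__(self, "method", normalize_method(self.method))
        if self.penalty is not None and self.penalty < 0:
            raise ChangePointError("penalty must be nonnegative")
        if self.max_cpts < 1:
            raise ChangePointError("max_cpts must be >= 1")

    def resolve_penalty(self, n: int) -> float:
        if self.penalty is not None:
            return float(self.penalty)
        return default_penalty(n, self.change_type)


@dataclass(frozen=True)
class Segmentation:
    """Change points over a series of length n.

    ``cpt_indices`` are strictly increasing 1-based positions, each the
    LAST position of a segment; the final position n is implied and never
    listed.  ``total_cost`` is the penalized objective actually minimized:
    sum of segment costs plus ``penalty`` per change point.
    """

    series_length: int
    cpt_indices: tuple[int, ...]
    total_cost: float

    @property
    def n_segments(self) -> int:
        return len(self.cpt_indices) + 1

    def segment_bounds(self) -> list[tuple[int, int]]:
        """1-based inclusive (start, end) per segment, bottom to top."""
        bounds = []
        start = 1
        for c in self.cpt_indices:
            bounds.append((start, c))
            start = c + 1
        bounds.append((start, self.series_length))
        return bounds


class _CostModel:
    """O(1) Gaussian segment costs from cumulative sums (1-based inclusive)."""

    def __init__(self, series: Sequence[float], change_type: str):
        x = np.asarray(series, dtype=float)
        if x.ndim != 1:
            raise ChangePointError("series must be one-dimensional")
        if not np.isfinite(x).all():
            raise ChangePointError("series contains non-finite values")
        self.n = len(x)
        self.change_type = change_type
        self.min_seg_len = MIN_SEG_LEN[change_type]
        self._s1 = np.concatenate(([0.0], np.cumsum(x)))
        self._s2 = np.concatenate(([0.0], np.cumsum(x * x)))
        if change_type == "variance":
            mu = x.mean() if self.n else 0.0
            dev = (x - mu) ** 2
            self._sdev = np.concatenate(([0.0], np.cumsum(dev)))

    def cost(self, i: int, j: int) -> float:
        """Cost of the single segment covering positions i..j (1-based)."""
        return float(self.cost_vec(np.asarray([i]), j)[0])

    def cost_vec(self, starts: np.ndarray, j: int) -> np.ndarray:
        """Costs of segments starts..j for a vector of start positions."""
        m = j - starts + 1.0
        if np.any(m < self.min_seg_len):
            raise ChangePointError(
                f"segment shorter than the minimum length "
                f"{self.min_seg_len} for change type {self.change_type!r}"
            )
        if self.change_type == "variance":
            v = (self._sdev[j] - self._sdev[starts - 1]) / m
            return m * np.log(np.maximum(v, VAR_FLOOR))
        s1 = self._s1[j] - self._s1[starts - 1]
        s2 = self._s2[j] - self._s2[starts - 1]
        rss = np.maximum(s2 - s1 * s1 / m, 0.0)
        if self.change_type == "mean":
            return rss
        v = rss / m
        return m * (LOG_2PI + np.log(np.maximum(v, VAR_FLOOR)) + 1.0)


def segment_cost(
    series: Sequence[float], i: int, j: int, change_type: str
) -> float:
    """Cost of treating positions i..j (1-based, inclusive) as one segment."""
    model = _CostModel(series, change_type)
    if not 1 <= i <= j <= model.n:
        raise ChangePointError(f"invalid segment bounds ({i}, {j}) for n={model.n}")
    return model.cost(i, j)


def _require_length(model: _CostModel) -> None:
    if model.n < 2 * model.min_seg_len:
        raise ChangePointError(
            f"series of length {model.n} is too short for change type "
            f"{model.change_type!r} (needs >= {2 * model.min_seg_len} points)"
        )


def detect_amoc(
    series: Sequence[float], settings: ChangePointSettings
) -> Segmentation:
    """At most one change: report the best split if it beats the penalty."""
    model = _CostModel(series, settings.change_type)
    _require_length(model)
    n = model.n
    pen = settings.resolve_penalty(n)
    lo, hi = model.min_seg_len, n - model.min_seg_len
    taus = np.arange(lo, hi + 1)
    left = np.array([model.cost(1, int(t)) for t in taus])
    right = model.cost_vec(taus + 1, n)
    split_costs = left + right
    best = int(np.argmin(split_costs))  # ties -> smaller tau
    no_split = model.cost(1, n)
    if no_split - split_costs[best] > pen:
        return Segmentation(n, (int(taus[best]),), float(split_costs[best] + pen))
    return Segmentation(n, (), float(no_split))


def detect_binseg(
    series: Sequence[float], settings: ChangePointSettings
) -> Segmentation:
    """Greedy binary segmentation bounded by ``max_cpts``."""
    model = _CostModel(series, settings.change_type)
    _require_length(model)
    n = model.n
    pen = settings.resolve_penalty(n)
    msl = model.min_seg_len

    def best_split(a: int, b: int) -> tuple[float, int] | None:
        # best internal split of segment a..b; None if too short
        if b - a + 1 < 2 * msl:
            return None
        taus = np.arange(a + msl - 1, b - msl + 1)
        left = np.array([model.cost(a, int(t)) for t in taus])
        right = model.cost_vec(taus + 1, b)
        whole = model.cost(a, b)
        gains = whole - (left + right)
        k = int(np.argmax(gains))
        # ties resolve toward the smaller index via argmax on first maximum
        return float(gains[k]), int(taus[k])

    segments: list[tuple[int, int]] = [(1, n)]
    cpts: list[int] = []
    while len(cpts) < settings.max_cpts:
        candidates = []
        for idx, (a, b) in enumerate(segments):
            res = best_split(a, b)
            if res is not None:
                gain, tau = res
                candidates.append((gain, tau, idx))
        if not candidates:
            break
        # largest gain wins; ties toward the smaller split index
        gain, tau, idx = max(candidates, key=lambda c: (c[0], -c[1]))
        if gain <= pen:
            break
        a, b = segments[idx]
        segments[idx : idx + 1] = [(a, tau), (tau + 1, b)]
        cpts.append(tau)
    cpts.sort()
    total = sum(model.cost(a, b) for a, b in segments) + pen * len(cpts)
    return Segmentation(n, tuple(cpts), float(total))


def detect_pelt(
    series: Sequence[float], settings: ChangePointSettings
) -> Segmentation:
    """Exact penalized optimum via dynamic programming over last change points.

    Candidate pruning (the PELT speed-up) is applied only for the "mean"
    cost, where the residual-sum-of-squares objective is subadditive and
    every position can end a segment, so the pruning theorem holds with
    K = 0.  For "variance"/"both" the 2-point minimum segment length
    invalidates that argument (a pruned candidate can become optimal
    again because the kept one cannot be extended by a single point), so
    the full optimal-partitioning recursion is used; exactness is the
    contract, pruning only an optimization.
    """
    model = _CostModel(series, settings.change_type)
    _require_length(model)
    n = model.n
    pen = settings.resolve_penalty(n)
    msl = model.min_seg_len
    prune = msl == 1

    F = np.full(n + 1, np.inf)
    F[0] = -pen
    last = np.zeros(n + 1, dtype=int)
    cands: list[int] = []
    for t in range(msl, n + 1):
        tau_new = t - msl
        if tau_new == 0 or tau_new >= msl:
            if np.isfinite(F[tau_new]):
                cands.append(tau_new)
        taus = np.asarray(cands)
        vals = F[taus] + model.cost_vec(taus + 1, t)
        k = int(np.argmin(vals))  # ties -> smallest tau (cands ascending)
        F[t] = vals[k] + pen
        last[t] = taus[k]
        if prune:
            # drop candidates that can never be optimal again (K = 0)
            keep = vals <= F[t]
            cands = [int(tau) for tau, ok in zip(taus, keep) if ok]
    cpts = []
    t = n
    while t > 0:
        tau = int(last[t])
        if tau > 0:
            cpts.append(tau)
        t = tau
    cpts.sort()
    return Segmentation(n, tuple(cpts), float(F[n]))


def detect_segneigh(
    series: Sequence[float], settings: ChangePointSettings
) -> Segmentation:
    """Segment-neighborhood dynamic program over 1..max_cpts+1 segments."""
    model = _CostModel(series, settings.change_type)
    _require_length(model)
    n = model.n
    pen = settings.resolve_penalty(n)
    msl = model.min_seg_len
    q_max = min(settings.max_cpts + 1, n // msl)

    # D[q-1][t] = min cost of splitting 1..t into q segments (unpenalized)
    D = np.full((q_max, n + 1), np.inf)
    arg = np.zeros((q_max, n + 1), dtype=int)
    for t in range(msl, n + 1):
        D[0][t] = model.cost(1, t)
    for q in range(2, q_max + 1):
        for t in range(q * msl, n + 1):
            lo, hi = (q - 1) * msl, t - msl
            s = np.arange(lo, hi + 1)
            finite = np.isfinite(D[q - 2][s])
            if not finite.any():
                continue
            s = s[finite]
            vals = D[q - 2][s] + model.cost_vec(s + 1, t)
            k = int(np.argmin(vals))  # ties -> smallest s
            D[q - 1][t] = vals[k]
            arg[q - 1][t] = s[k]
    totals = D[:, n] + pen * np.arange(q_max)
    q_best = int(np.argmin(totals)) + 1  # ties -> fewest segments
    cpts = []
    t = n
    for q in range(q_best, 1, -1):
        s = int(arg[q - 1][t])
        cpts.append(s)
        t = s
    cpts.sort()
    return Segmentation(n, tuple(cpts), float(totals[q_best - 1]))


_DISPATCH = {
    "AMOC": detect_amoc,
    "BinSeg": detect_binseg,
    "PELT": detect_pelt,
    "SegNeigh": detect_segneigh,
}


def detect_changepoints(
    series: Sequence[float], settings: ChangePointSettings
) -> Segmentation:
    """Run the configured search method on an (ascending-sorted) series."""
    return _DISPATCH[settings.method](series, settings)
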