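"""Trend discretization and the local trend score.

Local trend analysis (LTA) compares two equal-length time series through the
*direction* of their step-to-step changes rather than their values.  A numeric
series ``X_1..X_n`` is first reduced to a trend sequence ``d_1..d_{n-1}`` over
the alphabet {-1, 0, +1} ("down", "no change", "up"), where a threshold ``t``
on the relative change decides whether a step counts as a trend at all.  The
local trend score ``LT(D)`` is then the best sum of element-wise symbol
products over any pair of aligned windows whose starting offsets differ by at
most the delay ``D`` -- i.e. a maximal run of co-trending (or, for the
two-sided variant, anti-trending) behaviour.

This module provides the discretization, an O(m*(2D+1)) dynamic-programming
scorer with alignment reporting, an exhaustive brute-force scorer used as a
test oracle, and a vectorized batch scorer used by the permutation test and
the simulation harness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TrendSeries",
    "LTResult",
    "discretize",
    "discretize_values",
    "lt_score",
    "lt_score_bruteforce",
    "lt_scores_batch",
]


@dataclass(frozen=True)
class TrendSeries:
    """A trend symbol sequence in {-1, 0, +1} with the threshold that made it."""

    symbols: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        sym = np.asarray(self.symbols, dtype=np.int8)
        if sym.ndim != 1 or sym.size < 1:
            raise ValueError("trend sequence must be a non-empty 1-d array")
        if not np.isin(sym, (-1, 0, 1)).all():
            raise ValueError("trend symbols must lie in {-1, 0, 1}")
        object.__setattr__(self, "symbols", sym)

    def __len__(self) -> int:
        return self.symbols.size

    @property
    def observed_states(self) -> frozenset[int]:
        """The set of symbols actually present in the sequence."""
        return frozenset(np.unique(self.symbols).tolist())


@dataclass(frozen=True)
class LTResult:
    """Local trend score with the optimal alignment that attains it.

    ``start_x``/``start_y`` are 0-based window starts into the two trend
    sequences and ``length`` is the window length ``k``; the empty alignment
    (score 0, length 0) is always admissible, so ``score >= 0``.
    """

    score: int
    start_x: int
    start_y: int
    length: int
    delay_bound: int

    def __post_init__(self) -> None:
        if self.score < 0 or self.length < 0:
            raise ValueError("score and length must be non-negative")
        if self.length > 0 and abs(self.start_x - self.start_y) > self.delay_bound:
            raise ValueError("alignment offset exceeds the delay bound")


def discretize_values(values: np.ndarray, t: float = 0.0, *, strict: bool = False) -> np.ndarray:
    """Vectorized trend discretization; works on 1-d series or (batch, n) stacks.

    For ``X_i != 0`` the symbol is +1 when the relative change
    ``(X_{i+1}-X_i)/|X_i|`` is ``>= t``, -1 when it is ``<= -t`` and 0 in
    between; for ``X_i == 0`` the symbol is the sign of ``X_{i+1}``.  At
    ``t = 0`` the non-strict inequality assigns +1 to exactly-equal
    consecutive values (zero-heavy tables: see ``strict``).  With
    ``strict=True`` both trend branches use strict inequalities, so ties and
    sub-threshold changes map to 0.
    """
    x = np.asarray(values, dtype=float)
    if x.shape[-1] < 2:
        raise ValueError("need at least 2 observations to form a trend")
    if not np.isfinite(x).all():
        raise ValueError("series contains non-finite or missing values")
    x0, x1 = x[..., :-1], x[..., 1:]
    denom = np.abs(x0)
    nz = denom > 0
    ratio = np.divide(x1 - x0, denom, out=np.zeros_like(x0), where=nz)
    out = np.zeros(x0.shape, dtype=np.int8)
    if strict:
        up = ratio > t
        down = ratio < -t
    else:
        up = ratio >= t
        down = ~up & (ratio <= -t)
    out[nz & up] = 1
    out[nz & down] = -1
    out[~nz] = np.sign(x1[~nz])
    return out


def discretize(series, t: float = 0.0, *, strict: bool = False) -> TrendSeries:
    """Convert a numeric series of length n into its trend sequence (length n-1)."""
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("discretize expects a 1-d series")
    if t < 0:
        raise ValueError("threshold t must be >= 0")
    return TrendSeries(discretize_values(x, t, strict=strict), float(t))


def _symbols(d) -> np.ndarray:
    if isinstance(d, TrendSeries):
        return d.symbols
    arr = np.asarray(d, dtype=np.int8)
    if arr.ndim != 1:
        raise ValueError("trend sequence must be 1-d")
    if not np.isin(arr, (-1, 0, 1)).all():
        raise ValueError("trend symbols must lie in {-1, 0, 1}")
    return arr


def _offset_products(sx: np.ndarray, sy: np.ndarray, off: int) -> tuple[np.ndarray, int, int]:
    """Products along offset ``off = start_y - start_x`` plus the global starts
    of overlap position 0 in x and y."""
    if off >= 0:
        return sx[: sx.size - off] * sy[off:], 0, off
    return sx[-off:] * sy[: sy.size + off], -off, 0


def _best_window(prod: np.ndarray) -> tuple[int, int, int]:
    """Best (max-sum) window of a product sequence with deterministic ties.

    Returns ``(score, start, length)`` preferring, among score ties, the
    smallest start and then the shortest window.  The empty window scores 0.
    """
    L = prod.size
    pref = np.concatenate(([0], np.cumsum(prod, dtype=np.int64)))
    # suffix max of pref[e] over e > s, keeping the earliest attaining index
    suf_val = np.empty(L + 1, dtype=np.int64)
    suf_idx = np.empty(L + 1, dtype=np.int64)
    best_v, best_e = pref[L], L
    suf_val[L], suf_idx[L] = best_v, best_e
    for e in range(L - 1, 0, -1):
        if pref[e] >= best_v:  # prefer the smaller index on ties
            best_v, best_e = pref[e], e
        suf_val[e], suf_idx[e] = best_v, best_e
    score, start, length = 0, 0, 0
    for s in range(L):
        val = suf_val[s + 1] - pref[s]
        if val > score:
            score, start, length = int(val), s, int(suf_idx[s + 1] - s)
    return score, start, length


def lt_score(dx, dy, D: int = 0) -> LTResult:
    """Local trend score LT(D) by dynamic programming, with alignment.

    Maximizes ``sum_l dx[i+l]*dy[j+l]`` over all window starts with
    ``|i - j| <= D`` (the empty window, score 0, is admissible).  Among
    co-optimal alignments the one with smallest ``start_x``, then smallest
    ``start_y``, then smallest length is reported.
    """
    sx, sy = _symbols(dx), _symbols(dy)
    if sx.size != sy.size:
        raise ValueError("trend sequences must have equal length")
    if D < 0:
        raise ValueError("delay bound D must be >= 0")
    best = LTResult(0, 0, 0, 0, D)
    best_key = (0, 0, 0, 0)
    for off in range(-D, D + 1):
        if abs(off) >= sx.size:
            continue
        prod, x0, y0 = _offset_products(sx, sy, off)
        if prod.size == 0:
            continue
        score, s, k = _best_window(prod)
        if score == 0:
            continue
        key = (-score, x0 + s, y0 + s, k)
        if key < best_key:
            best_key = key
            best = LTResult(score, x0 + s, y0 + s, k, D)
    return best


def lt_score_bruteforce(dx, dy, D: int = 0) -> LTResult:
    """Exhaustive-enumeration scorer, the independent oracle for :func:`lt_score`.

    Enumerates every (i, j, k) with ``|i - j| <= D``; O(m^2 * (2D+1)).
    """
    sx, sy = _symbols(dx), _symbols(dy)
    if sx.size != sy.size:
        raise ValueError("trend sequences must have equal length")
    m = sx.size
    best_key = (0, 0, 0, 0)
    best = LTResult(0, 0, 0, 0, D)
    for i in range(m):
        for j in range(max(0, i - D), min(m, i + D + 1)):
            total = 0
            kmax = m - max(i, j)
            for k in range(1, kmax + 1):
                total += int(sx[i + k - 1]) * int(sy[j + k - 1])
                key = (-total, i, j, k)
                if total > 0 and key < best_key:
                    best_key = key
                    best = LTResult(total, i, j, k, D)
    return best


def lt_scores_batch(dx2: np.ndarray, dy2: np.ndarray, D: int = 0) -> np.ndarray:
    """LT(D) scores for a batch of symbol-sequence pairs, shape (R, m) -> (R,)."""
    dx2 = np.atleast_2d(np.asarray(dx2, dtype=np.int64))
    dy2 = np.atleast_2d(np.asarray(dy2, dtype=np.int64))
    if dx2.shape != dy2.shape:
        raise ValueError("batch shapes must match")
    R, m = dx2.shape
    best = np.zeros(R, dtype=np.int64)
    for off in range(-D, D + 1):
        if abs(off) >= m:
            continue
        if off >= 0:
            prod = dx2[:, : m - off] * dy2[:, off:]
        else:
            prod = dx2[:, -off:] * dy2[:, : m + off]
        pref = np.concatenate([np.zeros((R, 1), dtype=np.int64), np.cumsum(prod, axis=1)], axis=1)
        runmin = np.minimum.accumulate(pref[:, :-1], axis=1)
        np.maximum(best, (pref[:, 1:] - runmin).max(axis=1), out=best)
    return np.maximum(best, 0)
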