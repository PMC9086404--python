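"""Approximate and permutation p-values for the local trend score.

For a mean-zero stationary chain Z_i with long-run variance sigma^2, the
maximal-increment statistic H_m = max_{0<=i<=j<=m} (S_j - S_i) of its random
walk satisfies H_m / (sigma sqrt(m)) -> sup_{0<=v<=1} |W_v| in distribution
(by Levy's theorem the maximal increment of a Brownian path has the same law
as the supremum of its reflection, i.e. of |W|).  The local trend score with
delay bound D is treated as the maximum of 2D+1 such statistics, giving the
tail approximation

    P(LT(D) >= s)  ~  L_D(x) = 1 - Theta(x)^(2D+1),    x = s / (sigma sqrt(m)),

where Theta(x) = P(sup|W| <= x) is evaluated by its alternating theta series.

Three methods share this scaling and differ only in sigma:

* ``stlta`` -- sigma^2 from Markov transition parameters *estimated from the
  observed trend sequences* (valid for dependent stationary series);
* ``tlta`` -- sigma^2 fixed at the value implied by i.i.d. original series;
* ``permutation_test`` -- no asymptotics: one series is shuffled and
  re-scored (trend symbols by default, or original values with
  re-discretization for an exact test on exchangeable data).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import markov_variance as mv
from .trend_core import TrendSeries, discretize, discretize_values, lt_scores_batch

__all__ = [
    "SignificanceResult",
    "theta_cdf",
    "tail_LD",
    "p_value",
    "stlta",
    "tlta",
    "permutation_test",
]

_THETA_TOL = 1e-14
_THETA_MAX_TERMS = 1000
_X_FLOOR = 1e-8


@dataclass(frozen=True)
class SignificanceResult:
    """A scored pair with its significance assessment.

    ``x = score / (sigma * sqrt(m))`` is the scaled statistic entering the
    tail law; ``state_model`` records which variance formula applied
    ("two", "three" or "mixed"); degenerate fits (non-ergodic chains) carry
    ``p_value = nan``.
    """

    score: int
    m: int
    sigma: float
    x: float
    p_value: float
    method: str
    state_model: str | None = None
    degenerate: bool = False
    n_perm: int | None = None


def theta_cdf(x) -> np.ndarray | float:
    """Theta(x) = P(sup_{0<=v<=1} |W_v| <= x) for standard Brownian motion.

    Two complementary alternating series are used, each truncated once a
    term falls below 1e-14 (cap 1000 terms): the theta series
    (4/pi) sum_k (-1)^k/(2k+1) exp(-(2k+1)^2 pi^2/(8x^2)) for small x, and
    the reflection series 1 - 4 sum_k (-1)^k Phi_c((2k+1)x) (Phi_c the
    standard-normal upper tail) where it converges faster (x >= 1).
    """
    from scipy.stats import norm

    x_arr = np.asarray(x, dtype=float)
    scalar = x_arr.ndim == 0
    x_arr = np.atleast_1d(x_arr)
    out = np.zeros_like(x_arr)

    small = (x_arr > 0) & (x_arr < 1.0)
    if small.any():
        xs = x_arr[small]
        acc = np.zeros_like(xs)
        inv = np.pi**2 / (8.0 * xs**2)
        for k in range(_THETA_MAX_TERMS):
            term = ((-1.0) ** k / (2 * k + 1)) * np.exp(-((2 * k + 1) ** 2) * inv)
            acc += term
            if np.max(np.abs(term)) < _THETA_TOL:
                break
        out[small] = np.clip(4.0 / np.pi * acc, 0.0, 1.0)

    large = np.isfinite(x_arr) & (x_arr >= 1.0)
    if large.any():
        xs = x_arr[large]
        tail = np.zeros_like(xs)
        for k in range(_THETA_MAX_TERMS):
            term = 4.0 * (-1.0) ** k * norm.sf((2 * k + 1) * xs)
            tail += term
            if np.max(np.abs(term)) < _THETA_TOL:
                break
        out[large] = np.clip(1.0 - tail, 0.0, 1.0)

    out[np.isposinf(x_arr)] = 1.0
    return float(out[0]) if scalar else out


def tail_LD(x, D: int = 0) -> np.ndarray | float:
    """Upper-tail law L_D(x) = 1 - Theta(x)^(2D+1) of the scaled score.

    Monotone decreasing in x, non-decreasing in D; x <= 0 (or below 1e-8)
    returns 1 and x = +inf returns 0.
    """
    if D < 0:
        raise ValueError("delay bound D must be >= 0")
    x_arr = np.atleast_1d(np.asarray(x, dtype=float))
    p = 1.0 - np.asarray(theta_cdf(np.where(x_arr < _X_FLOOR, 0.0, x_arr))) ** (2 * D + 1)
    p = np.clip(p, 0.0, 1.0)
    return float(p[0]) if np.asarray(x).ndim == 0 else p


def p_value(
    score: int,
    m: int,
    sigma: float,
    D: int = 0,
    *,
    method: str = "STLTA",
    state_model: str | None = None,
) -> SignificanceResult:
    """Wrap a score into the tail approximation at chain length ``m``.

    The scaling length is the length of the product chain, i.e. n - 1 for
    original series of length n.  A score of 0 maps to p = 1; sigma <= 0
    yields a flagged degenerate result.
    """
    if m < 1:
        raise ValueError("chain length m must be >= 1")
    if not sigma > 0 or not math.isfinite(sigma):
        return SignificanceResult(
            int(score), m, float("nan"), float("nan"), float("nan"),
            method, state_model, degenerate=True,
        )
    x = score / (sigma * math.sqrt(m))
    p = 1.0 if score <= 0 else float(tail_LD(x, D))
    return SignificanceResult(int(score), m, float(sigma), float(x), p, method, state_model)


def _classify(trend: TrendSeries) -> str:
    states = trend.observed_states
    if len(states) == 1:
        return "degenerate"
    return "three" if 0 in states else "two"


def _fit_sigma(dx: TrendSeries, dy: TrendSeries) -> tuple[float, str]:
    """Estimate sigma and name the state model for an observed trend pair.

    Chains are classified by their observed symbol sets; a chain whose zero
    state never transitions onward (empty zero row) drops back to the
    two-state model.  Raises DegenerateChainError when no ergodic variance
    exists.
    """
    kinds = []
    params = []
    for tr in (dx, dy):
        kind = _classify(tr)
        if kind == "degenerate":
            raise mv.DegenerateChainError("single-state trend sequence")
        counts = mv.pair_counts(tr)
        if kind == "three":
            try:
                fitted = mv.estimate_three_state(counts)
            except mv.DegenerateChainError:
                kind = "two"
                fitted = mv.estimate_two_state(counts)
        else:
            fitted = mv.estimate_two_state(counts)
        params.append(fitted)
        kinds.append(kind)
    if kinds == ["two", "two"]:
        return mv.sigma2_two(*params) ** 0.5, "two"
    if kinds == ["three", "three"]:
        return mv.sigma2_three(*params) ** 0.5, "three"
    return mv.sigma2_mixed(*params) ** 0.5, "mixed"


def _score_pair(x, y, t: float, D: int, *, two_sided: bool, strict: bool):
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise ValueError("x and y must be 1-d series of equal length")
    if xv.size < 3:
        raise ValueError("need series of length >= 3")
    dx = discretize(xv, t, strict=strict)
    dy = discretize(yv, t, strict=strict)
    score = int(lt_scores_batch(dx.symbols[None, :], dy.symbols[None, :], D)[0])
    if two_sided:
        anti = int(lt_scores_batch(dx.symbols[None, :], -dy.symbols[None, :], D)[0])
        score = max(score, anti)
    return dx, dy, score


def stlta(
    x,
    y,
    t: float = 0.0,
    D: int = 0,
    *,
    two_sided: bool = False,
    strict: bool = False,
) -> SignificanceResult:
    """Theoretical p-value with data-estimated (stationary-chain) variance.

    Discretizes both series at threshold ``t``, fits the two-/three-/mixed-
    state Markov model to the observed trend chains, and plugs the resulting
    sigma into the Brownian tail law.  ``two_sided=True`` additionally scores
    the pair against the negated second trend sequence and keeps the larger
    score (default off: the score is the co-trending maximum as defined).
    """
    dx, dy, score = _score_pair(x, y, t, D, two_sided=two_sided, strict=strict)
    m = len(dx)
    try:
        sigma, model = _fit_sigma(dx, dy)
    except mv.DegenerateChainError:
        return SignificanceResult(
            score, m, float("nan"), float("nan"), float("nan"),
            "STLTA", None, degenerate=True,
        )
    return p_value(score, m, sigma, D, method="STLTA", state_model=model)


def tlta(
    x,
    y,
    t: float = 0.0,
    D: int = 0,
    *,
    marginal: str = "normal",
    two_sided: bool = False,
    strict: bool = False,
) -> SignificanceResult:
    """Theoretical p-value under the i.i.d.-original-series assumption.

    Identical scaling to :func:`stlta`, but sigma is fixed by the threshold
    alone: a = 1/3 (sigma^2 = 1.25) at t = 0, and the cached Monte-Carlo
    i.i.d. three-state parameters at t > 0.
    """
    dx, dy, score = _score_pair(x, y, t, D, two_sided=two_sided, strict=strict)
    m = len(dx)
    if t == 0:
        p = mv.iid_params(0.0)
        sigma2, model = mv.sigma2_two(p, p), "two"
    else:
        p3 = mv.iid_params(float(t), marginal)
        sigma2, model = mv.sigma2_three(p3, p3), "three"
    return p_value(score, m, sigma2**0.5, D, method="TLTA", state_model=model)


def permutation_test(
    x,
    y,
    t: float = 0.0,
    D: int = 0,
    n_perm: int = 1000,
    seed=None,
    rng=None,
    *,
    permute: str = "symbols",
    two_sided: bool = False,
    strict: bool = False,
    _chunk: int = 200_000,
) -> SignificanceResult:
    """Permutation p-value for the local trend score.

    ``permute="symbols"`` (default) uniformly shuffles the trend symbols of
    the second series and re-scores; this is the convention the published
    type-I-error grids follow.  ``permute="values"`` shuffles the original
    numeric values and re-discretizes: for exchangeable (i.i.d.) series this
    is an exact test, whereas the symbol permutation ignores the serial
    dependence that discretization itself induces and can be slightly
    anti-conservative even for i.i.d. data.  The add-one estimator
    p = (1 + #{perm >= observed}) / (n_perm + 1) avoids p = 0.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if permute not in ("symbols", "values"):
        raise ValueError("permute must be 'symbols' or 'values'")
    if rng is None:
        rng = np.random.default_rng(seed)
    dx, dy, observed = _score_pair(x, y, t, D, two_sided=two_sided, strict=strict)
    yv = np.asarray(y, dtype=float)
    m = len(dx)
    hits = 0
    rows = max(1, _chunk // max(1, yv.size))
    done = 0
    while done < n_perm:
        batch = min(rows, n_perm - done)
        if permute == "values":
            perm_y = rng.permuted(np.broadcast_to(yv, (batch, yv.size)).copy(), axis=1)
            dperm = discretize_values(perm_y, t, strict=strict)
        else:
            dperm = rng.permuted(
                np.broadcast_to(dy.symbols, (batch, m)).copy(), axis=1
            )
        dx_tile = np.broadcast_to(dx.symbols, dperm.shape)
        scores = lt_scores_batch(dx_tile, dperm, D)
        if two_sided:
            scores = np.maximum(scores, lt_scores_batch(dx_tile, -dperm, D))
        hits += int((scores >= observed).sum())
        done += batch
    p = (1 + hits) / (n_perm + 1)
    sigma_dummy = float("nan")
    x_stat = float("nan")
    return SignificanceResult(
        observed, m, sigma_dummy, x_stat, p, "PERMUTATION", None, False, n_perm
    )
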