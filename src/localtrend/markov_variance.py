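"""Markov-chain models for trend sequences and the long-run variance sigma^2.

Trend sequences derived from stationary series are modelled as first-order
Markov chains on {-1, +1} (two-state, threshold t = 0) or {-1, 0, +1}
(three-state, t > 0).  Both chains are assumed symmetric under sign flip, so
the two-state chain has a single stay probability ``a`` and the three-state
chain three parameters: stay ``b`` (T[-1,-1] = T[1,1]), flip ``c``
(T[-1,1] = T[1,-1]) and exit ``d`` (T[0,-1] = T[0,1]).

Under the null that the two original series are unrelated, the product chain
Z_i = d_i^X * d_i^Y has long-run variance

    sigma^2 = E(Z_1^2) + 2 * sum_{k>=1} E(Z_1 Z_{k+1})
            = E((d_1^X)^2) E((d_1^Y)^2) + 2 * sum_k E(d_1^X d_{k+1}^X) E(d_1^Y d_{k+1}^Y),

which sums to a closed geometric form because the lag-k autocovariances decay
as r^k = (2a-1)^k (two-state) or 2*phi_1*(b-c)^k (three-state, phi_1 the
stationary mass on +1).  These closed forms, the transition-count estimators
of (a) and (b, c, d), and a matrix-power autocovariance oracle live here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .trend_core import TrendSeries, discretize_values

__all__ = [
    "DegenerateChainError",
    "TwoStateParams",
    "ThreeStateParams",
    "PairCounts",
    "pair_counts",
    "estimate_two_state",
    "estimate_three_state",
    "sigma2_two",
    "sigma2_three",
    "sigma2_mixed",
    "autocov_exact",
    "iid_params",
]

#: numerical margin below which a decay product counts as non-ergodic
_DEGENERATE_TOL = 1e-9


class DegenerateChainError(ValueError):
    """Raised when a fitted chain admits no ergodic variance (e.g. a = 1)."""


@dataclass(frozen=True)
class TwoStateParams:
    """Symmetric two-state chain on {-1, +1} with stay probability ``a``."""

    a: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.a <= 1.0:
            raise ValueError("stay probability a must lie in [0, 1]")

    @property
    def r(self) -> float:
        """Lag-1 autocorrelation factor 2a - 1 (lag-k autocovariance is r^k)."""
        return 2.0 * self.a - 1.0

    @property
    def transition_matrix(self) -> np.ndarray:
        """Rows/columns ordered (-1, +1)."""
        a = self.a
        return np.array([[a, 1.0 - a], [1.0 - a, a]])

    @property
    def stationary(self) -> np.ndarray:
        return np.array([0.5, 0.5])


@dataclass(frozen=True)
class ThreeStateParams:
    """Symmetric three-state chain on {-1, 0, +1}.

    ``b`` = stay probability from +-1, ``c`` = flip probability between -1 and
    +1, ``d`` = exit probability from 0 to each of +-1; the implied entries
    are T[+-1, 0] = 1 - b - c and T[0, 0] = 1 - 2d.
    """

    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if min(self.b, self.c, self.d) < 0:
            raise ValueError("b, c, d must be non-negative")
        if self.b + self.c > 1.0 + 1e-12:
            raise ValueError("b + c must not exceed 1")
        if 2.0 * self.d > 1.0 + 1e-12:
            raise ValueError("2d must not exceed 1")

    @property
    def rho(self) -> float:
        """Decay factor b - c of the lag-k autocovariance 2*phi1*(b-c)^k."""
        return self.b - self.c

    @property
    def phi1(self) -> float:
        """Stationary probability of each of the +-1 states."""
        denom = 1.0 - self.b - self.c + 2.0 * self.d
        if denom <= _DEGENERATE_TOL:
            raise DegenerateChainError("stationary law undefined: 1 - b - c + 2d ~ 0")
        return self.d / denom

    @property
    def transition_matrix(self) -> np.ndarray:
        """Rows/columns ordered (-1, 0, +1)."""
        b, c, d = self.b, self.c, self.d
        return np.array(
            [
                [b, 1.0 - b - c, c],
                [d, 1.0 - 2.0 * d, d],
                [c, 1.0 - b - c, b],
            ]
        )

    @property
    def stationary(self) -> np.ndarray:
        p1 = self.phi1
        return np.array([p1, 1.0 - 2.0 * p1, p1])


@dataclass(frozen=True)
class PairCounts:
    """3x3 tally of consecutive symbol pairs, rows/cols ordered (-1, 0, +1)."""

    table: np.ndarray

    def __post_init__(self) -> None:
        tab = np.asarray(self.table, dtype=np.int64)
        if tab.shape != (3, 3) or (tab < 0).any():
            raise ValueError("pair-count table must be a non-negative 3x3 array")
        object.__setattr__(self, "table", tab)

    def count(self, u: int, v: int) -> int:
        return int(self.table[u + 1, v + 1])

    def row_sum(self, u: int) -> int:
        return int(self.table[u + 1].sum())

    @property
    def total(self) -> int:
        return int(self.table.sum())


def pair_counts(trend) -> PairCounts:
    """Tally adjacent symbol pairs (d_i, d_{i+1}) of a trend sequence."""
    sym = trend.symbols if isinstance(trend, TrendSeries) else np.asarray(trend, dtype=np.int8)
    if sym.size < 2:
        raise ValueError("need at least 2 trend symbols to count transitions")
    tab = np.zeros((3, 3), dtype=np.int64)
    np.add.at(tab, (sym[:-1] + 1, sym[1:] + 1), 1)
    return PairCounts(tab)


def _averaged_ratio(num_lo: int, den_lo: int, num_hi: int, den_hi: int) -> float:
    """Mean of the two row ratios; falls back to the single observed row."""
    if den_lo > 0 and den_hi > 0:
        return 0.5 * (num_lo / den_lo + num_hi / den_hi)
    if den_lo > 0:
        return num_lo / den_lo
    if den_hi > 0:
        return num_hi / den_hi
    raise DegenerateChainError("no transitions out of the +-1 states")


def estimate_two_state(counts: PairCounts) -> TwoStateParams:
    """Estimate the stay probability ``a`` from pair counts.

    a_hat = (n[-1,-1]/n[-1,.] + n[1,1]/n[1,.]) / 2 with row sums taken over
    the two signed states; if only one row is observed its ratio is used
    alone, and with neither row observed the chain is degenerate.
    """
    t = counts.table
    den_lo = int(t[0, 0] + t[0, 2])
    den_hi = int(t[2, 0] + t[2, 2])
    return TwoStateParams(_averaged_ratio(int(t[0, 0]), den_lo, int(t[2, 2]), den_hi))


def estimate_three_state(counts: PairCounts) -> ThreeStateParams:
    """Estimate (b, c, d) from pair counts of a three-state trend sequence.

    b_hat and c_hat average the two signed-row ratios (single-row fallback as
    for the two-state chain); d_hat = (n[0,-1]+n[0,1]) / (2 * n[0,.]).  An
    empty zero row means the zero state was only seen at the final position;
    the caller should then fall back to the two-state model.
    """
    t = counts.table
    den_lo, den_hi = counts.row_sum(-1), counts.row_sum(1)
    b = _averaged_ratio(int(t[0, 0]), den_lo, int(t[2, 2]), den_hi)
    c = _averaged_ratio(int(t[0, 2]), den_lo, int(t[2, 0]), den_hi)
    n0 = counts.row_sum(0)
    if n0 == 0:
        raise DegenerateChainError(
            "no transitions out of the 0 state; use the two-state model"
        )
    d = 0.5 * (t[1, 0] + t[1, 2]) / n0
    return ThreeStateParams(b, c, d)


def _geometric_factor(decay: float) -> float:
    """(1 + q)/(1 - q) = 1 + 2*sum_{k>=1} q^k for |q| < 1."""
    if abs(decay) >= 1.0 - _DEGENERATE_TOL:
        raise DegenerateChainError("autocovariance decay product has modulus ~ 1")
    return (1.0 + decay) / (1.0 - decay)


def sigma2_two(px: TwoStateParams, py: TwoStateParams) -> float:
    """Long-run variance of the product chain, both trends two-state:
    sigma^2 = (1 + r_X r_Y)/(1 - r_X r_Y) with r = 2a - 1."""
    return _geometric_factor(px.r * py.r)


def sigma2_three(px: ThreeStateParams, py: ThreeStateParams) -> float:
    """Both trends three-state:
    sigma^2 = (2 phi1_X)(2 phi1_Y)(1 + rho_X rho_Y)/(1 - rho_X rho_Y)."""
    return 4.0 * px.phi1 * py.phi1 * _geometric_factor(px.rho * py.rho)


def sigma2_mixed(p_first, p_second) -> float:
    """One two-state and one three-state trend (either argument order):
    sigma^2 = 2 phi1 * (1 + r rho)/(1 - r rho)."""
    if isinstance(p_first, TwoStateParams) and isinstance(p_second, ThreeStateParams):
        p2, p3 = p_first, p_second
    elif isinstance(p_first, ThreeStateParams) and isinstance(p_second, TwoStateParams):
        p2, p3 = p_second, p_first
    else:
        raise TypeError("sigma2_mixed needs one TwoStateParams and one ThreeStateParams")
    return 2.0 * p3.phi1 * _geometric_factor(p2.r * p3.rho)


def autocov_exact(params, k: int) -> float:
    """Lag-k autocovariance E(d_1 d_{k+1}) via an explicit k-step matrix power.

    Serves as the independent check of the closed forms (2a-1)^k and
    2*phi1*(b-c)^k used inside the sigma^2 formulas.
    """
    if k < 1:
        raise ValueError("lag k must be >= 1")
    T = params.transition_matrix
    pi = params.stationary
    states = np.array([-1.0, 1.0]) if T.shape[0] == 2 else np.array([-1.0, 0.0, 1.0])
    Tk = np.linalg.matrix_power(T, k)
    return float((pi * states) @ Tk @ states)


_MARGINALS = {
    "normal": lambda rng, size: rng.standard_normal(size),
    "uniform": lambda rng, size: rng.random(size),
    "exponential": lambda rng, size: rng.exponential(size=size),
}


@lru_cache(maxsize=32)
def iid_params(
    t: float,
    marginal: str = "normal",
    n_samples: int = 10**6,
    seed: int = 20220426,
):
    """Transition parameters implied by an i.i.d. original series.

    For ``t = 0`` the answer is distribution-free: the three orderings of
    (X_i, X_{i+1}, X_{i+2}) compatible with two given trend directions are
    equally likely, giving a = P(up|up) = (1/6)/(1/2) = 1/3 exactly.  For
    ``t > 0`` the parameters depend on the marginal; they are estimated from
    one long discretized i.i.d. sample (default: standard normal, 10^6
    draws, fixed seed) and cached.  Used by the TLTA comparator.
    """
    if t < 0:
        raise ValueError("threshold t must be >= 0")
    if t == 0:
        return TwoStateParams(1.0 / 3.0)
    if marginal not in _MARGINALS:
        raise ValueError(f"unknown marginal {marginal!r}; use one of {sorted(_MARGINALS)}")
    if n_samples < 10**5:
        warnings.warn(
            "iid_params Monte-Carlo sample below 1e5; estimates may be imprecise",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    sample = _MARGINALS[marginal](rng, n_samples)
    return estimate_three_state(pair_counts(discretize_values(sample, t)))
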