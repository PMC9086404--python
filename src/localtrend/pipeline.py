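"""All-pairs trend-association screening on a factors x time-points table.

Mirrors the usual microbiome workflow: read a wide OTU (or environmental
factor) abundance table, drop rarely observed factors (prevalence filter),
fill interior gaps by linear interpolation, score every unordered factor
pair with the chosen significance method, and control the false discovery
rate across the family of tests with Benjamini-Hochberg q-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .significance import SignificanceResult, permutation_test, stlta, tlta
from .trend_core import discretize, lt_score

__all__ = [
    "AbundanceTable",
    "EdgeRecord",
    "read_table",
    "prevalence_filter",
    "interpolate_missing",
    "all_pairs",
    "edges_to_frame",
    "make_fixture",
]


@dataclass(frozen=True)
class AbundanceTable:
    """Factors x ordered time points; missing observations are NaN."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("factor identifiers must be unique")

    @property
    def factors(self) -> list[str]:
        return [str(f) for f in self.data.index]

    @property
    def n_time(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class EdgeRecord:
    """One pairwise association; factor_a < factor_b lexicographically."""

    factor_a: str
    factor_b: str
    score: int
    D: int
    t: float
    sigma: float
    p_value: float
    q_value: float
    method: str
    state_model: str | None
    start_a: int
    start_b: int
    length: int
    degenerate: bool
    significant: bool


def read_table(path, format: str | None = None) -> AbundanceTable:
    """Read a wide TSV/CSV table: first column factor id, remaining columns
    time-ordered samples.  Blank cells and "NA" become missing values."""
    path = Path(path)
    if format is None:
        format = "tsv" if path.suffix.lower() in (".tsv", ".txt") else "csv"
    sep = "\t" if format == "tsv" else ","
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=["NA"])
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate factor identifiers: {dupes}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in {path.name}: {exc}") from exc
    return AbundanceTable(df)


def prevalence_filter(table: AbundanceTable, min_fraction: float) -> AbundanceTable:
    """Keep factors observed (non-missing and non-zero) in at least
    ``min_fraction`` of the time points."""
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must lie in (0, 1]")
    present = table.data.notna() & (table.data != 0)
    keep = present.mean(axis=1) >= min_fraction
    if not keep.any():
        raise ValueError("prevalence filter removed every factor")
    return AbundanceTable(table.data.loc[keep])


def interpolate_missing(table: AbundanceTable) -> AbundanceTable:
    """Fill interior gaps linearly (equally spaced time points); leading and
    trailing gaps take the nearest observed value."""
    n_obs = table.data.notna().sum(axis=1)
    if (n_obs == 0).any():
        empty = table.data.index[n_obs == 0].tolist()
        raise ValueError(f"factors with no observed values: {empty}")
    if (n_obs < 2).any():
        short = table.data.index[n_obs < 2].tolist()
        raise ValueError(f"factors with fewer than 2 observed values: {short}")
    filled = table.data.interpolate(method="linear", axis=1, limit_area="inside")
    filled = filled.ffill(axis=1).bfill(axis=1)
    return AbundanceTable(filled)


_METHODS = {
    "stlta": lambda x, y, t, D, n_perm, rng: stlta(x, y, t, D),
    "tlta": lambda x, y, t, D, n_perm, rng: tlta(x, y, t, D),
    "permutation": lambda x, y, t, D, n_perm, rng: permutation_test(
        x, y, t, D, n_perm=n_perm, rng=rng
    ),
}


def all_pairs(
    table: AbundanceTable,
    method: str = "stlta",
    t: float = 0.0,
    D: int = 3,
    alpha: float = 0.05,
    fdr_q: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> list[EdgeRecord]:
    """Score every unordered factor pair and attach BH-adjusted q-values.

    q-values are computed over the family of non-degenerate tests only; an
    edge is flagged significant when both p <= alpha and q <= fdr_q.  The
    result is independent of the input row order (factors are sorted).
    """
    if method not in _METHODS:
        raise ValueError(f"method must be one of {sorted(_METHODS)}")
    if table.data.isna().any().any():
        raise ValueError("table has missing values; run interpolate_missing first")
    names = sorted(table.factors)
    if len(names) < 2:
        raise ValueError("need at least 2 factors")
    data = {name: table.data.loc[name].to_numpy(dtype=float) for name in names}
    rng = np.random.default_rng(seed)
    raw: list[tuple[str, str, SignificanceResult, tuple[int, int, int]]] = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            res = _METHODS[method](data[a], data[b], t, D, n_perm, rng)
            aln = lt_score(discretize(data[a], t), discretize(data[b], t), D)
            raw.append((a, b, res, (aln.start_x, aln.start_y, aln.length)))
    pvals = np.array([r[2].p_value for r in raw])
    valid = ~np.isnan(pvals)
    qvals = np.full(pvals.shape, np.nan)
    if valid.any():
        qvals[valid] = multipletests(pvals[valid], method="fdr_bh")[1]
    edges = []
    for k, ((a, b, res, aln), p, q) in enumerate(zip(raw, pvals, qvals)):
        sig = bool(valid[k]) and bool(p <= alpha) and bool(q <= fdr_q)
        edges.append(
            EdgeRecord(
                a, b, res.score, D, t, res.sigma, p, q, res.method,
                res.state_model, aln[0], aln[1], aln[2], res.degenerate, sig,
            )
        )
    return edges


def edges_to_frame(edges: Sequence[EdgeRecord]) -> pd.DataFrame:
    """Edge records as a tidy frame, ready for TSV export."""
    return pd.DataFrame([vars(e) for e in edges])


def make_fixture(
    n_factors: int = 20,
    n_time: int = 100,
    planted_pairs: Sequence[tuple[int, int]] = (),
    autocorr: float = 0.3,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> AbundanceTable:
    """Synthetic OTU-like abundance table with optional planted associations.

    Each factor follows an AR(1) latent series (coefficient ``autocorr``)
    mapped through exp() to a positive abundance scale.  A planted pair
    (i, j) shares the *signs* of its innovations, so the two factors
    co-trend without being identical.  Missing values are injected uniformly
    at ``missing_rate``.
    """
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal((n_factors, n_time))
    for i, j in planted_pairs:
        eps[j] = np.sign(eps[i]) * np.abs(eps[j])
    latent = np.empty_like(eps)
    latent[:, 0] = eps[:, 0]
    for k in range(1, n_time):
        latent[:, k] = autocorr * latent[:, k - 1] + eps[:, k]
    values = np.exp(latent)
    if missing_rate > 0:
        mask = rng.random(values.shape) < missing_rate
        values = np.where(mask, np.nan, values)
    df = pd.DataFrame(
        values,
        index=[f"OTU_{i:03d}" for i in range(n_factors)],
        columns=[f"t{k:03d}" for k in range(n_time)],
    )
    return AbundanceTable(df)
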