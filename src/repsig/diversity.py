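"""Repertoire diversity and clonality statistics.

Hill numbers ``D_q = (sum_i p_i^q)^(1/(1-q))`` give the effective number of
equally abundant clonotypes at diversity order ``q`` (``D_0`` = richness,
``D_1`` = exp(Shannon), ``D_2`` = inverse Simpson).  The Simpson clonality
index ``SCI = sqrt(sum_i p_i^2)`` runs from ~0 (maximally diverse) to 1
(monoclonal).  Homeostasis bins partition repertoire space by per-clonotype
frequency into Small (0, 1e-4], Medium (1e-4, 1e-3], Large (1e-3, 1e-2]
and Hyperexpanded (1e-2, 1] (lower-exclusive, upper-inclusive).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, Sequence

import numpy as np
from scipy import stats

from .repertoire import Repertoire

__all__ = [
    "hill_diversity",
    "hill_profile",
    "simpson_clonality",
    "HOMEOSTASIS_BINS",
    "homeostasis_occupancy",
    "RankSumResult",
    "rank_sum_test",
]


def _frequencies(r: Repertoire | np.ndarray | Sequence[float]) -> np.ndarray:
    if isinstance(r, Repertoire):
        return r.frequencies
    p = np.asarray(r, dtype=float)
    if p.size == 0:
        raise ValueError("empty repertoire")
    if abs(p.sum() - 1.0) > 1e-9 or (p <= 0).any():
        raise ValueError("frequencies must be positive and sum to 1")
    return p


def hill_diversity(r: Repertoire | Sequence[float], q: float) -> float:
    """Effective number of equally abundant clonotypes at order ``q >= 0``.

    The q=1 case is the continuous limit exp(-sum p_i ln p_i).
    """
    if q < 0:
        raise ValueError(f"Hill order q must be >= 0, got {q}")
    p = _frequencies(r)
    if abs(q - 1.0) < 1e-12:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p**q) ** (1.0 / (1.0 - q)))


def hill_profile(r: Repertoire | Sequence[float], orders: Sequence[float] = (0, 1, 2)) -> Dict[float, float]:
    """Hill numbers at several orders (default richness, Shannon, Simpson)."""
    return {q: hill_diversity(r, q) for q in orders}


def simpson_clonality(r: Repertoire | Sequence[float]) -> float:
    """sqrt(sum p_i^2): 1 for a monoclonal sample, 1/sqrt(N) for uniform N."""
    p = _frequencies(r)
    return float(np.sqrt(np.sum(p**2)))


#: (name, lower-exclusive, upper-inclusive) frequency bins of repertoire space.
HOMEOSTASIS_BINS = (
    ("Small", 0.0, 1e-4),
    ("Medium", 1e-4, 1e-3),
    ("Large", 1e-3, 1e-2),
    ("Hyperexpanded", 1e-2, 1.0),
)


def homeostasis_occupancy(r: Repertoire | Sequence[float]) -> Dict[str, float]:
    """Fraction of repertoire space occupied by clones in each expansion bin.

    Each clonotype's frequency mass falls in exactly one half-open bin
    (lower < p <= upper); occupancies are >= 0 and sum to 1.
    """
    p = _frequencies(r)
    return {
        name: float(p[(p > lo) & (p <= hi)].sum()) for name, lo, hi in HOMEOSTASIS_BINS
    }


@dataclass(frozen=True)
class RankSumResult:
    p_value: float
    #: which sample has the larger mean rank: "x", "y" or "none"
    direction: str
    statistic: float  # rank sum of x
    method: str  # "exact" or "normal"


def _normal_approx_p(rank_sum_x: float, n: int, m: int, tie_term: float, alternative: str) -> float:
    """Tie-corrected normal approximation with continuity correction.

    ``tie_term`` is sum(t^3 - t) over tie groups in the pooled sample.
    """
    N = n + m
    mean = n * (N + 1) / 2.0
    var = n * m / 12.0 * ((N + 1) - tie_term / (N * (N - 1.0)))
    if var <= 0:
        return 1.0
    d = rank_sum_x - mean
    # continuity correction shrinks |d| by 0.5
    if alternative == "two-sided":
        z = (abs(d) - 0.5) / math.sqrt(var)
        return float(min(1.0, 2.0 * stats.norm.sf(max(z, 0.0))))
    if alternative == "greater":
        z = (d - 0.5) / math.sqrt(var)
    else:  # less
        z = (-d - 0.5) / math.sqrt(var)
    return float(stats.norm.sf(z))


def rank_sum_test(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
    exact_threshold: int = 12,
) -> RankSumResult:
    """Wilcoxon rank-sum (Mann-Whitney) test using midranks.

    The null distribution is enumerated exactly over all label assignments
    when ``n + m <= exact_threshold`` and the pooled sample has no ties;
    otherwise a tie-corrected normal approximation with continuity
    correction is used.  Degenerate input (all pooled values identical)
    returns p = 1 with direction "none".
    """
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"invalid alternative {alternative!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n, m = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w_x = float(ranks[:n].sum())
    mean_x = n * (n + m + 1) / 2.0

    if np.all(pooled == pooled[0]):
        return RankSumResult(1.0, "none", w_x, "degenerate")
    direction = "x" if w_x > mean_x else ("y" if w_x < mean_x else "none")

    has_ties = np.unique(pooled).size < pooled.size
    if n + m <= exact_threshold and not has_ties:
        # enumerate all C(n+m, n) assignments of ranks to sample x
        total = 0
        count = 0
        obs_dev = abs(w_x - mean_x)
        for combo in itertools.combinations(range(n + m), n):
            w = sum(ranks[i] for i in combo)
            total += 1
            if alternative == "two-sided":
                count += abs(w - mean_x) >= obs_dev - 1e-9
            elif alternative == "greater":
                count += w >= w_x - 1e-9
            else:
                count += w <= w_x + 1e-9
        return RankSumResult(count / total, direction, w_x, "exact")

    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    p = _normal_approx_p(w_x, n, m, tie_term, alternative)
    return RankSumResult(p, direction, w_x, "normal")


def rank_sum_p_rows(F: np.ndarray, pos_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-sided rank-sum screen over the rows of a matrix.

    For each row of ``F`` (values per sample, columns), tests the samples
    flagged by ``pos_mask`` against the rest using the same tie-corrected
    normal approximation as :func:`rank_sum_test`.  Returns ``(p, pos_higher)``
    where ``pos_higher`` flags rows whose positive group has the larger
    rank sum.  Used for screening thousands of clonotypes at once.
    """
    F = np.asarray(F, dtype=float)
    pos_mask = np.asarray(pos_mask, dtype=bool)
    n = int(pos_mask.sum())
    m = int((~pos_mask).sum())
    N = n + m
    if F.shape[1] != N or n == 0 or m == 0:
        raise ValueError("pos_mask must split the columns into two non-empty groups")
    ranks = stats.rankdata(F, axis=1)
    w = ranks[:, pos_mask].sum(axis=1)
    mean = n * (N + 1) / 2.0

    # per-row tie term: sum(t^3 - t) over groups of equal values, fully
    # vectorized via run-length segment ids on the sorted rows
    S = np.sort(F, axis=1)
    boundaries = np.ones_like(S, dtype=bool)
    boundaries[:, 1:] = S[:, 1:] != S[:, :-1]
    seg = np.cumsum(boundaries, axis=1) - 1  # group id within each row
    counts = np.zeros((F.shape[0], N), dtype=np.int64)
    rows_idx = np.repeat(np.arange(F.shape[0]), N)
    np.add.at(counts, (rows_idx, seg.ravel()), 1)
    c = counts.astype(float)
    tie_terms = (c**3 - c).sum(axis=1)

    var = n * m / 12.0 * ((N + 1) - tie_terms / (N * (N - 1.0)))
    d = np.abs(w - mean)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, (d - 0.5) / np.sqrt(np.maximum(var, 1e-300)), -np.inf)
    p = np.minimum(1.0, 2.0 * stats.norm.sf(np.maximum(z, 0.0)))
    p = np.where(var > 0, p, 1.0)
    return p, w > mean
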