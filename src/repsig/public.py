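"""Public (shared) clonotype tables and cross-sample sharing analyses.

A clonotype is *public* when its key (CDR3 amino-acid sequence, optionally
with V/J gene segments) is found in at least ``min_individuals`` samples.
Ranking public clonotypes by the fraction of samples carrying them yields a
rank-size spectrum that empirically follows a power law f(x) = k x^-alpha;
a larger exponent alpha means the cohort shares more of its top public
clonotypes.  Group spectra are compared with a nested-OLS F test on the
log-log regression slopes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Set

import numpy as np
import pandas as pd
from scipy import stats

from .repertoire import KEY_SEP, CohortSample, KeyMode, Repertoire

__all__ = [
    "PublicClonotypeTable",
    "PowerLawFit",
    "SlopeComparison",
    "build_public_table",
    "sharing_spectrum",
    "fit_power_law",
    "compare_power_law_fits",
    "jaccard_index",
    "morisita_horn",
]


@dataclass
class PublicClonotypeTable:
    """Clonotype-key x sample incidence/frequency matrices.

    ``incidence`` and ``frequency`` share the same (key x sample) shape;
    frequency is 0 exactly where incidence is False.  ``sharing_fraction``
    is the per-key fraction of cohort samples carrying the key.
    """

    key_mode: KeyMode
    incidence: pd.DataFrame  # bool, keys x samples
    frequency: pd.DataFrame  # float, keys x samples
    sharing_fraction: pd.Series  # float per key
    min_individuals: int

    @property
    def keys(self) -> pd.Index:
        return self.incidence.index

    @property
    def n_samples(self) -> int:
        return self.incidence.shape[1]

    def key_parts(self) -> pd.DataFrame:
        """Split keys back into their cdr3_aa / v_call / j_call components."""
        parts = self.keys.to_series().str.split(KEY_SEP, expand=True)
        cols = ["cdr3_aa"]
        if self.key_mode.uses_v:
            cols.append("v_call")
        if self.key_mode.uses_j:
            cols.append("j_call")
        parts.columns = cols
        return parts


def cohort_frequency_matrix(
    cohort: Sequence[CohortSample | Repertoire], key_mode: KeyMode | str
) -> pd.DataFrame:
    """Key x sample frequency matrix over the union of cohort keys (0 = absent)."""
    key_mode = KeyMode.coerce(key_mode)
    reps = [s.repertoire if isinstance(s, CohortSample) else s for s in cohort]
    series = {r.sample_id: r.key_frequencies(key_mode) for r in reps}
    F = pd.DataFrame(series).fillna(0.0)
    return F.sort_index()


def build_public_table(
    cohort: Sequence[CohortSample | Repertoire],
    key_mode: KeyMode | str = KeyMode.CDR3_V_J,
    min_individuals: int = 2,
) -> PublicClonotypeTable:
    """Restrict the cohort key universe to keys shared by >= ``min_individuals``.

    With ``min_individuals=1`` the table is simply the union of all keys.
    The result is invariant to sample order (keys are sorted).
    """
    if min_individuals < 1:
        raise ValueError(f"min_individuals must be >= 1, got {min_individuals}")
    if len(cohort) < 2:
        raise ValueError("a public table needs at least 2 samples")
    key_mode = KeyMode.coerce(key_mode)
    F = cohort_frequency_matrix(cohort, key_mode)
    incidence = F > 0
    n_carriers = incidence.sum(axis=1)
    keep = n_carriers >= min_individuals
    incidence = incidence.loc[keep]
    return PublicClonotypeTable(
        key_mode=key_mode,
        incidence=incidence,
        frequency=F.loc[keep],
        sharing_fraction=n_carriers.loc[keep] / F.shape[1],
        min_individuals=min_individuals,
    )


def sharing_spectrum(table: PublicClonotypeTable) -> pd.DataFrame:
    """Rank-size spectrum of sharing: percentile rank vs % of samples sharing.

    Keys are sorted by sharing fraction descending (ties by key, so the
    spectrum is deterministic); x = rank/|keys| in (0, 1], y = 100 *
    sharing_fraction.
    """
    if len(table.keys) == 0:
        raise ValueError("empty public table")
    s = table.sharing_fraction.sort_index().sort_values(ascending=False, kind="stable")
    n = len(s)
    return pd.DataFrame(
        {
            "key": s.index,
            "rank_percentile": np.arange(1, n + 1) / n,
            "sharing_pct": 100.0 * s.to_numpy(),
        }
    ).reset_index(drop=True)


@dataclass(frozen=True)
class PowerLawFit:
    """OLS fit of log10(sharing %) on log10(percentile rank): y = k * x^-alpha."""

    alpha: float
    k: float
    n_points: int
    rss: float


def _log_points(spectrum: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(spectrum["rank_percentile"], dtype=float)
    y = np.asarray(spectrum["sharing_pct"], dtype=float)
    ok = (x > 0) & (y > 0)
    return np.log10(x[ok]), np.log10(y[ok])


def fit_power_law(spectrum: pd.DataFrame) -> PowerLawFit:
    """Fit f(x) = k x^-alpha by ordinary least squares in log10-log10 space."""
    lx, ly = _log_points(spectrum)
    if lx.size < 3:
        raise ValueError(f"power-law fit needs >= 3 points with y > 0, got {lx.size}")
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    return PowerLawFit(
        alpha=float(-slope),
        k=float(10.0**intercept),
        n_points=int(lx.size),
        rss=float(np.sum(resid**2)),
    )


@dataclass(frozen=True)
class SlopeComparison:
    f_statistic: float
    df: tuple[int, int]
    p_value: float


def compare_power_law_fits(
    spectrum_a: pd.DataFrame, spectrum_b: pd.DataFrame
) -> SlopeComparison:
    """Extra-sum-of-squares F test for equal power-law exponents.

    Reduced model: separate intercepts, common log-log slope.  Full model:
    separate intercepts and slopes.  F has (1, n_a + n_b - 4) degrees of
    freedom under the null of equal exponents.
    """
    xa, ya = _log_points(spectrum_a)
    xb, yb = _log_points(spectrum_b)
    if xa.size < 3 or xb.size < 3:
        raise ValueError("both spectra must be fittable (>= 3 positive points)")
    n = xa.size + xb.size
    g = np.concatenate([np.zeros(xa.size), np.ones(xb.size)])
    x = np.concatenate([xa, xb])
    y = np.concatenate([ya, yb])

    def rss(design: np.ndarray) -> float:
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        r = y - design @ coef
        return float(r @ r)

    X_red = np.column_stack([1 - g, g, x])
    X_full = np.column_stack([1 - g, g, x * (1 - g), x * g])
    if np.linalg.matrix_rank(X_full) < 4:
        raise ValueError("degenerate (collinear) design; cannot compare slopes")
    rss_red, rss_full = rss(X_red), rss(X_full)
    df2 = n - 4
    if rss_full <= 0:
        # perfect fits: identical slopes give F = 0, different slopes +inf
        f = 0.0 if rss_red - rss_full <= 1e-12 * max(rss_red, 1.0) else np.inf
    else:
        f = max(0.0, (rss_red - rss_full) / (rss_full / df2))
    p = float(stats.f.sf(f, 1, df2))
    return SlopeComparison(f_statistic=float(f), df=(1, df2), p_value=p)


def jaccard_index(a: Iterable, b: Iterable) -> float:
    """|a n b| / |a u b|; 0 by convention when both sets are empty."""
    a, b = set(a), set(b)
    union = len(a | b)
    return len(a & b) / union if union else 0.0


def morisita_horn(
    r1: Repertoire, r2: Repertoire, key_mode: KeyMode | str = KeyMode.CDR3_V_J
) -> float:
    """Morisita-Horn similarity 2*sum(p*q) / (sum p^2 + sum q^2) in [0, 1].

    Computed over the union of clonotype keys, with frequency 0 for keys
    absent from a sample; 1 for identical repertoires, 0 for disjoint ones.
    """
    key_mode = KeyMode.coerce(key_mode)
    p = r1.key_frequencies(key_mode)
    q = r2.key_frequencies(key_mode)
    joined = pd.concat([p, q], axis=1).fillna(0.0)
    pv, qv = joined.iloc[:, 0].to_numpy(), joined.iloc[:, 1].to_numpy()
    denom = np.sum(pv**2) + np.sum(qv**2)
    if denom == 0:
        return 0.0
    return float(np.clip(2.0 * np.sum(pv * qv) / denom, 0.0, 1.0))
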