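"""Tissue-blood overlap of expanded clonotypes and reference-pool annotation.

The overlap analysis asks how many of a lesion's most expanded
tissue-infiltrating clonotypes recur in the matched peripheral blood, and
how expanded the recurrent clones are there.  The annotation analysis
matches public clonotypes exactly (by key) against externally supplied
reference pools, e.g. virus-specific or mismatch-repair-deficient
CRC-resident TCR lists consumed as plain TSV.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .diversity import HOMEOSTASIS_BINS
from .public import PublicClonotypeTable
from .repertoire import KEY_SEP, Clonotype, KeyMode, Repertoire, strip_allele

__all__ = [
    "ReferencePool",
    "OverlapReport",
    "read_pool_tsv",
    "top_expanded",
    "repertoire_overlap",
    "annotate_against_pool",
    "expansion_ratio",
    "expansion_ratios",
]


@dataclass
class ReferencePool:
    """A named set of clonotype keys at a declared key resolution."""

    name: str
    keys: frozenset
    key_mode: KeyMode
    tissue_frequency: Optional[pd.Series] = None  # optional per-key frequency


def read_pool_tsv(path: Path | str, name: Optional[str] = None) -> ReferencePool:
    """Read a reference pool TSV (cdr3_aa[, v_call, j_call][, tissue_frequency]).

    The pool's key mode is inferred from which gene-call columns are present.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "cdr3_aa" not in df.columns:
        raise ValueError(f"{path}: pool TSV must have a cdr3_aa column")
    has_v, has_j = "v_call" in df.columns, "j_call" in df.columns
    mode = {
        (False, False): KeyMode.CDR3,
        (False, True): KeyMode.CDR3_J,
        (True, False): KeyMode.CDR3_V,
        (True, True): KeyMode.CDR3_V_J,
    }[(has_v, has_j)]
    key = df["cdr3_aa"].astype(str)
    if has_v:
        key = key + KEY_SEP + df["v_call"].map(strip_allele)
    if has_j:
        key = key + KEY_SEP + df["j_call"].map(strip_allele)
    freq = None
    if "tissue_frequency" in df.columns:
        freq = pd.Series(pd.to_numeric(df["tissue_frequency"]).to_numpy(), index=key.to_numpy())
    return ReferencePool(
        name=name or path.stem, keys=frozenset(key), key_mode=mode, tissue_frequency=freq
    )


def top_expanded(r: Repertoire, n: int, key_mode: KeyMode | str = KeyMode.CDR3_V_J) -> pd.DataFrame:
    """Top-``n`` clonotype keys by frequency, ties broken lexicographically.

    Returns a DataFrame (key, frequency) with min(n, #keys) rows.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    freq = r.key_frequencies(key_mode)  # index sorted lexicographically
    ordered = freq.sort_index().sort_values(ascending=False, kind="stable")
    top = ordered.iloc[:n]
    return pd.DataFrame({"key": top.index, "frequency": top.to_numpy()})


def _homeostasis_bin(freq: float) -> str:
    for name, lo, hi in HOMEOSTASIS_BINS:
        if lo < freq <= hi:
            return name
    raise ValueError(f"frequency {freq} outside (0, 1]")


@dataclass
class OverlapReport:
    """Overlap of a tissue sample's top-expanded clonotypes with blood."""

    n_top: int
    n_overlap: int
    overlap_fraction: float
    #: per overlapping key: tissue/blood frequency and blood expansion bin
    detail: pd.DataFrame


def repertoire_overlap(
    tissue: Repertoire,
    blood: Repertoire,
    n: int = 100,
    key_mode: KeyMode | str = KeyMode.CDR3_V_J,
    public_keys: Optional[Sequence[str]] = None,
) -> OverlapReport:
    """How many of the tissue's top-``n`` expanded clonotypes recur in blood.

    Each overlapping key is annotated with its blood homeostasis bin and,
    when ``public_keys`` is given, whether it is a cohort-public clonotype.
    """
    key_mode = KeyMode.coerce(key_mode)
    top = top_expanded(tissue, n, key_mode)
    blood_freq = blood.key_frequencies(key_mode)
    hit = top["key"].isin(blood_freq.index)
    detail = top.loc[hit].rename(columns={"frequency": "tissue_frequency"}).copy()
    detail["blood_frequency"] = blood_freq.reindex(detail["key"]).to_numpy()
    detail["blood_bin"] = [_homeostasis_bin(f) for f in detail["blood_frequency"]]
    if public_keys is not None:
        detail["is_public"] = detail["key"].isin(set(public_keys)).to_numpy()
    n_top = len(top)
    n_overlap = int(hit.sum())
    return OverlapReport(
        n_top=n_top,
        n_overlap=n_overlap,
        overlap_fraction=n_overlap / n_top,
        detail=detail.reset_index(drop=True),
    )


def _project_keys(keys: pd.Index, from_mode: KeyMode, to_mode: KeyMode) -> pd.Series:
    """Re-key from a finer mode to a coarser one by dropping fields."""
    parts = keys.to_series().str.split(KEY_SEP, expand=True)
    cols = ["cdr3_aa"]
    if from_mode.uses_v:
        cols.append("v_call")
    if from_mode.uses_j:
        cols.append("j_call")
    parts.columns = cols
    out = parts["cdr3_aa"]
    if to_mode.uses_v:
        out = out + KEY_SEP + parts["v_call"]
    if to_mode.uses_j:
        out = out + KEY_SEP + parts["j_call"]
    return out


def annotate_against_pool(
    table: PublicClonotypeTable, pool: ReferencePool
) -> tuple[float, pd.Series]:
    """Exact-match annotation of public clonotypes against a reference pool.

    Returns the annotated fraction |table keys n pool| / |table keys| and
    the per-key hit flags.  When the pool is keyed more coarsely than the
    table, table keys are projected down to the pool's resolution; a pool
    finer than the table cannot be matched and raises ``ValueError``.
    """
    if not pool.key_mode.is_coarser_or_equal(table.key_mode):
        raise ValueError(
            f"pool key mode {pool.key_mode.value} is finer than table mode "
            f"{table.key_mode.value}; cannot re-key"
        )
    if pool.key_mode == table.key_mode:
        match_keys = table.keys.to_series()
    else:
        match_keys = _project_keys(table.keys, table.key_mode, pool.key_mode)
    flags = match_keys.isin(pool.keys)
    flags.index = table.keys
    flags.name = pool.name
    return float(flags.mean()), flags


def expansion_ratio(freq_tissue: float, freq_blood: float) -> float:
    """Tissue-over-blood expansion ratio for a clone detected in both."""
    if freq_tissue <= 0 or freq_blood <= 0:
        raise ValueError("expansion ratio requires positive frequencies in both samples")
    return freq_tissue / freq_blood


def expansion_ratios(
    tissue: Repertoire,
    blood: Repertoire,
    keys: Sequence[str],
    key_mode: KeyMode | str = KeyMode.CDR3_V_J,
) -> tuple[pd.Series, int]:
    """Expansion ratios for ``keys`` detected in both samples.

    Clones undetected in either sample are excluded (never mapped to 0 or
    infinity); the exclusion count is returned alongside the ratios.
    """
    tf = tissue.key_frequencies(key_mode).reindex(keys)
    bf = blood.key_frequencies(key_mode).reindex(keys)
    ok = tf.notna() & bf.notna()
    ratios = (tf[ok] / bf[ok]).rename("expansion_ratio")
    return ratios, int((~ok).sum())
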