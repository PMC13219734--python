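"""Core domain objects for bulk TCR-beta repertoires.

A *clonotype* is a unique productive rearrangement identified by its CDR3
amino-acid sequence and (optionally) its V and J gene segments at gene-level
resolution.  A *repertoire* is one sample's clonotype table with template
counts and frequencies normalized over productive templates.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "AA_ALPHABET",
    "KeyMode",
    "Clonotype",
    "Repertoire",
    "CohortSample",
    "clonotype_key",
    "strip_allele",
]

#: The 20 standard amino acids.  Productive CDR3s must be drawn from this
#: alphabet; stop codons ('*') and ambiguous residues ('X') are rejected.
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

KEY_SEP = "|"


class KeyMode(str, enum.Enum):
    """Resolution at which clonotypes are matched across samples.

    Sharing and signature analyses can match on the CDR3 amino-acid
    sequence alone or additionally require identical J and/or V gene
    segments (gene level, alleles stripped).
    """

    CDR3 = "CDR3aa"
    CDR3_J = "CDR3aa+J"
    CDR3_V = "CDR3aa+V"
    CDR3_V_J = "CDR3aa+V+J"

    @property
    def uses_v(self) -> bool:
        return self in (KeyMode.CDR3_V, KeyMode.CDR3_V_J)

    @property
    def uses_j(self) -> bool:
        return self in (KeyMode.CDR3_J, KeyMode.CDR3_V_J)

    @property
    def n_fields(self) -> int:
        """Number of matched fields; used to rank 'shorter' key modes."""
        return 1 + self.uses_v + self.uses_j

    @classmethod
    def coerce(cls, value: "KeyMode | str") -> "KeyMode":
        if isinstance(value, cls):
            return value
        try:
            return cls(value)
        except ValueError:
            valid = ", ".join(m.value for m in cls)
            raise ValueError(
                f"invalid key mode {value!r}; expected one of: {valid}"
            ) from None

    def is_coarser_or_equal(self, other: "KeyMode") -> bool:
        """True if this mode's matched fields are a subset of ``other``'s."""
        return (not self.uses_v or other.uses_v) and (not self.uses_j or other.uses_j)


def strip_allele(call: Optional[str]) -> Optional[str]:
    """Reduce a gene call to gene level, e.g. ``TRBV19*01`` -> ``TRBV19``."""
    if call is None or not isinstance(call, str):  # tolerates NaN from pandas
        return None
    call = call.strip()
    if not call:
        return None
    return call.split("*", 1)[0]


@dataclass(frozen=True)
class Clonotype:
    """One productive TCR-beta rearrangement within a sample.

    ``frequency`` is the fraction p_i of the sample's productive templates
    carried by this clonotype.
    """

    cdr3_aa: str
    v_call: Optional[str]
    j_call: Optional[str]
    templates: int
    frequency: float
    productive: bool = True

    def __post_init__(self) -> None:
        if not self.cdr3_aa:
            raise ValueError("cdr3_aa must be non-empty")
        if self.productive and not set(self.cdr3_aa) <= AA_ALPHABET:
            bad = sorted(set(self.cdr3_aa) - AA_ALPHABET)
            raise ValueError(
                f"productive CDR3 {self.cdr3_aa!r} contains invalid residues {bad}"
            )
        if self.templates < 1:
            raise ValueError(f"templates must be >= 1, got {self.templates}")
        if not (0.0 < self.frequency <= 1.0):
            raise ValueError(f"frequency must be in (0, 1], got {self.frequency}")


def clonotype_key(c: Clonotype, mode: KeyMode | str = KeyMode.CDR3_V_J) -> str:
    """Deterministic matching key for a clonotype under ``mode``.

    Keys are equal iff the fields selected by the mode are equal at gene
    level.  Raises ``ValueError`` when the mode requires a V or J call that
    the clonotype lacks.
    """
    mode = KeyMode.coerce(mode)
    parts = [c.cdr3_aa]
    if mode.uses_v:
        v = strip_allele(c.v_call)
        if v is None:
            raise ValueError(f"key mode {mode.value} requires v_call")
        parts.append(v)
    if mode.uses_j:
        j = strip_allele(c.j_call)
        if j is None:
            raise ValueError(f"key mode {mode.value} requires j_call")
        parts.append(j)
    return KEY_SEP.join(parts)


_COLUMNS = ["cdr3_aa", "v_call", "j_call", "templates"]


class Repertoire:
    """One sample's productive clonotype table.

    The constructor merges rows with identical (cdr3_aa, v_call, j_call),
    summing template counts, and computes frequencies over the retained
    productive templates.  Internally the table is a pandas DataFrame so
    repertoire-wide statistics are vectorized.
    """

    def __init__(self, sample_id: str, table: pd.DataFrame):
        if table.empty:
            raise ValueError(f"repertoire {sample_id!r} has no productive clonotypes")
        missing = [c for c in _COLUMNS if c not in table.columns and c != "v_call" and c != "j_call"]
        if missing:
            raise ValueError(f"repertoire table missing columns: {missing}")
        df = table.loc[:, [c for c in _COLUMNS if c in table.columns]].copy()
        for col in ("v_call", "j_call"):
            if col not in df.columns:
                df[col] = None
            else:
                df[col] = df[col].map(strip_allele)
        df["templates"] = df["templates"].astype(np.int64)
        if (df["templates"] < 1).any():
            raise ValueError("template counts must be >= 1")
        df = (
            df.groupby(["cdr3_aa", "v_call", "j_call"], dropna=False, sort=True)["templates"]
            .sum()
            .reset_index()
        )
        total = int(df["templates"].sum())
        df["frequency"] = df["templates"] / total
        self.sample_id = str(sample_id)
        self._df = df
        self.total_templates = total

    # -- constructors ----------------------------------------------------
    @classmethod
    def from_counts(
        cls,
        sample_id: str,
        cdr3_aa: Iterable[str],
        v_call: Iterable[Optional[str]],
        j_call: Iterable[Optional[str]],
        templates: Iterable[int],
    ) -> "Repertoire":
        return cls(
            sample_id,
            pd.DataFrame(
                {
                    "cdr3_aa": list(cdr3_aa),
                    "v_call": list(v_call),
                    "j_call": list(j_call),
                    "templates": list(templates),
                }
            ),
        )

    @classmethod
    def from_clonotypes(cls, sample_id: str, clonotypes: Iterable[Clonotype]) -> "Repertoire":
        rows = [(c.cdr3_aa, c.v_call, c.j_call, c.templates) for c in clonotypes]
        return cls(sample_id, pd.DataFrame(rows, columns=_COLUMNS))

    # -- accessors -------------------------------------------------------
    @property
    def table(self) -> pd.DataFrame:
        """Clonotype table (cdr3_aa, v_call, j_call, templates, frequency)."""
        return self._df

    @property
    def frequencies(self) -> np.ndarray:
        p = self._df["frequency"].to_numpy()
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("repertoire frequencies are not normalized")
        return p

    def __len__(self) -> int:
        return len(self._df)

    def __iter__(self) -> Iterator[Clonotype]:
        for row in self._df.itertuples(index=False):
            yield Clonotype(
                cdr3_aa=row.cdr3_aa,
                v_call=row.v_call,
                j_call=row.j_call,
                templates=int(row.templates),
                frequency=float(row.frequency),
            )

    def keys(self, mode: KeyMode | str = KeyMode.CDR3_V_J) -> pd.Series:
        """Vectorized clonotype keys under ``mode`` (one per table row)."""
        mode = KeyMode.coerce(mode)
        key = self._df["cdr3_aa"].astype(str)
        if mode.uses_v:
            v = self._df["v_call"]
            if v.isna().any():
                raise ValueError(f"key mode {mode.value} requires v_call for all rows")
            key = key + KEY_SEP + v
        if mode.uses_j:
            j = self._df["j_call"]
            if j.isna().any():
                raise ValueError(f"key mode {mode.value} requires j_call for all rows")
            key = key + KEY_SEP + j
        return key

    def key_frequencies(self, mode: KeyMode | str = KeyMode.CDR3_V_J) -> pd.Series:
        """Frequency per key under ``mode``; coarser modes merge rows."""
        freq = self._df["frequency"].groupby(self.keys(mode).to_numpy()).sum()
        freq.index.name = "key"
        return freq

    def key_set(self, mode: KeyMode | str = KeyMode.CDR3_V_J) -> frozenset:
        return frozenset(self.keys(mode))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"Repertoire({self.sample_id!r}, {len(self)} clonotypes, "
            f"{self.total_templates} templates)"
        )


@dataclass
class CohortSample:
    """A repertoire plus its phenotype label and optional metadata.

    ``group`` must come from ``label_set`` (default: the three-arm study
    design of non-carrier controls, cancer-free carriers ("previvor") and
    carriers with a cancer history ("survivor")).
    """

    repertoire: Repertoire
    group: str
    metadata: Mapping[str, object] = field(default_factory=dict)
    label_set: frozenset = frozenset({"control", "previvor", "survivor"})

    def __post_init__(self) -> None:
        if self.group not in self.label_set:
            raise ValueError(
                f"group {self.group!r} not in label set {sorted(self.label_set)}"
            )

    @property
    def sample_id(self) -> str:
        return self.repertoire.sample_id
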