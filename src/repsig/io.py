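"""Readers and writers for clonotype tables and cohort metadata.

Two TSV dialects are supported:

* **immunoseq** — Adaptive ImmunoSEQ-style exports (``aminoAcid`` /
  ``vGeneName`` / ``jGeneName`` / ``count (templates/reads)``, productive
  rows flagged ``In`` in ``sequenceStatus``).
* **airr** — the AIRR Rearrangement standard (``junction_aa`` / ``v_call``
  / ``j_call`` / ``duplicate_count``, boolean ``productive``).

Column names are resolved through a configurable :class:`ColumnMap`, so
vendor variants only need a different mapping, not a different reader.
Frequencies are always recomputed from template counts after productive
filtering rather than trusted from vendor frequency columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .repertoire import CohortSample, KeyMode, Repertoire

__all__ = [
    "ColumnMap",
    "DIALECTS",
    "read_immunoseq_tsv",
    "read_airr_tsv",
    "read_repertoire",
    "write_airr_tsv",
    "read_cohort_metadata",
    "read_cohort",
]


class RepertoireFormatError(ValueError):
    """A clonotype table is missing required columns or rows."""


@dataclass(frozen=True)
class ColumnMap:
    """Mapping from semantic fields to candidate column names, in priority order."""

    cdr3_aa: Sequence[str]
    v_call: Sequence[str]
    j_call: Sequence[str]
    templates: Sequence[str]
    productive: Sequence[str]
    #: values of the productive column treated as productive
    productive_true: frozenset = frozenset({"T", "TRUE", "True", "true", "In", "1"})

    def resolve(self, columns: Sequence[str], fld: str, required: bool = True) -> Optional[str]:
        for cand in getattr(self, fld):
            if cand in columns:
                return cand
        if required:
            raise RepertoireFormatError(
                f"missing required column for {fld!r}; expected one of "
                f"{list(getattr(self, fld))}"
            )
        return None


DIALECTS = {
    "immunoseq": ColumnMap(
        cdr3_aa=("aminoAcid", "amino_acid", "cdr3_amino_acid"),
        v_call=("vGeneName", "v_gene", "vMaxResolved"),
        j_call=("jGeneName", "j_gene", "jMaxResolved"),
        templates=("count (templates/reads)", "count_templates_reads", "templates", "count"),
        productive=("sequenceStatus", "sequence_status", "frame_type"),
    ),
    "airr": ColumnMap(
        cdr3_aa=("junction_aa", "cdr3_aa"),
        v_call=("v_call",),
        j_call=("j_call",),
        templates=("duplicate_count", "consensus_count"),
        productive=("productive",),
    ),
}


def _read_table(
    path: Path | str,
    cmap: ColumnMap,
    productive_only: bool,
    sample_id: Optional[str],
) -> Repertoire:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns)
    c_cdr3 = cmap.resolve(cols, "cdr3_aa")
    c_templates = cmap.resolve(cols, "templates")
    c_v = cmap.resolve(cols, "v_call", required=False)
    c_j = cmap.resolve(cols, "j_call", required=False)
    c_prod = cmap.resolve(cols, "productive", required=productive_only)

    if productive_only and c_prod is not None:
        keep = df[c_prod].isin(cmap.productive_true)
        df = df.loc[keep]
    df = df.loc[df[c_cdr3].notna() & (df[c_cdr3] != "")]
    if df.empty:
        raise RepertoireFormatError(f"{path}: no productive clonotypes after filtering")

    table = pd.DataFrame(
        {
            "cdr3_aa": df[c_cdr3],
            "v_call": df[c_v] if c_v is not None else None,
            "j_call": df[c_j] if c_j is not None else None,
            "templates": pd.to_numeric(df[c_templates]).round().astype(int),
        }
    )
    return Repertoire(sample_id or path.stem, table)


def read_immunoseq_tsv(
    path: Path | str,
    productive_only: bool = True,
    column_map: Optional[ColumnMap] = None,
    sample_id: Optional[str] = None,
) -> Repertoire:
    """Read an ImmunoSEQ-style clonotype TSV into a :class:`Repertoire`.

    Non-productive rows (out-of-frame or containing stop codons) are
    dropped when ``productive_only``; duplicate (cdr3, v, j) rows are
    merged by summing template counts and frequencies renormalized over
    the retained rows.
    """
    return _read_table(path, column_map or DIALECTS["immunoseq"], productive_only, sample_id)


def read_airr_tsv(
    path: Path | str,
    productive_only: bool = True,
    column_map: Optional[ColumnMap] = None,
    sample_id: Optional[str] = None,
) -> Repertoire:
    """Read an AIRR Rearrangement TSV; allele suffixes are stripped to gene level."""
    return _read_table(path, column_map or DIALECTS["airr"], productive_only, sample_id)


def read_repertoire(
    path: Path | str,
    dialect: str = "airr",
    productive_only: bool = True,
    sample_id: Optional[str] = None,
) -> Repertoire:
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {sorted(DIALECTS)}")
    return _read_table(path, DIALECTS[dialect], productive_only, sample_id)


def write_airr_tsv(repertoire: Optional[Repertoire], path: Path | str) -> None:
    """Write a repertoire as an AIRR Rearrangement TSV.

    Round-tripping through :func:`read_airr_tsv` reproduces the keys,
    counts and frequencies exactly (frequencies are recomputed from
    counts on read).  ``None`` or an absent repertoire writes a
    header-only file.
    """
    cols = ["junction_aa", "v_call", "j_call", "duplicate_count", "productive"]
    if repertoire is None:
        out = pd.DataFrame(columns=cols)
    else:
        t = repertoire.table
        out = pd.DataFrame(
            {
                "junction_aa": t["cdr3_aa"],
                "v_call": t["v_call"],
                "j_call": t["j_call"],
                "duplicate_count": t["templates"],
                "productive": "T",
            }
        )
    out.to_csv(path, sep="\t", index=False)


def read_cohort_metadata(path: Path | str) -> pd.DataFrame:
    """Read a cohort metadata TSV with at least ``sample_id`` and ``group``."""
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str})
    for col in ("sample_id", "group"):
        if col not in meta.columns:
            raise RepertoireFormatError(f"cohort metadata missing column {col!r}")
    return meta


def read_cohort(
    metadata_path: Path | str,
    data_dir: Optional[Path | str] = None,
    dialect: str = "airr",
    label_set: Optional[frozenset] = None,
) -> list[CohortSample]:
    """Load a cohort from a metadata TSV plus one clonotype TSV per sample.

    The per-sample file is taken from a ``path`` column when present,
    otherwise ``<data_dir>/<sample_id>.tsv``.
    """
    meta = read_cohort_metadata(metadata_path)
    base = Path(data_dir) if data_dir is not None else Path(metadata_path).parent
    samples = []
    for row in meta.itertuples(index=False):
        rel = getattr(row, "path", None) or f"{row.sample_id}.tsv"
        rep = read_repertoire(base / rel, dialect=dialect, sample_id=row.sample_id)
        extra = {
            k: v
            for k, v in row._asdict().items()
            if k not in ("sample_id", "group", "path") and pd.notna(v)
        }
        kwargs = {"label_set": label_set} if label_set is not None else {}
        samples.append(CohortSample(repertoire=rep, group=row.group, metadata=extra, **kwargs))
    return samples
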