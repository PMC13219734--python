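"""Synthetic TCR-beta cohorts with known ground truth.

The generator emulates the statistical structure the repertoire analyses
assume, with full ground-truth manifests for parameter-recovery tests:

* a shared **public clone pool** whose within-sample abundances follow a
  Zipf (rank power-law) distribution and whose per-sample inclusion
  probabilities follow a rank power law with exponent ``sharing_alpha``,
  so the cohort's sharing spectrum is itself approximately power-law;
* **planted signature clones** carried with probability ``incidence_pos``
  by positive samples and ``incidence_neg`` by negatives, with their
  frequencies multiplied by ``abundance_fold`` in positives;
* per-sample **private clones** absent from every other sample;
* finite sequencing depth: template counts are drawn multinomially, so
  rare clones drop out as they do in real data (``depth=None`` switches
  to deterministic rounding, which keeps every included clone and is used
  when the sharing law itself is under test).

Clone identities are random CDR3-like strings with V/J labels from fixed
catalogs; exact-match analytics do not need biologically realistic VDJ
generation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .overlap import ReferencePool, top_expanded
from .public import build_public_table
from .repertoire import CohortSample, KeyMode, Repertoire

__all__ = [
    "CohortSpec",
    "generate_cohort",
    "generate_matched_pair",
    "generate_reference_pool",
]

TRBV_CATALOG = (
    "TRBV2", "TRBV4-1", "TRBV5-1", "TRBV6-1", "TRBV7-2", "TRBV9",
    "TRBV10-3", "TRBV11-2", "TRBV12-3", "TRBV13", "TRBV14", "TRBV15",
    "TRBV18", "TRBV19", "TRBV20-1", "TRBV24-1", "TRBV25-1", "TRBV27",
    "TRBV28", "TRBV30",
)
TRBJ_CATALOG = (
    "TRBJ1-1", "TRBJ1-2", "TRBJ1-3", "TRBJ1-4", "TRBJ1-5", "TRBJ1-6",
    "TRBJ2-1", "TRBJ2-2", "TRBJ2-3", "TRBJ2-4", "TRBJ2-5", "TRBJ2-6",
    "TRBJ2-7",
)
_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for a two-arm synthetic cohort.

    Defaults describe a cohort of 40 positives and 40 negatives sequenced
    at 5e4 templates, drawing on a 10,000-clone public pool with 200
    planted signature clones carried by 60% of positives vs 10% of
    negatives at 5-fold higher frequency.
    """

    n_pos: int = 40
    n_neg: int = 40
    pool_size: int = 10_000
    private_rate: float = 500.0  # expected private clones per sample
    zipf_exponent: float = 1.0  # within-sample clone-abundance power law
    sharing_alpha: float = 0.35  # target sharing-spectrum exponent
    sharing_floor: float = 0.05  # inclusion probability of the rarest pool clone
    n_signature: int = 200
    incidence_pos: float = 0.6
    incidence_neg: float = 0.1
    abundance_fold: float = 5.0
    depth: Optional[int] = 50_000  # templates per sample; None = exact rounding
    positive_label: str = "previvor"
    negative_label: str = "control"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_signature > self.pool_size:
            raise ValueError(
                f"pool_size ({self.pool_size}) smaller than n_signature ({self.n_signature})"
            )
        for name in ("incidence_pos", "incidence_neg", "sharing_floor"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.abundance_fold < 1.0:
            raise ValueError(f"abundance_fold must be >= 1, got {self.abundance_fold}")
        for name in ("n_pos", "n_neg", "pool_size"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _random_cdr3(rng: np.random.Generator, existing: set) -> str:
    while True:
        length = int(rng.integers(6, 19))  # total 8..20 with the C...F frame
        s = "C" + "".join(rng.choice(_AA, size=length)) + "F"
        if s not in existing:
            existing.add(s)
            return s


def _random_keys(rng: np.random.Generator, n: int, existing: set) -> pd.DataFrame:
    cdr3 = [_random_cdr3(rng, existing) for _ in range(n)]
    return pd.DataFrame(
        {
            "cdr3_aa": cdr3,
            "v_call": rng.choice(TRBV_CATALOG, size=n),
            "j_call": rng.choice(TRBJ_CATALOG, size=n),
        }
    )


def _counts_from_weights(
    rng: np.random.Generator, weights: np.ndarray, depth: Optional[int]
) -> np.ndarray:
    probs = weights / weights.sum()
    if depth is None:
        # deterministic regime: every included clone is retained
        counts = np.maximum(1, np.round(probs * 1_000_000).astype(np.int64))
    else:
        counts = rng.multinomial(depth, probs)
    return counts


def generate_cohort(spec: CohortSpec) -> Tuple[List[CohortSample], Dict]:
    """Generate a labelled cohort plus its ground-truth manifest.

    The manifest records the planted signature keys (CDR3|V|J), the pool
    keys and per-sample carriage of the planted clones, so signature
    precision/recall can be computed exactly.  Identical specs (same seed)
    give identical cohorts.
    """
    rng = np.random.default_rng(spec.seed)
    existing: set = set()
    pool = _random_keys(rng, spec.pool_size, existing)
    K = spec.pool_size
    rank = np.arange(1, K + 1)
    weights = rank ** (-spec.zipf_exponent)
    include_p = np.minimum(1.0, spec.sharing_floor * (rank / K) ** (-spec.sharing_alpha))

    # plant signature clones at mid-abundance ranks so they survive
    # multinomial sampling at the configured depth
    lo, hi = max(1, K // 10), max(2, K // 2)
    sig_idx = rng.choice(np.arange(lo, hi), size=spec.n_signature, replace=False)
    sig_mask = np.zeros(K, dtype=bool)
    sig_mask[sig_idx] = True
    sig_keys = (
        pool.loc[sig_mask, "cdr3_aa"]
        + "|" + pool.loc[sig_mask, "v_call"]
        + "|" + pool.loc[sig_mask, "j_call"]
    ).tolist()

    labels = [spec.positive_label] * spec.n_pos + [spec.negative_label] * spec.n_neg
    samples: List[CohortSample] = []
    planted_carriage: Dict[str, int] = {}
    for i, group in enumerate(labels):
        positive = group == spec.positive_label
        inc = rng.random(K) < include_p
        sig_p = spec.incidence_pos if positive else spec.incidence_neg
        inc[sig_mask] = rng.random(spec.n_signature) < sig_p
        w = weights[inc].copy()
        if positive and spec.abundance_fold != 1.0:
            w[sig_mask[inc]] *= spec.abundance_fold
        tab = pool.loc[inc, ["cdr3_aa", "v_call", "j_call"]].copy()

        n_priv = rng.poisson(spec.private_rate)
        if n_priv:
            priv = _random_keys(rng, int(n_priv), existing)
            priv_rank = rng.integers(K // 2, K, size=int(n_priv))
            w = np.concatenate([w, priv_rank ** (-spec.zipf_exponent)])
            tab = pd.concat([tab, priv], ignore_index=True)

        counts = _counts_from_weights(rng, w, spec.depth)
        keep = counts > 0
        tab = tab.loc[keep].copy()
        tab["templates"] = counts[keep]
        sample_id = f"{'P' if positive else 'N'}{i:03d}"
        rep = Repertoire(sample_id, tab)
        samples.append(CohortSample(repertoire=rep, group=group))
        planted_carriage[sample_id] = int((inc & sig_mask).sum())

    manifest = {
        "spec": spec,
        "signature_keys": sorted(sig_keys),
        "signature_keys_cdr3": sorted(pool.loc[sig_mask, "cdr3_aa"]),
        "pool_keys": (pool["cdr3_aa"] + "|" + pool["v_call"] + "|" + pool["j_call"]).tolist(),
        "planted_carriage": planted_carriage,
    }
    return samples, manifest


def generate_matched_pair(
    n_clones: int = 5000,
    overlap_n: int = 18,
    top_n: int = 100,
    tissue_enrichment: float = 10.0,
    zipf_exponent: float = 1.0,
    depth: int = 50_000,
    seed: int = 0,
) -> Tuple[Repertoire, Repertoire, List[str]]:
    """A matched tissue/blood pair with an exact planted overlap.

    Exactly ``overlap_n`` of the tissue's ``top_n`` most expanded clones
    are planted into the blood at ``frequency / tissue_enrichment``; the
    blood's template counts are rounded deterministically (minimum one
    template for planted clones) so the planted overlap is exact.
    Returns (tissue, blood, planted keys).
    """
    if overlap_n > top_n:
        raise ValueError(f"overlap_n ({overlap_n}) cannot exceed top_n ({top_n})")
    if overlap_n > n_clones:
        raise ValueError("overlap_n cannot exceed the tissue clone count")
    rng = np.random.default_rng(seed)
    existing: set = set()
    tissue_tab = _random_keys(rng, n_clones, existing)
    w = np.arange(1, n_clones + 1) ** (-zipf_exponent)
    counts = rng.multinomial(depth, w / w.sum())
    tissue_tab["templates"] = counts
    tissue = Repertoire("tissue", tissue_tab.loc[counts > 0])

    top = top_expanded(tissue, top_n)
    chosen = top.iloc[
        sorted(rng.choice(len(top), size=overlap_n, replace=False))
    ]

    n_bg = n_clones // 2
    blood_tab = _random_keys(rng, n_bg, existing)
    bw = np.arange(1, n_bg + 1) ** (-zipf_exponent)
    blood_freq = bw / bw.sum()
    blood_counts = np.round(blood_freq * depth).astype(np.int64)

    planted_freq = chosen["frequency"].to_numpy() / tissue_enrichment
    planted_counts = np.maximum(1, np.round(planted_freq * depth).astype(np.int64))
    parts = chosen["key"].str.split("|", expand=True)
    planted_tab = pd.DataFrame(
        {"cdr3_aa": parts[0], "v_call": parts[1], "j_call": parts[2], "templates": planted_counts}
    )
    blood_tab["templates"] = blood_counts
    blood = Repertoire(
        "blood",
        pd.concat([blood_tab.loc[blood_counts > 0], planted_tab], ignore_index=True),
    )
    return tissue, blood, chosen["key"].tolist()


def generate_reference_pool(
    cohort: Sequence[CohortSample],
    hit_fraction: float,
    decoy_n: int = 0,
    seed: int = 0,
    key_mode: KeyMode | str = KeyMode.CDR3_V_J,
    min_individuals: int = 2,
    name: str = "synthetic-pool",
) -> ReferencePool:
    """A reference pool covering ``hit_fraction`` of the cohort's public keys.

    ``decoy_n`` novel keys absent from the cohort are added, emulating
    disease-specific TCR lists that only partially intersect a cohort.
    """
    if not (0.0 <= hit_fraction <= 1.0):
        raise ValueError(f"hit_fraction must be in [0, 1], got {hit_fraction}")
    key_mode = KeyMode.coerce(key_mode)
    rng = np.random.default_rng(seed)
    public = build_public_table(cohort, key_mode, min_individuals)
    keys = np.asarray(sorted(public.keys))
    n_hits = int(round(hit_fraction * len(keys)))
    hits = rng.choice(keys, size=n_hits, replace=False).tolist() if n_hits else []
    existing = {k.split("|", 1)[0] for k in keys}
    decoys = _random_keys(rng, decoy_n, existing) if decoy_n else None
    if decoys is not None:
        dk = decoys["cdr3_aa"].copy()
        if key_mode.uses_v:
            dk = dk + "|" + decoys["v_call"]
        if key_mode.uses_j:
            dk = dk + "|" + decoys["j_call"]
        hits.extend(dk.tolist())
    return ReferencePool(name=name, keys=frozenset(hits), key_mode=key_mode)
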