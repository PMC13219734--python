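"""Disease-signature selection and Gaussian naive Bayes classification.

The signature pipeline distinguishes a positive cohort (e.g. Lynch-syndrome
carriers) from a negative one (controls) using bulk TCR-beta repertoires:

1. **Candidate filtering.** A clonotype key enters the signature when it
   (i) is present in at least ``ceil(presence_ratio * n_pos)`` positive
   samples, (ii) is enriched in incidence in positives by a two-sided
   Fisher exact test at ``p < fisher_p``, and (iii) shows increased
   per-sample frequency in positives by a two-sided Wilcoxon rank-sum test
   at ``p < wilcoxon_p`` (absent samples contribute frequency 0).
2. **Scoring.** A sample's score is the arcsine-square-root transformed
   mean frequency of the signature clonotypes in that sample.
3. **Classification.** Class-conditional Gaussians over the score give a
   posterior probability of the positive class; performance is summarized
   by the AUROC.
4. **Model selection.** A leave-one-out cross-validated grid search over
   key mode, presence ratio and the two p-value cutoffs picks the
   hyperparameters; AUROC ties at two decimals prefer shorter key modes,
   then smaller signatures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

from .diversity import rank_sum_p_rows
from .public import cohort_frequency_matrix
from .repertoire import CohortSample, KeyMode, Repertoire

__all__ = [
    "Hyperparameters",
    "default_grid",
    "fisher_exact_2x2",
    "select_signature",
    "sample_score",
    "GaussianScoreModel",
    "SignatureModel",
    "fit_gnb",
    "posterior_positive",
    "ClassifierResult",
    "auroc",
    "train_model",
    "score_cohort",
    "split_cohort",
    "loocv_grid_search",
    "evaluate_holdout",
]

SD_FLOOR = 1e-6  # lower bound on class sds to avoid degenerate densities


@dataclass(frozen=True)
class Hyperparameters:
    """One point of the signature-selection grid."""

    key_mode: KeyMode = KeyMode.CDR3
    presence_ratio: float = 0.10
    fisher_p: float = 1e-4
    wilcoxon_p: float = 1e-4

    def __post_init__(self) -> None:
        object.__setattr__(self, "key_mode", KeyMode.coerce(self.key_mode))
        if not (0.0 < self.presence_ratio <= 1.0):
            raise ValueError(f"presence_ratio must be in (0, 1], got {self.presence_ratio}")
        for name in ("fisher_p", "wilcoxon_p"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {v}")


DEFAULT_PRESENCE_GRID: Tuple[float, ...] = (0.10, 0.50, 0.75)
DEFAULT_P_GRID: Tuple[float, ...] = (1e-1, 1e-2, 1e-4, 1e-10, 1e-15)


def default_grid(
    key_modes: Sequence[KeyMode | str] = tuple(KeyMode),
    presence_ratios: Sequence[float] = DEFAULT_PRESENCE_GRID,
    fisher_ps: Sequence[float] = DEFAULT_P_GRID,
    wilcoxon_ps: Sequence[float] = DEFAULT_P_GRID,
) -> list[Hyperparameters]:
    """The full factorial hyperparameter grid (4 x 3 x 5 x 5 by default)."""
    return [
        Hyperparameters(KeyMode.coerce(km), r, fp, wp)
        for km in key_modes
        for r in presence_ratios
        for fp in fisher_ps
        for wp in wilcoxon_ps
    ]


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Conditional on the margins, sums hypergeometric point probabilities not
    exceeding that of the observed table (with a small relative slack).
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("table entries must be non-negative integers")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def _fisher_p_lookup(n_pos: int, n_neg: int) -> np.ndarray:
    """p[a, c] for incidence tables [[a, n_pos - a], [c, n_neg - c]].

    Vectorized over the hypergeometric support for each column margin
    a + c, matching :func:`fisher_exact_2x2`.
    """
    N = n_pos + n_neg
    out = np.ones((n_pos + 1, n_neg + 1))
    for K in range(N + 1):
        lo, hi = max(0, K - n_neg), min(n_pos, K)
        support = np.arange(lo, hi + 1)
        pmf = stats.hypergeom.pmf(support, N, K, n_pos)
        for a, pa in zip(support, pmf):
            c = K - a
            out[a, c] = pmf[pmf <= pa * (1 + 1e-7)].sum()
    return np.minimum(out, 1.0)


@dataclass
class _CandidateStats:
    """Per-key screening statistics on one training split."""

    keys: pd.Index
    n_pos: int
    n_neg: int
    pos_carriers: np.ndarray
    neg_carriers: np.ndarray
    fisher_p: np.ndarray
    wilcoxon_p: np.ndarray
    freq_pos_higher: np.ndarray


def _candidate_stats(F: pd.DataFrame, pos_mask: np.ndarray) -> _CandidateStats:
    pos_mask = np.asarray(pos_mask, dtype=bool)
    n_pos, n_neg = int(pos_mask.sum()), int((~pos_mask).sum())
    X = F.to_numpy()
    pres = X > 0
    a = pres[:, pos_mask].sum(axis=1)
    c = pres[:, ~pos_mask].sum(axis=1)
    fisher = _fisher_p_lookup(n_pos, n_neg)[a, c]
    wilc, pos_higher = rank_sum_p_rows(X, pos_mask)
    return _CandidateStats(
        keys=F.index,
        n_pos=n_pos,
        n_neg=n_neg,
        pos_carriers=a,
        neg_carriers=c,
        fisher_p=fisher,
        wilcoxon_p=wilc,
        freq_pos_higher=pos_higher,
    )


def _signature_mask(cs: _CandidateStats, hp: Hyperparameters) -> np.ndarray:
    min_carriers = math.ceil(hp.presence_ratio * cs.n_pos)
    inc_pos_higher = cs.pos_carriers / cs.n_pos > cs.neg_carriers / cs.n_neg
    return (
        (cs.pos_carriers >= min_carriers)
        & (cs.fisher_p < hp.fisher_p)
        & inc_pos_higher
        & (cs.wilcoxon_p < hp.wilcoxon_p)
        & cs.freq_pos_higher
    )


def _labels(cohort: Sequence[CohortSample], positive_label: str | Sequence[str]) -> np.ndarray:
    pos = {positive_label} if isinstance(positive_label, str) else set(positive_label)
    return np.array([s.group in pos for s in cohort], dtype=bool)


def select_signature(
    training: Sequence[CohortSample],
    positive_label: str | Sequence[str],
    hp: Hyperparameters,
) -> frozenset:
    """Clonotype keys passing the presence, Fisher and Wilcoxon filters.

    All three filters require enrichment in the positive class; an empty
    result is a valid outcome, not an error.
    """
    labels = _labels(training, positive_label)
    if labels.sum() < 2 or (~labels).sum() < 2:
        raise ValueError("need at least 2 samples per class to select a signature")
    F = cohort_frequency_matrix(training, hp.key_mode)
    cs = _candidate_stats(F, labels)
    return frozenset(F.index[_signature_mask(cs, hp)])


def sample_score(
    r: Repertoire, signature: Sequence[str], key_mode: KeyMode | str
) -> float:
    """Arcsine-sqrt transformed mean signature-clonotype frequency in a sample."""
    signature = list(signature)
    if not signature:
        raise ValueError("signature must be non-empty")
    freq = r.key_frequencies(key_mode)
    m = float(freq.reindex(signature).fillna(0.0).sum()) / len(signature)
    return float(np.arcsin(np.sqrt(np.clip(m, 0.0, 1.0))))


def _scores_from_matrix(F: pd.DataFrame, sig_mask: np.ndarray) -> np.ndarray:
    m = F.to_numpy()[sig_mask].sum(axis=0) / sig_mask.sum()
    return np.arcsin(np.sqrt(np.clip(m, 0.0, 1.0)))


@dataclass(frozen=True)
class GaussianScoreModel:
    """Class-conditional Gaussians over the signature score."""

    mu_pos: float
    sigma_pos: float
    mu_neg: float
    sigma_neg: float
    prior_pos: float


def fit_gnb(
    scores_pos: Sequence[float], scores_neg: Sequence[float], prior_pos: float = 0.5
) -> GaussianScoreModel:
    """Estimate per-class Normal(mean, sd) from training scores.

    Sample standard deviations are floored at ``SD_FLOOR`` so a class with
    constant scores still yields a proper density.
    """
    sp = np.asarray(scores_pos, dtype=float)
    sn = np.asarray(scores_neg, dtype=float)
    if sp.size < 2 or sn.size < 2:
        raise ValueError("need at least 2 scores per class to fit the Gaussians")
    if not (0.0 < prior_pos < 1.0):
        raise ValueError(f"prior_pos must be in (0, 1), got {prior_pos}")
    return GaussianScoreModel(
        mu_pos=float(sp.mean()),
        sigma_pos=max(float(sp.std(ddof=1)), SD_FLOOR),
        mu_neg=float(sn.mean()),
        sigma_neg=max(float(sn.std(ddof=1)), SD_FLOOR),
        prior_pos=float(prior_pos),
    )


def posterior_positive(model: GaussianScoreModel, scores: Sequence[float]) -> np.ndarray:
    """P(positive | score) under the two-Gaussian model (log-space, stable)."""
    s = np.asarray(scores, dtype=float)
    lp = stats.norm.logpdf(s, model.mu_pos, model.sigma_pos) + np.log(model.prior_pos)
    ln = stats.norm.logpdf(s, model.mu_neg, model.sigma_neg) + np.log1p(-model.prior_pos)
    m = np.maximum(lp, ln)
    return np.exp(lp - m) / (np.exp(lp - m) + np.exp(ln - m))


@dataclass
class SignatureModel:
    """A fitted signature classifier: selected keys plus score Gaussians."""

    hyperparameters: Hyperparameters
    signature_keys: frozenset
    gaussians: GaussianScoreModel

    def score(self, r: Repertoire) -> float:
        return sample_score(r, sorted(self.signature_keys), self.hyperparameters.key_mode)

    def posterior(self, r: Repertoire) -> float:
        return float(posterior_positive(self.gaussians, [self.score(r)])[0])


@dataclass
class ClassifierResult:
    auroc: float
    roc_points: pd.DataFrame  # threshold, fpr, tpr
    scores: pd.DataFrame  # sample_id, label, score, posterior


def auroc(scores: Sequence[float], labels: Sequence[bool]) -> ClassifierResult:
    """Rank-based AUROC (ties get half credit) with the ROC curve.

    Equals the probability that a random positive sample outscores a
    random negative one.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC requires both classes to be represented")
    ranks = stats.rankdata(s)
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    area = float(u / (n_pos * n_neg))
    fpr, tpr, thr = roc_curve(y.astype(int), s)
    roc = pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr})
    tbl = pd.DataFrame({"label": y, "score": s})
    return ClassifierResult(auroc=area, roc_points=roc, scores=tbl)


def train_model(
    training: Sequence[CohortSample],
    positive_label: str | Sequence[str],
    hp: Hyperparameters,
    prior_pos: Optional[float] = None,
) -> SignatureModel:
    """Select the signature and fit the score Gaussians on training data only."""
    labels = _labels(training, positive_label)
    signature = select_signature(training, positive_label, hp)
    if not signature:
        raise ValueError("selected signature is empty; the classifier is undefined")
    sig = sorted(signature)
    scores = np.array(
        [sample_score(s.repertoire, sig, hp.key_mode) for s in training]
    )
    if prior_pos is None:
        prior_pos = float(labels.mean())
    gauss = fit_gnb(scores[labels], scores[~labels], prior_pos)
    return SignatureModel(hyperparameters=hp, signature_keys=signature, gaussians=gauss)


def score_cohort(
    model: SignatureModel,
    cohort: Sequence[CohortSample],
    positive_label: str | Sequence[str],
) -> ClassifierResult:
    """Score and classify a cohort with a fitted model; returns the AUROC."""
    labels = _labels(cohort, positive_label)
    sig = sorted(model.signature_keys)
    s = np.array(
        [sample_score(x.repertoire, sig, model.hyperparameters.key_mode) for x in cohort]
    )
    res = auroc(s, labels)
    res.scores = pd.DataFrame(
        {
            "sample_id": [x.sample_id for x in cohort],
            "label": labels,
            "score": s,
            "posterior": posterior_positive(model.gaussians, s),
        }
    )
    return res


def split_cohort(
    cohort: Sequence[CohortSample],
    validation_fraction: float = 0.2,
    seed: int = 1234,
    stratify: bool = True,
) -> tuple[list[CohortSample], list[CohortSample]]:
    """Seeded random split into training and held-out validation sets.

    Stratified by group label by default so both arms appear in both sets.
    """
    if not (0.0 < validation_fraction < 1.0):
        raise ValueError("validation_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    cohort = list(cohort)
    val_idx: set[int] = set()
    if stratify:
        groups: Dict[str, list[int]] = {}
        for i, s in enumerate(cohort):
            groups.setdefault(s.group, []).append(i)
        for idxs in groups.values():
            k = int(round(validation_fraction * len(idxs)))
            val_idx.update(rng.choice(idxs, size=k, replace=False).tolist())
    else:
        k = int(round(validation_fraction * len(cohort)))
        val_idx.update(rng.choice(len(cohort), size=k, replace=False).tolist())
    training = [s for i, s in enumerate(cohort) if i not in val_idx]
    validation = [s for i, s in enumerate(cohort) if i in val_idx]
    return training, validation


def _mode_order(mode: KeyMode) -> tuple[int, str]:
    return (mode.n_fields, mode.value)


def loocv_grid_search(
    training: Sequence[CohortSample],
    grid: Sequence[Hyperparameters],
    positive_label: str | Sequence[str],
    reselect_per_fold: bool = True,
    prior_pos: Optional[float] = None,
) -> tuple[Hyperparameters, pd.DataFrame]:
    """Leave-one-out cross-validated grid search over hyperparameters.

    Each sample is held out once and scored by a model built from the
    remaining samples; the signature is reselected within each fold by
    default (leakage-free), or selected once on the full training set when
    ``reselect_per_fold`` is False.  A fold whose signature comes out
    empty contributes a held-out posterior of 0.  The best combination
    maximizes the LOOCV AUROC; ties at two decimal places are broken by
    shorter key mode, then smaller full-training signature size.

    Returns the winning hyperparameters and a per-combination table with
    columns ``key_mode, presence_ratio, fisher_p, wilcoxon_p,
    loocv_auroc, signature_size``.
    """
    training = list(training)
    labels = _labels(training, positive_label)
    n = len(training)
    if labels.sum() < 3 or (~labels).sum() < 3:
        raise ValueError("LOOCV grid search needs at least 3 samples per class")
    if prior_pos is None:
        prior_pos = float(labels.mean())

    by_mode: Dict[KeyMode, list[Hyperparameters]] = {}
    for hp in grid:
        by_mode.setdefault(hp.key_mode, []).append(hp)

    held_out: Dict[Hyperparameters, np.ndarray] = {hp: np.zeros(n) for hp in grid}
    sig_size_full: Dict[Hyperparameters, int] = {}

    for mode, hps in by_mode.items():
        F = cohort_frequency_matrix(training, mode)
        X = F.to_numpy()
        full_stats = _candidate_stats(F, labels)
        for hp in hps:
            sig_size_full[hp] = int(_signature_mask(full_stats, hp).sum())
        for i in range(n):
            keep = np.ones(n, dtype=bool)
            keep[i] = False
            if reselect_per_fold:
                fold_stats = _candidate_stats(F.iloc[:, keep], labels[keep])
            else:
                fold_stats = full_stats
            score_cache: Dict[bytes, np.ndarray] = {}
            for hp in hps:
                mask = _signature_mask(fold_stats, hp)
                if not mask.any():
                    held_out[hp][i] = 0.0
                    continue
                key = mask.tobytes()
                scores = score_cache.get(key)
                if scores is None:
                    scores = np.arcsin(
                        np.sqrt(np.clip(X[mask].sum(axis=0) / mask.sum(), 0.0, 1.0))
                    )
                    score_cache[key] = scores
                tr = scores[keep]
                gauss = fit_gnb(tr[labels[keep]], tr[~labels[keep]], prior_pos)
                held_out[hp][i] = float(posterior_positive(gauss, [scores[i]])[0])

    rows = []
    for hp in grid:
        area = auroc(held_out[hp], labels).auroc
        rows.append(
            {
                "key_mode": hp.key_mode.value,
                "presence_ratio": hp.presence_ratio,
                "fisher_p": hp.fisher_p,
                "wilcoxon_p": hp.wilcoxon_p,
                "loocv_auroc": area,
                "signature_size": sig_size_full[hp],
            }
        )
    table = pd.DataFrame(rows)

    def sort_key(idx: int) -> tuple:
        hp = grid[idx]
        a = rows[idx]["loocv_auroc"]
        return (
            -round(a, 2),
            _mode_order(hp.key_mode),
            sig_size_full[hp],
            -a,
            hp.presence_ratio,
            hp.fisher_p,
            hp.wilcoxon_p,
        )

    best = grid[min(range(len(grid)), key=sort_key)]
    return best, table


def evaluate_holdout(
    training: Sequence[CohortSample],
    validation: Sequence[CohortSample],
    hp: Hyperparameters,
    positive_label: str | Sequence[str],
    prior_pos: Optional[float] = None,
) -> tuple[ClassifierResult, SignatureModel]:
    """Train on ``training`` only, then score the held-out validation set.

    No validation sample influences signature selection or the Gaussian
    fits, so perturbing validation-only data cannot change the model.
    """
    model = train_model(training, positive_label, hp, prior_pos=prior_pos)
    return score_cohort(model, validation, positive_label), model
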