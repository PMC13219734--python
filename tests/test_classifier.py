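"""Signature selection, scoring, Gaussian naive Bayes and LOOCV grid search."""

import math

import numpy as np
import pytest
from scipy import stats

from repsig.classify import (
    GaussianScoreModel,
    Hyperparameters,
    auroc,
    default_grid,
    evaluate_holdout,
    fisher_exact_2x2,
    fit_gnb,
    loocv_grid_search,
    posterior_positive,
    sample_score,
    select_signature,
    split_cohort,
    train_model,
)
from repsig.repertoire import KeyMode, Repertoire
from repsig.synth import CohortSpec, generate_cohort

from conftest import make_sample


def fisher_oracle(a, b, c, d):
    """Exhaustive two-sided Fisher p by enumerating the hypergeometric support."""
    r1, r2, k = a + b, c + d, a + c
    n = r1 + r2
    denom = math.comb(n, k)
    obs = math.comb(r1, a) * math.comb(r2, c)
    total = 0
    for x in range(max(0, k - r2), min(r1, k) + 1):
        w = math.comb(r1, x) * math.comb(r2, k - x)
        if w <= obs * (1 + 1e-7):
            total += w
    return total / denom


class TestFisherExact:
    def test_mode_table_gives_one(self):
        assert fisher_exact_2x2(5, 5, 5, 5) == 1.0

    def test_diagonal_two_by_two(self):
        # margins (2,2)/(2,2): P(a=2)=P(a=0)=1/6, P(a=1)=2/3 -> p = 1/3
        assert fisher_exact_2x2(2, 0, 0, 2) == pytest.approx(1 / 3, abs=1e-12)

    def test_negative_entry_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(-1, 2, 3, 4)

    def test_matches_enumeration_oracle_on_random_tables(self):
        rng = np.random.default_rng(20)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 7, size=4)
            assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
                fisher_oracle(a, b, c, d), abs=1e-10
            )


def _two_group_cohort(n_pos=4, n_neg=4, enriched=("CAAAAF",), background=("CCCCCF", "CDDDDF")):
    """Tiny cohort where `enriched` keys appear only in positives."""
    cohort = []
    for i in range(n_pos):
        counts = {k: 50 for k in enriched}
        counts.update({k: 10 for k in background})
        cohort.append(make_sample(f"p{i}", "positive", counts))
    for i in range(n_neg):
        cohort.append(make_sample(f"n{i}", "negative", {k: 10 for k in background}))
    return cohort


class TestSelectSignature:
    def test_perfectly_separating_clone_selected(self):
        cohort = _two_group_cohort(n_pos=20, n_neg=20)
        hp = Hyperparameters(KeyMode.CDR3, 0.5, 1e-4, 1e-4)
        assert select_signature(cohort, "positive", hp) == {"CAAAAF"}

    def test_identical_clone_excluded(self):
        cohort = _two_group_cohort(n_pos=10, n_neg=10)
        hp = Hyperparameters(KeyMode.CDR3, 0.1, 0.99, 0.99)
        sig = select_signature(cohort, "positive", hp)
        assert "CCCCCF" not in sig and "CDDDDF" not in sig

    def test_planted_clones_recovered_with_high_precision_recall(self):
        cohort, manifest = generate_cohort(CohortSpec(
            n_pos=25, n_neg=25, pool_size=3000, n_signature=60, private_rate=100,
            incidence_pos=0.7, incidence_neg=0.05, abundance_fold=5, depth=30_000, seed=21))
        hp = Hyperparameters(KeyMode.CDR3, 0.10, 1e-4, 1e-4)
        sig = select_signature(cohort, "previvor", hp)
        truth = set(manifest["signature_keys_cdr3"])
        precision = len(sig & truth) / len(sig)
        recall = len(sig & truth) / len(truth)
        assert precision >= 0.8 and recall >= 0.8

    def test_relaxing_any_cutoff_never_shrinks_signature(self):
        cohort, _ = generate_cohort(CohortSpec(
            n_pos=15, n_neg=15, pool_size=2000, n_signature=50, private_rate=50,
            depth=20_000, seed=22))
        base = Hyperparameters(KeyMode.CDR3, 0.5, 1e-2, 1e-2)
        sig0 = select_signature(cohort, "previvor", base)
        for relaxed in (
            Hyperparameters(KeyMode.CDR3, 0.1, 1e-2, 1e-2),
            Hyperparameters(KeyMode.CDR3, 0.5, 1e-1, 1e-2),
            Hyperparameters(KeyMode.CDR3, 0.5, 1e-2, 1e-1),
        ):
            assert select_signature(cohort, "previvor", relaxed) >= sig0


class TestSampleScore:
    def test_no_signature_clone_present_scores_zero(self, toy_repertoire):
        assert sample_score(toy_repertoire, ["CWWWWF"], KeyMode.CDR3) == 0.0

    def test_single_present_clone_mean_halved(self):
        r = Repertoire.from_counts("s", ["CAAAAF", "CCCCCF"], ["TRBV1"] * 2, ["TRBJ1"] * 2, [1, 99])
        score = sample_score(r, ["CAAAAF", "CWWWWF"], KeyMode.CDR3)
        assert score == pytest.approx(np.arcsin(np.sqrt(0.005)), abs=1e-9)
        assert score == pytest.approx(0.07077, abs=1e-5)

    def test_upper_bound_pi_over_two(self):
        r = Repertoire.from_counts("s", ["CAAAAF"], ["TRBV1"], ["TRBJ1"], [5])
        assert sample_score(r, ["CAAAAF"], KeyMode.CDR3) == pytest.approx(np.pi / 2)

    def test_empty_signature_rejected(self, toy_repertoire):
        with pytest.raises(ValueError):
            sample_score(toy_repertoire, [], KeyMode.CDR3)


class TestGaussianNaiveBayes:
    def test_midpoint_posterior_half(self):
        m = GaussianScoreModel(mu_pos=1.0, sigma_pos=0.2, mu_neg=0.0, sigma_neg=0.2, prior_pos=0.5)
        assert posterior_positive(m, [0.5])[0] == pytest.approx(0.5)

    def test_extreme_score_limits(self):
        m = GaussianScoreModel(mu_pos=1.0, sigma_pos=0.2, mu_neg=0.0, sigma_neg=0.2, prior_pos=0.5)
        assert posterior_positive(m, [100.0])[0] == pytest.approx(1.0)
        assert posterior_positive(m, [-100.0])[0] == pytest.approx(0.0)

    def test_parameter_recovery_from_large_sample(self):
        rng = np.random.default_rng(30)
        pos = rng.normal(0.8, 0.1, 10_000)
        neg = rng.normal(0.3, 0.05, 10_000)
        m = fit_gnb(pos, neg, prior_pos=0.4)
        assert m.mu_pos == pytest.approx(0.8, rel=0.02)
        assert m.sigma_pos == pytest.approx(0.1, rel=0.02)
        assert m.mu_neg == pytest.approx(0.3, rel=0.02)
        assert m.sigma_neg == pytest.approx(0.05, rel=0.02)

    def test_constant_class_scores_get_floored_sd(self):
        m = fit_gnb([0.5, 0.5, 0.5], [0.1, 0.2, 0.3])
        assert m.sigma_pos > 0

    def test_too_few_scores_rejected(self):
        with pytest.raises(ValueError):
            fit_gnb([0.5], [0.1, 0.2])


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([0.9, 0.8, 0.1, 0.2], [True, True, False, False]).auroc == 1.0

    def test_all_ties_give_half(self):
        assert auroc([0.5] * 6, [True, False] * 3).auroc == 0.5

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(100):
            n = int(rng.integers(4, 30))
            scores = np.round(rng.random(n), 1)  # coarse grid forces ties
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            pos, neg = scores[labels], scores[~labels]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert auroc(scores, labels).auroc == pytest.approx(
                wins / (len(pos) * len(neg)), abs=1e-12
            )

    def test_invariant_under_monotone_transform_and_prior(self):
        rng = np.random.default_rng(32)
        scores = rng.random(40)
        labels = rng.random(40) < 0.4
        base = auroc(scores, labels).auroc
        assert auroc(np.exp(3 * scores), labels).auroc == pytest.approx(base)
        # posterior is a monotone transform of the score for equal sds, so
        # AUROC is independent of the prior
        for prior in (0.1, 0.5, 0.9):
            m = GaussianScoreModel(0.7, 0.1, 0.4, 0.1, prior)
            assert auroc(posterior_positive(m, scores), labels).auroc == pytest.approx(base)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([0.1, 0.2], [True, True])


class TestLoocvGridSearch:
    def test_separable_cohort_reaches_auroc_one(self):
        cohort = _two_group_cohort(n_pos=6, n_neg=6)
        hp = Hyperparameters(KeyMode.CDR3, 0.5, 0.05, 0.05)
        best, table = loocv_grid_search(cohort, [hp], "positive")
        assert best == hp
        assert table["loocv_auroc"].iloc[0] == 1.0

    def test_tie_prefers_shorter_key_mode(self):
        cohort = _two_group_cohort(n_pos=6, n_neg=6)
        grid = [
            Hyperparameters(KeyMode.CDR3_V_J, 0.5, 0.05, 0.05),
            Hyperparameters(KeyMode.CDR3, 0.5, 0.05, 0.05),
        ]
        best, table = loocv_grid_search(cohort, grid, "positive")
        assert table["loocv_auroc"].round(2).nunique() == 1
        assert best.key_mode == KeyMode.CDR3

    def test_label_permuted_cohort_is_uninformative(self):
        """Permuting labels destroys the signal: mean LOOCV AUROC near chance.

        A single-permutation LOOCV AUROC at n=24 has a null standard
        deviation around 0.15, so the chance band is asserted on the mean
        over several permutations.
        """
        cohort, _ = generate_cohort(CohortSpec(
            n_pos=12, n_neg=12, pool_size=2000, n_signature=50, private_rate=50,
            depth=20_000, seed=33))
        rng = np.random.default_rng(33)
        groups = [s.group for s in cohort]
        hp = Hyperparameters(KeyMode.CDR3, 0.1, 0.1, 0.1)
        values = []
        for _ in range(6):
            perm = rng.permutation(len(groups))
            shuffled = [
                type(s)(repertoire=s.repertoire, group=groups[perm[i]])
                for i, s in enumerate(cohort)
            ]
            _, table = loocv_grid_search(shuffled, [hp], "previvor")
            values.append(table["loocv_auroc"].iloc[0])
        assert 0.35 <= np.mean(values) <= 0.65

    def test_reselect_per_fold_false_selects_once(self):
        cohort = _two_group_cohort(n_pos=5, n_neg=5)
        hp = Hyperparameters(KeyMode.CDR3, 0.5, 0.05, 0.05)
        best, table = loocv_grid_search(cohort, [hp], "positive", reselect_per_fold=False)
        assert table["loocv_auroc"].iloc[0] == 1.0


class TestHoldoutEvaluation:
    def test_training_and_identical_validation_agree(self):
        cohort = _two_group_cohort(n_pos=8, n_neg=8)
        hp = Hyperparameters(KeyMode.CDR3, 0.5, 0.05, 0.05)
        res, _ = evaluate_holdout(cohort, cohort, hp, "positive")
        assert res.auroc == 1.0

    def test_end_to_end_separated_cohort(self):
        cohort, _ = generate_cohort(CohortSpec(
            n_pos=25, n_neg=25, pool_size=3000, n_signature=60, private_rate=100,
            incidence_pos=0.7, incidence_neg=0.05, abundance_fold=5, depth=30_000, seed=34))
        training, validation = split_cohort(cohort, 0.2, seed=34)
        hp = Hyperparameters(KeyMode.CDR3, 0.10, 1e-4, 1e-4)
        res, model = evaluate_holdout(training, validation, hp, "previvor")
        assert res.auroc >= 0.9
        assert len(model.signature_keys) > 0

    def test_validation_data_cannot_leak_into_model(self):
        cohort, _ = generate_cohort(CohortSpec(
            n_pos=15, n_neg=15, pool_size=2000, n_signature=50, private_rate=50,
            depth=20_000, seed=35))
        training, validation = split_cohort(cohort, 0.2, seed=35)
        hp = Hyperparameters(KeyMode.CDR3, 0.1, 1e-2, 1e-2)
        _, model_a = evaluate_holdout(training, validation, hp, "previvor")
        # permute validation-set repertoires among samples and relabel them
        permuted = [
            type(v)(repertoire=validation[(i + 1) % len(validation)].repertoire,
                    group="control" if v.group == "previvor" else "previvor")
            for i, v in enumerate(validation)
        ]
        _, model_b = evaluate_holdout(training, permuted, hp, "previvor")
        assert model_a.signature_keys == model_b.signature_keys
        assert model_a.gaussians == model_b.gaussians  # bit-identical floats

    def test_empty_signature_is_undefined_model(self):
        cohort = _two_group_cohort(n_pos=4, n_neg=4)
        hp = Hyperparameters(KeyMode.CDR3, 1.0, 1e-15, 1e-15)
        with pytest.raises(ValueError, match="empty"):
            evaluate_holdout(cohort[:6], cohort[6:], hp, "positive")


class TestSplitCohort:
    def test_stratified_split_sizes(self):
        cohort, _ = generate_cohort(CohortSpec(
            n_pos=10, n_neg=10, pool_size=500, n_signature=0, private_rate=10,
            depth=5000, seed=36))
        tr, va = split_cohort(cohort, 0.2, seed=1234)
        assert len(va) == 4 and len(tr) == 16
        assert sum(s.group == "previvor" for s in va) == 2

    def test_same_seed_same_split(self):
        cohort = _two_group_cohort(n_pos=10, n_neg=10)
        a = split_cohort(cohort, 0.3, seed=7)
        b = split_cohort(cohort, 0.3, seed=7)
        assert [s.sample_id for s in a[1]] == [s.sample_id for s in b[1]]
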