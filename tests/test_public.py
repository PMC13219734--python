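"""Public clonotype tables, sharing spectra, power-law fits and similarity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from repsig.public import (
    build_public_table,
    compare_power_law_fits,
    fit_power_law,
    jaccard_index,
    morisita_horn,
    sharing_spectrum,
)
from repsig.repertoire import KeyMode, Repertoire

from conftest import make_sample


def _spectrum(x, y):
    return pd.DataFrame({"rank_percentile": x, "sharing_pct": y})


class TestBuildPublicTable:
    def _cohort(self):
        return [
            make_sample("s1", "control", {"CASSAF": 5, "CASSGF": 3}),
            make_sample("s2", "control", {"CASSAF": 2, "CASSCF": 1}),
            make_sample("s3", "control", {"CASSDF": 4}),
        ]

    def test_public_requires_two_carriers(self):
        table = build_public_table(self._cohort(), KeyMode.CDR3)
        assert list(table.keys) == ["CASSAF"]
        assert table.sharing_fraction.loc["CASSAF"] == pytest.approx(2 / 3)

    def test_min_individuals_one_gives_union(self):
        table = build_public_table(self._cohort(), KeyMode.CDR3, min_individuals=1)
        assert len(table.keys) == 4  # union of all distinct keys

    def test_invalid_min_individuals(self):
        with pytest.raises(ValueError):
            build_public_table(self._cohort(), KeyMode.CDR3, min_individuals=0)

    def test_frequency_positive_exactly_where_incident(self):
        table = build_public_table(self._cohort(), KeyMode.CDR3, min_individuals=1)
        assert ((table.frequency.to_numpy() > 0) == table.incidence.to_numpy()).all()

    def test_sample_order_invariance(self):
        cohort = self._cohort()
        t1 = build_public_table(cohort, KeyMode.CDR3)
        t2 = build_public_table(cohort[::-1], KeyMode.CDR3)
        assert list(t1.keys) == list(t2.keys)
        pd.testing.assert_series_equal(t1.sharing_fraction, t2.sharing_fraction)


class TestSharingSpectrum:
    def test_rank_percentiles_and_percentages(self):
        cohort = [
            make_sample(f"s{i}", "control", counts)
            for i, counts in enumerate([
                {"CAAAAF": 1, "CCCCCF": 1}, {"CAAAAF": 1, "CDDDDF": 1},
                {"CCCCCF": 1, "CDDDDF": 1}, {"CEEEEF": 1, "CFFFFF": 1},
            ])
        ]
        # CAAAAF, CCCCCF, CDDDDF each shared by 2 of 4 samples
        spec = sharing_spectrum(build_public_table(cohort, KeyMode.CDR3))
        assert spec["rank_percentile"].tolist() == pytest.approx([1 / 3, 2 / 3, 1.0])
        assert spec["sharing_pct"].tolist() == pytest.approx([50, 50, 50])
        assert spec["key"].tolist() == sorted(spec["key"])  # ties broken lexicographically

    def test_single_key_gets_percentile_one(self):
        cohort = [make_sample("a", "control", {"CASSAF": 1}),
                  make_sample("b", "control", {"CASSAF": 1})]
        spec = sharing_spectrum(build_public_table(cohort, KeyMode.CDR3))
        assert spec["rank_percentile"].tolist() == [1.0]
        assert spec["sharing_pct"].tolist() == [100.0]

    def test_spectrum_monotone_nonincreasing(self):
        from repsig.synth import CohortSpec, generate_cohort

        cohort, _ = generate_cohort(CohortSpec(
            n_pos=10, n_neg=10, pool_size=2000, n_signature=0,
            private_rate=50, depth=20_000, seed=2))
        spec = sharing_spectrum(build_public_table(cohort, KeyMode.CDR3_V_J))
        y = spec["sharing_pct"].to_numpy()
        assert (np.diff(y) <= 1e-12).all()


class TestPowerLawFit:
    def test_noiseless_recovery(self):
        x = np.linspace(0.01, 1, 200)
        fit = fit_power_law(_spectrum(x, 10 * x ** (-0.4)))
        assert fit.alpha == pytest.approx(0.4, abs=1e-9)
        assert fit.k == pytest.approx(10.0, abs=1e-9)
        assert fit.rss <= 1e-18

    def test_constant_spectrum_gives_alpha_zero(self):
        x = np.linspace(0.1, 1, 10)
        fit = fit_power_law(_spectrum(x, np.full(10, 25.0)))
        assert fit.alpha == pytest.approx(0.0, abs=1e-12)

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError, match=">= 3 points"):
            fit_power_law(_spectrum([0.5, 1.0], [2.0, 1.0]))

    def test_alpha_invariant_to_y_rescaling(self):
        rng = np.random.default_rng(0)
        x = np.linspace(0.01, 1, 100)
        y = 5 * x ** (-0.3) * 10 ** rng.normal(0, 0.02, 100)
        f1, f2 = fit_power_law(_spectrum(x, y)), fit_power_law(_spectrum(x, 7 * y))
        assert f1.alpha == pytest.approx(f2.alpha, abs=1e-12)
        assert f2.k == pytest.approx(7 * f1.k, rel=1e-9)


class TestSlopeComparison:
    def test_identical_spectra_give_f_zero(self):
        rng = np.random.default_rng(1)
        x = np.linspace(0.01, 1, 50)
        y = 10 * x ** (-0.35) * 10 ** rng.normal(0, 0.05, 50)
        res = compare_power_law_fits(_spectrum(x, y), _spectrum(x, y))
        assert res.f_statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0, abs=1e-9)

    def test_null_type_one_error(self):
        rng = np.random.default_rng(2024)
        x = np.linspace(0.01, 1, 100)
        rejections = 0
        for _ in range(500):
            ya = 10 * x ** (-0.35) * 10 ** rng.normal(0, 0.05, 100)
            yb = 10 * x ** (-0.35) * 10 ** rng.normal(0, 0.05, 100)
            rejections += compare_power_law_fits(_spectrum(x, ya), _spectrum(x, yb)).p_value < 0.05
        assert 0.03 <= rejections / 500 <= 0.07

    def test_distinct_exponents_detected(self):
        rng = np.random.default_rng(3)
        x = np.linspace(1e-4, 1, 10_000)
        ya = 10 * x ** (-0.30) * 10 ** rng.normal(0, 0.05, x.size)
        yb = 10 * x ** (-0.45) * 10 ** rng.normal(0, 0.05, x.size)
        assert compare_power_law_fits(_spectrum(x, ya), _spectrum(x, yb)).p_value < 1e-3

    def test_degenerate_design_raises(self):
        x = np.full(5, 0.5)
        with pytest.raises(ValueError, match="degenerate"):
            compare_power_law_fits(_spectrum(x, x), _spectrum(x, x))


class TestJaccard:
    def test_signature_overlap_worked_example(self, aa_word):
        b = {f"C{aa_word(i)}F" for i in range(13_340)}
        a = set(list(b)[:7]) | {f"C{aa_word(i + 20_000)}W" for i in range(567)}
        assert len(a) == 574 and len(a & b) == 7
        assert jaccard_index(a, b) == pytest.approx(0.0005, abs=5e-5)

    def test_identical_and_disjoint(self):
        assert jaccard_index({"a", "b"}, {"a", "b"}) == 1.0
        assert jaccard_index({"a"}, {"b"}) == 0.0
        assert jaccard_index(set(), set()) == 0.0

    @settings(derandomize=True, max_examples=50)
    @given(st.sets(st.integers(0, 30)), st.sets(st.integers(0, 30)))
    def test_symmetric_and_bounded(self, a, b):
        j = jaccard_index(a, b)
        assert j == jaccard_index(b, a)
        assert 0.0 <= j <= 1.0
        if a and a == b:
            assert j == 1.0


class TestMorisitaHorn:
    def test_identical_repertoires(self, toy_repertoire):
        assert morisita_horn(toy_repertoire, toy_repertoire) == pytest.approx(1.0)

    def test_disjoint_repertoires(self):
        r1 = Repertoire.from_counts("a", ["CASSAF"], ["TRBV1"], ["TRBJ1"], [3])
        r2 = Repertoire.from_counts("b", ["CASSGF"], ["TRBV1"], ["TRBJ1"], [3])
        assert morisita_horn(r1, r2) == 0.0

    def test_hand_evaluation(self):
        r1 = Repertoire.from_counts("a", ["CAAAAF", "CCCCCF"], ["TRBV1"] * 2, ["TRBJ1"] * 2, [1, 1])
        r2 = Repertoire.from_counts("b", ["CAAAAF", "CDDDDF"], ["TRBV1"] * 2, ["TRBJ1"] * 2, [1, 1])
        # p=(.5,.5,0), q=(.5,0,.5): 2*0.25 / (0.5+0.5) = 0.5
        assert morisita_horn(r1, r2) == pytest.approx(0.5)

    def test_symmetry(self, toy_repertoire, uniform_repertoire):
        other = uniform_repertoire(7)
        assert morisita_horn(toy_repertoire, other) == pytest.approx(
            morisita_horn(other, toy_repertoire)
        )
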