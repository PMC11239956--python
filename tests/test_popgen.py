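import numpy as np
import pytest

from helpers import amova_oracle, hwe_enumeration_oracle, weir_cockerham_fst
from conftest import random_genotype_matrix

from skyisland import GenotypeMatrix, popgen, synthdata


def make_matrix(G, pops, groups=None):
    G = np.asarray(G, dtype=float)
    return GenotypeMatrix(
        genotypes=G,
        individual_ids=[f"i{k}" for k in range(G.shape[0])],
        population=list(pops),
        group=list(groups) if groups is not None else None,
    )


# ----------------------------------------------------------------------
# Per-locus statistics
# ----------------------------------------------------------------------

class TestLocusStatistics:
    def test_unbiased_he_hand_example(self):
        """Genotypes {0,0,2,2}: p=0.5, Ho=0, He=2*0.25*(8/7), Fis=1."""
        g = make_matrix([[0], [0], [2], [2]], ["A"] * 4)
        row = popgen.locus_statistics(g).iloc[0]
        assert row.p_hat == 0.5
        assert row.ho == 0.0
        assert row.he == pytest.approx(2 * 0.25 * 8 / 7)
        assert row.pi == row.he
        assert row.fis == pytest.approx(1.0)

    def test_all_heterozygous_gives_negative_fis(self):
        g = make_matrix([[1], [1], [1], [1]], ["A"] * 4)
        row = popgen.locus_statistics(g).iloc[0]
        assert row.ho == 1.0
        assert row.fis < 0

    def test_monomorphic_locus_flagged_not_raised(self):
        g = make_matrix([[0, 1], [0, 1], [0, 0]], ["A"] * 3)
        stats = popgen.locus_statistics(g)
        assert bool(stats.iloc[0].monomorphic)
        assert np.isnan(stats.iloc[0].fis)

    def test_all_missing_locus_skipped(self):
        G = np.array([[0.0, np.nan], [2.0, np.nan]])
        g = make_matrix(G, ["A", "A"])
        stats = popgen.locus_statistics(g)
        assert len(stats) == 1
        assert stats.iloc[0].locus_id == "locus_0"

    def test_by_population_layout(self):
        g = make_matrix([[0], [2], [1], [1]], ["A", "A", "B", "B"])
        stats = popgen.locus_statistics(g, by_population=True)
        assert set(stats.population) == {"A", "B"}
        assert len(stats) == 2


# ----------------------------------------------------------------------
# HWE exact test
# ----------------------------------------------------------------------

class TestHweExactTest:
    def test_monomorphic_p_is_one(self):
        assert popgen.hwe_exact_test(7, 0, 0) == 1.0

    @pytest.mark.parametrize("table", [(3, 4, 3), (5, 1, 4), (0, 10, 0), (2, 2, 2)])
    def test_matches_enumeration_oracle(self, table):
        assert popgen.hwe_exact_test(*table) == pytest.approx(
            hwe_enumeration_oracle(*table), abs=1e-12
        )

    def test_enumeration_equivalence_all_small_tables(self):
        """Exhaustive agreement with the oracle for every table with n <= 12."""
        for n in range(2, 13):
            for n_aa in range(n + 1):
                for n_ab in range(n - n_aa + 1):
                    n_bb = n - n_aa - n_ab
                    got = popgen.hwe_exact_test(n_aa, n_ab, n_bb)
                    want = hwe_enumeration_oracle(n_aa, n_ab, n_bb)
                    assert got == pytest.approx(want, abs=1e-10), (n_aa, n_ab, n_bb)

    def test_conservative_size_under_null(self):
        """Rejection rate at alpha=0.05 under HWE stays below nominal."""
        rng = np.random.default_rng(7)
        n = 50
        genos = rng.binomial(1, 0.5, size=(2000, 2, n)).sum(axis=1)
        rejected = 0
        for row in genos:
            aa = int((row == 0).sum()); ab = int((row == 1).sum())
            p = popgen.hwe_exact_test(aa, ab, n - aa - ab)
            rejected += p < 0.05
        assert rejected / 2000 <= 0.05


# ----------------------------------------------------------------------
# Pairwise differences
# ----------------------------------------------------------------------

class TestPairwiseDifferences:
    def test_identical_rows_zero(self):
        g = make_matrix([[1, 2, 0], [1, 2, 0]], ["A", "B"])
        D = popgen.pairwise_difference_matrix(g)
        assert D[0, 1] == 0.0

    def test_hand_count(self):
        g = make_matrix([[0, 2, 1], [2, 2, 0]], ["A", "B"])
        D = popgen.pairwise_difference_matrix(g)
        assert D[0, 1] == 3.0

    def test_missing_rescaling(self):
        G = np.array([[0.0, 2.0, 1.0], [2.0, 2.0, np.nan]])
        g = make_matrix(G, ["A", "B"])
        assert popgen.pairwise_difference_matrix(g)[0, 1] == pytest.approx(2 * 3 / 2)
        assert popgen.pairwise_difference_matrix(g, rescale_missing=False)[0, 1] == 2.0

    def test_disjoint_calls_error_names_pair(self):
        G = np.array([[0.0, np.nan], [np.nan, 2.0]])
        g = make_matrix(G, ["A", "B"])
        with pytest.raises(ValueError, match="i0.*i1"):
            popgen.pairwise_difference_matrix(g)


# ----------------------------------------------------------------------
# AMOVA
# ----------------------------------------------------------------------

class TestAmova:
    def test_phi_one_with_no_within_variation(self, two_pop_matrix):
        res = popgen.amova(two_pop_matrix, "pops", n_permutations=0)
        assert res.phi_st == pytest.approx(1.0)

    def test_identical_populations_nonpositive_sigma(self):
        block = [[0, 1, 2], [2, 1, 0], [1, 1, 1]]
        g = make_matrix(block + block, ["A"] * 3 + ["B"] * 3)
        res = popgen.amova(g, "pops", n_permutations=199, seed=0)
        assert res.variance_components["among_populations"] <= 0
        assert res.p_values["phi_st"] > 0.05

    def test_percent_variation_sums_to_100(self):
        g = synthdata.simulate_hierarchical_genotypes(
            synthdata.SimGenotypeSpec(n_loci=50, inds_per_pop=4, seed=5)
        )
        res = popgen.amova(g, "groups/pops", n_permutations=0)
        assert sum(res.percent_variation.values()) == pytest.approx(100.0, abs=1e-9)

    @pytest.mark.parametrize("metric", ["allele_mismatch", "manhattan"])
    @pytest.mark.parametrize("two_level", [False, True])
    def test_matches_bruteforce_oracle(self, metric, two_level):
        """Components and Φ match the definitional double-sum oracle."""
        rng = np.random.default_rng(11)
        for _ in range(25):
            g = random_genotype_matrix(
                rng, n_pops=4 if two_level else 3, inds_per_pop=3,
                n_loci=int(rng.integers(5, 30)), with_groups=two_level,
            )
            D2 = popgen.squared_distance_matrix(g, metric=metric)
            want = amova_oracle(
                D2, g.population, g.group if two_level else None
            )
            res = popgen.amova(
                g, "groups/pops" if two_level else "pops",
                n_permutations=0, metric=metric,
            )
            for key, val in want["sigma"].items():
                assert res.variance_components[key] == pytest.approx(val, abs=1e-10)
            assert res.phi_st == pytest.approx(want["phi_st"], abs=1e-10)
            if two_level:
                assert res.phi_ct == pytest.approx(want["phi_ct"], abs=1e-10)
                assert res.phi_sc == pytest.approx(want["phi_sc"], abs=1e-10)

    def test_zero_total_variance_raises(self):
        g = make_matrix([[1, 1], [1, 1], [1, 1], [1, 1]], ["A", "A", "B", "B"])
        with pytest.raises(ValueError, match="variance"):
            popgen.amova(g, "pops", n_permutations=0, metric="manhattan")

    def test_permutation_p_uniform_under_null(self):
        """Null (fct=fsc=0) permutation p-values are approximately uniform."""
        from scipy.stats import kstest

        pvals = []
        for seed in range(60):
            g = synthdata.simulate_hierarchical_genotypes(
                synthdata.SimGenotypeSpec(
                    n_groups=1, pops_per_group=3, inds_per_pop=5, n_loci=60,
                    fct_target=0.0, fsc_target=0.0, seed=seed,
                )
            )
            res = popgen.amova(g, "pops", n_permutations=99, seed=seed)
            pvals.append(res.p_values["phi_st"])
        assert kstest(pvals, "uniform").pvalue > 0.01


# ----------------------------------------------------------------------
# Pairwise Φ_ST
# ----------------------------------------------------------------------

class TestPairwisePhiSt:
    def test_matches_amova_on_the_pair(self):
        rng = np.random.default_rng(3)
        g = random_genotype_matrix(rng, n_pops=3, inds_per_pop=4, n_loci=20)
        fst = popgen.pairwise_phi_st(g, n_permutations=0)
        pops = np.asarray(g.population)
        for a, b in [(0, 1), (0, 2), (1, 2)]:
            idx = np.flatnonzero((pops == f"P{a}") | (pops == f"P{b}"))
            sub = g.subset_individuals(idx)
            res = popgen.amova(sub, "pops", n_permutations=0)
            assert fst.fst[a, b] == pytest.approx(res.phi_st, abs=1e-12)

    def test_duplicated_population_floors_to_zero(self):
        block = [[0, 1, 2, 0], [2, 1, 0, 2], [1, 0, 1, 1]]
        g = make_matrix(block + block, ["A"] * 3 + ["B"] * 3)
        fst = popgen.pairwise_phi_st(g, n_permutations=0)
        assert fst.fst[0, 1] <= 0
        assert fst.fst_floored[0, 1] == 0.0

    def test_linearization_algebra(self):
        fst = popgen.FstMatrix(
            populations=["A", "B"],
            fst=np.array([[0.0, 0.5], [0.5, 0.0]]),
            fst_floored=np.array([[0.0, 0.5], [0.5, 0.0]]),
            linearized=np.array([[0.0, 1.0], [1.0, 0.0]]),
            p_values=np.array([[1.0, 0.01], [0.01, 1.0]]),
        )
        assert fst.linearized[0, 1] == fst.fst[0, 1] / (1 - fst.fst[0, 1])
        assert fst.significant[0, 1]

    def test_small_population_skipped_with_nan(self):
        g = make_matrix([[0, 1], [2, 1], [1, 0]], ["A", "A", "B"])
        fst = popgen.pairwise_phi_st(g, n_permutations=0)
        assert np.isnan(fst.fst[0, 1])


# ----------------------------------------------------------------------
# Completeness filter
# ----------------------------------------------------------------------

class TestCompletenessFilter:
    def test_call_rate_and_population_presence(self):
        G = np.array(
            [
                [0.0, np.nan, 1.0],
                [1.0, np.nan, np.nan],
                [2.0, 1.0, np.nan],
                [0.0, 2.0, np.nan],
            ]
        )
        g = make_matrix(G, ["A", "A", "B", "B"])
        filtered, report = popgen.completeness_filter(
            g, min_call_fraction=0.5, min_populations=2
        )
        # locus 0: full; locus 1: 50% but only pop B; locus 2: 25%
        assert filtered.locus_ids == ["locus_0"]
        assert report.kept.tolist() == [True, False, False]


# ----------------------------------------------------------------------
# Parameter recovery (generator + estimator round trip)
# ----------------------------------------------------------------------

class TestParameterRecovery:
    def test_weir_cockerham_near_zero_without_structure(self):
        vals = []
        for seed in range(5):
            g = synthdata.simulate_hierarchical_genotypes(
                synthdata.SimGenotypeSpec(
                    n_groups=1, pops_per_group=3, inds_per_pop=15, n_loci=500,
                    fct_target=0.0, fsc_target=0.0, seed=seed,
                )
            )
            vals.append(weir_cockerham_fst(g.genotypes, g.population))
        assert abs(np.mean(vals)) < 0.01

    def test_two_level_recovery_and_ordering(self):
        """fct=0.30/fsc=0.02 round trip: Φ_CT within ±0.05, among ≫ within-group."""
        g = synthdata.simulate_hierarchical_genotypes(
            synthdata.SimGenotypeSpec(seed=42)
        )
        res = popgen.amova(g, "groups/pops", n_permutations=0)
        assert res.phi_ct == pytest.approx(0.30, abs=0.05)
        assert (
            res.percent_variation["among_groups"]
            > 5 * res.percent_variation["among_populations"]
        )
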