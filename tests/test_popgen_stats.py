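import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import gammaln

import sdapower as sp
from sdapower.popgen_stats import LocusStats, _genotype_array_logprob

from conftest import make_table


class TestAlleleFrequencies:
    def test_all_homozygous_single_allele(self):
        t = make_table({"A": 3}, np.full((3, 1, 2), 5))
        m = sp.allele_frequencies(t)
        np.testing.assert_allclose(m.frequencies("A", 0), [1.0])

    def test_single_heterozygote(self):
        t = make_table({"A": 1}, [[[1, 2]]])
        m = sp.allele_frequencies(t)
        np.testing.assert_allclose(m.frequencies("A", 0), [0.5, 0.5])

    def test_missing_excluded_from_counts(self):
        # 10 genotypes, 2 missing -> 16 called alleles
        geno = np.ones((10, 1, 2), dtype=int)
        geno[3] = 0
        geno[7] = 0
        t = make_table({"A": 10}, geno)
        m = sp.allele_frequencies(t)
        assert m.total("A", 0) == 16

    def test_zero_count_population_flagged(self):
        geno = np.array([[[1, 1]], [[0, 0]]])
        t = make_table({"A": 1, "B": 1}, geno)
        m = sp.allele_frequencies(t)
        assert ("B", "loc0") in m.zero_count_flags
        assert m.total("B", 0) == 0

    def test_inventory_pooled_over_populations(self):
        geno = np.array([[[1, 1]], [[2, 3]]])
        t = make_table({"A": 1, "B": 1}, geno)
        m = sp.allele_frequencies(t)
        np.testing.assert_array_equal(m.inventories[0], [1, 2, 3])
        assert m.k(0) == 3


class TestPic:
    def test_monomorphic_is_zero(self):
        assert sp.pic(np.array([1.0])) == 0.0

    def test_biallelic_half(self):
        # 1 - 0.5 - 2*(0.25*0.25) = 0.375
        assert sp.pic(np.array([0.5, 0.5])) == pytest.approx(0.375)

    def test_empty_vector_errors(self):
        with pytest.raises(ValueError):
            sp.pic(np.array([]))

    def test_matches_double_sum_definition(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            k = rng.integers(2, 8)
            p = rng.dirichlet(np.ones(k))
            expected = (
                1.0
                - np.sum(p**2)
                - sum(
                    2 * p[i] ** 2 * p[j] ** 2
                    for i, j in itertools.combinations(range(k), 2)
                )
            )
            assert sp.pic(p) == pytest.approx(expected, abs=1e-12)

    @given(st.lists(st.floats(0.01, 1.0), min_size=1, max_size=12))
    def test_pic_at_most_expected_heterozygosity(self, weights):
        p = np.array(weights) / np.sum(weights)
        he = 1.0 - float(np.sum(p**2))
        assert sp.pic(p) <= he + 1e-12
        assert sp.pic(p) < 1.0


def _wc_theta_oracle(table, pop_a, pop_b):
    """Independent scalar transcription of the Weir & Cockerham (1984)
    two-population variance components, genotype by genotype."""
    r = 2
    sum_a = sum_abc = 0.0
    for l in range(table.n_loci):
        samples = {}
        for pop in (pop_a, pop_b):
            rows = [
                i
                for i in range(table.n_individuals)
                if table.population_labels[i] == pop
                and not table.missing_mask[i, l]
            ]
            samples[pop] = [tuple(table.alleles[i, l]) for i in rows]
        n1, n2 = len(samples[pop_a]), len(samples[pop_b])
        if n1 < 1 or n2 < 1:
            continue
        alleles = sorted(
            {a for g in samples[pop_a] + samples[pop_b] for a in g}
        )
        if len(alleles) < 2:
            continue
        nbar = (n1 + n2) / 2
        nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1)
        if nbar <= 1:
            continue
        for allele in alleles:
            p1 = sum(g.count(allele) for g in samples[pop_a]) / (2 * n1)
            p2 = sum(g.count(allele) for g in samples[pop_b]) / (2 * n2)
            h1 = sum(
                1 for g in samples[pop_a] if allele in g and g[0] != g[1]
            ) / n1
            h2 = sum(
                1 for g in samples[pop_b] if allele in g and g[0] != g[1]
            ) / n2
            pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
            s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / (
                (r - 1) * nbar
            )
            hbar = (n1 * h1 + n2 * h2) / (n1 + n2)
            a = (nbar / nc) * (
                s2
                - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4)
                / (nbar - 1)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar)
                - s2 * (r - 1) / r
                - hbar * (2 * nbar - 1) / (4 * nbar)
            )
            c = hbar / 2
            sum_a += a
            sum_abc += a + b + c
    return sum_a / sum_abc


class TestPairwiseFst:
    def test_complete_fixation_gives_one(self):
        geno = np.concatenate(
            [np.full((5, 3, 2), 1), np.full((5, 3, 2), 2)], axis=0
        )
        t = make_table({"A": 5, "B": 5}, geno)
        assert sp.pairwise_fst(t, "A", "B") == pytest.approx(1.0)

    def test_identical_samples_near_zero(self):
        rng = np.random.default_rng(2)
        block = rng.integers(1, 4, size=(10, 4, 2))
        t = make_table(
            {"A": 10, "B": 10}, np.concatenate([block, block], axis=0)
        )
        assert sp.pairwise_fst(t, "A", "B") <= 0.02

    def test_matches_independent_transcription(self):
        rng = np.random.default_rng(5)
        geno = rng.integers(1, 6, size=(24, 6, 2))
        geno[rng.random((24, 6)) < 0.1] = 0  # some missing data
        geno = np.where(geno[:, :, :1] == 0, 0, geno)
        t = make_table({"A": 12, "B": 12}, geno)
        theta = sp.pairwise_fst(t, "A", "B")
        assert theta == pytest.approx(
            _wc_theta_oracle(t, "A", "B"), abs=1e-10
        )

    def test_no_shared_typed_locus_errors(self):
        geno = np.array([[[1, 1]], [[0, 0]]])
        t = make_table({"A": 1, "B": 1}, geno)
        with pytest.raises(ValueError):
            sp.pairwise_fst(t, "A", "B")


class TestMutualInformation:
    def test_identical_frequencies_zero(self):
        block = np.array([[[1, 2]], [[1, 2]]])
        t = make_table(
            {"A": 2, "B": 2}, np.concatenate([block, block], axis=0)
        )
        assert sp.mutual_information(t, "A", "B") == pytest.approx(0.0)

    def test_fixed_alternatives_give_ln2(self):
        geno = np.concatenate(
            [np.full((4, 2, 2), 1), np.full((4, 2, 2), 2)], axis=0
        )
        t = make_table({"A": 4, "B": 4}, geno)
        assert sp.mutual_information(t, "A", "B") == pytest.approx(
            np.log(2)
        )

    def test_symmetric_and_relabel_invariant(self):
        rng = np.random.default_rng(4)
        geno = rng.integers(1, 5, size=(20, 3, 2))
        t = make_table({"A": 10, "B": 10}, geno)
        i_ab = sp.mutual_information(t, "A", "B")
        assert i_ab == pytest.approx(sp.mutual_information(t, "B", "A"))
        # permute allele codes: information content unchanged
        perm = {1: 7, 2: 3, 3: 9, 4: 1}
        relabelled = np.vectorize(perm.get)(geno)
        t2 = make_table({"A": 10, "B": 10}, relabelled)
        assert sp.mutual_information(t2, "A", "B") == pytest.approx(i_ab)

    def test_nonnegative(self, two_pop_table):
        assert sp.mutual_information(two_pop_table, "A", "B") >= 0


def exact_hwe_pvalue(allele_counts, n):
    """Full enumeration of biallelic genotype arrays given allele counts:
    exact probability-ordering p-value."""
    m1, m2 = allele_counts
    assert m1 + m2 == 2 * n

    def logprob(n11, n12, n22):
        return (
            gammaln(n + 1)
            - gammaln(n11 + 1)
            - gammaln(n12 + 1)
            - gammaln(n22 + 1)
            + n12 * np.log(2.0)
            + gammaln(m1 + 1)
            + gammaln(m2 + 1)
            - gammaln(2 * n + 1)
        )

    probs = []
    for n12 in range(m1 % 2, min(m1, m2) + 1, 2):
        n11 = (m1 - n12) // 2
        n22 = (m2 - n12) // 2
        probs.append((n12, np.exp(logprob(n11, n12, n22))))
    return probs


class TestHweTest:
    def test_monomorphic_returns_one(self):
        t = make_table({"A": 5}, np.full((5, 1, 2), 3))
        assert sp.hwe_test(t, "A", "loc0") == 1.0

    def test_all_heterozygotes_significant(self):
        t = make_table({"A": 20}, np.tile([1, 2], (20, 1, 1)))
        p = sp.hwe_test(t, "A", "loc0", n_permutations=2000, seed=1)
        assert p < 0.05

    def test_invalid_permutation_count(self):
        t = make_table({"A": 5}, np.full((5, 1, 2), 3))
        with pytest.raises(ValueError):
            sp.hwe_test(t, "A", "loc0", n_permutations=0)

    @pytest.mark.parametrize("n12", [0, 4, 8])
    def test_monte_carlo_matches_enumeration(self, n12):
        # 10 individuals, biallelic with 8 copies of allele 1
        n, m1 = 10, 8
        n11 = (m1 - n12) // 2
        n22 = n - n11 - n12
        geno = (
            [[1, 1]] * n11 + [[1, 2]] * n12 + [[2, 2]] * n22
        )
        t = make_table({"A": n}, np.array(geno).reshape(n, 1, 2))
        dist = exact_hwe_pvalue((m1, 2 * n - m1), n)
        obs = dict(dist)[n12]
        exact = sum(p for _, p in dist if p <= obs + 1e-12)
        nperm = 4000
        p_mc = sp.hwe_test(t, "A", "loc0", n_permutations=nperm, seed=2)
        se = np.sqrt(exact * (1 - exact) / nperm)
        assert abs(p_mc - exact) <= 3 * se + 2 / nperm

    def test_permutation_conditional_probability_normalises(self):
        # Levene probabilities over all biallelic arrays sum to 1
        dist = exact_hwe_pvalue((6, 8), 7)
        assert sum(p for _, p in dist) == pytest.approx(1.0)
        # and the implementation's log-probability agrees with the oracle
        geno = np.array([[1, 1], [1, 1], [1, 2], [1, 2], [2, 2], [2, 2], [2, 2]])
        lp = _genotype_array_logprob(geno)
        assert np.exp(lp) == pytest.approx(dict(dist)[2])


def _stats(pics):
    return [
        LocusStats(
            locus=f"l{i}",
            pic=p,
            observed_heterozygosity=0.5,
            expected_heterozygosity=0.5,
            hwe_pvalues={},
            sample_sizes={},
        )
        for i, p in enumerate(pics)
    ]


class TestRankLoci:
    def test_highest_first_order(self):
        ranked = sp.rank_loci(_stats([0.3, 0.9, 0.5]), sp.HIGHEST_FIRST)
        assert ranked == ["l1", "l2", "l0"]

    def test_ties_keep_input_order(self):
        ranked = sp.rank_loci(_stats([0.5, 0.5, 0.5]), sp.HIGHEST_FIRST)
        assert ranked == ["l0", "l1", "l2"]

    def test_lowest_is_reverse_of_highest_when_distinct(self):
        stats = _stats([0.3, 0.9, 0.5, 0.7])
        hi = sp.rank_loci(stats, sp.HIGHEST_FIRST)
        lo = sp.rank_loci(stats, sp.LOWEST_FIRST)
        assert lo == hi[::-1]

    def test_unknown_direction_errors(self):
        with pytest.raises(ValueError):
            sp.rank_loci(_stats([0.1]), "sideways")


def test_hwe_screen_flags_loci_failing_in_two_populations():
    # one locus wildly out of HWE in both pops, one in equilibrium
    rng = np.random.default_rng(9)
    bad = np.tile([1, 2], (40, 1, 1))  # all heterozygous in every pop
    good = rng.choice([1, 2], size=(40, 1, 2))
    geno = np.concatenate([bad, good], axis=1)
    t = make_table({"A": 20, "B": 20}, geno)
    report = sp.hwe_screen(t, n_permutations=3000, seed=3)
    flagged = report[report["flagged_for_exclusion"]]["locus"].unique()
    assert "loc0" in flagged
    assert "loc1" not in flagged
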