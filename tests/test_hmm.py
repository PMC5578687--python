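import itertools
import math

import numpy as np
import pytest
from scipy.linalg import expm

from kinforest.hmm import (
    GenotypeMatrix,
    build_table,
    emission_prob,
    emission_tables,
    error_channel,
    hwe_genotype_probs,
    marginal_loglik,
    pair_loglik_hmm,
    transition_matrix,
)
from kinforest.relationships import (
    FULL_SIB,
    HALF_SIB,
    PARENT_OFFSPRING,
    enumerate_relationships,
    k_coefficients,
    lik_key,
    rel,
    self_rel,
    unrelated,
)
from conftest import random_genotypes


class TestMarginal:
    def test_single_het_locus_no_error(self):
        assert marginal_loglik(np.array([1]), np.array([0.5])) == \
            pytest.approx(math.log(0.5))

    def test_all_missing_is_zero(self):
        assert marginal_loglik(np.full(5, -1), np.full(5, 0.3)) == 0.0

    def test_hand_summed_error_model(self):
        # g = 2 observed at p = 0.2 with 1% per-allele error:
        # sum over true genotypes of HWE(g') * P(g' -> 2)
        p, e = 0.2, 0.01
        hwe = [(1 - p) ** 2, 2 * p * (1 - p), p ** 2]
        flip = [e ** 2, e * (1 - e), (1 - e) ** 2]
        expected = math.log(sum(h * f for h, f in zip(hwe, flip)))
        assert marginal_loglik(np.array([2]), np.array([p]), e) == \
            pytest.approx(expected)

    def test_bad_frequency_raises(self):
        with pytest.raises(ValueError):
            marginal_loglik(np.array([0]), np.array([1.0]))


class TestEmissions:
    @pytest.mark.parametrize("p", [0.05, 0.2, 0.35, 0.5, 0.65, 0.8, 0.95])
    @pytest.mark.parametrize("err", [0.0, 0.01, 0.05])
    def test_rows_are_distributions(self, p, err):
        tab = emission_tables(np.array([p]), err)
        for s in range(3):
            assert tab[0, s].sum() == pytest.approx(1.0)

    def test_state0_factorizes(self):
        p = 0.3
        hwe = hwe_genotype_probs(np.array([p]))[0]
        for gi, gj in itertools.product(range(3), repeat=2):
            assert emission_prob(gi, gj, 0, p) == \
                pytest.approx(hwe[gi] * hwe[gj])

    def test_state2_requires_identity_without_error(self):
        assert emission_prob(0, 2, 2, 0.4) == 0.0
        assert emission_prob(1, 1, 2, 0.4) == pytest.approx(2 * 0.4 * 0.6)

    def test_state1_brute_force_two_allele_model(self):
        # shared allele A ~ freq; each individual adds one free allele
        p = 0.5
        assert emission_prob(0, 0, 1, p) == pytest.approx(0.5 ** 3)
        for gi, gj in itertools.product(range(3), repeat=2):
            total = 0.0
            for a in (0, 1):
                pa = p if a == 1 else 1 - p
                for bi in (0, 1):
                    for bj in (0, 1):
                        pb = (p if bi else 1 - p) * (p if bj else 1 - p)
                        if a + bi == gi and a + bj == gj:
                            total += pa * pb
            assert emission_prob(gi, gj, 1, p) == pytest.approx(total)


class TestTransitions:
    def test_zero_distance_is_identity(self):
        for r in (FULL_SIB, HALF_SIB, rel(2, 2, 2)):
            assert transition_matrix(r, 0.0) == pytest.approx(np.eye(3))

    def test_infinite_distance_is_stationary(self):
        T = transition_matrix(HALF_SIB, 1e9)
        for row in T:
            assert row == pytest.approx(np.array([0.5, 0.5, 0.0]))
        T = transition_matrix(FULL_SIB, 1e9)
        for row in T:
            assert row == pytest.approx(np.array([0.25, 0.5, 0.25]))

    def test_stationarity(self):
        for r in (FULL_SIB, HALF_SIB, rel(1, 2, 2), rel(3, 4, 2)):
            pi = np.array(k_coefficients(r))
            T = transition_matrix(r, 7.3)
            assert pi @ T == pytest.approx(pi)

    @pytest.mark.parametrize("r", [HALF_SIB, FULL_SIB, rel(2, 3, 1)])
    def test_chapman_kolmogorov(self, r):
        T1 = transition_matrix(r, 12.0)
        T2 = transition_matrix(r, 30.0)
        T3 = transition_matrix(r, 42.0)
        assert T1 @ T2 == pytest.approx(T3)

    def test_full_sib_matches_generator_exponential(self):
        # the full-sib chain is the product of two independent parental
        # chains with symmetric switch rate 2/Morgan; its generator on IBD
        # counts follows by aggregating the 4-state Kronecker sum
        q1 = np.array([[-2.0, 2.0], [2.0, -2.0]])
        Q4 = np.kron(q1, np.eye(2)) + np.kron(np.eye(2), q1)
        # states (0,0),(0,1),(1,0),(1,1) -> counts 0,1,1,2
        agg = np.array([[1, 0, 0], [0, 1, 0], [0, 1, 0], [0, 0, 1]], float)
        d = 0.5  # 50 cM
        P4 = expm(Q4 * d)
        start = {0: [1, 0, 0, 0], 1: [0, 1, 0, 0], 2: [0, 0, 0, 1]}
        expected = np.vstack([np.array(start[c]) @ P4 @ agg for c in range(3)])
        assert transition_matrix(FULL_SIB, 50.0) == pytest.approx(expected)

    def test_leaving_rate_scales_with_meioses(self):
        d = 1.0
        stay_close = transition_matrix(rel(1, 2, 2), d)[1, 1]   # m = 3
        stay_far = transition_matrix(rel(3, 4, 2), d)[1, 1]     # m = 7
        assert stay_far < stay_close

    def test_closed_forms_raise(self):
        with pytest.raises(ValueError):
            transition_matrix(unrelated(), 10.0)
        with pytest.raises(ValueError):
            transition_matrix(self_rel(), 10.0)


class TestForward:
    def test_unrelated_factorizes(self):
        gm = random_genotypes(2, np.full(300, 0.4), seed=1, error_rate=0.01)
        ll = pair_loglik_hmm(gm.genotypes[0], gm.genotypes[1], unrelated(), gm)
        m0 = marginal_loglik(gm.genotypes[0], gm.freqs, 0.01)
        m1 = marginal_loglik(gm.genotypes[1], gm.freqs, 0.01)
        assert ll == pytest.approx(m0 + m1, abs=1e-9)

    def test_unlinked_equals_mixture_closed_form(self):
        gm = random_genotypes(2, np.full(200, 0.3), seed=2)
        for r in (FULL_SIB, HALF_SIB, rel(2, 2, 2)):
            ll = pair_loglik_hmm(gm.genotypes[0], gm.genotypes[1], r, gm)
            ks = k_coefficients(r)
            tab = emission_tables(gm.freqs, 0.0)
            mix = np.log(sum(
                ks[s] * tab[np.arange(gm.L), s, gm.genotypes[0], gm.genotypes[1]]
                for s in range(3))).sum()
            assert ll == pytest.approx(mix, abs=1e-8)

    def test_chromosome_restart(self):
        # two loci on different chromosomes: product of single-locus mixtures
        freqs = np.array([0.3, 0.6])
        gm = GenotypeMatrix(np.array([[0, 1], [0, 2]], np.int8), freqs,
                            np.array([0.0, 0.0]), np.array([1, 2]),
                            error_rate=0.0)
        ll = pair_loglik_hmm(gm.genotypes[0], gm.genotypes[1], FULL_SIB, gm)
        tab = emission_tables(freqs, 0.0)
        ks = k_coefficients(FULL_SIB)
        expected = sum(
            math.log(sum(ks[s] * tab[l, s, gm.genotypes[0][l], gm.genotypes[1][l]]
                         for s in range(3)))
            for l in range(2))
        assert ll == pytest.approx(expected, abs=1e-9)

    def test_linked_loci_match_path_enumeration(self):
        # 3 linked loci, half sibs, no error: brute-force sum over the 2^3
        # hidden paths of the two-state chain
        freqs = np.array([0.3, 0.5, 0.7])
        cm = np.array([0.0, 10.0, 25.0])
        gm = GenotypeMatrix(np.array([[0, 1, 2], [1, 1, 0]], np.int8),
                            freqs, cm, np.ones(3), error_rate=0.0)
        ll = pair_loglik_hmm(gm.genotypes[0], gm.genotypes[1], HALF_SIB, gm)
        tab = emission_tables(freqs, 0.0)
        T1 = transition_matrix(HALF_SIB, 10.0)
        T2 = transition_matrix(HALF_SIB, 15.0)
        pi = k_coefficients(HALF_SIB)
        total = 0.0
        for path in itertools.product((0, 1), repeat=3):
            pr = pi[path[0]] * T1[path[0], path[1]] * T2[path[1], path[2]]
            for l, s in enumerate(path):
                pr *= tab[l, s, gm.genotypes[0][l], gm.genotypes[1][l]]
            total += pr
        assert ll == pytest.approx(math.log(total), abs=1e-9)

    def test_missing_marginalized(self):
        freqs = np.full(4, 0.4)
        g1 = np.array([1, -1, 2, -1], np.int8)
        g2 = np.array([-1, -1, 0, 1], np.int8)
        gm = GenotypeMatrix(np.vstack([g1, g2]), freqs, np.zeros(4),
                            np.arange(4), error_rate=0.0)
        ll = pair_loglik_hmm(g1, g2, HALF_SIB, gm)
        assert np.isfinite(ll)
        # fully-missing pair contributes nothing
        both = pair_loglik_hmm(np.full(4, -1, np.int8), np.full(4, -1, np.int8),
                               HALF_SIB, gm)
        assert both == pytest.approx(0.0)


class TestTable:
    def test_single_individual_only_marginals(self):
        gm = random_genotypes(1, np.full(50, 0.4), seed=3)
        tbl = build_table(gm)
        assert tbl.n == 1
        assert tbl.marginal_loglik(0) == pytest.approx(
            marginal_loglik(gm.genotypes[0], gm.freqs, 0.0))

    def test_unrelated_entry_factorizes_exactly(self):
        gm = random_genotypes(3, np.full(100, 0.3), seed=4, error_rate=0.01)
        tbl = build_table(gm)
        for i, j in itertools.combinations(range(3), 2):
            assert tbl.pair_loglik(i, j, unrelated()) == pytest.approx(
                tbl.marginal_loglik(i) + tbl.marginal_loglik(j), abs=1e-9)

    def test_orientation_symmetry(self):
        gm = random_genotypes(2, np.full(80, 0.45), seed=5)
        tbl = build_table(gm)
        avun = rel(1, 2, 2)
        assert tbl.pair_loglik(0, 1, avun) == \
            tbl.pair_loglik(1, 0, avun.swapped())

    def test_entry_counts(self):
        gm = random_genotypes(2, np.full(60, 0.25), seed=6)
        tbl = build_table(gm, [unrelated(), PARENT_OFFSPRING])
        assert len(tbl.marginal) == 2
        assert {("unrelated",), ("k", 1, 1, 0)} == set(tbl.class_keys)


def test_likelihood_ratio_detects_close_relatives(rng):
    """Gene-dropped pairs with kinship >= 1/16 prefer the true class to
    unrelated in >= 95% of simulated pairs at 3000 unlinked loci."""
    from kinforest.pedigree import Pedigree
    from kinforest.simulate import GenomeSpec, gene_drop, simulate_founders

    L = 3000
    freqs = np.clip(rng.beta(0.8, 0.8, L), 0.05, 0.95)
    genome = GenomeSpec(np.zeros(L), np.arange(L))  # unlinked
    ped = Pedigree(parents={"i": ("a", "b"), "m": ("a", "b"), "j": ("m",)},
                   sampled=["i", "j"])  # avuncular pair, phi = 1/8
    hits = 0
    reps = 100
    for k in range(reps):
        haps, _, _ = simulate_founders(4, genome, seed=1000 + k, freqs=freqs)
        drop = gene_drop(ped, haps, freqs, genome, seed=k)
        gm = drop.gm
        ll_true = pair_loglik_hmm(gm.genotypes[0], gm.genotypes[1],
                                  rel(1, 2, 2), gm)
        ll_unrel = pair_loglik_hmm(gm.genotypes[0], gm.genotypes[1],
                                   unrelated(), gm)
        hits += ll_true > ll_unrel
    assert hits >= 95


def test_truncating_loci_reduces_information():
    """|loglik(R) - loglik(unrelated)| shrinks on average when loci are
    dropped (trend over 50 replicates)."""
    from kinforest.pedigree import Pedigree
    from kinforest.simulate import GenomeSpec, gene_drop, simulate_founders

    L = 400
    rng = np.random.Generator(np.random.PCG64(7))
    freqs = np.clip(rng.beta(0.8, 0.8, L), 0.05, 0.95)
    genome = GenomeSpec(np.zeros(L), np.arange(L))
    ped = Pedigree(parents={"i": ("m",), "j": ("m",)}, sampled=["i", "j"])
    full, half = [], []
    for k in range(50):
        haps, _, _ = simulate_founders(3, genome, seed=2000 + k, freqs=freqs)
        drop = gene_drop(ped, haps, freqs, genome, seed=k)
        gm = drop.gm
        sub = gm.subset_loci(np.arange(L // 2))
        for g, acc in ((gm, full), (sub, half)):
            d = pair_loglik_hmm(g.genotypes[0], g.genotypes[1], HALF_SIB, g) - \
                pair_loglik_hmm(g.genotypes[0], g.genotypes[1], unrelated(), g)
            acc.append(abs(d))
    assert np.mean(full) > np.mean(half)
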