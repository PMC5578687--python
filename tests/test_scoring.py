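import math
from itertools import combinations

import numpy as np
import pytest
from scipy.stats import poisson

from kinforest.hmm import GenotypeMatrix, build_table
from kinforest.oracle import full_loglik_unlinked
from kinforest.pedigree import Pedigree, singleton_forest
from kinforest.relationships import PARENT_OFFSPRING, unrelated
from kinforest.scoring import alt_cl, delta_score, local_cl, total_score
from kinforest.simulate import GenomeSpec, gene_drop, simulate_founders
from conftest import random_genotypes


def _dropped_family(ped, L=3000, seed=0, freqs=None):
    rng = np.random.Generator(np.random.PCG64(seed))
    if freqs is None:
        freqs = np.clip(rng.beta(0.8, 0.8, L), 0.05, 0.95)
    genome = GenomeSpec(np.zeros(L), np.arange(L))  # independent loci
    haps, _, _ = simulate_founders(len(ped.parents) + 2, genome,
                                   seed=seed, freqs=freqs)
    return gene_drop(ped, haps, freqs, genome, seed=seed + 1).gm


class TestLocalCL:
    def test_k1_is_marginal(self):
        gm = random_genotypes(1, np.full(50, 0.4), seed=1)
        tbl = build_table(gm)
        ped = singleton_forest([0])
        assert local_cl(ped, tbl) == pytest.approx(tbl.marginal_loglik(0))

    def test_k2_is_pairwise_likelihood(self):
        gm = random_genotypes(2, np.full(50, 0.4), seed=2)
        tbl = build_table(gm)
        ped = Pedigree(parents={1: (0,)}, sampled=[0, 1],
                       genotype_index={0: 0, 1: 1})
        assert local_cl(ped, tbl) == pytest.approx(
            tbl.pair_loglik(0, 1, PARENT_OFFSPRING))

    def test_all_unrelated_triple_collapses_to_marginals(self):
        gm = random_genotypes(3, np.full(80, 0.3), seed=3)
        tbl = build_table(gm)
        # three samples in one component connected only through marriages
        ped = Pedigree(parents={"x": (0, 1), "y": (1, 2)},
                       sampled=[0, 1, 2], genotype_index={i: i for i in range(3)})
        comp = ped.components()
        assert len(comp) == 1
        want = sum(tbl.marginal_loglik(i) for i in range(3))
        assert local_cl(ped, tbl, comp[0]) == pytest.approx(want, abs=1e-9)


class TestAltCL:
    def test_k2_reduces_to_single_pair_term(self):
        gm = random_genotypes(2, np.full(60, 0.35), seed=4)
        tbl = build_table(gm)
        ped = Pedigree(parents={1: (0,)}, sampled=[0, 1],
                       genotype_index={0: 0, 1: 1})
        assert alt_cl(ped, tbl) == pytest.approx(
            tbl.pair_loglik(0, 1, PARENT_OFFSPRING))

    def test_all_unrelated_collapses_to_marginals(self):
        gm = random_genotypes(3, np.full(80, 0.3), seed=5)
        tbl = build_table(gm)
        ped = Pedigree(parents={"x": (0, 1), "y": (1, 2)},
                       sampled=[0, 1, 2], genotype_index={i: i for i in range(3)})
        want = sum(tbl.marginal_loglik(i) for i in range(3))
        assert alt_cl(ped, tbl, ped.components()[0]) == \
            pytest.approx(want, abs=1e-9)


class TestTotalScore:
    def test_singletons_beta_zero(self):
        gm = random_genotypes(4, np.full(40, 0.3), seed=6)
        tbl = build_table(gm)
        ped = singleton_forest(list(range(4)))
        br = total_score(ped, tbl, beta=0.0, lam=4.0)
        assert br.total_log_score == pytest.approx(
            sum(tbl.marginal_loglik(i) for i in range(4)))

    def test_singletons_poisson_term(self):
        gm = random_genotypes(4, np.full(40, 0.3), seed=7)
        tbl = build_table(gm)
        ped = singleton_forest(list(range(4)))
        br = total_score(ped, tbl, beta=1.0, lam=4.0)
        want = sum(tbl.marginal_loglik(i) for i in range(4)) + \
            poisson.logpmf(4, 4)
        assert br.total_log_score == pytest.approx(want)
        assert br.q == 4

    def test_merge_delta_algebra(self):
        gm = random_genotypes(3, np.full(70, 0.4), seed=8)
        tbl = build_table(gm)
        before = singleton_forest(list(range(3)))
        after = Pedigree(parents={1: (0,), 0: (), 2: ()}, sampled=[0, 1, 2],
                         genotype_index={i: i for i in range(3)})
        beta, lam = 1.0, 3.0
        d = total_score(after, tbl, beta, lam).total_log_score - \
            total_score(before, tbl, beta, lam).total_log_score
        want = (tbl.pair_loglik(0, 1, PARENT_OFFSPRING)
                - tbl.marginal_loglik(0) - tbl.marginal_loglik(1)
                + poisson.logpmf(2, lam) - poisson.logpmf(3, lam))
        assert d == pytest.approx(want, abs=1e-9)
        assert delta_score(before, after, tbl, beta, lam, touched=[0, 1]) == \
            pytest.approx(want, abs=1e-8)

    def test_null_edit_delta_zero(self):
        gm = random_genotypes(2, np.full(30, 0.4), seed=9)
        tbl = build_table(gm)
        ped = singleton_forest([0, 1])
        assert delta_score(ped, ped, tbl, 1.0, 2.0, touched=[0]) == 0.0


class TestOracleAgreement:
    """Composite vs exact full likelihood on a six-member nuclear family at
    independent loci: ordering preserved, unit scaling closer than the
    alternative scaling."""

    @pytest.fixture(scope="class")
    def family_scan(self, nuclear_family_cls=None):
        ped = Pedigree(parents={"M": (), "F": (), "C1": ("M", "F"),
                                "C2": ("M", "F"), "C3": ("M", "F"),
                                "C4": ("M", "F")},
                       sampled=["M", "F", "C1", "C2", "C3", "C4"])
        gm = _dropped_family(ped, L=3000, seed=11)
        tbl = build_table(gm)
        samp = ["M", "F", "C1", "C2", "C3", "C4"]
        # ladder from everyone-unrelated to the true pedigree: attach the
        # children one at a time
        configs = []
        for k in range(5):
            parents = {"M": (), "F": ()}
            for c in ["C1", "C2", "C3", "C4"][:k]:
                parents[c] = ("M", "F")
            for c in ["C1", "C2", "C3", "C4"][k:]:
                parents[c] = ()
            configs.append(Pedigree(parents=parents, sampled=samp))
        return ped, gm, tbl, configs

    def test_ordering_preserved_and_scales(self, family_scan):
        truth, gm, tbl, configs = family_scan
        fulls, locals_, alts = [], [], []
        for cfg in configs:
            fulls.append(full_loglik_unlinked(cfg, gm))
            locals_.append(sum(
                __import__("kinforest.scoring", fromlist=["component_logcl"])
                .component_logcl(cfg, comp, tbl) for comp in cfg.components()))
        # composite = full exactly for k <= 2 components; here compare the
        # whole-forest scores
        assert np.argsort(fulls).tolist() == np.argsort(locals_).tolist()
        assert fulls[-1] == max(fulls)  # truth is the full-likelihood argmax
        # alternative scaling on the complete-family component: flatter
        # surface and farther from the full likelihood at the truth
        full_comp = [full_loglik_unlinked(c, gm) for c in configs[-2:]]
        complete = configs[-1]
        comp = complete.components()
        fam_comp = [c for c in comp if len(c) > 2][0]
        lc = local_cl(complete, tbl, fam_comp)
        ac = alt_cl(complete, tbl, fam_comp)
        fl = full_loglik_unlinked(complete, gm)
        assert abs(lc - fl) < abs(ac - fl)

    def test_alt_surface_flatter(self, family_scan):
        """Forest-level scan from all-unrelated to the truth: the 1/(k-1)
        scaling gives a much flatter surface than the unit scaling."""
        truth, gm, tbl, configs = family_scan
        from kinforest.scoring import component_logcl

        def forest_alt(cfg):
            s = 0.0
            for c in cfg.components():
                H = [x for x in c if x in cfg.sampled]
                if len(H) >= 2:
                    s += alt_cl(cfg, tbl, c)
                elif len(H) == 1:
                    s += tbl.marginal_loglik(H[0])
            return s

        def forest_local(cfg):
            return sum(component_logcl(cfg, c, tbl) for c in cfg.components())

        lc = [forest_local(c) for c in configs]
        ac = [forest_alt(c) for c in configs]
        fl = [full_loglik_unlinked(c, gm) for c in configs]
        assert (max(ac) - min(ac)) < 0.5 * (max(fl) - min(fl))
        # alternative scaling still preserves the full-likelihood ordering
        assert np.argsort(ac).tolist() == np.argsort(fl).tolist()

    def test_composite_equals_full_for_pairs(self):
        ped = Pedigree(parents={"j": ("i",), "i": ()}, sampled=["i", "j"])
        gm = _dropped_family(ped, L=500, seed=12)
        tbl = build_table(gm)
        comp = ped.components()[0]
        assert local_cl(ped, tbl, comp) == pytest.approx(
            full_loglik_unlinked(ped, gm), abs=1e-6)


def test_delta_score_matches_recompute_on_random_moves():
    """Annealer-internal incremental deltas equal a full recompute: 500
    random accepted/rejected moves on a 15-sample forest."""
    from kinforest.anneal import AnnealConfig, run

    gm = random_genotypes(15, np.clip(
        np.random.Generator(np.random.PCG64(3)).beta(0.8, 0.8, 600),
        0.05, 0.95), seed=13, error_rate=0.01)
    tbl = build_table(gm)
    cfg = AnnealConfig(C=100, f=1.3, I=500, t0=0.05, beta=1.0, seed=99,
                       check_every=50, stall_stages=10**6, engine="python")
    # check_every triggers the internal full-recompute guard every 50
    # proposals; a mismatch raises
    run(tbl, cfg)
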