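import math

import numpy as np
import pytest

from kinforest.anneal import (
    MOVES,
    AnnealConfig,
    _Annealer,
    accept,
    multi_start,
    propose,
    run,
)
from kinforest.hmm import build_table
from kinforest.pedigree import Pedigree, singleton_forest
from kinforest.scoring import total_score
from kinforest.simulate import GenomeSpec, gene_drop, simulate_founders
from conftest import random_genotypes


class TestAccept:
    def test_nonnegative_delta_always_accepted(self, rng):
        assert accept(0.0, 0.5, rng)
        assert accept(12.3, 0.0, rng)

    def test_zero_temperature_accepts_everything(self, rng):
        assert all(accept(-50.0, 0.0, rng) for _ in range(100))

    def test_acceptance_rate_matches_exponential(self):
        rng = np.random.Generator(np.random.PCG64(4))
        n = 100_000
        hits = sum(accept(-2.0, 1.0, rng) for _ in range(n))
        want = math.exp(-2)
        se = math.sqrt(want * (1 - want) / n)
        assert abs(hits / n - want) < 4 * se

    def test_deterministic_given_stream(self):
        a = np.random.Generator(np.random.PCG64(9))
        b = np.random.Generator(np.random.PCG64(9))
        seq_a = [accept(-1.0, 0.7, a) for _ in range(200)]
        seq_b = [accept(-1.0, 0.7, b) for _ in range(200)]
        assert seq_a == seq_b


class TestConfig:
    def test_cooling_factor_must_exceed_one(self):
        with pytest.raises(ValueError):
            AnnealConfig(f=1.0)

    def test_move_catalog_has_22_distinct_types(self):
        names = [name for name, _ in MOVES]
        assert len(names) == 22
        assert len(set(names)) == 22


class TestProposals:
    def test_random_proposals_keep_states_valid(self):
        """1000 proposals on a running annealer: every accepted state passes
        the full validity check (enforced by check_every)."""
        gm = random_genotypes(10, np.clip(
            np.random.Generator(np.random.PCG64(1)).beta(0.8, 0.8, 300),
            0.05, 0.95), seed=2, error_rate=0.01)
        tbl = build_table(gm)
        cfg = AnnealConfig(C=200, f=1.2, I=1000, t0=0.05, beta=1.0, seed=3,
                           check_every=100, stall_stages=10**6,
                           engine="python")
        ped, br, info = run(tbl, cfg)  # check_every raises on any violation
        assert ped.validate() == []

    def test_null_edits_counted_rejected(self):
        gm = random_genotypes(2, np.full(50, 0.4), seed=4)
        tbl = build_table(gm)
        cfg = AnnealConfig(C=50, f=1.2, I=200, seed=5, check_every=0,
                           stall_stages=10**6)
        ped, br, info = run(tbl, cfg)
        total_tried = sum(v[0] for v in info["moves"].values())
        assert total_tried == info["proposals"]


class TestRun:
    def _sib_pair_fixture(self, seed=0):
        truth = Pedigree(parents={"s1": ("m", "f"), "s2": ("m", "f"),
                                  "u": ()}, sampled=["s1", "s2", "u"])
        rng = np.random.Generator(np.random.PCG64(seed))
        L = 3000
        freqs = np.clip(rng.beta(0.8, 0.8, L), 0.05, 0.95)
        genome = GenomeSpec(np.zeros(L), np.arange(L))
        haps, _, _ = simulate_founders(5, genome, seed=seed, freqs=freqs)
        gm = gene_drop(truth, haps, freqs, genome, seed=seed + 1).gm
        return truth, build_table(gm)

    def test_sib_pair_recovered_against_exhaustive_oracle(self):
        """Exhaustively score every <=3-sample configuration; the annealer
        must find the top one, which links exactly the sib pair."""
        truth, tbl = self._sib_pair_fixture(seed=31)
        ids = ["s1", "s2", "u"]
        configs = {
            "singletons": singleton_forest(ids),
            "sibs": Pedigree(parents={"s1": ("a", "b"), "s2": ("a", "b"),
                                      "u": ()}, sampled=ids),
            "s1u_sibs": Pedigree(parents={"s1": ("a", "b"), "u": ("a", "b"),
                                          "s2": ()}, sampled=ids),
            "s2u_sibs": Pedigree(parents={"s2": ("a", "b"), "u": ("a", "b"),
                                          "s1": ()}, sampled=ids),
            "po12": Pedigree(parents={"s2": ("s1",), "u": ()}, sampled=ids),
            "po_u": Pedigree(parents={"u": ("s1",), "s2": ()}, sampled=ids),
            "half12": Pedigree(parents={"s1": ("g",), "s2": ("g",), "u": ()},
                               sampled=ids),
        }
        beta, lam = 10.0, 3.0
        scores = {k: total_score(p, tbl, beta, lam).total_log_score
                  for k, p in configs.items()}
        assert max(scores, key=scores.get) == "sibs"
        cfg = AnnealConfig(C=500, f=1.15, I=20_000, t0=0.05, beta=beta,
                           seed=7, check_every=0, stall_stages=5, reheats=1)
        ped, br, info = run(tbl, cfg)
        assert br.total_log_score >= scores["sibs"] - 1e-6
        assert ped.relationship_between("s1", "s2").full_sib
        assert ped.relationship_between("s1", "u").kind == "unrelated"

    def test_strong_regularizer_keeps_unrelated_apart(self):
        gm = random_genotypes(6, np.clip(
            np.random.Generator(np.random.PCG64(8)).beta(0.8, 0.8, 1000),
            0.05, 0.95), seed=9, error_rate=0.01)
        tbl = build_table(gm)
        # under a Poisson mean above n every merge shrinks the prior, so a
        # large beta keeps all unrelated individuals apart
        cfg = AnnealConfig(C=300, f=1.2, I=6000, t0=0.05, beta=200.0,
                           lam=12.0, seed=10, check_every=0, stall_stages=4)
        ped, br, info = run(tbl, cfg)
        assert br.q == 6  # prior dominates: everyone stays a singleton

    def test_best_trace_nondecreasing(self):
        gm = random_genotypes(5, np.full(200, 0.4), seed=11, error_rate=0.01)
        tbl = build_table(gm)
        cfg = AnnealConfig(C=100, f=1.2, I=2000, seed=12, check_every=0,
                           stall_stages=10**6)
        ped, br, info = run(tbl, cfg)
        bests = [tr["best"] for tr in info["trace"]]
        assert all(a <= b + 1e-12 for a, b in zip(bests, bests[1:]))

    def test_bit_reproducible(self):
        gm = random_genotypes(6, np.full(300, 0.35), seed=13, error_rate=0.01)
        tbl = build_table(gm)
        cfg = AnnealConfig(C=200, f=1.15, I=4000, seed=21, check_every=0,
                           stall_stages=10**6)
        a = run(tbl, cfg)
        b = run(tbl, cfg)
        assert a[1].total_log_score == b[1].total_log_score
        assert a[0].isomorphic(b[0])


class TestMultiStart:
    def test_single_restart_equals_run(self):
        gm = random_genotypes(4, np.full(150, 0.4), seed=14, error_rate=0.01)
        tbl = build_table(gm)
        cfg = AnnealConfig(C=100, f=1.2, I=1500, seed=33, n_restarts=1,
                           check_every=0, stall_stages=10**6)
        ped, br, scores = multi_start(tbl, cfg)
        seed0 = int(np.random.SeedSequence(33).generate_state(1)[0]) % (2**31)
        solo = run(tbl, AnnealConfig(**{**cfg.__dict__, "seed": seed0}))
        assert scores == [solo[1].total_log_score]
        assert br.total_log_score == solo[1].total_log_score

    def test_winner_is_argmax_of_run_scores(self):
        gm = random_genotypes(4, np.full(150, 0.4), seed=15, error_rate=0.01)
        tbl = build_table(gm)
        cfg = AnnealConfig(C=100, f=1.2, I=1500, seed=34, n_restarts=3,
                           check_every=0, stall_stages=10**6)
        ped, br, scores = multi_start(tbl, cfg)
        assert br.total_log_score == pytest.approx(max(scores))
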