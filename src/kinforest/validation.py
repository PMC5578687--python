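"""End-to-end validation experiments: scenario recovery and the
genome-scale LD-pruning yield.

These are the study conditions used by the acceptance suite and by
``scripts/acceptance.py``; they are ordinary library code and can be rerun
with any seed.
"""
from __future__ import annotations

import numpy as np

from .anneal import AnnealConfig, multi_start
from .hmm import build_table
from .pedigree import isomorphic
from .simulate import (
    HUMAN_AUTOSOME_BP,
    NE_DEFAULT,
    RECOMB_DEFAULT,
    MUT_DEFAULT,
    make_scenario,
    prune_mask,
)

#: markers per scenario fixture (the marker count of the published
#: simulations after LD pruning)
SCENARIO_MARKERS = 10_000


def scenario_anneal_config(seed: int, n_restarts: int = 3) -> AnnealConfig:
    """The frozen annealing schedule for scenario-scale samples (n ~ 20)."""
    return AnnealConfig(
        seed=seed, beta=10.0, lam=None, C=2000, f=1.08, t0=0.02,
        I=450_000, reheats=8, stall_stages=6, n_restarts=n_restarts,
        check_every=0,
    )


def run_scenario_replicate(name: str, seed: int,
                           n_markers: int = SCENARIO_MARKERS,
                           n_restarts: int = 3):
    """Simulate one scenario fixture and infer its pedigree.

    Returns (exact_match: bool, estimated Pedigree, truth Pedigree,
    ScoreBreakdown, per-run scores).
    """
    sc = make_scenario(name, seed=seed, n_markers=n_markers)
    table = build_table(sc.gm)
    cfg = scenario_anneal_config(seed=seed + 10_000, n_restarts=n_restarts)
    ped, breakdown, scores = multi_start(table, cfg, sex=sc.gm.sex)
    return isomorphic(ped, sc.truth), ped, sc.truth, breakdown, scores


def scenario_recovery_rate(name: str, n_replicates: int, seed: int = 0,
                           n_markers: int = SCENARIO_MARKERS,
                           n_restarts: int = 3, verbose: bool = False) -> float:
    """Fraction of replicates whose maximum-composite-likelihood pedigree is
    exactly isomorphic to the truth."""
    hits = 0
    for k in range(n_replicates):
        ok = run_scenario_replicate(name, seed + 1 + k, n_markers,
                                    n_restarts)[0]
        hits += ok
        if verbose:
            print(f"  scenario {name} replicate {k + 1}/{n_replicates}: "
                  f"{'exact' if ok else 'miss'}", flush=True)
    return hits / n_replicates


def autosome_pruned_marker_count(seed: int = 0, r2: float = 0.05,
                                 n_founders: int = 100,
                                 chunk_bp: int = 5_000_000,
                                 verbose: bool = False,
                                 chrom_bp=None) -> int:
    """Coalescent founder panel over the 22 human autosomes, LD-pruned.

    Each chromosome is simulated in independent ``chunk_bp`` pieces (long
    -range LD beyond a few cM is negligible, and piecewise simulation keeps
    the coalescent tractable); pruning compares every marker against all
    kept markers on the same chromosome (no window), keeping the earlier
    marker of an offending pair.
    """
    import msprime

    if chrom_bp is None:
        chrom_bp = HUMAN_AUTOSOME_BP
    ss = np.random.SeedSequence(seed)
    total = 0
    for ci, length in enumerate(chrom_bp):
        n_chunks = int(np.ceil(length / chunk_bp))
        seeds = ss.spawn(1)[0].generate_state(2 * n_chunks) % (2 ** 31 - 1) + 1
        dos_parts = []
        cm_parts = []
        off = 0.0
        for k in range(n_chunks):
            clen = min(chunk_bp, length - k * chunk_bp)
            ts = msprime.sim_ancestry(
                samples=n_founders, population_size=NE_DEFAULT,
                sequence_length=clen, recombination_rate=RECOMB_DEFAULT,
                random_seed=int(seeds[2 * k]))
            ts = msprime.sim_mutations(
                ts, rate=MUT_DEFAULT, random_seed=int(seeds[2 * k + 1]),
                model=msprime.BinaryMutationModel())
            G = ts.genotype_matrix()
            dos_parts.append((G[:, 0::2] + G[:, 1::2]).astype(np.int8).T)
            cm_parts.append(ts.sites_position * RECOMB_DEFAULT * 100.0 + off)
            off += clen * RECOMB_DEFAULT * 100.0
        dos = np.concatenate(dos_parts, axis=1)
        cm = np.concatenate(cm_parts)
        keep = prune_mask(dos, cm, np.full(len(cm), ci + 1), r2,
                          window_cm=1e9)
        total += int(keep.sum())
        if verbose:
            print(f"  chr{ci + 1}: {len(cm)} sites -> {int(keep.sum())} "
                  f"kept", flush=True)
    return total
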