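"""Exact full-likelihood oracle for small pedigrees at independent loci.

Brute-force enumeration of all members' true genotypes: tractable for
pedigrees of up to ~8 individuals, and only valid when loci are unlinked
(the per-locus likelihoods factorize).  This is a verification tool for the
composite-likelihood approximation, not an inference engine; no general
peeling algorithm is provided.
"""
from __future__ import annotations

from itertools import product

import numpy as np

from .hmm import GenotypeMatrix, error_channel, hwe_genotype_probs
from .pedigree import Pedigree


def _transmission_prob(p: float) -> np.ndarray:
    """T[gm, gf, gc]: child genotype given both parents (Mendelian)."""
    # allele transmitted by a parent with genotype g: P(alt) = g / 2
    t = np.array([0.0, 0.5, 1.0])
    T = np.zeros((3, 3, 3))
    for gm in range(3):
        for gf in range(3):
            pa, pb = t[gm], t[gf]
            T[gm, gf, 0] = (1 - pa) * (1 - pb)
            T[gm, gf, 1] = pa * (1 - pb) + (1 - pa) * pb
            T[gm, gf, 2] = pa * pb
    return T


def _single_parent_prob(p: float) -> np.ndarray:
    """S[gp, gc]: child genotype given one parent; the other gamete is a
    population draw with alt frequency p."""
    t = np.array([0.0, 0.5, 1.0])
    S = np.zeros((3, 3))
    for gp in range(3):
        pa = t[gp]
        S[gp, 0] = (1 - pa) * (1 - p)
        S[gp, 1] = pa * (1 - p) + (1 - pa) * p
        S[gp, 2] = pa * p
    return S


def full_loglik_unlinked(ped: Pedigree, gm: GenotypeMatrix) -> float:
    """Exact log P(X | pedigree) at independent loci by enumerating every
    member's true genotype (cost 3^N per locus)."""
    nodes = _topo_order(ped)
    N = len(nodes)
    if N > 10:
        raise ValueError("oracle limited to small pedigrees (<= 10 members)")
    idx = {v: i for i, v in enumerate(nodes)}
    M = error_channel(gm.error_rate)
    L = gm.L
    obs = {s: np.asarray(gm.genotypes[gm.ids.index(s)]) for s in ped.sampled
           if s in ped.parents}

    hwe = hwe_genotype_probs(gm.freqs)  # (L, 3)
    T = _transmission_prob(0.0)  # Mendelian: frequency-free
    # per-locus single-parent tables: (L, 3, 3)
    t = np.array([0.0, 0.5, 1.0])
    p = gm.freqs
    S = np.zeros((L, 3, 3))
    for gp in range(3):
        S[:, gp, 0] = (1 - t[gp]) * (1 - p)
        S[:, gp, 1] = t[gp] * (1 - p) + (1 - t[gp]) * p
        S[:, gp, 2] = t[gp] * p

    acc = np.zeros(L)
    for assign in product(range(3), repeat=N):
        w = np.ones(L)
        for v in nodes:
            g = assign[idx[v]]
            ps = ped.parents[v]
            if len(ps) == 0:
                w = w * hwe[:, g]
            elif len(ps) == 1:
                w = w * S[:, assign[idx[ps[0]]], g]
            else:
                w = w * T[assign[idx[ps[0]]], assign[idx[ps[1]]], g]
            if v in obs:
                o = obs[v]
                m = o >= 0
                w[m] *= M[g, o[m]]
        acc += w
    return float(np.log(acc).sum())


def _topo_order(ped: Pedigree) -> list:
    out, seen = [], set()

    def visit(v):
        if v in seen:
            return
        seen.add(v)
        for p in ped.parents[v]:
            visit(p)
        out.append(v)

    for v in sorted(ped.parents, key=str):
        visit(v)
    return out
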