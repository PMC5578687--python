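"""Pairwise genotype likelihoods under an IBD hidden Markov model.

For each pair of individuals and each candidate relationship class the
likelihood P(X_i, X_j | R) is computed by a forward pass along the genome.
The hidden state is the number of allele pairs shared identical by descent
(0, 1 or 2); its stationary distribution is the relationship's Cotterman
coefficients (k0, k1, k2) and IBD tracts break up at a rate proportional to
the total meiosis count m = u + d per Morgan (so more distant relatives have
shorter shared segments).  Emissions assume Hardy-Weinberg equilibrium and
inter-locus independence given the IBD state (markers are LD-pruned before
inference), with an independent per-allele genotyping-error channel.

Two transition families are used:

* classes with k2 = 0: a two-state chain on {IBD0, IBD1}; the rate of
  leaving IBD1 is m per Morgan (segment lengths ~ Exp(m)) - every crossover
  on the connecting path breaks sharing - with the re-entry rate set by
  stationarity.  One exception: for two-ancestor (couple) classes with one
  member a child of the couple itself (avuncular, grand-avuncular, ...),
  a crossover in the couple-child's meiosis can hand sharing over from one
  couple haplotype to the other, merging abutting tracts; the exact
  first-moment rate is m - 1/2, which matches gene-dropped data to under
  one percent.
* full siblings: the product of two independent parental two-state chains,
  each with symmetric switch rate 2 per Morgan, aggregated by IBD count.

Both are proper continuous-time Markov chains, so Chapman-Kolmogorov holds
and distance 0 / infinity give the identity / stationary rows.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numba import njit

from .relationships import (
    Relationship,
    enumerate_relationships,
    k_coefficients,
    lik_key,
)

MISSING = -1


# --------------------------------------------------------------------- data
@dataclass
class GenotypeMatrix:
    """n x L matrix of alt-allele dosages with frequencies and a genetic map.

    ``genotypes`` uses {0, 1, 2} dosages with -1 for missing.  ``freqs`` are
    the population frequencies of the counted allele, strictly inside (0, 1).
    ``cm`` holds genetic positions (centimorgans), nondecreasing within each
    chromosome; ``chrom`` the per-locus chromosome labels.
    """

    genotypes: np.ndarray
    freqs: np.ndarray
    cm: np.ndarray
    chrom: np.ndarray
    error_rate: float = 0.01
    ids: Optional[list] = None
    sex: dict = field(default_factory=dict)
    age: dict = field(default_factory=dict)
    bp: Optional[np.ndarray] = None

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        self.cm = np.asarray(self.cm, dtype=np.float64)
        self.chrom = np.asarray(self.chrom)
        if self.ids is None:
            self.ids = list(range(self.genotypes.shape[0]))
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D (individuals x loci)")
        L = self.genotypes.shape[1]
        if not (len(self.freqs) == len(self.cm) == len(self.chrom) == L):
            raise ValueError("freqs / map / chrom lengths must match loci")
        if np.any((self.freqs <= 0) | (self.freqs >= 1)):
            raise ValueError("allele frequencies must lie strictly in (0, 1)")
        for c in np.unique(self.chrom):
            pos = self.cm[self.chrom == c]
            if np.any(np.diff(pos) < 0):
                raise ValueError(f"genetic positions decrease on chromosome {c}")

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    @property
    def L(self) -> int:
        return self.genotypes.shape[1]

    def subset_loci(self, mask) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            self.genotypes[:, mask], self.freqs[mask], self.cm[mask],
            self.chrom[mask], self.error_rate, list(self.ids),
            dict(self.sex), dict(self.age),
            None if self.bp is None else self.bp[mask],
        )

    def interlocus_morgans(self) -> np.ndarray:
        """Distance in Morgans from the previous locus; negative marks a
        chromosome start (the HMM chain restarts there)."""
        d = np.empty(self.L)
        d[0] = -1.0
        if self.L > 1:
            same = self.chrom[1:] == self.chrom[:-1]
            d[1:] = np.where(same, (self.cm[1:] - self.cm[:-1]) / 100.0, -1.0)
        return d


def estimate_frequencies(genotypes: np.ndarray, pseudocount: float = 0.5) -> np.ndarray:
    """Sample allele frequencies with a pseudo-count keeping them off 0/1."""
    g = np.asarray(genotypes)
    obs = g >= 0
    alt = np.where(obs, g, 0).sum(axis=0)
    tot = 2 * obs.sum(axis=0)
    return (alt + pseudocount) / (tot + 2 * pseudocount)


# ----------------------------------------------------------------- emissions
def error_channel(error_rate: float) -> np.ndarray:
    """3x3 matrix M[true, observed] for independent per-allele flips."""
    e = float(error_rate)
    return np.array([
        [(1 - e) ** 2, 2 * e * (1 - e), e ** 2],
        [e * (1 - e), (1 - e) ** 2 + e ** 2, e * (1 - e)],
        [e ** 2, 2 * e * (1 - e), (1 - e) ** 2],
    ])


def hwe_genotype_probs(freqs: np.ndarray) -> np.ndarray:
    p = np.asarray(freqs, dtype=np.float64)
    q = 1.0 - p
    return np.stack([q * q, 2 * p * q, p * p], axis=-1)


def emission_tables(freqs: np.ndarray, error_rate: float) -> np.ndarray:
    """Array (L, 3, 3, 3): [locus, IBD state, g_i, g_j] -> probability of the
    observed genotype pair, genotyping error included."""
    p = np.asarray(freqs, dtype=np.float64)
    hwe = hwe_genotype_probs(p)
    L = len(p)
    # IBD0: independent HWE draws
    s0 = np.einsum("li,lj->lij", hwe, hwe)
    # IBD1: one shared allele plus one free allele each
    one = 1.0 - p
    p1_ref = np.stack([one, p, np.zeros(L)], axis=1)   # shared allele = 0
    p1_alt = np.stack([np.zeros(L), one, p], axis=1)   # shared allele = 1
    s1 = (one[:, None, None] * np.einsum("li,lj->lij", p1_ref, p1_ref)
          + p[:, None, None] * np.einsum("li,lj->lij", p1_alt, p1_alt))
    # IBD2: identical true genotypes
    s2 = np.zeros((L, 3, 3))
    for g in range(3):
        s2[:, g, g] = hwe[:, g]
    true = np.stack([s0, s1, s2], axis=1)  # (L, 3, 3, 3)
    M = error_channel(error_rate)
    return np.einsum("ai,lsab,bj->lsij", M, true, M)


def emission_prob(g_i: int, g_j: int, ibd_state: int, p: float,
                  error_rate: float = 0.0) -> float:
    """Single-locus emission probability P(g_i, g_j | IBD state)."""
    if ibd_state not in (0, 1, 2):
        raise ValueError("ibd_state must be 0, 1 or 2")
    tab = emission_tables(np.array([p]), error_rate)
    return float(tab[0, ibd_state, g_i, g_j])


def marginal_loglik(genos_i: np.ndarray, freqs: np.ndarray,
                    error_rate: float = 0.0) -> float:
    """log P(X_i): Hardy-Weinberg with the genotyping-error channel, summed
    over non-missing loci (missing loci contribute 0)."""
    g = np.asarray(genos_i)
    p = np.asarray(freqs, dtype=np.float64)
    if len(g) != len(p):
        raise ValueError("genotype and frequency lengths differ")
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("allele frequencies must lie strictly in (0, 1)")
    hwe_obs = hwe_genotype_probs(p) @ error_channel(error_rate)
    obs = g >= 0
    return float(np.log(hwe_obs[obs, g[obs]]).sum())


# --------------------------------------------------------------- transitions
def _chain_params(key) -> tuple[np.ndarray, float, bool]:
    """(stationary pi, relaxation rate per Morgan, full-sib flag)."""
    if key == ("fs",):
        return np.array([0.25, 0.5, 0.25]), 4.0, True
    if key == ("self",):
        return np.array([0.0, 0.0, 1.0]), 0.0, False
    if key == ("unrelated",):
        return np.array([1.0, 0.0, 0.0]), 0.0, False
    _, m, a, cc = key
    k1 = a * 2.0 ** (-(m - 1))
    k0 = 1.0 - k1
    if k0 == 0.0:  # parent-offspring: IBD1 everywhere, degenerate chain
        return np.array([0.0, 1.0, 0.0]), 0.0, False
    # exact first-moment calibration of the tract-boundary process under
    # Haldane crossovers: single-ancestor paths break at every path
    # crossover (rate m), while couple-ancestor paths merge abutting tracts
    # at source handoffs in each couple-child's meiosis (rate m - c/2, with
    # c mosaic meioses: 1 if one member is the couple's own child, else 2)
    if a == 2 and cc == 1:
        leave = m - 0.5
    else:
        leave = float(m)
    return np.array([k0, k1, 0.0]), leave / k0, False


def transition_matrix(rel: Relationship, dist_cM: float) -> np.ndarray:
    """3x3 transition matrix over IBD states across ``dist_cM`` centimorgans.

    Raises for self and unrelated, whose likelihoods have closed forms and
    need no chain.
    """
    key = lik_key(rel)
    if key in (("self",), ("unrelated",)):
        raise ValueError(f"no HMM chain for {rel}: use the closed form")
    if dist_cM < 0:
        raise ValueError("distance must be nonnegative")
    d = dist_cM / 100.0
    if key == ("fs",):
        w = np.exp(-4.0 * d)
        same, diff = (1 + w) / 2.0, (1 - w) / 2.0
        return np.array([
            [same * same, 2 * same * diff, diff * diff],
            [same * diff, same * same + diff * diff, same * diff],
            [diff * diff, 2 * same * diff, same * same],
        ])
    pi, lam, _ = _chain_params(key)
    w = np.exp(-lam * d)
    return w * np.eye(3) + (1 - w) * np.tile(pi, (3, 1))


# ------------------------------------------------------------------- forward
@njit(cache=True)
def _forward(gi, gj, emis, hwe_obs, dist, pi0, pi1, pi2, lam, fs):  # pragma: no cover
    L = gi.shape[0]
    a0 = a1 = a2 = 0.0
    loglik = 0.0
    for l in range(L):
        d = dist[l]
        if d < 0.0:
            b0, b1, b2 = pi0, pi1, pi2
        elif fs:
            w = np.exp(-4.0 * d)
            s = (1.0 + w) / 2.0
            f = (1.0 - w) / 2.0
            b0 = a0 * s * s + a1 * s * f + a2 * f * f
            b1 = a0 * 2 * s * f + a1 * (s * s + f * f) + a2 * 2 * s * f
            b2 = a0 * f * f + a1 * s * f + a2 * s * s
        else:
            w = np.exp(-lam * d)
            tot = a0 + a1 + a2
            b0 = w * a0 + (1.0 - w) * tot * pi0
            b1 = w * a1 + (1.0 - w) * tot * pi1
            b2 = w * a2 + (1.0 - w) * tot * pi2
        x = gi[l]
        y = gj[l]
        if x >= 0 and y >= 0:
            e0 = emis[l, 0, x, y]
            e1 = emis[l, 1, x, y]
            e2 = emis[l, 2, x, y]
        elif x >= 0:
            e0 = e1 = e2 = hwe_obs[l, x]
        elif y >= 0:
            e0 = e1 = e2 = hwe_obs[l, y]
        else:
            e0 = e1 = e2 = 1.0
        a0 = b0 * e0
        a1 = b1 * e1
        a2 = b2 * e2
        c = a0 + a1 + a2
        if c <= 0.0:  # impossible genotype pair under this relationship
            return -np.inf
        loglik += np.log(c)
        a0 /= c
        a1 /= c
        a2 /= c
    return loglik


def pair_loglik_hmm(genos_i: np.ndarray, genos_j: np.ndarray,
                    rel: Relationship, gm: GenotypeMatrix,
                    emis: Optional[np.ndarray] = None,
                    hwe_obs: Optional[np.ndarray] = None,
                    dist: Optional[np.ndarray] = None) -> float:
    """Forward-algorithm log P(X_i, X_j | R) along the genome.

    The chain restarts with the stationary distribution at every chromosome
    start; when all loci are unlinked this reduces exactly to the per-locus
    mixture sum_s k_s * emission(g_i, g_j, s).  Missing genotypes are
    marginalized.
    """
    if emis is None:
        emis = emission_tables(gm.freqs, gm.error_rate)
    if hwe_obs is None:
        hwe_obs = hwe_genotype_probs(gm.freqs) @ error_channel(gm.error_rate)
    if dist is None:
        dist = gm.interlocus_morgans()
    pi, lam, fs = _chain_params(lik_key(rel))
    return float(_forward(
        np.ascontiguousarray(genos_i, dtype=np.int8),
        np.ascontiguousarray(genos_j, dtype=np.int8),
        emis, hwe_obs, dist, pi[0], pi[1], pi[2], lam, fs,
    ))


# --------------------------------------------------------------------- table
class PairLikelihoodTable:
    """Precomputed pairwise log-likelihoods for every pair and every
    relationship likelihood class, plus per-individual marginals.

    The table is indexed by the likelihood-equivalence class of a
    relationship (see :func:`kinforest.relationships.lik_key`); swapping the
    pair leaves the value unchanged because the chain and emissions are
    exchangeable.
    """

    def __init__(self, ids: list, marginal: np.ndarray, class_keys: list,
                 ll: np.ndarray):
        self.ids = list(ids)
        self.marginal = np.asarray(marginal, dtype=np.float64)
        self.class_keys = list(class_keys)
        self.ll = np.asarray(ll, dtype=np.float64)
        self.class_index = {k: i for i, k in enumerate(self.class_keys)}
        self.id_index = {s: i for i, s in enumerate(self.ids)}

    @property
    def n(self) -> int:
        return len(self.ids)

    def marginal_loglik(self, i) -> float:
        return float(self.marginal[self.id_index[i]])

    def pair_loglik(self, i, j, rel: Relationship) -> float:
        key = lik_key(rel)
        if key not in self.class_index:
            raise KeyError(f"relationship class {key} not in table")
        return float(self.ll[self.class_index[key],
                             self.id_index[i], self.id_index[j]])

    def save(self, path):
        np.savez(path, marginal=self.marginal, ll=self.ll,
                 ids=np.array([str(i) for i in self.ids], dtype=object),
                 class_keys=np.array([repr(k) for k in self.class_keys], dtype=object))


def build_table(gm: GenotypeMatrix,
                rels: Optional[Sequence[Relationship]] = None) -> PairLikelihoodTable:
    """Precompute the full pairwise table: O(n^2 s L).

    The result is deterministic given the inputs and independent of the
    evaluation order over pairs.
    """
    if rels is None:
        rels = enumerate_relationships()
    keys = []
    for r in rels:
        k = lik_key(r)
        if k not in keys:
            keys.append(k)
    if ("unrelated",) not in keys:
        keys.append(("unrelated",))
    n, L = gm.n, gm.L
    emis = emission_tables(gm.freqs, gm.error_rate)
    hwe_obs = hwe_genotype_probs(gm.freqs) @ error_channel(gm.error_rate)
    dist = gm.interlocus_morgans()
    genos = np.ascontiguousarray(gm.genotypes, dtype=np.int8)

    marg = np.empty(n)
    obs = genos >= 0
    logh = np.log(hwe_obs)
    for i in range(n):
        m = obs[i]
        marg[i] = logh[m, genos[i, m]].sum()

    ll = np.zeros((len(keys), n, n))
    for ci, key in enumerate(keys):
        if key == ("unrelated",):
            ll[ci] = marg[:, None] + marg[None, :]
            continue
        pi, lam, fs = _chain_params(key)
        for i in range(n):
            for j in range(i + 1, n):
                v = _forward(genos[i], genos[j], emis, hwe_obs, dist,
                             pi[0], pi[1], pi[2], lam, fs)
                ll[ci, i, j] = v
                ll[ci, j, i] = v
    return PairLikelihoodTable(gm.ids, marg, keys, ll)


def table_cache_key(gm: GenotypeMatrix,
                    rels: Optional[Sequence[Relationship]] = None) -> str:
    """Content hash identifying a (data, relationship list) combination."""
    import hashlib

    h = hashlib.sha1()
    h.update(np.ascontiguousarray(gm.genotypes).tobytes())
    h.update(np.ascontiguousarray(gm.freqs).tobytes())
    h.update(np.ascontiguousarray(gm.cm).tobytes())
    h.update(str(list(gm.chrom)).encode())
    h.update(repr(gm.error_rate).encode())
    if rels is None:
        rels = enumerate_relationships()
    h.update(repr(sorted(repr(lik_key(r)) for r in rels)).encode())
    return h.hexdigest()


def load_or_build_table(gm: GenotypeMatrix, cache_dir=None,
                        rels: Optional[Sequence[Relationship]] = None
                        ) -> PairLikelihoodTable:
    """Build the pairwise table, reusing an on-disk cache keyed by the data
    hash and relationship list so repeated annealing runs skip the
    O(n^2 s L) precomputation."""
    import pickle
    from pathlib import Path

    if cache_dir is None:
        return build_table(gm, rels)
    cache = Path(cache_dir) / f"pairtable_{table_cache_key(gm, rels)}.pkl"
    if cache.exists():
        with open(cache, "rb") as fh:
            return pickle.load(fh)
    tbl = build_table(gm, rels)
    cache.parent.mkdir(parents=True, exist_ok=True)
    with open(cache, "wb") as fh:
        pickle.dump(tbl, fh)
    return tbl
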