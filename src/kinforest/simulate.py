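"""Synthetic-data generation: founder haplotypes, gene-dropping, genotyping
error, and LD pruning.

Two founder generators are provided.  The coalescent generator uses msprime
with human-like parameters (Ne = 10,000, recombination 1.3e-8 per bp,
mutation 1.25e-8 per bp over the 22 autosome lengths) and produces realistic
site-frequency spectra and background LD.  The fast generator draws
linkage-equilibrium haplotypes at a supplied frequency spectrum on an
evenly spaced genetic map; it is the default for desk-scale pipelines and
unit tests, where background LD is assumed to have been removed by pruning
anyway.

Gene-dropping transmits recombinant gametes down a truth pedigree with
crossovers as a Poisson process on the centimorgan map (Haldane, no
interference).  Founder-haplotype origin labels are carried along so the
realized IBD state of any pair is known exactly.  Genotyping error flips
each of the two alleles of a genotype independently.  LD pruning is greedy
left-to-right: a marker is kept iff its squared genotype correlation with
every already-kept marker within a trailing genetic window stays at or
below the threshold (computed on a founder panel, not on the related
samples themselves).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit

from .hmm import GenotypeMatrix, estimate_frequencies
from .pedigree import Pedigree
from .scenarios import scenario_pedigree

# GRCh37 autosome lengths (bp), chromosomes 1..22
HUMAN_AUTOSOME_BP = [
    249250621, 243199373, 198022430, 191154276, 180915260, 171115067,
    159138663, 146364022, 141213431, 135534747, 135006516, 133851895,
    115169878, 107349540, 102531392, 90354753, 81195210, 78077248,
    59128983, 63025520, 48129895, 51304566,
]

NE_DEFAULT = 10_000
RECOMB_DEFAULT = 1.3e-8
MUT_DEFAULT = 1.25e-8


# ------------------------------------------------------------------ genomes
@dataclass
class GenomeSpec:
    """Marker scaffold: genetic positions (cM) and chromosome labels."""

    cm: np.ndarray
    chrom: np.ndarray

    @property
    def L(self) -> int:
        return len(self.cm)


def desk_genome(n_markers: int = 3000, n_chrom: int = 22,
                cm_per_chrom: float = 150.0) -> GenomeSpec:
    """Evenly spaced marker scaffold used for scaled-down pipelines."""
    per = np.full(n_chrom, n_markers // n_chrom)
    per[: n_markers % n_chrom] += 1
    cm, chrom = [], []
    for c in range(n_chrom):
        m = per[c]
        cm.extend(np.linspace(0, cm_per_chrom, m + 2)[1:-1])
        chrom.extend([c + 1] * m)
    return GenomeSpec(np.array(cm), np.array(chrom))


def draw_frequency_spectrum(L: int, rng: np.random.Generator,
                            low: float = 0.05, high: float = 0.95) -> np.ndarray:
    """Array-like post-QC allele-frequency spectrum: Beta(0.8, 0.8) truncated
    away from fixation."""
    f = rng.beta(0.8, 0.8, size=L)
    return np.clip(f, low, high)


def simulate_founder_haplotypes(n_hap: int, freqs: np.ndarray,
                                rng: np.random.Generator) -> np.ndarray:
    """Linkage-equilibrium founder haplotypes at the given frequencies."""
    return (rng.random((n_hap, len(freqs))) < freqs[None, :]).astype(np.int8)


def simulate_founders(n_founders: int, genome: Optional[GenomeSpec] = None,
                      seed: int = 0, freqs: Optional[np.ndarray] = None):
    """Fast founder generator: returns (haplotypes (2n, L), freqs, genome).

    ``freqs`` defaults to a draw from the truncated-Beta spectrum.  Same
    seed, same output.
    """
    rng = np.random.Generator(np.random.PCG64(seed))
    if genome is None:
        genome = desk_genome()
    if freqs is None:
        freqs = draw_frequency_spectrum(genome.L, rng)
    haps = simulate_founder_haplotypes(2 * n_founders, freqs, rng)
    return haps, np.asarray(freqs), genome


def simulate_founders_msprime(n_founders: int,
                              chrom_bp=None,
                              Ne: float = NE_DEFAULT,
                              recomb: float = RECOMB_DEFAULT,
                              mut: float = MUT_DEFAULT,
                              seed: int = 0):
    """Coalescent founder haplotypes, one chromosome at a time.

    Yields (haplotypes (2n, L_c) int8, cm positions, chromosome index) to
    keep genome-scale runs within memory.
    """
    import msprime

    if chrom_bp is None:
        chrom_bp = HUMAN_AUTOSOME_BP
    rng = np.random.SeedSequence(seed)
    seeds = rng.generate_state(2 * len(chrom_bp)) % (2 ** 31 - 1) + 1
    for k, length in enumerate(chrom_bp):
        ts = msprime.sim_ancestry(
            samples=n_founders, population_size=Ne, sequence_length=length,
            recombination_rate=recomb, random_seed=int(seeds[2 * k]),
        )
        ts = msprime.sim_mutations(ts, rate=mut, random_seed=int(seeds[2 * k + 1]),
                                   model=msprime.BinaryMutationModel())
        haps = ts.genotype_matrix().T.astype(np.int8)  # (2n, L)
        pos = ts.sites_position
        cm = pos * recomb * 100.0
        yield haps, cm, k + 1


# --------------------------------------------------------------- gene drop
def _meiosis(hapA, hapB, origA, origB, cm, chrom_starts, rng):
    """One recombinant gamete (Haldane crossovers on the cM map)."""
    L = len(cm)
    phase = np.empty(L, dtype=np.int8)
    for s, e in chrom_starts:
        span = cm[e - 1] - cm[s]
        k = rng.poisson(span / 100.0)
        cur = int(rng.integers(2))
        if k == 0:
            phase[s:e] = cur
        else:
            bps = np.sort(rng.uniform(cm[s], cm[e - 1], size=k))
            idx = np.searchsorted(bps, cm[s:e], side="right")
            phase[s:e] = (cur + idx) % 2
    gam = np.where(phase == 0, hapA, hapB)
    org = np.where(phase == 0, origA, origB)
    return gam, org


@dataclass
class DropResult:
    """Gene-drop output: genotypes of sampled individuals plus per-member
    haplotypes and founder-origin labels (for exact realized-IBD checks)."""

    gm: GenotypeMatrix
    haplotypes: dict
    origins: dict

    def ibd_states(self, i, j) -> np.ndarray:
        oi, oj = self.origins[i], self.origins[j]
        m0 = (oi[0] == oj[0]) | (oi[0] == oj[1])
        m1 = (oi[1] == oj[0]) | (oi[1] == oj[1])
        return m0.astype(np.int8) + m1.astype(np.int8)


def gene_drop(truth: Pedigree, founder_haps: np.ndarray, freqs: np.ndarray,
              genome: GenomeSpec, seed: int = 0,
              error_rate: float = 0.0) -> DropResult:
    """Drop founder haplotypes down the truth pedigree.

    Every parentless individual consumes two pool haplotypes; a single-parent
    individual receives one recombinant gamete and one fresh pool haplotype
    (its unrepresented parent is an unrelated population member).  Raises if
    the pedigree is invalid or the pool is too small.
    """
    viol = truth.validate()
    if viol:
        raise ValueError(f"invalid truth pedigree: {viol[:3]}")
    rng = np.random.Generator(np.random.PCG64(seed))
    order = _topo(truth)
    chrom_starts = _chrom_ranges(genome.chrom)
    cm = genome.cm
    haps: dict = {}
    orig: dict = {}
    cursor = 0

    def fresh():
        nonlocal cursor
        if cursor >= founder_haps.shape[0]:
            raise ValueError("founder haplotype pool exhausted")
        h = founder_haps[cursor]
        o = np.full(len(cm), cursor, dtype=np.int32)
        cursor += 1
        return h.copy(), o

    for v in order:
        ps = truth.parents[v]
        gams = []
        for p in ps:
            hA, hB = haps[p]
            oA, oB = orig[p]
            gams.append(_meiosis(hA, hB, oA, oB, cm, chrom_starts, rng))
        while len(gams) < 2:
            gams.append(fresh())
        haps[v] = (gams[0][0], gams[1][0])
        orig[v] = (gams[0][1], gams[1][1])

    ids = sorted(truth.sampled, key=str)
    G = np.array([haps[s][0] + haps[s][1] for s in ids], dtype=np.int8)
    gm = GenotypeMatrix(G, freqs, cm, genome.chrom, error_rate=error_rate,
                        ids=ids, sex={s: truth.sex[s] for s in ids if s in truth.sex})
    out = DropResult(gm, haps, orig)
    if error_rate > 0:
        out = DropResult(add_genotyping_error(gm, error_rate,
                                              rng.integers(2 ** 31)),
                         haps, orig)
    return out


def _topo(ped: Pedigree) -> list:
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


def _chrom_ranges(chrom: np.ndarray) -> list[tuple[int, int]]:
    ranges = []
    s = 0
    for i in range(1, len(chrom) + 1):
        if i == len(chrom) or chrom[i] != chrom[s]:
            ranges.append((s, i))
            s = i
    return ranges


# ---------------------------------------------------------- genotyping error
def add_genotyping_error(gm: GenotypeMatrix, rate: float,
                         seed: int = 0) -> GenotypeMatrix:
    """Flip each of the two alleles of every genotype independently with the
    given probability (so 0 <-> 2 needs two flips).  Missing stays missing."""
    if not 0 <= rate <= 1:
        raise ValueError("error rate must be in [0, 1]")
    rng = np.random.Generator(np.random.PCG64(seed))
    g = gm.genotypes
    a1 = (g >= 1).astype(np.int8)
    a2 = (g >= 2).astype(np.int8)
    f1 = rng.random(g.shape) < rate
    f2 = rng.random(g.shape) < rate
    out = (a1 ^ f1) + (a2 ^ f2)
    out = np.where(g < 0, g, out).astype(np.int8)
    return GenotypeMatrix(out, gm.freqs, gm.cm, gm.chrom, gm.error_rate,
                          list(gm.ids), dict(gm.sex), dict(gm.age), gm.bp)


# ------------------------------------------------------------------ pruning
@njit(cache=True)
def _prune_kernel(ZT, cm, chrom, r2max, window_cm):  # pragma: no cover
    # ZT is (L, n): each marker's standardized dosage vector is contiguous
    L, n = ZT.shape
    keep = np.zeros(L, dtype=np.bool_)
    kept = np.empty(L, dtype=np.int64)
    nk = 0
    for l in range(L):
        ok = True
        for t in range(nk - 1, -1, -1):
            k = kept[t]
            if chrom[k] != chrom[l] or cm[l] - cm[k] > window_cm:
                break
            r = 0.0
            for i in range(n):
                r += ZT[k, i] * ZT[l, i]
            r /= n
            if r * r > r2max:
                ok = False
                break
        if ok:
            keep[l] = True
            kept[nk] = l
            nk += 1
    return keep


def ld_prune(gm: GenotypeMatrix, r2_threshold: float = 0.05,
             window_cm: float = 0.5,
             panel: Optional[np.ndarray] = None) -> GenotypeMatrix:
    """Greedy windowed LD pruning.

    Scans markers left to right and keeps a marker iff its squared genotype
    correlation with every kept marker in the trailing ``window_cm`` window
    (same chromosome) is <= the threshold; of an offending pair the earlier
    marker survives.  ``panel`` supplies the genotype matrix (individuals x
    loci) used for the correlations - typically unrelated founders - and
    defaults to the matrix being pruned.  The output marker set is a
    subsequence of the input.
    """
    if not 0 < r2_threshold <= 1:
        raise ValueError("r2 threshold must be in (0, 1]")
    X = gm.genotypes if panel is None else np.asarray(panel)
    keep = _prune_kernel(_standardized_t(X), gm.cm,
                         _chrom_codes(gm.chrom), r2_threshold, window_cm)
    return gm.subset_loci(keep)


def prune_mask(X: np.ndarray, cm: np.ndarray, chrom: np.ndarray,
               r2_threshold: float = 0.05, window_cm: float = 0.5) -> np.ndarray:
    """Pruning mask for a raw dosage matrix (no GenotypeMatrix wrapper)."""
    return _prune_kernel(_standardized_t(np.asarray(X)),
                         np.asarray(cm, float), _chrom_codes(chrom),
                         r2_threshold, window_cm)


def _standardized_t(X) -> np.ndarray:
    """Marker-major standardized dosages (L, n) float32."""
    X = X.astype(np.float32)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = np.float32(np.inf)
    return np.ascontiguousarray(((X - mu) / sd).T)


def _chrom_codes(chrom) -> np.ndarray:
    _, codes = np.unique(np.asarray(chrom), return_inverse=True)
    return codes.astype(np.int64)


# ---------------------------------------------------------------- scenarios
@dataclass
class ScenarioData:
    truth: Pedigree
    gm: GenotypeMatrix            # pruned, error-added, panel frequencies
    panel: np.ndarray             # founder-panel dosages on the same loci
    meta: dict = field(default_factory=dict)


def make_scenario(name: str, seed: int = 0, scale: str = "desk",
                  n_markers: int = 3000, error_rate: float = 0.01,
                  r2: float = 0.05, window_cm: float = 0.5,
                  panel_size: int = 100) -> ScenarioData:
    """End-to-end fixture for one validation scenario.

    founders -> gene-drop through the frozen truth pedigree -> per-allele
    genotyping error -> LD pruning at ``r2`` based on a ``panel_size``-founder
    panel, whose pseudo-counted allele frequencies are attached for
    inference.  Sampled sexes are declared; ages are withheld.
    """
    truth = scenario_pedigree(name)
    ss = np.random.SeedSequence(seed)
    s_founder, s_drop, s_panel_err, s_err = [int(x) for x in
                                             ss.generate_state(4) % (2 ** 31)]
    if scale != "desk":
        raise NotImplementedError(
            "full autosome scenarios are assembled via simulate_founders_msprime")
    genome = desk_genome(n_markers)
    need = _pool_requirement(truth) + 2 * panel_size
    haps, freqs, genome = simulate_founders(need // 2 + 1, genome,
                                            seed=s_founder)
    panel_haps = haps[: 2 * panel_size]
    pool = haps[2 * panel_size:]
    panel = (panel_haps[0::2] + panel_haps[1::2]).astype(np.int8)

    drop = gene_drop(truth, pool, freqs, genome, seed=s_drop)
    gm = add_genotyping_error(drop.gm, error_rate, seed=s_err)
    panel_gm = GenotypeMatrix(panel, freqs, genome.cm, genome.chrom,
                              error_rate=error_rate)
    panel_gm = add_genotyping_error(panel_gm, error_rate, seed=s_panel_err)

    freq_est = estimate_frequencies(panel_gm.genotypes)
    # the panel carries the same per-allele error channel as the samples, so
    # its raw allele frequency estimates target p*(1-e) + (1-p)*e; invert
    freq_est = np.clip((freq_est - error_rate) / (1 - 2 * error_rate),
                       1e-4, 1 - 1e-4)
    ok = (freq_est > 1e-4) & (freq_est < 1 - 1e-4)
    gm = GenotypeMatrix(gm.genotypes, freq_est, gm.cm, gm.chrom,
                        error_rate=error_rate, ids=gm.ids, sex=gm.sex)
    gm = gm.subset_loci(ok)
    panel_d = panel_gm.genotypes[:, ok]
    keep = prune_mask(panel_d, gm.cm, gm.chrom, r2, window_cm)
    gm = gm.subset_loci(keep)
    return ScenarioData(truth=truth, gm=gm, panel=panel_d[:, keep],
                        meta={"scenario": name, "seed": seed,
                              "n_markers": int(gm.L), "r2": r2,
                              "drop": drop})


def _pool_requirement(ped: Pedigree) -> int:
    need = 0
    for v in ped.parents:
        need += 2 - len(ped.parents[v])
    return need
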