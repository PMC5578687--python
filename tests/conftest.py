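import numpy as np
import pytest

from kinforest.hmm import GenotypeMatrix
from kinforest.pedigree import FEMALE, MALE, Pedigree


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(12345))


@pytest.fixture
def nuclear_family():
    """Two founders and four children, everyone sampled."""
    parents = {"M": (), "F": (), "C1": ("M", "F"), "C2": ("M", "F"),
               "C3": ("M", "F"), "C4": ("M", "F")}
    sex = {"M": MALE, "F": FEMALE}
    return Pedigree(parents=parents, sex=sex,
                    sampled=["M", "F", "C1", "C2", "C3", "C4"])


@pytest.fixture
def half_cousin_mating():
    """Half first cousins producing a child: an inbreeding loop (7 nodes)."""
    parents = {
        "G": (),                 # shared grandparent
        "P1": ("G",), "P2": ("G",),
        "A": ("P1",), "B": ("P2",),
        "K": ("A", "B"),         # child of half first cousins
    }
    return Pedigree(parents=parents, sampled=["K"])


def unlinked_genome(L, freqs=None, seed=0):
    """Each locus on its own chromosome: fully unlinked."""
    rng = np.random.Generator(np.random.PCG64(seed))
    if freqs is None:
        freqs = np.clip(rng.beta(0.8, 0.8, L), 0.05, 0.95)
    return freqs, np.zeros(L), np.arange(L)


def random_genotypes(n, freqs, seed=0, error_rate=0.0):
    rng = np.random.Generator(np.random.PCG64(seed))
    L = len(freqs)
    g = (rng.random((n, L)) < freqs).astype(np.int8) + \
        (rng.random((n, L)) < freqs).astype(np.int8)
    cm = np.zeros(L)
    chrom = np.arange(L)
    return GenotypeMatrix(g, freqs, cm, chrom, error_rate=error_rate)
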