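"""Frozen truth pedigrees for the four validation scenarios.

The published study describes four family structures (A-D) by their node
counts, sampling patterns, generation spans and the range of sampled
pairwise kinships; the drawings do not pin down every edge.  The topologies
below are frozen reference structures satisfying every stated constraint:

* A: 10 singletons plus a 45-member, 5-generation family with 10 sampled
  and 35 missing members; sampled kinships span 1/4 (full sibs) to 1/256
  (third cousins).
* B: 4 singletons plus four family clusters of 15-18 members, 4 sampled
  each, spanning multiple generations with kinships from 1/4 to 1/256.
* C: 9 singletons plus a 16-member, 5-generation pedigree with 9 sampled
  and 7 missing members in which every sampled family member has a sampled
  parent or child.
* D: a harder variant of C in which one sampled cluster connects to the
  rest only through an avuncular relationship (its linking parent and
  grandparents are unsampled).

Sampled individuals have declared sexes (known at inference time); latent
members carry sexes only for internal consistency of the truth graphs.
"""
from __future__ import annotations

from .pedigree import FEMALE, MALE, Pedigree
from .relationships import kinship

__all__ = ["scenario_pedigree", "SCENARIOS"]


def _with_singletons(parents, sex, sampled, n_singletons):
    for k in range(1, n_singletons + 1):
        sid = f"U{k}"
        parents[sid] = ()
        sex[sid] = MALE if k % 2 else FEMALE
        sampled.append(sid)
    return Pedigree(parents=parents, sex=sex, sampled=sampled)


def _scenario_c() -> Pedigree:
    parents = {
        "S1": ("F1", "F2"), "B2": ("F1", "F2"),
        "S2": ("S1", "C1"), "S3": ("S1", "C1"),
        "M1": ("B2",),
        "S4": ("M1",),
        "S5": ("S2", "E1"), "S6": ("S2", "E1"),
        "S7": ("S4",),
        "S8": ("S5", "H1"), "S9": ("S5", "H1"),
    }
    sex = {"F1": MALE, "F2": FEMALE, "S1": MALE, "C1": FEMALE, "B2": FEMALE,
           "M1": MALE, "S2": MALE, "S3": FEMALE, "E1": FEMALE, "S4": FEMALE,
           "S5": MALE, "S6": FEMALE, "S7": MALE, "H1": FEMALE, "S8": MALE,
           "S9": FEMALE}
    sampled = [f"S{i}" for i in range(1, 10)]
    return _with_singletons(parents, sex, sampled, 9)


def _scenario_d() -> Pedigree:
    # like C, but the parent (L2) and grandparents (L1, C1) linking the
    # {S5, S6, S8, S9} cluster are unsampled: its closest sampled relative
    # is the aunt S3 (avuncular).
    parents = {
        "L1": ("F1", "F2"), "B2": ("F1", "F2"),
        "L2": ("L1", "C1"), "S3": ("L1", "C1"),
        "S5": ("L2", "E1"), "S6": ("L2", "E1"),
        "S10": ("S3",),
        "S11": ("S10",),
        "M1": ("B2",),
        "S4": ("M1",),
        "S7": ("S4",),
        "S8": ("S5", "H1"), "S9": ("S5", "H1"),
    }
    sex = {"F1": MALE, "F2": FEMALE, "L1": MALE, "C1": FEMALE, "B2": FEMALE,
           "L2": MALE, "S3": FEMALE, "E1": FEMALE, "M1": MALE,
           "S4": FEMALE, "S5": MALE, "S6": FEMALE, "S7": MALE, "H1": FEMALE,
           "S8": MALE, "S9": FEMALE, "S10": MALE, "S11": FEMALE}
    sampled = ["S3", "S4", "S5", "S6", "S7", "S8", "S9", "S10", "S11"]
    return _with_singletons(parents, sex, sampled, 9)


def _deep_branch(parents, sex, tag):
    """A 4-generation lineage hanging off founder couple A/B (14 nodes)."""
    c, d = f"C{tag}", f"D{tag}"
    parents[c] = ("A", "B")
    parents[d] = ()
    sex[c] = MALE
    sex[d] = FEMALE
    e1, e2, f1, f2 = f"E{tag}1", f"E{tag}2", f"F{tag}1", f"F{tag}2"
    parents[e1] = (c, d)
    parents[e2] = (c, d)
    parents[f1] = ()
    parents[f2] = ()
    sex.update({e1: MALE, e2: FEMALE, f1: FEMALE, f2: MALE})
    g1, g2, g3 = f"G{tag}1", f"G{tag}2", f"G{tag}3"
    parents[g1] = (e1, f1)
    parents[g2] = (e1, f1)
    parents[g3] = (e2, f2)
    sex.update({g1: MALE, g2: FEMALE, g3: MALE})
    h1, h2 = f"H{tag}1", f"H{tag}2"
    parents[h1] = ()
    parents[h2] = ()
    sex.update({h1: FEMALE, h2: FEMALE})
    k1, k2, k3 = f"K{tag}1", f"K{tag}2", f"K{tag}3"
    parents[k1] = (g1, h1)
    parents[k2] = (g1, h1)
    parents[k3] = (g3, h2)
    sex.update({k1: MALE, k2: FEMALE, k3: MALE})


def _scenario_a() -> Pedigree:
    parents = {"A": (), "B": ()}
    sex = {"A": MALE, "B": FEMALE}
    for tag in ("1", "2", "3"):
        _deep_branch(parents, sex, tag)
    # one extra fifth-generation child to reach 45 members
    parents["K14"] = ("G11", "H11")
    sex["K14"] = FEMALE
    sampled = ["G11", "K11", "K12", "K13",
               "G21", "K21", "K22", "K23",
               "K31", "K33"]
    return _with_singletons(parents, sex, sampled, 10)


def _cluster_b(tag: str, size: int, parents, sex, sampled):
    """One family cluster for scenario B: two lineages from a founder
    couple; ``size`` in 15..18 controls optional spouses/siblings."""
    a, b = f"{tag}A", f"{tag}B"
    parents[a] = ()
    parents[b] = ()
    sex[a] = MALE
    sex[b] = FEMALE
    n = [a, b]

    def add(name, ps, sx):
        parents[f"{tag}{name}"] = tuple(f"{tag}{p}" for p in ps)
        sex[f"{tag}{name}"] = sx
        n.append(f"{tag}{name}")

    add("C1", ("A", "B"), MALE)
    add("C2", ("A", "B"), FEMALE)
    add("D1", (), FEMALE)
    add("D2", (), MALE)
    add("E1", ("C1", "D1"), MALE)
    add("E2", ("C2", "D2"), FEMALE)
    add("F1", (), FEMALE)
    add("F2", (), MALE)
    add("G1", ("E1", "F1"), MALE)
    add("G2", ("E2", "F2"), FEMALE)
    add("H1", (), FEMALE)
    add("K1", ("G1", "H1"), MALE)
    add("K2", ("G2",), FEMALE)  # single known parent
    # 15 members so far; optional extras
    if size >= 16:
        add("K1b", ("G1", "H1"), FEMALE)
    if size >= 17:
        add("E1b", ("C1", "D1"), FEMALE)
    if size >= 18:
        add("G1b", ("E1", "F1"), FEMALE)
    assert len(n) == size
    sampled.extend([f"{tag}G1", f"{tag}K1", f"{tag}K2", f"{tag}E2"])


def _scenario_b() -> Pedigree:
    parents: dict = {}
    sex: dict = {}
    sampled: list = []
    for tag, size in (("P", 15), ("Q", 16), ("R", 17), ("S", 18)):
        _cluster_b(tag, size, parents, sex, sampled)
    return _with_singletons(parents, sex, sampled, 4)


SCENARIOS = {"A": _scenario_a, "B": _scenario_b, "C": _scenario_c,
             "D": _scenario_d}


def scenario_pedigree(name: str) -> Pedigree:
    """The frozen truth pedigree for scenario ``name`` in {A, B, C, D},
    singletons included."""
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}")
    return SCENARIOS[name]()
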