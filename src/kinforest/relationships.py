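"""Outbred pairwise relationship classes and their IBD-sharing coefficients.

A pairwise relationship in an outbred pedigree is summarized by the number of
meioses from each individual up to the most recent common ancestor(s) (``u``
and ``d``) and the number of common ancestors at that level (``a``, 1 or 2).
Full siblings (u = d = 1, a = 2) are the only outbred class besides self with
a nonzero probability of sharing two alleles identical by descent.
"""
from __future__ import annotations

from dataclasses import dataclass

SELF = "self"
UNRELATED = "unrelated"
LINEAL_OR_COLLATERAL = "lineal_or_collateral"


@dataclass(frozen=True, order=True)
class Relationship:
    """A pairwise relationship class for outbred individuals.

    ``u`` is the number of meioses from the first individual up to the common
    ancestor(s), ``d`` the number from the second.  For lineal relationships
    (parent, grandparent, ...) exactly one of ``u``, ``d`` is zero and a = 1.
    """

    kind: str
    u: int = 0
    d: int = 0
    a: int = 0
    full_sib: bool = False

    @property
    def meioses(self) -> int:
        return self.u + self.d

    def swapped(self) -> "Relationship":
        """The same relationship seen from the other individual."""
        return Relationship(self.kind, self.d, self.u, self.a, self.full_sib)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if self.kind == SELF:
            return "self"
        if self.kind == UNRELATED:
            return "unrelated"
        if self.full_sib:
            return "full-sibs"
        return f"(u={self.u},d={self.d},a={self.a})"


def self_rel() -> Relationship:
    return Relationship(SELF)


def unrelated() -> Relationship:
    return Relationship(UNRELATED)


def rel(u: int, d: int, a: int) -> Relationship:
    """Build a lineal/collateral relationship; full sibs detected automatically."""
    if u < 0 or d < 0 or a not in (1, 2):
        raise ValueError(f"invalid relationship (u={u}, d={d}, a={a})")
    if (u == 0 or d == 0) and a != 1:
        raise ValueError("lineal relationships have a single common ancestor")
    fs = u == 1 and d == 1 and a == 2
    return Relationship(LINEAL_OR_COLLATERAL, u, d, a, fs)


FULL_SIB = rel(1, 1, 2)
PARENT_OFFSPRING = rel(0, 1, 1)
HALF_SIB = rel(1, 1, 1)


def k_coefficients(r: Relationship) -> tuple[float, float, float]:
    """Cotterman coefficients (k0, k1, k2): probabilities of sharing 0/1/2
    allele pairs IBD at a random autosomal locus."""
    if r.kind == SELF:
        return (0.0, 0.0, 1.0)
    if r.kind == UNRELATED:
        return (1.0, 0.0, 0.0)
    if r.full_sib:
        return (0.25, 0.5, 0.25)
    k1 = r.a * 2.0 ** (-(r.u + r.d - 1))
    return (1.0 - k1, k1, 0.0)


def kinship(r: Relationship) -> float:
    """Kinship coefficient phi = k1/4 + k2/2."""
    k0, k1, k2 = k_coefficients(r)
    return k1 / 4.0 + k2 / 2.0


def lik_key(r: Relationship):
    """Collapse a relationship onto its likelihood-equivalence class.

    Two outbred classes with the same (k0, k1, k2) and the same total meiosis
    count m = u + d give identical pairwise genotype likelihoods under the
    IBD HMM (e.g. half sibs and grandparent-grandchild).
    """
    if r.kind == SELF:
        return ("self",)
    if r.kind == UNRELATED:
        return ("unrelated",)
    if r.full_sib:
        return ("fs",)
    if r.a == 2:
        # two-ancestor classes additionally split by whether one member is
        # a child of the couple: the IBD tract-boundary rate differs (see
        # hmm module notes on source handoffs)
        return ("k", r.u + r.d, 2, 1 if min(r.u, r.d) == 1 else 2)
    return ("k", r.u + r.d, 1, 0)


def enumerate_relationships(max_generations: int = 5) -> list[Relationship]:
    """All outbred pairwise relationship classes realizable in a pedigree
    spanning at most ``max_generations`` generations.

    Classes are canonicalized with u <= d; the swapped orientation describes
    the same unordered pair.  Includes self, unrelated, and full siblings.
    """
    if not 2 <= max_generations <= 5:
        raise ValueError("max_generations must be in [2, 5]")
    depth = max_generations - 1  # max meioses up to an ancestor in the graph
    out = [unrelated(), self_rel()]
    for d in range(1, depth + 1):  # lineal
        out.append(rel(0, d, 1))
    for u in range(1, depth + 1):  # collateral
        for d in range(u, depth + 1):
            out.append(rel(u, d, 1))
            out.append(rel(u, d, 2))
    return out
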