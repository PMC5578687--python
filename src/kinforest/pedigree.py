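"""Pedigree graphs: validity rules, relationship extraction, isomorphism.

A pedigree is a forest of "local pedigrees" (connected components) over
sampled and latent individuals.  Edges run from child to parent; each
individual has 0, 1 or 2 parents.  Outbreeding is assumed: the only
undirected cycles permitted are those created by full siblings (two children
sharing both parents).
"""
from __future__ import annotations

import itertools
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .relationships import (
    Relationship,
    rel,
    self_rel,
    unrelated,
)

MALE = "M"
FEMALE = "F"

DEFAULT_MAX_GENERATIONS = 5


@dataclass
class Individual:
    """A single pedigree member.

    Sampled individuals carry an index into the genotype matrix; latent
    (unsampled) individuals never do.
    """

    id: object
    sex: Optional[str] = None  # "M", "F" or None (unknown)
    sampled: bool = False
    age: Optional[float] = None
    genotype_index: Optional[int] = None


class Pedigree:
    """A forest of local pedigrees.

    Parameters
    ----------
    parents:
        mapping id -> tuple of parent ids (length 0..2).  Parents referenced
        but absent from the mapping are added as founders.
    sex:
        mapping id -> "M"/"F" for individuals with declared sex.
    sampled:
        iterable of sampled ids (must be nodes of the graph).
    mz_pairs:
        pairs of ids treated as duplicates/monozygotic twins ("self"
        relationship).  Restricted to childless full siblings.
    age:
        mapping id -> age for individuals with known age.
    """

    def __init__(self, parents=None, sex=None, sampled=None, mz_pairs=None,
                 age=None, genotype_index=None):
        self.parents: dict = {i: tuple(p) for i, p in (parents or {}).items()}
        for i, ps in list(self.parents.items()):
            for p in ps:
                self.parents.setdefault(p, ())
        self.sex: dict = {k: v for k, v in (sex or {}).items() if v in (MALE, FEMALE)}
        self.sampled: set = set(sampled or [])
        self.mz_pairs: set = {frozenset(p) for p in (mz_pairs or [])}
        self.age: dict = dict(age or {})
        if genotype_index is None:
            genotype_index = {s: i for i, s in enumerate(sorted(self.sampled, key=str))}
        self.genotype_index: dict = dict(genotype_index)

    # ------------------------------------------------------------------ basic
    def individuals(self) -> Iterable:
        return self.parents.keys()

    def __contains__(self, i) -> bool:
        return i in self.parents

    def __len__(self) -> int:
        return len(self.parents)

    def individual(self, i) -> Individual:
        return Individual(
            id=i,
            sex=self.sex.get(i),
            sampled=i in self.sampled,
            age=self.age.get(i),
            genotype_index=self.genotype_index.get(i) if i in self.sampled else None,
        )

    def copy(self) -> "Pedigree":
        p = Pedigree.__new__(Pedigree)
        p.parents = dict(self.parents)
        p.sex = dict(self.sex)
        p.sampled = set(self.sampled)
        p.mz_pairs = set(self.mz_pairs)
        p.age = dict(self.age)
        p.genotype_index = dict(self.genotype_index)
        return p

    def children_map(self) -> dict:
        ch: dict = {i: [] for i in self.parents}
        for c, ps in self.parents.items():
            for p in ps:
                ch[p].append(c)
        return ch

    def edges(self) -> list:
        return [(c, p) for c, ps in self.parents.items() for p in ps]

    # ------------------------------------------------------------- components
    def components(self) -> list[frozenset]:
        """Connected components of the undirected parent-child graph."""
        ch = self.children_map()
        seen: set = set()
        comps = []
        for start in self.parents:
            if start in seen:
                continue
            comp = set()
            dq = deque([start])
            while dq:
                v = dq.popleft()
                if v in comp:
                    continue
                comp.add(v)
                dq.extend(self.parents[v])
                dq.extend(ch[v])
            seen |= comp
            comps.append(frozenset(comp))
        return comps

    def component_of(self, i) -> frozenset:
        ch = self.children_map()
        comp = set()
        dq = deque([i])
        while dq:
            v = dq.popleft()
            if v in comp:
                continue
            comp.add(v)
            dq.extend(self.parents[v])
            dq.extend(ch[v])
        return frozenset(comp)

    # ------------------------------------------------------------- ancestry
    def ancestor_depths(self, i) -> dict:
        """Map ancestor -> meiosis count from ``i`` (self at 0).

        In valid outbred pedigrees the path to any ancestor is unique, so the
        depth is well defined.
        """
        out = {i: 0}
        dq = deque([i])
        while dq:
            v = dq.popleft()
            dv = out[v]
            for p in self.parents[v]:
                if p not in out:
                    out[p] = dv + 1
                    dq.append(p)
        return out

    def relationship_between(self, i, j) -> Relationship:
        """The outbred relationship class between two individuals induced by
        the graph (unrelated iff they share no common ancestor)."""
        if i not in self.parents or j not in self.parents:
            raise KeyError(f"{i!r} or {j!r} not in pedigree")
        if i == j or frozenset((i, j)) in self.mz_pairs:
            return self_rel()
        ai = self.ancestor_depths(i)
        aj = self.ancestor_depths(j)
        common = ai.keys() & aj.keys()
        if not common:
            return unrelated()
        best = min(ai[c] + aj[c] for c in common)
        mins = [c for c in common if ai[c] + aj[c] == best]
        u = ai[mins[0]]
        d = aj[mins[0]]
        a = len(mins)
        # outbred graphs admit a unique decomposition: minimal common
        # ancestors are a single individual or one spouse couple
        assert a <= 2, "ambiguous common-ancestor set; pedigree is not outbred"
        if a == 2:
            assert ai[mins[1]] == u and aj[mins[1]] == d
        return rel(u, d, a)

    def generation_depth(self, comp: Optional[frozenset] = None) -> int:
        """Longest child -> ancestor chain, counted in generations (nodes)."""
        nodes = comp if comp is not None else self.parents.keys()
        memo: dict = {}

        def depth(v):
            if v in memo:
                return memo[v]
            memo[v] = 1  # cycle guard; validated separately
            memo[v] = 1 + max((depth(p) for p in self.parents[v]), default=0)
            return memo[v]

        return max((depth(v) for v in nodes), default=0)

    # ------------------------------------------------------------- validation
    def validate(self, max_generations: int = DEFAULT_MAX_GENERATIONS) -> list[str]:
        """Diagnostic check of all pedigree invariants.

        Returns an empty list iff the pedigree is valid; otherwise one
        human-readable violation descriptor per problem.  Never raises.
        """
        v: list[str] = []
        ch = self.children_map()

        for i, ps in self.parents.items():
            if len(ps) > 2:
                v.append(f"{i}: more than two parents {ps}")
            if len(set(ps)) != len(ps):
                v.append(f"{i}: duplicated parent in {ps}")
            if i in ps:
                v.append(f"{i}: is its own parent")

        for s in self.sampled:
            if s not in self.parents:
                v.append(f"sampled individual {s} missing from graph")

        # directed cycles (an individual its own ancestor)
        state: dict = {}

        def has_cycle(x) -> bool:
            stack = [(x, iter(self.parents.get(x, ())))]
            state[x] = 1
            while stack:
                node, it = stack[-1]
                adv = next(it, None)
                if adv is None:
                    state[node] = 2
                    stack.pop()
                    continue
                st = state.get(adv)
                if st == 1:
                    return True
                if st is None:
                    state[adv] = 1
                    stack.append((adv, iter(self.parents.get(adv, ()))))
            return False

        cyclic = False
        for i in self.parents:
            if state.get(i) is None and has_cycle(i):
                v.append(f"directed cycle through ancestry of {i}")
                cyclic = True
        if cyclic:
            return v  # depth / loop analysis meaningless with directed cycles

        # sexes: spouse graph must 2-color consistently with declared sexes
        couple_adj: dict = {i: set() for i in self.parents}
        for i, ps in self.parents.items():
            if len(ps) == 2:
                couple_adj[ps[0]].add(ps[1])
                couple_adj[ps[1]].add(ps[0])
        for compset in self._couple_components(couple_adj):
            ref = min(compset, key=str)
            parity = self._couple_parity(couple_adj, compset, ref)
            if parity is None:
                v.append(f"sex conflict: odd spouse cycle through {ref}")
                continue
            decl = sorted((i for i in compset if i in self.sex), key=str)
            for i in decl[1:]:
                same = parity[i] == parity[decl[0]]
                if same != (self.sex[i] == self.sex[decl[0]]):
                    v.append(
                        f"declared sexes of {decl[0]} and {i} conflict with spouse graph"
                    )

        # age: parents older than children when both known
        for c, ps in self.parents.items():
            for p in ps:
                if c in self.age and p in self.age and self.age[p] <= self.age[c]:
                    v.append(f"parent {p} not older than child {c}")

        # undirected cycles: only full-sib cycles allowed.  In each component
        # the cycle-space dimension E - V + 1 must equal the number of cycles
        # forced by couples with multiple shared children.
        for comp in self.components():
            E = sum(len(self.parents[i]) for i in comp)
            V = len(comp)
            couple_children: dict = {}
            for i in comp:
                ps = self.parents[i]
                if len(ps) == 2:
                    couple_children.setdefault(frozenset(ps), 0)
                    couple_children[frozenset(ps)] += 1
            allowed = sum(c - 1 for c in couple_children.values())
            if E - V + 1 != allowed:
                v.append(
                    f"component {sorted(map(str, comp))[:6]}...: undirected cycle(s) "
                    "not attributable to full siblings (inbreeding or double-cousin loop)"
                )
            depth = self.generation_depth(comp)
            if depth > max_generations:
                v.append(
                    f"component of {next(iter(comp))}: spans {depth} generations "
                    f"(cap {max_generations})"
                )

        # monozygotic pairs: childless full siblings only
        for pair in self.mz_pairs:
            a, b = tuple(pair)
            if a not in self.parents or b not in self.parents:
                v.append(f"mz pair {a},{b}: member missing")
                continue
            if set(self.parents[a]) != set(self.parents[b]) or not self.parents[a]:
                v.append(f"mz pair {a},{b}: members are not full siblings")
            if ch[a] or ch[b]:
                v.append(f"mz pair {a},{b}: members must be childless")
        return v

    @staticmethod
    def _couple_components(adj: dict) -> list[set]:
        seen: set = set()
        comps = []
        for s in adj:
            if s in seen or not adj[s]:
                continue
            comp = set()
            dq = deque([s])
            while dq:
                x = dq.popleft()
                if x in comp:
                    continue
                comp.add(x)
                dq.extend(adj[x])
            seen |= comp
            comps.append(comp)
        return comps

    @staticmethod
    def _couple_parity(adj: dict, comp: set, ref) -> Optional[dict]:
        parity = {ref: 0}
        dq = deque([ref])
        while dq:
            x = dq.popleft()
            for y in adj[x]:
                if y not in parity:
                    parity[y] = 1 - parity[x]
                    dq.append(y)
                elif parity[y] == parity[x]:
                    return None
        return parity

    # --------------------------------------------------------- canonical form
    def canonical(self) -> "Pedigree":
        """Drop latent individuals that cannot affect any sampled genotype
        distribution: childless latents, and parentless latents with a single
        child.  Applied before isomorphism comparison and after SA moves."""
        p = self.copy()
        changed = True
        while changed:
            changed = False
            ch = p.children_map()
            for i in list(p.parents):
                if i in p.sampled or any(i in pr for pr in p.mz_pairs):
                    continue
                nch = len(ch.get(i, ()))
                if nch == 0 or (nch <= 1 and not p.parents[i]):
                    for c in ch.get(i, ()):
                        p.parents[c] = tuple(x for x in p.parents[c] if x != i)
                    del p.parents[i]
                    p.sex.pop(i, None)
                    p.age.pop(i, None)
                    changed = True
                    break
        return p

    # ------------------------------------------------------------ isomorphism
    def isomorphic(self, other: "Pedigree") -> bool:
        """True iff a bijection exists that fixes every sampled individual,
        respects declared sexes, and maps parent edges onto parent edges in
        both directions.  Compared on canonical forms (latent members that
        cannot influence genotypes are ignored on both sides)."""
        if self.sampled != other.sampled:
            raise ValueError("sampled id sets differ")
        a = self.canonical()
        b = other.canonical()
        if len(a.parents) != len(b.parents):
            return False
        if len(a.edges()) != len(b.edges()):
            return False
        if a.mz_pairs != b.mz_pairs:
            return False

        lat_a = sorted((i for i in a.parents if i not in a.sampled), key=str)
        lat_b = [i for i in b.parents if i not in b.sampled]
        if len(lat_a) != len(lat_b):
            return False

        cha, chb = a.children_map(), b.children_map()

        def sig(ped, chm, i):
            ps = ped.parents[i]
            return (
                len(ps),
                sum(1 for x in ps if x in ped.sampled),
                len(chm[i]),
                tuple(sorted((str(c) for c in chm[i] if c in ped.sampled))),
                tuple(sorted(str(x) for x in ps if x in ped.sampled)),
            )

        sig_a = {i: sig(a, cha, i) for i in lat_a}
        sig_b = {i: sig(b, chb, i) for i in lat_b}

        def sex_ok(x, y):
            sx, sy = a.sex.get(x), b.sex.get(y)
            return sx is None or sy is None or sx == sy

        mapping: dict = {s: s for s in a.sampled}
        used: set = set()

        def consistent(x, y):
            # cheap pruning: every already-mapped neighbor must correspond;
            # the final edge-set equality check makes the match exact
            mapped_pars = {mapping[p] for p in a.parents[x] if p in mapping}
            if not mapped_pars <= set(b.parents[y]):
                return False
            for c in cha[x]:
                if c in mapping and y not in b.parents[mapping[c]]:
                    return False
            return True

        def bt(k: int) -> bool:
            if k == len(lat_a):
                # final edge-set equality check under the mapping
                ea = {(mapping[c], mapping[p]) for c, p in a.edges()}
                eb = set(b.edges())
                return ea == eb
            x = lat_a[k]
            for y in lat_b:
                if y in used or sig_a[x] != sig_b[y] or not sex_ok(x, y):
                    continue
                mapping[x] = y
                used.add(y)
                if consistent(x, y) and bt(k + 1):
                    return True
                del mapping[x]
                used.discard(y)
            return False

        # sampled-only sanity: sampled-sampled edges must match exactly
        ea_s = {(c, p) for c, p in a.edges() if c in a.sampled and p in a.sampled}
        eb_s = {(c, p) for c, p in b.edges() if c in b.sampled and p in b.sampled}
        if ea_s != eb_s:
            return False
        for s in a.sampled:
            if not sex_ok(s, s):
                return False
        return bt(0)


def isomorphic(est: Pedigree, truth: Pedigree) -> bool:
    """Exact-pedigree match: node bijection fixing sampled individuals and
    mapping edges onto edges in both directions."""
    return est.isomorphic(truth)


def validate(ped: Pedigree, max_generations: int = DEFAULT_MAX_GENERATIONS) -> list[str]:
    return ped.validate(max_generations=max_generations)


def singleton_forest(sampled_ids, sex=None, age=None) -> Pedigree:
    """The all-unrelated starting state: every sampled individual a singleton."""
    return Pedigree(parents={i: () for i in sampled_ids}, sex=sex,
                    sampled=sampled_ids, age=age)
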