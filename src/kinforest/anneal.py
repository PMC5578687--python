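"""Simulated annealing over pedigree forests.

The search state is a forest of local pedigrees over the sampled individuals
plus latent connectors.  Starting from the all-singleton configuration,
local graph perturbations ("moves") are proposed and accepted with
probability min[(CL_new / CL_old)^t, 1]; ``t`` acts as an inverse
temperature that grows by a factor ``f`` per stage, so the chain becomes
greedier over time.  Invalid proposals (cycles, too many generations, sex or
age conflicts, inbreeding loops) are rejected outright.  The best-scoring
configuration ever encountered is reported, optionally over several
independently seeded restarts.

The move catalog instantiates three classes of perturbation: (1) relabeling
the relationship of a pair among likelihood-adjacent classes
(parent-offspring <-> full/half siblings, grandparental <-> half siblings,
avuncular reversals, edge stretch/contract, duplicate-sample marking);
(2) larger rearrangements that split a local pedigree, join two pedigrees
through new common ancestors, or both; and (3) symmetry moves that swap an
individual with a descendant when ages are unknown or flip unobserved
sexes.  The catalog is data-driven (``MOVES``) and individual moves can be
re-weighted or disabled through ``AnnealConfig.move_weights``.
"""
from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.stats import poisson

from .hmm import PairLikelihoodTable
from .pedigree import Pedigree, singleton_forest
from .scoring import ScoreBreakdown, total_score

__all__ = ["AnnealConfig", "MoveOutcome", "MOVES", "accept", "propose",
           "run", "multi_start"]


# ---------------------------------------------------------------- config
@dataclass
class AnnealConfig:
    """Tuning parameters of the annealer.

    ``C`` proposals are made per temperature stage; after each stage the
    inverse temperature is multiplied by ``f`` > 1 (set ``cooling="paper"``
    to divide instead).  The run stops after ``I`` proposals or when the
    best score has improved by less than ``e`` over ``stall_stages``
    consecutive stages.
    """

    C: int = 1000
    f: float = 1.05
    I: int = 2_000_000
    e: float = 1e-4
    t0: float = 0.1
    n_restarts: int = 3
    seed: int = 0
    max_generations: int = 5
    beta: float = 1.0
    lam: Optional[float] = None  # None -> sample size n
    move_weights: Optional[dict] = None
    cooling: str = "standard"  # "standard": greedier over time; "paper": t/f
    use_ages: bool = True
    stall_stages: int = 40
    reheats: int = 0  # extra anneal cycles restarted from the best state
    check_every: int = 10_000  # full-recompute consistency guard; 0 disables
    engine: str = "fast"  # "fast": compiled kernel; "python": reference loop

    def __post_init__(self):
        if self.f <= 1:
            raise ValueError("cooling factor f must exceed 1")
        if self.I <= 0 or self.C <= 0:
            raise ValueError("I and C must be positive")

    @classmethod
    def desk(cls, seed: int = 0, **kw) -> "AnnealConfig":
        """Reduced schedule for small samples (n ~ 20, thousands of markers)."""
        defaults = dict(C=3000, f=1.07, I=400_000, t0=0.05, stall_stages=10,
                        reheats=10, beta=10.0, seed=seed)
        defaults.update(kw)
        return cls(**defaults)


@dataclass
class MoveOutcome:
    move: str
    accepted: bool
    delta: float
    valid: bool


def accept(delta_logscore: float, temperature: float,
           rng: np.random.Generator) -> bool:
    """Accept with probability min(exp(t * delta), 1), computed in log space."""
    if temperature < 0:
        raise ValueError("temperature must be nonnegative")
    if delta_logscore >= 0:
        return True
    logp = temperature * delta_logscore
    if logp >= 0:
        return True
    return math.log(rng.random()) < logp


# ------------------------------------------------------------ internal state
class _Annealer:
    """Mutable search state with incremental component scoring."""

    def __init__(self, table: PairLikelihoodTable, config: AnnealConfig,
                 sex: Optional[dict] = None, age: Optional[dict] = None,
                 start: Optional[Pedigree] = None):
        self.table = table
        self.cfg = config
        self.sampled = set(table.ids)
        self.sex = dict(sex or {})
        self.age = dict(age or {}) if config.use_ages else {}
        if start is None:
            start = singleton_forest(table.ids, sex=self.sex, age=self.age)
        self.P: dict = dict(start.parents)
        self.mz: set = set(start.mz_pairs)
        self.sex_flip: set = set()  # spouse-component anchors with flipped colors
        self._latent_counter = 0
        self.n = len(table.ids)
        self.lam = config.lam if config.lam is not None else float(self.n)
        self.beta = config.beta
        # log Poisson pmf over plausible component counts
        qmax = self.n + 64
        self._logpois = poisson.logpmf(np.arange(qmax + 1), self.lam)
        self.row = dict(table.id_index)
        self.cls = dict(table.class_index)
        self.marg = table.marginal
        self.ll = table.ll
        self._memo: dict = {}
        self.C_cur: dict = self._children(self.P)
        self._affinity = self._build_affinity()
        self._rebuild_components()

    def _build_affinity(self) -> dict:
        """Per sampled individual: partners weighted by pairwise evidence.

        The weight of (i, j) is the best relatedness gain over the unrelated
        baseline, floored at a small epsilon so every partner stays
        reachable.  Used only to steer proposals; acceptance probabilities
        are untouched, so the scoring model is unaffected.
        """
        n = len(self.table.ids)
        gains = np.full((n, n), 0.0)
        unrel = self.marg[:, None] + self.marg[None, :]
        for ci, key in enumerate(self.table.class_keys):
            if key in (("unrelated",), ("self",)):
                continue
            np.maximum(gains, self.ll[ci] - unrel, out=gains)
        out = {}
        ids = self.table.ids
        for x, i in enumerate(ids):
            w = np.maximum(gains[x], 0.0) + 0.5
            w[x] = 0.0
            out[i] = (list(ids), np.cumsum(w / w.sum()))
        return out

    def affinity_partner(self, i, rng):
        """Draw a sampled partner for i, biased toward pairs whose genotype
        evidence favors some relatedness."""
        ent = self._affinity.get(i)
        if ent is None:
            return None
        ids, cw = ent
        return ids[int(np.searchsorted(cw, rng.random()))]

    # -------------------------------------------------------------- plumbing
    def new_latent(self):
        self._latent_counter += 1
        return f"~{self._latent_counter}"

    @staticmethod
    def _children(P: dict) -> dict:
        C: dict = {i: [] for i in P}
        for c, ps in P.items():
            for p in ps:
                C[p].append(c)
        return C

    def _rebuild_components(self):
        C = self._children(self.P)
        self.comp_of: dict = {}
        self.comp_nodes: dict = {}
        self.comp_score: dict = {}
        cid = 0
        for start in self.P:
            if start in self.comp_of:
                continue
            nodes = self._bfs(self.P, C, start)
            for v in nodes:
                self.comp_of[v] = cid
            self.comp_nodes[cid] = nodes
            self.comp_score[cid] = self._pairs_score(self.P, nodes)
            cid += 1
        self._next_cid = cid
        self.q = len(self.comp_nodes)
        self.cur_pairs = float(sum(self.comp_score.values()))

    @staticmethod
    def _bfs(P: dict, C: dict, start) -> frozenset:
        seen = {start}
        dq = deque([start])
        while dq:
            v = dq.popleft()
            for w in P[v]:
                if w not in seen:
                    seen.add(w)
                    dq.append(w)
            for w in C.get(v, ()):
                if w not in seen:
                    seen.add(w)
                    dq.append(w)
        return frozenset(seen)

    def total(self) -> float:
        return self.cur_pairs + self.beta * self._logpois[min(self.q, len(self._logpois) - 1)]

    def pedigree(self) -> Pedigree:
        return Pedigree(parents=dict(self.P), sex=self._assigned_sexes(),
                        sampled=self.sampled, mz_pairs=self.mz, age=self.age)

    def _assigned_sexes(self) -> dict:
        """Declared sexes plus a lazy, consistent assignment for unknown-sex
        spouses (2-coloring of the co-parent graph; the flip-sex move toggles
        the color of components without any declared member)."""
        out = dict(self.sex)
        adj: dict = {}
        for v in self.P:
            if len(self.P[v]) == 2:
                a, b = self.P[v]
                adj.setdefault(a, set()).add(b)
                adj.setdefault(b, set()).add(a)
        seen: set = set()
        for s in adj:
            if s in seen:
                continue
            comp = [s]
            parity = {s: 0}
            dq = deque([s])
            while dq:
                x = dq.popleft()
                for y in sorted(adj[x], key=str):
                    if y not in parity:
                        parity[y] = 1 - parity[x]
                        comp.append(y)
                        dq.append(y)
            seen.update(comp)
            decl = sorted((v for v in comp if v in self.sex), key=str)
            if decl:
                base = 0 if self.sex[decl[0]] == MALE_HINT else 1
                base ^= parity[decl[0]]
            else:
                ref = min(comp, key=str)
                base = 1 if ref in self.sex_flip else 0
            for v in comp:
                if v not in out:
                    out[v] = MALE_HINT if (parity[v] ^ base) == 0 else FEMALE_HINT
        return out

    # -------------------------------------------------------------- scoring
    def _ancestors(self, P: dict, i) -> dict:
        out = {i: 0}
        dq = deque([i])
        while dq:
            v = dq.popleft()
            dv = out[v]
            for p in P[v]:
                if p not in out:
                    out[p] = dv + 1
                    dq.append(p)
        return out

    def _pair_class_row(self, anc_i: dict, anc_j: dict, i, j, mz: set):
        if frozenset((i, j)) in mz:
            return self.cls[("self",)]
        best = None
        a = 0
        u = d = 0
        for c, du in anc_i.items():
            dj = anc_j.get(c)
            if dj is None:
                continue
            s = du + dj
            if best is None or s < best:
                best = s
                a = 1
                u, d = du, dj
            elif s == best:
                a += 1
        if best is None:
            return self.cls[("unrelated",)]
        if u == 1 and d == 1 and a == 2:
            return self.cls[("fs",)]
        if a >= 2:
            return self.cls.get(("k", best, 2, 1 if min(u, d) == 1 else 2))
        return self.cls.get(("k", best, 1, 0))

    def _pairs_score(self, P: dict, nodes) -> float:
        H = sorted((v for v in nodes if v in self.sampled), key=str)
        k = len(H)
        if k == 0:
            return 0.0
        if k == 1:
            return float(self.marg[self.row[H[0]]])
        sig = self._signature(P, nodes, H)
        hit = self._memo.get(sig)
        if hit is not None:
            return hit
        anc = {v: self._ancestors(P, v) for v in H}
        s = 0.0
        for x in range(k):
            i = H[x]
            ai = anc[i]
            ri = self.row[i]
            for y in range(x + 1, k):
                j = H[y]
                row = self._pair_class_row(ai, anc[j], i, j, self.mz)
                if row is None:  # relationship outside the table: forbid
                    return -math.inf
                s += self.ll[row, ri, self.row[j]]
        s -= (k - 2) * sum(self.marg[self.row[i]] for i in H)
        if len(self._memo) > 400_000:
            self._memo.clear()
        self._memo[sig] = s
        return s

    def _signature(self, P: dict, nodes, H):
        label: dict = {}
        for idx, s in enumerate(sorted(H, key=str)):
            label[s] = idx
        nxt = len(H)
        order = deque(sorted(H, key=str))
        C: dict = {}
        for c in nodes:
            for p in P[c]:
                C.setdefault(p, []).append(c)
        seen = set(label)
        while order:
            v = order.popleft()
            for w in list(P[v]) + sorted(C.get(v, ()), key=str):
                if w not in seen:
                    label[w] = nxt
                    nxt += 1
                    seen.add(w)
                    order.append(w)
        if len(label) < len(nodes):  # disconnected latents (shouldn't persist)
            for w in sorted((x for x in nodes if x not in label), key=str):
                label[w] = nxt
                nxt += 1
        edges = []
        for c in nodes:
            lc = label[c]
            for p in P[c]:
                edges.append((lc, label[p]))
        edges.sort()
        mzl = sorted(tuple(sorted(label[x] for x in pr))
                     for pr in self.mz if all(x in label for x in pr))
        return (tuple(sorted(map(str, H))), tuple(edges), tuple(mzl))

    # ------------------------------------------------------------ validation
    def _validate_comp(self, P: dict, nodes) -> bool:
        # parent arity and self-parenting
        for v in nodes:
            ps = P[v]
            if len(ps) > 2 or len(set(ps)) != len(ps) or v in ps:
                return False
        # directed cycles + generation depth via iterative longest-chain
        depth: dict = {}
        state: dict = {}
        for root in nodes:
            if root in depth:
                continue
            stack = [root]
            while stack:
                v = stack[-1]
                st = state.get(v)
                if st == 1:
                    d = 1 + max((depth[p] for p in P[v]), default=0)
                    depth[v] = d
                    state[v] = 2
                    stack.pop()
                    continue
                if st == 2:
                    stack.pop()
                    continue
                state[v] = 1
                for p in P[v]:
                    if state.get(p) == 1:
                        return False  # directed cycle
                    if p not in depth:
                        stack.append(p)
        if max((depth[v] for v in nodes), default=0) > self.cfg.max_generations:
            return False
        # undirected cycles: only full-sib loops allowed
        E = sum(len(P[v]) for v in nodes)
        couples: dict = {}
        for v in nodes:
            if len(P[v]) == 2:
                key = frozenset(P[v])
                couples[key] = couples.get(key, 0) + 1
        if E - len(nodes) + 1 != sum(c - 1 for c in couples.values()):
            return False
        # sexes: spouse graph 2-colorable respecting declared sexes
        adj: dict = {}
        for v in nodes:
            if len(P[v]) == 2:
                a, b = P[v]
                adj.setdefault(a, set()).add(b)
                adj.setdefault(b, set()).add(a)
        seen: set = set()
        for s in adj:
            if s in seen:
                continue
            parity = {s: 0}
            dq = deque([s])
            comp = [s]
            while dq:
                x = dq.popleft()
                for y in adj[x]:
                    if y not in parity:
                        parity[y] = 1 - parity[x]
                        comp.append(y)
                        dq.append(y)
                    elif parity[y] == parity[x]:
                        return False
            seen.update(comp)
            decl = [v for v in comp if v in self.sex]
            for i in decl[1:]:
                if (parity[i] == parity[decl[0]]) != (self.sex[i] == self.sex[decl[0]]):
                    return False
        # ages when known
        if self.age:
            for c in nodes:
                ac = self.age.get(c)
                if ac is None:
                    continue
                for p in P[c]:
                    ap = self.age.get(p)
                    if ap is not None and ap <= ac:
                        return False
        # duplicate pairs must stay childless full siblings
        if self.mz:
            C = None
            for pr in self.mz:
                a, b = tuple(pr)
                if a in nodes or b in nodes:
                    if a not in P or b not in P:
                        return False
                    if set(P[a]) != set(P[b]) or not P[a]:
                        return False
                    if C is None:
                        C = self._children(P)
                    if C.get(a) or C.get(b):
                        return False
        return True

    # ------------------------------------------------------- proposal engine
    def consider(self, edit, rng: np.random.Generator, t: float) -> MoveOutcome:
        name, changes = edit
        if changes is None:
            return MoveOutcome(name, False, 0.0, False)
        set_parents, mz_add, mz_del = changes
        touched = set()
        for c, ps in set_parents.items():
            touched.add(c)
            touched.update(ps)
            touched.update(self.P.get(c, ()))
        for pr in (mz_add or []):
            touched.update(pr)
        for pr in (mz_del or []):
            touched.update(pr)

        P2 = dict(self.P)
        for c, ps in set_parents.items():
            P2[c] = tuple(ps)
            for p in ps:
                P2.setdefault(p, ())
        mz2 = self.mz
        if mz_add or mz_del:
            mz2 = set(self.mz)
            mz2 |= set(map(frozenset, mz_add or []))
            mz2 -= set(map(frozenset, mz_del or []))

        # canonical cleanup of latents around the touched region
        C2 = self._children(P2)
        protected = set()
        for pr in mz2:
            protected |= pr
        changed = True
        while changed:
            changed = False
            region = set()
            for v in touched:
                if v in P2:
                    region.add(v)
                    region.update(P2[v])
            for v in sorted(region, key=str):
                if v not in P2 or v in self.sampled or v in protected:
                    continue
                nch = len(C2.get(v, ()))
                if nch == 0 or (nch <= 1 and not P2[v]):
                    for c in C2.get(v, ()):
                        P2[c] = tuple(x for x in P2[c] if x != v)
                        touched.add(c)
                    for p in P2[v]:
                        C2[p] = [x for x in C2[p] if x != v]
                        touched.add(p)
                    del P2[v]
                    C2.pop(v, None)
                    touched.discard(v)
                    changed = True

        touched = {v for v in touched if v in P2 or v in self.P}
        if not touched:
            return MoveOutcome(name, False, 0.0, False)

        # affected components before / after
        old_cids = {self.comp_of[v] for v in touched if v in self.comp_of}
        new_comps = []
        seen: set = set()
        for v in sorted(touched, key=str):
            if v in seen or v not in P2:
                continue
            comp = self._bfs(P2, C2, v)
            seen |= comp
            new_comps.append(comp)

        old_mz = self.mz
        self.mz = mz2  # _pairs_score reads self.mz
        try:
            new_scores = [self._pairs_score(P2, comp) for comp in new_comps]
        finally:
            self.mz = old_mz
        if any(not math.isfinite(s) for s in new_scores):
            return MoveOutcome(name, False, 0.0, False)

        old_pairs = sum(self.comp_score[c] for c in old_cids)
        dq = len(new_comps) - len(old_cids)
        q2 = self.q + dq
        delta = (sum(new_scores) - old_pairs
                 + self.beta * (self._logpois[min(q2, len(self._logpois) - 1)]
                                - self._logpois[min(self.q, len(self._logpois) - 1)]))

        if not accept(delta, t, rng):
            return MoveOutcome(name, False, float(delta), True)

        # validity is only checked for would-be-accepted states: score-based
        # rejection already filters most proposals, and scoring an invalid
        # graph is safe (class lookups fail to -inf)
        for comp in new_comps:
            if not self._validate_comp(P2, comp):
                return MoveOutcome(name, False, float(delta), False)

        # commit
        removed = set(self.P) - set(P2)
        self.P = P2
        self.C_cur = C2
        self.mz = mz2
        for cid in old_cids:
            nodes = self.comp_nodes.pop(cid)
            self.comp_score.pop(cid)
            for v in nodes:
                self.comp_of.pop(v, None)
        for comp, sc in zip(new_comps, new_scores):
            cid = self._next_cid
            self._next_cid += 1
            self.comp_nodes[cid] = comp
            self.comp_score[cid] = sc
            for v in comp:
                self.comp_of[v] = cid
        for v in removed:
            self.comp_of.pop(v, None)
            self.sex_flip.discard(v)
        self.q = q2
        self.cur_pairs += sum(new_scores) - old_pairs
        return MoveOutcome(name, True, float(delta), True)


# ------------------------------------------------------------------- moves
def _rand(rng, seq):
    return seq[rng.integers(len(seq))] if len(seq) else None


def _pick(ann, rng, cands, bias: float = 0.7):
    """Prefer sampled individuals: moves aimed at genotyped nodes are far
    more likely to change the score than edits among latent scaffolding."""
    if not cands:
        return None
    if rng.random() < bias:
        samp = [v for v in cands if v in ann.sampled]
        if samp:
            return samp[rng.integers(len(samp))]
    return cands[rng.integers(len(cands))]


def _edges(P: dict) -> list:
    return [(c, p) for c, ps in P.items() for p in ps]


def _replace(ps, old, new) -> tuple:
    return tuple(new if x == old else x for x in ps)


def _swap_edit(ann, C, i, j):
    """Exchange the graph positions of i and j (parents and children)."""
    def sig(ps):
        return tuple(j if x == i else i if x == j else x for x in ps)

    sp = {i: sig(ann.P[j]), j: sig(ann.P[i])}
    for c in sorted(set(C.get(i, [])) | set(C.get(j, [])), key=str):
        if c not in (i, j):
            sp[c] = sig(ann.P[c])
    return sp


def mv_po_to_fullsib(ann, C, rng):
    E = _edges(ann.P)
    if not E:
        return None
    c, p = _rand(rng, E)
    ps = ann.P[p]
    sp = {}
    if len(ps) == 2:
        newp = ps
    elif len(ps) == 1:
        newp = (ps[0], ann.new_latent())
        sp[p] = newp
    else:
        newp = (ann.new_latent(), ann.new_latent())
        sp[p] = newp
    sp[c] = newp
    return (sp, None, None)


def mv_fullsib_to_po(ann, C, rng):
    cands = [v for v in ann.P if len(ann.P[v]) == 2]
    c1 = _rand(rng, cands)
    if c1 is None:
        return None
    sibs = [s for s in C[ann.P[c1][0]]
            if s != c1 and set(ann.P[s]) == set(ann.P[c1])]
    c2 = _rand(rng, sibs)
    if c2 is None:
        return None
    return ({c2: (c1,)}, None, None)


def mv_po_to_halfsib(ann, C, rng):
    E = _edges(ann.P)
    if not E:
        return None
    c, p = _rand(rng, E)
    other = tuple(x for x in ann.P[c] if x != p)
    sp = {}
    if ann.P[p]:
        g = _rand(rng, ann.P[p])
    else:
        g = ann.new_latent()
        sp[p] = (g,)
    sp[c] = other + (g,)
    return (sp, None, None)


def _half_sib_pair(ann, C, rng):
    gs = [v for v in ann.P if len(C.get(v, ())) >= 2]
    g = _rand(rng, gs)
    if g is None:
        return None
    kids = C[g]
    c1 = _rand(rng, kids)
    c2 = _rand(rng, [x for x in kids if x != c1])
    if c2 is None:
        return None
    return g, c1, c2


def mv_halfsib_to_po(ann, C, rng):
    hit = _half_sib_pair(ann, C, rng)
    if hit is None:
        return None
    g, c1, c2 = hit
    if c1 in ann.P[c2]:
        return None
    return ({c2: _replace(ann.P[c2], g, c1)}, None, None)


def _avuncular_triple(ann, C, rng):
    i = _rand(rng, list(ann.P))
    if not ann.P[i]:
        return None
    sibs = [s for par in ann.P[i] for s in C.get(par, ()) if s != i]
    m = _rand(rng, sibs)
    if m is None:
        return None
    j = _rand(rng, C.get(m, []))
    if j is None:
        return None
    return i, m, j


def mv_avuncular_reverse(ann, C, rng):
    hit = _avuncular_triple(ann, C, rng)
    if hit is None:
        return None
    i, m, j = hit
    return (_swap_edit(ann, C, i, j), None, None)


def mv_gp_to_halfsib(ann, C, rng):
    E = [(c, p) for c, p in _edges(ann.P) if ann.P[p]]
    if not E:
        return None
    j, m = _rand(rng, E)
    i = _rand(rng, ann.P[m])
    sp = {}
    if ann.P[i]:
        x = _rand(rng, ann.P[i])
    else:
        x = ann.new_latent()
        sp[i] = (x,)
    sp[j] = _replace(ann.P[j], m, x)
    return (sp, None, None)


def mv_halfsib_to_gp(ann, C, rng):
    hit = _half_sib_pair(ann, C, rng)
    if hit is None:
        return None
    g, c1, c2 = hit
    m = ann.new_latent()
    return ({m: (c1,), c2: _replace(ann.P[c2], g, m)}, None, None)


def mv_halfsib_to_avuncular(ann, C, rng):
    hit = _half_sib_pair(ann, C, rng)
    if hit is None:
        return None
    g, c1, c2 = hit
    m = ann.new_latent()
    return ({m: tuple(ann.P[c1]), c2: _replace(ann.P[c2], g, m)}, None, None)


def mv_avuncular_to_halfsib(ann, C, rng):
    hit = _avuncular_triple(ann, C, rng)
    if hit is None:
        return None
    i, m, j = hit
    shared = sorted(set(ann.P[i]) & set(ann.P[m]), key=str)
    g = _rand(rng, shared)
    if g is None:
        return None
    return ({j: _replace(ann.P[j], m, g)}, None, None)


def mv_mz_mark(ann, C, rng):
    cands = [v for v in ann.P if len(ann.P[v]) == 2 and not C.get(v, ())]
    c1 = _rand(rng, cands)
    if c1 is None:
        return None
    sibs = [s for s in C[ann.P[c1][0]]
            if s != c1 and set(ann.P[s]) == set(ann.P[c1])
            and not C.get(s, ()) and frozenset((c1, s)) not in ann.mz]
    c2 = _rand(rng, sibs)
    if c2 is None:
        return None
    return ({}, [(c1, c2)], None)


def mv_mz_unmark(ann, C, rng):
    pairs = sorted(ann.mz, key=lambda p: sorted(map(str, p)))
    pr = _rand(rng, pairs)
    if pr is None:
        return None
    return ({}, None, [tuple(pr)])


def mv_add_edge_stretch(ann, C, rng):
    E = _edges(ann.P)
    if not E:
        return None
    c, p = _rand(rng, E)
    m = ann.new_latent()
    return ({m: (p,), c: _replace(ann.P[c], p, m)}, None, None)


def mv_remove_edge_contract(ann, C, rng):
    cands = [v for v in ann.P if ann.P[v] and C.get(v, ())]
    m = _rand(rng, cands)
    if m is None:
        return None
    p = _rand(rng, ann.P[m])
    c = _rand(rng, C[m])
    return ({c: _replace(ann.P[c], m, p)}, None, None)


def mv_attach_parent_edge(ann, C, rng):
    js = [v for v in ann.P if len(ann.P[v]) < 2]
    j = _pick(ann, rng, js)
    if j is None:
        return None
    i = None
    if j in ann.sampled and rng.random() < 0.7:
        i = ann.affinity_partner(j, rng)
        if i == j or i in ann.P[j]:
            i = None
    if i is None:
        i = _pick(ann, rng, [v for v in ann.P if v != j and v not in ann.P[j]])
    if i is None:
        return None
    return ({j: ann.P[j] + (i,)}, None, None)


def mv_detach_parent_edge(ann, C, rng):
    E = _edges(ann.P)
    if not E:
        return None
    c, p = _rand(rng, E)
    return ({c: tuple(x for x in ann.P[c] if x != p)}, None, None)


def mv_split_detach_subtree(ann, C, rng):
    vs = [v for v in ann.P if ann.P[v]]
    v = _rand(rng, vs)
    if v is None:
        return None
    return ({v: ()}, None, None)


def mv_split_children_subset(ann, C, rng):
    ps = [v for v in ann.P if len(C.get(v, ())) >= 2]
    p = _rand(rng, ps)
    if p is None:
        return None
    kids = C[p]
    take = [c for c in kids if rng.random() < 0.5]
    if not take:
        take = [_rand(rng, kids)]
    # taking every child relocates the whole sibling group; the old parent
    # couple is retired by cleanup
    return ({c: () for c in take}, None, None)


def mv_join_halfsib(ann, C, rng):
    # also serves within a component: two half sibs acquiring a shared
    # second parent become full sibs (the validator rejects bad cycles)
    cands = [v for v in ann.P if len(ann.P[v]) < 2]
    i = _pick(ann, rng, cands)
    if i is None:
        return None
    j = None
    if i in ann.sampled and rng.random() < 0.7:
        j = ann.affinity_partner(i, rng)
        if j == i or j is None or len(ann.P[j]) >= 2:
            j = None
    if j is None:
        j = _pick(ann, rng, [v for v in cands if v != i])
    if j is None:
        return None
    g = ann.new_latent()
    return ({i: ann.P[i] + (g,), j: ann.P[j] + (g,)}, None, None)


def _join_chain(ann, sp, x, depth, anc):
    """Attach x at ``depth`` meioses below ancestor spec ``anc`` (a node or a
    couple tuple); returns False if x has no free parent slot."""
    if depth == 1:
        if isinstance(anc, tuple):
            if ann.P[x] or x in sp:
                return False
            sp[x] = anc
        else:
            if len(ann.P[x]) >= 2 or x in sp:
                return False
            sp[x] = ann.P[x] + (anc,)
        return True
    top = ann.new_latent()
    sp[top] = anc if isinstance(anc, tuple) else (anc,)
    prev = top
    for _ in range(depth - 2):
        m = ann.new_latent()
        sp[m] = (prev,)
        prev = m
    if len(ann.P[x]) >= 2 or x in sp:
        return False
    sp[x] = ann.P[x] + (prev,)
    return True


def mv_join_common_ancestor(ann, C, rng):
    nodes = list(ann.P)
    i = _pick(ann, rng, nodes)
    j = None
    if i in ann.sampled and rng.random() < 0.7:
        j = ann.affinity_partner(i, rng)
        if j == i:
            j = None
    if j is None:
        j = _pick(ann, rng, [v for v in nodes if v != i])
    if j is None:
        return None
    du = int(rng.integers(1, 3))
    dd = int(rng.integers(1, 3))
    couple = bool(rng.random() < 0.5)
    sp: dict = {}
    if couple:
        anc = (ann.new_latent(), ann.new_latent())
    else:
        anc = ann.new_latent()
    if not _join_chain(ann, sp, i, du, anc):
        return None
    if not _join_chain(ann, sp, j, dd, anc):
        return None
    return (sp, None, None)


def mv_split_then_join(ann, C, rng):
    # atomic detach-and-reattach: lift v (with its descendants) out of its
    # ancestry and rewire it onto j as a child, a half sib, or a parent -
    # crossing in one step valleys that split + join alone cannot
    vs = [v for v in ann.P if ann.P[v]]
    v = _pick(ann, rng, vs)
    if v is None:
        return None
    j = None
    if v in ann.sampled and rng.random() < 0.7:
        j = ann.affinity_partner(v, rng)
        if j == v:
            j = None
    if j is None:
        j = _pick(ann, rng, [x for x in ann.P if x != v])
    if j is None or j == v:
        return None
    mode = int(rng.integers(3))
    if mode == 0:  # v becomes a child of j
        return ({v: (j,)}, None, None)
    if mode == 1:  # v becomes a parent of j (j needs a free slot)
        if len(ann.P[j]) >= 2 or v in ann.P[j]:
            return None
        return ({v: (), j: ann.P[j] + (v,)}, None, None)
    g = ann.new_latent()  # v and j become half sibs
    if len(ann.P[j]) >= 2:
        return None
    return ({v: (g,), j: ann.P[j] + (g,)}, None, None)


def mv_swap_with_descendant(ann, C, rng):
    i = _rand(rng, list(ann.P))
    j = i
    steps = int(rng.integers(1, 4))
    for _ in range(steps):
        kids = C.get(j, ())
        nxt = _rand(rng, kids)
        if nxt is None:
            break
        j = nxt
    if j == i:
        return None
    return (_swap_edit(ann, C, i, j), None, None)


def mv_flip_sex(ann, C, rng):
    latents = [v for v in ann.P if v not in ann.sex]
    v = _rand(rng, latents)
    if v is None:
        return None
    return ("sex", v)


#: The move catalog: every perturbation class the sampler can draw from.
MOVES: list[tuple[str, Callable]] = [
    ("po_to_fullsib", mv_po_to_fullsib),
    ("fullsib_to_po", mv_fullsib_to_po),
    ("po_to_halfsib", mv_po_to_halfsib),
    ("halfsib_to_po", mv_halfsib_to_po),
    ("avuncular_reverse", mv_avuncular_reverse),
    ("gp_to_halfsib", mv_gp_to_halfsib),
    ("halfsib_to_gp", mv_halfsib_to_gp),
    ("halfsib_to_avuncular", mv_halfsib_to_avuncular),
    ("avuncular_to_halfsib", mv_avuncular_to_halfsib),
    ("mz_mark", mv_mz_mark),
    ("mz_unmark", mv_mz_unmark),
    ("add_edge_stretch", mv_add_edge_stretch),
    ("remove_edge_contract", mv_remove_edge_contract),
    ("attach_parent_edge", mv_attach_parent_edge),
    ("detach_parent_edge", mv_detach_parent_edge),
    ("split_detach_subtree", mv_split_detach_subtree),
    ("split_children_subset", mv_split_children_subset),
    ("join_halfsib", mv_join_halfsib),
    ("join_common_ancestor", mv_join_common_ancestor),
    ("split_then_join", mv_split_then_join),
    ("swap_with_descendant", mv_swap_with_descendant),
    ("flip_sex", mv_flip_sex),
]


def propose(ann: "_Annealer", rng: np.random.Generator,
            weights: Optional[np.ndarray] = None):
    """Draw a move type and generate a candidate edit (None = infeasible)."""
    if weights is None:
        k = int(rng.integers(len(MOVES)))
    else:
        k = int(rng.choice(len(MOVES), p=weights))
    name, fn = MOVES[k]
    return name, fn(ann, ann.C_cur, rng)


def _move_weights(cfg: AnnealConfig) -> Optional[np.ndarray]:
    if not cfg.move_weights:
        return None
    w = np.array([cfg.move_weights.get(name, 1.0) for name, _ in MOVES],
                 dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("invalid move weights")
    return w / w.sum()


def _consistency_check(ann: "_Annealer"):
    ped = ann.pedigree()
    viol = ped.validate(max_generations=ann.cfg.max_generations)
    if viol:
        raise RuntimeError(f"annealer reached invalid state: {viol}")
    br = total_score(ped, ann.table, ann.beta, ann.lam)
    if abs(br.total_log_score - ann.total()) > 1e-6:
        raise RuntimeError(
            f"incremental score {ann.total():.9f} != recomputed "
            f"{br.total_log_score:.9f}")


def run(table: PairLikelihoodTable, config: AnnealConfig,
        sex: Optional[dict] = None, age: Optional[dict] = None,
        start: Optional[Pedigree] = None):
    """One annealing run; returns (best pedigree, ScoreBreakdown, trace).

    The best configuration ever *encountered* is returned, not the final
    state.  Bit-reproducible for a fixed config seed.
    """
    if config.engine == "fast":
        return _run_fast(table, config, sex=sex, age=age, start=start)
    rng = np.random.Generator(np.random.PCG64(config.seed))
    ann = _Annealer(table, config, sex=sex, age=age, start=start)
    weights = _move_weights(config)
    t = config.t0
    best_score = ann.total()
    best_ped = ann.pedigree()
    proposals = 0
    stage = 0
    stalled = 0
    reheats_left = config.reheats
    trace = []
    move_stats: dict = {name: [0, 0] for name, _ in MOVES}
    while proposals < config.I:
        stage_start_best = best_score
        n_acc = 0
        budget = min(config.C, config.I - proposals)
        for _ in range(budget):
            name, edit = propose(ann, rng, weights)
            if edit == None:  # noqa: E711 - edit may be a tuple
                out = MoveOutcome(name, False, 0.0, False)
            elif isinstance(edit, tuple) and len(edit) == 2 and edit[0] == "sex":
                v = edit[1]
                anchor = ann.spouse_anchor(v)
                ann.sex_flip ^= {anchor}
                out = MoveOutcome(name, True, 0.0, True)
            else:
                out = ann.consider((name, edit), rng, t)
            proposals += 1
            st = move_stats[out.move]
            st[0] += 1
            st[1] += out.accepted
            if out.accepted:
                n_acc += 1
                cur = ann.total()
                if cur > best_score + 1e-12:
                    best_score = cur
                    best_ped = ann.pedigree()
            if config.check_every and proposals % config.check_every == 0:
                _consistency_check(ann)
        trace.append({"stage": stage, "t": t, "best": best_score,
                      "current": ann.total(),
                      "accept_rate": n_acc / max(budget, 1)})
        if config.cooling == "paper":
            t = t / config.f
        else:
            t = t * config.f
        stage += 1
        if best_score - stage_start_best < config.e and t >= 1.0:
            # only count stalls once the chain has cooled into its greedy
            # phase; cold stages rarely improve the incumbent by design
            stalled += 1
            if stalled >= config.stall_stages:
                if reheats_left > 0 and proposals < config.I:
                    reheats_left -= 1
                    stalled = 0
                    t = config.t0
                    ann = _Annealer(table, config, sex=sex, age=age,
                                    start=best_ped)
                else:
                    break
        else:
            stalled = 0
    best_ped = best_ped.canonical()
    breakdown = total_score(best_ped, table, config.beta,
                            config.lam if config.lam is not None else float(ann.n))
    return best_ped, breakdown, {"trace": trace, "moves": move_stats,
                                 "proposals": proposals}


MALE_HINT = "M"
FEMALE_HINT = "F"


def multi_start(table: PairLikelihoodTable, config: AnnealConfig,
                sex: Optional[dict] = None, age: Optional[dict] = None):
    """Best configuration over ``config.n_restarts`` independently seeded
    runs, with the per-run score list (to report spread across restarts)."""
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s) for s in ss.generate_state(max(config.n_restarts, 1))]
    results = []
    for sd in seeds:
        cfg = AnnealConfig(**{**config.__dict__, "seed": sd % (2 ** 31)})
        results.append(run(table, cfg, sex=sex, age=age))
    scores = [r[1].total_log_score for r in results]
    k = int(np.argmax(scores))
    best_ped, breakdown, info = results[k]
    return best_ped, breakdown, scores


def _spouse_anchor(P: dict, v):
    adj: dict = {}
    for x in P:
        if len(P[x]) == 2:
            a, b = P[x]
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
    if v not in adj:
        return v
    seen = {v}
    dq = deque([v])
    while dq:
        x = dq.popleft()
        for y in adj[x]:
            if y not in seen:
                seen.add(y)
                dq.append(y)
    return min(seen, key=str)


_Annealer.spouse_anchor = lambda self, v: _spouse_anchor(self.P, v)


def _run_fast(table: PairLikelihoodTable, config: AnnealConfig,
              sex: Optional[dict] = None, age: Optional[dict] = None,
              start: Optional[Pedigree] = None):
    """Compiled-kernel twin of the reference run loop (see _engine)."""
    from . import _engine as E

    n = table.n
    N = n + 64
    sexd = np.zeros(N, dtype=np.int8)
    agearr = np.full(N, np.nan)
    for k, i in enumerate(table.ids):
        s = (sex or {}).get(i)
        sexd[k] = 1 if s == "M" else 2 if s == "F" else 0
        if config.use_ages and age and i in age:
            agearr[k] = float(age[i])
    lam = config.lam if config.lam is not None else float(n)
    logpois = poisson.logpmf(np.arange(n + 64), lam)
    cidx, c_fs, c_self, c_unrel = E.prepare_class_index(table)
    affcum = E.build_affinity_cum(table)
    w = _move_weights(config)
    if w is None:
        w = np.full(len(MOVES), 1.0 / len(MOVES))
    move_cw = np.cumsum(w)
    par, mzp, alive, _ = E.state_arrays(table, start, N)
    max_stages = 8192
    trace_best = np.full(max_stages, np.nan)
    trace_cur = np.full(max_stages, np.nan)
    move_stats = np.zeros((len(MOVES), 2), dtype=np.int64)
    rng = np.random.Generator(np.random.PCG64(config.seed))
    best, proposals, nstage, cur = E.anneal_kernel(
        n, N, np.ascontiguousarray(table.ll), table.marginal, cidx,
        c_fs, c_self, c_unrel, logpois, float(config.beta), sexd, agearr,
        affcum, int(config.max_generations), float(config.t0),
        float(config.f), int(config.C), int(config.I), float(config.e),
        int(config.stall_stages), int(config.reheats),
        config.cooling == "paper", move_cw, rng, par, mzp, alive,
        trace_best, trace_cur, move_stats,
    )
    best_ped = E.decode_state(table, par, mzp, alive, sex, age).canonical()
    viol = best_ped.validate(max_generations=config.max_generations)
    if viol:
        raise RuntimeError(f"engine produced invalid pedigree: {viol}")
    breakdown = total_score(best_ped, table, config.beta, lam)
    if abs(breakdown.total_log_score - best) > 1e-6:
        raise RuntimeError(
            f"engine score {best:.9f} disagrees with recompute "
            f"{breakdown.total_log_score:.9f}")
    t = config.t0
    trace = []
    for s in range(nstage):
        trace.append({"stage": s, "t": t, "best": trace_best[s],
                      "current": trace_cur[s], "accept_rate": float("nan")})
        t = t / config.f if config.cooling == "paper" else t * config.f
    stats = {name: [int(move_stats[k, 0]), int(move_stats[k, 1])]
             for k, (name, _) in enumerate(MOVES)}
    return best_ped, breakdown, {"trace": trace, "moves": stats,
                                 "proposals": int(proposals)}
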