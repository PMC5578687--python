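"""Composite-likelihood scoring of pedigree configurations.

The composite likelihood of a local pedigree with sampled members H
(k = |H|) is

    CL(H) = P(X_1)                                 if k = 1
    CL(H) = prod_{(i,j) in H} P(X_i, X_j | R_ij)
            / prod_{i in H} P(X_i)^(k-2)           otherwise

i.e. the product of pairwise likelihoods rescaled so that each individual's
marginal is counted exactly once; when all pairs are unrelated it collapses
to the product of marginals (and for k <= 2 it *is* the full likelihood).
The score of a forest is the sum of its components' log CL plus a Poisson
regularizer beta * log Pr(Q = q) on the number q of local pedigrees, which
penalizes spurious joins in large samples.

An alternative scaling ("composite likelihood A") divides the pairwise
product by k - 1.  The printed product runs over ordered pairs i != j, but
taken literally that double-counts every pair and breaks the defining
property that the score collapses to the product of marginals when everyone
is unrelated; we therefore take the product over unordered pairs with
exponent 1/(k-1), which does collapse correctly and reduces to the single
pairwise term at k = 2.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional

from scipy.stats import poisson

from .hmm import PairLikelihoodTable
from .pedigree import Pedigree


@dataclass
class ScoreBreakdown:
    per_component_logCL: dict
    q: int
    beta: float
    lam: float
    total_log_score: float
    pairs_log: float = 0.0

    def regularizer(self) -> float:
        return self.beta * poisson.logpmf(self.q, self.lam)


def component_logcl(ped: Pedigree, comp, table: PairLikelihoodTable) -> float:
    """log CL of a single connected component (sampled members only count)."""
    H = sorted((i for i in comp if i in ped.sampled), key=str)
    k = len(H)
    if k == 0:
        return 0.0
    if k == 1:
        return table.marginal_loglik(H[0])
    s = 0.0
    for i, j in combinations(H, 2):
        s += table.pair_loglik(i, j, ped.relationship_between(i, j))
    s -= (k - 2) * sum(table.marginal_loglik(i) for i in H)
    return s


def local_cl(component_ped: Pedigree, table: PairLikelihoodTable,
             comp=None) -> float:
    """log composite likelihood of one local pedigree (Eq. CL above)."""
    if comp is None:
        comps = component_ped.components()
        if len(comps) != 1:
            raise ValueError("local_cl expects a single connected component")
        comp = comps[0]
    return component_logcl(component_ped, comp, table)


def alt_cl(component_ped: Pedigree, table: PairLikelihoodTable,
           comp=None) -> float:
    """Alternative composite likelihood: unordered pairwise product scaled
    by 1/(k-1).  Defined for k >= 2."""
    if comp is None:
        comps = component_ped.components()
        if len(comps) != 1:
            raise ValueError("alt_cl expects a single connected component")
        comp = comps[0]
    H = sorted((i for i in comp if i in component_ped.sampled), key=str)
    k = len(H)
    if k < 2:
        raise ValueError("alt_cl requires at least two sampled members")
    s = 0.0
    for i, j in combinations(H, 2):
        s += table.pair_loglik(i, j, component_ped.relationship_between(i, j))
    return s / (k - 1)


def total_score(ped: Pedigree, table: PairLikelihoodTable,
                beta: float = 1.0, lam: Optional[float] = None) -> ScoreBreakdown:
    """Regularized log score of a pedigree forest.

    ``q`` counts connected components over all individuals, singletons
    included.  ``lam`` defaults to the number of sampled individuals.
    """
    if lam is None:
        lam = float(len(ped.sampled))
    if lam <= 0 or beta < 0:
        raise ValueError("need lam > 0 and beta >= 0")
    comps = ped.components()
    per = {}
    pairs_log = 0.0
    for comp in comps:
        key = min(comp, key=str)
        per[key] = component_logcl(ped, comp, table)
        pairs_log += per[key]
    q = len(comps)
    total = pairs_log + beta * poisson.logpmf(q, lam)
    return ScoreBreakdown(per, q, beta, lam, float(total), pairs_log)


def delta_score(before: Pedigree, after: Pedigree, table: PairLikelihoodTable,
                beta: float = 1.0, lam: Optional[float] = None,
                touched=None) -> float:
    """Change in total score from ``before`` to ``after``.

    When ``touched`` (an iterable of individuals whose neighborhoods the edit
    modified) is given, only affected components are rescored; the result
    equals the full recompute up to float round-off.
    """
    if lam is None:
        lam = float(len(before.sampled))
    if touched is None:
        return total_score(after, table, beta, lam).total_log_score - \
            total_score(before, table, beta, lam).total_log_score
    touched = set(touched)
    old_comps, new_comps = [], []
    seen: set = set()
    for t in touched:
        if t in before.parents and t not in seen:
            c = before.component_of(t)
            seen |= c
            old_comps.append(c)
    seen = set()
    for t in touched:
        if t in after.parents and t not in seen:
            c = after.component_of(t)
            seen |= c
            new_comps.append(c)
    d = 0.0
    for c in new_comps:
        d += component_logcl(after, c, table)
    for c in old_comps:
        d -= component_logcl(before, c, table)
    d += beta * (poisson.logpmf(len(after.components()), lam)
                 - poisson.logpmf(len(before.components()), lam))
    return float(d)
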