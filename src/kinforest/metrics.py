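"""Evaluation of inferred pedigrees against the truth.

Two pairwise error measures are used.  The indicator error ``e`` is 0 iff
the estimated relationship has exactly the Cotterman coefficients of the
true one (so half sibs mistaken for grandparent-grandchild count as
correct: both are (1/2, 1/2, 0)).  The kinship distance
``d = |phi_hat - phi| / phi`` grades how far a wrong call is in expected
genome sharing; it is undefined for truly unrelated pairs, for which the
false-positive rate (share of pairs called related) is reported instead.
Whole-pedigree accuracy is the fraction of replicates whose estimate is
exactly isomorphic to the truth (sampled nodes fixed).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .hmm import PairLikelihoodTable
from .pedigree import Pedigree, isomorphic
from .relationships import (
    Relationship,
    enumerate_relationships,
    k_coefficients,
    kinship,
    lik_key,
    unrelated,
)

#: The kinship bins used for reporting, matching the phi categories of the
#: validation study: 0, 1/256, 1/128, ..., 1/4 (plus 1/2 for completeness).
PHI_BINS = (0.0, 1 / 512, 1 / 256, 1 / 128, 1 / 64, 1 / 32, 1 / 16, 1 / 8,
            1 / 4, 1 / 2)


class UnrelatedTruthError(ValueError):
    """Raised when d is requested for a truly unrelated pair: the kinship
    distance is undefined at phi = 0; report a false-positive rate instead."""


def pairwise_error_e(true_rel: Relationship, est_rel: Relationship) -> int:
    """0 iff k1 and k2 of the estimated relationship equal the truth's."""
    kt = k_coefficients(true_rel)
    ke = k_coefficients(est_rel)
    return 0 if (kt[1] == ke[1] and kt[2] == ke[2]) else 1


def kinship_distance_d(true_rel: Relationship, est_rel: Relationship) -> float:
    """Relative kinship distance |phi_hat - phi| / phi (phi > 0 required)."""
    phi = kinship(true_rel)
    if phi == 0:
        raise UnrelatedTruthError(
            "d undefined for unrelated truth; use the false-positive rate")
    return abs(kinship(est_rel) - phi) / phi


def exact_match_rate(estimates: Sequence[Pedigree],
                     truths: Sequence[Pedigree]) -> float:
    """Fraction of replicates whose estimate is isomorphic to its truth."""
    if len(estimates) != len(truths):
        raise ValueError("paired lists required")
    if not estimates:
        return float("nan")
    return float(np.mean([isomorphic(e, t) for e, t in zip(estimates, truths)]))


@dataclass
class PairwiseReport:
    """Per-pair truth/estimate comparison with phi-binned aggregates."""

    table: pd.DataFrame
    mean_e_by_bin: pd.Series
    median_d_by_bin: pd.Series
    false_positive_rate: float


def compare_pedigrees(est: Pedigree, truth: Pedigree) -> PairwiseReport:
    """Pairwise e and d for every sampled pair, binned by true phi."""
    if est.sampled != truth.sampled:
        raise ValueError("sampled sets differ")
    rows = []
    for i, j in combinations(sorted(truth.sampled, key=str), 2):
        rt = truth.relationship_between(i, j)
        re_ = est.relationship_between(i, j)
        phi_t, phi_e = kinship(rt), kinship(re_)
        rows.append({
            "i": i, "j": j, "phi_true": phi_t, "phi_hat": phi_e,
            "e": pairwise_error_e(rt, re_),
            "d": abs(phi_e - phi_t) / phi_t if phi_t > 0 else np.nan,
        })
    df = pd.DataFrame(rows)
    related = df[df.phi_true > 0]
    unrel = df[df.phi_true == 0]
    by_bin = related.groupby("phi_true")
    fpr = float((unrel.phi_hat > 0).mean()) if len(unrel) else np.nan
    return PairwiseReport(
        table=df,
        mean_e_by_bin=by_bin.e.mean(),
        median_d_by_bin=by_bin.d.median(),
        false_positive_rate=fpr,
    )


def pairwise_baseline(table: PairLikelihoodTable, c: float = 1.0,
                      rels: Optional[Sequence[Relationship]] = None) -> dict:
    """Per-pair argmax baseline: assign each pair the relationship with the
    highest pairwise likelihood, the unrelated entry scaled by ``c`` > 0
    (+log c in log space).  Ties break toward the smaller-kinship class."""
    if c <= 0:
        raise ValueError("c must be positive")
    if rels is None:
        rels = [r for r in enumerate_relationships() if r.kind != "self"]
    logc = float(np.log(c))
    out = {}
    ids = table.ids
    for x in range(len(ids)):
        for y in range(x + 1, len(ids)):
            i, j = ids[x], ids[y]
            best = None
            best_key = None
            for r in rels:
                v = table.pair_loglik(i, j, r)
                if r.kind == "unrelated":
                    v += logc
                key = (-v, kinship(r), str(lik_key(r)))
                if best is None or key < best:
                    best = key
                    best_key = r
            out[(i, j)] = best_key
    return out


def relative_detection_roc(scores: Sequence[float],
                           truth: Sequence[bool]) -> list[tuple[float, float]]:
    """ROC points for detecting related pairs from a per-pair score
    (higher = more related).  Includes the (0,0) and (1,1) endpoints and is
    monotone in the sweep."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(truth, dtype=bool)
    if len(s) != len(y):
        raise ValueError("scores and labels must align")
    P = max(int(y.sum()), 1)
    N = max(int((~y).sum()), 1)
    order = np.argsort(-s, kind="stable")
    tp = fp = 0
    pts = [(0.0, 0.0)]
    prev = None
    for k in order:
        if prev is not None and s[k] != prev:
            pts.append((fp / N, tp / P))
        if y[k]:
            tp += 1
        else:
            fp += 1
        prev = s[k]
    pts.append((fp / N, tp / P))
    if pts[-1] != (1.0, 1.0):
        pts.append((1.0, 1.0))
    return pts


def roc_auc(points: Sequence[tuple[float, float]]) -> float:
    xs, ys = zip(*points)
    return float(np.trapezoid(ys, xs))
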