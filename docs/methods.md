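# Methods

## The model

`kinforest` estimates the pedigree of a sample of `n` genotyped individuals
from biallelic SNP dosages.  The parameter of interest is a *forest of
local pedigrees*: a graph over the sampled individuals plus latent
(ungenotyped) connectors, in which an edge is a parent-offspring link.
Individuals are assumed outbred; the only permitted undirected cycles are
those created by full siblings, and each connected component may span at
most five generations (configurable).

### Pairwise relationship classes

An outbred pairwise relationship is `(u, d, a)`: the meiosis counts from
each individual to the most recent common ancestor(s) and the number of
those ancestors (1 or 2).  Its Cotterman coefficients are

    k2 = 0           (except full siblings (1/4, 1/2, 1/4) and self)
    k1 = a * 2^-(u+d-1)
    k0 = 1 - k1 - k2

and the kinship coefficient is `phi = k1/4 + k2/2`.  Under the five
generation cap, `u, d <= 4`, so the enumerable classes run from
parent-offspring (`phi = 1/4`) down to half third cousins (`phi = 1/512`).
Classes with equal `(k0, k1, k2)` *and* equal total meiosis count
`m = u + d` (for example half sibs and grandparent-grandchild) are
genotype-likelihood equivalent; they are distinguished, if at all, only by
the joint structure of the pedigree and by declared sexes and ages.

### Pairwise likelihoods: the IBD hidden Markov model

`P(X_i, X_j | R)` is computed by a forward pass over the genome with the
hidden state the number of alleles shared identical by descent (0, 1, 2).
The stationary distribution is `(k0, k1, k2)`; IBD tracts break up at rate
`m` per Morgan (expected tract length `100/m` cM), the re-entry rate being
fixed by stationarity.  For single-ancestor paths this rate is exact under
Haldane crossovers: every path crossover terminates sharing.  For
two-ancestor (couple) classes whose closer member is the couple's own
child (u or d equal to 1: avuncular, grand-avuncular, ...), a crossover in
the couple-child's meiosis switches the shared source between the couple's
haplotypes and with probability 1/2 hands the tract over rather than
ending it, so abutting tracts merge; the exact first-moment boundary rate
is `m - 1/2`, verified against gene-dropped data (e.g. 1.75 predicted vs
1.74 observed boundaries per Morgan for the u=1, d=3 couple class; deeper
couple classes such as first cousins measure `m` to within one percent).
This calibration matters: the equal-kinship alias pair ((m, a=1) versus
(m+1, a=2)) is separated only by this rate, and the uncalibrated
meiosis-count rate sits almost exactly at the likelihood-neutral point
between the two hypotheses.  Full siblings use the product of two
independent parental chains (symmetric switch rate 2 per Morgan each),
aggregated over the IBD count; all constructions are proper
continuous-time Markov chains.
The published method delegates its pairwise likelihood to an external
IBD-HMM and notes that any pairwise likelihood definition can be plugged
in; the meiosis-rate parameterization used here is self-contained and has
closed forms that the test-suite verifies against matrix exponentials and
brute-force path sums.

Emissions assume Hardy-Weinberg equilibrium at supplied allele frequencies
and inter-locus independence given the IBD state (markers are LD-pruned
before inference).  Genotyping error is an independent per-allele flip with
probability `e` (default 0.01) applied through a 3x3 channel on both
individuals.  Missing genotypes are marginalized.  The chain restarts at
its stationary distribution on every chromosome.

All pairwise values are precomputed into a table: `O(n^2 s L)` for `s`
likelihood-distinct classes (19 under the default cap).  Unrelated entries
are stored as the exact sum of the two marginals, so the factorization
identity holds to machine precision.

### Composite likelihood

For a local pedigree with sampled members H (k = |H|),

    log CL(H) = sum_{i<j in H} log P(X_i, X_j | R_ij)
                - (k - 2) * sum_{i in H} log P(X_i)           (k >= 2)

with `log CL = log P(X_1)` for k = 1.  For k <= 2 this *is* the full
likelihood, and when all pairs are unrelated it collapses to the sum of
marginals.  The score of a forest adds the component scores plus a Poisson
regularizer on the number of components q (singletons included):

    log CL*(X) = sum_components log CL + beta * log Poisson(q; lambda)

`lambda` defaults to n (an `n/2` option matches the low-marker usage
reported for the published empirical analysis).  An alternative scaling
(product of unordered pairwise likelihoods to the power `1/(k-1)`) is
provided as `alt_cl`; it preserves the full-likelihood ordering but is a
much flatter surface, which the tests verify against an exact small-family
oracle at independent loci.

### Choice of beta (default 10)

`beta = 1` makes the per-join prior penalty at q near n about 0.6 log
units.  Measured on desk-scale fixtures (18 samples, thousands of pruned
markers), the *maximum* spurious gain of attaching one truly unrelated
individual to an existing family through a distant (m >= 5) relationship
has a null distribution reaching ~6 log units - so under `beta = 1` the
maximum-score configuration provably differs from the truth by several
false attachments, and no search can report the true pedigree.  The
default `beta = 10` makes the marginal penalty for one extra join exceed
that null tail while leaving genuine close-relative gains (tens to
hundreds of log units) untouched.  The regularizer still carries a
structural subtlety: the *first* join from the all-singleton state is
prior-free under `lambda = n` (the Poisson pmf is flat between q = n-1 and
n), so false-positive control for the very first merge rests entirely on
the likelihood.

## The search

Simulated annealing from the all-singleton state.  A proposal is one of 22
move types in three classes: (1) pair-relationship relabels among
likelihood-adjacent classes (parent-offspring <-> full/half sibs,
grandparental <-> half sibs, avuncular reversals and conversions, edge
stretch/contract, monozygotic-pair marking); (2) component surgery -
splits (detach a sub-pedigree, orphan a child subset), joins through new
common ancestors at most two meioses above each endpoint (deeper links are
built incrementally by stretch moves), and an atomic detach-and-reattach;
(3) symmetry moves: swap an individual with a descendant when ages are
unknown, flip the sex coloring of a latent spouse group.  Invalid
proposals are rejected outright.  Acceptance is
`min[(CL_new / CL_old)^t, 1]`; `t` is treated as an *inverse* temperature
multiplied by `f > 1` per stage of `C` proposals, because a rule that
cools as printed (dividing t) becomes more permissive over time and
never converges; a `cooling="paper"` flag restores the literal reading.

Two search aids do not alter the scoring model: proposals that need a
partner for a join or re-attachment draw sampled partners with probability
proportional to their best pairwise relatedness gain over the unrelated
baseline (informed proposals); and when the chain stalls after cooling it
can reheat from the incumbent best state (`reheats`).  The best-scoring
state ever encountered is reported, over `n_restarts` independently seeded
runs; results are bit-reproducible for a fixed seed.

## The synthetic-data generator

The generator reproduces the validation conditions of the study design:
four frozen scenario pedigrees (A: 45-member five-generation family with
10 of 45 sampled plus 10 singletons; B: four clusters of 15-18 members
with 4 sampled each plus 4 singletons; C: 16-member pedigree with 9
sampled, 7 missing, plus 9 singletons, every sampled family member having
a sampled parent or child; D: a variant of C whose sampled sub-cluster
hangs off the rest only through an avuncular link).  Sampled pairwise
kinships span 1/4 to 1/256 in every scenario.  Published drawings do not
pin every edge; the frozen topologies satisfy all printed constraints and
ship as the reference truth.

Founder haplotypes come either from msprime (Ne = 10,000, recombination
1.3e-8/bp, mutation 1.25e-8/bp, 22 human autosome lengths - used for the
genome-scale LD-pruning experiment) or from a fast linkage-equilibrium
generator (Bernoulli haplotypes at a truncated-Beta(0.8, 0.8) frequency
spectrum on an evenly spaced 22-chromosome map), which is the default for
scenario fixtures: after r^2 pruning the real pipeline is close to linkage
equilibrium anyway, and the fast generator makes the HMM's emission
assumptions exactly true so that scenario failures isolate search and
model-resolution effects rather than residual-LD artifacts.  What passing
scenario tests do *not* show is robustness to background LD, allele
frequency misspecification beyond a 100-founder panel, or population
structure.

Gene-dropping transmits recombinant gametes (Haldane crossovers as a
Poisson process on the cM map, no interference); founder-origin labels are
carried so realized IBD is known exactly.  Single-parent members receive
one fresh population haplotype.  Genotyping error flips each allele
independently (0.01).  A 100-founder panel is simulated alongside each
scenario; allele frequencies are estimated from it with a 0.5 pseudo-count
and deconvolved for the error channel, and LD pruning correlations are
computed on the panel, not on the related samples.

LD pruning is greedy left-to-right: a marker survives iff its squared
dosage correlation with every kept marker in the trailing window (same
chromosome) stays at or below the threshold.  The window is genetic
(default 0.5 cM); the published pipeline pruned with PLINK whose window
settings are not printed, and the genome-scale marker yield depends on
them - the default was chosen once so that a full-autosome coalescent
panel pruned at r^2 = 0.05 lands near the reported "about 10,000 markers"
order of magnitude.

## Problem sizes and numerical choices

Scenario fixtures default to 10,000 pruned markers, the marker count of
the published simulations.  At 3,000 markers the likelihood gap between
equal-k1 alias structures (for example `(m, a=1)` versus `(m+1, a=2)`
wirings) is of order one log unit and exact recovery degrades for
information-theoretic reasons, so the desk-scale validation keeps the
published marker count and scales down the replicate count instead (20
replicates for scenario C, 30 for D, 3 restarts each).  Tolerances:
the unrelated-factorization identity is asserted at 1e-9 absolute;
incremental score deltas are guarded against a full recompute at 1e-6
(checked every `check_every` proposals); impossible genotype pairs under a
relationship give a -inf log-likelihood rather than an error.  Ties in the
argmax baseline break toward the smaller kinship class.  Degenerate
inputs: monomorphic sites are dropped before inference; frequencies are
clamped off 0 and 1; missing genotypes contribute nothing.

## Known limitations

Inbred pedigrees, double first cousins and other non-full-sib cycles are
rejected, not modeled.  Half sibs, grandparental and avuncular wirings
with equal `(k, m)` are only resolved through joint structure, sex and age
constraints, and genuinely non-identifiable cases exist.  The annealer is
a heuristic: the best-encountered configuration can sit in a local
optimum, which is why multiple restarts (and their score spread) are
reported.  X-chromosome models, phased input, and population-structure
frequency adjustment are out of scope.
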