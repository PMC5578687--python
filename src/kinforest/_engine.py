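"""Array-based annealing kernel (numba).

The Python annealer in :mod:`kinforest.anneal` is the reference
implementation of the move catalog and scoring; this module is its
compiled twin, used by ``run()`` for production searches where the budget
is millions of proposals (a few microseconds each).  Nodes live in
fixed-size int32 arrays: sampled individuals occupy slots ``0..n-1``,
latent connectors are allocated from a free list.  Every proposal forks
the graph buffers, edits the fork, scores the affected components before
and after, applies the annealing acceptance rule, validates the accepted
state, and commits by buffer swap.  The kernel's final incremental score
is audited against the pure Python scorer by the caller.
"""
from __future__ import annotations

import numpy as np
from numba import njit

NONE = -1
MAXC = 12          # max children per node tracked
STACK = 96

# move indices, matching kinforest.anneal.MOVES order
(M_PO2FS, M_FS2PO, M_PO2HS, M_HS2PO, M_AVREV, M_GP2HS, M_HS2GP, M_HS2AV,
 M_AV2HS, M_MZMARK, M_MZUNMARK, M_STRETCH, M_CONTRACT, M_ATTACH, M_DETACH,
 M_SPLITSUB, M_SPLITCH, M_JOINHS, M_JOINCA, M_SPLITJOIN, M_SWAPDESC,
 M_FLIPSEX) = range(22)


# ----------------------------------------------------------------- helpers
@njit(cache=True)
def _chd_remove(chd, nch, p, c):
    for k in range(nch[p]):
        if chd[p, k] == c:
            chd[p, k] = chd[p, nch[p] - 1]
            nch[p] -= 1
            return


@njit(cache=True)
def _chd_add(chd, nch, p, c):
    if nch[p] < MAXC:
        chd[p, nch[p]] = c
    nch[p] += 1  # counts beyond MAXC make the proposal invalid later


@njit(cache=True)
def _set_par(par, chd, nch, tlist, tn, c, p0, p1):
    """Replace c's parent row, maintaining child lists and the touched set."""
    for s in range(2):
        old = par[c, s]
        if old >= 0:
            _chd_remove(chd, nch, old, c)
            if tn[0] < tlist.shape[0]:
                tlist[tn[0]] = old
                tn[0] += 1
    par[c, 0] = p0
    par[c, 1] = p1
    for s in range(2):
        p = par[c, s]
        if p >= 0:
            _chd_add(chd, nch, p, c)
            if tn[0] < tlist.shape[0]:
                tlist[tn[0]] = p
                tn[0] += 1
    if tn[0] < tlist.shape[0]:
        tlist[tn[0]] = c
        tn[0] += 1


@njit(cache=True)
def _alloc(alive, par, nch, freelist, nfree):
    if nfree[0] == 0:
        return -1
    nfree[0] -= 1
    v = freelist[nfree[0]]
    alive[v] = True
    par[v, 0] = NONE
    par[v, 1] = NONE
    nch[v] = 0
    return v


@njit(cache=True)
def _free(alive, freelist, nfree, v):
    alive[v] = False
    freelist[nfree[0]] = v
    nfree[0] += 1


@njit(cache=True)
def _comp_members(par, nch, chd, start, members, seen, stamp):
    head = 0
    cnt = 1
    members[0] = start
    seen[start] = stamp
    while head < cnt:
        v = members[head]
        head += 1
        for s in range(2):
            p = par[v, s]
            if p >= 0 and seen[p] != stamp:
                seen[p] = stamp
                members[cnt] = p
                cnt += 1
        for k in range(min(nch[v], MAXC)):
            c = chd[v, k]
            if seen[c] != stamp:
                seen[c] = stamp
                members[cnt] = c
                cnt += 1
    return cnt


@njit(cache=True)
def _score_comp(par, members, cnt, n_samp, mzp, ll, marg, cidx,
                c_fs, c_self, c_unrel, danc):
    """log composite likelihood of one component."""
    k = 0
    for t in range(cnt):
        if members[t] < n_samp:
            k += 1
    if k == 0:
        return 0.0
    H = np.empty(k, dtype=np.int32)
    j = 0
    for t in range(cnt):
        if members[t] < n_samp:
            H[j] = members[t]
            j += 1
    H.sort()
    if k == 1:
        return marg[H[0]]
    # ancestor depths (min meioses) of each sampled member to every node
    for a in range(k):
        for t in range(cnt):
            danc[a, members[t]] = -1
        stack = np.empty(STACK, dtype=np.int32)
        dstack = np.empty(STACK, dtype=np.int32)
        top = 0
        stack[0] = H[a]
        dstack[0] = 0
        top = 1
        guard = 0
        while top > 0:
            guard += 1
            if guard > 200 * cnt:  # pathological graph: force rejection
                return -np.inf
            top -= 1
            v = stack[top]
            d = dstack[top]
            if danc[a, v] >= 0 and danc[a, v] <= d:
                continue
            danc[a, v] = d
            for s in range(2):
                p = par[v, s]
                if p >= 0 and top < STACK - 2:
                    stack[top] = p
                    dstack[top] = d + 1
                    top += 1
    total = 0.0
    msum = 0.0
    for a in range(k):
        msum += marg[H[a]]
    for a in range(k):
        for b in range(a + 1, k):
            i = H[a]
            jj = H[b]
            if mzp[i] == jj:
                ci = c_self
            else:
                best = 127
                na = 0
                bu = 0
                bd = 0
                for t in range(cnt):
                    v = members[t]
                    da = danc[a, v]
                    db = danc[b, v]
                    if da >= 0 and db >= 0:
                        s = da + db
                        if s < best:
                            best = s
                            na = 1
                            bu = da
                            bd = db
                        elif s == best:
                            na += 1
                if best == 127:
                    ci = c_unrel
                elif bu == 1 and bd == 1 and na >= 2:
                    ci = c_fs
                elif best <= 9:
                    if na >= 2:
                        cc = 1 if min(bu, bd) == 1 else 2
                        ci = cidx[best, 2, cc]
                    else:
                        ci = cidx[best, 1, 0]
                else:
                    ci = -1
            if ci < 0:
                return -np.inf
            total += ll[ci, i, jj]
    return total - (k - 2) * msum


@njit(cache=True)
def _validate_comp(par, nch, chd, members, cnt, n_samp, mzp, sexd, age,
                   max_gen, lidx, aux, aux2):
    """Validity of one component; lidx/aux/aux2 are scratch arrays (len N).
    lidx must be dedicated to this function (it holds node -> local index
    maps between calls and must never alias the BFS stamp arrays)."""
    # arity / duplicates / overflow
    for t in range(cnt):
        v = members[t]
        if nch[v] > MAXC:
            return False
        p0 = par[v, 0]
        p1 = par[v, 1]
        if p0 == v or p1 == v:
            return False
        if p0 >= 0 and p0 == p1:
            return False
    # longest generation chain + directed cycles (iterative DFS)
    # aux: 0 unvisited, 1 in-progress, 2 done; aux2: depth
    for t in range(cnt):
        aux[members[t]] = 0
        aux2[members[t]] = 0
    for t in range(cnt):
        root = members[t]
        if aux[root] != 0:
            continue
        stack = np.empty(4 * STACK, dtype=np.int32)
        top = 0
        stack[0] = root
        top = 1
        guard = 0
        while top > 0:
            guard += 1
            if guard > 200 * cnt:
                return False
            v = stack[top - 1]
            if aux[v] == 0:
                aux[v] = 1
                pushed = False
                for s in range(2):
                    p = par[v, s]
                    if p >= 0:
                        if aux[p] == 1:
                            return False  # directed cycle
                        if aux[p] == 0:
                            if top >= stack.shape[0] - 1:
                                return False
                            stack[top] = p
                            top += 1
                            pushed = True
                if pushed:
                    continue
            # children resolved or revisit: finalize
            d = 1
            ok = True
            for s in range(2):
                p = par[v, s]
                if p >= 0:
                    if aux[p] != 2:
                        ok = False
                        break
                    if aux2[p] + 1 > d:
                        d = aux2[p] + 1
            if ok:
                aux2[v] = d
                aux[v] = 2
                top -= 1
            # else: parents still pending on the stack
        # pass
    deepest = 0
    for t in range(cnt):
        if aux2[members[t]] > deepest:
            deepest = aux2[members[t]]
    if deepest > max_gen:
        return False
    # undirected cycles: E - V + 1 must equal sum over couples (children-1)
    E = 0
    two = 0
    distinct = 0
    for t in range(cnt):
        v = members[t]
        for s in range(2):
            if par[v, s] >= 0:
                E += 1
        if par[v, 0] >= 0 and par[v, 1] >= 0:
            two += 1
            first = True
            for u in range(t):
                w = members[u]
                if par[w, 0] >= 0 and par[w, 1] >= 0:
                    same = (par[w, 0] == par[v, 0] and par[w, 1] == par[v, 1]) \
                        or (par[w, 0] == par[v, 1] and par[w, 1] == par[v, 0])
                    if same:
                        first = False
                        break
            if first:
                distinct += 1
    if E - cnt + 1 != two - distinct:
        return False
    # sexes: spouse graph 2-colorable respecting declared sexes
    # union-find with parity over comp-local indices
    for t in range(cnt):
        lidx[members[t]] = t          # node -> local index
        aux[members[t]] = t           # UF parent (local)
        aux2[members[t]] = 0          # parity to UF parent
    for t in range(cnt):
        v = members[t]
        if par[v, 0] >= 0 and par[v, 1] >= 0:
            a = par[v, 0]
            b = par[v, 1]
            # find roots with parity
            ra = lidx[a]
            pa = 0
            g1 = 0
            while aux[members[ra]] != ra:
                pa ^= aux2[members[ra]]
                ra = aux[members[ra]]
                g1 += 1
                if g1 > cnt + 2:
                    return False
            rb = lidx[b]
            pb = 0
            g1 = 0
            while aux[members[rb]] != rb:
                pb ^= aux2[members[rb]]
                rb = aux[members[rb]]
                g1 += 1
                if g1 > cnt + 2:
                    return False
            if ra == rb:
                if pa == pb:
                    return False  # odd spouse cycle
            else:
                aux[members[ra]] = rb
                aux2[members[ra]] = pa ^ pb ^ 1
    # declared-sex consistency within each UF set
    for t in range(cnt):
        v = members[t]
        if v < n_samp and sexd[v] != 0:
            rv = t
            pv = 0
            g1 = 0
            while aux[members[rv]] != rv:
                pv ^= aux2[members[rv]]
                rv = aux[members[rv]]
                g1 += 1
                if g1 > cnt + 2:
                    return False
            for u in range(t):
                w = members[u]
                if w < n_samp and sexd[w] != 0:
                    rw = u
                    pw = 0
                    g1 = 0
                    while aux[members[rw]] != rw:
                        pw ^= aux2[members[rw]]
                        rw = aux[members[rw]]
                        g1 += 1
                        if g1 > cnt + 2:
                            return False
                    if rw == rv:
                        if (pv == pw) != (sexd[v] == sexd[w]):
                            return False
    # ages
    for t in range(cnt):
        v = members[t]
        if v < n_samp and age[v] == age[v]:
            for s in range(2):
                p = par[v, s]
                if p >= 0 and p < n_samp and age[p] == age[p]:
                    if age[p] <= age[v]:
                        return False
    # duplicate (mz) pairs: childless full siblings
    for t in range(cnt):
        v = members[t]
        m = mzp[v]
        if m >= 0:
            if mzp[m] != v:
                return False
            if nch[v] > 0 or nch[m] > 0:
                return False
            if par[v, 0] < 0:
                return False
            same = (par[v, 0] == par[m, 0] and par[v, 1] == par[m, 1]) or \
                   (par[v, 0] == par[m, 1] and par[v, 1] == par[m, 0])
            if not same:
                return False
    return True


# -------------------------------------------------------------------- moves
@njit(cache=True)
def _rand_alive(rng, alive, N, n_samp, bias):
    """Random alive node, preferring sampled slots with probability bias."""
    if rng.random() < bias:
        return int(rng.integers(0, n_samp))
    for _ in range(24):
        v = int(rng.integers(0, N))
        if alive[v]:
            return v
    return int(rng.integers(0, n_samp))


@njit(cache=True)
def _rand_child(rng, par, alive, N, n_samp):
    """Random alive node that has at least one parent (a random edge)."""
    for _ in range(24):
        v = _rand_alive(rng, alive, N, n_samp, 0.55)
        if par[v, 0] >= 0 or par[v, 1] >= 0:
            return v
    return -1


@njit(cache=True)
def _rand_parent_of(rng, par, v):
    if par[v, 0] >= 0 and par[v, 1] >= 0:
        return par[v, int(rng.integers(0, 2))]
    if par[v, 0] >= 0:
        return par[v, 0]
    return par[v, 1]


@njit(cache=True)
def _affinity_partner(rng, affcum, i):
    r = rng.random()
    n = affcum.shape[1]
    lo = 0
    hi = n - 1
    while lo < hi:
        mid = (lo + hi) // 2
        if affcum[i, mid] < r:
            lo = mid + 1
        else:
            hi = mid
    return lo


@njit(cache=True)
def _partner(rng, affcum, alive, N, n_samp, i):
    """Join partner: affinity-steered for sampled i, random otherwise."""
    if i < n_samp and rng.random() < 0.7:
        j = _affinity_partner(rng, affcum, i)
        if j != i:
            return j
    for _ in range(24):
        j = _rand_alive(rng, alive, N, n_samp, 0.55)
        if j != i:
            return j
    return -1


@njit(cache=True)
def _replace_par(par, chd, nch, tlist, tn, c, old, new):
    p0 = par[c, 0]
    p1 = par[c, 1]
    if p0 == old:
        _set_par(par, chd, nch, tlist, tn, c, new, p1)
    elif p1 == old:
        _set_par(par, chd, nch, tlist, tn, c, p0, new)


@njit(cache=True)
def _swap_nodes(par, chd, nch, alive, N, tlist, tn, i, j):
    """Exchange the graph positions of i and j."""
    # collect children of i and j first (lists change during edits)
    ci = np.empty(MAXC, dtype=np.int32)
    nci = min(nch[i], MAXC)
    for k in range(nci):
        ci[k] = chd[i, k]
    cj = np.empty(MAXC, dtype=np.int32)
    ncj = min(nch[j], MAXC)
    for k in range(ncj):
        cj[k] = chd[j, k]
    pi0, pi1 = par[i, 0], par[i, 1]
    pj0, pj1 = par[j, 0], par[j, 1]

    def sw(x):
        if x == i:
            return j
        if x == j:
            return i
        return x

    _set_par(par, chd, nch, tlist, tn, i, sw(pj0), sw(pj1))
    _set_par(par, chd, nch, tlist, tn, j, sw(pi0), sw(pi1))
    for k in range(nci):
        c = ci[k]
        if c != i and c != j:
            _replace_par(par, chd, nch, tlist, tn, c, i, j)
    for k in range(ncj):
        c = cj[k]
        if c != i and c != j:
            _replace_par(par, chd, nch, tlist, tn, c, j, i)


@njit(cache=True)
def _apply_move(mk, rng, par, chd, nch, alive, mzp, flip, freelist, nfree,
                tlist, tn, N, n_samp, affcum):
    """Generate and apply one move on the working buffers.

    Returns 1 on success, 0 if infeasible (null edit)."""
    if mk == M_PO2FS:
        c = _rand_child(rng, par, alive, N, n_samp)
        if c < 0:
            return 0
        p = _rand_parent_of(rng, par, c)
        if par[p, 0] < 0:
            g = _alloc(alive, par, nch, freelist, nfree)
            if g < 0:
                return 0
            _set_par(par, chd, nch, tlist, tn, p, g, par[p, 1])
        if par[p, 1] < 0:
            g = _alloc(alive, par, nch, freelist, nfree)
            if g < 0:
                return 0
            _set_par(par, chd, nch, tlist, tn, p, par[p, 0], g)
        _set_par(par, chd, nch, tlist, tn, c, par[p, 0], par[p, 1])
        return 1

    if mk == M_FS2PO:
        for _ in range(12):
            c1 = _rand_alive(rng, alive, N, n_samp, 0.55)
            if par[c1, 0] >= 0 and par[c1, 1] >= 0:
                p = par[c1, 0]
                for k in range(min(nch[p], MAXC)):
                    c2 = chd[p, k]
                    if c2 != c1 and (
                        (par[c2, 0] == par[c1, 0] and par[c2, 1] == par[c1, 1])
                        or (par[c2, 0] == par[c1, 1] and par[c2, 1] == par[c1, 0])):
                        _set_par(par, chd, nch, tlist, tn, c2, c1, NONE)
                        return 1
        return 0

    if mk == M_PO2HS:
        c = _rand_child(rng, par, alive, N, n_samp)
        if c < 0:
            return 0
        p = _rand_parent_of(rng, par, c)
        other = par[c, 0] if par[c, 1] == p else par[c, 1]
        if par[p, 0] >= 0 or par[p, 1] >= 0:
            x = _rand_parent_of(rng, par, p)
        else:
            x = _alloc(alive, par, nch, freelist, nfree)
            if x < 0:
                return 0
            _set_par(par, chd, nch, tlist, tn, p, x, NONE)
        if x == other:
            return 0
        _set_par(par, chd, nch, tlist, tn, c, other, x)
        return 1

    if mk == M_HS2PO or mk == M_HS2GP or mk == M_HS2AV:
        for _ in range(12):
            g = _rand_alive(rng, alive, N, n_samp, 0.4)
            if nch[g] >= 2 and nch[g] <= MAXC:
                c1 = chd[g, int(rng.integers(0, nch[g]))]
                c2 = chd[g, int(rng.integers(0, nch[g]))]
                if c1 == c2:
                    return 0
                if mk == M_HS2PO:
                    if c1 == par[c2, 0] or c1 == par[c2, 1]:
                        return 0
                    _replace_par(par, chd, nch, tlist, tn, c2, g, c1)
                elif mk == M_HS2GP:
                    m = _alloc(alive, par, nch, freelist, nfree)
                    if m < 0:
                        return 0
                    _set_par(par, chd, nch, tlist, tn, m, c1, NONE)
                    _replace_par(par, chd, nch, tlist, tn, c2, g, m)
                else:
                    m = _alloc(alive, par, nch, freelist, nfree)
                    if m < 0:
                        return 0
                    _set_par(par, chd, nch, tlist, tn, m, par[c1, 0], par[c1, 1])
                    _replace_par(par, chd, nch, tlist, tn, c2, g, m)
                return 1
        return 0

    if mk == M_AVREV or mk == M_AV2HS:
        i = _rand_alive(rng, alive, N, n_samp, 0.55)
        if par[i, 0] < 0 and par[i, 1] < 0:
            return 0
        p = _rand_parent_of(rng, par, i)
        if nch[p] < 2 or nch[p] > MAXC:
            return 0
        m = chd[p, int(rng.integers(0, nch[p]))]
        if m == i or nch[m] == 0 or nch[m] > MAXC:
            return 0
        j = chd[m, int(rng.integers(0, nch[m]))]
        if j == i:
            return 0
        if mk == M_AVREV:
            _swap_nodes(par, chd, nch, alive, N, tlist, tn, i, j)
        else:
            _replace_par(par, chd, nch, tlist, tn, j, m, p)
        return 1

    if mk == M_GP2HS:
        j = _rand_child(rng, par, alive, N, n_samp)
        if j < 0:
            return 0
        m = _rand_parent_of(rng, par, j)
        if par[m, 0] < 0 and par[m, 1] < 0:
            return 0
        i = _rand_parent_of(rng, par, m)
        if par[i, 0] >= 0 or par[i, 1] >= 0:
            x = _rand_parent_of(rng, par, i)
        else:
            x = _alloc(alive, par, nch, freelist, nfree)
            if x < 0:
                return 0
            _set_par(par, chd, nch, tlist, tn, i, x, NONE)
        _replace_par(par, chd, nch, tlist, tn, j, m, x)
        return 1

    if mk == M_MZMARK:
        for _ in range(12):
            c1 = _rand_alive(rng, alive, N, n_samp, 0.8)
            if par[c1, 0] >= 0 and par[c1, 1] >= 0 and nch[c1] == 0 \
                    and mzp[c1] < 0:
                p = par[c1, 0]
                for k in range(min(nch[p], MAXC)):
                    c2 = chd[p, k]
                    if c2 != c1 and nch[c2] == 0 and mzp[c2] < 0 and (
                        (par[c2, 0] == par[c1, 0] and par[c2, 1] == par[c1, 1])
                        or (par[c2, 0] == par[c1, 1] and par[c2, 1] == par[c1, 0])):
                        mzp[c1] = c2
                        mzp[c2] = c1
                        tlist[tn[0]] = c1
                        tn[0] += 1
                        tlist[tn[0]] = c2
                        tn[0] += 1
                        return 1
        return 0

    if mk == M_MZUNMARK:
        for _ in range(12):
            v = _rand_alive(rng, alive, N, n_samp, 0.8)
            if mzp[v] >= 0:
                w = mzp[v]
                mzp[v] = NONE
                mzp[w] = NONE
                tlist[tn[0]] = v
                tn[0] += 1
                tlist[tn[0]] = w
                tn[0] += 1
                return 1
        return 0

    if mk == M_STRETCH:
        c = _rand_child(rng, par, alive, N, n_samp)
        if c < 0:
            return 0
        p = _rand_parent_of(rng, par, c)
        m = _alloc(alive, par, nch, freelist, nfree)
        if m < 0:
            return 0
        _set_par(par, chd, nch, tlist, tn, m, p, NONE)
        _replace_par(par, chd, nch, tlist, tn, c, p, m)
        return 1

    if mk == M_CONTRACT:
        for _ in range(12):
            m = _rand_alive(rng, alive, N, n_samp, 0.3)
            if (par[m, 0] >= 0 or par[m, 1] >= 0) and 0 < nch[m] <= MAXC:
                p = _rand_parent_of(rng, par, m)
                c = chd[m, int(rng.integers(0, nch[m]))]
                if p == par[c, 0] or p == par[c, 1]:
                    return 0
                _replace_par(par, chd, nch, tlist, tn, c, m, p)
                return 1
        return 0

    if mk == M_ATTACH:
        j = _rand_alive(rng, alive, N, n_samp, 0.55)
        if par[j, 0] >= 0 and par[j, 1] >= 0:
            return 0
        i = _partner(rng, affcum, alive, N, n_samp, j)
        if i < 0 or i == par[j, 0] or i == par[j, 1]:
            return 0
        _set_par(par, chd, nch, tlist, tn, j,
                 par[j, 0] if par[j, 0] >= 0 else i,
                 i if par[j, 0] >= 0 else NONE)
        return 1

    if mk == M_DETACH:
        c = _rand_child(rng, par, alive, N, n_samp)
        if c < 0:
            return 0
        p = _rand_parent_of(rng, par, c)
        _replace_par(par, chd, nch, tlist, tn, c, p, NONE)
        # normalize (x, -1) ordering
        if par[c, 0] < 0 and par[c, 1] >= 0:
            _set_par(par, chd, nch, tlist, tn, c, par[c, 1], NONE)
        return 1

    if mk == M_SPLITSUB:
        v = _rand_child(rng, par, alive, N, n_samp)
        if v < 0:
            return 0
        _set_par(par, chd, nch, tlist, tn, v, NONE, NONE)
        return 1

    if mk == M_SPLITCH:
        for _ in range(12):
            p = _rand_alive(rng, alive, N, n_samp, 0.4)
            if 2 <= nch[p] <= MAXC:
                take = np.empty(MAXC, dtype=np.int32)
                nt = 0
                kids = np.empty(MAXC, dtype=np.int32)
                nk = nch[p]
                for k in range(nk):
                    kids[k] = chd[p, k]
                for k in range(nk):
                    if rng.random() < 0.5:
                        take[nt] = kids[k]
                        nt += 1
                if nt == 0:
                    take[0] = kids[int(rng.integers(0, nk))]
                    nt = 1
                # taking every child relocates the whole sibling group and
                # retires the old parent couple via cleanup
                mode = int(rng.integers(0, 3))
                if mode == 0:
                    for k in range(nt):
                        _set_par(par, chd, nch, tlist, tn, take[k], NONE, NONE)
                    return 1
                if mode == 1:
                    g1 = _alloc(alive, par, nch, freelist, nfree)
                    g2 = _alloc(alive, par, nch, freelist, nfree)
                    if g1 < 0 or g2 < 0:
                        return 0
                    for k in range(nt):
                        _set_par(par, chd, nch, tlist, tn, take[k], g1, g2)
                    return 1
                anchor = -1
                for k in range(nt):
                    if take[k] < n_samp and rng.random() < 0.8:
                        anchor = _affinity_partner(rng, affcum, take[k])
                        break
                if anchor < 0:
                    anchor = _rand_alive(rng, alive, N, n_samp, 0.55)
                if anchor == p:
                    return 0
                for k in range(nt):
                    if take[k] == anchor:
                        return 0
                g = _alloc(alive, par, nch, freelist, nfree)
                if g < 0:
                    return 0
                for k in range(nt):
                    _set_par(par, chd, nch, tlist, tn, take[k], anchor, g)
                return 1
        return 0

    if mk == M_JOINHS:
        i = _rand_alive(rng, alive, N, n_samp, 0.55)
        if par[i, 0] >= 0 and par[i, 1] >= 0:
            return 0
        j = _partner(rng, affcum, alive, N, n_samp, i)
        if j < 0 or (par[j, 0] >= 0 and par[j, 1] >= 0):
            return 0
        g = _alloc(alive, par, nch, freelist, nfree)
        if g < 0:
            return 0
        _set_par(par, chd, nch, tlist, tn, i,
                 par[i, 0] if par[i, 0] >= 0 else g,
                 g if par[i, 0] >= 0 else NONE)
        _set_par(par, chd, nch, tlist, tn, j,
                 par[j, 0] if par[j, 0] >= 0 else g,
                 g if par[j, 0] >= 0 else NONE)
        return 1

    if mk == M_JOINCA:
        i = _rand_alive(rng, alive, N, n_samp, 0.55)
        j = _partner(rng, affcum, alive, N, n_samp, i)
        if j < 0:
            return 0
        du = 1 + int(rng.integers(0, 2))
        dd = 1 + int(rng.integers(0, 2))
        couple = rng.random() < 0.5
        if couple:
            g1 = _alloc(alive, par, nch, freelist, nfree)
            g2 = _alloc(alive, par, nch, freelist, nfree)
            if g1 < 0 or g2 < 0:
                return 0
            for side in range(2):
                x = i if side == 0 else j
                dep = du if side == 0 else dd
                if dep == 1:
                    if par[x, 0] >= 0 or par[x, 1] >= 0:
                        return 0
                    _set_par(par, chd, nch, tlist, tn, x, g1, g2)
                else:
                    if par[x, 0] >= 0 and par[x, 1] >= 0:
                        return 0
                    m = _alloc(alive, par, nch, freelist, nfree)
                    if m < 0:
                        return 0
                    _set_par(par, chd, nch, tlist, tn, m, g1, g2)
                    _set_par(par, chd, nch, tlist, tn, x,
                             par[x, 0] if par[x, 0] >= 0 else m,
                             m if par[x, 0] >= 0 else NONE)
        else:
            g = _alloc(alive, par, nch, freelist, nfree)
            if g < 0:
                return 0
            for side in range(2):
                x = i if side == 0 else j
                dep = du if side == 0 else dd
                if par[x, 0] >= 0 and par[x, 1] >= 0:
                    return 0
                top = g
                if dep > 1:
                    m = _alloc(alive, par, nch, freelist, nfree)
                    if m < 0:
                        return 0
                    _set_par(par, chd, nch, tlist, tn, m, g, NONE)
                    top = m
                _set_par(par, chd, nch, tlist, tn, x,
                         par[x, 0] if par[x, 0] >= 0 else top,
                         top if par[x, 0] >= 0 else NONE)
        return 1

    if mk == M_SPLITJOIN:
        v = _rand_child(rng, par, alive, N, n_samp)
        if v < 0:
            return 0
        j = _partner(rng, affcum, alive, N, n_samp, v)
        if j < 0:
            return 0
        mode = int(rng.integers(0, 3))
        if mode == 0:
            _set_par(par, chd, nch, tlist, tn, v, j, NONE)
        elif mode == 1:
            if (par[j, 0] >= 0 and par[j, 1] >= 0) or v == par[j, 0] \
                    or v == par[j, 1]:
                return 0
            _set_par(par, chd, nch, tlist, tn, v, NONE, NONE)
            _set_par(par, chd, nch, tlist, tn, j,
                     par[j, 0] if par[j, 0] >= 0 else v,
                     v if par[j, 0] >= 0 else NONE)
        else:
            if par[j, 0] >= 0 and par[j, 1] >= 0:
                return 0
            g = _alloc(alive, par, nch, freelist, nfree)
            if g < 0:
                return 0
            _set_par(par, chd, nch, tlist, tn, v, g, NONE)
            _set_par(par, chd, nch, tlist, tn, j,
                     par[j, 0] if par[j, 0] >= 0 else g,
                     g if par[j, 0] >= 0 else NONE)
        return 1

    if mk == M_SWAPDESC:
        i = _rand_alive(rng, alive, N, n_samp, 0.55)
        j = i
        steps = 1 + int(rng.integers(0, 3))
        for _ in range(steps):
            if nch[j] == 0 or nch[j] > MAXC:
                break
            j = chd[j, int(rng.integers(0, nch[j]))]
        if j == i:
            return 0
        _swap_nodes(par, chd, nch, alive, N, tlist, tn, i, j)
        return 1

    # M_FLIPSEX: toggle the sex coloring of a latent spouse group
    for _ in range(12):
        v = int(rng.integers(0, N))
        if alive[v] and v >= n_samp:
            flip[v] = 1 - flip[v]
            return 2  # accepted, zero delta
    return 0


@njit(cache=True)
def _cleanup(par, chd, nch, alive, mzp, freelist, nfree, tlist, tn, n_samp):
    """Drop latents that cannot affect sampled genotypes near the edit."""
    changed = True
    while changed:
        changed = False
        for t in range(tn[0]):
            v = tlist[t]
            if v < n_samp or not alive[v] or mzp[v] >= 0:
                continue
            if nch[v] == 0:
                _set_par(par, chd, nch, tlist, tn, v, NONE, NONE)
                _free(alive, freelist, nfree, v)
                changed = True
            elif par[v, 0] < 0 and par[v, 1] < 0 and nch[v] == 1:
                c = chd[v, 0]
                _replace_par(par, chd, nch, tlist, tn, c, v, NONE)
                if par[c, 0] < 0 and par[c, 1] >= 0:
                    _set_par(par, chd, nch, tlist, tn, c, par[c, 1], NONE)
                _free(alive, freelist, nfree, v)
                changed = True


# ------------------------------------------------------------------- kernel
@njit(cache=True)
def _full_state(par, nch, chd, alive, N, n_samp, mzp, ll, marg, cidx,
                c_fs, c_self, c_unrel, danc, members, seen, stampbox):
    """(sum of component scores, number of components) over the whole forest."""
    total = 0.0
    q = 0
    stampbox[0] += 1
    st = stampbox[0]
    for v in range(N):
        if alive[v] and seen[v] != st:
            cnt = _comp_members(par, nch, chd, v, members, seen, st)
            total += _score_comp(par, members, cnt, n_samp, mzp, ll, marg,
                                 cidx, c_fs, c_self, c_unrel, danc)
            q += 1
    return total, q


@njit(cache=True)
def _rebuild_derived(par, alive, N, nch, chd, freelist, nfree):
    for v in range(N):
        nch[v] = 0
    for c in range(N):
        if alive[c]:
            for s in range(2):
                p = par[c, s]
                if p >= 0:
                    _chd_add(chd, nch, p, c)
    nfree[0] = 0
    for v in range(N - 1, -1, -1):
        if not alive[v]:
            freelist[nfree[0]] = v
            nfree[0] += 1


@njit(cache=True)
def anneal_kernel(n_samp, N, ll, marg, cidx, c_fs, c_self, c_unrel,
                  logpois, beta, sexd, age, affcum, max_gen,
                  t0, f, C, I, e, stall_stages, reheats, cool_paper,
                  move_cw, rng, par_init, mzp_init, alive_init,
                  trace_best, trace_cur, move_stats):
    """Full annealing run; returns (best_score, proposals, n_stages,
    cur_score) and fills best state into par_init/mzp_init/alive_init."""
    # current buffers
    parA = par_init.copy()
    mzpA = mzp_init.copy()
    aliveA = alive_init.copy()
    nchA = np.zeros(N, dtype=np.int32)
    chdA = np.zeros((N, MAXC), dtype=np.int32)
    freeA = np.zeros(N, dtype=np.int32)
    nfreeA = np.zeros(1, dtype=np.int32)
    _rebuild_derived(parA, aliveA, N, nchA, chdA, freeA, nfreeA)
    # proposal buffers
    parB = parA.copy()
    mzpB = mzpA.copy()
    aliveB = aliveA.copy()
    nchB = nchA.copy()
    chdB = chdA.copy()
    freeB = freeA.copy()
    nfreeB = nfreeA.copy()

    flip = np.zeros(N, dtype=np.int8)
    members = np.empty(N, dtype=np.int32)
    seen = np.zeros(N, dtype=np.int64)
    seen2 = np.zeros(N, dtype=np.int64)
    aux = np.zeros(N, dtype=np.int32)
    aux2 = np.zeros(N, dtype=np.int32)
    lidx = np.zeros(N, dtype=np.int32)
    danc = np.empty((n_samp, N), dtype=np.int8)
    stampbox = np.zeros(1, dtype=np.int64)
    tlist = np.zeros(160, dtype=np.int32)
    tn = np.zeros(1, dtype=np.int32)

    pairs, q = _full_state(parA, nchA, chdA, aliveA, N, n_samp, mzpA, ll,
                           marg, cidx, c_fs, c_self, c_unrel, danc, members,
                           seen, stampbox)
    cur = pairs + beta * logpois[q]
    best = cur
    best_par = parA.copy()
    best_mzp = mzpA.copy()
    best_alive = aliveA.copy()

    t = t0
    proposals = 0
    stage = 0
    stalled = 0
    reheats_left = reheats
    max_stages = trace_best.shape[0]

    while proposals < I and stage < max_stages:
        stage_best0 = best
        budget = min(C, I - proposals)
        for _ in range(budget):
            proposals += 1
            # pick a move
            r = rng.random()
            mk = 0
            while mk < 21 and move_cw[mk] < r:
                mk += 1
            move_stats[mk, 0] += 1
            if mk == M_FLIPSEX:
                ok = _apply_move(mk, rng, parA, chdA, nchA, aliveA, mzpA,
                                 flip, freeA, nfreeA, tlist, tn, N, n_samp,
                                 affcum)
                if ok == 2:
                    move_stats[mk, 1] += 1
                continue
            # fork current -> proposal
            parB[:] = parA
            mzpB[:] = mzpA
            aliveB[:] = aliveA
            nchB[:] = nchA
            chdB[:] = chdA
            freeB[:] = freeA
            nfreeB[0] = nfreeA[0]
            tn[0] = 0
            ok = _apply_move(mk, rng, parB, chdB, nchB, aliveB, mzpB, flip,
                             freeB, nfreeB, tlist, tn, N, n_samp, affcum)
            if ok == 0 or tn[0] > tlist.shape[0] - 8:
                continue
            _cleanup(parB, chdB, nchB, aliveB, mzpB, freeB, nfreeB, tlist,
                     tn, n_samp)
            if tn[0] > tlist.shape[0] - 8:
                continue
            # old affected components (current buffers)
            stampbox[0] += 1
            st_old = stampbox[0]
            sum_old = 0.0
            n_old = 0
            for x in range(tn[0]):
                v = tlist[x]
                if v < N and aliveA[v] and seen[v] != st_old:
                    cnt = _comp_members(parA, nchA, chdA, v, members, seen,
                                        st_old)
                    sum_old += _score_comp(parA, members, cnt, n_samp, mzpA,
                                           ll, marg, cidx, c_fs, c_self,
                                           c_unrel, danc)
                    n_old += 1
            # new affected components (proposal buffers)
            stampbox[0] += 1
            st_new = stampbox[0]
            sum_new = 0.0
            n_new = 0
            bad = False
            for x in range(tn[0]):
                v = tlist[x]
                if v < N and aliveB[v] and seen2[v] != st_new:
                    cnt = _comp_members(parB, nchB, chdB, v, members, seen2,
                                        st_new)
                    s = _score_comp(parB, members, cnt, n_samp, mzpB, ll,
                                    marg, cidx, c_fs, c_self, c_unrel, danc)
                    if s == -np.inf:
                        bad = True
                        break
                    sum_new += s
                    n_new += 1
            if bad:
                continue
            q2 = q + (n_new - n_old)
            if q2 < 1 or q2 >= logpois.shape[0]:
                continue
            delta = sum_new - sum_old + beta * (logpois[q2] - logpois[q])
            if delta < 0.0:
                lp = t * delta
                if np.log(rng.random()) >= lp:
                    continue
            # validate each new affected component
            stampbox[0] += 1
            st_val = stampbox[0]
            valid = True
            for x in range(tn[0]):
                v = tlist[x]
                if v < N and aliveB[v] and seen2[v] != st_val:
                    cnt = _comp_members(parB, nchB, chdB, v, members, seen2,
                                        st_val)
                    if not _validate_comp(parB, nchB, chdB, members, cnt,
                                          n_samp, mzpB, sexd, age, max_gen,
                                          lidx, aux, aux2):
                        valid = False
                        break
            if not valid:
                continue
            # commit: swap buffer roles
            tmp = parA; parA = parB; parB = tmp
            tmp2 = mzpA; mzpA = mzpB; mzpB = tmp2
            tmp3 = aliveA; aliveA = aliveB; aliveB = tmp3
            tmp4 = nchA; nchA = nchB; nchB = tmp4
            tmp5 = chdA; chdA = chdB; chdB = tmp5
            tmp6 = freeA; freeA = freeB; freeB = tmp6
            tmp7 = nfreeA; nfreeA = nfreeB; nfreeB = tmp7
            q = q2
            cur = cur + delta
            move_stats[mk, 1] += 1
            if cur > best + 1e-12:
                best = cur
                best_par[:] = parA
                best_mzp[:] = mzpA
                best_alive[:] = aliveA
        trace_best[stage] = best
        trace_cur[stage] = cur
        if cool_paper:
            t = t / f
        else:
            t = t * f
        stage += 1
        if best - stage_best0 < e and t >= 1.0:
            stalled += 1
            if stalled >= stall_stages:
                if reheats_left > 0 and proposals < I:
                    reheats_left -= 1
                    stalled = 0
                    t = t0
                    parA[:] = best_par
                    mzpA[:] = best_mzp
                    aliveA[:] = best_alive
                    _rebuild_derived(parA, aliveA, N, nchA, chdA, freeA,
                                     nfreeA)
                    pairs, q = _full_state(parA, nchA, chdA, aliveA, N,
                                           n_samp, mzpA, ll, marg, cidx,
                                           c_fs, c_self, c_unrel, danc,
                                           members, seen, stampbox)
                    cur = pairs + beta * logpois[q]
                else:
                    break
        else:
            stalled = 0

    par_init[:] = best_par
    mzp_init[:] = best_mzp
    alive_init[:] = best_alive
    return best, proposals, stage, cur


# ------------------------------------------------------------ python facade
def prepare_class_index(table):
    """(cidx array, fs/self/unrelated indices) for the kernel."""
    cidx = np.full((10, 3, 3), -1, dtype=np.int32)
    for key, row in table.class_index.items():
        if key[0] == "k":
            _, m, a, cc = key
            if m <= 9:
                cidx[m, a, cc] = row
    return (cidx, table.class_index[("fs",)], table.class_index[("self",)],
            table.class_index[("unrelated",)])


def build_affinity_cum(table):
    """Cumulative partner-sampling weights per sampled individual."""
    n = table.n
    gains = np.zeros((n, n))
    unrel = table.marginal[:, None] + table.marginal[None, :]
    for key, ci in table.class_index.items():
        if key in (("unrelated",), ("self",)):
            continue
        np.maximum(gains, table.ll[ci] - unrel, out=gains)
    w = np.maximum(gains, 0.0) + 0.5
    np.fill_diagonal(w, 0.0)
    w /= w.sum(axis=1, keepdims=True)
    return np.cumsum(w, axis=1)


def state_arrays(table, start, N):
    """Encode a starting Pedigree into kernel arrays."""
    n = table.n
    par = np.full((N, 2), NONE, dtype=np.int32)
    mzp = np.full(N, NONE, dtype=np.int32)
    alive = np.zeros(N, dtype=np.bool_)
    alive[:n] = True
    slot = {v: i for i, v in enumerate(table.ids)}
    if start is not None:
        nxt = n
        for v in sorted(start.parents, key=str):
            if v not in slot:
                if nxt >= N:
                    raise ValueError("start pedigree too large for the engine")
                slot[v] = nxt
                alive[nxt] = True
                nxt += 1
        for c, ps in start.parents.items():
            for s, p in enumerate(ps[:2]):
                par[slot[c], s] = slot[p]
        for pair in start.mz_pairs:
            a, b = tuple(pair)
            mzp[slot[a]] = slot[b]
            mzp[slot[b]] = slot[a]
    return par, mzp, alive, slot


def decode_state(table, par, mzp, alive, sex, age):
    """Kernel arrays back to a Pedigree (latent slots get fresh names)."""
    from .pedigree import Pedigree

    n = table.n
    name = {}
    for v in range(len(alive)):
        if alive[v]:
            name[v] = table.ids[v] if v < n else f"~{v}"
    parents = {}
    for v, nm in name.items():
        parents[nm] = tuple(name[p] for p in par[v] if p >= 0)
    mz = []
    for v in range(len(alive)):
        if alive[v] and 0 <= mzp[v] and v < mzp[v]:
            mz.append((name[v], name[mzp[v]]))
    return Pedigree(parents=parents, sex=dict(sex or {}), sampled=table.ids,
                    mz_pairs=mz, age=dict(age or {}))
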