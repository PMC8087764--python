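"""Low-level structured-coalescent kernels (numba-compiled).

Conventions: time runs backward from the present in generations; haploid
lineages in a diploid deme of size N coalesce pairwise at rate 1/(2N);
migration rates are backward per-lineage rates m[i, j] (a lineage currently
in deme i jumps to deme j).  Population events are encoded as
(time, src, dst, fraction): fraction == 1 is a clean split (all lineages of
``src`` move to ``dst`` and ``src`` is retired), fraction < 1 is an
admixture pulse.  Events are sorted by time.
"""

import numpy as np
from numba import njit

ERR_OK = 0
ERR_STUCK = 1  # isolated demes that can never share an ancestor


@njit(cache=True)
def _pick_lineage(lin_deme, k, d, r):
    """Index of the r-th active lineage currently in deme d."""
    c = 0
    for i in range(k):
        if lin_deme[i] == d:
            if c == r:
                return i
            c += 1
    return -1


@njit(cache=True)
def _sim_tree(deme0, N, M, mig_end, ev_time, ev_src, ev_dst, ev_frac,
              parent, node_time, lin_node, lin_deme, cnt, alive):
    """Simulate one genealogy; fills parent/node_time (2n-1 nodes).

    Returns (root_id, err).  parent[root] = -1.
    """
    n = deme0.shape[0]
    D = N.shape[0]
    for d in range(D):
        cnt[d] = 0
        alive[d] = True
    for i in range(n):
        lin_node[i] = i
        lin_deme[i] = deme0[i]
        parent[i] = -1
        node_time[i] = 0.0
        cnt[deme0[i]] += 1
    for v in range(2 * n - 1):
        parent[v] = -1
        node_time[v] = 0.0
    k = n
    t = 0.0
    ei = 0
    nxt = n
    nev = ev_time.shape[0]
    while k > 1:
        coal_tot = 0.0
        for d in range(D):
            if cnt[d] > 1:
                coal_tot += cnt[d] * (cnt[d] - 1) / (4.0 * N[d])
        mig_tot = 0.0
        if t < mig_end:
            for d in range(D):
                if cnt[d] > 0:
                    row = 0.0
                    for j in range(D):
                        if j != d and alive[j]:
                            row += M[d, j]
                    mig_tot += cnt[d] * row
        total = coal_tot + mig_tot
        tb = np.inf
        if ei < nev:
            tb = ev_time[ei]
        if t < mig_end and mig_end < tb:
            tb = mig_end
        if total <= 0.0:
            if tb == np.inf:
                return nxt - 1, ERR_STUCK
            t = tb
        else:
            dt = np.random.exponential(1.0 / total)
            if t + dt >= tb:
                t = tb
            else:
                t = t + dt
                u = np.random.random() * total
                if u < coal_tot:
                    acc = 0.0
                    dpick = D - 1
                    for d in range(D):
                        if cnt[d] > 1:
                            acc += cnt[d] * (cnt[d] - 1) / (4.0 * N[d])
                            if u < acc:
                                dpick = d
                                break
                    kd = cnt[dpick]
                    r1 = np.random.randint(0, kd)
                    r2 = np.random.randint(0, kd - 1)
                    if r2 >= r1:
                        r2 += 1
                    i1 = _pick_lineage(lin_deme, k, dpick, r1)
                    i2 = _pick_lineage(lin_deme, k, dpick, r2)
                    a = lin_node[i1]
                    b = lin_node[i2]
                    parent[a] = nxt
                    parent[b] = nxt
                    node_time[nxt] = t
                    lin_node[i1] = nxt
                    lin_node[i2] = lin_node[k - 1]
                    lin_deme[i2] = lin_deme[k - 1]
                    k -= 1
                    cnt[dpick] -= 1
                    nxt += 1
                else:
                    u -= coal_tot
                    acc = 0.0
                    done = False
                    for d in range(D):
                        if cnt[d] == 0 or done:
                            continue
                        for j in range(D):
                            if j != d and alive[j]:
                                acc += cnt[d] * M[d, j]
                                if u < acc:
                                    r = np.random.randint(0, cnt[d])
                                    idx = _pick_lineage(lin_deme, k, d, r)
                                    lin_deme[idx] = j
                                    cnt[d] -= 1
                                    cnt[j] += 1
                                    done = True
                                    break
                continue
        # boundary reached: process all events scheduled at exactly t
        while ei < nev and ev_time[ei] <= t:
            s = ev_src[ei]
            dd = ev_dst[ei]
            f = ev_frac[ei]
            for i in range(k):
                if lin_deme[i] == s:
                    if f >= 1.0 or np.random.random() < f:
                        lin_deme[i] = dd
                        cnt[s] -= 1
                        cnt[dd] += 1
            if f >= 1.0:
                alive[s] = False
            ei += 1
    return nxt - 1, ERR_OK


@njit(cache=True)
def tmrca_batch(n_reps, deme0, N, M, mig_end, ev_time, ev_src, ev_dst,
                ev_frac, seed):
    """Root times of ``n_reps`` independent genealogies."""
    np.random.seed(seed)
    n = deme0.shape[0]
    parent = np.empty(2 * n - 1, np.int64)
    node_time = np.empty(2 * n - 1, np.float64)
    lin_node = np.empty(n, np.int64)
    lin_deme = np.empty(n, np.int64)
    cnt = np.empty(N.shape[0], np.int64)
    alive = np.empty(N.shape[0], np.bool_)
    out = np.empty(n_reps, np.float64)
    for r in range(n_reps):
        root, err = _sim_tree(deme0, N, M, mig_end, ev_time, ev_src, ev_dst,
                              ev_frac, parent, node_time, lin_node, lin_deme,
                              cnt, alive)
        if err != ERR_OK:
            out[r] = np.nan
        else:
            out[r] = node_time[root]
    return out


@njit(cache=True)
def msfs_branch_lengths(n_trees, deme0, N, M, mig_end, ev_time, ev_src,
                        ev_dst, ev_frac, axis_of_deme, axis_n, seed):
    """Accumulate genealogy branch length per joint-SFS cell.

    Cells are indexed in C order over dimensions (axis_n[a] + 1); branches
    whose descendant-count vector is monomorphic across all axes (all zero
    or all equal to the axis sample sizes) carry no observable mutation and
    are skipped.  Returns (flat_lengths, n_failed_trees).
    """
    np.random.seed(seed)
    n = deme0.shape[0]
    D = N.shape[0]
    A = axis_n.shape[0]
    strides = np.empty(A, np.int64)
    ncell = 1
    for a in range(A - 1, -1, -1):
        strides[a] = ncell
        ncell *= axis_n[a] + 1
    L = np.zeros(ncell, np.float64)
    parent = np.empty(2 * n - 1, np.int64)
    node_time = np.empty(2 * n - 1, np.float64)
    lin_node = np.empty(n, np.int64)
    lin_deme = np.empty(n, np.int64)
    cnt = np.empty(D, np.int64)
    alive = np.empty(D, np.bool_)
    cax = np.empty((2 * n - 1, A), np.int64)
    failed = 0
    for rep in range(n_trees):
        root, err = _sim_tree(deme0, N, M, mig_end, ev_time, ev_src, ev_dst,
                              ev_frac, parent, node_time, lin_node, lin_deme,
                              cnt, alive)
        if err != ERR_OK:
            failed += 1
            continue
        for v in range(2 * n - 1):
            for a in range(A):
                cax[v, a] = 0
        for i in range(n):
            a = axis_of_deme[deme0[i]]
            if a >= 0:
                cax[i, a] = 1
        for v in range(2 * n - 1):
            if v == root:
                continue
            p = parent[v]
            for a in range(A):
                cax[p, a] += cax[v, a]
        for v in range(2 * n - 1):
            if v == root:
                continue
            allzero = True
            allfull = True
            idx = 0
            for a in range(A):
                c = cax[v, a]
                if c > 0:
                    allzero = False
                if c < axis_n[a]:
                    allfull = False
                idx += c * strides[a]
            if allzero or allfull:
                continue
            L[idx] += node_time[parent[v]] - node_time[v]
    return L, failed


@njit(cache=True)
def joint_count_sample(n_trees, muts_per_tree, deme0, N, M, mig_end, ev_time,
                       ev_src, ev_dst, ev_frac, axis_of_deme, axis_n, seed):
    """Per-SNP joint derived-allele counts across demes.

    Simulates ``n_trees`` independent genealogies and drops
    ``muts_per_tree`` mutations on each, sampled proportionally to branch
    length among branches observable as polymorphic in the pooled sample.
    Returns (counts[n_snps, A], tree_id[n_snps], n_snps).
    """
    np.random.seed(seed)
    n = deme0.shape[0]
    D = N.shape[0]
    A = axis_n.shape[0]
    parent = np.empty(2 * n - 1, np.int64)
    node_time = np.empty(2 * n - 1, np.float64)
    lin_node = np.empty(n, np.int64)
    lin_deme = np.empty(n, np.int64)
    cnt = np.empty(D, np.int64)
    alive = np.empty(D, np.bool_)
    cax = np.empty((2 * n - 1, A), np.int64)
    bl = np.empty(2 * n - 1, np.float64)
    out = np.zeros((n_trees * muts_per_tree, A), np.int64)
    tree_id = np.empty(n_trees * muts_per_tree, np.int64)
    m = 0
    for rep in range(n_trees):
        root, err = _sim_tree(deme0, N, M, mig_end, ev_time, ev_src, ev_dst,
                              ev_frac, parent, node_time, lin_node, lin_deme,
                              cnt, alive)
        if err != ERR_OK:
            continue
        for v in range(2 * n - 1):
            for a in range(A):
                cax[v, a] = 0
        for i in range(n):
            a = axis_of_deme[deme0[i]]
            if a >= 0:
                cax[i, a] = 1
        for v in range(2 * n - 1):
            if v == root:
                continue
            p = parent[v]
            for a in range(A):
                cax[p, a] += cax[v, a]
        tot = 0.0
        for v in range(2 * n - 1):
            bl[v] = 0.0
            if v == root:
                continue
            allzero = True
            allfull = True
            for a in range(A):
                c = cax[v, a]
                if c > 0:
                    allzero = False
                if c < axis_n[a]:
                    allfull = False
            if allzero or allfull:
                continue
            bl[v] = node_time[parent[v]] - node_time[v]
            tot += bl[v]
        if tot <= 0.0:
            continue
        for _ in range(muts_per_tree):
            u = np.random.random() * tot
            acc = 0.0
            pick = -1
            for v in range(2 * n - 1):
                if bl[v] > 0.0:
                    acc += bl[v]
                    if u < acc:
                        pick = v
                        break
            if pick < 0:
                continue
            for a in range(A):
                out[m, a] = cax[pick, a]
            tree_id[m] = rep
            m += 1
    return out, tree_id, m


@njit(cache=True)
def sim_tree_once(deme0, N, M, mig_end, ev_time, ev_src, ev_dst, ev_frac,
                  seed):
    """One genealogy: (parent, node_time, root, err)."""
    np.random.seed(seed)
    n = deme0.shape[0]
    D = N.shape[0]
    parent = np.empty(2 * n - 1, np.int64)
    node_time = np.empty(2 * n - 1, np.float64)
    lin_node = np.empty(n, np.int64)
    lin_deme = np.empty(n, np.int64)
    cnt = np.empty(D, np.int64)
    alive = np.empty(D, np.bool_)
    root, err = _sim_tree(deme0, N, M, mig_end, ev_time, ev_src, ev_dst,
                          ev_frac, parent, node_time, lin_node, lin_deme,
                          cnt, alive)
    return parent, node_time, root, err
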