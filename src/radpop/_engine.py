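"""Numba kernels for the structured-coalescent simulator.

The engine simulates genealogies backward in time under a compiled event
schedule (see :mod:`radpop.models`).  Within a deme of haploid size ``N``
each lineage pair coalesces at rate ``1/N`` per generation; continuous
migration moves single lineages at their per-lineage backward rate; a
migration pulse moves each lineage of the source deme independently with
its proportion; a divergence moves every lineage of the source deme into
the destination deme and retires the source.

A genealogy is returned as its merge records: merge ``m`` joins nodes
``left[m]`` and ``right[m]`` at time ``tm[m]`` into internal node
``n_tot + m`` (leaves are ``0 .. n_tot-1``, deme 0 first).  Because a
lineage subtends a fixed leaf set for its whole life, per-class branch
lengths for the expected SFS are accumulated from merge records alone.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# schedule kind codes (must match models.KIND_CODES)
_SIZE, _DIV, _MIG, _PULSE = 0, 1, 2, 3

STATUS_OK = 0
STATUS_STRANDED = 1


@njit(cache=True)
def _sim_tree(n_demes, samples, init_sizes, ev_times, ev_kinds, ev_a, ev_b, ev_x,
              lin_deme, pos, members, cnt, sizes, mig, left, right, tm):
    """Simulate one genealogy; fills merge records. Returns a status code."""
    n_tot = 0
    for d in range(n_demes):
        n_tot += samples[d]
    # init state
    alive = np.ones(n_demes, dtype=np.uint8)
    for d in range(n_demes):
        sizes[d] = init_sizes[d]
        cnt[d] = 0
        for e in range(n_demes):
            mig[d, e] = 0.0
    lid = 0
    for d in range(n_demes):
        for _ in range(samples[d]):
            members[d, cnt[d]] = lid
            pos[lid] = cnt[d]
            lin_deme[lid] = d
            cnt[d] += 1
            lid += 1
    k = n_tot
    t = 0.0
    ei = 0
    nm = 0
    next_id = n_tot
    n_ev = ev_times.shape[0]

    while k > 1:
        tot = 0.0
        for d in range(n_demes):
            c = cnt[d]
            if c > 1:
                tot += 0.5 * c * (c - 1) / sizes[d]
            if c > 0:
                for e in range(n_demes):
                    if e != d and mig[d, e] > 0.0:
                        tot += c * mig[d, e]
        if ei < n_ev:
            t_ev = ev_times[ei]
        else:
            t_ev = np.inf
        if tot > 0.0:
            dt = np.random.exponential(1.0 / tot)
        else:
            dt = np.inf
        if t + dt >= t_ev:
            if not np.isfinite(t_ev):
                return STATUS_STRANDED
            t = t_ev
            kind = ev_kinds[ei]
            A = ev_a[ei]
            B = ev_b[ei]
            X = ev_x[ei]
            ei += 1
            if kind == _SIZE:
                sizes[A] = X
            elif kind == _DIV:
                for ii in range(cnt[A]):
                    l = members[A, ii]
                    lin_deme[l] = B
                    members[B, cnt[B]] = l
                    pos[l] = cnt[B]
                    cnt[B] += 1
                cnt[A] = 0
                alive[A] = 0
                for e in range(n_demes):
                    mig[A, e] = 0.0
                    mig[e, A] = 0.0
            elif kind == _MIG:
                # rates touching a retired deme are inert
                if alive[A] == 1 and alive[B] == 1:
                    mig[A, B] = X
            else:  # pulse: move each source lineage with probability X
                if alive[B] == 0:
                    continue
                for ii in range(cnt[A] - 1, -1, -1):
                    if np.random.random() < X:
                        l = members[A, ii]
                        last = cnt[A] - 1
                        ml = members[A, last]
                        members[A, ii] = ml
                        pos[ml] = ii
                        cnt[A] = last
                        members[B, cnt[B]] = l
                        pos[l] = cnt[B]
                        lin_deme[l] = B
                        cnt[B] += 1
            continue
        # spontaneous event
        t += dt
        u = np.random.random() * tot
        acc = 0.0
        chosen = False
        for d in range(n_demes):
            c = cnt[d]
            if c > 1:
                r = 0.5 * c * (c - 1) / sizes[d]
                if u < acc + r:
                    # coalescence in deme d: pick an unordered pair
                    i1 = int(np.random.random() * c)
                    if i1 >= c:
                        i1 = c - 1
                    i2 = int(np.random.random() * (c - 1))
                    if i2 >= c - 1:
                        i2 = c - 2
                    if i2 >= i1:
                        i2 += 1
                    c1 = members[d, i1]
                    c2 = members[d, i2]
                    left[nm] = c1
                    right[nm] = c2
                    tm[nm] = t
                    nn = next_id
                    next_id += 1
                    members[d, i1] = nn
                    pos[nn] = i1
                    lin_deme[nn] = d
                    last = c - 1
                    ml = members[d, last]
                    members[d, i2] = ml
                    pos[ml] = i2
                    cnt[d] = last
                    nm += 1
                    k -= 1
                    chosen = True
                    break
                acc += r
            if c > 0:
                for e in range(n_demes):
                    if e != d and mig[d, e] > 0.0:
                        r = c * mig[d, e]
                        if u < acc + r:
                            ii = int(np.random.random() * c)
                            if ii >= c:
                                ii = c - 1
                            l = members[d, ii]
                            last = c - 1
                            ml = members[d, last]
                            members[d, ii] = ml
                            pos[ml] = ii
                            cnt[d] = last
                            members[e, cnt[e]] = l
                            pos[l] = cnt[e]
                            lin_deme[l] = e
                            cnt[e] += 1
                            chosen = True
                            break
                        acc += r
            if chosen:
                break
        # (floating-point slack: if nothing chosen, loop again)
    return STATUS_OK


@njit(cache=True)
def _accumulate_branch_classes(seed, n_sims, n_demes, samples, init_sizes,
                               ev_times, ev_kinds, ev_a, ev_b, ev_x, out):
    """Accumulate total branch length per (deme0, deme1) leaf-count class.

    ``out`` has shape (n0+1, n1+1) and receives summed branch lengths in
    generations over ``n_sims`` independent genealogies.  Classes for demes
    beyond the second are collapsed into deme 0 (only 1- and 2-deme
    spectra are produced).  Returns a status code.
    """
    np.random.seed(seed)
    n_tot = 0
    for d in range(n_demes):
        n_tot += samples[d]
    n_nodes = 2 * n_tot - 1
    lin_deme = np.empty(n_nodes, dtype=np.int64)
    pos = np.empty(n_nodes, dtype=np.int64)
    members = np.empty((n_demes, n_tot), dtype=np.int64)
    cnt = np.empty(n_demes, dtype=np.int64)
    sizes = np.empty(n_demes, dtype=np.float64)
    mig = np.empty((n_demes, n_demes), dtype=np.float64)
    left = np.empty(n_tot - 1, dtype=np.int64)
    right = np.empty(n_tot - 1, dtype=np.int64)
    tm = np.empty(n_tot - 1, dtype=np.float64)
    nd0 = np.empty(n_nodes, dtype=np.int64)
    nd1 = np.empty(n_nodes, dtype=np.int64)
    birth = np.empty(n_nodes, dtype=np.float64)

    for _ in range(n_sims):
        status = _sim_tree(n_demes, samples, init_sizes, ev_times, ev_kinds,
                           ev_a, ev_b, ev_x, lin_deme, pos, members, cnt,
                           sizes, mig, left, right, tm)
        if status != STATUS_OK:
            return status
        lid = 0
        for d in range(n_demes):
            for _s in range(samples[d]):
                nd0[lid] = 1 if d != 1 else 0
                nd1[lid] = 1 if d == 1 else 0
                birth[lid] = 0.0
                lid += 1
        for m in range(n_tot - 1):
            c1 = left[m]
            c2 = right[m]
            tmm = tm[m]
            out[nd0[c1], nd1[c1]] += tmm - birth[c1]
            out[nd0[c2], nd1[c2]] += tmm - birth[c2]
            node = n_tot + m
            nd0[node] = nd0[c1] + nd0[c2]
            nd1[node] = nd1[c1] + nd1[c2]
            birth[node] = tmm
    return STATUS_OK


@njit(cache=True)
def _sim_locus(seed, n_demes, samples, init_sizes,
               ev_times, ev_kinds, ev_a, ev_b, ev_x,
               theta_locus, site_buf, left, right, tm):
    """Simulate one genealogy and drop infinite-sites mutations.

    ``theta_locus`` is mu * locus_length (expected mutations per branch
    generation); each mutation yields one biallelic site whose carrier set
    is the subtended clade, written as a 0/1 row of ``site_buf``.  Returns
    (status, n_sites, tmrca); sites beyond the buffer are dropped.
    """
    n_tot = 0
    for d in range(n_demes):
        n_tot += samples[d]
    n_nodes = 2 * n_tot - 1
    lin_deme = np.empty(n_nodes, dtype=np.int64)
    pos = np.empty(n_nodes, dtype=np.int64)
    members = np.empty((n_demes, n_tot), dtype=np.int64)
    cnt = np.empty(n_demes, dtype=np.int64)
    sizes = np.empty(n_demes, dtype=np.float64)
    mig = np.empty((n_demes, n_demes), dtype=np.float64)

    np.random.seed(seed)
    status = _sim_tree(n_demes, samples, init_sizes, ev_times, ev_kinds,
                       ev_a, ev_b, ev_x, lin_deme, pos, members, cnt,
                       sizes, mig, left, right, tm)
    if status != STATUS_OK:
        return status, 0, 0.0

    # leaf membership per node, built bottom-up from the merge records
    memb = np.zeros((n_nodes, n_tot), dtype=np.uint8)
    birth = np.zeros(n_nodes, dtype=np.float64)
    for l in range(n_tot):
        memb[l, l] = 1
    n_sites = 0
    cap = site_buf.shape[0]
    for m in range(n_tot - 1):
        c1 = left[m]
        c2 = right[m]
        tmm = tm[m]
        node = n_tot + m
        for s in range(n_tot):
            memb[node, s] = memb[c1, s] | memb[c2, s]
        birth[node] = tmm
        # mutations on the two child branches closed by this merge
        for child in (c1, c2):
            blen = tmm - birth[child]
            nmut = np.random.poisson(theta_locus * blen)
            for _ in range(nmut):
                if n_sites < cap:
                    for s in range(n_tot):
                        site_buf[n_sites, s] = memb[child, s]
                    n_sites += 1
    return STATUS_OK, n_sites, tm[n_tot - 2]
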