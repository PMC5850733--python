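"""Numba kernels for the MCMC hot path: JC pruning and the MSC
coalescent density over integer-indexed populations."""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["jc_loglik_kernel", "coal_logdensity_kernel"]

_NEG_INF = -np.inf


@njit(cache=False)
def jc_loglik_kernel(post, left, right, age, tipcode, counts, ntips):
    """JC log-likelihood by pruning.

    ``post``: internal nodes in postorder; ``tipcode``: (ntips, P) int8
    with 4 = ambiguous; uniform stationary frequencies.
    """
    P = tipcode.shape[1]
    nnodes = age.size
    partial = np.empty((nnodes, P, 4))
    for t in range(ntips):
        for p in range(P):
            c = tipcode[t, p]
            if c == 4:
                for s in range(4):
                    partial[t, p, s] = 1.0
            else:
                for s in range(4):
                    partial[t, p, s] = 0.0
                partial[t, p, c] = 1.0
    for oi in range(post.size):
        i = post[oi]
        for ci in range(2):
            ch = left[i] if ci == 0 else right[i]
            e = np.exp(-4.0 * (age[i] - age[ch]) / 3.0)
            pd = 0.25 - 0.25 * e
            for p in range(P):
                tot = (partial[ch, p, 0] + partial[ch, p, 1]
                       + partial[ch, p, 2] + partial[ch, p, 3])
                base = pd * tot
                if ci == 0:
                    for s in range(4):
                        partial[i, p, s] = base + e * partial[ch, p, s]
                else:
                    for s in range(4):
                        partial[i, p, s] *= base + e * partial[ch, p, s]
    root = post[post.size - 1]
    total = 0.0
    for p in range(P):
        site = 0.25 * (partial[root, p, 0] + partial[root, p, 1]
                       + partial[root, p, 2] + partial[root, p, 3])
        if site <= 0.0:
            return _NEG_INF
        total += counts[p] * np.log(site)
    return total


@njit(cache=False)
def coal_logdensity_kernel(ages, node_pop0, pop_parent, pop_order, lo, hi,
                           theta, k_base):
    """MSC log-density of one gene tree.

    ``ages``: internal-node ages; ``node_pop0``: species-MRCA population
    index per internal node; populations are processed children-first
    (``pop_order``), accumulating surviving lineages into parents.
    """
    m = ages.size
    npops = lo.size
    nev = np.zeros(npops, np.int64)
    ev = np.empty((npops, m))
    for i in range(m):
        a = ages[i]
        pop = node_pop0[i]
        if a < lo[pop]:
            return _NEG_INF
        while hi[pop] <= a:
            pop = pop_parent[pop]
        ev[pop, nev[pop]] = a
        nev[pop] += 1
    # insertion sort per population
    for p in range(npops):
        for i in range(1, nev[p]):
            x = ev[p, i]
            j = i - 1
            while j >= 0 and ev[p, j] > x:
                ev[p, j + 1] = ev[p, j]
                j -= 1
            ev[p, j + 1] = x
    k_in = k_base.copy()
    logd = 0.0
    for oi in range(npops):
        p = pop_order[oi]
        k = k_in[p]
        par = pop_parent[p]
        surv = k - nev[p]
        if par >= 0:
            k_in[par] += surv
        elif surv != 1:
            return _NEG_INF
        if k <= 1 and nev[p] == 0:
            continue
        th = theta[p]
        if th <= 0.0:
            return _NEG_INF
        t = lo[p]
        kk = k
        for e in range(nev[p]):
            u = ev[p, e]
            logd += np.log(2.0 / th) - (kk * (kk - 1) / th) * (u - t)
            kk -= 1
            t = u
        if hi[p] < 1e300:
            logd -= (kk * (kk - 1) / th) * (hi[p] - t)
    return logd
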