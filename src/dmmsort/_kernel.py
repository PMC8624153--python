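"""Numba-compiled inner loop of the event-driven simulation.

Sites are flat indices s = row*side + col.  Undirected lattice edges are
indexed e = 2*s (site to right neighbor) and e = 2*s + 1 (site to down
neighbor), 2*side**2 in total; homotypic edges carry rate 0.

Individual rates span many orders of magnitude (exp of sums of bond
strengths up to +-80), so an incrementally maintained total rate would be
destroyed by floating-point cancellation.  Instead the edge array is split
into fixed-size blocks whose partial sums are re-summed exactly whenever a
member edge changes; the total is the (short) sum over block sums, and
event selection walks blocks first, then edges within the chosen block.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: edges per selection block; small enough that re-summing the dirty blocks
#: after a switch is cheap, large enough to keep the block scan short
BLOCK = 32


@njit(cache=True)
def _neighbor_table(side):
    S = side * side
    nbr = np.empty((S, 4), np.int64)  # up, down, left, right
    for s in range(S):
        r = s // side
        c = s % side
        nbr[s, 0] = ((r - 1) % side) * side + c
        nbr[s, 1] = ((r + 1) % side) * side + c
        nbr[s, 2] = r * side + (c - 1) % side
        nbr[s, 3] = r * side + (c + 1) % side
    return nbr


@njit(cache=True)
def _edge_rate(types, nbr, beta, x, y):
    tx = types[x]
    ty = types[y]
    if tx == ty:
        return 0.0
    e = 0.0
    for k in range(4):
        e += beta[tx, types[nbr[x, k]]]
        e += beta[ty, types[nbr[y, k]]]
    return np.exp(-e)


@njit(cache=True)
def _all_rates(types, nbr, beta, rates):
    S = types.shape[0]
    for s in range(S):
        rates[2 * s] = _edge_rate(types, nbr, beta, s, nbr[s, 3])
        rates[2 * s + 1] = _edge_rate(types, nbr, beta, s, nbr[s, 1])


@njit(cache=True)
def _block_sum(rates, j, E):
    lo = j * BLOCK
    hi = min(lo + BLOCK, E)
    s = 0.0
    for e in range(lo, hi):
        s += rates[e]
    return s


@njit(cache=True)
def _homotypic_count(types, nbr):
    d = 0
    for s in range(types.shape[0]):
        if types[s] == types[nbr[s, 3]]:
            d += 1
        if types[s] == types[nbr[s, 1]]:
            d += 1
    return d


@njit(cache=True)
def gillespie_run(types, beta, side, rec, rng, record_wait):
    """Advance the configuration by rec[-1] switches, recording the homotypic
    contact count at every switch index listed in ``rec`` (strictly
    increasing, starting at 0).

    ``types`` (flat, length side**2) is modified in place.  Per switch the
    random stream is consumed in a fixed order: one uniform for the pair,
    one for the waiting time.  Returns (d at recorded indices, waiting
    times or empty array).
    """
    S = side * side
    E = 2 * S
    nb = (E + BLOCK - 1) // BLOCK
    nbr = _neighbor_table(side)
    rates = np.zeros(E)
    _all_rates(types, nbr, beta, rates)
    bsum = np.empty(nb)
    for j in range(nb):
        bsum[j] = _block_sum(rates, j, E)
    d = _homotypic_count(types, nbr)

    n_rec = rec.shape[0]
    n_switches = rec[n_rec - 1]
    d_rec = np.empty(n_rec, np.int64)
    waits = np.empty(n_switches if record_wait else 0)
    ri = 0
    if rec[0] == 0:
        d_rec[0] = d
        ri = 1

    sites = np.empty(10, np.int64)
    edges = np.empty(40, np.int64)
    dirty = np.empty(40, np.int64)

    for t in range(1, n_switches + 1):
        total = 0.0
        for j in range(nb):
            total += bsum[j]
        if total <= 0.0:
            raise RuntimeError("frozen state: total switch rate is zero")

        # --- two-level proportional selection: block, then edge
        u = rng.random() * total
        blk = -1
        acc = 0.0
        for j in range(nb):
            b = bsum[j]
            if b > 0.0:
                acc += b
                if u < acc:
                    blk = j
                    break
        if blk == -1:  # rounding overshoot: last live block
            for j in range(nb - 1, -1, -1):
                if bsum[j] > 0.0:
                    blk = j
                    break
        if blk == -1:
            raise RuntimeError("frozen state: no live switch event")
        chosen = -1
        acc2 = acc - bsum[blk]
        lo = blk * BLOCK
        hi = min(lo + BLOCK, E)
        for e in range(lo, hi):
            r = rates[e]
            if r > 0.0:
                acc2 += r
                if u < acc2:
                    chosen = e
                    break
        if chosen == -1:  # rounding overshoot inside the block
            for e in range(hi - 1, lo - 1, -1):
                if rates[e] > 0.0:
                    chosen = e
                    break
        w = -np.log1p(-rng.random()) / total
        if record_wait:
            waits[t - 1] = w

        x = chosen >> 1
        y = nbr[x, 1] if chosen & 1 else nbr[x, 3]
        tx = types[x]
        ty = types[y]

        # --- homotypic-count delta from the local neighborhood
        hb = 0
        ha = 0
        for k in range(4):
            z = nbr[x, k]
            if z != y:
                tz = types[z]
                if tz == tx:
                    hb += 1
                if tz == ty:
                    ha += 1
            z = nbr[y, k]
            if z != x:
                tz = types[z]
                if tz == ty:
                    hb += 1
                if tz == tx:
                    ha += 1
        d += ha - hb

        types[x] = ty
        types[y] = tx

        # --- recompute every edge incident to a site whose neighborhood
        #     contains x or y: the 4 incident edges of the 10 sites
        #     {x, y} U N(x) U N(y)
        sites[0] = x
        sites[1] = y
        for k in range(4):
            sites[2 + k] = nbr[x, k]
            sites[6 + k] = nbr[y, k]
        ne = 0
        for i in range(10):
            s = sites[i]
            for cand in (2 * s, 2 * s + 1, 2 * nbr[s, 2], 2 * nbr[s, 0] + 1):
                seen = False
                for j in range(ne):
                    if edges[j] == cand:
                        seen = True
                        break
                if not seen:
                    edges[ne] = cand
                    ne += 1
        nd = 0
        for j in range(ne):
            e = edges[j]
            s = e >> 1
            p = nbr[s, 1] if e & 1 else nbr[s, 3]
            rates[e] = _edge_rate(types, nbr, beta, s, p)
            bj = e // BLOCK
            seen = False
            for i in range(nd):
                if dirty[i] == bj:
                    seen = True
                    break
            if not seen:
                dirty[nd] = bj
                nd += 1
        for i in range(nd):
            bsum[dirty[i]] = _block_sum(rates, dirty[i], E)

        if ri < n_rec and t == rec[ri]:
            d_rec[ri] = d
            ri += 1

    return d_rec, waits
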