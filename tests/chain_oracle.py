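"""Exact jump-chain oracle for small two-type lattices.

Enumerates every configuration with fixed type counts, builds the full
transition matrix of the discrete jump chain (successive configurations of
the switch process, transition probability rate/total), solves its
stationary distribution and returns the exact stationary expectation of the
order indicator.  Independent of the simulation engine: it only uses the
single-pair switch rate.
"""

import itertools

import numpy as np

import dmmsort as dm


def enumerate_states(side, counts):
    """All type grids with ``counts[0]`` type-0 cells, as a list of flat
    position tuples (type-0 site indices)."""
    return list(itertools.combinations(range(side * side), counts[0]))


def _grid(state, side):
    g = np.ones(side * side, dtype=np.int64)
    g[list(state)] = 0
    return dm.LatticeConfig(g.reshape(side, side), 2)


def stationary_expected_omega(side, counts, params, extremes=None):
    """E[omega] under the stationary distribution of the jump chain."""
    states = enumerate_states(side, counts)
    index = {s: i for i, s in enumerate(states)}
    n = len(states)
    if extremes is None:
        extremes = dm.order_extremes(side, 2, counts)
    P = np.zeros((n, n))
    omega = np.empty(n)
    for i, state in enumerate(states):
        cfg = _grid(state, side)
        omega[i] = dm.order_indicator(cfg, extremes)
        table = dm.build_event_table(cfg, params)
        total = table.total_rate
        zeros = frozenset(state)
        for (x, y), rate in table.events.items():
            sx = x[0] * side + x[1]
            sy = y[0] * side + y[1]
            if sx in zeros:
                new = (zeros - {sx}) | {sy}
            else:
                new = (zeros - {sy}) | {sx}
            j = index[tuple(sorted(new))]
            P[i, j] += rate / total
    evals, evecs = np.linalg.eig(P.T)
    k = np.argmin(np.abs(evals - 1.0))
    pi = np.real(evecs[:, k])
    pi = pi / pi.sum()
    assert np.all(pi > -1e-12)
    return float(pi @ omega), extremes


def batch_mean_se(values, n_batches=100):
    """Monte-Carlo standard error of the mean via batch means."""
    values = np.asarray(values)
    usable = (values.size // n_batches) * n_batches
    batches = values[:usable].reshape(n_batches, -1).mean(axis=1)
    return float(batches.mean()), float(batches.std(ddof=1) / np.sqrt(n_batches))
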