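"""Event-driven stochastic simulation of the differential-migration model.

A Gillespie scheme over the adjacent heterotypic pairs of the current
configuration: each pair is one event whose rate comes from the switch-rate
rule; a switch is sampled proportionally to its rate, an exponential waiting
time is drawn from the total rate, the switch is applied and only the events
whose neighborhoods were touched are recomputed.  Trajectories are indexed
by the number of switches performed, which is the model's notion of time;
the physical waiting times are recorded separately on request.

Two interchangeable backends exist: a transparent pure-Python event table
(:class:`EventTable` / :func:`step`) used for inspection and verification,
and a numba kernel used by :func:`run` for production-scale simulations.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _kernel
from .core import (
    AdhesionParams,
    FrozenStateError,
    LatticeConfig,
    SingleTypeError,
    Site,
    switch_rate,
    von_neumann_neighbors,
)
from .metrics import OrderExtremes, order_extremes, total_homotypic

__all__ = ["EventTable", "Trajectory", "build_event_table", "step", "run"]

#: steps between full re-summations of the pure-Python event table's total
REFRESH_INTERVAL = 10_000

Pair = tuple[Site, Site]


def _canon(x: Site, y: Site) -> Pair:
    return (x, y) if x <= y else (y, x)


class EventTable:
    """Rates of all adjacent heterotypic pairs of a configuration.

    Pairs are stored unordered (one event per physical exchange).  The total
    rate is maintained incrementally under local updates; ``refresh`` re-sums
    it to cap floating-point drift.
    """

    def __init__(self, events: dict[Pair, float], params: AdhesionParams):
        self.events = events
        self.params = params
        self.total_rate = float(sum(events.values()))

    def __len__(self) -> int:
        return len(self.events)

    def refresh(self) -> None:
        self.total_rate = float(sum(self.events.values()))

    def update_local(self, config: LatticeConfig, x: Site, y: Site) -> None:
        """Recompute every pair with a member in {x, y} or their neighborhoods,
        after the switch at (x, y) has been applied to ``config``."""
        side = config.side
        affected = {x, y}
        affected.update(von_neumann_neighbors(x, side))
        affected.update(von_neumann_neighbors(y, side))
        for s in affected:
            for nb in von_neumann_neighbors(s, side):
                pair = _canon(s, nb)
                rate = switch_rate(config, pair[0], pair[1], self.params)
                old = self.events.pop(pair, 0.0)
                if rate > 0.0:
                    self.events[pair] = rate
                self.total_rate += rate - old


def build_event_table(config: LatticeConfig, params: AdhesionParams) -> EventTable:
    """One event per unordered adjacent heterotypic pair of the configuration."""
    if np.count_nonzero(config.counts) < 2:
        raise SingleTypeError("configuration holds fewer than two cell types")
    side = config.side
    t = config.types
    events: dict[Pair, float] = {}
    for r in range(side):
        for c in range(side):
            x = (r, c)
            for y in ((r, (c + 1) % side), ((r + 1) % side, c)):
                if t[x] != t[y]:
                    events[_canon(x, y)] = switch_rate(config, x, y, params)
    return EventTable(events, params)


def step(
    config: LatticeConfig, table: EventTable, rng: np.random.Generator
) -> tuple[Pair, float]:
    """One Gillespie step: sample a pair with probability rate/total, draw an
    exponential waiting time from the total rate, apply the switch in place
    and update the table locally.  The random stream is consumed pair-first,
    then waiting time."""
    total = table.total_rate
    if total <= 0.0:
        raise FrozenStateError("total switch rate is zero; no event can occur")
    u = rng.random() * total
    chosen = last = None
    acc = 0.0
    for pair, rate in table.events.items():
        last = pair
        acc += rate
        if u < acc:
            chosen = pair
            break
    if chosen is None:  # incremental-total drift overshoot
        chosen = last
    waiting = -np.log1p(-rng.random()) / total
    x, y = chosen
    config.types[x], config.types[y] = config.types[y], config.types[x]
    table.update_local(config, x, y)
    return chosen, float(waiting)


@dataclass
class Trajectory:
    """Switch-indexed record of one simulation.

    ``switch_index[t]`` counts applied switches; ``omega`` is the order
    indicator at those indices.  Provenance (bond strengths, lattice, seed,
    stride) travels with the data so a run table row can be rebuilt.
    """

    switch_index: np.ndarray
    omega: np.ndarray
    waiting_times: np.ndarray | None = None
    final_config: LatticeConfig | None = field(default=None, repr=False)
    beta_flat: np.ndarray | None = None
    side: int | None = None
    counts: tuple[int, ...] | None = None
    seed: int | None = None
    record_stride: int | None = None

    @property
    def n_switches(self) -> int:
        return int(self.switch_index[-1])

    def to_csv(self, path: str | Path, sidecar: bool = True) -> None:
        """Write switch_index/omega (and mean-free waiting times are not
        aggregated: per-switch waiting times, when recorded, go to a third
        column aligned with the recorded indices' cumulative count)."""
        path = Path(path)
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            if self.waiting_times is not None and len(self.waiting_times):
                cum = np.concatenate([[0.0], np.cumsum(self.waiting_times)])
                w.writerow(["switch_index", "omega", "elapsed_time"])
                for i, om in zip(self.switch_index, self.omega):
                    w.writerow([int(i), f"{om:.10g}", f"{cum[int(i)]:.10g}"])
            else:
                w.writerow(["switch_index", "omega"])
                for i, om in zip(self.switch_index, self.omega):
                    w.writerow([int(i), f"{om:.10g}"])
        if sidecar:
            meta = {
                "beta": None if self.beta_flat is None else list(map(float, self.beta_flat)),
                "side": self.side,
                "counts": None if self.counts is None else list(map(int, self.counts)),
                "seed": self.seed,
                "record_stride": self.record_stride,
                "n_switches": self.n_switches,
            }
            path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def _record_indices(n_switches: int, stride: int) -> np.ndarray:
    if n_switches == 0:
        return np.array([0], dtype=np.int64)
    idx = np.arange(0, n_switches + 1, stride, dtype=np.int64)
    if idx[-1] != n_switches:
        idx = np.append(idx, n_switches)
    return idx


def run(
    config0: LatticeConfig,
    params: AdhesionParams,
    n_switches: int,
    record_stride: int | None = None,
    seed: int | None = None,
    record_waiting_times: bool = False,
    engine: str = "fast",
    extremes: OrderExtremes | None = None,
) -> Trajectory:
    """Simulate ``n_switches`` cell switches from ``config0`` and record the
    order indicator every ``record_stride`` switches (default: about 1000
    recorded points) plus the first and last index.

    ``engine='fast'`` runs the numba kernel; ``engine='reference'`` runs the
    pure-Python event table, practical only for small lattices.  Both are
    reproducible bit-for-bit given the seed.
    """
    if n_switches < 0:
        raise ValueError("n_switches must be >= 0")
    if config0.n_types < 2 or np.count_nonzero(config0.counts) < 2:
        if n_switches > 0:
            raise SingleTypeError("configuration holds fewer than two cell types")
    if params.n_types < config0.n_types:
        raise ValueError("params cover fewer types than the configuration holds")
    if record_stride is None:
        record_stride = max(1, n_switches // 1000)
    rec = _record_indices(n_switches, record_stride)
    if extremes is None:
        extremes = order_extremes(config0.side, config0.n_types, config0.counts)
    rng = np.random.default_rng(seed)

    if engine == "fast":
        types = np.ascontiguousarray(config0.types.ravel().copy())
        beta = np.ascontiguousarray(params.beta, dtype=np.float64)
        try:
            d_rec, waits = _kernel.gillespie_run(
                types, beta, config0.side, rec, rng, bool(record_waiting_times)
            )
        except RuntimeError as err:
            raise FrozenStateError(str(err)) from None
        final = LatticeConfig(
            types.reshape(config0.side, config0.side), config0.n_types, seed
        )
    elif engine == "reference":
        cfg = config0.copy()
        table = build_event_table(cfg, params) if n_switches > 0 else None
        d_rec = np.empty(rec.size, dtype=np.int64)
        waits = np.empty(n_switches if record_waiting_times else 0)
        ri = 0
        if rec[0] == 0:
            d_rec[0] = total_homotypic(cfg)
            ri = 1
        for t in range(1, n_switches + 1):
            _, w = step(cfg, table, rng)
            if record_waiting_times:
                waits[t - 1] = w
            if t % REFRESH_INTERVAL == 0:
                table.refresh()
            if ri < rec.size and t == rec[ri]:
                d_rec[ri] = total_homotypic(cfg)
                ri += 1
        final = cfg
    else:
        raise ValueError(f"unknown engine {engine!r}")

    # constructive anchors can in principle be beaten on incommensurate
    # lattices; keep omega inside its nominal range
    omega = np.clip(
        (d_rec - extremes.d_min) / (extremes.d_max - extremes.d_min), 0.0, 1.0
    )
    return Trajectory(
        switch_index=rec,
        omega=omega.astype(float),
        waiting_times=waits if record_waiting_times else None,
        final_config=final,
        beta_flat=params.to_flat(),
        side=config0.side,
        counts=tuple(int(c) for c in config0.counts),
        seed=seed,
        record_stride=record_stride,
    )
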