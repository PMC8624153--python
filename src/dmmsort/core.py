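"""Lattice geometry, adhesion parameters and the elementary cell-switch rule.

The model lives on a periodic square lattice whose sites each hold exactly
one cell of one of ``N`` types.  Two adjacent heterotypic cells exchange
positions at a rate that decays exponentially with the total bond strength
the pair has to its von Neumann neighborhood, so strongly bound cells are
slow to move.  Homotypic exchanges leave the configuration unchanged and
are excluded from the dynamics.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AdhesionParams",
    "LatticeConfig",
    "DegenerateLatticeError",
    "SingleTypeError",
    "FrozenStateError",
    "NotAdjacentError",
    "HomotypicSwitchError",
    "ImperfectPatternWarning",
    "von_neumann_neighbors",
    "switch_rate",
    "apply_switch",
    "random_config",
    "reference_config",
    "default_counts",
    "flat_index_pairs",
]

Site = tuple[int, int]


class DegenerateLatticeError(ValueError):
    """Lattice too small for the 4-neighbor geometry (side < 3)."""


class SingleTypeError(ValueError):
    """Fewer than two cell types present: no heterotypic pair can exist."""


class FrozenStateError(RuntimeError):
    """Total switch rate is zero; the dynamics cannot advance."""


class NotAdjacentError(ValueError):
    """The two sites are not von Neumann neighbors under periodic wrap."""


class HomotypicSwitchError(ValueError):
    """Requested switch of two same-type cells, which is a no-op by construction."""


class ImperfectPatternWarning(UserWarning):
    """A reference pattern cannot tile the requested lattice without wrap defects."""


def flat_index_pairs(n_types: int) -> list[tuple[int, int]]:
    """Canonical ordering of the bond-strength vector: homotypic entries
    (0,0)..(N-1,N-1) first, then heterotypic pairs (i,j), i<j, lexicographic."""
    hom = [(i, i) for i in range(n_types)]
    het = [(i, j) for i in range(n_types) for j in range(i + 1, n_types)]
    return hom + het


@dataclass(frozen=True)
class AdhesionParams:
    """Symmetric matrix of dimensionless bond strengths beta_ij.

    Positive entries model binding that hinders motility (adhesion plus
    relaxed cortical tension); negative entries model repulsion that
    enhances motility.  The flat-vector form for N types has length
    N + N(N-1)/2, homotypic entries first.
    """

    beta: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.beta, dtype=float)
        if b.ndim != 2 or b.shape[0] != b.shape[1]:
            raise ValueError(f"beta must be a square matrix, got shape {b.shape}")
        if b.shape[0] < 2:
            raise ValueError("at least two cell types are required")
        if not np.allclose(b, b.T, atol=1e-12, rtol=0.0):
            raise ValueError("beta must be symmetric (beta_ij == beta_ji)")
        object.__setattr__(self, "beta", 0.5 * (b + b.T))

    @property
    def n_types(self) -> int:
        return self.beta.shape[0]

    @classmethod
    def from_flat(cls, flat: Sequence[float]) -> "AdhesionParams":
        """Build from the canonical flat vector (homotypic first, then i<j pairs)."""
        flat = np.asarray(flat, dtype=float)
        # length N + N(N-1)/2 = N(N+1)/2
        n = int(round((np.sqrt(8 * flat.size + 1) - 1) / 2))
        if n * (n + 1) // 2 != flat.size or n < 2:
            raise ValueError(f"flat vector of length {flat.size} does not match any N >= 2")
        beta = np.zeros((n, n))
        for value, (i, j) in zip(flat, flat_index_pairs(n)):
            beta[i, j] = beta[j, i] = value
        return cls(beta)

    def to_flat(self) -> np.ndarray:
        return np.array([self.beta[i, j] for i, j in flat_index_pairs(self.n_types)])

    def shifted(self, theta: float) -> "AdhesionParams":
        """All bond strengths shifted by a common constant."""
        return AdhesionParams(self.beta + float(theta))

    def relabeled(self, perm: Sequence[int]) -> "AdhesionParams":
        """Apply a permutation of type labels consistently to rows and columns."""
        p = np.asarray(perm)
        return AdhesionParams(self.beta[np.ix_(p, p)])


class LatticeConfig:
    """Periodic square grid assigning one cell type to each site.

    ``types`` is a (side, side) integer array; per-type cell counts are
    conserved by every switch.
    """

    __slots__ = ("types", "n_types", "seed")

    def __init__(self, types: np.ndarray, n_types: int | None = None, seed: int | None = None):
        t = np.asarray(types, dtype=np.int64)
        if t.ndim != 2 or t.shape[0] != t.shape[1]:
            raise ValueError(f"types must be a square grid, got shape {t.shape}")
        if t.shape[0] < 3:
            raise DegenerateLatticeError("side must be >= 3 for distinct von Neumann neighbors")
        if t.min() < 0:
            raise ValueError("cell types must be nonnegative integers")
        inferred = int(t.max()) + 1
        if n_types is None:
            n_types = inferred
        elif n_types < inferred:
            raise ValueError(f"n_types={n_types} but grid contains type {inferred - 1}")
        self.types = t
        self.n_types = int(n_types)
        self.seed = seed

    @property
    def side(self) -> int:
        return self.types.shape[0]

    @property
    def counts(self) -> np.ndarray:
        return np.bincount(self.types.ravel(), minlength=self.n_types)

    def copy(self) -> "LatticeConfig":
        return LatticeConfig(self.types.copy(), self.n_types, self.seed)

    def same_grid(self, other: "LatticeConfig") -> bool:
        return self.side == other.side and np.array_equal(self.types, other.types)

    # -- serialization ----------------------------------------------------

    def to_text(self, path: str | Path) -> None:
        """Plain integer grid: one lattice row per line, whitespace-separated."""
        np.savetxt(path, self.types, fmt="%d")

    @classmethod
    def from_text(cls, path: str | Path, n_types: int | None = None) -> "LatticeConfig":
        return cls(np.loadtxt(path, dtype=np.int64, ndmin=2), n_types)

    def to_json(self) -> dict:
        return {
            "side": self.side,
            "n_types": self.n_types,
            "counts": self.counts.tolist(),
            "types": self.types.ravel().tolist(),
            "seed": self.seed,
        }

    @classmethod
    def from_json(cls, obj: dict | str) -> "LatticeConfig":
        if isinstance(obj, str):
            obj = json.loads(obj)
        side = obj["side"]
        grid = np.asarray(obj["types"], dtype=np.int64).reshape(side, side)
        return cls(grid, obj.get("n_types"), obj.get("seed"))


def von_neumann_neighbors(site: Site, side: int) -> list[Site]:
    """The four von Neumann (Manhattan-distance-1) neighbors with periodic wrap,
    in (up, down, left, right) order."""
    if side < 3:
        raise DegenerateLatticeError("side must be >= 3 for four distinct neighbors")
    r, c = site
    return [
        ((r - 1) % side, c),
        ((r + 1) % side, c),
        (r, (c - 1) % side),
        (r, (c + 1) % side),
    ]


def _check_adjacent(x: Site, y: Site, side: int) -> None:
    dr = abs(x[0] - y[0])
    dc = abs(x[1] - y[1])
    dr = min(dr, side - dr)
    dc = min(dc, side - dc)
    if dr + dc != 1:
        raise NotAdjacentError(f"sites {x} and {y} are not adjacent on a side-{side} torus")


def switch_rate(config: LatticeConfig, x: Site, y: Site, params: AdhesionParams) -> float:
    """Rate at which the cells at adjacent sites x and y exchange positions.

    Zero for a homotypic pair.  For a heterotypic pair the rate is
    ``exp(-(sum_{z in N(x)} beta[w(x), w(z)] + sum_{z in N(y)} beta[w(y), w(z)]))``
    where each neighborhood includes the partner site, giving eight bond
    terms in total.
    """
    side = config.side
    _check_adjacent(x, y, side)
    t = config.types
    wx, wy = t[x], t[y]
    if wx == wy:
        return 0.0
    exponent = 0.0
    for z in von_neumann_neighbors(x, side):
        exponent += params.beta[wx, t[z]]
    for z in von_neumann_neighbors(y, side):
        exponent += params.beta[wy, t[z]]
    return float(np.exp(-exponent))


def apply_switch(config: LatticeConfig, x: Site, y: Site) -> LatticeConfig:
    """Exchange the cells at adjacent heterotypic sites x and y.

    Returns a new configuration; per-type counts are unchanged.  A
    homotypic pair is rejected because such an exchange would be a no-op.
    """
    _check_adjacent(x, y, config.side)
    if config.types[x] == config.types[y]:
        raise HomotypicSwitchError(f"sites {x} and {y} hold the same type; switch is a no-op")
    new = config.copy()
    new.types[x], new.types[y] = config.types[y], config.types[x]
    return new


def default_counts(side: int, n_types: int) -> np.ndarray:
    """Near-equal per-type counts on a side x side lattice; when side**2 is not
    divisible by N the remainder goes one cell at a time to the lowest type
    indices."""
    total = side * side
    base, rem = divmod(total, n_types)
    counts = np.full(n_types, base, dtype=np.int64)
    counts[:rem] += 1
    return counts


def random_config(
    side: int,
    counts: Sequence[int],
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> LatticeConfig:
    """Uniformly random placement of a fixed multiset of cell types."""
    counts = np.asarray(counts, dtype=np.int64)
    if counts.sum() != side * side:
        raise ValueError(f"counts sum to {counts.sum()}, expected side**2 = {side * side}")
    if rng is None:
        rng = np.random.default_rng(seed)
    flat = np.repeat(np.arange(counts.size, dtype=np.int64), counts)
    grid = rng.permutation(flat).reshape(side, side)
    return LatticeConfig(grid, n_types=counts.size, seed=seed)


def reference_config(kind: str, side: int, n_types: int) -> LatticeConfig:
    """Deterministic reference patterns used to anchor the order indicator.

    ``stripes``
        Row-major fill of the near-equal counts: N horizontal bands, the
        fully phase-separated extreme.
    ``chessboard``
        Two-type alternating parity pattern, the all-heterotypic extreme
        for N=2.  On an odd side the periodic wrap necessarily creates one
        defect row and column of homotypic contacts (warned).
    ``diagonal_stripes``
        Type (row + col) mod N; every in-row and in-column contact is
        heterotypic, with wrap defects whenever side mod N != 0 (warned).
    """
    if side < 3:
        raise DegenerateLatticeError("side must be >= 3")
    if kind == "stripes":
        counts = default_counts(side, n_types)
        flat = np.repeat(np.arange(n_types, dtype=np.int64), counts)
        return LatticeConfig(flat.reshape(side, side), n_types)
    if kind == "chessboard":
        if n_types != 2:
            raise ValueError("chessboard pattern is defined for exactly 2 types")
        if side % 2:
            warnings.warn(
                f"side {side} is odd: periodic chessboard has a defect wrap row/column",
                ImperfectPatternWarning,
                stacklevel=2,
            )
        r, c = np.indices((side, side))
        return LatticeConfig(((r + c) % 2).astype(np.int64), 2)
    if kind == "diagonal_stripes":
        if side % n_types:
            warnings.warn(
                f"side {side} not divisible by {n_types}: diagonal stripes have wrap defects",
                ImperfectPatternWarning,
                stacklevel=2,
            )
        r, c = np.indices((side, side))
        return LatticeConfig(((r + c) % n_types).astype(np.int64), n_types)
    raise ValueError(f"unknown reference pattern {kind!r}")
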