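"""Derived scalar parameters of a bond-strength vector.

Three linear(ized) functionals of the flat bond-strength vector organize the
dynamics of the model:

* the scaling parameter ``beta_s`` (sum of all distinct entries) only
  rescales waiting times, because adding a constant theta to every bond
  strength multiplies every switch rate by exp(-8*theta);
* the effective adhesion parameter ``beta_star`` -- the unique (up to scale)
  relabeling-invariant linear functional orthogonal to the scaling
  direction -- predicts the asymptotic segregation level, with critical
  value 0 separating mixing from sorting;
* the convergence-speed parameter ``beta_delta`` measures the distance to
  the type-symmetric vector with the same beta_s and beta_star; larger
  values mean more switches are needed to reach the asymptotic level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .core import AdhesionParams, flat_index_pairs

__all__ = [
    "SystemParams",
    "HeuristicRates",
    "a_s_vector",
    "a_star_vector",
    "scaling_param",
    "effective_adhesion",
    "convergence_speed",
    "pairwise_deltas",
    "symmetric_projection",
    "system_params",
    "heuristic_rates",
    "tension_to_eap",
]


def a_s_vector(n_types: int) -> np.ndarray:
    """Direction of the scaling functional in flat coordinates: all ones."""
    m = n_types + n_types * (n_types - 1) // 2
    return np.ones(m)


def a_star_vector(n_types: int) -> np.ndarray:
    """Direction of the effective adhesion functional in flat coordinates:
    1 on the N homotypic entries, -2/(N-1) on the heterotypic ones (the
    normalization fixes the homotypic coefficient a = 1).  Orthogonal to
    the all-ones scaling direction for every N."""
    n_het = n_types * (n_types - 1) // 2
    return np.concatenate([np.ones(n_types), np.full(n_het, -2.0 / (n_types - 1))])


def scaling_param(params: AdhesionParams) -> float:
    """Sum of all homotypic plus all distinct heterotypic bond strengths."""
    return float(params.to_flat().sum())


def effective_adhesion(params: AdhesionParams) -> float:
    """Effective adhesion parameter: sum of homotypic entries minus
    2/(N-1) times the sum of distinct heterotypic entries.

    For N=2 this is beta_00 + beta_11 - 2*beta_01; for N=3 it reduces to
    the homotypic sum minus the heterotypic sum.
    """
    return float(params.to_flat() @ a_star_vector(params.n_types))


def symmetric_projection(params: AdhesionParams) -> AdhesionParams:
    """Type-symmetric vector with the same scaling and effective adhesion
    parameters: homotypic entries replaced by their mean, heterotypic
    entries by theirs."""
    n = params.n_types
    hom = float(np.mean(np.diag(params.beta)))
    iu = np.triu_indices(n, k=1)
    het = float(np.mean(params.beta[iu]))
    beta = np.full((n, n), het)
    np.fill_diagonal(beta, hom)
    return AdhesionParams(beta)


def pairwise_deltas(params: AdhesionParams) -> dict[tuple[int, int], float]:
    """Per-pair homotypic differences |beta_ii - beta_jj| for i < j."""
    d = np.diag(params.beta)
    n = params.n_types
    return {(i, j): float(abs(d[i] - d[j])) for i in range(n) for j in range(i + 1, n)}


def convergence_speed(params: AdhesionParams, method: str = "auto") -> float:
    """Convergence-speed parameter.

    ``method='pairwise'`` gives |beta_00 - beta_11| (two types only), the
    form used to label the two-type experiments; ``method='distance'`` gives
    the Euclidean distance of the flat vector to its symmetric projection
    (heterotypic entries counted once), the only form available for N >= 3.
    For two types the two differ exactly by a factor 1/sqrt(2).
    ``'auto'`` selects pairwise for N=2 and distance otherwise.
    """
    n = params.n_types
    if method == "auto":
        method = "pairwise" if n == 2 else "distance"
    if method == "pairwise":
        if n != 2:
            raise ValueError("pairwise convergence speed is defined for N=2 only")
        return float(abs(params.beta[0, 0] - params.beta[1, 1]))
    if method == "distance":
        sym = symmetric_projection(params)
        return float(np.linalg.norm(params.to_flat() - sym.to_flat()))
    raise ValueError(f"unknown method {method!r}")


@dataclass(frozen=True)
class SystemParams:
    """The derived scalars of a bond-strength vector."""

    beta_s: float
    beta_star: float
    beta_delta: float
    pairwise_deltas: dict[tuple[int, int], float]


def system_params(params: AdhesionParams) -> SystemParams:
    return SystemParams(
        beta_s=scaling_param(params),
        beta_star=effective_adhesion(params),
        beta_delta=convergence_speed(params),
        pairwise_deltas=pairwise_deltas(params),
    )


class HeuristicRates(NamedTuple):
    c_mix: float
    c_unmix_0: float
    c_unmix_1: float
    unmix_mix_ratio: float


def heuristic_rates(params: AdhesionParams) -> HeuristicRates:
    """Two-type limit-scenario switch rates.

    ``c_mix`` is the rate of a mixing switch at a straight interface between
    two clusters, exp(-(3*beta_00 + 3*beta_11 + 2*beta_01)).  ``c_unmix_w``
    is the rate at which a lone type-w cell inside a cluster of the other
    type exchanges with a given neighbor, exp(-(3*beta_(1-w)(1-w) +
    5*beta_01)).  The ratio c_unmix_0*c_unmix_1 / c_mix**2 equals
    exp(3*beta_star) identically: it exceeds 1 (unmixing beats mixing)
    exactly when the effective adhesion parameter is positive.
    """
    if params.n_types != 2:
        raise ValueError("heuristic rates are defined for two-type systems only")
    b00, b11, b01 = params.beta[0, 0], params.beta[1, 1], params.beta[0, 1]
    c_mix = float(np.exp(-(3.0 * (b00 + b11) + 2.0 * b01)))
    c_unmix_0 = float(np.exp(-(3.0 * b11 + 5.0 * b01)))
    c_unmix_1 = float(np.exp(-(3.0 * b00 + 5.0 * b01)))
    ratio = c_unmix_0 * c_unmix_1 / c_mix**2
    return HeuristicRates(c_mix, c_unmix_0, c_unmix_1, float(ratio))


def tension_to_eap(tensions: np.ndarray) -> float:
    """Effective adhesion parameter implied by a 2x2 relative contact-tension
    matrix, under the identification beta_ij = -T_ij (high tension = low
    adhesion): beta_star = -T_00 - T_11 + 2*T_01."""
    T = np.asarray(tensions, dtype=float)
    if T.shape != (2, 2) or not np.allclose(T, T.T, atol=1e-12, rtol=0.0):
        raise ValueError("tensions must be a symmetric 2x2 matrix")
    return effective_adhesion(AdhesionParams(-T))
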