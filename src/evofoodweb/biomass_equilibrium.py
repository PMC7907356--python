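"""Donor-controlled biomass equilibria and the extinction cascade.

Population biomasses in one habitat satisfy the self-consistent transport
relation

    B(i) = gamma_{i0} * R + lambda * sum_j (gamma_ij B(j) - gamma_ji B(i)),

where ``gamma_{i0}`` is species *i*'s share of the external resource ``R``
and ``lambda`` is the transfer efficiency.  The first term in the sum is
*i*'s intake from each of its prey; the second is what *i*'s own predators
take from it.  Both flows are proportional to the *prey's* standing
biomass — predator abundance never feeds back on prey, so the system is
donor-controlled with no top-down effects.  Because every feeding-share
column sums to 1 over the prey's predator set, predation gains and losses
cancel in the community total and

    sum_i B(i) = R   exactly,

whenever the resource has at least one consumer: the resource amount and
the extinction threshold jointly cap how many populations a habitat can
carry (R / threshold).

Writing ``G`` for the species-by-species share matrix and
``p_j = sum_k gamma_kj`` (1 for preyed species, else 0), the relation is
the linear system ``(I + lambda*diag(p) - lambda*G) B = gamma_col0 * R``.
The matrix is strictly column diagonally dominant with nonpositive
off-diagonals — a nonsingular M-matrix — so the solution exists, is
unique, and is componentwise nonnegative.

A population persists only if its equilibrium biomass density reaches the
extinction threshold (1 by default).  :func:`apply_extinction_cascade`
removes sub-threshold populations one at a time — smallest biomass first,
ties broken by smaller species id — re-solving after every removal, so a
removal can drag further species below threshold (secondary extinctions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trophic_network import (
    DEFAULT_CUTOFF,
    InteractionMatrices,
    Resource,
    SpeciesTraits,
    build_matrices,
)

__all__ = [
    "LocalWeb",
    "CascadeReport",
    "solve_equilibrium",
    "fixed_point_oracle",
    "apply_extinction_cascade",
]


@dataclass
class LocalWeb:
    """One habitat's community: species, interaction matrices, biomasses."""

    species_ids: list[int]
    traits: list[SpeciesTraits]
    matrices: InteractionMatrices
    biomasses: np.ndarray
    resource: Resource

    @classmethod
    def assemble(
        cls,
        species_ids: list[int],
        traits: list[SpeciesTraits],
        resource: Resource,
        delta: float,
        cutoff: float = DEFAULT_CUTOFF,
    ) -> "LocalWeb":
        """Build matrices for the given species; biomasses start at zero."""
        if len(set(species_ids)) != len(species_ids):
            raise ValueError("species ids must be unique within a web")
        mats = build_matrices(traits, resource, delta, cutoff)
        return cls(
            species_ids=list(species_ids),
            traits=list(traits),
            matrices=mats,
            biomasses=np.zeros(len(traits)),
            resource=resource,
        )

    def __len__(self) -> int:
        return len(self.species_ids)


@dataclass
class CascadeReport:
    """Removals performed by one extinction cascade, in order.

    ``cascade_iteration`` is the 1-based position of the removal in the
    cascade; values >= 2 mark secondary extinctions (caused by a preceding
    removal in the same cascade rather than by the triggering event).
    """

    removed: list[tuple[int, int, float]] = field(default_factory=list)

    def __bool__(self) -> bool:
        return bool(self.removed)


def _linear_parts(
    gamma: np.ndarray, efficiency: float, R: float
) -> tuple[np.ndarray, np.ndarray]:
    """Matrix M = I + lambda*diag(p) - lambda*G and inflow vector of the system.

    ``p`` holds the species-column sums of the share matrix (the predation
    pressure: 1 for preyed species, 0 for top species).  Cannibalistic
    shares appear identically in gains and losses and cancel.
    """
    n = gamma.shape[0]
    G = gamma[:, 1:]
    p = G.sum(axis=0)
    M = np.eye(n) * (1.0 + efficiency * p) - efficiency * G
    c = gamma[:, 0] * R
    return M, c


def solve_equilibrium(
    web: LocalWeb, efficiency: float, R: float | None = None
) -> np.ndarray:
    """Unique nonnegative equilibrium biomass vector of the web.

    Solved directly as a linear system.  Species with no prey (all-zero
    share row) receive biomass exactly 0.  The returned vector additionally
    satisfies the conservation bound ``sum(B) <= R``, with equality exactly
    when the resource has at least one consumer.
    """
    if not 0 < efficiency < 1:
        raise ValueError("efficiency must lie strictly between 0 and 1")
    if R is None:
        R = web.resource.amount_per_habitat
    n = len(web)
    if n == 0:
        return np.zeros(0)
    M, c = _linear_parts(web.matrices.feeding_share, efficiency, R)
    B = np.linalg.solve(M, c)
    # exact zeros for prey-less species; clip solver noise on the rest
    B[~web.matrices.strength.any(axis=1)] = 0.0
    np.maximum(B, 0.0, out=B)
    if B.sum() > R * (1 + 1e-9):
        raise AssertionError("total biomass exceeds the resource input")
    return B


def fixed_point_oracle(
    web: LocalWeb,
    efficiency: float,
    R: float | None = None,
    tol: float = 1e-12,
    max_iter: int = 100_000,
    damping: float = 0.5,
) -> np.ndarray:
    """Independent iterative solution of the biomass relation.

    Damped Picard iteration ``B <- (1-w) B + w (c + A B)`` from ``B = 0``
    with ``A = lambda*(G - diag(p))``, until the max-norm change drops
    below ``tol``.  ``A`` has real spectrum in ``(-2*lambda, 0]`` (it is a
    weighted-Laplacian-like matrix; exactly ``{-lambda*p}`` on feed-forward
    webs), so the damped map with ``w = 0.5`` is a contraction.  Serves as
    a slow, structurally different check on :func:`solve_equilibrium`.
    """
    if not 0 < efficiency < 1:
        raise ValueError("efficiency must lie strictly between 0 and 1")
    if R is None:
        R = web.resource.amount_per_habitat
    n = len(web)
    if n == 0:
        return np.zeros(0)
    M, c = _linear_parts(web.matrices.feeding_share, efficiency, R)
    A = np.eye(n) - M  # = lambda * (G - diag(p))
    B = np.zeros(n)
    for _ in range(max_iter):
        B_new = (1.0 - damping) * B + damping * (c + A @ B)
        if np.max(np.abs(B_new - B)) < tol:
            return B_new
        B = B_new
    raise RuntimeError("fixed-point iteration failed to converge")


def apply_extinction_cascade(
    web: LocalWeb,
    threshold: float = 1.0,
    efficiency: float = 0.65,
    delta: float = 0.25,
    cutoff: float = DEFAULT_CUTOFF,
) -> tuple[LocalWeb, CascadeReport]:
    """Remove sub-threshold populations until the whole web is viable.

    One species is removed per round: the one with the smallest biomass
    strictly below ``threshold`` (ties broken by smaller species id).  The
    matrices are rebuilt and the equilibrium re-solved after each removal;
    survivors are exactly the species whose final biomass is >= threshold.
    May return an empty web.
    """
    ids = list(web.species_ids)
    traits = list(web.traits)
    report = CascadeReport()
    iteration = 0
    while True:
        current = LocalWeb.assemble(ids, traits, web.resource, delta, cutoff)
        B = solve_equilibrium(current, efficiency)
        current.biomasses = B
        below = [k for k in range(len(ids)) if B[k] < threshold]
        if not below:
            break
        # smallest biomass first; ties by smaller species id
        pick = min(below, key=lambda k: (B[k], ids[k]))
        iteration += 1
        report.removed.append((ids[pick], iteration, float(B[pick])))
        del ids[pick], traits[pick]
    return current, report
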