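"""Species traits, Gaussian feeding kernels, and competition-normalized feeding shares.

A species is defined by three heritable traits on a logarithmic body-mass
axis: its log body mass ``m``, the center ``f`` of its Gaussian feeding
kernel, and the kernel width ``s``.  A predator *i* attacks prey *j* with
strength

    a_ij = exp(-(f_i - m_j)^2 / (2 s_i))      if |f_i - m_j| <= c * s_i,
    a_ij = 0                                   otherwise,

where ``c`` truncates the kernel tails (default 1.0).  Because speciation
draws ``f`` at least one unit below ``m`` and widths never exceed 1, the
default cutoff makes every prey strictly lighter than its consumer, so
evolved webs are ordered by body mass.  Predators sharing a
prey compete: the best-adapted predator (largest ``a`` on that prey, written
``a*``) takes the largest share, and each predator's share is obtained by
normalizing

    F_ij = exp(-((a* - a_ij) / delta)^2)

over the prey's realized predator set, giving the feeding shares
``gamma_ij`` (each prey column sums to 1).  ``delta`` tunes how strongly the
best predator dominates.  The external resource occupies prey column 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SpeciesTraits",
    "Resource",
    "InteractionMatrices",
    "interaction_strength",
    "competition_weights",
    "build_matrices",
    "strength_matrix",
    "feeding_share_matrix",
    "matrices_to_edge_list",
]

#: Default kernel cutoff: interaction is zero beyond ``c * s`` from the center.
DEFAULT_CUTOFF = 1.0


@dataclass(frozen=True)
class SpeciesTraits:
    """The three heritable trait values defining a species.

    All traits live on the same (natural-)logarithmic body-mass scale.
    ``feeding_center`` always lies below ``log_body_mass`` for species
    produced by speciation, because the center is drawn from the interval
    ``[m - dm1, m - dm2]`` with ``dm2 >= 1``.
    """

    log_body_mass: float
    feeding_center: float
    feeding_width: float

    def __post_init__(self) -> None:
        if not self.feeding_width > 0:
            raise ValueError(
                f"feeding_width must be positive, got {self.feeding_width}"
            )


@dataclass(frozen=True)
class Resource:
    """The external energy source, present in equal amount on every habitat."""

    log_body_mass: float = 0.0
    amount_per_habitat: float = 25.0

    def __post_init__(self) -> None:
        if not self.amount_per_habitat > 0:
            raise ValueError("resource amount must be positive")


@dataclass
class InteractionMatrices:
    """Pairwise interaction strengths and feeding shares for one habitat.

    Rows index predators (the habitat's species, in order), columns index
    prey with the resource in column 0 and species ``k`` in column ``k+1``.
    ``feeding_share`` columns belonging to prey with at least one predator
    sum to exactly 1; shares are positive exactly where strengths are.
    """

    strength: np.ndarray = field(repr=False)
    feeding_share: np.ndarray = field(repr=False)

    @property
    def n_species(self) -> int:
        return self.strength.shape[0]


def interaction_strength(
    predator: SpeciesTraits, prey_log_mass: float, cutoff: float = DEFAULT_CUTOFF
) -> float:
    """Gaussian feeding-kernel strength of ``predator`` on a prey of given log mass.

    Returns a value in [0, 1]; exactly 0 beyond ``cutoff * feeding_width``
    from the kernel center.  Symmetric in the sign of ``f - m``.
    """
    s = predator.feeding_width
    if not s > 0:
        raise ValueError("feeding_width must be positive")
    d = predator.feeding_center - prey_log_mass
    if abs(d) > cutoff * s:
        return 0.0
    return float(np.exp(-(d * d) / (2.0 * s)))


def competition_weights(
    strengths: dict[int, float], delta: float
) -> dict[int, float]:
    """Feeding shares gamma for the predator set of one prey.

    ``strengths`` maps predator index -> interaction strength ``a_ij`` (all
    positive).  The share of predator *i* is ``F_i / sum_k F_k`` with
    ``F_i = exp(-((a* - a_i)/delta)^2)`` and ``a*`` the largest strength, so
    the best predator always receives the largest share.
    """
    if not strengths:
        raise ValueError("prey has no consumers; competition_weights undefined")
    if not delta > 0:
        raise ValueError("delta must be positive")
    a = np.asarray(list(strengths.values()), dtype=float)
    if np.any(a <= 0):
        raise ValueError("all interaction strengths must be positive")
    f = np.exp(-(((a.max() - a) / delta) ** 2))
    gamma = f / f.sum()
    return dict(zip(strengths.keys(), gamma))


def strength_matrix(
    species: list[SpeciesTraits],
    resource: Resource,
    cutoff: float = DEFAULT_CUTOFF,
) -> np.ndarray:
    """All pairwise interaction strengths; shape (n, n+1), resource column 0."""
    n = len(species)
    a = np.zeros((n, n + 1))
    masses = np.concatenate(
        ([resource.log_body_mass], [sp.log_body_mass for sp in species])
    )
    for i, sp in enumerate(species):
        d = sp.feeding_center - masses
        with np.errstate(under="ignore"):
            row = np.exp(-(d * d) / (2.0 * sp.feeding_width))
        row[np.abs(d) > cutoff * sp.feeding_width] = 0.0
        a[i] = row
    return a


def feeding_share_matrix(strength: np.ndarray, delta: float) -> np.ndarray:
    """Column-normalize a strength matrix into feeding shares.

    Columns (prey) with no predator stay all-zero; every other column sums
    to exactly 1.
    """
    if not delta > 0:
        raise ValueError("delta must be positive")
    gamma = np.zeros_like(strength)
    if strength.size == 0:
        return gamma
    a_star = strength.max(axis=0)
    has_pred = a_star > 0
    with np.errstate(under="ignore"):
        f = np.exp(-(((a_star[None, :] - strength) / delta) ** 2))
    f[strength == 0] = 0.0
    col_sum = f.sum(axis=0)
    gamma[:, has_pred] = f[:, has_pred] / col_sum[has_pred]
    return gamma


def build_matrices(
    species: list[SpeciesTraits],
    resource: Resource,
    delta: float,
    cutoff: float = DEFAULT_CUTOFF,
) -> InteractionMatrices:
    """Interaction strengths and feeding shares for a habitat's species list.

    Species with an all-zero strength row (no prey at all, resource
    included) get an all-zero share row and will receive zero biomass in the
    equilibrium solve.
    """
    a = strength_matrix(species, resource, cutoff)
    gamma = feeding_share_matrix(a, delta)
    return InteractionMatrices(strength=a, feeding_share=gamma)


def matrices_to_edge_list(
    matrices: InteractionMatrices, species_ids: list[int]
) -> pd.DataFrame:
    """Flatten the matrices into a TSV-friendly edge list.

    Prey id 0 denotes the resource; realized links only (strength > 0).
    """
    pred, prey = np.nonzero(matrices.strength)
    ids = np.asarray(species_ids, dtype=np.int64)
    prey_ids = np.where(prey == 0, 0, ids[np.maximum(prey - 1, 0)])
    return pd.DataFrame(
        {
            "predator_id": ids[pred],
            "prey_id": prey_ids,
            "strength": matrices.strength[pred, prey],
            "feeding_share": matrices.feeding_share[pred, prey],
        }
    )
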