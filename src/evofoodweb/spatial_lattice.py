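"""Periodic square-lattice geometry: neighborhoods, toroidal distances, SAR shells.

Habitats live on a ``width x height`` torus.  Each habitat has the four
von-Neumann neighbors (with wraparound), distance is the minimum number of
nearest-neighbor steps (per-axis wrapped Manhattan distance), and
species-area sampling uses nested shells: the set of habitats within
distance ``k`` of a start habitat.  Habitats are identified by a single
row-major integer index; helpers convert to/from ``(x, y)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np

__all__ = ["Lattice"]


@dataclass(frozen=True)
class Lattice:
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width < 2 or self.height < 2:
            raise ValueError("lattice must be at least 2x2")

    @property
    def n_habitats(self) -> int:
        return self.width * self.height

    def index(self, x: int, y: int) -> int:
        return (y % self.height) * self.width + (x % self.width)

    def coords(self, habitat: int) -> tuple[int, int]:
        self._check(habitat)
        return habitat % self.width, habitat // self.width

    def _check(self, habitat: int) -> None:
        if not 0 <= habitat < self.n_habitats:
            raise IndexError(f"habitat {habitat} outside 0..{self.n_habitats - 1}")

    def neighbors(self, habitat: int) -> set[int]:
        """The 4 von-Neumann neighbors under wraparound (fewer if collapsed on 2-wide axes)."""
        x, y = self.coords(habitat)
        return {
            self.index(x - 1, y),
            self.index(x + 1, y),
            self.index(x, y - 1),
            self.index(x, y + 1),
        }

    @cached_property
    def neighbor_table(self) -> np.ndarray:
        """(H, 4) int array of neighbor indices (duplicates possible on 2-wide axes)."""
        table = np.empty((self.n_habitats, 4), dtype=np.int64)
        for h in range(self.n_habitats):
            x, y = self.coords(h)
            table[h] = (
                self.index(x - 1, y),
                self.index(x + 1, y),
                self.index(x, y - 1),
                self.index(x, y + 1),
            )
        return table

    def torus_distance(self, a: int, b: int) -> int:
        """Minimum number of nearest-neighbor steps between two habitats."""
        self._check(a)
        self._check(b)
        ax, ay = self.coords(a)
        bx, by = self.coords(b)
        dx = abs(ax - bx)
        dy = abs(ay - by)
        return min(dx, self.width - dx) + min(dy, self.height - dy)

    @cached_property
    def distance_matrix(self) -> np.ndarray:
        """(H, H) matrix of toroidal distances."""
        xs = np.arange(self.n_habitats) % self.width
        ys = np.arange(self.n_habitats) // self.width
        dx = np.abs(xs[:, None] - xs[None, :])
        dy = np.abs(ys[:, None] - ys[None, :])
        dx = np.minimum(dx, self.width - dx)
        dy = np.minimum(dy, self.height - dy)
        return dx + dy

    def nested_shells(self, start: int, max_radius: int) -> list[set[int]]:
        """Nested habitat sets of increasing radius around ``start``.

        Element ``k`` is the set of habitats at toroidal distance <= k; the
        sets are strictly nested until the whole lattice is covered
        (|shell k| = 2k^2 + 2k + 1 before wraparound saturation).
        """
        if max_radius < 0:
            raise ValueError("max_radius must be >= 0")
        self._check(start)
        d = self.distance_matrix[start]
        return [set(np.flatnonzero(d <= k).tolist()) for k in range(max_radius + 1)]

    def max_distance(self) -> int:
        return self.width // 2 + self.height // 2
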