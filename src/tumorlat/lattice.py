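"""Lattice geometries, neighborhoods, and occupancy queries.

Four lattice types are supported:

* regular 2D/3D with the Moore neighborhood (all surrounding sites,
  ``3**d - 1`` of them) or the von Neumann neighborhood (axis-adjacent
  sites, ``2*d``);
* hexagonal 2D, stored in axial integer coordinates (6 neighbors);
* "hexagonal" 3D, realized as the face-centered cubic (FCC) lattice:
  integer triples with even coordinate sum, 12 equidistant neighbors.

Coordinates are plain integer tuples and the lattice is unbounded; a
simulation stores occupancy sparsely as a ``dict`` mapping coordinate to
cell id, so there are no domain walls and no boundary conditions.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

Coord = Tuple[int, ...]
Occupancy = Dict[Coord, int]

_SQRT2 = math.sqrt(2.0)
_SQRT3_2 = math.sqrt(3.0) / 2.0


class LatticeError(ValueError):
    """A coordinate or lattice specification violates a lattice constraint."""


def _regular_offsets(dimension: int, neighborhood: str) -> Tuple[Coord, ...]:
    if neighborhood == "moore":
        offs = [
            v
            for v in itertools.product((-1, 0, 1), repeat=dimension)
            if any(v)
        ]
    elif neighborhood == "von_neumann":
        offs = []
        for axis in range(dimension):
            for sign in (-1, 1):
                v = [0] * dimension
                v[axis] = sign
                offs.append(tuple(v))
    else:
        raise LatticeError(f"unknown neighborhood {neighborhood!r}")
    return tuple(sorted(offs))


# Axial coordinates: the six hex neighbors.
_HEX2D_OFFSETS = tuple(
    sorted([(1, 0), (-1, 0), (0, 1), (0, -1), (1, -1), (-1, 1)])
)

# FCC: permutations of (+-1, +-1, 0); every offset has even coordinate sum,
# so the even-sum sublattice is closed under neighbor steps.
_FCC_OFFSETS = tuple(
    sorted(
        {
            v
            for v in itertools.product((-1, 0, 1), repeat=3)
            if sum(abs(x) for x in v) == 2
        }
    )
)


@dataclass(frozen=True)
class LatticeSpec:
    """Immutable description of a lattice family plus neighborhood rule.

    ``offsets`` is the ordered tuple of integer displacement vectors to the
    adjacent sites ("directions"); the order is lexicographic and fixed so
    that seeded runs are reproducible.
    """

    dimension: int
    family: str  # "regular" | "hexagonal"
    neighborhood: str  # "moore" | "von_neumann" | "hex"
    offsets: Tuple[Coord, ...] = field(init=False)

    def __post_init__(self) -> None:
        if self.dimension not in (2, 3):
            raise LatticeError(f"dimension must be 2 or 3, got {self.dimension}")
        if self.family == "regular":
            if self.neighborhood not in ("moore", "von_neumann"):
                raise LatticeError(
                    "regular lattice requires neighborhood 'moore' or "
                    f"'von_neumann', got {self.neighborhood!r}"
                )
            offs = _regular_offsets(self.dimension, self.neighborhood)
        elif self.family == "hexagonal":
            if self.neighborhood != "hex":
                raise LatticeError(
                    "hexagonal lattice admits only the 'hex' neighborhood "
                    f"(got {self.neighborhood!r})"
                )
            offs = _HEX2D_OFFSETS if self.dimension == 2 else _FCC_OFFSETS
        else:
            raise LatticeError(f"unknown lattice family {self.family!r}")
        object.__setattr__(self, "offsets", offs)

    @property
    def n_neighbors(self) -> int:
        return len(self.offsets)

    def origin(self) -> Coord:
        return (0,) * self.dimension

    def validate_coord(self, c: Coord) -> None:
        if len(c) != self.dimension:
            raise LatticeError(f"coordinate {c} has wrong dimension")
        if self.family == "hexagonal" and self.dimension == 3 and sum(c) % 2:
            raise LatticeError(f"coordinate {c} is not on the FCC sublattice")


def make_lattice(
    family: str = "regular", dimension: int = 3, neighborhood: str = "moore"
) -> LatticeSpec:
    """Build a :class:`LatticeSpec`; hexagonal lattices force ``hex``."""
    if family == "hexagonal":
        neighborhood = "hex"
    return LatticeSpec(dimension=dimension, family=family, neighborhood=neighborhood)


def neighbors(c: Coord, spec: LatticeSpec) -> List[Coord]:
    """Adjacent sites of ``c``, in the spec's fixed offset order."""
    spec.validate_coord(c)
    return [tuple(a + b for a, b in zip(c, off)) for off in spec.offsets]


def phi(c: Coord, occupancy: Occupancy, spec: LatticeSpec) -> float:
    """Proportion of empty sites among the neighbors of ``c`` (in [0, 1])."""
    nbrs = neighbors(c, spec)
    empty = sum(1 for n in nbrs if n not in occupancy)
    return empty / len(nbrs)


def l_min(
    c: Coord,
    direction_index: int,
    occupancy: Occupancy,
    spec: LatticeSpec,
    cap: int | None = None,
) -> int:
    """Consecutive occupied sites from ``c`` toward the nearest empty site.

    Walks along ``spec.offsets[direction_index]`` starting at the adjacent
    site and counts occupied sites up to (not including) the first empty
    one; 0 means the adjacent site itself is empty.  ``cap`` bounds the
    walk (a finite tumor always has an empty site along any ray, so hitting
    the cap indicates an internal inconsistency and raises).
    """
    off = spec.offsets[direction_index]
    if cap is None:
        cap = len(occupancy) + 1
    pos = c
    count = 0
    while count <= cap:
        pos = tuple(a + b for a, b in zip(pos, off))
        if pos not in occupancy:
            return count
        count += 1
    raise LatticeError(
        f"l_min search from {c} along {off} exceeded cap {cap}; "
        "occupancy map appears unbounded along this ray"
    )


def l_min_all(
    c: Coord, occupancy: Occupancy, spec: LatticeSpec
) -> List[int]:
    """``l_min`` for every direction, in offset order."""
    return [l_min(c, i, occupancy, spec) for i in range(len(spec.offsets))]


def to_cartesian(c: Coord, spec: LatticeSpec) -> Tuple[float, ...]:
    """Real-space embedding with unit nearest-neighbor distance.

    Regular lattices map identically (von Neumann neighbors then sit at
    distance 1; Moore diagonals are farther, as on any square grid).
    Hex-2D uses the axial basis x' = x + y/2, y' = y*sqrt(3)/2; FCC scales
    the integer triple by 1/sqrt(2).
    """
    spec.validate_coord(c)
    if spec.family == "regular":
        return tuple(float(x) for x in c)
    if spec.dimension == 2:
        x, y = c
        return (x + 0.5 * y, y * _SQRT3_2)
    return tuple(x / _SQRT2 for x in c)
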