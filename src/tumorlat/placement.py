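"""Placement of the displaced daughter cell: the four push methods.

At division one daughter keeps the parent's site; these rules decide
where the other goes and which pre-existing cells shift:

1. a uniformly random direction; the whole chain of occupied sites along
   that ray shifts one step outward until an empty site absorbs it;
2. fill a random empty neighbor if any; otherwise a direction sampled
   with probability proportional to ``1/l_min`` and the ``l_min`` cells
   along that ray shifted en bloc;
3. fill if possible; otherwise the daughter takes the argmin-``l_min``
   neighbor and each displaced cell hops one step in its own current
   argmin-``l_min`` direction, recomputed at every hop, until an empty
   site ends the chain;
4. fill if possible; otherwise the argmin-``l_min`` direction is chosen
   once and the ``l_min`` cells along it shift en bloc.

Under the step/linear density models a dividing cell always has an empty
neighbor (its rate is zero otherwise), so methods 2-4 reduce to the fill
rule and behave identically; method 1 keeps its pushing semantics in all
models.  Displaced cells retain all state; only coordinates change.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

import numpy as np

from .lattice import Coord, LatticeSpec, l_min_all, neighbors

# (cell_id, old_coord, new_coord) for every pre-existing cell that shifted.
Move = Tuple[int, Coord, Coord]


class PlacementError(RuntimeError):
    pass


def _add(c: Coord, off: Coord, times: int = 1) -> Coord:
    return tuple(a + times * b for a, b in zip(c, off))


def _argmin_indices(values: Sequence[float]) -> List[int]:
    m = min(values)
    return [i for i, v in enumerate(values) if v == m]


def _ray_shift(
    occupancy: Dict[Coord, int],
    cells: Dict[int, "object"],
    origin: Coord,
    off: Coord,
    n: int,
) -> List[Move]:
    """Shift the ``n`` consecutive occupants at origin+off .. origin+n*off
    one step outward (the site at origin+(n+1)*off must be empty)."""
    moves: List[Move] = []
    for i in range(n, 0, -1):
        old = _add(origin, off, i)
        new = _add(origin, off, i + 1)
        if new in occupancy:
            raise PlacementError(f"ray shift target {new} is occupied")
        cid = occupancy.pop(old)
        occupancy[new] = cid
        cells[cid].coord = new
        moves.append((cid, old, new))
    return moves


def push_weights(
    occupancy: Dict[Coord, int], spec: LatticeSpec, origin: Coord
) -> np.ndarray:
    """Method-2 direction probabilities, proportional to ``1/l_min``.

    Directions whose adjacent site is empty (``l_min = 0``) get all the
    weight split uniformly among them, matching the fill rule that always
    runs first.
    """
    lmins = l_min_all(origin, occupancy, spec)
    w = np.zeros(len(lmins))
    zero = [i for i, l in enumerate(lmins) if l == 0]
    if zero:
        w[zero] = 1.0
    else:
        w[:] = [1.0 / l for l in lmins]
    return w / w.sum()


def place_fill_empty(
    occupancy: Dict[Coord, int],
    spec: LatticeSpec,
    origin: Coord,
    rng: np.random.Generator,
    new_id: int,
) -> Tuple[Coord, List[Move]]:
    """Put the daughter on a uniformly random empty neighbor; nobody moves."""
    empties = [n for n in neighbors(origin, spec) if n not in occupancy]
    if not empties:
        raise PlacementError(f"no empty neighbor of {origin} to fill")
    target = empties[int(rng.integers(len(empties)))]
    occupancy[target] = new_id
    return target, []


def place_push1(
    occupancy: Dict[Coord, int],
    cells: Dict[int, "object"],
    spec: LatticeSpec,
    origin: Coord,
    rng: np.random.Generator,
    new_id: int,
    direction_index: int | None = None,
) -> Tuple[Coord, List[Move]]:
    if direction_index is None:
        direction_index = int(rng.integers(len(spec.offsets)))
    off = spec.offsets[direction_index]
    # Count the occupied run along the ray.
    n = 0
    pos = _add(origin, off)
    cap = len(occupancy) + 1
    while pos in occupancy:
        n += 1
        if n > cap:
            raise PlacementError("push ray exceeded population size")
        pos = _add(pos, off)
    moves = _ray_shift(occupancy, cells, origin, off, n)
    target = _add(origin, off)
    occupancy[target] = new_id
    return target, moves


def place_push2(
    occupancy: Dict[Coord, int],
    cells: Dict[int, "object"],
    spec: LatticeSpec,
    origin: Coord,
    rng: np.random.Generator,
    new_id: int,
) -> Tuple[Coord, List[Move]]:
    probs = push_weights(occupancy, spec, origin)
    d = int(rng.choice(len(probs), p=probs))
    off = spec.offsets[d]
    lm = l_min_all(origin, occupancy, spec)[d]
    moves = _ray_shift(occupancy, cells, origin, off, lm)
    target = _add(origin, off)
    occupancy[target] = new_id
    return target, moves


def _argmin_direction(
    occupancy: Dict[Coord, int],
    spec: LatticeSpec,
    c: Coord,
    rng: np.random.Generator,
) -> Tuple[int, int]:
    """(direction index, its l_min); ties broken uniformly at random."""
    lmins = l_min_all(c, occupancy, spec)
    ties = _argmin_indices(lmins)
    d = ties[int(rng.integers(len(ties)))] if len(ties) > 1 else ties[0]
    return d, lmins[d]


def place_push3(
    occupancy: Dict[Coord, int],
    cells: Dict[int, "object"],
    spec: LatticeSpec,
    origin: Coord,
    rng: np.random.Generator,
    new_id: int,
) -> Tuple[Coord, List[Move]]:
    d, lm = _argmin_direction(occupancy, spec, origin, rng)
    target = _add(origin, spec.offsets[d])
    moves: List[Move] = []
    if lm == 0:
        occupancy[target] = new_id
        return target, moves
    moving = occupancy[target]
    occupancy[target] = new_id  # block the site before resolving the chain
    cur = target
    guard = len(cells) + 2
    while True:
        if len(moves) > guard:
            raise PlacementError("push-3 chain exceeded population size")
        d2, _ = _argmin_direction(occupancy, spec, cur, rng)
        nxt = _add(cur, spec.offsets[d2])
        occupant = occupancy.get(nxt)
        occupancy[nxt] = moving
        cells[moving].coord = nxt
        moves.append((moving, cur, nxt))
        if occupant is None:
            return target, moves
        moving = occupant
        cur = nxt


def place_push4(
    occupancy: Dict[Coord, int],
    cells: Dict[int, "object"],
    spec: LatticeSpec,
    origin: Coord,
    rng: np.random.Generator,
    new_id: int,
) -> Tuple[Coord, List[Move]]:
    d, lm = _argmin_direction(occupancy, spec, origin, rng)
    off = spec.offsets[d]
    moves = _ray_shift(occupancy, cells, origin, off, lm)
    target = _add(origin, off)
    occupancy[target] = new_id
    return target, moves


def place(
    occupancy: Dict[Coord, int],
    cells: Dict[int, "object"],
    spec: LatticeSpec,
    origin: Coord,
    method: int,
    e2_model: str,
    rng: np.random.Generator,
    new_id: int,
    direction_index: int | None = None,
) -> Tuple[Coord, List[Move]]:
    """Dispatch to the configured push method.

    Methods 2-4 first try to fill an empty neighbor and only push when
    the dividing cell is fully enclosed; method 1 always pushes along a
    random direction, in every density model.
    """
    if method == 1:
        return place_push1(
            occupancy, cells, spec, origin, rng, new_id, direction_index
        )
    if method not in (2, 3, 4):
        raise PlacementError(f"unknown push method {method}")
    if any(n not in occupancy for n in neighbors(origin, spec)):
        return place_fill_empty(occupancy, spec, origin, rng, new_id)
    if e2_model in ("step", "linear"):
        raise PlacementError(
            "division scheduled with no empty neighbor under the "
            f"{e2_model} model; its rate should have been zero"
        )
    if method == 2:
        return place_push2(occupancy, cells, spec, origin, rng, new_id)
    if method == 3:
        return place_push3(occupancy, cells, spec, origin, rng, new_id)
    return place_push4(occupancy, cells, spec, origin, rng, new_id)
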