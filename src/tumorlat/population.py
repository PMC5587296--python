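"""Cell state, differentiation, genealogy, and event effects.

The cell hierarchy follows the cancer stem cell (CSC) model: a CSC
divides symmetrically (two CSC daughters) with probability ``p_s`` and
asymmetrically otherwise, producing one CSC (which keeps the site) and
one transient amplifying cell (TAC) with a division budget
``omega = omega_max``.  A TAC division gives both daughters
``omega - 1``; at ``omega = 0`` they are terminally differentiated cells
(TDCs) and never divide again, though they still die and migrate.

Every division retires the parent's genealogy node and appends two
daughter nodes, so the genealogy is a strict binary tree rooted at the
initial cell; a node's depth ``nu`` is the number of division events in
its ancestry, and branch lengths are node lifespans in simulation time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Literal, Optional, Set, Tuple

import numpy as np

from . import placement
from .kinetics import DriverEffect, MutationModel, draw_new_mutations
from .lattice import Coord, LatticeSpec, neighbors

CellType = Literal["CSC", "TAC", "TDC"]


class PopulationError(RuntimeError):
    """An event was requested that violates a population contract."""


@dataclass
class Cell:
    """One live cell occupying a single lattice node."""

    id: int
    coord: Coord
    cell_type: CellType
    omega: int
    t_birth: float
    t_last_division: float
    parent_id: Optional[int]
    beta_effects: Tuple[float, ...] = ()
    delta_effects: Tuple[float, ...] = ()
    rho_effects: Tuple[float, ...] = ()

    @property
    def can_divide(self) -> bool:
        return self.cell_type != "TDC"


@dataclass
class GenealogyRecord:
    id: int
    parent_id: Optional[int]
    t_birth: float
    nu: int
    t_end: Optional[float] = None  # division or death time; None while alive


class Genealogy:
    """Append-only binary tree of every cell ever created."""

    def __init__(self) -> None:
        self._records: Dict[int, GenealogyRecord] = {}

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, cell_id: int) -> bool:
        return cell_id in self._records

    def add(self, cell_id: int, parent_id: Optional[int], t_birth: float) -> None:
        if cell_id in self._records:
            raise PopulationError(f"duplicate genealogy id {cell_id}")
        if parent_id is None:
            nu = 0
        else:
            parent = self._records[parent_id]
            nu = parent.nu + 1
        self._records[cell_id] = GenealogyRecord(cell_id, parent_id, t_birth, nu)

    def close(self, cell_id: int, t_end: float) -> None:
        self._records[cell_id].t_end = t_end

    def record(self, cell_id: int) -> GenealogyRecord:
        return self._records[cell_id]

    def parent(self, cell_id: int) -> Optional[int]:
        return self._records[cell_id].parent_id

    def nu(self, cell_id: int) -> int:
        return self._records[cell_id].nu

    def records(self) -> List[GenealogyRecord]:
        return [self._records[i] for i in sorted(self._records)]

    def mrca(self, a: int, b: int) -> int:
        """Most recent common ancestor by depth-equalizing parent walks."""
        ra, rb = self._records[a], self._records[b]
        ia, ib = ra.id, rb.id
        da, db = ra.nu, rb.nu
        while da > db:
            ia = self._records[ia].parent_id
            da -= 1
        while db > da:
            ib = self._records[ib].parent_id
            db -= 1
        while ia != ib:
            ia = self._records[ia].parent_id
            ib = self._records[ib].parent_id
            if ia is None or ib is None:
                raise PopulationError("cells are not in the same tree")
        return ia


@dataclass
class PopulationState:
    """Full mutable simulation state: clock, occupancy, live cells, tree."""

    spec: LatticeSpec
    t: float = 0.0
    occupancy: Dict[Coord, int] = field(default_factory=dict)
    cells: Dict[int, Cell] = field(default_factory=dict)
    genealogy: Genealogy = field(default_factory=Genealogy)
    n_births: int = 0
    n_deaths: int = 0
    _next_id: int = 0

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def new_id(self) -> int:
        i = self._next_id
        self._next_id += 1
        return i

    def add_cell(self, cell: Cell) -> None:
        if cell.coord in self.occupancy:
            raise PopulationError(f"site {cell.coord} already occupied")
        self.occupancy[cell.coord] = cell.id
        self.cells[cell.id] = cell
        self.genealogy.add(cell.id, cell.parent_id, cell.t_birth)

    def check_injective(self) -> None:
        """Debug assertion: occupancy and cell coordinates agree one-to-one."""
        assert len(self.occupancy) == len(self.cells)
        for coord, cid in self.occupancy.items():
            assert self.cells[cid].coord == coord


def initialize(
    spec: LatticeSpec, omega_max: int, initial_type: CellType = "CSC"
) -> PopulationState:
    """One CSC at the origin at t = 0, with a full division budget."""
    state = PopulationState(spec=spec)
    root = Cell(
        id=state.new_id(),
        coord=spec.origin(),
        cell_type=initial_type,
        omega=omega_max,
        t_birth=0.0,
        t_last_division=0.0,
        parent_id=None,
    )
    state.add_cell(root)
    return state


def _daughter_types(
    parent: Cell, p_s: float, omega_max: int, rng: np.random.Generator
) -> Tuple[Tuple[CellType, int], Tuple[CellType, int]]:
    """(resident, displaced) type/omega pairs for the two daughters."""
    if parent.cell_type == "CSC":
        if p_s >= 1.0 or rng.random() < p_s:
            return ("CSC", omega_max), ("CSC", omega_max)
        # Asymmetric division: the stem daughter keeps the site.
        return ("CSC", omega_max), ("TAC", omega_max)
    if parent.cell_type == "TAC":
        w = parent.omega - 1
        t: CellType = "TDC" if w <= 0 else "TAC"
        return (t, max(w, 0)), (t, max(w, 0))
    raise PopulationError(f"cell {parent.id} is a TDC and cannot divide")


def execute_division(
    state: PopulationState,
    cell_id: int,
    push_method: int,
    e2_model: str,
    p_s: float,
    omega_max: int,
    mutation_model: MutationModel,
    rng: np.random.Generator,
) -> Tuple[List[int], Set[Coord]]:
    """Divide ``cell_id`` into two daughters; returns (daughter ids, changed coords).

    The resident daughter keeps the parent's site; the displaced daughter
    is placed by the configured push method, possibly shifting a chain of
    pre-existing cells outward.  Each daughter independently draws new
    driver mutations on top of the inherited effect lists.
    """
    parent = state.cells.get(cell_id)
    if parent is None:
        raise PopulationError(f"cell {cell_id} is not alive")
    if not parent.can_divide:
        raise PopulationError(f"cell {cell_id} is a TDC and cannot divide")
    t = state.t
    (res_type, res_omega), (disp_type, disp_omega) = _daughter_types(
        parent, p_s, omega_max, rng
    )

    # Retire the parent.
    del state.cells[cell_id]
    del state.occupancy[parent.coord]
    state.genealogy.close(cell_id, t)

    daughters: List[Cell] = []
    for dtype, domega in ((res_type, res_omega), (disp_type, disp_omega)):
        new_effects = draw_new_mutations(mutation_model, rng)
        cell = Cell(
            id=state.new_id(),
            coord=parent.coord,  # displaced daughter re-coordinated below
            cell_type=dtype,
            omega=domega,
            t_birth=t,
            t_last_division=t,
            parent_id=cell_id,
            beta_effects=parent.beta_effects
            + tuple(e.s for e in new_effects if e.mutation_class == "birth"),
            delta_effects=parent.delta_effects
            + tuple(e.s for e in new_effects if e.mutation_class == "death"),
            rho_effects=parent.rho_effects
            + tuple(e.s for e in new_effects if e.mutation_class == "migration"),
        )
        daughters.append(cell)
    resident, displaced = daughters

    state.occupancy[resident.coord] = resident.id
    state.cells[resident.id] = resident
    state.genealogy.add(resident.id, cell_id, t)

    target, moves = placement.place(
        state.occupancy, state.cells, state.spec, parent.coord, push_method,
        e2_model, rng, new_id=displaced.id,
    )
    displaced.coord = target
    state.cells[displaced.id] = displaced
    state.genealogy.add(displaced.id, cell_id, t)

    state.n_births += 1
    changed: Set[Coord] = {target}
    for _, old, new in moves:
        changed.add(old)
        changed.add(new)
    return [resident.id, displaced.id], changed


def execute_death(state: PopulationState, cell_id: int) -> Set[Coord]:
    """Remove a live cell; its node becomes empty."""
    cell = state.cells.pop(cell_id, None)
    if cell is None:
        raise PopulationError(f"cell {cell_id} is not alive")
    del state.occupancy[cell.coord]
    state.genealogy.close(cell_id, state.t)
    state.n_deaths += 1
    return {cell.coord}


def execute_migration(
    state: PopulationState,
    cell_id: int,
    rng: np.random.Generator,
    prefer_empty: bool = False,
) -> Set[Coord]:
    """Single-step move of a cell to an adjacent site (swap if occupied).

    The target neighbor is chosen uniformly among all adjacent sites; with
    ``prefer_empty`` the choice is restricted to empty neighbors when any
    exist.  Moving to an occupied site exchanges the two cells' positions.
    """
    cell = state.cells.get(cell_id)
    if cell is None:
        raise PopulationError(f"cell {cell_id} is not alive")
    nbrs = neighbors(cell.coord, state.spec)
    if prefer_empty:
        empty = [n for n in nbrs if n not in state.occupancy]
        if empty:
            nbrs = empty
    target = nbrs[rng.integers(len(nbrs))]
    origin = cell.coord
    other_id = state.occupancy.get(target)
    if other_id is None:
        del state.occupancy[origin]
        state.occupancy[target] = cell_id
        cell.coord = target
    else:
        other = state.cells[other_id]
        state.occupancy[origin] = other_id
        state.occupancy[target] = cell_id
        cell.coord, other.coord = target, origin
    return {origin, target}


def coupled_division_death_outcome(
    alpha: float, rng: np.random.Generator
) -> Literal["division", "death"]:
    """Fate of a coupled division/death event: death with probability alpha."""
    if not 0.0 <= alpha <= 1.0:
        raise PopulationError(f"alpha must be in [0, 1], got {alpha}")
    return "death" if rng.random() < alpha else "division"
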