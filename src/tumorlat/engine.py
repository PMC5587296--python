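"""Event-driven simulation loop.

Every live cell carries pending waiting times for division, death, and
migration; the globally smallest firing time is executed, the clock
advances by that increment, and only the affected cells draw new clocks
(unaffected cells keep theirs, which for absolute firing times is the
reuse-with-subtraction rule).  Division clocks are gamma with shape
``k_b`` and are conditioned on the cell's current cycle age when they
must be re-drawn; death and migration default to exponential clocks
(``k_d = k_m = 1``), which are memoryless and never need invalidation.

With the step or linear density model a cell's division rate depends on
its empty-neighbor proportion, so after any event that changes occupancy
the division clocks of cells whose composed rate actually changed are
re-drawn.  Under the constant-rate model only the cells directly
involved in an event reschedule.

Synchronous division (``k_b = inf``) produces exactly tied firing
times; tied events are executed within one instant in uniformly shuffled
order, each seeing the occupancy left by the previous one.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set, Tuple

import numpy as np

from .config import SimulationConfig
from .kinetics import (
    driver_effect_product,
    e2_coefficient,
    sample_residual_waiting_time,
    sample_waiting_time,
)
from .lattice import Coord, make_lattice, neighbors, phi
from .population import (
    Cell,
    Genealogy,
    PopulationState,
    coupled_division_death_outcome,
    execute_death,
    execute_division,
    execute_migration,
    initialize,
)

#: Residual returned for an overdue division clock (fires "immediately").
OVERDUE_EPSILON = 2.0 ** -30

_BIRTH, _DEATH, _MIGRATION, _ENV = "birth", "death", "migration", "env"


@dataclass
class RunResult:
    """Everything a finished run produced."""

    config: SimulationConfig
    state: PopulationState
    growth: List[Tuple[float, int]]
    termination: str  # "max_cells" | "max_time" | "extinction" | "halted"
    founders: Optional[List[int]]
    event_counts: Dict[str, int]

    @property
    def genealogy(self) -> Genealogy:
        return self.state.genealogy

    @property
    def final_time(self) -> float:
        return self.state.t

    @property
    def n_cells(self) -> int:
        return self.state.n_cells


class Engine:
    """One seeded simulation run driven by a single event queue."""

    def __init__(self, config: SimulationConfig):
        self.config = config
        self.spec = make_lattice(config.lattice, config.dimension, config.neighborhood)
        self.rng = np.random.default_rng(config.seed)
        self.state = initialize(self.spec, config.omega_max)
        self._mutation_model = config.mutation_model
        self._heap: List[Tuple[float, int, str, Optional[int], int]] = []
        self._seq = 0
        self._versions: Dict[Tuple[int, str], int] = {}
        self._birth_rate_cache: Dict[int, float] = {}
        self.env_multiplier = 1.0
        self._env_idx = 0
        self._env_schedule = sorted(config.env_schedule)
        self.growth: List[Tuple[float, int]] = [(0.0, 1)]
        self.founders: Optional[List[int]] = None
        self.event_counts = {k: 0 for k in (_BIRTH, _DEATH, _MIGRATION, _ENV)}
        self._density_dependent = config.e2_model in ("step", "linear")
        self._schedule_cell(next(iter(self.state.cells)))
        self._schedule_env()

    # ---------------------------------------------------------------- rates

    def _birth_rate(self, cell: Cell) -> float:
        if not cell.can_divide:
            return 0.0
        rate = (
            self.config.beta0
            * driver_effect_product(cell.beta_effects)
            * self.env_multiplier
        )
        if rate > 0.0 and self._density_dependent:
            rate *= e2_coefficient(
                self.config.e2_model, phi(cell.coord, self.state.occupancy, self.spec)
            )
        return rate

    def _death_rate(self, cell: Cell) -> float:
        if self.config.death_mode == "coupled":
            return 0.0  # death rides on the division clock
        return (
            self.config.delta0
            * driver_effect_product(cell.delta_effects)
            * self.env_multiplier
        )

    def _migration_rate(self, cell: Cell) -> float:
        return (
            self.config.rho0
            * driver_effect_product(cell.rho_effects)
            * self.env_multiplier
        )

    # ------------------------------------------------------------ scheduling

    def _push(self, time: float, kind: str, cell_id: Optional[int], version: int) -> None:
        heapq.heappush(self._heap, (time, self._seq, kind, cell_id, version))
        self._seq += 1

    def _schedule_birth(self, cell: Cell) -> None:
        rate = self._birth_rate(cell)
        self._birth_rate_cache[cell.id] = rate
        if rate <= 0.0:
            return
        tau = self.state.t - cell.t_last_division
        w = sample_residual_waiting_time(
            self.config.k_b, rate, tau, self.rng, overdue_epsilon=OVERDUE_EPSILON
        )
        version = self._versions.get((cell.id, _BIRTH), 0)
        self._push(self.state.t + w, _BIRTH, cell.id, version)

    def _schedule_death(self, cell: Cell) -> None:
        rate = self._death_rate(cell)
        if rate <= 0.0:
            return
        w = sample_waiting_time(self.config.k_d, rate, self.rng)
        version = self._versions.get((cell.id, _DEATH), 0)
        self._push(self.state.t + w, _DEATH, cell.id, version)

    def _schedule_migration(self, cell: Cell) -> None:
        rate = self._migration_rate(cell)
        if rate <= 0.0:
            return
        w = sample_waiting_time(self.config.k_m, rate, self.rng)
        version = self._versions.get((cell.id, _MIGRATION), 0)
        self._push(self.state.t + w, _MIGRATION, cell.id, version)

    def _schedule_cell(self, cell_id: int) -> None:
        cell = self.state.cells[cell_id]
        self._schedule_birth(cell)
        self._schedule_death(cell)
        self._schedule_migration(cell)

    def _schedule_env(self) -> None:
        if self._env_idx < len(self._env_schedule):
            t_env, _ = self._env_schedule[self._env_idx]
            self._push(t_env, _ENV, None, self._env_idx)

    def _drop_cell_bookkeeping(self, cell_id: int) -> None:
        self._birth_rate_cache.pop(cell_id, None)
        for kind in (_BIRTH, _DEATH, _MIGRATION):
            self._versions.pop((cell_id, kind), None)

    def _invalidate_births(self, changed: Set[Coord], exclude: Set[int]) -> None:
        """Re-draw division clocks of cells whose composed rate changed.

        ``changed`` holds every coordinate whose occupancy (or occupant)
        an event touched; cells sitting on or adjacent to those sites are
        the only ones whose empty-neighbor proportion can have moved.
        """
        if not self._density_dependent:
            return
        affected: Set[int] = set()
        occupancy = self.state.occupancy
        for coord in changed:
            cid = occupancy.get(coord)
            if cid is not None:
                affected.add(cid)
            for nbr in neighbors(coord, self.spec):
                cid = occupancy.get(nbr)
                if cid is not None:
                    affected.add(cid)
        for cid in affected - exclude:
            cell = self.state.cells[cid]
            new_rate = self._birth_rate(cell)
            if new_rate == self._birth_rate_cache.get(cid):
                continue  # clock reuse is exact while the rate is unchanged
            key = (cid, _BIRTH)
            self._versions[key] = self._versions.get(key, 0) + 1
            self._schedule_birth(cell)

    # -------------------------------------------------------------- stepping

    def _valid(self, entry: Tuple[float, int, str, Optional[int], int]) -> bool:
        _, _, kind, cell_id, version = entry
        if kind == _ENV:
            return version == self._env_idx
        return (
            cell_id in self.state.cells
            and self._versions.get((cell_id, kind), 0) == version
        )

    def _pop_batch(self) -> List[Tuple[float, int, str, Optional[int], int]]:
        """All currently valid events tied at the minimal firing time."""
        heap = self._heap
        while heap and not self._valid(heap[0]):
            heapq.heappop(heap)
        if not heap:
            return []
        first = heapq.heappop(heap)
        batch = [first]
        t0 = first[0]
        while heap and heap[0][0] == t0:
            entry = heapq.heappop(heap)
            if self._valid(entry):
                batch.append(entry)
        if len(batch) > 1:
            order = self.rng.permutation(len(batch))
            batch = [batch[i] for i in order]
        return batch

    def _execute(self, entry: Tuple[float, int, str, Optional[int], int]) -> None:
        t, _, kind, cell_id, _ = entry
        self.state.t = t
        rng = self.rng
        if kind == _ENV:
            self.env_multiplier = self._env_schedule[self._env_idx][1]
            self._env_idx += 1
            self.event_counts[_ENV] += 1
            # New environment: every clock is re-drawn from scratch.
            for cid in self.state.cells:
                for kd in (_BIRTH, _DEATH, _MIGRATION):
                    key = (cid, kd)
                    self._versions[key] = self._versions.get(key, 0) + 1
            for cid in self.state.cells:
                self._schedule_cell(cid)
            self._schedule_env()
            return
        if kind == _BIRTH:
            if self.config.death_mode == "coupled":
                fate = coupled_division_death_outcome(self.config.alpha, rng)
                if fate == "death":
                    self._do_death(cell_id)
                    return
            self._do_division(cell_id)
        elif kind == _DEATH:
            self._do_death(cell_id)
        elif kind == _MIGRATION:
            changed = execute_migration(
                self.state, cell_id, rng, self.config.migration_prefer_empty
            )
            self.event_counts[_MIGRATION] += 1
            self._schedule_migration(self.state.cells[cell_id])
            self._invalidate_births(changed, exclude=set())

    def _do_division(self, cell_id: int) -> None:
        daughters, changed = execute_division(
            self.state,
            cell_id,
            self.config.push_method,
            self.config.e2_model,
            self.config.p_s,
            self.config.omega_max,
            self._mutation_model,
            self.rng,
        )
        self.event_counts[_BIRTH] += 1
        self._drop_cell_bookkeeping(cell_id)
        self.growth.append((self.state.t, self.state.n_cells))
        for did in daughters:
            self._schedule_cell(did)
        if self.founders is None and self.state.n_cells >= self.config.n_founders:
            alive = sorted(self.state.cells)
            self.founders = alive[: self.config.n_founders]
        self._invalidate_births(changed, exclude=set(daughters))

    def _do_death(self, cell_id: int) -> None:
        changed = execute_death(self.state, cell_id)
        self.event_counts[_DEATH] += 1
        self._drop_cell_bookkeeping(cell_id)
        self.growth.append((self.state.t, self.state.n_cells))
        self._invalidate_births(changed, exclude=set())

    def step(self) -> int:
        """Execute one instant (all tied minimal events); returns event count."""
        batch = self._pop_batch()
        executed = 0
        for entry in batch:
            if not self._valid(entry):
                continue
            self._execute(entry)
            executed += 1
            if self.state.n_cells >= self.config.max_cells:
                break
        return executed

    def run(self) -> RunResult:
        """Loop until a stopping rule fires; fully reproducible from the seed."""
        cfg = self.config
        termination = "halted"
        while True:
            if self.state.n_cells >= cfg.max_cells:
                termination = "max_cells"
                break
            if self.state.n_cells == 0:
                termination = "extinction"
                break
            heap = self._heap
            while heap and not self._valid(heap[0]):
                heapq.heappop(heap)
            if not heap:
                termination = "halted"  # e.g. fully encased by TDCs
                break
            if heap[0][0] > cfg.max_time:
                self.state.t = cfg.max_time
                termination = "max_time"
                break
            self.step()
        return RunResult(
            config=cfg,
            state=self.state,
            growth=self.growth,
            termination=termination,
            founders=self.founders,
            event_counts=dict(self.event_counts),
        )


def run(config: SimulationConfig) -> RunResult:
    """Build an :class:`Engine` for ``config`` and run it to completion."""
    return Engine(config).run()
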