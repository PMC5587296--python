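import numpy as np
import pytest
from scipy import stats as sps

from tumorlat.kinetics import MutationModel
from tumorlat.lattice import make_lattice, neighbors
from tumorlat.population import (
    Cell,
    PopulationError,
    coupled_division_death_outcome,
    execute_death,
    execute_division,
    execute_migration,
    initialize,
)

NULL_MUT = MutationModel()


def _divide(state, cid, rng, p_s=1.0, omega_max=5, push=2, e2="constant"):
    return execute_division(state, cid, push, e2, p_s, omega_max, NULL_MUT, rng)


@pytest.fixture
def state3d(moore3d):
    return initialize(moore3d, omega_max=5)


def test_initialize_single_csc(state3d):
    assert state3d.n_cells == 1
    (cell,) = state3d.cells.values()
    assert cell.cell_type == "CSC"
    assert cell.coord == (0, 0, 0)
    assert cell.omega == 5
    assert state3d.t == 0.0


def test_initialize_fcc_origin_parity():
    spec = make_lattice("hexagonal", 3)
    state = initialize(spec, omega_max=5)
    (cell,) = state.cells.values()
    spec.validate_coord(cell.coord)


def test_symmetric_division_gives_two_csc(state3d, rng):
    daughters, _ = _divide(state3d, 0, rng, p_s=1.0)
    assert state3d.n_cells == 2
    assert all(state3d.cells[d].cell_type == "CSC" for d in daughters)


def test_asymmetric_division_resident_stays_stem(state3d, rng):
    daughters, _ = _divide(state3d, 0, rng, p_s=0.0)
    resident, displaced = daughters
    assert state3d.cells[resident].cell_type == "CSC"
    assert state3d.cells[resident].coord == (0, 0, 0)
    tac = state3d.cells[displaced]
    assert tac.cell_type == "TAC"
    assert tac.omega == 5


def test_tac_division_decrements_omega_until_tdc(state3d, rng):
    daughters, _ = _divide(state3d, 0, rng, p_s=0.0)
    tac = daughters[1]
    assert state3d.cells[tac].omega == 5
    d2, _ = _divide(state3d, tac, rng)
    assert all(state3d.cells[d].omega == 4 for d in d2)
    assert all(state3d.cells[d].cell_type == "TAC" for d in d2)
    # Exhaust the budget of one branch.
    cur = d2[0]
    while state3d.cells[cur].cell_type == "TAC":
        cur = _divide(state3d, cur, rng)[0][0]
    assert state3d.cells[cur].cell_type == "TDC"
    assert state3d.cells[cur].omega == 0


def test_tdc_division_is_contract_violation(state3d, rng):
    daughters, _ = _divide(state3d, 0, rng, p_s=0.0)
    cur = daughters[1]
    while state3d.cells[cur].cell_type == "TAC":
        cur = _divide(state3d, cur, rng)[0][0]
    with pytest.raises(PopulationError):
        _divide(state3d, cur, rng)


def test_division_conserves_occupancy(state3d, rng):
    for _ in range(40):
        cid = list(state3d.cells)[int(rng.integers(state3d.n_cells))]
        n_before = state3d.n_cells
        _divide(state3d, cid, rng)
        assert state3d.n_cells == n_before + 1
        state3d.check_injective()


def test_death_frees_the_site(state3d, rng):
    _divide(state3d, 0, rng)
    cid = next(iter(state3d.cells))
    coord = state3d.cells[cid].coord
    execute_death(state3d, cid)
    assert coord not in state3d.occupancy
    with pytest.raises(PopulationError):
        execute_death(state3d, cid)


def test_death_to_extinction(state3d):
    execute_death(state3d, 0)
    assert state3d.n_cells == 0


def test_birth_death_audit(state3d, rng):
    for _ in range(30):
        cid = list(state3d.cells)[int(rng.integers(state3d.n_cells))]
        _divide(state3d, cid, rng)
    for _ in range(10):
        cid = list(state3d.cells)[int(rng.integers(state3d.n_cells))]
        execute_death(state3d, cid)
    assert state3d.n_cells == 1 + state3d.n_births - state3d.n_deaths


def test_isolated_migration_uniform_over_neighbors(moore2d, rng):
    state = initialize(moore2d, omega_max=5)
    counts = {off: 0 for off in moore2d.offsets}
    for _ in range(8_000):
        cell = next(iter(state.cells.values()))
        old = cell.coord
        execute_migration(state, cell.id, rng)
        moved = tuple(a - b for a, b in zip(cell.coord, old))
        counts[moved] += 1
    freqs = np.array(list(counts.values()))
    assert freqs.sum() == 8_000
    _, p = sps.chisquare(freqs)
    assert p > 0.001


def test_enclosed_migration_swaps(state3d, rng):
    # Surround the focal cell completely, then migrate it.
    focal = state3d.cells[0]
    for i, coord in enumerate(neighbors(focal.coord, state3d.spec)):
        state3d.add_cell(
            Cell(
                id=state3d.new_id(), coord=coord, cell_type="CSC", omega=5,
                t_birth=0.0, t_last_division=0.0, parent_id=0,
            )
        )
    n_before = state3d.n_cells
    occupied_before = set(state3d.occupancy)
    execute_migration(state3d, 0, rng)
    assert state3d.n_cells == n_before
    assert set(state3d.occupancy) == occupied_before  # pure position swap
    assert state3d.cells[0].coord != (0, 0, 0)
    state3d.check_injective()


def test_migration_changes_at_most_one_site(state3d, rng):
    _divide(state3d, 0, rng)
    before = set(state3d.occupancy)
    cid = next(iter(state3d.cells))
    execute_migration(state3d, cid, rng)
    after = set(state3d.occupancy)
    assert len(before ^ after) <= 2
    assert state3d.n_cells == len(after)


def test_coupled_fate(rng):
    assert coupled_division_death_outcome(0.0, rng) == "division"
    assert coupled_division_death_outcome(1.0, rng) == "death"
    n = 50_000
    deaths = sum(
        coupled_division_death_outcome(0.2, rng) == "death" for _ in range(n)
    )
    se = np.sqrt(0.2 * 0.8 / n)
    assert abs(deaths / n - 0.2) < 3 * se


def test_genealogy_rooted_forest(state3d, rng):
    for _ in range(20):
        cid = list(state3d.cells)[int(rng.integers(state3d.n_cells))]
        _divide(state3d, cid, rng)
    g = state3d.genealogy
    for cid in state3d.cells:
        cur = cid
        while g.parent(cur) is not None:
            cur = g.parent(cur)
        assert cur == 0


def test_daughters_inherit_and_draw_mutations(state3d):
    rng = np.random.default_rng(0)
    model = MutationModel(mu_beta=1.0, s_mean_beta=0.2, s_sd_beta=0.0)
    daughters, _ = execute_division(
        state3d, 0, 2, "constant", 1.0, 5, model, rng
    )
    for d in daughters:
        assert state3d.cells[d].beta_effects == (0.2,)
    d2, _ = execute_division(
        state3d, daughters[0], 2, "constant", 1.0, 5, model, rng
    )
    for d in d2:
        assert state3d.cells[d].beta_effects == (0.2, 0.2)
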