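import numpy as np
import pytest

from tumorlat import SimulationConfig, run
from tumorlat.io import make_fixture
from tumorlat.population import Genealogy
from tumorlat import stats

from conftest import ancestor_path, brute_force_fst


def test_synchronous_tree_distances():
    g, leaves = make_fixture("synchronous_tree")
    a, b, c, d = leaves  # (a,b) siblings under one clade, (c,d) under the other
    assert stats.genealogical_distance(g, a, a) == 0.0
    assert stats.genealogical_distance(g, a, b, "divisions") == 2.0
    assert stats.genealogical_distance(g, a, c, "divisions") == 4.0
    # Time units at the snapshot t=2: newborn siblings are at distance 0.
    assert stats.genealogical_distance(g, a, b, "time", snapshot_time=2.0) == 0.0
    assert stats.genealogical_distance(g, a, c, "time", snapshot_time=2.0) == 2.0


def test_star_tree_fst_is_zero():
    g, leaves = make_fixture("star_tree")
    dists = {
        stats.genealogical_distance(g, a, b, "divisions")
        for a in leaves
        for b in leaves
        if a != b
    }
    assert dists == {2.0}
    assert stats.fst_pair(g, leaves[:3], leaves[3:], "divisions") == 0.0


def _two_clade_tree(depth=5):
    """Root with two clades; one sibling pair hangs at the given depth."""
    g = Genealogy()
    g.add(0, None, 0.0)
    g.close(0, 1.0)
    nid = 1
    tips = []
    for _ in range(2):
        parent = 0
        for level in range(depth - 1):
            g.add(nid, parent, float(level + 1))
            g.close(nid, float(level + 2))
            parent = nid
            nid += 1
        pair = []
        for _ in range(2):
            g.add(nid, parent, float(depth))
            pair.append(nid)
            nid += 1
        tips.append(pair)
    return g, tips


def test_fst_two_distant_sibling_pairs():
    g, (pa, pb) = _two_clade_tree(depth=5)
    assert stats.genealogical_distance(g, pa[0], pa[1], "divisions") == 2.0
    assert stats.genealogical_distance(g, pa[0], pb[0], "divisions") == 10.0
    assert stats.fst_pair(g, pa, pb, "divisions") == pytest.approx(0.8)


def test_fst_invariant_to_uniform_branch_scaling():
    g, (pa, pb) = _two_clade_tree(depth=4)
    base = stats.fst_pair(g, pa, pb, "time", snapshot_time=4.0)
    scaled = Genealogy()
    for rec in g.records():
        scaled.add(rec.id, rec.parent_id, rec.t_birth * 3.0)
        if rec.t_end is not None:
            scaled.close(rec.id, rec.t_end * 3.0)
    assert stats.fst_pair(scaled, pa, pb, "time", snapshot_time=12.0) == pytest.approx(base)


def test_fst_overlapping_regions_rejected():
    g, leaves = make_fixture("star_tree")
    with pytest.raises(stats.StatsError):
        stats.fst_pair(g, leaves[:3], leaves[2:], "divisions")


def test_divisions_per_cell_synchronous():
    res = run(SimulationConfig(seed=0, max_cells=256))
    nu = stats.divisions_per_cell(res.genealogy, res.state.cells)
    assert set(nu.values()) == {8}


def test_divisions_per_cell_varies_at_k1():
    res = run(SimulationConfig(seed=1, k_b=1.0, max_cells=256))
    nu = list(stats.divisions_per_cell(res.genealogy, res.state.cells).values())
    assert min(nu) < 8 < max(nu)


def test_nu_matches_independent_depth_traversal():
    res = run(SimulationConfig(seed=2, k_b=1.0, max_cells=256))
    g = res.genealogy
    checked = 0
    for cid in res.state.cells:
        assert g.nu(cid) == len(ancestor_path(g, cid)) - 1
        checked += 1
    assert checked >= 200


def test_lineage_fractions_synchronous_exact():
    res = run(SimulationConfig(seed=0, max_cells=512))
    fr = stats.lineage_fractions(res.genealogy, res.state.cells, n_founders=4)
    assert list(fr.values()) == [0.25, 0.25, 0.25, 0.25]
    assert sum(fr.values()) == 1.0


def test_lineage_fraction_single_founder_is_one():
    res = run(SimulationConfig(seed=0, max_cells=64))
    fr = stats.lineage_fractions(res.genealogy, res.state.cells, n_founders=1)
    assert list(fr.values()) == [1.0]


def test_lineage_fractions_deviate_at_k1():
    spreads = []
    for seed in range(5):
        res = run(SimulationConfig(seed=seed, k_b=1.0, max_cells=512))
        fr = stats.lineage_fractions(res.genealogy, res.state.cells, n_founders=4)
        assert sum(fr.values()) == pytest.approx(1.0)
        spreads.append(max(fr.values()) - min(fr.values()))
    assert max(spreads) > 0.0


def test_founders_from_genealogy_matches_engine():
    res = run(SimulationConfig(seed=0, max_cells=128, n_founders=4))
    assert stats.founders_from_genealogy(res.genealogy, 4) == res.founders


def test_subregion_sizes_and_nearest_property(rng):
    res = run(SimulationConfig(seed=3, k_b=1.0, max_cells=200))
    state = res.state
    whole = stats.sample_subregion(state, state.n_cells, rng)
    assert set(whole.member_ids) == set(state.cells)
    single = stats.sample_subregion(state, 1, rng)
    assert single.member_ids == (single.central_id,)

    from tumorlat.lattice import to_cartesian
    import math

    sub = stats.sample_subregion(state, 20, rng)
    focal = np.array(to_cartesian(state.cells[sub.central_id].coord, state.spec))
    dist = lambda cid: math.dist(
        focal, to_cartesian(state.cells[cid].coord, state.spec)
    )
    max_inside = max(dist(c) for c in sub.member_ids)
    excluded = set(state.cells) - set(sub.member_ids)
    min_outside = min(dist(c) for c in excluded)
    assert max_inside <= min_outside + 1e-12


def test_fst_module_matches_brute_force(rng):
    res = run(SimulationConfig(seed=4, k_b=1.0, max_cells=128))
    g = res.genealogy
    ids = sorted(res.state.cells)
    for _ in range(30):
        picked = rng.choice(len(ids), size=10, replace=False)
        a = [ids[i] for i in picked[:5]]
        b = [ids[i] for i in picked[5:]]
        assert stats.fst_pair(g, a, b, "divisions") == pytest.approx(
            brute_force_fst(g, a, b)
        )


def test_fst_profile_records_are_disjoint_and_positive_distance(rng):
    res = run(SimulationConfig(seed=5, k_b=1.0, max_cells=256))
    records, corr = stats.fst_distance_profile(
        res.state, res.genealogy, n_pairs=10, size=10, rng=rng
    )
    assert len(records) == 10
    assert all(r.distance > 0 for r in records)
    assert all(0.0 <= r.fst <= 1.0 for r in records)
    assert np.isfinite(corr)


def test_growth_curve_table():
    res = run(SimulationConfig(seed=0, max_cells=16))
    df = stats.growth_curve(res.growth)
    assert list(df.columns) == ["t", "n"]
    assert df.iloc[0].tolist() == [0.0, 1.0]
    assert stats.time_to_size(res.growth, 8) == 3.0
    single = stats.growth_curve([(0.0, 1)])
    assert len(single) == 1
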