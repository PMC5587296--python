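import numpy as np
import pytest

from tumorlat.lattice import make_lattice


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def moore3d():
    return make_lattice("regular", 3, "moore")


@pytest.fixture
def moore2d():
    return make_lattice("regular", 2, "moore")


def brute_force_l_min(c, offset, occupancy, limit=10_000):
    """Independent ray walk: count occupied sites before the first empty one."""
    count = 0
    pos = tuple(a + b for a, b in zip(c, offset))
    while pos in occupancy:
        count += 1
        assert count < limit
        pos = tuple(a + b for a, b in zip(pos, offset))
    return count


def ancestor_path(genealogy, cid):
    """List of node ids from cid up to the root, inclusive (independent walk)."""
    path = [cid]
    while True:
        parent = genealogy.parent(path[-1])
        if parent is None:
            return path
        path.append(parent)


def brute_force_division_distance(genealogy, a, b):
    """Pairwise division distance as the symmetric difference of ancestries."""
    pa, pb = set(ancestor_path(genealogy, a)), set(ancestor_path(genealogy, b))
    return len(pa ^ pb)


def brute_force_fst(genealogy, region_a, region_b):
    """Hudson-style F_ST by explicit double loops (division units)."""
    def mean_within(ids):
        vals = [
            brute_force_division_distance(genealogy, ids[i], ids[j])
            for i in range(len(ids))
            for j in range(i + 1, len(ids))
        ]
        return sum(vals) / len(vals)

    between = [
        brute_force_division_distance(genealogy, a, b)
        for a in region_a
        for b in region_b
    ]
    pi_w = 0.5 * (mean_within(list(region_a)) + mean_within(list(region_b)))
    pi_b = sum(between) / len(between)
    if pi_b <= 0:
        return 0.0
    return min(max(1.0 - pi_w / pi_b, 0.0), 1.0)
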