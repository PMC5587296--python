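"""Analysis layer: growth curves, division counts, founder lineages, and
branch-length F_ST against physical distance.

``nu`` is a cell's depth in the division tree — the number of division
events between the initial cell and the cell itself.  Founder-lineage
fractions partition the final tumor among the first ``n`` cells that
were alive simultaneously.  Differentiation between two spatial
subregions is measured as ``F_ST = 1 - pi_w / pi_b`` (the Hudson/Slatkin
form), where ``pi_w`` is the average of the two within-region mean
pairwise genealogical distances and ``pi_b`` the between-region mean;
with branch lengths this is the infinite-marker expectation of sequence
differentiation, so no genetic markers need to be simulated.  Distances
can be counted in division events (default) or in time units, where live
cells' terminal branches extend to the sampling time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Literal, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .lattice import to_cartesian
from .population import Genealogy, PopulationState

DistanceUnits = Literal["divisions", "time"]


class StatsError(ValueError):
    pass


# ------------------------------------------------------------------ nu

def divisions_per_cell(genealogy: Genealogy, live_ids: Iterable[int]) -> Dict[int, int]:
    """Number of ancestral division events for each requested cell."""
    return {cid: genealogy.nu(cid) for cid in live_ids}


# ------------------------------------------------------------ founders

def founders_from_genealogy(genealogy: Genealogy, n_founders: int) -> List[int]:
    """The first ``n_founders`` cells alive simultaneously.

    Replays the genealogy's birth/end times in order; within one instant
    all simultaneous events are applied before the population size is
    read (synchronous cohorts change size in jumps).  If the size jumps
    past ``n_founders`` within an instant, the ``n_founders``
    earliest-created cells among those alive are taken.
    """
    events: List[Tuple[float, int, int]] = []  # (time, +1/-1, id)
    for rec in genealogy.records():
        events.append((rec.t_birth, 1, rec.id))
        if rec.t_end is not None:
            events.append((rec.t_end, -1, rec.id))
    # Closing the parent must precede adding its daughters at a shared time.
    events.sort(key=lambda e: (e[0], e[1], e[2]))
    alive: set = set()
    i = 0
    while i < len(events):
        t = events[i][0]
        while i < len(events) and events[i][0] == t:
            _, delta, cid = events[i]
            if delta > 0:
                alive.add(cid)
            else:
                alive.discard(cid)
            i += 1
        if len(alive) >= n_founders:
            return sorted(alive)[:n_founders]
    raise StatsError(
        f"population never reached {n_founders} simultaneous cells"
    )


def lineage_fractions(
    genealogy: Genealogy,
    live_ids: Iterable[int],
    n_founders: int | None = None,
    founders: Sequence[int] | None = None,
) -> Dict[int, float]:
    """Fraction of live cells descending from each founder (sums to 1)."""
    if founders is None:
        if n_founders is None:
            raise StatsError("give either n_founders or an explicit founder list")
        founders = founders_from_genealogy(genealogy, n_founders)
    founder_set = set(founders)
    counts: Dict[int, int] = {f: 0 for f in founders}
    assignment: Dict[int, int] = {f: f for f in founders}

    def founder_of(cid: int) -> int:
        path = []
        cur = cid
        while cur not in assignment:
            path.append(cur)
            parent = genealogy.parent(cur)
            if parent is None:
                raise StatsError(f"cell {cid} does not descend from any founder")
            cur = parent
        f = assignment[cur]
        for node in path:
            assignment[node] = f
        return f

    live = list(live_ids)
    if not live:
        raise StatsError("no live cells")
    for cid in live:
        counts[founder_of(cid)] += 1
    n = len(live)
    return {f: counts[f] / n for f in founders}


# ---------------------------------------------------------- subregions

@dataclass(frozen=True)
class Subregion:
    """A spatially compact sample: a focal cell plus its nearest neighbors."""

    member_ids: Tuple[int, ...]
    central_id: int
    centroid: Tuple[float, ...]


def sample_subregion(
    state: PopulationState,
    size: int,
    rng: np.random.Generator,
    exclude: Iterable[int] = (),
) -> Subregion:
    """Uniform-random focal cell plus its ``size - 1`` nearest live cells.

    Nearness is Euclidean in the Cartesian embedding; ties are broken by
    a random permutation.  Cells in ``exclude`` are not eligible, which
    lets two disjoint subregions be drawn from one tumor.
    """
    excluded = set(exclude)
    ids = [cid for cid in state.cells if cid not in excluded]
    if len(ids) < size:
        raise StatsError(f"need {size} eligible cells, have {len(ids)}")
    coords = np.array(
        [to_cartesian(state.cells[cid].coord, state.spec) for cid in ids]
    )
    focal_idx = int(rng.integers(len(ids)))
    d2 = np.sum((coords - coords[focal_idx]) ** 2, axis=1)
    tiebreak = rng.permutation(len(ids))
    order = np.lexsort((tiebreak, d2))
    members = tuple(ids[i] for i in order[:size])
    centroid = tuple(coords[order[:size]].mean(axis=0))
    return Subregion(
        member_ids=members, central_id=ids[focal_idx], centroid=centroid
    )


# ----------------------------------------------------------- distances

def genealogical_distance(
    genealogy: Genealogy,
    id_a: int,
    id_b: int,
    units: DistanceUnits = "divisions",
    snapshot_time: Optional[float] = None,
) -> float:
    """Branch-length path between two cells through their MRCA.

    In ``divisions`` units the distance is ``nu_a + nu_b - 2*nu_mrca``.
    In ``time`` units each node contributes its lifespan; cells still
    alive extend to ``snapshot_time`` (default: the latest event time in
    the genealogy), reflecting that live cells are sampled together.
    """
    if id_a == id_b:
        return 0.0
    m = genealogy.mrca(id_a, id_b)
    if units == "divisions":
        return float(genealogy.nu(id_a) + genealogy.nu(id_b) - 2 * genealogy.nu(m))
    if units != "time":
        raise StatsError(f"unknown units {units!r}")
    if snapshot_time is None:
        snapshot_time = max(
            rec.t_end if rec.t_end is not None else rec.t_birth
            for rec in genealogy.records()
        )
    total = 0.0
    for cid in (id_a, id_b):
        cur = cid
        while cur != m:
            rec = genealogy.record(cur)
            end = rec.t_end if rec.t_end is not None else snapshot_time
            total += end - rec.t_birth
            cur = rec.parent_id
    return total


def _mean_pairwise(
    genealogy: Genealogy,
    ids_a: Sequence[int],
    ids_b: Sequence[int] | None,
    units: DistanceUnits,
    snapshot_time: Optional[float],
) -> float:
    """Mean distance over within- (ids_b None) or between-group pairs."""
    total = 0.0
    n = 0
    if ids_b is None:
        for i in range(len(ids_a)):
            for j in range(i + 1, len(ids_a)):
                total += genealogical_distance(
                    genealogy, ids_a[i], ids_a[j], units, snapshot_time
                )
                n += 1
    else:
        for a in ids_a:
            for b in ids_b:
                total += genealogical_distance(genealogy, a, b, units, snapshot_time)
                n += 1
    return total / n if n else 0.0


def fst_pair(
    genealogy: Genealogy,
    region_a: Sequence[int],
    region_b: Sequence[int],
    units: DistanceUnits = "divisions",
    snapshot_time: Optional[float] = None,
) -> float:
    """``1 - pi_within / pi_between`` for two disjoint cell sets, in [0, 1]."""
    if set(region_a) & set(region_b):
        raise StatsError("subregions overlap")
    if len(region_a) < 2 or len(region_b) < 2:
        raise StatsError("each subregion needs at least 2 cells")
    pi_w = 0.5 * (
        _mean_pairwise(genealogy, region_a, None, units, snapshot_time)
        + _mean_pairwise(genealogy, region_b, None, units, snapshot_time)
    )
    pi_b = _mean_pairwise(genealogy, region_a, region_b, units, snapshot_time)
    if pi_b <= 0.0:
        return 0.0
    return min(max(1.0 - pi_w / pi_b, 0.0), 1.0)


# -------------------------------------------------- F_ST versus distance

@dataclass(frozen=True)
class FstRecord:
    pair_index: int
    fst: float
    distance: float
    central_a: int
    central_b: int


def fst_distance_profile(
    state: PopulationState,
    genealogy: Genealogy,
    n_pairs: int,
    size: int = 20,
    units: DistanceUnits = "divisions",
    rng: np.random.Generator | None = None,
) -> Tuple[List[FstRecord], float]:
    """Sample disjoint subregion pairs; returns records and the Pearson
    correlation between F_ST and the Euclidean distance of the central
    cells (isolation by distance)."""
    if rng is None:
        rng = np.random.default_rng()
    if state.n_cells < 2 * size:
        raise StatsError(
            f"need at least {2 * size} live cells, have {state.n_cells}"
        )
    snapshot = state.t
    records: List[FstRecord] = []
    for idx in range(n_pairs):
        a = sample_subregion(state, size, rng)
        b = sample_subregion(state, size, rng, exclude=a.member_ids)
        ca = to_cartesian(state.cells[a.central_id].coord, state.spec)
        cb = to_cartesian(state.cells[b.central_id].coord, state.spec)
        dist = math.dist(ca, cb)
        f = fst_pair(genealogy, a.member_ids, b.member_ids, units, snapshot)
        records.append(FstRecord(idx, f, dist, a.central_id, b.central_id))
    fsts = np.array([r.fst for r in records])
    dists = np.array([r.distance for r in records])
    if len(records) < 2 or fsts.std() == 0.0 or dists.std() == 0.0:
        corr = float("nan")
    else:
        corr = float(np.corrcoef(dists, fsts)[0, 1])
    return records, corr


# -------------------------------------------------------- growth curve

def growth_curve(event_log: Sequence[Tuple[float, int]]) -> pd.DataFrame:
    """Table of (t, n) with one row per population-size change."""
    return pd.DataFrame(event_log, columns=["t", "n"])


def time_to_size(event_log: Sequence[Tuple[float, int]], size: int) -> float:
    """First clock time at which the population reached ``size``."""
    for t, n in event_log:
        if n >= size:
            return t
    raise StatsError(f"population never reached {size} cells")
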