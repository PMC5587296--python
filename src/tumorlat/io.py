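"""Output writers, Newick export, and small deterministic test fixtures.

All tabular output is TSV (header row, UTF-8, '.' decimal separator),
row-ordered by cell id, so a rerun with the same seed is byte-identical.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Dict, List, Tuple

import pandas as pd
import yaml

from . import __version__
from .engine import RunResult
from .kinetics import driver_effect_product, e2_coefficient
from .lattice import Coord, make_lattice, phi, to_cartesian
from .population import Genealogy


class FixtureError(ValueError):
    pass


def _final_env_multiplier(result: RunResult) -> float:
    mult = 1.0
    for t_env, m in sorted(result.config.env_schedule):
        if t_env <= result.state.t:
            mult = m
    return mult


def population_table(result: RunResult) -> pd.DataFrame:
    """Snapshot of live cells with composed current rates."""
    cfg = result.config
    state = result.state
    spec = state.spec
    env = _final_env_multiplier(result)
    rows = []
    for cid in sorted(state.cells):
        cell = state.cells[cid]
        local_phi = phi(cell.coord, state.occupancy, spec)
        c1 = 0.0 if cell.cell_type == "TDC" else 1.0
        beta = (
            cfg.beta0
            * c1
            * driver_effect_product(cell.beta_effects)
            * env
            * e2_coefficient(cfg.e2_model, local_phi)
        )
        delta = cfg.delta0 * driver_effect_product(cell.delta_effects) * env
        rho = cfg.rho0 * driver_effect_product(cell.rho_effects) * env
        cart = to_cartesian(cell.coord, spec)
        row = {"id": cid, "parent_id": cell.parent_id}
        for name, value in zip("xyz", cell.coord):
            row[name] = value
        for name, value in zip(("cx", "cy", "cz"), cart):
            row[name] = value
        row.update(
            type=cell.cell_type,
            omega=cell.omega,
            t_birth=cell.t_birth,
            t_last_division=cell.t_last_division,
            nu=state.genealogy.nu(cid),
            beta=beta,
            delta=delta,
            rho=rho,
            n_drivers_beta=len(cell.beta_effects),
            n_drivers_delta=len(cell.delta_effects),
            n_drivers_rho=len(cell.rho_effects),
        )
        rows.append(row)
    return pd.DataFrame(rows)


def genealogy_table(genealogy: Genealogy) -> pd.DataFrame:
    rows = [
        {
            "id": rec.id,
            "parent_id": rec.parent_id,
            "t_birth": rec.t_birth,
            "t_death": rec.t_end,
            "nu": rec.nu,
        }
        for rec in genealogy.records()
    ]
    return pd.DataFrame(rows)


def genealogy_newick(
    genealogy: Genealogy, live_ids, snapshot_time: float
) -> str:
    """Newick string for the genealogy of the given live cells.

    Branch lengths are node lifespans in simulation time; live leaves
    extend to ``snapshot_time``.  Unary internal nodes (ancestors with a
    single surviving descendant line) are collapsed into the child
    branch.
    """
    live = set(live_ids)
    needed = set()
    for cid in live:
        cur = cid
        while cur is not None and cur not in needed:
            needed.add(cur)
            cur = genealogy.parent(cur)
    children: Dict[int, List[int]] = {}
    root = None
    for cid in sorted(needed):
        parent = genealogy.parent(cid)
        if parent is None:
            root = cid
        else:
            children.setdefault(parent, []).append(cid)

    def length(cid: int) -> float:
        rec = genealogy.record(cid)
        end = rec.t_end if rec.t_end is not None else snapshot_time
        return end - rec.t_birth

    def render(cid: int, extra: float) -> str:
        kids = children.get(cid, [])
        if not kids:
            return f"{cid}:{length(cid) + extra:g}"
        if len(kids) == 1:  # collapse unary node into the child branch
            return render(kids[0], extra + length(cid))
        inner = ",".join(render(k, 0.0) for k in kids)
        return f"({inner}):{length(cid) + extra:g}"

    if root is None:
        raise FixtureError("genealogy has no root")
    kids = children.get(root, [])
    if not kids:
        return f"{root};"
    if len(kids) == 1:
        return render(kids[0], 0.0) + ";"
    return "(" + ",".join(render(k, 0.0) for k in kids) + ");"


def write_outputs(
    result: RunResult, out_dir, newick: bool = False
) -> Dict[str, Path]:
    """Write population.tsv, genealogy.tsv, growth.tsv, metadata.yaml
    (and optionally genealogy.nwk); returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    pop = population_table(result)
    paths["population"] = out / "population.tsv"
    pop.to_csv(paths["population"], sep="\t", index=False)

    gen = genealogy_table(result.genealogy)
    paths["genealogy"] = out / "genealogy.tsv"
    gen.to_csv(paths["genealogy"], sep="\t", index=False)

    growth = pd.DataFrame(result.growth, columns=["t", "n"])
    paths["growth"] = out / "growth.tsv"
    growth.to_csv(paths["growth"], sep="\t", index=False)

    meta = {
        "config": result.config.to_dict(),
        "version": __version__,
        "termination": result.termination,
        "final_time": float(result.state.t),
        "n_cells": result.state.n_cells,
        "event_counts": result.event_counts,
        "founders": result.founders,
    }
    paths["metadata"] = out / "metadata.yaml"
    with open(paths["metadata"], "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)

    if newick:
        nwk = genealogy_newick(
            result.genealogy, result.state.cells.keys(), result.state.t
        )
        paths["newick"] = out / "genealogy.nwk"
        paths["newick"].write_text(nwk + "\n")
    return paths


# ------------------------------------------------------------- fixtures

def make_fixture(name: str):
    """Small deterministic structures for the placement and stats tests.

    ``corridor``   -- (occupancy, spec, origin): a 7x7 occupied block with
                      one empty site at (3, 0), so the unique shortest
                      escape from the center runs along +x.
    ``ring``       -- (occupancy, spec, center): a 2D hex cell whose six
                      neighbors are all occupied (the encapsulation
                      barrier: phi = 0 at the center).
    ``synchronous_tree`` -- (genealogy, leaf_ids): two synchronous
                      division rounds; four leaves, all with nu = 2.
    ``star_tree``  -- (genealogy, leaf_ids): six leaves hanging directly
                      off the root, all pairs equidistant.
    """
    if name == "corridor":
        spec = make_lattice("regular", 2, "moore")
        occupancy: Dict[Coord, int] = {}
        cid = 0
        for x in range(-3, 4):
            for y in range(-3, 4):
                if (x, y) == (3, 0):
                    continue
                occupancy[(x, y)] = cid
                cid += 1
        return occupancy, spec, (0, 0)
    if name == "ring":
        spec = make_lattice("hexagonal", 2)
        occupancy = {(0, 0): 0}
        for i, off in enumerate(spec.offsets, start=1):
            occupancy[off] = i
        return occupancy, spec, (0, 0)
    if name == "synchronous_tree":
        g = Genealogy()
        g.add(0, None, 0.0)
        g.close(0, 1.0)
        for cid in (1, 2):
            g.add(cid, 0, 1.0)
            g.close(cid, 2.0)
        g.add(3, 1, 2.0)
        g.add(4, 1, 2.0)
        g.add(5, 2, 2.0)
        g.add(6, 2, 2.0)
        return g, [3, 4, 5, 6]
    if name == "star_tree":
        g = Genealogy()
        g.add(0, None, 0.0)
        g.close(0, 1.0)
        leaves = list(range(1, 7))
        for cid in leaves:
            g.add(cid, 0, 1.0)
        return g, leaves
    raise FixtureError(f"unknown fixture {name!r}")
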