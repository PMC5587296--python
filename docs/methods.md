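# Methods

This note documents the model as implemented, the defaults and why they
were chosen, the numerical decisions, and the known limitations.

## Model and assumptions

`tumorlat` is a single-node-per-cell ("cellular automaton") simulator:
one cell per lattice node, no normal cells, no extracellular matrix, and
an environment that affects the tumor but is not changed by it. The
lattice is unbounded (sparse occupancy, integer coordinates, no boundary
conditions), since growth starts from a single cell and never meets a
wall.

Four lattice types are available. Hex-2D uses axial integer coordinates
with offsets (±1,0), (0,±1), (1,−1), (−1,1) and the Cartesian embedding
x' = x + y/2, y' = y·√3/2. The 3D hexagonal lattice is the
face-centered cubic (FCC) lattice, represented as integer triples with
even coordinate sum; its 12 offsets are the signed permutations of
(1,1,0) and the embedding divides by √2 so all nearest neighbors sit at
distance 1. The Moore neighborhood on a regular lattice has 3^d − 1
sites (8 in 2D, 26 in 3D) and the von Neumann neighborhood 2d. All
offset tables are enumerated in a fixed lexicographic order so that
seeded runs are exactly reproducible.

## Event scheduling

The engine keeps a binary heap of absolute firing times with lazy
deletion: stale entries carry a version stamp and are skipped at pop
time. Keeping an absolute firing time while the clock advances is
exactly the "subtract the elapsed time and reuse" rule and is the
correct conditional distribution as long as the cell's rate has not
changed. When a cell's composed division rate *does* change (its
empty-neighbor proportion moved under the step/linear models, a global
environment change, a driver mutation), the division clock is re-drawn
from the gamma tail conditioned on the cell's current cycle age
`tau = t − t_last_division`. This re-draw is a modeling choice, not a
mathematical identity: an alternative would be to rescale the remaining
time. Death and migration default to exponential clocks (`k_d = k_m =
1`), which are memoryless, so their pending times are never invalidated
by neighborhood changes; after a global environment change every clock
is re-drawn (for non-exponential death/migration shapes this restarts
their cycle, which is an approximation we accept since those shapes are
rarely used).

Tied firing times occur only in the synchronous limit `k_b = inf`, where
a whole cohort divides in the same instant. All valid events tied at the
minimal time are executed within one instant in uniformly shuffled
order, each seeing the occupancy left by its predecessors — placement on
a lattice is inherently sequential even when the clock is synchronous.
With `beta0 = 1` the firing times are exact integer floats, so cohort
ties are exact.

An overdue division clock — `k_b = inf` with cycle age ≥ 1/rate after a
rate increase, or a finite-shape tail whose mass has numerically
vanished (below 1e−12) — fires after an epsilon of 2^−30 time units
rather than raising, so a rate jump makes the backlog clear essentially
immediately. The library function raises by default; only the engine
opts into the epsilon.

## Cell types and events

The initial cell is a CSC with `omega = omega_max`. A CSC division is
symmetric (two CSCs) with probability `p_s`; otherwise the daughter that
keeps the parent's site stays a CSC and the displaced daughter is a TAC
— the paper-style asymmetric division does not say which daughter is
which, and keeping the stem cell at its niche is the common convention.
A TAC division gives both daughters `omega − 1` (the budget is a
property of lineage depth, not split between daughters); at zero they
are TDCs. TDCs never divide (`beta_C1 = 0`) but still die and migrate.
Driver mutations are drawn independently per daughter per division,
keeping the daughters exchangeable; each mutation multiplies one rate
class by `1 + s` with `s` Gaussian, clamped below so that `s ≤ −1` gives
rate 0 rather than a negative rate.

Migration picks a uniformly random neighbor (all neighbors, not just
empty ones — configurable with `migration_prefer_empty`); an occupied
target results in a position swap. Death simply empties the node. A
coupled division/death mode replaces the independent death clock with a
Bernoulli fate at each division-clock firing (death with probability
`alpha`).

Every division retires the parent's genealogy node and creates two
daughter nodes, making the genealogy a strict binary tree. This is
behaviorally identical to the "one daughter persists" narration — both
daughters re-draw clocks and mutations either way — and it makes depth
(`nu`), MRCA lookups, and branch lengths unambiguous.

## Statistics

* `nu` is genealogy depth: the number of division events between the
  root and the cell.
* Founders are the first `n` cells alive simultaneously (the live set at
  the first instant the population size reaches `n`); each live cell is
  assigned to the unique founder on its ancestor path. If a synchronous
  cohort jumps the size past `n` within one instant, the `n`
  earliest-created cells among those alive are taken.
* Subregions operationalize "a random 20-cell subregion" as a uniformly
  random focal cell plus its 19 nearest live cells in the Cartesian
  embedding (ties shuffled). This produces spatially compact regions
  resembling multiregional biopsies; scattered sampling would be an
  alternative reading.
* `F_ST = 1 − pi_w/pi_b` (Hudson/Slatkin form), where `pi_w` is the
  average of the two within-region mean pairwise genealogical distances
  and `pi_b` the between-region mean, clamped to [0, 1] and defined as 0
  when `pi_b = 0`. Branch lengths are counted in division events by
  default (genealogies are naturally drawn in division generations) or
  in time units, where live cells' terminal branches extend to the
  sampling time; the estimator is invariant to uniform branch scaling.
  No estimator is canonical for branch-length differentiation; this one
  is the infinite-marker expectation of the classic ratio form.

## Defaults and reference settings

| parameter | default | meaning |
| --- | --- | --- |
| lattice / dimension / neighborhood | regular / 3 / moore | comparable with earlier regular-lattice simulators |
| `k_b` | inf | synchronous division (deterministic cycle) |
| `k_d`, `k_m` | 1 | exponential death/migration clocks |
| `beta0` | 1 | time unit = one cell cycle |
| `delta0`, `rho0` | 0 | division dominates death/migration in a growing tumor |
| `e2_model` | constant | density-independent division |
| `push_method` | 2 | fill-then-weighted-push placement |
| `p_s` | 1 | all-CSC population (the classic special case) |
| `omega_max` | 5 | TAC budget in the differentiation scenarios |
| `mu_*`, `s_*` | 0 | neutral evolution |
| `max_cells` | 16384 | 2^14-cell stopping rule |

Under these defaults the growth curve is the stepwise closed form
`N_t = 2^t`, every cell ends with `nu = 14`, and the first four cells
found exact quarters — the analytic fixture the test suite checks
end-to-end. With `k_b = 1` the expected size is `N_t = e^t`.

## What the simulations show and do not show

The simulator *is* the study object here: there is no external data, so
"synthetic data" means the simulated tumors themselves, generated at the
reference settings above. Directional claims (density models slow
growth; migration relieves crowding under step/linear but not constant;
small `p_s` with no death/migration can seal a tumor inside a TDC
shell; isolation by distance is stronger under linear+fill than under
constant+push1) are tested on 2048–4096-cell tumors over 10–100 seeds;
the isolation-by-distance contrast is tested as the F_ST-vs-distance
regression slope, which separates the two settings robustly at these
sizes, whereas the scale-free Pearson correlation does not. These
problem sizes are the package's test conditions; the qualitative
orderings are size-stable but the quantitative values (time to size,
mean F_ST) of course are not.

Real tumors violate several framework assumptions — cells are not
lattice-bound, stroma and immune interactions are ignored, the
environment is spatially uniform (`E1` is global), and passenger
mutations are not simulated (F_ST is the infinite-marker expectation,
not an estimate from finite markers). Passing tests validate the
simulator's internal consistency and its agreement with the analytic
limits, not biological realism.

## Known limitations

* The positional environment function is reduced to a global
  time-varying multiplier; spatial E1 gradients (distance to vessels)
  are out of scope.
* Only the FCC variant of the 3D hexagonal lattice is implemented (not
  hexagonal close-packed).
* Death/migration clocks with non-exponential shapes are drawn once at
  cell creation and restarted on environment changes; no cycle-age
  conditioning is applied to them.
* Shape parameters in (0, 1) are accepted but not specially handled;
  `k = 1` is the exponential case.
* The event loop is single-threaded Python; ~10^4–10^5 cells are
  practical, gland/compartment-level aggregation is not implemented.
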