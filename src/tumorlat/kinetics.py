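"""Waiting-time distributions and rate composition.

The time to a cell's next division is gamma distributed with shape ``k``
and mean ``1/rate``: ``k = 1`` is the exponential (memoryless) case used
by most earlier lattice simulators, large ``k`` concentrates the waiting
time around the mean to mimic a cell cycle, and ``k = inf`` is the
deterministic limit in which every division takes exactly ``1/rate``.
For a cell whose last division was ``tau`` ago, the next division time is
drawn from the gamma tail conditioned on exceeding ``tau``.

A cell's potential birth rate is the product ``beta0 * C1 * C2 * E1 * E2``:

* C1 — cell type: 1 for a cancer stem cell (CSC) or transient amplifying
  cell (TAC) with remaining budget, 0 for a terminally differentiated
  cell (TDC);
* C2 — driver-mutation load: the product of ``(1 + s)`` over accumulated
  mutations, clamped at 0 so a strongly deleterious draw cannot make the
  rate negative;
* E1 — a global environment multiplier (treatment, nutrients), identical
  for all cells;
* E2 — local density response: constant (1), step (1 iff any neighbor
  site is empty), or linear (the empty-neighbor proportion ``phi``).

Death and migration rates compose the same way with their own base rates;
their C1 and E2 factors are fixed at 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Literal, Sequence

import numpy as np
from scipy import special

INFINITY = math.inf

MutationClass = Literal["birth", "death", "migration"]
E2Model = Literal["constant", "step", "linear"]

#: Truncated-tail mass below which a residual draw is considered overdue.
_TAIL_EPS = 1e-12


class KineticsError(ValueError):
    pass


def _check_shape(k: float) -> float:
    k = float(k)
    if not k > 0:
        raise KineticsError(f"shape parameter must be positive, got {k}")
    return k


def sample_waiting_time(k: float, rate: float, rng: np.random.Generator) -> float:
    """One draw of a waiting time with mean ``1/rate`` and shape ``k``.

    ``k = inf`` returns exactly ``1/rate`` (the delta-function limit);
    ``k = 1`` is exponential; otherwise gamma(shape ``k``, scale
    ``1/(k*rate)``), so that E[w] = 1/rate and Var[w] = 1/(k*rate**2).
    """
    k = _check_shape(k)
    if not rate > 0:
        raise KineticsError(f"rate must be positive, got {rate}")
    if math.isinf(k):
        return 1.0 / rate
    if k == 1.0:
        return float(rng.exponential(1.0 / rate))
    return float(rng.gamma(k, 1.0 / (k * rate)))


def sample_residual_waiting_time(
    k: float,
    rate: float,
    tau: float,
    rng: np.random.Generator,
    overdue_epsilon: float | None = None,
) -> float:
    """Residual time to the next division for a cell of cycle age ``tau``.

    Draws the total waiting time ``w`` from the gamma distribution
    conditioned on ``w > tau`` (inverse CDF on the truncated tail) and
    returns the strictly positive residual ``w - tau``.  ``k = 1`` is
    memoryless and reduces to a plain exponential draw; ``k = inf``
    returns ``1/rate - tau`` when positive.

    When the conditioning tail has numerically vanished (tail mass below
    ``1e-12``), or ``k = inf`` with ``tau >= 1/rate``, the division is
    overdue: if ``overdue_epsilon`` is given, that value is returned (the
    event fires essentially immediately); otherwise a
    :class:`KineticsError` is raised.
    """
    k = _check_shape(k)
    if not rate > 0:
        raise KineticsError(f"rate must be positive, got {rate}")
    if tau < 0:
        raise KineticsError(f"tau must be nonnegative, got {tau}")
    if tau == 0.0:
        return sample_waiting_time(k, rate, rng)
    if math.isinf(k):
        residual = 1.0 / rate - tau
        if residual > 0:
            return residual
        if overdue_epsilon is not None:
            return overdue_epsilon
        raise KineticsError(
            f"deterministic division overdue: tau={tau} >= 1/rate={1.0 / rate}"
        )
    if k == 1.0:
        return float(rng.exponential(1.0 / rate))
    # Gamma(shape k, scale 1/(k*rate)); work in units of the scale.
    x_tau = tau * k * rate
    cdf_tau = float(special.gammainc(k, x_tau))
    tail = 1.0 - cdf_tau
    if tail <= _TAIL_EPS:
        if overdue_epsilon is not None:
            return overdue_epsilon
        raise KineticsError(
            f"residual tail mass {tail:.3g} below support at tau={tau}"
        )
    u = cdf_tau + rng.random() * tail
    total = float(special.gammaincinv(k, u)) / (k * rate)
    residual = total - tau
    if residual <= 0.0:
        # Inverse-CDF rounding can land exactly on tau.
        residual = math.ulp(tau)
    return residual


@dataclass(frozen=True)
class RateComponents:
    """The five multiplicative factors of a potential event rate."""

    base: float
    c1: float = 1.0
    c2: float = 1.0
    e1: float = 1.0
    e2: float = 1.0


def compose_rate(components: RateComponents) -> float:
    """Product of the five factors (``base * c1 * c2 * e1 * e2``)."""
    rate = (
        components.base
        * components.c1
        * components.c2
        * components.e1
        * components.e2
    )
    if rate < 0:
        raise KineticsError(f"composed rate is negative: {rate}")
    return rate


@dataclass(frozen=True)
class DriverEffect:
    """A single driver mutation's relative effect on one rate class."""

    mutation_class: MutationClass
    s: float


def driver_effect_product(effects: Iterable[DriverEffect | float]) -> float:
    """Mutation-load coefficient: product of ``max(0, 1 + s)`` over effects.

    Accepts raw ``s`` values or :class:`DriverEffect` records; the empty
    list gives 1.  Clamping at 0 makes a mutation with ``s <= -1``
    lethal-equivalent instead of producing a negative rate.
    """
    prod = 1.0
    for eff in effects:
        s = eff.s if isinstance(eff, DriverEffect) else float(eff)
        prod *= max(0.0, 1.0 + s)
    return prod


def e2_coefficient(model: E2Model, phi: float) -> float:
    """Local-density birth coefficient: constant 1, step 1{phi>0}, or phi."""
    if not 0.0 <= phi <= 1.0:
        raise KineticsError(f"phi must be in [0, 1], got {phi}")
    if model == "constant":
        return 1.0
    if model == "step":
        return 0.0 if phi <= 0.0 else 1.0
    if model == "linear":
        return phi
    raise KineticsError(f"unknown E2 model {model!r}")


@dataclass(frozen=True)
class MutationModel:
    """Per-division driver-mutation process for the three rate classes.

    Each class independently gains one mutation per division with
    probability ``mu_<class>``; its effect ``s`` is Gaussian with the
    class mean and standard deviation (``sigma = 0`` gives ``s = s_mean``
    exactly).
    """

    mu_beta: float = 0.0
    mu_delta: float = 0.0
    mu_rho: float = 0.0
    s_mean_beta: float = 0.0
    s_sd_beta: float = 0.0
    s_mean_delta: float = 0.0
    s_sd_delta: float = 0.0
    s_mean_rho: float = 0.0
    s_sd_rho: float = 0.0

    def __post_init__(self) -> None:
        for name in ("mu_beta", "mu_delta", "mu_rho"):
            mu = getattr(self, name)
            if not 0.0 <= mu <= 1.0:
                raise KineticsError(f"{name} must be in [0, 1], got {mu}")
        for name in ("s_sd_beta", "s_sd_delta", "s_sd_rho"):
            sd = getattr(self, name)
            if sd < 0:
                raise KineticsError(f"{name} must be nonnegative, got {sd}")

    @property
    def is_null(self) -> bool:
        return self.mu_beta == self.mu_delta == self.mu_rho == 0.0


def draw_new_mutations(
    model: MutationModel, rng: np.random.Generator
) -> List[DriverEffect]:
    """Mutations acquired by one daughter cell at one division."""
    out: List[DriverEffect] = []
    for cls, mu, mean, sd in (
        ("birth", model.mu_beta, model.s_mean_beta, model.s_sd_beta),
        ("death", model.mu_delta, model.s_mean_delta, model.s_sd_delta),
        ("migration", model.mu_rho, model.s_mean_rho, model.s_sd_rho),
    ):
        if mu > 0.0 and rng.random() < mu:
            s = mean if sd == 0.0 else float(rng.normal(mean, sd))
            out.append(DriverEffect(cls, s))
    return out
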