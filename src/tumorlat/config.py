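"""Run configuration: every simulator option, validation, YAML round-trip.

Defaults reproduce the baseline neutral setting: a regular 3D lattice
with the Moore neighborhood, synchronous division (``k_b = inf``,
``beta0 = 1``), constant-rate density model, push method 2, all-stem
population (``p_s = 1``), no death, migration, or driver mutations, and
a stop at 2**14 cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import List, Tuple

import yaml

from .kinetics import MutationModel


class ConfigError(ValueError):
    pass


def _parse_shape(value) -> float:
    if isinstance(value, str):
        if value.lower() in ("inf", "infinity"):
            return math.inf
        value = float(value)
    value = float(value)
    if not value > 0:
        raise ConfigError(f"shape parameter must be positive, got {value}")
    return value


@dataclass
class SimulationConfig:
    # Lattice
    lattice: str = "regular"  # "regular" | "hexagonal"
    dimension: int = 3
    neighborhood: str = "moore"  # "moore" | "von_neumann" ("hex" forced for hexagonal)
    # Waiting-time shapes
    k_b: float = math.inf
    k_d: float = 1.0
    k_m: float = 1.0
    # Potential base rates
    beta0: float = 1.0
    delta0: float = 0.0
    rho0: float = 0.0
    # Local-density model and placement
    e2_model: str = "constant"  # "constant" | "step" | "linear"
    push_method: int = 2
    migration_prefer_empty: bool = False
    # Death coupling
    death_mode: str = "independent"  # "independent" | "coupled"
    alpha: float = 0.0
    # Differentiation
    p_s: float = 1.0
    omega_max: int = 5
    # Driver mutations
    mu_beta: float = 0.0
    mu_delta: float = 0.0
    mu_rho: float = 0.0
    s_mean_beta: float = 0.0
    s_sd_beta: float = 0.0
    s_mean_delta: float = 0.0
    s_sd_delta: float = 0.0
    s_mean_rho: float = 0.0
    s_sd_rho: float = 0.0
    # Global environment: list of (time, multiplier), applied to all rates
    env_schedule: List[Tuple[float, float]] = field(default_factory=list)
    # Stopping rules
    max_cells: int = 16384
    max_time: float = math.inf
    # Analysis / bookkeeping
    n_founders: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        self.k_b = _parse_shape(self.k_b)
        self.k_d = _parse_shape(self.k_d)
        self.k_m = _parse_shape(self.k_m)
        self.env_schedule = [(float(t), float(m)) for t, m in self.env_schedule]
        self.validate()

    def validate(self) -> None:
        bad = []
        if self.lattice not in ("regular", "hexagonal"):
            bad.append(f"lattice={self.lattice!r}")
        if self.dimension not in (2, 3):
            bad.append(f"dimension={self.dimension}")
        if self.lattice == "regular" and self.neighborhood not in (
            "moore",
            "von_neumann",
        ):
            bad.append(f"neighborhood={self.neighborhood!r}")
        if self.lattice == "hexagonal" and self.neighborhood not in ("hex",):
            bad.append(
                f"neighborhood={self.neighborhood!r} (hexagonal lattice admits only 'hex')"
            )
        for name in ("beta0", "delta0", "rho0"):
            if getattr(self, name) < 0:
                bad.append(f"{name}={getattr(self, name)}")
        if self.e2_model not in ("constant", "step", "linear"):
            bad.append(f"e2_model={self.e2_model!r}")
        if self.push_method not in (1, 2, 3, 4):
            bad.append(f"push_method={self.push_method}")
        if self.death_mode not in ("independent", "coupled"):
            bad.append(f"death_mode={self.death_mode!r}")
        for name in ("alpha", "p_s", "mu_beta", "mu_delta", "mu_rho"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                bad.append(f"{name}={v}")
        for name in ("s_sd_beta", "s_sd_delta", "s_sd_rho"):
            if getattr(self, name) < 0:
                bad.append(f"{name}={getattr(self, name)}")
        if self.omega_max < 0:
            bad.append(f"omega_max={self.omega_max}")
        if self.max_cells < 1:
            bad.append(f"max_cells={self.max_cells}")
        if self.n_founders < 1:
            bad.append(f"n_founders={self.n_founders}")
        if any(m < 0 for _, m in self.env_schedule):
            bad.append("env_schedule multipliers must be nonnegative")
        if bad:
            raise ConfigError("invalid configuration: " + ", ".join(bad))

    @property
    def mutation_model(self) -> MutationModel:
        return MutationModel(
            mu_beta=self.mu_beta,
            mu_delta=self.mu_delta,
            mu_rho=self.mu_rho,
            s_mean_beta=self.s_mean_beta,
            s_sd_beta=self.s_sd_beta,
            s_mean_delta=self.s_mean_delta,
            s_sd_delta=self.s_sd_delta,
            s_mean_rho=self.s_mean_rho,
            s_sd_rho=self.s_sd_rho,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("k_b", "k_d", "k_m", "max_time"):
            if math.isinf(d[key]):
                d[key] = "inf"
        d["env_schedule"] = [list(pair) for pair in self.env_schedule]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "max_time" in d and isinstance(d["max_time"], str):
            d["max_time"] = math.inf if d["max_time"].lower() == "inf" else float(
                d["max_time"]
            )
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**d)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(data)


def load_config(path=None, **overrides) -> SimulationConfig:
    """Config from an optional YAML file plus keyword overrides."""
    if path is not None:
        base = SimulationConfig.from_yaml(path).to_dict()
    else:
        base = {}
    base.update({k: v for k, v in overrides.items() if v is not None})
    return SimulationConfig.from_dict(base)
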