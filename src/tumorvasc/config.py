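"""Simulation configuration: versioned schema, strict validation, YAML I/O.

Unknown keys are errors (the model has ~60 parameters; silent typos in a
config would otherwise go unnoticed).  All lengths are micrometers, times
hours unless a field says days, concentrations dimensionless in [0, 1].
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import yaml

from .cell_model import CellCycleParams
from .coupling import CouplingParams
from .init_synth import VasculatureGenSpec
from .mechanics import ForceParams
from .vasculature import AngiogenesisParams

SCHEMA_VERSION = 1

SUBSTANCES = ("nutrients", "VEGF", "DOX", "TRA")

#: default diffusion/decay per substance: D from the mass-scaling rule
#: anchored at glucose, decay from half-life data / surrogate fits
DEFAULT_SUBSTANCE_PARAMS = {
    "nutrients": {"D": 50.0, "lam": 0.0},
    "VEGF": {"D": 10.53, "lam": 0.01},
    "DOX": {"D": 34.61, "lam": 0.012},
    "TRA": {"D": 5.37, "lam": 0.004},
}


@dataclass
class SubstanceConfig:
    name: str
    enabled: bool = True
    D: float = 50.0               # um^2/h
    lam: float = 0.0              # 1/h
    bc: str = "neumann"           # "neumann" | "dirichlet"
    bc_value: float = 0.0         # Dirichlet boundary value
    initial: float = 0.0

    def __post_init__(self) -> None:
        if self.name not in SUBSTANCES:
            raise ValueError(f"unknown substance {self.name!r}")
        if self.bc not in ("neumann", "dirichlet"):
            raise ValueError("bc must be 'neumann' or 'dirichlet'")
        if self.D <= 0 or self.lam < 0:
            raise ValueError("need D > 0 and lam >= 0")
        if not (0.0 <= self.initial <= 1.0 and 0.0 <= self.bc_value <= 1.0):
            raise ValueError("concentrations must lie in [0, 1]")

    def bc_spec(self):
        return "neumann" if self.bc == "neumann" else ("dirichlet",
                                                       self.bc_value)


@dataclass
class TreatmentConfig:
    """Schedules as day ranges, e.g. dox_days: [[6, 7], [8, 9]]."""

    dox_days: list = field(default_factory=list)
    tra_days: list = field(default_factory=list)
    chi_max: float = 0.75
    tau_up: float = 12.0
    tau_down: float = 48.0

    def windows_hours(self, which: str) -> list:
        days = self.dox_days if which == "dox" else self.tra_days
        return [(24.0 * float(a), 24.0 * float(b)) for a, b in days]


@dataclass
class SimulationConfig:
    schema_version: int = SCHEMA_VERSION
    seed: int = 0
    # domain: cube centered at the origin, shared lattice for all substances
    domain_edge: float = 600.0
    grid_points: int = 40
    # time stepping
    dt: float = 0.1                       # agent step, hours
    total_days: float = 30.0
    vessel_shutoff_day: Optional[float] = None
    output_cadence_steps: int = 10
    # initial state
    n_cells: int = 200
    initial_cell_state: str = "Q"
    vessel_file: Optional[str] = None
    generate_vessels: bool = False
    # module toggles
    angiogenesis_enabled: bool = True
    vegf_vessel_sink: bool = True         # vessels deplete VEGF locally
    # parameter blocks
    substances: dict = field(default_factory=dict)
    cell_cycle: CellCycleParams = field(default_factory=CellCycleParams)
    forces: ForceParams = field(default_factory=ForceParams)
    angiogenesis: AngiogenesisParams = field(
        default_factory=AngiogenesisParams)
    coupling: CouplingParams = field(default_factory=CouplingParams)
    treatment: TreatmentConfig = field(default_factory=TreatmentConfig)
    vasc_gen: VasculatureGenSpec = field(default_factory=VasculatureGenSpec)

    def __post_init__(self) -> None:
        if self.schema_version != SCHEMA_VERSION:
            raise ValueError(
                f"unsupported schema_version {self.schema_version}")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.total_days <= 0:
            raise ValueError("total_days must be positive")
        if (self.vessel_shutoff_day is not None
                and self.vessel_shutoff_day > self.total_days):
            raise ValueError("vessel_shutoff_day must be <= total_days")
        if self.domain_edge <= 0 or self.grid_points < 3:
            raise ValueError("need domain_edge > 0 and grid_points >= 3")
        if self.initial_cell_state not in ("Q", "H"):
            raise ValueError("initial_cell_state must be 'Q' or 'H'")
        if self.output_cadence_steps < 1:
            raise ValueError("output_cadence_steps must be >= 1")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        # fill substance table with defaults, validate entries
        full = {}
        for name in SUBSTANCES:
            entry = dict(DEFAULT_SUBSTANCE_PARAMS[name])
            entry.update(self.substances.get(name, {}))
            if isinstance(entry.get("bc"), SubstanceConfig):
                raise ValueError("substance entries must be plain mappings")
            full[name] = _build(SubstanceConfig, {"name": name, **entry})
        unknown = set(self.substances) - set(SUBSTANCES)
        if unknown:
            raise ValueError(f"unknown substances in config: {sorted(unknown)}")
        self.substances = full

    @property
    def grid_h(self) -> float:
        return self.domain_edge / (self.grid_points - 1)

    @property
    def n_steps(self) -> int:
        return int(round(self.total_days * 24.0 / self.dt))

    def treatment_state(self):
        from .treatment import TreatmentState

        t = self.treatment
        return TreatmentState(
            dox_windows=t.windows_hours("dox"),
            tra_windows=t.windows_hours("tra"),
            chi_max=t.chi_max, tau_up=t.tau_up, tau_down=t.tau_down)


def _build(cls, data: dict):
    """Instantiate a dataclass from a mapping, rejecting unknown keys."""
    if not isinstance(data, dict):
        raise ValueError(f"expected a mapping for {cls.__name__}")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(
            f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        if isinstance(value, list) and key in ("domain_lo", "domain_hi",
                                               "parent_diameter_range",
                                               "exclusion_center"):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


_BLOCKS = {
    "cell_cycle": CellCycleParams,
    "forces": ForceParams,
    "angiogenesis": AngiogenesisParams,
    "coupling": CouplingParams,
    "treatment": TreatmentConfig,
    "vasc_gen": VasculatureGenSpec,
}


def config_from_dict(data: dict) -> SimulationConfig:
    """Build and validate a :class:`SimulationConfig` from a plain mapping."""
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    data = dict(data)
    kwargs = {}
    for key, cls in _BLOCKS.items():
        if key in data:
            kwargs[key] = _build(cls, data.pop(key))
    names = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs.update(data)
    return _build(SimulationConfig, kwargs)


def config_to_dict(cfg: SimulationConfig) -> dict:
    out = dataclasses.asdict(cfg)
    out["substances"] = {
        name: {k: v for k, v in dataclasses.asdict(sc).items()
               if k != "name"}
        for name, sc in cfg.substances.items()}
    for key in ("vasc_gen",):
        block = out[key]
        for k, v in block.items():
            if isinstance(v, tuple):
                block[k] = list(v)
    return out


def load_config(path) -> SimulationConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data or {})


def save_config(cfg: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)
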