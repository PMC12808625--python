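"""Run configuration: schema, defaults, YAML/JSON loading.

A run is fully described by a flat mapping with four groups of keys
(model parameter overrides, fractional orders, solver grid/tolerances,
feedback gains) plus output/logging plumbing.  Unknown keys are rejected
so that typos fail loudly.  ``seed`` exists only for diagnostics that
randomize (Lyapunov perturbation directions); the solvers themselves are
deterministic.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .fixed_order import SolverConfig, config_hash
from .model import ControlGains, ModelParameters
from .operators import FractionalOrderSpec

__all__ = ["RunConfig", "load_config", "dump_config"]

_SOLVER_KEYS = ("dt", "T", "rel_tol", "abs_tol", "stop_delta", "scheme",
                "bootstrap", "poly_order", "blowup_threshold")


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for one simulation run."""

    parameters: dict = field(default_factory=dict)
    alpha: float = 1.0
    beta: object = "const:1"
    beta_derivative_mode: str = "forward_difference"
    dt: float = 0.001
    T: float = 120.0
    rel_tol: float = 1e-6
    abs_tol: float = 1e-8
    stop_delta: float = 1e-8
    scheme: str = "fixed"
    bootstrap: str = "two_point"
    poly_order: int = 3
    blowup_threshold: float = 1e6
    d1: float = 0.2
    d3: float = 0.1
    y0: tuple = (0.0, 1.5, 1.0)
    output: str | None = None
    log_level: str = "INFO"
    seed: int | None = None

    def __post_init__(self):
        # delegate to the domain objects so every constraint is checked
        # (and error messages name the offending field)
        self.model_parameters()
        self.orders()
        self.solver_config()
        self.control_gains()
        if len(tuple(self.y0)) != 3:
            raise ConfigurationError(
                f"y0 must have exactly 3 components, got {self.y0!r}")

    def model_parameters(self) -> ModelParameters:
        try:
            return ModelParameters.from_mapping(self.parameters)
        except (TypeError, ValueError) as exc:
            raise ConfigurationError(f"parameters: {exc}") from None

    def orders(self) -> FractionalOrderSpec:
        return FractionalOrderSpec(
            alpha=self.alpha, beta=self.beta,
            beta_derivative_mode=self.beta_derivative_mode)

    def solver_config(self) -> SolverConfig:
        return SolverConfig(**{k: getattr(self, k) for k in _SOLVER_KEYS})

    def control_gains(self) -> ControlGains:
        return ControlGains(d1=self.d1, d3=self.d3)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["y0"] = list(self.y0)
        return d

    @property
    def hash(self) -> str:
        return config_hash(self.as_dict())


def _from_mapping(data: dict) -> RunConfig:
    allowed = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - allowed
    if unknown:
        raise ConfigurationError(
            f"unknown config keys: {sorted(unknown)}; allowed: "
            f"{sorted(allowed)}")
    if "y0" in data:
        data = dict(data)
        data["y0"] = tuple(data["y0"])
    try:
        return RunConfig(**data)
    except TypeError as exc:
        raise ConfigurationError(str(exc)) from None


def load_config(path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration.

    An empty file yields all defaults (classical orders alpha=1,
    beta=const:1, gains (0.2, 0.1), dt=0.001, T=120).
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    text = path.read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"cannot parse {path}: {exc}") from None
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigurationError(
            f"config root must be a mapping, got {type(data).__name__}")
    return _from_mapping(data)


def dump_config(cfg: RunConfig, path=None) -> str:
    """Serialize a config to YAML; load(dump(load(x))) is idempotent."""
    text = yaml.safe_dump(cfg.as_dict(), sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text
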