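"""Simulation presets for the twelve published figure configurations.

Each preset bundles the fractional order ``alpha``, the fractal-exponent
profile, the feedback gains and the grid used for one family of phase
portraits / time series (figure ids 2-13).  The gain table in the source
material indexes its rows 1-12 while the figures are numbered 2-13;
presets are keyed by figure id, with ``table_row = figure - 1`` recorded
on each preset as the cross-reference.

Initial conditions: the three published triples are available through
``INITIAL_CONDITIONS``; which triple belongs to which figure is not
stated, so presets default to the first, ``(0, 1.5, 1)``, with the others
selectable via ``y0_index``.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace

import yaml

from .errors import ConfigurationError
from .fixed_order import SolverConfig, Trajectory, simulate_fixed
from .model import ControlGains, ModelParameters
from .operators import FractionalOrderSpec
from .variable_order import simulate_vo

__all__ = [
    "INITIAL_CONDITIONS",
    "LATE_WINDOW_START",
    "ScenarioPreset",
    "ScenarioResult",
    "PRESETS",
    "list_scenarios",
    "get_scenario",
    "run_scenario",
    "preset_to_yaml",
    "preset_from_yaml",
]

#: The three published initial-condition triples.
INITIAL_CONDITIONS = ((0.0, 1.5, 1.0), (0.5, 1.0, 1.0), (1.4, -1.5, 1.31))

#: Start of the late comparison window used for sup-norm contrasts: long
#: enough for transients to pass at the default horizon T=120.
LATE_WINDOW_START = 20.0


@dataclass(frozen=True)
class ScenarioPreset:
    """One figure configuration: orders, memory type, gains and grid."""

    figure: int
    alpha: float
    beta_profile: str
    d1: float
    d3: float
    memory_type: str
    dt: float = 0.001
    T: float = 120.0

    def __post_init__(self):
        if self.d1 < 0 or self.d3 < 0:
            raise ConfigurationError("preset gains must be non-negative")
        # fail early on malformed profiles / grids
        FractionalOrderSpec(alpha=self.alpha, beta=self.beta_profile)
        SolverConfig(dt=self.dt, T=self.T)

    @property
    def table_row(self) -> int:
        return self.figure - 1

    @property
    def is_variable_order(self) -> bool:
        return FractionalOrderSpec(
            alpha=self.alpha, beta=self.beta_profile).constant_beta() is None

    def orders(self) -> FractionalOrderSpec:
        return FractionalOrderSpec(alpha=self.alpha, beta=self.beta_profile)

    def gains(self) -> ControlGains:
        return ControlGains(d1=self.d1, d3=self.d3)

    def solver_config(self, dt: float | None = None,
                      T: float | None = None) -> SolverConfig:
        return SolverConfig(
            dt=dt if dt is not None else self.dt,
            T=T if T is not None else self.T,
            scheme="variable" if self.is_variable_order else "fixed")


def _preset(figure, alpha, beta, d1, d3, memory):
    return ScenarioPreset(figure=figure, alpha=alpha, beta_profile=beta,
                          d1=d1, d3=d3, memory_type=memory)


#: Figure id -> preset (table rows 1-12 shifted by one).
PRESETS: dict[int, ScenarioPreset] = {
    2: _preset(2, 1.0, "const:1", 0.20, 0.10, "constant"),
    3: _preset(3, 1.0, "const:0.98", 0.20, 0.10, "constant"),
    4: _preset(4, 0.98, "const:1", 0.20, 0.10, "constant"),
    5: _preset(5, 0.98, "cos_slow", 0.22, 0.12, "oscillatory variable order"),
    6: _preset(6, 1.0, "tanh1p", 0.25, 0.12, "gradual memory accumulation"),
    7: _preset(7, 1.0, "sigmoid", 0.25, 0.15, "sigmoidal adaptation"),
    8: _preset(8, 1.0, "const:1", 0.20, 0.10, "fixed memory, varying alpha"),
    9: _preset(9, 1.0, "const:0.98", 0.20, 0.10, "fixed memory, varying alpha"),
    10: _preset(10, 0.98, "const:1", 0.20, 0.10, "fixed memory, varying alpha"),
    11: _preset(11, 0.98, "cos_slow", 0.22, 0.12, "time-varying adaptive"),
    12: _preset(12, 1.0, "tanh1p", 0.25, 0.12, "delayed stabilization"),
    13: _preset(13, 1.0, "sigmoid", 0.25, 0.15, "sigmoidal delay"),
}


def list_scenarios() -> list[ScenarioPreset]:
    return [PRESETS[k] for k in sorted(PRESETS)]


def get_scenario(figure_id: int) -> ScenarioPreset:
    """Preset for one figure id (2-13)."""
    try:
        return PRESETS[figure_id]
    except KeyError:
        raise ConfigurationError(
            f"unknown figure id {figure_id!r}; valid ids: {sorted(PRESETS)}"
        ) from None


@dataclass
class ScenarioResult:
    """Controlled/uncontrolled trajectories plus a comparison summary."""

    preset: ScenarioPreset
    controlled: Trajectory | None
    uncontrolled: Trajectory | None
    summary: dict


def _run_one(preset, y0, gains, dt, T, p):
    cfg = preset.solver_config(dt=dt, T=T)
    orders = preset.orders()
    if preset.is_variable_order:
        return simulate_vo(y0, p, gains, orders, cfg)
    return simulate_fixed(y0, p, gains, orders, cfg)


def run_scenario(figure_id: int, controlled="both", y0_index: int = 0,
                 dt: float | None = None, T: float | None = None,
                 p: ModelParameters | None = None) -> ScenarioResult:
    """Run one preset with and/or without feedback control.

    ``controlled`` is True, False or ``"both"``.  ``y0_index`` selects one
    of the three published initial triples.  ``dt``/``T`` override the
    preset grid (e.g. reduced horizons for quick checks).  The summary
    reports sup-norms over the late window ``[LATE_WINDOW_START, T]``
    (clipped to half the horizon for short runs) and divergence flags.
    """
    preset = get_scenario(figure_id)
    if not 0 <= y0_index < len(INITIAL_CONDITIONS):
        raise ConfigurationError(
            f"y0_index must be in 0..{len(INITIAL_CONDITIONS) - 1}, "
            f"got {y0_index!r}")
    y0 = INITIAL_CONDITIONS[y0_index]
    horizon = T if T is not None else preset.T
    window_start = min(LATE_WINDOW_START, 0.5 * horizon)

    traj_c = traj_u = None
    if controlled in (True, "both"):
        traj_c = _run_one(preset, y0, preset.gains(), dt, T, p)
    if controlled in (False, "both"):
        traj_u = _run_one(preset, y0, ControlGains(), dt, T, p)

    summary = {
        "figure": figure_id,
        "y0": list(y0),
        "late_window": [window_start, horizon],
    }
    if traj_c is not None:
        summary["controlled"] = {
            "termination": traj_c.termination,
            "diverged": traj_c.diverged,
            "sup_norm_late": traj_c.sup_norm(window_start),
        }
    if traj_u is not None:
        summary["uncontrolled"] = {
            "termination": traj_u.termination,
            "diverged": traj_u.diverged,
            "sup_norm_late": traj_u.sup_norm(window_start),
        }
    return ScenarioResult(preset=preset, controlled=traj_c,
                          uncontrolled=traj_u, summary=summary)


def preset_to_yaml(preset: ScenarioPreset) -> str:
    """Serialize a preset to YAML (round-trips bit-exactly)."""
    return yaml.safe_dump(asdict(preset), sort_keys=True)


def preset_from_yaml(text: str) -> ScenarioPreset:
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigurationError("preset YAML must be a mapping")
    try:
        return ScenarioPreset(**data)
    except TypeError as exc:
        raise ConfigurationError(f"bad preset fields: {exc}") from None
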