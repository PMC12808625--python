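"""Fixed-order CF-FF integrator (Newton-interpolation / Adams-Bashforth type).

With a constant fractal exponent ``beta``, the CF-FF initial value problem
is discretized on the uniform grid ``t_n = n*dt`` by scaling the RHS,
``U_n = beta * t_n**(beta-1) * f_n``, and updating

``y_{n+1} = y_n + (1-alpha)/Bhat(alpha) * (U_n - U_{n-1})
          + alpha/Bhat(alpha) * P_n(U) * dt``

where ``P_n`` is the third-order Newton (Adams-Bashforth) polynomial
``(5/12) U_{n-2} - (4/3) U_{n-1} + (23/12) U_n`` for ``n >= 2``, with a
two-point version ``(3/2) U_n - (1/2) U_{n-1}`` at ``n = 1`` and the
single-point (Euler-type) value at ``n = 0``.  The first term is the local
(non-singular kernel) memory difference; the second is the quadrature of
the integral term.  At ``alpha = beta = 1`` the scheme is exactly
classical 3-step Adams-Bashforth.

The factor ``beta * t**(beta-1)`` is applied exactly once (inside ``U``);
the update prefactors are ``(1-alpha)/Bhat`` and ``alpha/Bhat``.  At
``t = 0`` the scaled RHS follows the short-memory convention: it is set to
zero whenever ``beta < 1`` (where ``t**(beta-1)`` is singular) and equals
``f_0`` at ``beta = 1`` (where the scale factor is exactly 1).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError, DomainError
from .model import ControlGains, ModelParameters, make_scalar_rhs
from .operators import FractionalOrderSpec, bhat

__all__ = [
    "SolverConfig",
    "ScaledRHSSample",
    "Trajectory",
    "scale_rhs",
    "newton_poly",
    "step_fixed",
    "bootstrap_steps",
    "integrate_fixed",
    "simulate_fixed",
]

_AB3 = (5.0 / 12.0, -4.0 / 3.0, 23.0 / 12.0)


@dataclass(frozen=True)
class SolverConfig:
    """Time grid, tolerances and scheme selection.

    ``stop_delta`` is the sup-norm stopping threshold (``<= 0`` disables
    early stopping); ``rel_tol``/``abs_tol`` are the accuracy targets used
    by self-convergence checks and the equilibrium solver (the one-pass
    explicit scheme itself is not iterative).  ``poly_order`` selects the
    quadrature polynomial for ``n >= 2``: 3 (default, third-order Newton)
    or 2 (the two-point scheme, which is the constant-beta limit of the
    variable-order integrator).  States exceeding ``blowup_threshold`` in
    magnitude terminate the run with a divergence flag.
    """

    dt: float = 0.001
    T: float = 120.0
    rel_tol: float = 1e-6
    abs_tol: float = 1e-8
    stop_delta: float = 1e-8
    scheme: str = "fixed"
    bootstrap: str = "two_point"
    poly_order: int = 3
    blowup_threshold: float = 1e6

    def __post_init__(self):
        if self.dt <= 0:
            raise ConfigurationError(f"dt must be positive, got {self.dt!r}")
        if self.T <= 0:
            raise ConfigurationError(f"T must be positive, got {self.T!r}")
        n = self.T / self.dt
        if abs(n - round(n)) > 1e-6 * max(1.0, n):
            raise ConfigurationError(
                f"T/dt = {n!r} must be integral within rounding")
        if self.scheme not in ("fixed", "variable"):
            raise ConfigurationError(
                f"scheme must be 'fixed' or 'variable', got {self.scheme!r}")
        if self.bootstrap not in ("euler", "two_point"):
            raise ConfigurationError(
                f"bootstrap must be 'euler' or 'two_point', got {self.bootstrap!r}")
        if self.poly_order not in (2, 3):
            raise ConfigurationError(
                f"poly_order must be 2 or 3, got {self.poly_order!r}")

    @property
    def n_steps(self) -> int:
        return int(round(self.T / self.dt))

    def replace(self, **kw) -> "SolverConfig":
        return replace(self, **kw)

    def as_dict(self) -> dict:
        return {
            "dt": self.dt, "T": self.T, "rel_tol": self.rel_tol,
            "abs_tol": self.abs_tol, "stop_delta": self.stop_delta,
            "scheme": self.scheme, "bootstrap": self.bootstrap,
            "poly_order": self.poly_order,
            "blowup_threshold": self.blowup_threshold,
        }


@dataclass(frozen=True)
class ScaledRHSSample:
    """Scaled RHS values ``beta * t**(beta-1) * (phi, psi, mu)`` at one node."""

    U: float
    V: float
    W: float


@dataclass
class Trajectory:
    """Time-indexed state sequence plus run metadata.

    ``metadata`` records scheme, orders, gains, termination reason and the
    solver configuration, and carries a config hash so a run is
    reproducible from its sidecar alone.
    """

    times: np.ndarray
    states: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape != (self.times.size, 3):
            raise DomainError(
                f"states shape {self.states.shape} does not match "
                f"{self.times.size} time points")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise DomainError("times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    @property
    def diverged(self) -> bool:
        return self.metadata.get("termination") == "diverged"

    @property
    def termination(self) -> str:
        return self.metadata.get("termination", "unknown")

    def sup_norm(self, t_min: float = 0.0, t_max: float | None = None) -> float:
        """Sup-norm of the state over the window ``[t_min, t_max]``.

        Returns ``inf`` when the window contains no samples (e.g. a run
        that diverged before reaching it).
        """
        mask = self.times >= t_min
        if t_max is not None:
            mask &= self.times <= t_max
        if not np.any(mask):
            return math.inf
        return float(np.max(np.abs(self.states[mask])))


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable configuration dict."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def scale_rhs(f_val: float, t_n: float, beta: float) -> float:
    """``beta * t_n**(beta-1) * f_val``; short-memory convention at 0.

    At ``t_n = 0`` the weight is singular for ``beta < 1`` and the scaled
    sample is set to zero; at ``beta = 1`` the weight equals 1 and the raw
    RHS value is returned.
    """
    if t_n < 0:
        raise DomainError(f"t_n must be non-negative, got {t_n!r}")
    if t_n == 0.0:
        return f_val if beta == 1.0 else 0.0
    if beta == 1.0:
        return f_val
    return beta * t_n ** (beta - 1.0) * f_val


def newton_poly(f_nm2: float, f_nm1: float, f_n: float) -> float:
    """Third-order Newton polynomial ``(5/12)f_{n-2} - (4/3)f_{n-1} + (23/12)f_n``.

    These are the classical 3-step Adams-Bashforth weights; they sum to 1,
    so constants are reproduced exactly.
    """
    return _AB3[0] * f_nm2 + _AB3[1] * f_nm1 + _AB3[2] * f_n


def step_fixed(y_n, u_nm2, u_nm1, u_n, alpha: float, dt: float) -> np.ndarray:
    """One fixed-order update from already-scaled RHS history.

    ``u_*`` are length-3 arrays of scaled samples at nodes n-2, n-1, n
    (``n >= 2``); ``y_n`` the current state.  Returns ``y_{n+1}``.
    """
    y_n = np.asarray(y_n, dtype=float)
    u_nm2 = np.asarray(u_nm2, dtype=float)
    u_nm1 = np.asarray(u_nm1, dtype=float)
    u_n = np.asarray(u_n, dtype=float)
    bh = bhat(alpha)
    mem = (1.0 - alpha) / bh * (u_n - u_nm1)
    quad = alpha / bh * newton_poly(u_nm2, u_nm1, u_n) * dt
    return y_n + mem + quad


def integrate_fixed(rhs, y0, alpha: float, beta: float,
                    cfg: SolverConfig) -> Trajectory:
    """Integrate ``FFED y = rhs`` with constant orders on the cfg grid.

    ``rhs(t, y1, y2, y3) -> (f1, f2, f3)`` works on plain floats.  Generic
    over the vector field; :func:`simulate_fixed` binds the glucose-insulin
    model.  Terminates at ``T``, at the sup-norm stopping criterion
    (checked from the second step onward), or on blow-up (flagged
    ``diverged``, trajectory truncated at the last finite state).
    """
    if not (0.0 < alpha <= 1.0):
        raise ConfigurationError(f"alpha must lie in (0, 1], got {alpha!r}")
    if not (0.0 < beta <= 1.0):
        raise ConfigurationError(f"beta must lie in (0, 1], got {beta!r}")
    dt = cfg.dt
    N = cfg.n_steps
    bh = bhat(alpha)
    cm = (1.0 - alpha) / bh
    cq = alpha / bh * dt
    two_pt = cfg.bootstrap == "two_point"
    order3 = cfg.poly_order == 3
    stop = cfg.stop_delta
    lim = cfg.blowup_threshold
    c0, c1, c2 = _AB3
    classical = beta == 1.0

    ys = np.empty((N + 1, 3))
    y1, y2, y3 = (float(v) for v in y0)
    for v, name in ((y1, "y1"), (y2, "y2"), (y3, "y3")):
        if not math.isfinite(v):
            raise DomainError(f"initial state component {name} is not finite")
    ys[0] = (y1, y2, y3)

    u1p = u2p = u3p = 0.0       # U_{n-1}
    u1pp = u2pp = u3pp = 0.0    # U_{n-2}
    termination = "reached_T"
    n_last = N
    bm1 = beta - 1.0
    isfinite = math.isfinite

    for n in range(N):
        t = n * dt
        f1, f2, f3 = rhs(t, y1, y2, y3)
        if n == 0:
            w = 1.0 if classical else 0.0
        elif classical:
            w = 1.0
        else:
            w = beta * t ** bm1
        u1 = w * f1
        u2 = w * f2
        u3 = w * f3
        if n >= 2:
            if order3:
                p1 = c0 * u1pp + c1 * u1p + c2 * u1
                p2 = c0 * u2pp + c1 * u2p + c2 * u2
                p3 = c0 * u3pp + c1 * u3p + c2 * u3
            else:
                p1 = 1.5 * u1 - 0.5 * u1p
                p2 = 1.5 * u2 - 0.5 * u2p
                p3 = 1.5 * u3 - 0.5 * u3p
        elif n == 1 and two_pt:
            p1 = 1.5 * u1 - 0.5 * u1p
            p2 = 1.5 * u2 - 0.5 * u2p
            p3 = 1.5 * u3 - 0.5 * u3p
        else:
            p1, p2, p3 = u1, u2, u3
        ny1 = y1 + cm * (u1 - u1p) + cq * p1
        ny2 = y2 + cm * (u2 - u2p) + cq * p2
        ny3 = y3 + cm * (u3 - u3p) + cq * p3
        if not (isfinite(ny1) and isfinite(ny2) and isfinite(ny3)):
            n_last = n
            termination = "diverged"
            break
        ys[n + 1] = (ny1, ny2, ny3)
        if abs(ny1) > lim or abs(ny2) > lim or abs(ny3) > lim:
            n_last = n + 1
            termination = "diverged"
            break
        if (stop > 0.0 and n >= 1
                and abs(ny1 - y1) < stop and abs(ny2 - y2) < stop
                and abs(ny3 - y3) < stop):
            n_last = n + 1
            termination = "converged"
            break
        u1pp, u2pp, u3pp = u1p, u2p, u3p
        u1p, u2p, u3p = u1, u2, u3
        y1, y2, y3 = ny1, ny2, ny3

    times = np.arange(n_last + 1) * dt
    metadata = {
        "scheme": "fixed",
        "alpha": alpha,
        "beta": beta,
        "termination": termination,
        "config": cfg.as_dict(),
    }
    metadata["config_hash"] = config_hash(metadata["config"])
    return Trajectory(times=times, states=ys[: n_last + 1], metadata=metadata)


def _resolve_run(p, g, orders):
    p = p if p is not None else ModelParameters()
    g = g if g is not None else ControlGains()
    orders = orders if orders is not None else FractionalOrderSpec()
    return p, g, orders


def simulate_fixed(y0, p: ModelParameters | None = None,
                   g: ControlGains | None = None,
                   orders: FractionalOrderSpec | None = None,
                   cfg: SolverConfig | None = None) -> Trajectory:
    """Run the fixed-order scheme on the (controlled) glucose-insulin model.

    ``orders`` must carry a constant fractal exponent; use
    :func:`cfglucose.variable_order.simulate_vo` for time-varying
    ``beta(t)``.
    """
    p, g, orders = _resolve_run(p, g, orders)
    cfg = cfg if cfg is not None else SolverConfig()
    beta = orders.constant_beta()
    if beta is None:
        raise ConfigurationError(
            "simulate_fixed requires a constant beta; the profile "
            f"{orders.beta!r} is time-varying (use simulate_vo)")
    traj = integrate_fixed(make_scalar_rhs(p, g), y0, orders.alpha, beta, cfg)
    traj.metadata.update({
        "gains": {"d1": g.d1, "d3": g.d3},
        "y0": [float(v) for v in y0],
        "model": "glucose_insulin_v1",
        "gamma2_sign_convention": p.gamma2_sign_convention,
    })
    return traj


def bootstrap_steps(y0, p: ModelParameters | None = None,
                    g: ControlGains | None = None,
                    orders: FractionalOrderSpec | None = None,
                    cfg: SolverConfig | None = None) -> tuple[np.ndarray, np.ndarray]:
    """States ``y_1, y_2`` produced by the startup of the fixed scheme.

    Node 0 uses the single-point (Euler-type) quadrature ``P_0 = U_0``;
    node 1 uses the two-point polynomial ``(3/2)U_1 - (1/2)U_0`` (or Euler
    again if ``cfg.bootstrap == 'euler'``), both with the same
    memory-difference term as the main stepper.
    """
    cfg = cfg if cfg is not None else SolverConfig()
    short = cfg.replace(T=2 * cfg.dt, stop_delta=0.0)
    traj = simulate_fixed(y0, p, g, orders, short)
    if len(traj) < 3:
        raise DomainError("bootstrap diverged before completing two steps")
    return traj.states[1].copy(), traj.states[2].copy()
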