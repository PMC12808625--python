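"""Three-state glucose-insulin regulatory vector field.

The model is a cubic Lotka-Volterra-type system in three abstract
physiological states ``(y1, y2, y3)`` (glucose / insulin / beta-cell axis;
the biological labels are carried as metadata only, see
:data:`STATE_LABELS`).  The vector field is

.. math::

    \\dot y_1 &= -a_1 y_1 + a_2 y_1 y_2 + a_3 y_2^2 + a_4 y_2^3
                 + a_5 y_3 + a_6 y_3^2 + a_7 y_3^3 + a_{20}, \\\\
    \\dot y_2 &= -a_8 y_1 y_2 - a_9 y_1^2 - a_{10} y_1^3
                 + a_{11} y_2 (1 - y_2) - a_{12} y_3 - a_{13} y_3^2
                 - a_{14} y_3^3 + a_{21}, \\\\
    \\dot y_3 &= a_{15} y_2 + a_{16} y_2^2 + a_{17} y_2^3
                 - a_{18} y_3 - a_{19} y_2 y_3,

with the 21 kinetic constants of Shabestari et al. (2018) /
Elsadany et al. as defaults.  Linear state feedback subtracts
``d1*(y1 + y2)`` from the first equation and ``d3*(y1 + y3)`` from the
third one.

The sign of the ``a8`` cross term differs between published restatements
of the model; the canonical form here uses ``-a8*y1*y2`` and the
alternative is selectable through
``ModelParameters.gamma2_sign_convention``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields, replace

import numpy as np

from .errors import ConfigurationError, DomainError

__all__ = [
    "DEFAULT_PARAMETER_VALUES",
    "STATE_LABELS",
    "ModelParameters",
    "ControlGains",
    "EquilibriumResult",
    "rhs_uncontrolled",
    "rhs_controlled",
    "jacobian",
    "find_equilibrium",
    "make_scalar_rhs",
]

#: Informal biological labels for the three states.  The literature is not
#: consistent about which state is glucose and which is insulin, so these
#: are metadata only and never enter any computation.
STATE_LABELS = ("glucose", "insulin", "beta_cell_activity")

#: Default kinetic constants (Shabestari et al. 2018 parameterization),
#: versioned as v1.  Units follow the source: a1 in 1/min, a2 in
#: 1/(L*uU*min), a20 in mmol/(L*min), a21 in uU/(mL*min), etc.
DEFAULT_PARAMETER_VALUES = {
    "a1": 2.04, "a2": 0.10, "a3": 1.09, "a4": -1.08, "a5": 0.03,
    "a6": -0.06, "a7": 2.01, "a8": 0.22, "a9": -3.84, "a10": -1.20,
    "a11": 0.30, "a12": 1.37, "a13": -0.30, "a14": 0.22, "a15": 0.30,
    "a16": -1.35, "a17": 0.50, "a18": -0.42, "a19": -0.15, "a20": -0.19,
    "a21": -0.56,
}

_PARAM_NAMES = tuple(DEFAULT_PARAMETER_VALUES)


@dataclass(frozen=True)
class ModelParameters:
    """The 21 kinetic constants of the regulatory model.

    The default constructor loads the published values exactly.  Any field
    may be overridden; all values must be finite.

    ``gamma2_sign_convention`` selects the sign of the ``a8*y1*y2`` term in
    the second equation: ``"system"`` (canonical, ``-a8``) or
    ``"existence"`` (``+a8``, the variant appearing in some restatements).
    """

    a1: float = 2.04
    a2: float = 0.10
    a3: float = 1.09
    a4: float = -1.08
    a5: float = 0.03
    a6: float = -0.06
    a7: float = 2.01
    a8: float = 0.22
    a9: float = -3.84
    a10: float = -1.20
    a11: float = 0.30
    a12: float = 1.37
    a13: float = -0.30
    a14: float = 0.22
    a15: float = 0.30
    a16: float = -1.35
    a17: float = 0.50
    a18: float = -0.42
    a19: float = -0.15
    a20: float = -0.19
    a21: float = -0.56
    gamma2_sign_convention: str = "system"

    def __post_init__(self):
        for name in _PARAM_NAMES:
            value = getattr(self, name)
            if not math.isfinite(value):
                raise DomainError(f"parameter {name} must be finite, got {value!r}")
        if self.gamma2_sign_convention not in ("system", "existence"):
            raise ConfigurationError(
                "gamma2_sign_convention must be 'system' or 'existence', "
                f"got {self.gamma2_sign_convention!r}"
            )

    @property
    def gamma2_sign(self) -> float:
        """Sign multiplying the a8*y1*y2 term (-1 canonical)."""
        return -1.0 if self.gamma2_sign_convention == "system" else 1.0

    @classmethod
    def from_mapping(cls, mapping) -> "ModelParameters":
        """Build from a dict keyed ``a1..a21`` (plus the sign convention).

        Unknown keys are rejected; missing keys fall back to defaults.
        """
        allowed = set(_PARAM_NAMES) | {"gamma2_sign_convention"}
        unknown = set(mapping) - allowed
        if unknown:
            raise ConfigurationError(
                f"unknown model parameter keys: {sorted(unknown)}"
            )
        return cls(**mapping)

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def replace(self, **kw) -> "ModelParameters":
        return replace(self, **kw)


@dataclass(frozen=True)
class ControlGains:
    """Linear feedback gains.

    ``d1`` acts on the first equation through ``(y1 + y2)``, ``d3`` on the
    third through ``(y1 + y3)``.  Both must be non-negative.  ``k1``/``k3``
    are the optional proportional tuning multipliers from the eigenvalue
    shift rule ``d_i = k_i * |Re(lambda_max)|``; values outside
    ``[0.1, 0.3]`` trigger a warning (the rule's recommended range), not an
    error.
    """

    d1: float = 0.0
    d3: float = 0.0
    k1: float | None = None
    k3: float | None = None

    def __post_init__(self):
        if not (math.isfinite(self.d1) and math.isfinite(self.d3)):
            raise ConfigurationError("gains must be finite")
        if self.d1 < 0 or self.d3 < 0:
            raise ConfigurationError(
                f"feedback gains must be non-negative, got d1={self.d1}, d3={self.d3}"
            )
        for name in ("k1", "k3"):
            k = getattr(self, name)
            if k is not None and not (0.1 <= k <= 0.3):
                warnings.warn(
                    f"{name}={k} lies outside the recommended tuning range [0.1, 0.3]",
                    stacklevel=3,
                )

    @property
    def is_zero(self) -> bool:
        return self.d1 == 0.0 and self.d3 == 0.0


ZERO_GAINS = ControlGains(0.0, 0.0)


def _validate_state(y):
    y = np.asarray(y, dtype=float)
    if y.shape != (3,):
        raise DomainError(f"state must have exactly 3 components, got shape {y.shape}")
    for i, name in enumerate(("y1", "y2", "y3")):
        if not math.isfinite(y[i]):
            raise DomainError(f"state component {name} is not finite: {y[i]!r}")
    return y


def rhs_uncontrolled(t, y, p: ModelParameters | None = None) -> np.ndarray:
    """Uncontrolled vector field (gamma1, gamma2, gamma3) at state ``y``.

    ``t`` is accepted for interface uniformity; the field is autonomous.
    """
    if p is None:
        p = ModelParameters()
    y = _validate_state(y)
    y1, y2, y3 = y
    s = p.gamma2_sign
    g1 = (-p.a1 * y1 + p.a2 * y1 * y2 + p.a3 * y2 ** 2 + p.a4 * y2 ** 3
          + p.a5 * y3 + p.a6 * y3 ** 2 + p.a7 * y3 ** 3 + p.a20)
    g2 = (s * p.a8 * y1 * y2 - p.a9 * y1 ** 2 - p.a10 * y1 ** 3
          + p.a11 * y2 * (1.0 - y2) - p.a12 * y3 - p.a13 * y3 ** 2
          - p.a14 * y3 ** 3 + p.a21)
    g3 = (p.a15 * y2 + p.a16 * y2 ** 2 + p.a17 * y2 ** 3
          - p.a18 * y3 - p.a19 * y2 * y3)
    return np.array([g1, g2, g3])


def rhs_controlled(t, y, p: ModelParameters | None = None,
                   g: ControlGains | None = None) -> np.ndarray:
    """Controlled vector field: uncontrolled minus the linear feedback.

    Subtracts ``(d1*(y1+y2), 0, d3*(y1+y3))`` component-wise.
    """
    out = rhs_uncontrolled(t, y, p)
    if g is not None and not g.is_zero:
        y = np.asarray(y, dtype=float)
        out[0] -= g.d1 * (y[0] + y[1])
        out[2] -= g.d3 * (y[0] + y[2])
    return out


def jacobian(t, y, p: ModelParameters | None = None,
             g: ControlGains | None = None) -> np.ndarray:
    """Analytic Jacobian of the controlled vector field at ``y``."""
    if p is None:
        p = ModelParameters()
    y = _validate_state(y)
    y1, y2, y3 = y
    s = p.gamma2_sign
    d1 = g.d1 if g is not None else 0.0
    d3 = g.d3 if g is not None else 0.0
    J = np.empty((3, 3))
    J[0, 0] = -p.a1 + p.a2 * y2 - d1
    J[0, 1] = p.a2 * y1 + 2.0 * p.a3 * y2 + 3.0 * p.a4 * y2 ** 2 - d1
    J[0, 2] = p.a5 + 2.0 * p.a6 * y3 + 3.0 * p.a7 * y3 ** 2
    J[1, 0] = s * p.a8 * y2 - 2.0 * p.a9 * y1 - 3.0 * p.a10 * y1 ** 2
    J[1, 1] = s * p.a8 * y1 + p.a11 * (1.0 - 2.0 * y2)
    J[1, 2] = -p.a12 - 2.0 * p.a13 * y3 - 3.0 * p.a14 * y3 ** 2
    J[2, 0] = -d3
    J[2, 1] = p.a15 + 2.0 * p.a16 * y2 + 3.0 * p.a17 * y2 ** 2 - p.a19 * y3
    J[2, 2] = -p.a18 - p.a19 * y2 - d3
    return J


@dataclass(frozen=True)
class EquilibriumResult:
    """Outcome of the damped-Newton equilibrium search.

    ``converged`` is False when the residual tolerance was not met within
    the iteration budget; ``state`` then holds the best iterate found and
    ``residual`` its sup-norm residual, so a bad root is never silent.
    """

    state: np.ndarray
    residual: float
    converged: bool
    iterations: int


def find_equilibrium(p: ModelParameters | None = None,
                     g: ControlGains | None = None,
                     y_init=(0.0, 0.0, 0.0),
                     tol: float = 1e-10,
                     max_iter: int = 200) -> EquilibriumResult:
    """Damped Newton search for a root of the controlled vector field.

    Uses the analytic Jacobian with backtracking line search (step halving
    until the sup-norm residual decreases).  Returns an
    :class:`EquilibriumResult`; check ``converged`` before trusting the
    root.
    """
    if p is None:
        p = ModelParameters()
    y = _validate_state(y_init).copy()
    f = rhs_controlled(0.0, y, p, g)
    res = float(np.max(np.abs(f)))
    best_y, best_res = y.copy(), res
    it = 0
    for it in range(1, max_iter + 1):
        if best_res < tol:
            break
        J = jacobian(0.0, y, p, g)
        try:
            step = np.linalg.solve(J, -f)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(J, -f, rcond=None)[0]
        lam = 1.0
        improved = False
        for _ in range(40):
            y_new = y + lam * step
            if np.all(np.isfinite(y_new)):
                f_new = rhs_controlled(0.0, y_new, p, g)
                res_new = float(np.max(np.abs(f_new)))
                if res_new < res:
                    y, f, res = y_new, f_new, res_new
                    improved = True
                    break
            lam *= 0.5
        if not improved:
            break
        if res < best_res:
            best_y, best_res = y.copy(), res
    return EquilibriumResult(state=best_y, residual=best_res,
                             converged=best_res < tol, iterations=it)


def make_scalar_rhs(p: ModelParameters | None = None,
                    g: ControlGains | None = None):
    """Closure evaluating the (controlled) RHS on plain floats.

    This is the solver hot path: no array allocation, no validation per
    call.  Returns ``rhs(t, y1, y2, y3) -> (f1, f2, f3)``.
    """
    if p is None:
        p = ModelParameters()
    a1, a2, a3, a4, a5, a6, a7 = p.a1, p.a2, p.a3, p.a4, p.a5, p.a6, p.a7
    a8s = p.gamma2_sign * p.a8
    a9, a10, a11, a12, a13, a14 = p.a9, p.a10, p.a11, p.a12, p.a13, p.a14
    a15, a16, a17, a18, a19 = p.a15, p.a16, p.a17, p.a18, p.a19
    a20, a21 = p.a20, p.a21
    d1 = g.d1 if g is not None else 0.0
    d3 = g.d3 if g is not None else 0.0

    def rhs(t, y1, y2, y3):
        y2sq = y2 * y2
        y3sq = y3 * y3
        f1 = (-a1 * y1 + a2 * y1 * y2 + a3 * y2sq + a4 * y2sq * y2
              + a5 * y3 + a6 * y3sq + a7 * y3sq * y3 + a20
              - d1 * (y1 + y2))
        f2 = (a8s * y1 * y2 - a9 * y1 * y1 - a10 * y1 * y1 * y1
              + a11 * y2 * (1.0 - y2) - a12 * y3 - a13 * y3sq
              - a14 * y3sq * y3 + a21)
        f3 = (a15 * y2 + a16 * y2sq + a17 * y2sq * y2
              - a18 * y3 - a19 * y2 * y3 - d3 * (y1 + y3))
        return f1, f2, f3

    return rhs
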