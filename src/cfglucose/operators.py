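"""Caputo-Fabrizio fractal-fractional operator ingredients.

The Caputo-Fabrizio (CF) derivative replaces the power-law kernel of the
classical Caputo operator with the non-singular exponential kernel
``exp(-alpha*(t - mu)/(1 - alpha))``, normalized by
``Bhat(alpha) = 1 - alpha + alpha/Gamma(alpha)``.  The fractal-fractional
(FF) extension differentiates with respect to ``t**beta`` instead of
``t``; in the variable-order (VO) formulation the fractal exponent
``beta(t)`` evolves with time, modeling time-varying memory intensity
(e.g. circadian changes in insulin sensitivity).

This module provides the scalar building blocks used by both integrators:

* :func:`bhat` - the CF normalization constant;
* the shipped ``beta(t)`` profiles and their derivatives
  (:func:`beta_eval`, :func:`beta_derivative`);
* the identity ``d/dt t**beta(t) = t**beta(t) * (beta'(t) ln t + beta(t)/t)``
  (:func:`t_pow_beta_rate`);
* the VO kernel coefficient ``kappa_n`` and the auxiliary integrand
  ``g_n`` (:func:`kappa`, :func:`g_term`);
* the CF-FF integral as a reference quadrature (:func:`cf_ff_integral`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Union

import numpy as np

from .errors import ConfigurationError, DomainError

__all__ = [
    "BETA_MIN",
    "PROFILES",
    "FractionalOrderSpec",
    "VOKernelTerms",
    "bhat",
    "beta_eval",
    "beta_derivative",
    "t_pow_beta_rate",
    "kappa",
    "g_term",
    "cf_ff_integral",
]

#: Lower clip for beta(t): keeps exponents t**(beta-1) finite and the
#: fractal order inside (0, 1].  None of the shipped profiles ever reach it.
BETA_MIN = 1e-3


def bhat(alpha: float) -> float:
    """CF normalization ``Bhat(alpha) = 1 - alpha + alpha/Gamma(alpha)``.

    Equals 1 exactly at both endpoints: at ``alpha=1`` trivially, and at
    ``alpha=0`` as the continuous limit (``alpha/Gamma(alpha) ->
    alpha**2/Gamma(alpha+1) -> 0``).
    """
    if not (0.0 <= alpha <= 1.0) or not math.isfinite(alpha):
        raise DomainError(f"alpha must lie in [0, 1], got {alpha!r}")
    if alpha == 0.0:
        return 1.0
    if alpha == 1.0:
        return 1.0
    return 1.0 - alpha + alpha / math.gamma(alpha)


# --- beta(t) profiles ------------------------------------------------------

def _sigmoid(t):
    return 1.0 / (1.0 + math.exp(-t))


#: Named variable-order profiles: name -> (value, analytic derivative).
PROFILES: dict[str, tuple[Callable[[float], float], Callable[[float], float]]] = {
    # slow circadian-like oscillation
    "cos_slow": (lambda t: 0.97 + 0.03 * math.cos(t / 10.0),
                 lambda t: -0.003 * math.sin(t / 10.0)),
    # faster oscillation used in the worked kernel-coefficient example
    "cos_fast": (lambda t: 0.95 + 0.02 * math.cos(t),
                 lambda t: -0.02 * math.sin(t)),
    # gradual memory accumulation
    "tanh1p": (lambda t: math.tanh(1.0 + t),
               lambda t: 1.0 / math.cosh(1.0 + t) ** 2),
    # sigmoidal adaptation
    "sigmoid": (_sigmoid,
                lambda t: _sigmoid(t) * (1.0 - _sigmoid(t))),
}


def _resolve_profile(beta, beta_prime=None):
    """Normalize a beta specification to ``(value_fn, deriv_fn_or_None,
    constant_or_None)``; raw (unclipped) functions."""
    if isinstance(beta, (int, float)):
        b = float(beta)
        return (lambda t: b), (lambda t: 0.0), b
    if isinstance(beta, str):
        if beta.startswith("const:"):
            try:
                b = float(beta.split(":", 1)[1])
            except ValueError:
                raise ConfigurationError(f"malformed constant profile {beta!r}")
            return (lambda t: b), (lambda t: 0.0), b
        if beta in PROFILES:
            fn, dfn = PROFILES[beta]
            return fn, dfn, None
        raise ConfigurationError(
            f"unknown beta profile {beta!r}; known: "
            f"{sorted(PROFILES)} or 'const:<value>'"
        )
    if callable(beta):
        return beta, beta_prime, None
    raise ConfigurationError(f"cannot interpret beta profile {beta!r}")


@dataclass(frozen=True)
class FractionalOrderSpec:
    """Fractional order ``alpha`` and fractal exponent profile ``beta(t)``.

    ``beta`` may be a number, a named profile (``'cos_slow'``,
    ``'cos_fast'``, ``'tanh1p'``, ``'sigmoid'``, ``'const:<v>'``) or a
    callable ``t -> beta``; for callables an analytic derivative can be
    supplied via ``beta_prime``.  ``beta_derivative_mode`` selects how
    ``beta'`` is evaluated in :func:`g_term` and
    :func:`t_pow_beta_rate`: ``'forward_difference'`` (default, matching
    the discrete kernel coefficient) or ``'analytic'``.
    """

    alpha: float = 1.0
    beta: Union[float, str, Callable[[float], float]] = 1.0
    beta_derivative_mode: str = "forward_difference"
    beta_prime: Optional[Callable[[float], float]] = None

    def __post_init__(self):
        if not (0.0 < self.alpha <= 1.0):
            raise ConfigurationError(
                f"alpha must lie in (0, 1], got {self.alpha!r}")
        if self.beta_derivative_mode not in ("forward_difference", "analytic"):
            raise ConfigurationError(
                "beta_derivative_mode must be 'forward_difference' or "
                f"'analytic', got {self.beta_derivative_mode!r}")
        # fail early on unknown profile names
        _resolve_profile(self.beta, self.beta_prime)

    def constant_beta(self) -> Optional[float]:
        """Clipped beta value if the profile is constant, else None."""
        _, _, const = _resolve_profile(self.beta, self.beta_prime)
        if const is None:
            return None
        return min(1.0, max(BETA_MIN, const))

    def beta_function(self) -> Callable[[float], float]:
        """Clipped value function ``t -> beta(t)``."""
        fn, _, _ = _resolve_profile(self.beta, self.beta_prime)
        return lambda t: min(1.0, max(BETA_MIN, fn(t)))

    def beta_prime_function(self) -> Optional[Callable[[float], float]]:
        """Analytic derivative of the raw profile, if available."""
        _, dfn, _ = _resolve_profile(self.beta, self.beta_prime)
        return dfn


@dataclass(frozen=True)
class VOKernelTerms:
    """Kernel coefficient and auxiliary integrand at one VO node."""

    kappa_n: float
    g_n: float


def beta_eval(spec: FractionalOrderSpec, t: float) -> float:
    """Profile value at ``t``, clipped to ``[BETA_MIN, 1]``."""
    if t < 0:
        raise DomainError(f"t must be non-negative, got {t!r}")
    return spec.beta_function()(t)


def beta_derivative(spec: FractionalOrderSpec, t: float,
                    dt: float | None = None) -> float:
    """``beta'(t)`` per the spec's derivative mode.

    Forward-difference mode returns ``(beta(t+dt) - beta(t))/dt`` on the
    clipped profile (first-order accurate, exactly the slope used by the
    discrete kernel coefficient); analytic mode returns the closed-form
    derivative of the raw profile.
    """
    if t < 0:
        raise DomainError(f"t must be non-negative, got {t!r}")
    if spec.beta_derivative_mode == "analytic":
        dfn = spec.beta_prime_function()
        if dfn is None:
            raise ConfigurationError(
                "analytic beta derivative requested but no closed form is "
                "available for this profile; supply beta_prime or use "
                "forward_difference mode")
        return dfn(t)
    if dt is None or dt <= 0:
        raise DomainError("forward_difference mode requires dt > 0")
    fn = spec.beta_function()
    return (fn(t + dt) - fn(t)) / dt


def t_pow_beta_rate(spec: FractionalOrderSpec, t: float,
                    dt: float = 1e-6) -> float:
    """``d/dt t**beta(t) = t**beta(t) * (beta'(t) ln t + beta(t)/t)``.

    Singular at ``t = 0``; ``dt`` is the step used when the derivative
    mode is forward-difference.
    """
    if t <= 0:
        raise DomainError(f"the identity requires t > 0, got {t!r}")
    b = beta_eval(spec, t)
    bp = beta_derivative(spec, t, dt)
    return t ** b * (bp * math.log(t) + b / t)


def kappa(spec: FractionalOrderSpec, t_n: float, dt: float) -> float:
    """VO kernel coefficient at node ``t_n``:

    ``kappa_n = t_n**beta(t_n) * ( (beta(t_n+dt)-beta(t_n))/dt * ln t_n
    + beta(t_n)/t_n )``, with the forward-difference slope exactly as in
    the discrete scheme.  Undefined at ``t_n <= 0`` (the solver handles
    the initial node separately).
    """
    if t_n <= 0:
        raise DomainError(f"kappa requires t_n > 0, got {t_n!r}")
    if dt <= 0:
        raise DomainError(f"dt must be positive, got {dt!r}")
    fn = spec.beta_function()
    b = fn(t_n)
    slope = (fn(t_n + dt) - fn(t_n)) / dt
    return t_n ** b * (slope * math.log(t_n) + b / t_n)


def g_term(spec: FractionalOrderSpec, t_n: float, dt: float,
           h_val: float) -> float:
    """Auxiliary VO integrand
    ``g_n = h_val * (beta'(t_n) ln t_n + beta(t_n)/t_n) * t_n**beta(t_n)``.

    ``beta'`` follows ``spec.beta_derivative_mode``; in the default
    forward-difference mode this equals ``h_val * kappa(spec, t_n, dt)``
    identically.
    """
    if t_n <= 0:
        raise DomainError(f"g_term requires t_n > 0, got {t_n!r}")
    b = beta_eval(spec, t_n)
    bp = beta_derivative(spec, t_n, dt)
    return h_val * (bp * math.log(t_n) + b / t_n) * t_n ** b


def vo_kernel_terms(spec: FractionalOrderSpec, t_n: float, dt: float,
                    h_val: float) -> VOKernelTerms:
    """Convenience bundle of ``kappa_n`` and ``g_n`` at one node."""
    return VOKernelTerms(kappa_n=kappa(spec, t_n, dt),
                         g_n=g_term(spec, t_n, dt, h_val))


def cf_ff_integral(f, alpha: float, beta: float, t: float) -> float:
    """CF-FF integral of a sampled function on ``[0, t]``:

    ``alpha*beta/Bhat(alpha) * int_0^t mu**(alpha-1) f(mu) dmu
    + beta*(1-alpha)*t**(beta-1)/Bhat(alpha) * f(t)``.

    ``f`` holds samples on a uniform grid over ``[0, t]``.  The weakly
    singular integral is evaluated by product integration: exact moments
    of ``mu**(alpha-1)`` against the piecewise-linear interpolant of the
    samples (the trapezoid-rule analogue that remains well defined at the
    ``mu = 0`` endpoint).  Reference/validation utility; not used on the
    solver hot path.
    """
    f = np.asarray(f, dtype=float)
    if f.ndim != 1 or f.size == 0:
        raise DomainError("f must be a non-empty 1-D sample array")
    if not (0.0 < alpha <= 1.0):
        raise DomainError(f"alpha must lie in (0, 1], got {alpha!r}")
    if t <= 0:
        raise DomainError(f"t must be positive, got {t!r}")
    if f.size == 1:
        raise DomainError("need at least two samples to integrate")
    n = f.size - 1
    h = t / n
    mu = np.linspace(0.0, t, n + 1)
    a, b = mu[:-1], mu[1:]
    c1 = (f[1:] - f[:-1]) / h
    c0 = f[:-1] - c1 * a
    m0 = (b ** alpha - a ** alpha) / alpha
    m1 = (b ** (alpha + 1) - a ** (alpha + 1)) / (alpha + 1)
    integral = float(np.sum(c0 * m0 + c1 * m1))
    bh = bhat(alpha)
    local = beta * (1.0 - alpha) * t ** (beta - 1.0) / bh * float(f[-1])
    return alpha * beta / bh * integral + local
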