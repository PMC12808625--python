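"""Linearization-based feedback design.

The chaotic regulatory system is stabilized by linear state feedback
``u = -K z`` with gain row ``K = [d1, 0, d3]`` entering through the input
map ``B``, giving the closed-loop matrix ``A_cl = A - B K``.  Gains are
tuned proportionally to the dominant unstable eigenvalue:
``d_i = k_i * |Re(lambda_max)|`` with ``k_i in [0.1, 0.3]``.

Eigenvalues are always computed with a dense eigensolver and
cross-checked against the trace identity; published closed-loop spectra
for this example are known to be inconsistent with the trace of the
printed matrices and are never asserted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError
from .model import ControlGains

__all__ = [
    "NOMINAL_A",
    "NOMINAL_B",
    "LinearSystem",
    "SpectralReport",
    "gain_row",
    "closed_loop",
    "spectrum",
    "tune_gains",
    "gain_sweep",
    "stability_boundary",
]

#: Nominal linearized glucose subsystem of the worked gain-tuning example.
NOMINAL_A = np.array([
    [0.0, 1.0, 0.0],
    [-2.0, -0.1, 1.0],
    [0.0, -3.0, -0.2],
])

#: Input map of the worked example (feedback enters the second equation).
NOMINAL_B = np.array([[0.0], [1.0], [0.0]])


@dataclass(frozen=True)
class LinearSystem:
    """State matrix, input map and gain row of the feedback loop."""

    A: np.ndarray
    B: np.ndarray
    K: np.ndarray

    def __post_init__(self):
        A = np.asarray(self.A, dtype=float)
        B = np.asarray(self.B, dtype=float).reshape(-1, 1)
        K = np.asarray(self.K, dtype=float).reshape(1, -1)
        if A.shape != (3, 3) or B.shape != (3, 1) or K.shape != (1, 3):
            raise DomainError("expected A: 3x3, B: 3x1, K: 1x3")
        if K[0, 1] != 0.0:
            raise DomainError("the middle entry of the gain row must be 0")
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "B", B)
        object.__setattr__(self, "K", K)

    @property
    def closed_loop_matrix(self) -> np.ndarray:
        return closed_loop(self.A, self.B, self.K)


@dataclass(frozen=True)
class SpectralReport:
    """Eigenvalues (sorted by descending real part), abscissa, stability."""

    eigenvalues: tuple
    spectral_abscissa: float
    stable: bool


def gain_row(g: ControlGains) -> np.ndarray:
    """Gain row ``[d1, 0, d3]`` for a :class:`ControlGains`."""
    return np.array([[g.d1, 0.0, g.d3]])


def closed_loop(A, B, K) -> np.ndarray:
    """Closed-loop matrix ``A - B K``.

    ``B`` may be a column or flat 3-vector, ``K`` a row or flat 3-vector
    or a :class:`ControlGains` (expanded to ``[d1, 0, d3]``).
    """
    A = np.asarray(A, dtype=float)
    if isinstance(K, ControlGains):
        K = gain_row(K)
    B = np.asarray(B, dtype=float).reshape(-1, 1)
    K = np.asarray(K, dtype=float).reshape(1, -1)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise DomainError(f"A must be square, got shape {A.shape}")
    if B.shape[0] != A.shape[0] or K.shape[1] != A.shape[1]:
        raise DomainError(
            f"shape mismatch: A {A.shape}, B {B.shape}, K {K.shape}")
    return A - B @ K


def spectrum(M) -> SpectralReport:
    """Eigenvalues of ``M`` via a dense eigensolver, with stability flag.

    The spectral abscissa is the maximum real part; ``stable`` means it is
    strictly negative.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise DomainError(f"matrix must be square, got shape {M.shape}")
    if not np.all(np.isfinite(M)):
        raise DomainError("matrix has non-finite entries")
    eig = np.linalg.eigvals(M)
    order = np.argsort(-eig.real)
    eig = eig[order]
    abscissa = float(eig[0].real)
    return SpectralReport(eigenvalues=tuple(complex(v) for v in eig),
                          spectral_abscissa=abscissa,
                          stable=abscissa < 0.0)


def tune_gains(lambda_max_re: float, k1: float, k3: float) -> ControlGains:
    """Proportional rule ``d_i = k_i * |Re(lambda_max)|``.

    ``k1``/``k3`` outside the recommended range [0.1, 0.3] only warn (via
    :class:`ControlGains`), since applied gains in practice may exceed the
    rule.
    """
    mag = abs(lambda_max_re)
    return ControlGains(d1=k1 * mag, d3=k3 * mag, k1=k1, k3=k3)


def gain_sweep(A, B, d1_grid, d3_grid) -> pd.DataFrame:
    """Spectral abscissa of ``A - B [d1, 0, d3]`` over a gain grid.

    Returns a DataFrame with columns ``d1, d3, spectral_abscissa,
    stable``, one row per grid point (row-major over ``d1_grid`` then
    ``d3_grid``).
    """
    rows = []
    for d1 in np.asarray(d1_grid, dtype=float).ravel():
        for d3 in np.asarray(d3_grid, dtype=float).ravel():
            rep = spectrum(closed_loop(A, B, [d1, 0.0, d3]))
            rows.append({"d1": d1, "d3": d3,
                         "spectral_abscissa": rep.spectral_abscissa,
                         "stable": rep.stable})
    return pd.DataFrame(rows)


def stability_boundary(sweep: pd.DataFrame) -> pd.DataFrame:
    """Rows of a gain sweep adjacent to a sign change of the abscissa.

    Consecutive rows (in sweep order) whose abscissae differ in sign
    bracket the stability boundary; both members of each bracketing pair
    are returned.
    """
    a = sweep["spectral_abscissa"].to_numpy()
    flips = np.nonzero(np.sign(a[:-1]) * np.sign(a[1:]) < 0)[0]
    idx = sorted(set(flips) | set(flips + 1))
    return sweep.iloc[idx].reset_index(drop=True)
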