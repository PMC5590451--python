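"""Numerical integrators: forward-Euler (SFD), exact NSFD schemes, and RK45.

The nonstandard finite-difference (NSFD) scheme replaces the forward-difference
denominator ``h`` with a denominator function ``phi(h) = h + O(h^2)`` and
weights the previous iterate by ``varphi(h) = 1 + O(h)``:

    (u_{n+1} - varphi(h) u_n) / phi(h) = A u_n  (+ forcing)

Choosing phi and varphi from the system's own eigenvalues makes the one-step
map equal to the exact flow ``exp(A h)``, so the scheme reproduces the
continuous solution at every node for ANY step size — an "exact" scheme in
Mickens' sense.  The weights must be built from the matrix eigenvalues
``mu = -lam < 0`` (decaying exponentials); see :mod:`nsfdpk.analytic`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .analytic import general_solution, propagator_weights
from .model import (
    DoseMode,
    DoseRegimen,
    PKParameters,
    build_rate_matrix,
    eigen_decompose,
)

__all__ = [
    "Grid",
    "Method",
    "SchemeCoefficients",
    "Trajectory",
    "sfd_integrate",
    "nsfd_coefficients",
    "nsfd_step_matrix",
    "nsfd_integrate",
    "nsfd_integrate_bolus",
    "nsfd_integrate_infusion",
    "nsfd_integrate_infusion_substitution",
    "rk45_integrate",
    "RK45_RTOL",
    "RK45_ATOL",
]

# defaults chosen so the adaptive reference tracks the closed form to ~1e-8
# on the benchmark problems (see docs/methods.md)
RK45_RTOL = 1e-6
RK45_ATOL = 1e-9


@dataclass(frozen=True)
class Grid:
    """Uniform time grid t_n = t0 + n*h, n = 0..N."""

    h: float
    N: int
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.h <= 0:
            raise ValueError("step size h must be positive")
        if self.N < 1:
            raise ValueError("N must be >= 1")

    @property
    def T(self) -> float:
        return self.t0 + self.N * self.h

    @property
    def nodes(self) -> np.ndarray:
        return self.t0 + self.h * np.arange(self.N + 1)

    @classmethod
    def from_N(cls, N: int, T: float, t0: float = 0.0) -> "Grid":
        """Grid with exactly N steps covering [t0, t0+T]; h = T/N exactly."""
        return cls(h=T / N, N=N, t0=t0)

    @classmethod
    def from_h(cls, h: float, T: float, t0: float = 0.0) -> "Grid":
        """Grid of step h covering [t0, t0+T]; T must be an integer multiple of h."""
        if h <= 0:
            raise ValueError("step size h must be positive")
        N = round(T / h)
        if N < 1 or abs(N * h - T) > 1e-9 * max(T, 1.0):
            raise ValueError(f"horizon T={T} is not an integer multiple of h={h}")
        return cls(h=h, N=N, t0=t0)


class Method(str, Enum):
    ANALYTIC = "analytic"
    SFD = "sfd"
    NSFD = "nsfd"
    RK45 = "rk45"


@dataclass(frozen=True)
class SchemeCoefficients:
    """NSFD denominator function phi(h) (time-like) and weight varphi(h)."""

    phi_denom: float
    phi_weight: float


@dataclass
class Trajectory:
    """Node times and per-compartment concentrations for one method."""

    grid: Grid
    c: np.ndarray
    p: np.ndarray
    method: Method

    def __post_init__(self) -> None:
        n = self.grid.N + 1
        if len(self.c) != n or len(self.p) != n:
            raise ValueError("c and p must have N+1 entries")

    @property
    def t(self) -> np.ndarray:
        return self.grid.nodes

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "c": self.c, "p": self.p})


def _forcing(regimen: DoseRegimen) -> np.ndarray:
    return np.array([regimen.I0, 0.0])


def sfd_integrate(
    params: PKParameters, regimen: DoseRegimen, grid: Grid
) -> Trajectory:
    """Explicit forward-Euler recursion u_{n+1} = u_n + h (A u_n + forcing).

    Blow-up or oscillation at large h is genuine behavior of this scheme and
    is not guarded against.
    """
    A = build_rate_matrix(params).as_array()
    b = _forcing(regimen)
    u = np.empty((grid.N + 1, 2))
    u[0] = regimen.initial_state
    h = grid.h
    for n in range(grid.N):
        u[n + 1] = u[n] + h * (A @ u[n] + b)
    return Trajectory(grid=grid, c=u[:, 0], p=u[:, 1], method=Method.SFD)


def nsfd_coefficients(params: PKParameters, h: float) -> SchemeCoefficients:
    """Exact-scheme coefficients phi(h), varphi(h) from the matrix eigenvalues.

    With distinct eigenvalues mu1 != mu2:

        phi    = (e^{mu1 h} - e^{mu2 h}) / (mu1 - mu2)
        varphi = (mu1 e^{mu2 h} - mu2 e^{mu1 h}) / (mu1 - mu2)

    and the confluent limit phi = h e^{mu h}, varphi = (1 - mu h) e^{mu h}.
    Both satisfy the Mickens contracts phi(h) = h + O(h^2), varphi = 1 + O(h),
    and varphi*I + phi*A is exactly exp(A h).
    """
    if h <= 0:
        raise ValueError("step size h must be positive")
    eig = eigen_decompose(params)
    varphi, phi = propagator_weights(eig, h)
    return SchemeCoefficients(phi_denom=float(phi), phi_weight=float(varphi))


def nsfd_step_matrix(params: PKParameters, h: float) -> np.ndarray:
    """One-step matrix M = varphi(h) I + phi(h) A = exp(A h)."""
    co = nsfd_coefficients(params, h)
    A = build_rate_matrix(params).as_array()
    return co.phi_weight * np.eye(2) + co.phi_denom * A


def nsfd_integrate_bolus(
    params: PKParameters, regimen: DoseRegimen, grid: Grid
) -> Trajectory:
    """Exact NSFD scheme for the homogeneous (bolus) system.

    Update: (u_{n+1} - varphi u_n)/phi = A u_n, i.e. u_{n+1} = M u_n with
    M = exp(A h); every node coincides with the closed form.
    """
    if regimen.mode != DoseMode.BOLUS:
        raise ValueError("bolus scheme requires a bolus regimen")
    M = nsfd_step_matrix(params, grid.h)
    u = np.empty((grid.N + 1, 2))
    u[0] = regimen.initial_state
    for n in range(grid.N):
        u[n + 1] = M @ u[n]
    return Trajectory(grid=grid, c=u[:, 0], p=u[:, 1], method=Method.NSFD)


def nsfd_integrate_infusion(
    params: PKParameters, regimen: DoseRegimen, grid: Grid
) -> Trajectory:
    """Exact NSFD scheme for the constant-infusion system.

    The one-step map is the exact affine flow over h:
    u_{k+1} = M u_k + (M - I) A^{-1} b with b = (I0, 0), whose fixed point is
    the steady state -A^{-1} b.  A is invertible because det A = k10*k21 > 0.
    """
    if regimen.mode != DoseMode.INFUSION:
        raise ValueError("infusion scheme requires an infusion regimen")
    A = build_rate_matrix(params).as_array()
    det = params.k10 * params.k21
    if det == 0.0:
        raise ValueError("k10*k21 must be nonzero for the infusion scheme")
    M = nsfd_step_matrix(params, grid.h)
    b = _forcing(regimen)
    v = (M - np.eye(2)) @ np.linalg.solve(A, b)
    u = np.empty((grid.N + 1, 2))
    u[0] = regimen.initial_state
    for n in range(grid.N):
        u[n + 1] = M @ u[n] + v
    return Trajectory(grid=grid, c=u[:, 0], p=u[:, 1], method=Method.NSFD)


def nsfd_integrate_infusion_substitution(
    params: PKParameters, regimen: DoseRegimen, grid: Grid
) -> Trajectory:
    """Infusion NSFD via node substitution into the general closed form.

    Alternative formulation used for cross-validation: each step evaluates
    the exact solution over an interval of length h starting from the current
    node, (c_k, p_k) -> exact solution at time h.  Agrees with
    :func:`nsfd_integrate_infusion` to rounding.
    """
    if regimen.mode != DoseMode.INFUSION:
        raise ValueError("infusion scheme requires an infusion regimen")
    u = np.empty((grid.N + 1, 2))
    u[0] = regimen.initial_state
    for n in range(grid.N):
        c_next, p_next = general_solution(
            params, grid.h, u[n, 0], u[n, 1], regimen.I0
        )
        u[n + 1] = (float(c_next), float(p_next))
    return Trajectory(grid=grid, c=u[:, 0], p=u[:, 1], method=Method.NSFD)


def nsfd_integrate(
    params: PKParameters, regimen: DoseRegimen, grid: Grid
) -> Trajectory:
    """Dispatch to the bolus or infusion exact scheme by regimen mode."""
    if regimen.mode == DoseMode.BOLUS:
        return nsfd_integrate_bolus(params, regimen, grid)
    return nsfd_integrate_infusion(params, regimen, grid)


def rk45_integrate(
    params: PKParameters,
    regimen: DoseRegimen,
    grid: Grid,
    rtol: float = RK45_RTOL,
    atol: float = RK45_ATOL,
) -> Trajectory:
    """Adaptive Dormand–Prince reference solution sampled at the grid nodes.

    A conventional embedded Runge–Kutta 4(5) pair with dense output; offers no
    exactness guarantee, only tolerance-controlled accuracy.
    """
    A = build_rate_matrix(params).as_array()
    b = _forcing(regimen)
    nodes = grid.nodes
    sol = solve_ivp(
        lambda t, u: A @ u + b,
        (nodes[0], nodes[-1]),
        regimen.initial_state,
        method="RK45",
        rtol=rtol,
        atol=atol,
        dense_output=True,
    )
    vals = sol.sol(nodes)
    return Trajectory(grid=grid, c=vals[0], p=vals[1], method=Method.RK45)


def analytic_trajectory(
    params: PKParameters, regimen: DoseRegimen, grid: Grid
) -> Trajectory:
    """Closed-form solution sampled on the grid, packaged as a Trajectory."""
    c, p = general_solution(params, grid.nodes, regimen.c0, regimen.p0, regimen.I0)
    return Trajectory(grid=grid, c=np.asarray(c), p=np.asarray(p), method=Method.ANALYTIC)
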