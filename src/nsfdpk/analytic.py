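"""Closed-form solutions of the two-compartment model.

These are the ground truth against which every numerical scheme is measured.

The homogeneous propagator ``Phi(t) = exp(A*t)`` of a 2x2 matrix with
eigenvalues ``mu1, mu2`` has the Lagrange–Sylvester representation

    Phi(t) = varphi(t) * I + phi(t) * A

with scalar weights

    phi(t)    = (exp(mu1 t) - exp(mu2 t)) / (mu1 - mu2)
    varphi(t) = (mu1 exp(mu2 t) - mu2 exp(mu1 t)) / (mu1 - mu2)

and the confluent limit ``phi = t*exp(mu t)``, ``varphi = (1 - mu t) exp(mu t)``
for a repeated eigenvalue.  The general solution with constant infusion is then
``u(t) = u* + Phi(t) (u0 - u*)`` where ``u*`` is the steady state — a form that
stays exact in floating point as t -> infinity because the transient is a pure
product of decaying exponentials (no subtraction of large terms).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    DoseRegimen,
    EigenSystem,
    PKParameters,
    build_rate_matrix,
    eigen_decompose,
    equilibrium,
)

__all__ = [
    "Case1Coefficients",
    "Case2Coefficients",
    "case1_coefficients",
    "case2_coefficients",
    "propagator_weights",
    "bolus_solution",
    "infusion_solution",
    "infusion_solution_modal",
    "general_solution",
]


@dataclass(frozen=True)
class Case1Coefficients:
    """Bolus mode weights: c(t) = E e^{-lam1 t} + (1-E) e^{-lam2 t}."""

    E: float
    lam1: float
    lam2: float


@dataclass(frozen=True)
class Case2Coefficients:
    """Infusion mode amplitudes: c(t) = I0/k10 + A1 tau1 e^{mu1 t} + A2 tau2 e^{mu2 t}."""

    A1: float
    A2: float
    tau1: float
    tau2: float
    c_part: float
    p_part: float


def case1_coefficients(params: PKParameters) -> Case1Coefficients:
    """Modal weights of the bolus closed form, E = (lam1 - k21)/(lam1 - lam2)."""
    eig = eigen_decompose(params)
    if eig.repeated:
        raise ValueError("modal weights undefined for a repeated eigenvalue; "
                         "use general_solution")
    E = (eig.lam1 - params.k21) / (eig.lam1 - eig.lam2)
    return Case1Coefficients(E=E, lam1=eig.lam1, lam2=eig.lam2)


def case2_coefficients(params: PKParameters, I0: float) -> Case2Coefficients:
    """Infusion-mode amplitudes from the zero initial condition.

    A1 = (I0/k10) (k12 tau2 - k21) / (k21 (tau1 - tau2)) and
    A2 = (I0/k10) (k21 - k12 tau1) / (k21 (tau1 - tau2)), with tau the first
    eigenvector components.  Requires k12 > 0 (otherwise the eigenvectors
    cannot be scaled to unit second component).
    """
    if I0 <= 0:
        raise ValueError("infusion coefficients require I0 > 0")
    if params.k12 <= 0:
        raise ValueError("modal amplitudes require k12 > 0; use general_solution")
    eig = eigen_decompose(params)
    eq = equilibrium(params, DoseRegimen.infusion(I0))
    k12, k21, k10 = params.k12, params.k21, params.k10
    tau1, tau2 = eig.tau1, eig.tau2
    A1 = (I0 / k10) * (k12 * tau2 - k21) / (k21 * (tau1 - tau2))
    A2 = (I0 / k10) * (k21 - k12 * tau1) / (k21 * (tau1 - tau2))
    return Case2Coefficients(A1=A1, A2=A2, tau1=tau1, tau2=tau2,
                             c_part=eq.c_star, p_part=eq.p_star)


def propagator_weights(eig: EigenSystem, t: np.ndarray | float) -> tuple[np.ndarray, np.ndarray]:
    """Scalar weights (varphi, phi) with exp(A t) = varphi*I + phi*A.

    Vectorized over t; handles the repeated-eigenvalue limit exactly.
    """
    t = np.asarray(t, dtype=float)
    mu1, mu2 = eig.mu1, eig.mu2
    if eig.repeated:
        e = np.exp(mu1 * t)
        phi = t * e
        varphi = (1.0 - mu1 * t) * e
    else:
        e1, e2 = np.exp(mu1 * t), np.exp(mu2 * t)
        phi = (e1 - e2) / (mu1 - mu2)
        varphi = (mu1 * e2 - mu2 * e1) / (mu1 - mu2)
    return varphi, phi


def _check_times(t: np.ndarray | float) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be nonnegative")
    return t


def general_solution(
    params: PKParameters,
    t: np.ndarray | float,
    c_init: float,
    p_init: float,
    I0: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact solution from an arbitrary initial state, with or without infusion.

    Returns (c, p) with the shape of ``t``.  The infusion steady state is
    subtracted before propagation so both compartments decay monotonically to
    their limits without catastrophic cancellation at large t.
    """
    t = _check_times(t)
    if I0 < 0:
        raise ValueError("infusion rate must be nonnegative")
    eig = eigen_decompose(params)
    A = build_rate_matrix(params).as_array()
    if I0 > 0:
        eq = equilibrium(params, DoseRegimen.infusion(I0))
        u_star = eq.as_array()
    else:
        u_star = np.zeros(2)
    d0 = np.array([c_init, p_init]) - u_star
    varphi, phi = propagator_weights(eig, t)
    # Phi(t) @ d0, expanded per component so t may be any shape
    c_dev = varphi * d0[0] + phi * (A[0, 0] * d0[0] + A[0, 1] * d0[1])
    p_dev = varphi * d0[1] + phi * (A[1, 0] * d0[0] + A[1, 1] * d0[1])
    return u_star[0] + c_dev, u_star[1] + p_dev


def bolus_solution(
    params: PKParameters, t: np.ndarray | float
) -> tuple[np.ndarray, np.ndarray]:
    """Bolus closed form with c(0)=1, p(0)=0.

    c(t) = E e^{-lam1 t} + (1-E) e^{-lam2 t} and
    p(t) = k12/(lam2 - lam1) (e^{-lam1 t} - e^{-lam2 t}); falls back to the
    propagator form when the eigenvalue is repeated (k12 = 0, k10 = k21).
    """
    t = _check_times(t)
    eig = eigen_decompose(params)
    if eig.repeated:
        return general_solution(params, t, 1.0, 0.0, 0.0)
    co = case1_coefficients(params)
    e1, e2 = np.exp(-co.lam1 * t), np.exp(-co.lam2 * t)
    c = co.E * e1 + (1.0 - co.E) * e2
    p = params.k12 / (co.lam2 - co.lam1) * (e1 - e2)
    return c, p


def infusion_solution(
    params: PKParameters, I0: float, t: np.ndarray | float
) -> tuple[np.ndarray, np.ndarray]:
    """Infusion closed form with c(0)=p(0)=0 and constant input rate I0 > 0.

    Algebraically this is the modal form
    c(t) = I0/k10 + A1 tau1 e^{mu1 t} + A2 tau2 e^{mu2 t},
    p(t) = k12 I0/(k10 k21) + A1 e^{mu1 t} + A2 e^{mu2 t}
    (see :func:`case2_coefficients`), but it is evaluated through the
    propagator form of :func:`general_solution`: the modal amplitudes scale
    like 1/k12 and cancel catastrophically for small transfer rates, while
    the propagator form is uniformly well-conditioned (and covers k12 = 0,
    where no modal amplitudes exist).  :func:`infusion_solution_modal` keeps
    the literal modal evaluation for cross-validation.
    """
    if I0 <= 0:
        raise ValueError("infusion requires I0 > 0")
    t = _check_times(t)
    return general_solution(params, t, 0.0, 0.0, I0)


def infusion_solution_modal(
    params: PKParameters, I0: float, t: np.ndarray | float
) -> tuple[np.ndarray, np.ndarray]:
    """Literal modal evaluation of the infusion closed form (requires k12 > 0).

    Cross-validation path only; prefer :func:`infusion_solution`, which is
    well-conditioned for small k12.
    """
    t = _check_times(t)
    co = case2_coefficients(params, I0)
    eig = eigen_decompose(params)
    e1, e2 = np.exp(eig.mu1 * t), np.exp(eig.mu2 * t)
    c = co.c_part + co.A1 * co.tau1 * e1 + co.A2 * co.tau2 * e2
    p = co.p_part + co.A1 * e1 + co.A2 * e2
    return c, p


def solution_for(
    params: PKParameters, regimen: DoseRegimen, t: np.ndarray | float
) -> tuple[np.ndarray, np.ndarray]:
    """Exact solution for an arbitrary regimen (dispatch on its initial state and I0)."""
    return general_solution(params, t, regimen.c0, regimen.p0, regimen.I0)
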