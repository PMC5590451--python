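"""Two-compartment pharmacokinetic model: rate matrix, eigenstructure, equilibria.

The model tracks the drug concentration in a central (plasma) compartment
``c`` and a peripheral (tissue) compartment ``p``, exchanging by first-order
transfer and eliminated from the central compartment only::

    dc/dt = k21*p - k12*c - k10*c + I(t)
    dp/dt = k12*c - k21*p

with ``I(t) = 0`` for an I.V. bolus (the dose enters as the initial condition
``c(0)``) and ``I(t) = I0`` constant for an I.V. infusion.

Sign conventions
----------------
Two eigenvalue conventions coexist in the pharmacokinetics literature:
positive *decay rates* ``lam1 >= lam2 > 0`` (the closed forms use
``exp(-lam*t)``) and the rate matrix's actual *eigenvalues*
``mu = -lam < 0``.  :class:`EigenSystem` stores both so every downstream
formula can name which one it consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "PKParameters",
    "DoseMode",
    "DoseRegimen",
    "RateMatrix",
    "EigenSystem",
    "EquilibriumPoint",
    "StabilityLabel",
    "StabilityReport",
    "build_rate_matrix",
    "eigen_decompose",
    "equilibrium",
    "classify_stability",
    "direction_field",
]


@dataclass(frozen=True)
class PKParameters:
    """First-order rate constants of the two-compartment model (min^-1).

    Parameters
    ----------
    k10 : float
        Elimination (clearance) rate from the central compartment. Must be > 0.
    k12 : float
        Central -> peripheral transfer rate. May be 0 (no tissue uptake).
    k21 : float
        Peripheral -> central return rate. Must be > 0.
    """

    k10: float
    k12: float
    k21: float

    def __post_init__(self) -> None:
        for name in ("k10", "k12", "k21"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.k10 <= 0:
            raise ValueError(f"k10 must be positive, got {self.k10}")
        if self.k21 <= 0:
            raise ValueError(f"k21 must be positive, got {self.k21}")
        if self.k12 < 0:
            raise ValueError(f"k12 must be nonnegative, got {self.k12}")


class DoseMode(str, Enum):
    BOLUS = "bolus"
    INFUSION = "infusion"


@dataclass(frozen=True)
class DoseRegimen:
    """Dosing regimen: bolus initial condition or constant infusion rate.

    A bolus enters as the initial central concentration ``c0`` (normalized to
    1 in the reference experiments) with zero infusion.  An infusion is a
    constant zero-order input ``I0`` in mg/(min*mL), optionally derived from a
    dose rate ``D`` (mg/min) and distribution volume ``Vp`` (mL) as
    ``I0 = D/Vp``.
    """

    mode: DoseMode
    c0: float = 0.0
    p0: float = 0.0
    I0: float = 0.0

    def __post_init__(self) -> None:
        if self.mode == DoseMode.BOLUS and self.I0 != 0.0:
            raise ValueError("bolus regimen requires I0 = 0")
        if self.mode == DoseMode.INFUSION and self.I0 <= 0.0:
            raise ValueError("infusion regimen requires I0 > 0")
        if self.c0 < 0 or self.p0 < 0:
            raise ValueError("initial concentrations must be nonnegative")

    @classmethod
    def bolus(cls, c0: float = 1.0, p0: float = 0.0) -> "DoseRegimen":
        return cls(mode=DoseMode.BOLUS, c0=c0, p0=p0)

    @classmethod
    def infusion(
        cls,
        I0: float | None = None,
        *,
        D: float | None = None,
        Vp: float | None = None,
        c0: float = 0.0,
        p0: float = 0.0,
    ) -> "DoseRegimen":
        """Infusion regimen from a rate I0 directly, or from dose D and volume Vp."""
        if I0 is None:
            if D is None or Vp is None:
                raise ValueError("give I0, or both D and Vp")
            if Vp <= 0:
                raise ValueError("Vp must be positive")
            I0 = D / Vp
        return cls(mode=DoseMode.INFUSION, c0=c0, p0=p0, I0=I0)

    @property
    def initial_state(self) -> np.ndarray:
        return np.array([self.c0, self.p0], dtype=float)


@dataclass(frozen=True)
class RateMatrix:
    """System matrix A for the state (c, p), row-major entries in min^-1."""

    a11: float
    a12: float
    a21: float
    a22: float

    def as_array(self) -> np.ndarray:
        return np.array([[self.a11, self.a12], [self.a21, self.a22]], dtype=float)


@dataclass(frozen=True)
class EigenSystem:
    """Eigenstructure of the rate matrix.

    ``lam1 >= lam2 > 0`` are decay rates, ``mu1 = -lam1 <= mu2 = -lam2 < 0``
    the matrix eigenvalues.  ``tau1, tau2`` are the first components of the
    eigenvectors scaled so the second component is 1 (NaN when k12 = 0, where
    that scaling is impossible for the fast mode).
    """

    lam1: float
    lam2: float
    mu1: float
    mu2: float
    tau1: float
    tau2: float
    discriminant: float
    repeated: bool


@dataclass(frozen=True)
class EquilibriumPoint:
    c_star: float
    p_star: float

    def as_array(self) -> np.ndarray:
        return np.array([self.c_star, self.p_star], dtype=float)


class StabilityLabel(str, Enum):
    ASYMPTOTICALLY_STABLE_NODE = "asymptotically_stable_node"
    DEGENERATE_NODE = "degenerate_node"
    OTHER = "other"


@dataclass(frozen=True)
class StabilityReport:
    label: StabilityLabel
    eigen_signs: tuple[int, int]


def build_rate_matrix(params: PKParameters) -> RateMatrix:
    """Rate matrix of the (c, p) system.

    Column sums are (-k10, 0): mass leaves the closed two-state system only
    through elimination from the central compartment.
    """
    return RateMatrix(
        a11=-(params.k10 + params.k12),
        a12=params.k21,
        a21=params.k12,
        a22=-params.k21,
    )


def eigen_decompose(params: PKParameters) -> EigenSystem:
    """Eigenvalues and eigenvectors of the rate matrix in closed form.

    The characteristic polynomial is
    ``mu^2 + (k10+k12+k21)*mu + k10*k21 = 0``, so the decay rates satisfy
    ``lam1+lam2 = k10+k12+k21`` and ``lam1*lam2 = k10*k21``.  The discriminant
    ``(k10+k12+k21)^2 - 4*k10*k21`` equals ``(k10-k21)^2`` when k12 = 0 and is
    strictly positive whenever k12 > 0, so a repeated root occurs only for
    k12 = 0 with k10 = k21.
    """
    k10, k12, k21 = params.k10, params.k12, params.k21
    trace_neg = k10 + k12 + k21
    disc = trace_neg * trace_neg - 4.0 * k10 * k21
    # analytically disc >= 0 for admissible rates; clip rounding noise
    disc = max(disc, 0.0)
    root = math.sqrt(disc)
    lam1 = 0.5 * (trace_neg + root)
    lam2 = 0.5 * (trace_neg - root)
    repeated = disc == 0.0
    mu1, mu2 = -lam1, -lam2
    if k12 > 0.0:
        tau1 = (k21 + mu1) / k12
        tau2 = (k21 + mu2) / k12
    else:
        tau1 = tau2 = math.nan
    return EigenSystem(
        lam1=lam1, lam2=lam2, mu1=mu1, mu2=mu2,
        tau1=tau1, tau2=tau2, discriminant=disc, repeated=repeated,
    )


def equilibrium(params: PKParameters, regimen: DoseRegimen) -> EquilibriumPoint:
    """Steady state of the infusion system: c* = I0/k10, p* = k12*I0/(k10*k21).

    The bolus case (I0 = 0) returns the origin.  The steady state scales
    linearly in I0 and inversely in k10.
    """
    I0 = regimen.I0
    c_star = I0 / params.k10
    p_star = params.k12 * I0 / (params.k10 * params.k21)
    return EquilibriumPoint(c_star=c_star, p_star=p_star)


def classify_stability(eig: EigenSystem) -> StabilityReport:
    """Classify the equilibrium from the eigenvalue signs.

    Two distinct real negative eigenvalues give an asymptotically stable
    node; a repeated negative eigenvalue a degenerate (improper) node.  For
    all admissible parameters here the eigenvalues are real and negative.
    """
    signs = (int(math.copysign(1, eig.mu1)) if eig.mu1 != 0 else 0,
             int(math.copysign(1, eig.mu2)) if eig.mu2 != 0 else 0)
    if eig.mu1 < 0 and eig.mu2 < 0:
        label = (StabilityLabel.DEGENERATE_NODE if eig.repeated
                 else StabilityLabel.ASYMPTOTICALLY_STABLE_NODE)
    else:
        label = StabilityLabel.OTHER
    return StabilityReport(label=label, eigen_signs=signs)


def model_rhs(params: PKParameters, regimen: DoseRegimen, state: np.ndarray) -> np.ndarray:
    """Right-hand side (dc/dt, dp/dt) of the model at a state (c, p)."""
    A = build_rate_matrix(params).as_array()
    forcing = np.array([regimen.I0, 0.0])
    return A @ np.asarray(state, dtype=float) + forcing


def direction_field(
    params: PKParameters,
    regimen: DoseRegimen,
    c_range: tuple[float, float],
    p_range: tuple[float, float],
    n_points: int = 10,
) -> pd.DataFrame:
    """Vector field of the planar system on a uniform grid, for phase portraits.

    Returns a DataFrame with columns ``c, p, dcdt, dpdt`` — one row per grid
    point, ``n_points**2`` rows in total.  The derivative vanishes exactly at
    the equilibrium point.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2 per axis")
    c_lo, c_hi = c_range
    p_lo, p_hi = p_range
    if not (c_hi > c_lo and p_hi > p_lo):
        raise ValueError("ranges must be nonempty")
    cs = np.linspace(c_lo, c_hi, n_points)
    ps = np.linspace(p_lo, p_hi, n_points)
    C, P = np.meshgrid(cs, ps, indexing="ij")
    A = build_rate_matrix(params).as_array()
    dC = A[0, 0] * C + A[0, 1] * P + regimen.I0
    dP = A[1, 0] * C + A[1, 1] * P
    return pd.DataFrame({
        "c": C.ravel(), "p": P.ravel(),
        "dcdt": dC.ravel(), "dpdt": dP.ravel(),
    })
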