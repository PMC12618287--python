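"""Strain energy, invariants and analytic nominal stress for the
incompressible 4-fiber-family model.

The deformation of a strip cut along the vessel axes is taken as a pure
stretch, diagonal in cylindrical coordinates (R, Theta, Z):
``F = diag(lam_R, lam_T, lam_Z)``.  With the two diagonal fiber families
balanced at +/-beta this is a consistent assumption for strip tension (no
in-plane shear develops).  The strain energy is

    W = mu/2 (I1 - 3) + sum_j k1_j / (4 k2_j) * (exp(k2_j (I4_j - 1)^2) - 1)

with I1 = lam_R^2 + lam_T^2 + lam_Z^2 and, for a family at angle beta_j
from the circumferential axis (fibers lie in the Theta-Z surface),
I4_j = lam_T^2 cos^2(beta_j) + lam_Z^2 sin^2(beta_j).

Nominal (first Piola-Kirchhoff) principal stresses follow from
P_ii = dW/dlam_i - p / lam_i, where p is the incompressibility multiplier
fixed by a traction boundary condition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import FourFiberParams

__all__ = [
    "PrincipalStretches",
    "EnergyAndStress",
    "EnergyOverflowError",
    "invariants",
    "strain_energy",
    "energy_gradient",
    "pk1_stress",
    "evaluate_state",
]

#: exponent above which exp() is treated as diverged rather than evaluated
_EXP_ARG_MAX = 700.0
#: below this k2 the exponential term switches to its series limit
_K2_TINY = 1e-8
_INCOMP_TOL = 1e-12


class EnergyOverflowError(FloatingPointError):
    """The exponential fiber term diverged (exponent too large to represent)."""


@dataclass(frozen=True)
class PrincipalStretches:
    """Principal stretches of a strip in cylindrical axes.

    lam_R is the thickness (radial) stretch, lam_T circumferential,
    lam_Z longitudinal.  All must be positive.
    """

    lam_R: float
    lam_T: float
    lam_Z: float

    def __post_init__(self) -> None:
        for name in ("lam_R", "lam_T", "lam_Z"):
            v = getattr(self, name)
            if not (v > 0.0 and math.isfinite(v)):
                raise ValueError(f"{name} must be positive and finite, got {v}")

    @classmethod
    def incompressible(cls, lam_T: float, lam_Z: float) -> "PrincipalStretches":
        """Build a volume-preserving state, thickness stretch from det F = 1."""
        return cls(lam_R=1.0 / (lam_T * lam_Z), lam_T=lam_T, lam_Z=lam_Z)

    @property
    def J(self) -> float:
        """Volume ratio det F."""
        return self.lam_R * self.lam_T * self.lam_Z

    def check_incompressible(self) -> None:
        if abs(self.J - 1.0) > _INCOMP_TOL:
            raise ValueError(f"stretches violate incompressibility: det F = {self.J!r}")


@dataclass(frozen=True)
class EnergyAndStress:
    """Energy density, nominal stresses and invariants at one state."""

    W: float
    P_RR: float
    P_TT: float
    P_ZZ: float
    p: float
    I1: float
    I4: tuple[float, float, float, float]


def invariants(
    stretches: PrincipalStretches, params: FourFiberParams
) -> tuple[float, np.ndarray]:
    """First invariant of C and the four fiber invariants I4_j.

    Family order is fixed: circumferential, longitudinal, +beta, -beta.
    """
    lT2 = stretches.lam_T**2
    lZ2 = stretches.lam_Z**2
    I1 = stretches.lam_R**2 + lT2 + lZ2
    c2, s2 = params.family_cos2_sin2()
    I4 = lT2 * c2 + lZ2 * s2
    return I1, I4


def _fiber_energy_term(k1: float, k2: float, x: float, tension_only: bool) -> float:
    """k1/(4 k2) (exp(k2 x^2) - 1) with x = I4 - 1, series limit for tiny k2."""
    if k1 == 0.0 or (tension_only and x <= 0.0):
        return 0.0
    arg = k2 * x * x
    if arg > _EXP_ARG_MAX:
        raise EnergyOverflowError(
            f"fiber energy diverged: k2 (I4-1)^2 = {arg:.3g} exceeds exp range"
        )
    if k2 < _K2_TINY:
        # series of (exp(k2 x^2) - 1)/(4 k2): x^2/4 * (1 + k2 x^2/2 + ...)
        return 0.25 * k1 * x * x * (1.0 + 0.5 * arg)
    return k1 / (4.0 * k2) * math.expm1(arg)


def strain_energy(
    stretches: PrincipalStretches,
    params: FourFiberParams,
    *,
    tension_only: bool = False,
) -> float:
    """Strain energy density W in kPa.

    With ``tension_only=True`` a fiber family contributes nothing while
    shorter than its reference length (I4 < 1); the default evaluates the
    exponential term for all I4, as the energy is written.
    """
    I1, I4 = invariants(stretches, params)
    W = 0.5 * params.mu * (I1 - 3.0)
    for k1, k2, i4 in zip(params.family_k1(), params.family_k2(), I4):
        W += _fiber_energy_term(k1, k2, i4 - 1.0, tension_only)
    return W


def _fiber_stress_factor(k1: float, k2: float, x: float, tension_only: bool) -> float:
    """2 dW_fiber/dI4 = k1 x exp(k2 x^2), guarded like the energy."""
    if k1 == 0.0 or (tension_only and x <= 0.0):
        return 0.0
    arg = k2 * x * x
    if arg > _EXP_ARG_MAX:
        raise EnergyOverflowError(
            f"fiber stress diverged: k2 (I4-1)^2 = {arg:.3g} exceeds exp range"
        )
    return k1 * x * math.exp(arg)


def energy_gradient(
    stretches: PrincipalStretches,
    params: FourFiberParams,
    *,
    tension_only: bool = False,
) -> tuple[float, float, float]:
    """Analytic (dW/dlam_R, dW/dlam_T, dW/dlam_Z).

    Fibers lie in the Theta-Z surface, so only the matrix contributes to
    the radial component.
    """
    _, I4 = invariants(stretches, params)
    dR = params.mu * stretches.lam_R
    dT = params.mu * stretches.lam_T
    dZ = params.mu * stretches.lam_Z
    c2s, s2s = params.family_cos2_sin2()
    for k1, k2, i4, c2, s2 in zip(params.family_k1(), params.family_k2(), I4, c2s, s2s):
        f = _fiber_stress_factor(k1, k2, i4 - 1.0, tension_only)
        if f != 0.0:
            dT += f * stretches.lam_T * c2
            dZ += f * stretches.lam_Z * s2
    return dR, dT, dZ


def pk1_stress(
    stretches: PrincipalStretches,
    params: FourFiberParams,
    p: float,
    *,
    tension_only: bool = False,
) -> tuple[float, float, float]:
    """Analytic nominal stresses (P_RR, P_TT, P_ZZ) in kPa.

    ``p`` is the incompressibility multiplier (kPa); each component is
    dW/dlam_i - p/lam_i.
    """
    dR, dT, dZ = energy_gradient(stretches, params, tension_only=tension_only)
    return (
        dR - p / stretches.lam_R,
        dT - p / stretches.lam_T,
        dZ - p / stretches.lam_Z,
    )


def evaluate_state(
    stretches: PrincipalStretches,
    params: FourFiberParams,
    p: float,
    *,
    tension_only: bool = False,
) -> EnergyAndStress:
    """Bundle energy, stresses and invariants for one deformation state."""
    I1, I4 = invariants(stretches, params)
    W = strain_energy(stretches, params, tension_only=tension_only)
    P_RR, P_TT, P_ZZ = pk1_stress(stretches, params, p, tension_only=tension_only)
    return EnergyAndStress(
        W=W, P_RR=P_RR, P_TT=P_TT, P_ZZ=P_ZZ, p=p, I1=I1, I4=tuple(float(v) for v in I4)
    )
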