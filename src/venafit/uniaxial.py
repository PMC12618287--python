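"""Uniaxial strip tension for the incompressible 4-fiber-family model.

A strip cut in the circumferential or longitudinal direction is loaded
along its axis; the faces are traction free.  Incompressibility fixes the
thickness stretch as the reciprocal of the in-plane product, and the
traction-free thickness direction fixes the multiplier analytically,
``p = mu * lam_R**2`` (no fiber family has a radial component).  The
remaining unknown — the in-plane transverse stretch — is the root of the
zero-transverse-nominal-stress equation, found by safeguarded bracketing.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

try:  # JIT for the hot per-point root-finding kernel
    from numba import njit as _njit
except ImportError:  # pragma: no cover - numba is a hard dependency in practice

    def _njit(*args, **kwargs):
        def deco(f):
            return f

        return deco if not (args and callable(args[0])) else args[0]

from .constitutive import PrincipalStretches, _EXP_ARG_MAX
from .params import FourFiberParams

__all__ = [
    "StripDirection",
    "Curve",
    "UniaxialSolution",
    "SolverError",
    "solve_transverse",
    "transverse_stretches",
    "stress_at_stretch",
    "simulate_curve",
    "stretch_at_stress",
]

#: default bracket for the transverse stretch after one widening
_WIDE_BRACKET = (0.3, 1.5)
#: absolute residual tolerance is this times max(1, P_load), kPa
_RESIDUAL_RTOL = 1e-9


class StripDirection(enum.Enum):
    """Loading direction of a strip: along Theta or along Z."""

    CIRCUMFERENTIAL = "circumferential"
    LONGITUDINAL = "longitudinal"

    @classmethod
    def parse(cls, label: str) -> "StripDirection":
        s = str(label).strip().lower()
        if s in ("circ", "circumferential", "c", "theta"):
            return cls.CIRCUMFERENTIAL
        if s in ("long", "longit", "longitudinal", "l", "axial", "z"):
            return cls.LONGITUDINAL
        raise ValueError(f"unknown strip direction: {label!r}")

    @property
    def short(self) -> str:
        return "circ" if self is StripDirection.CIRCUMFERENTIAL else "long"


class SolverError(RuntimeError):
    """Transverse-stretch root-finding failed; carries diagnostics."""


@dataclass(frozen=True)
class Curve:
    """Ordered (stretch, nominal stress) samples for one strip or one
    representative direction.  Stress in kPa, stretch dimensionless."""

    stretch: np.ndarray
    stress: np.ndarray
    direction: StripDirection | None = None
    donor_id: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "stretch", np.asarray(self.stretch, dtype=float))
        object.__setattr__(self, "stress", np.asarray(self.stress, dtype=float))
        if self.stretch.ndim != 1 or self.stretch.shape != self.stress.shape:
            raise ValueError("stretch and stress must be 1-D arrays of equal length")

    def __len__(self) -> int:
        return self.stretch.size


@dataclass(frozen=True)
class UniaxialSolution:
    """Solved uniaxial state: stretches, multiplier, loading stress and the
    residual transverse stress left by the root-finder (kPa)."""

    stretches: PrincipalStretches
    p: float
    P_load: float
    residual: float
    direction: StripDirection


def _family_arrays(params: FourFiberParams):
    c2, s2 = params.family_cos2_sin2()
    return np.asarray(params.family_k1()), np.asarray(params.family_k2()), c2, s2


def _stress_components(lam_load, u, direction, params, tension_only=False):
    """Vectorized (P_transverse, P_load) at in-plane stretches.

    ``lam_load`` and ``u`` broadcast; ``u`` is the in-plane transverse
    stretch.  Exponents are clipped at the overflow threshold, which keeps
    the residual finite and sign-correct for bracketing.
    """
    k1, k2, c2, s2 = _family_arrays(params)
    lam_load = np.asarray(lam_load, dtype=float)
    u = np.asarray(u, dtype=float)
    if direction is StripDirection.CIRCUMFERENTIAL:
        lamT, lamZ = lam_load, u
        w_load, w_trans = c2, s2
    else:
        lamT, lamZ = u, lam_load
        w_load, w_trans = s2, c2
    with np.errstate(over="ignore", invalid="ignore"):
        lamR = 1.0 / (lamT * lamZ)
        p = params.mu * lamR**2
        x = (lamT[..., None] ** 2 * c2 + lamZ[..., None] ** 2 * s2) - 1.0
        if tension_only:
            x = np.where(x > 0.0, x, 0.0)
        f = k1 * x * np.exp(np.minimum(k2 * x * x, _EXP_ARG_MAX))
        P_trans = params.mu * u + (f * w_trans).sum(axis=-1) * u - p / u
        P_load = params.mu * lam_load + (f * w_load).sum(axis=-1) * lam_load - p / lam_load
    return P_trans, P_load


def _transverse_stiffness(lam_load, u, direction, params):
    """Vectorized d(P_transverse)/du — the slope of the root equation.

    Sets the attainable residual floor: with u known to ~eps relative,
    |P_trans| cannot be driven below ~eps * |dg * u|.
    """
    k1, k2, c2, s2 = _family_arrays(params)
    lam_load = np.asarray(lam_load, dtype=float)
    u = np.asarray(u, dtype=float)
    if direction is StripDirection.CIRCUMFERENTIAL:
        w_fix, w_var = c2, s2
    else:
        w_fix, w_var = s2, c2
    with np.errstate(over="ignore", invalid="ignore"):
        la2 = lam_load**2
        x = la2[..., None] * w_fix + u[..., None] ** 2 * w_var - 1.0
        E = np.exp(np.minimum(k2 * x * x, _EXP_ARG_MAX))
        fib = (k1 * x * E * w_var).sum(axis=-1)
        dfib = (k1 * E * (1.0 + 2.0 * k2 * x * x) * w_var**2).sum(axis=-1)
        return params.mu + fib + 2.0 * u**2 * dfib + 3.0 * params.mu / (la2 * u**4)


def _residual_tolerance(lam_load, u, P_load, direction, params, rtol):
    """Requested tolerance plus the double-precision floor of the root."""
    floor = 32.0 * np.finfo(float).eps * np.abs(
        _transverse_stiffness(lam_load, u, direction, params) * u
    )
    return rtol * np.maximum(1.0, np.abs(P_load)) + floor


def solve_transverse(
    lam_load: float,
    direction: StripDirection,
    params: FourFiberParams,
    *,
    tension_only: bool = False,
) -> UniaxialSolution:
    """Solve one loading step: find the transverse stretch at which the
    in-plane transverse nominal stress vanishes.

    The bracket starts at [1/lam_load, 1] (between area-preserving
    in-plane contraction and no contraction) and is widened once to
    [0.3, 1.5] if the residual does not change sign there.
    """
    if not (lam_load >= 1.0 and math.isfinite(lam_load)):
        raise ValueError(f"loading stretch must be >= 1, got {lam_load}")

    def g(u: float) -> float:
        return float(_stress_components(lam_load, u, direction, params, tension_only)[0])

    if lam_load == 1.0:
        u = 1.0
    else:
        u = _bracketed_root(g, lam_load, direction)
    return _solution_at(lam_load, u, direction, params, tension_only)


def _bracketed_root(g, lam_load: float, direction: StripDirection) -> float:
    lo, hi = 1.0 / lam_load, 1.0
    glo, ghi = g(lo), g(hi)
    if glo == 0.0:
        return lo
    if ghi == 0.0:
        return hi
    if glo * ghi > 0.0:
        lo, hi = _WIDE_BRACKET
        glo, ghi = g(lo), g(hi)
        if glo * ghi > 0.0:
            raise SolverError(
                f"no sign change for transverse stress of the {direction.value} strip "
                f"at lam_load={lam_load:.6g}: g({lo})={glo:.6g}, g({hi})={ghi:.6g}"
            )
    return brentq(g, lo, hi, xtol=1e-14, rtol=8.9e-16, maxiter=200)


def _solution_at(lam_load, u, direction, params, tension_only) -> UniaxialSolution:
    P_trans, P_load = _stress_components(lam_load, u, direction, params, tension_only)
    P_trans, P_load = float(P_trans), float(P_load)
    residual = abs(P_trans)
    tol = float(_residual_tolerance(lam_load, u, P_load, direction, params, _RESIDUAL_RTOL))
    if residual > tol:
        raise SolverError(
            f"transverse residual {residual:.3e} kPa exceeds tolerance {tol:.3e} "
            f"({direction.value} strip, lam_load={lam_load:.6g})"
        )
    if direction is StripDirection.CIRCUMFERENTIAL:
        stretches = PrincipalStretches.incompressible(lam_T=lam_load, lam_Z=u)
    else:
        stretches = PrincipalStretches.incompressible(lam_T=u, lam_Z=lam_load)
    return UniaxialSolution(
        stretches=stretches,
        p=params.mu * stretches.lam_R**2,
        P_load=P_load,
        residual=residual,
        direction=direction,
    )


def transverse_stretches(
    lam_loads,
    direction: StripDirection,
    params: FourFiberParams,
    *,
    tension_only: bool = False,
    residual_rtol: float = _RESIDUAL_RTOL,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized loading sweep: transverse stretches and loading stresses
    for an array of loading stretches (Chandrupatla bracketing, same
    tolerances as the scalar path).

    Returns ``(u, P_load)``.  Raises :class:`SolverError` naming the first
    failing stretch if any element cannot be solved.
    """
    lam = np.atleast_1d(np.asarray(lam_loads, dtype=float))
    if np.any(lam < 1.0) or not np.all(np.isfinite(lam)):
        bad = lam[(lam < 1.0) | ~np.isfinite(lam)][0]
        raise ValueError(f"loading stretch must be >= 1, got {bad}")

    u = np.ones_like(lam)
    active = lam > 1.0
    if np.any(active):
        u[active] = _newton_bisect(lam[active], direction, params, tension_only)
    P_trans, P_load = _stress_components(lam, u, direction, params, tension_only)
    tol = _residual_tolerance(lam, u, P_load, direction, params, residual_rtol)
    bad = np.abs(P_trans) > tol
    if np.any(bad):
        i = int(np.argmax(bad))
        raise SolverError(
            f"transverse residual {abs(P_trans[i]):.3e} kPa exceeds tolerance at "
            f"lam_load={lam[i]:.6g} ({direction.value} strip)"
        )
    return u, P_load


@_njit(cache=False)
def _newton_kernel(la, mu, k1, k2, w_fix, w_var, wide_lo, wide_hi, xatol, maxiter):
    """Per-element safeguarded Newton on the zero-transverse-stress
    equation (scalar loop, JIT-compiled).

    Returns (u, status); status 1 flags an element with no sign change
    even on the widened bracket."""
    n = la.size
    out = np.empty(n)
    status = np.zeros(n, dtype=np.int64)
    eps4 = 4.0 * 2.220446049250313e-16
    for i in range(n):
        la2 = la[i] * la[i]

        def _g(u):
            fib = 0.0
            dfib = 0.0
            for j in range(4):
                x = la2 * w_fix[j] + u * u * w_var[j] - 1.0
                arg = k2[j] * x * x
                if arg > 700.0:
                    arg = 700.0
                E = np.exp(arg)
                fib += k1[j] * x * E * w_var[j]
                dfib += k1[j] * E * (1.0 + 2.0 * k2[j] * x * x) * w_var[j] * w_var[j]
            g = mu * u + fib * u - mu / (la2 * u**3)
            dg = mu + fib + 2.0 * u * u * dfib + 3.0 * mu / (la2 * u**4)
            return g, dg

        lo = 1.0 / la[i]
        hi = 1.0
        glo, _d = _g(lo)
        ghi, _d = _g(hi)
        if not (glo * ghi <= 0.0):
            lo, hi = wide_lo, wide_hi
            glo, _d = _g(lo)
            ghi, _d = _g(hi)
            if not ((glo <= 0.0 and ghi >= 0.0) or (glo >= 0.0 and ghi <= 0.0)):
                status[i] = 1
                out[i] = np.nan
                continue
        sign_lo = 1.0 if glo > 0.0 else (-1.0 if glo < 0.0 else 0.0)
        u = 0.5 * (lo + hi)
        prev_width = hi - lo
        stall = 0
        for _ in range(maxiter):
            g, dg = _g(u)
            sg = 1.0 if g > 0.0 else (-1.0 if g < 0.0 else 0.0)
            if sg == sign_lo:
                lo = u
            else:
                hi = u
            width = hi - lo
            if width <= xatol + eps4 * abs(u):
                break
            # extremely stiff residuals (huge k2) make Newton crawl in
            # near-constant steps; force bisection when the bracket stops
            # halving so progress stays geometric
            if width > 0.5 * prev_width:
                stall += 1
            else:
                stall = 0
            prev_width = width
            step = g / dg
            # raw Newton correction at rounding level: converged (checked
            # before safeguarding can discard the refined iterate)
            if np.isfinite(step) and abs(step) <= eps4 * abs(u):
                u = u - step
                break
            u_new = u - step
            if stall >= 2 or not (np.isfinite(u_new) and lo <= u_new <= hi):
                u_new = 0.5 * (lo + hi)
                stall = 0
            u = u_new
        out[i] = u
    return out, status


def _newton_bisect(
    la: np.ndarray,
    direction: StripDirection,
    params: FourFiberParams,
    tension_only: bool,
    *,
    xatol: float = 1e-15,
    maxiter: int = 250,
) -> np.ndarray:
    """Safeguarded Newton on the zero-transverse-stress equation, one
    bracket per element, with the analytic derivative and bisection
    fallback.  Same bracketing policy as the scalar path: [1/lam, 1],
    widened once to [0.3, 1.5]."""
    k1, k2, c2, s2 = _family_arrays(params)
    if direction is StripDirection.CIRCUMFERENTIAL:
        w_fix, w_var = c2, s2  # I4 = lam^2 c2 + u^2 s2; transverse weight s2
    else:
        w_fix, w_var = s2, c2
    if tension_only:
        # the compressed-fiber switch is state-dependent; use the scalar
        # brentq path, which evaluates the switched residual
        out = np.empty(la.size)
        for i, l in enumerate(la):
            def g(u, _l=float(l)):
                return float(_stress_components(_l, u, direction, params, True)[0])

            out[i] = _bracketed_root(g, float(l), direction)
        return out
    u, status = _newton_kernel(
        np.ascontiguousarray(la, dtype=float),
        float(params.mu),
        np.ascontiguousarray(k1, dtype=float),
        np.ascontiguousarray(k2, dtype=float),
        np.ascontiguousarray(w_fix, dtype=float),
        np.ascontiguousarray(w_var, dtype=float),
        float(_WIDE_BRACKET[0]),
        float(_WIDE_BRACKET[1]),
        float(xatol),
        int(maxiter),
    )
    if np.any(status != 0):
        i = int(np.argmax(status != 0))
        raise SolverError(
            f"no sign change for transverse stress of the {direction.value} "
            f"strip at lam_load={la[i]:.6g} even on bracket {_WIDE_BRACKET}"
        )
    return u


def stress_at_stretch(
    params: FourFiberParams,
    direction: StripDirection,
    lam_load: float,
    *,
    tension_only: bool = False,
) -> float:
    """Nominal stress (kPa) in the loading direction at one stretch."""
    return solve_transverse(lam_load, direction, params, tension_only=tension_only).P_load


def simulate_curve(
    params: FourFiberParams,
    direction: StripDirection,
    lam_max: float,
    n_points: int,
    *,
    tension_only: bool = False,
) -> Curve:
    """Forward-simulate the loading branch on a uniform stretch grid."""
    if not lam_max > 1.0:
        raise ValueError(f"lam_max must exceed 1, got {lam_max}")
    if n_points < 2:
        raise ValueError(f"n_points must be >= 2, got {n_points}")
    lam = np.linspace(1.0, lam_max, n_points)
    _, P = transverse_stretches(lam, direction, params, tension_only=tension_only)
    return Curve(stretch=lam, stress=P, direction=direction)


def stretch_at_stress(
    params: FourFiberParams,
    direction: StripDirection,
    target_kPa: float,
    *,
    lam_cap: float = 4.0,
    tension_only: bool = False,
) -> float:
    """Invert the loading curve: the stretch at which the nominal stress
    reaches ``target_kPa``.  Expands an upper bound geometrically, then
    bisects; used to size simulation grids for a requested stress range."""
    if target_kPa <= 0.0:
        return 1.0
    hi = 1.02
    while hi < lam_cap:
        if stress_at_stretch(params, direction, hi, tension_only=tension_only) >= target_kPa:
            break
        hi = 1.0 + (hi - 1.0) * 1.6
    else:
        raise SolverError(
            f"stress {target_kPa} kPa not reached below stretch {lam_cap} "
            f"({direction.value})"
        )

    def h(lam: float) -> float:
        return stress_at_stretch(params, direction, lam, tension_only=tension_only) - target_kPa

    return brentq(h, 1.0, hi, xtol=1e-12, rtol=8.9e-16, maxiter=200)
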