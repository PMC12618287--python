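"""Initial and tangent Young's moduli of a loading curve.

Both moduli are least-squares slopes of nominal stress versus engineering
strain (stretch minus one) over a stress window: the initial modulus over
a low-stress window near the origin (default 0–0.5 kPa) and the tangent
modulus in a window centred on a target stress (default 100 +/- 10 kPa).
Slopes are reported in MPa.  A local regression window is used rather
than a two-point difference because it is robust to sampling noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .uniaxial import Curve

__all__ = ["ModulusResult", "ModulusWindowError", "initial_modulus", "tangent_modulus", "curve_moduli"]

_KPA_TO_MPA = 1e-3


class ModulusWindowError(ValueError):
    """Too few curve points fall inside the requested stress window."""


@dataclass(frozen=True)
class ModulusResult:
    """Initial and tangent moduli with the windows and point counts used."""

    E_ini_MPa: float
    E_100_MPa: float
    window_ini_kPa: tuple[float, float]
    window_100_kPa: tuple[float, float]
    n_points_ini: int
    n_points_100: int


def _window_slope_MPa(curve: Curve, lo: float, hi: float) -> tuple[float, int]:
    mask = (curve.stress >= lo) & (curve.stress <= hi)
    n = int(mask.sum())
    if n < 2:
        raise ModulusWindowError(
            f"only {n} point(s) with stress in [{lo:g}, {hi:g}] kPa "
            f"(curve spans {curve.stress.min():g}–{curve.stress.max():g} kPa); "
            "resample the curve more densely or widen the window"
        )
    strain = curve.stretch[mask] - 1.0
    stress = curve.stress[mask]
    if np.ptp(strain) == 0.0:
        raise ModulusWindowError("all in-window points share one strain value")
    slope_kPa = np.polyfit(strain, stress, 1)[0]
    return float(slope_kPa) * _KPA_TO_MPA, n


def initial_modulus(
    curve: Curve, window: tuple[float, float] = (0.0, 0.5)
) -> tuple[float, int]:
    """Initial Young's modulus in MPa: the OLS slope of stress versus
    engineering strain over the low-stress window (default 0–0.5 kPa).

    Returns ``(E_ini_MPa, n_points_used)``.
    """
    lo, hi = window
    if not hi > lo:
        raise ValueError(f"empty window [{lo}, {hi}]")
    return _window_slope_MPa(curve, lo, hi)


def tangent_modulus(
    curve: Curve, at_stress: float = 100.0, half_window: float = 10.0
) -> tuple[float, int]:
    """Tangent Young's modulus in MPa at ``at_stress`` kPa: the OLS slope
    over the window ``at_stress +/- half_window``.

    Returns ``(E_MPa, n_points_used)``.  Raises if the curve does not
    span the window, naming its maximum stress.
    """
    if half_window <= 0.0:
        raise ValueError("half_window must be positive")
    top = at_stress + half_window
    if curve.stress.max() < top:
        raise ModulusWindowError(
            f"curve reaches only {curve.stress.max():.3g} kPa, below the "
            f"{top:g} kPa needed for a tangent modulus at {at_stress:g} kPa"
        )
    return _window_slope_MPa(curve, at_stress - half_window, top)


def curve_moduli(
    curve: Curve,
    *,
    ini_window: tuple[float, float] = (0.0, 0.5),
    at_stress: float = 100.0,
    half_window: float = 10.0,
) -> ModulusResult:
    """Both moduli of one curve, with provenance of windows and counts."""
    e_ini, n_ini = initial_modulus(curve, ini_window)
    e_tan, n_tan = tangent_modulus(curve, at_stress, half_window)
    return ModulusResult(
        E_ini_MPa=e_ini,
        E_100_MPa=e_tan,
        window_ini_kPa=tuple(ini_window),
        window_100_kPa=(at_stress - half_window, at_stress + half_window),
        n_points_ini=n_ini,
        n_points_100=n_tan,
    )
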