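"""Constitutive parameters of the 4-fiber-family model.

The model superposes a neo-Hookean matrix (shear-like modulus ``mu``) and
four exponential fiber families lying in the circumferential–longitudinal
surface of the vessel wall: one circumferential (angle 0), one longitudinal
(angle 90 deg) and a symmetric diagonal pair at ``+/- beta_deg`` from the
circumferential axis.  The diagonal pair shares one (k1, k2), the
circumferential family is fixed at angle 0 and the longitudinal at 90 deg,
which leaves eight independent parameters.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, fields
from pathlib import Path


class ParameterError(ValueError):
    """Raised when constitutive parameters violate their admissibility bounds."""


@dataclass(frozen=True)
class FourFiberParams:
    """The eight independent parameters of the 4-fiber-family model.

    Attributes
    ----------
    mu : float
        Neo-Hookean matrix parameter, kPa.  Must be positive.
    k1_circ, k1_axial, k1_diag : float
        Stress-like fiber stiffness of the circumferential, longitudinal
        and diagonal families, kPa.  Non-negative.
    k2_circ, k2_axial, k2_diag : float
        Dimensionless exponential stiffening exponents.  Positive (they
        appear in a denominator; the k2 -> 0 limit is handled analytically
        in the energy evaluation).
    beta_deg : float
        Angle of the diagonal pair from the circumferential axis, degrees,
        in [0, 90].  The pair sits at +beta and -beta with identical
        stiffness, so only the magnitude matters for in-surface stretches.
    """

    mu: float
    k1_circ: float
    k2_circ: float
    k1_axial: float
    k2_axial: float
    k1_diag: float
    k2_diag: float
    beta_deg: float

    def __post_init__(self) -> None:
        if not (self.mu > 0.0 and math.isfinite(self.mu)):
            raise ParameterError(f"mu must be positive and finite, got {self.mu}")
        for name in ("k1_circ", "k1_axial", "k1_diag"):
            v = getattr(self, name)
            if not (v >= 0.0 and math.isfinite(v)):
                raise ParameterError(f"{name} must be >= 0 and finite, got {v}")
        for name in ("k2_circ", "k2_axial", "k2_diag"):
            v = getattr(self, name)
            if not (v > 0.0 and math.isfinite(v)):
                raise ParameterError(f"{name} must be > 0 and finite, got {v}")
        if not 0.0 <= self.beta_deg <= 90.0:
            raise ParameterError(
                f"beta_deg must lie in [0, 90] degrees, got {self.beta_deg}"
            )

    # Family bookkeeping: order fixed as (circumferential, longitudinal,
    # +beta diagonal, -beta diagonal).  Fibers have no radial component.

    @property
    def beta_rad(self) -> float:
        return math.radians(self.beta_deg)

    def family_angles_rad(self) -> tuple[float, float, float, float]:
        b = self.beta_rad
        return (0.0, math.pi / 2.0, b, -b)

    def family_k1(self) -> tuple[float, float, float, float]:
        return (self.k1_circ, self.k1_axial, self.k1_diag, self.k1_diag)

    def family_k2(self) -> tuple[float, float, float, float]:
        return (self.k2_circ, self.k2_axial, self.k2_diag, self.k2_diag)

    def family_cos2_sin2(self):
        """Squared direction cosines (cos^2 b_j, sin^2 b_j) per family.

        Values below 1e-30 are snapped to exact zero so that a family at
        exactly 0 or 90 degrees contributes nothing across its normal —
        the rounding residue of cos(pi/2) would otherwise leak arbitrarily
        large exponential terms into the wrong stress component.
        """
        import numpy as np

        ang = np.asarray(self.family_angles_rad())
        c2 = np.cos(ang) ** 2
        s2 = np.sin(ang) ** 2
        c2[c2 < 1e-30] = 0.0
        s2[s2 < 1e-30] = 0.0
        return c2, s2

    # ------------------------------------------------------------------ I/O

    _JSON_KEYS = {
        "mu": "mu_kPa",
        "k1_circ": "k1_circ_kPa",
        "k2_circ": "k2_circ",
        "k1_axial": "k1_axial_kPa",
        "k2_axial": "k2_axial",
        "k1_diag": "k1_diag_kPa",
        "k2_diag": "k2_diag",
        "beta_deg": "beta_deg",
    }

    def to_dict(self) -> dict[str, float]:
        """Flat dict using the on-disk key names (units in the keys)."""
        raw = asdict(self)
        return {self._JSON_KEYS[k]: float(v) for k, v in raw.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "FourFiberParams":
        inv = {v: k for k, v in cls._JSON_KEYS.items()}
        unknown = set(d) - set(inv)
        if unknown:
            raise ParameterError(f"unknown parameter keys: {sorted(unknown)}")
        missing = set(inv) - set(d)
        if missing:
            raise ParameterError(f"missing parameter keys: {sorted(missing)}")
        kwargs = {inv[k]: float(v) for k, v in d.items()}
        return cls(**kwargs)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "FourFiberParams":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def as_array(self):
        """Parameter vector in declaration order (used by the optimizer)."""
        import numpy as np

        return np.array([getattr(self, f.name) for f in fields(self)], dtype=float)
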