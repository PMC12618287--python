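"""From raw specimen measurements to per-donor representative curves.

Each donor contributes several strips per direction.  The loading branch
of each strip is cleaned to a strictly monotone stress–stretch curve, and
the strips of one donor and direction are averaged into a single
representative curve sampled at ``m`` nominal-stress levels spanning a
fixed range (default 20 levels over 0–200 kPa).  Averaging is
stress-parameterized by default: at each stress level the specimens'
stretches (interpolated from stretch-vs-stress) are averaged
arithmetically.  A stretch-parameterized alternative is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .uniaxial import StripDirection

__all__ = [
    "SpecimenRecord",
    "RepresentativeCurve",
    "SpecimenRejected",
    "to_nominal_stress",
    "clean_loading_branch",
    "build_representative",
    "read_specimens_csv",
    "representative_curves_frame",
]

log = logging.getLogger(__name__)

#: N/mm^2 (MPa) expressed in kPa
_MPA_TO_KPA = 1000.0


class SpecimenRejected(ValueError):
    """A specimen cannot be used; the message carries the reason."""


@dataclass(frozen=True)
class SpecimenRecord:
    """One strip's loading data plus identifying metadata.

    Samples are either (stretch, nominal stress kPa) — ``stretch``/
    ``stress`` set — or raw (elongation mm, force N) — ``elongation``/
    ``force`` set, which additionally requires ``width_mm``,
    ``thickness_mm`` and ``gauge_length_mm`` for conversion.
    """

    specimen_id: str
    donor_id: str
    direction: StripDirection
    vein_type: str = ""
    stretch: np.ndarray | None = None
    stress: np.ndarray | None = None
    elongation: np.ndarray | None = None
    force: np.ndarray | None = None
    width_mm: float | None = None
    thickness_mm: float | None = None
    gauge_length_mm: float | None = None

    def __post_init__(self) -> None:
        for name in ("stretch", "stress", "elongation", "force"):
            v = getattr(self, name)
            if v is not None:
                object.__setattr__(self, name, np.asarray(v, dtype=float))
        has_ss = self.stretch is not None and self.stress is not None
        has_fe = self.elongation is not None and self.force is not None
        if not (has_ss or has_fe):
            raise ValueError(
                f"specimen {self.specimen_id}: needs either stretch/stress or "
                "elongation/force samples"
            )

    @property
    def is_converted(self) -> bool:
        return self.stretch is not None and self.stress is not None


@dataclass(frozen=True)
class RepresentativeCurve:
    """Per-donor, per-direction averaged curve on a fixed stress grid."""

    donor_id: str
    direction: StripDirection
    stretch: np.ndarray
    stress: np.ndarray
    n_specimens: int
    vein_type: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "stretch", np.asarray(self.stretch, dtype=float))
        object.__setattr__(self, "stress", np.asarray(self.stress, dtype=float))
        if np.any(np.diff(self.stress) <= 0.0):
            raise ValueError("representative stresses must be strictly increasing")

    @property
    def m(self) -> int:
        return self.stress.size

    def __len__(self) -> int:
        return self.stress.size


def to_nominal_stress(record: SpecimenRecord) -> SpecimenRecord:
    """Convert force–elongation samples to stretch and nominal stress.

    Nominal stress = force over the undeformed cross-section
    (width x thickness); stretch = 1 + elongation / gauge length.
    Already-converted records pass through unchanged.
    """
    if record.is_converted:
        return record
    missing = [
        n
        for n in ("width_mm", "thickness_mm", "gauge_length_mm")
        if getattr(record, n) is None
    ]
    if missing:
        raise SpecimenRejected(
            f"specimen {record.specimen_id}: force–elongation input needs "
            f"geometry {missing}"
        )
    area_mm2 = record.width_mm * record.thickness_mm
    if area_mm2 <= 0.0:
        raise SpecimenRejected(
            f"specimen {record.specimen_id}: non-positive cross-section"
        )
    stress_kPa = record.force / area_mm2 * _MPA_TO_KPA  # N/mm^2 -> kPa
    stretch = 1.0 + record.elongation / record.gauge_length_mm
    return replace(record, stretch=stretch, stress=stress_kPa)


def clean_loading_branch(record: SpecimenRecord, *, min_points: int = 5) -> SpecimenRecord:
    """Reduce a raw loading branch to a strictly monotone curve.

    Zero-shifts to the first sample (stress offset removed, stretch
    normalised to 1), collapses duplicate stretches (stress averaged),
    and prunes to the strictly increasing stress envelope: a point
    survives only if its stress exceeds every earlier surviving stress.
    """
    record = to_nominal_stress(record)
    lam = record.stretch.astype(float)
    P = record.stress.astype(float)
    if lam.size < min_points:
        raise SpecimenRejected(
            f"specimen {record.specimen_id}: only {lam.size} raw points"
        )
    if lam[0] <= 0.0:
        raise SpecimenRejected(f"specimen {record.specimen_id}: non-positive stretch")
    P = P - P[0]
    lam = lam / lam[0]

    # collapse duplicated stretches (mean stress per unique stretch)
    lam_u, inverse = np.unique(lam, return_inverse=True)
    if lam_u.size != lam.size:
        P = np.bincount(inverse, weights=P) / np.bincount(inverse)
        lam = lam_u

    keep = np.empty(lam.size, dtype=bool)
    last = -np.inf
    for i, v in enumerate(P):
        keep[i] = v > last
        if keep[i]:
            last = v
    keep[0] = P[0] >= 0.0  # the zero-shifted origin survives
    lam, P = lam[keep], P[keep]
    if lam.size < min_points:
        raise SpecimenRejected(
            f"specimen {record.specimen_id}: {lam.size} points after monotone "
            f"pruning (need >= {min_points})"
        )
    return replace(record, stretch=lam, stress=P)


def _interp_stretch_at(record: SpecimenRecord, stress_grid: np.ndarray) -> np.ndarray:
    """Monotone piecewise-linear stretch as a function of stress."""
    return np.interp(stress_grid, record.stress, record.stretch)


def build_representative(
    records: list[SpecimenRecord],
    m: int = 20,
    stress_max: float = 200.0,
    *,
    include_anchor: bool = False,
    parameterization: str = "stress",
    on_short: str = "truncate",
) -> RepresentativeCurve:
    """Average one donor's cleaned specimens (one direction) into a
    representative curve of ``m`` points.

    The stress grid is ``m`` uniform levels on ``(0, stress_max]``
    (10, 20, ..., 200 kPa with the defaults).  ``include_anchor``
    prepends the reference point (1, 0).  A specimen whose maximum stress
    falls short of ``stress_max`` either truncates the grid to the common
    maximum (``on_short="truncate"``, logged) or raises
    (``on_short="reject"``).  ``parameterization="stretch"`` averages
    stress at fixed stretch instead (grid on the common stretch range).
    """
    if len(records) < 2:
        raise ValueError(
            f"need at least 2 usable specimens, got {len(records)}"
        )
    if m < 2:
        raise ValueError("m must be >= 2")
    donors = {r.donor_id for r in records}
    directions = {r.direction for r in records}
    if len(donors) != 1 or len(directions) != 1:
        raise ValueError(
            f"records mix donors {donors} or directions {directions}"
        )
    records = [clean_loading_branch(r) if not _is_clean(r) else r for r in records]

    if parameterization == "stress":
        common_max = min(float(r.stress[-1]) for r in records)
        if common_max < stress_max:
            if on_short == "reject":
                raise SpecimenRejected(
                    f"a specimen of donor {records[0].donor_id} tops out at "
                    f"{common_max:.1f} kPa < {stress_max:.1f} kPa"
                )
            log.info(
                "donor %s %s: stress range truncated %.1f -> %.1f kPa",
                records[0].donor_id,
                records[0].direction.short,
                stress_max,
                common_max,
            )
            stress_max = common_max
        grid = np.linspace(stress_max / m, stress_max, m)
        stretches = np.vstack([_interp_stretch_at(r, grid) for r in records])
        lam = stretches.mean(axis=0)
        stress = grid
    elif parameterization == "stretch":
        lam_max = min(float(r.stretch[-1]) for r in records)
        lam_grid = np.linspace(1.0, lam_max, m + 1)[1:]
        stresses = np.vstack(
            [np.interp(lam_grid, r.stretch, r.stress) for r in records]
        )
        lam = lam_grid
        stress = stresses.mean(axis=0)
    else:
        raise ValueError(f"unknown parameterization {parameterization!r}")

    if include_anchor:
        lam = np.concatenate([[1.0], lam])
        stress = np.concatenate([[0.0], stress])
    r0 = records[0]
    return RepresentativeCurve(
        donor_id=r0.donor_id,
        direction=r0.direction,
        stretch=lam,
        stress=stress,
        n_specimens=len(records),
        vein_type=r0.vein_type,
    )


def _is_clean(record: SpecimenRecord) -> bool:
    if not record.is_converted or record.stress.size < 2:
        return False
    return bool(
        record.stress[0] >= 0.0
        and np.all(np.diff(record.stress) > 0.0)
        and abs(record.stretch[0] - 1.0) < 1e-12
    )


# --------------------------------------------------------------------- I/O

_REQUIRED_SS = ["specimen_id", "donor_id", "direction", "stretch", "nominal_stress_kPa"]
_REQUIRED_FE = ["specimen_id", "donor_id", "direction", "elongation_mm", "force_N"]


def read_specimens_csv(
    path, geometry_path=None, *, vein_type_col: str = "vein_type"
) -> list[SpecimenRecord]:
    """Read the long-format specimens CSV (one row per sample point).

    Columns: specimen_id, donor_id, [vein_type], direction, and either
    stretch + nominal_stress_kPa or elongation_mm + force_N; the latter
    needs a geometry sidecar CSV (specimen_id, width_mm, thickness_mm,
    gauge_length_mm).
    """
    df = pd.read_csv(path)
    is_ss = set(_REQUIRED_SS) <= set(df.columns)
    is_fe = set(_REQUIRED_FE) <= set(df.columns)
    if not (is_ss or is_fe):
        need = set(_REQUIRED_SS) - set(df.columns)
        raise ValueError(
            f"{path}: missing required columns {sorted(need)} "
            f"(or the force/elongation equivalents)"
        )
    geom = None
    if geometry_path is not None:
        geom = pd.read_csv(geometry_path).set_index("specimen_id")
    records = []
    for sid, g in df.groupby("specimen_id", sort=True):
        g = g.reset_index(drop=True)
        meta = dict(
            specimen_id=str(sid),
            donor_id=str(g["donor_id"].iloc[0]),
            direction=StripDirection.parse(g["direction"].iloc[0]),
            vein_type=str(g[vein_type_col].iloc[0]) if vein_type_col in g else "",
        )
        if geom is not None and sid in geom.index:
            row = geom.loc[sid]
            for col, name in (
                ("width_mm", "width_mm"),
                ("thickness_mm", "thickness_mm"),
                ("gauge_length_mm", "gauge_length_mm"),
            ):
                if col in row.index:
                    meta[name] = float(row[col])
        if is_ss:
            rec = SpecimenRecord(
                stretch=g["stretch"].to_numpy(),
                stress=g["nominal_stress_kPa"].to_numpy(),
                **meta,
            )
        else:
            rec = SpecimenRecord(
                elongation=g["elongation_mm"].to_numpy(),
                force=g["force_N"].to_numpy(),
                **meta,
            )
        records.append(rec)
    return records


def representative_curves_frame(curves: list[RepresentativeCurve]) -> pd.DataFrame:
    """Long-format frame of representative curves for CSV output."""
    rows = []
    for c in curves:
        for lam, P in zip(c.stretch, c.stress):
            rows.append(
                dict(
                    donor_id=c.donor_id,
                    vein_type=c.vein_type,
                    direction=c.direction.short,
                    stretch=lam,
                    nominal_stress_kPa=P,
                )
            )
    return pd.DataFrame(rows)
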