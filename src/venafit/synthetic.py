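"""Virtual uniaxial tensile studies for pipeline testing.

Emulates the structure of a strip-test campaign on human veins: a handful
of donors, 3–4 strips per direction per donor, J-shaped anisotropic
loading curves spanning at least 0–200 kPa nominal stress, a small rate
of failed experiments, and two flavours of disturbance:

* specimen-level variability — a multiplicative rescaling of the strain
  axis, ``lam - 1 -> s (lam - 1)`` with ``s = exp(N(0, sd))``, mimicking
  gauge-length and clamping variation while keeping the donor's ground
  truth well defined;
* measurement noise — i.i.d. multiplicative lognormal noise on stress
  (heteroscedastic: absolute scatter grows with load, as in tensile data).

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .curves import SpecimenRecord
from .params import FourFiberParams
from .uniaxial import (
    SolverError,
    StripDirection,
    simulate_curve,
    stretch_at_stress,
)

__all__ = ["SyntheticStudy", "StudyData", "draw_donor_params", "generate_specimen", "generate_study"]

#: log-uniform draw ranges bracketing the magnitudes reported for veins
_DRAW_RANGES = {
    "mu": (1.0, 1e3),
    "k1": (1.0, 2e3),
    "k2": (0.5, 5e3),
}
_BETA_RANGE_DEG = (30.0, 80.0)


@dataclass(frozen=True)
class SyntheticStudy:
    """Configuration of one virtual study (the generator's conditions)."""

    n_donors: int = 10
    specimens_per_direction: tuple[int, int] = (3, 4)
    noise_stress_rel: float = 0.05
    specimen_scale_sd: float = 0.05
    dropout_prob: float = 0.07
    n_points: int = 150
    stress_max: float = 200.0
    stretch_margin: float = 1.15
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.specimens_per_direction
        if not (2 <= lo <= hi):
            raise ValueError("specimens_per_direction must be >= 2 and ordered")
        if not 0.0 <= self.dropout_prob < 1.0:
            raise ValueError("dropout_prob must lie in [0, 1)")
        if self.noise_stress_rel < 0 or self.specimen_scale_sd < 0:
            raise ValueError("noise magnitudes must be non-negative")


@dataclass
class StudyData:
    """A generated study: per-donor ground truth plus specimen records."""

    config: SyntheticStudy
    truth: dict[str, FourFiberParams]
    vein_type: dict[str, str]
    records: list[SpecimenRecord] = field(default_factory=list)

    def specimens_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            for lam, P in zip(r.stretch, r.stress):
                rows.append(
                    dict(
                        specimen_id=r.specimen_id,
                        donor_id=r.donor_id,
                        vein_type=r.vein_type,
                        direction=r.direction.short,
                        stretch=lam,
                        nominal_stress_kPa=P,
                    )
                )
        return pd.DataFrame(rows)

    def geometry_frame(self) -> pd.DataFrame:
        seen, rows = set(), []
        for r in self.records:
            if r.specimen_id in seen:
                continue
            seen.add(r.specimen_id)
            rows.append(
                dict(
                    specimen_id=r.specimen_id,
                    width_mm=r.width_mm,
                    thickness_mm=r.thickness_mm,
                    gauge_length_mm=r.gauge_length_mm,
                )
            )
        return pd.DataFrame(rows)

    def write(self, out_dir) -> dict[str, Path]:
        """Emit specimens.csv, geometry.csv and truth.json."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "specimens": out / "specimens.csv",
            "geometry": out / "geometry.csv",
            "truth": out / "truth.json",
        }
        self.specimens_frame().to_csv(paths["specimens"], index=False)
        self.geometry_frame().to_csv(paths["geometry"], index=False)
        manifest = dict(
            seed=self.config.seed,
            config={k: v for k, v in asdict(self.config).items()},
            donors={
                d: dict(vein_type=self.vein_type[d], params=p.to_dict())
                for d, p in self.truth.items()
            },
        )
        paths["truth"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        return paths


def _admissible(params: FourFiberParams, stress_max: float) -> bool:
    """True when both directions produce a strictly monotone loading curve
    up to the target stress."""
    try:
        for direction in StripDirection:
            lam_top = stretch_at_stress(params, direction, stress_max)
            curve = simulate_curve(params, direction, lam_top, 100)
            if np.any(np.diff(curve.stress) <= 0.0):
                return False
    except (SolverError, OverflowError):
        return False
    return True


def draw_donor_params(
    group: str,
    rng: np.random.Generator,
    *,
    stress_max: float = 200.0,
    max_redraws: int = 100,
) -> FourFiberParams:
    """Draw one donor's ground-truth parameters from log-uniform ranges
    spanning the magnitudes reported for venous tissue, screened for an
    admissible (monotone, solvable) response up to ``stress_max``.

    The two vein groups share the draw ranges — the reported magnitudes
    overlap almost completely between them — so ``group`` is bookkeeping.
    """
    if group not in ("BV", "GSV"):
        raise ValueError(f"unknown group {group!r}")

    def logu(lo, hi):
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    for _ in range(max_redraws):
        params = FourFiberParams(
            mu=logu(*_DRAW_RANGES["mu"]),
            k1_circ=logu(*_DRAW_RANGES["k1"]),
            k2_circ=logu(*_DRAW_RANGES["k2"]),
            k1_axial=logu(*_DRAW_RANGES["k1"]),
            k2_axial=logu(*_DRAW_RANGES["k2"]),
            k1_diag=logu(*_DRAW_RANGES["k1"]),
            k2_diag=logu(*_DRAW_RANGES["k2"]),
            beta_deg=float(rng.uniform(*_BETA_RANGE_DEG)),
        )
        if _admissible(params, stress_max):
            return params
    raise RuntimeError(f"no admissible parameter draw in {max_redraws} attempts")


def generate_specimen(
    truth: FourFiberParams,
    direction: StripDirection,
    rng: np.random.Generator,
    *,
    specimen_id: str,
    donor_id: str,
    vein_type: str = "",
    noise_stress_rel: float = 0.05,
    specimen_scale_sd: float = 0.05,
    n_points: int = 150,
    stress_max: float = 200.0,
    stretch_margin: float = 1.15,
    max_retries: int = 20,
) -> SpecimenRecord:
    """Forward-simulate one noisy strip record.

    The clean curve is sampled on a uniform stretch grid reaching
    ``stretch_margin`` times past the stretch at ``stress_max`` (a video
    extensometer at fixed frame rate and constant crosshead speed samples
    roughly uniformly in stretch).  The record is re-noised (bounded
    retries) in the rare event that noise pushes its peak below
    ``stress_max``.
    """
    lam_at_max = stretch_at_stress(truth, direction, stress_max)
    lam_top = 1.0 + (lam_at_max - 1.0) * stretch_margin
    clean = simulate_curve(truth, direction, lam_top, n_points)
    width = float(rng.uniform(3.0, 5.0))
    thickness = float(rng.uniform(0.3, 0.8))
    gauge = float(rng.uniform(6.0, 10.0))
    for _ in range(max_retries):
        s = float(np.exp(rng.normal(0.0, specimen_scale_sd))) if specimen_scale_sd else 1.0
        lam = 1.0 + s * (clean.stretch - 1.0)
        if noise_stress_rel:
            P = clean.stress * np.exp(rng.normal(0.0, noise_stress_rel, clean.stress.size))
        else:
            P = clean.stress.copy()
        if P.max() >= stress_max:
            break
    return SpecimenRecord(
        specimen_id=specimen_id,
        donor_id=donor_id,
        direction=direction,
        vein_type=vein_type,
        stretch=lam,
        stress=P,
        width_mm=width,
        thickness_mm=thickness,
        gauge_length_mm=gauge,
    )


def generate_study(config: SyntheticStudy, out_dir=None) -> StudyData:
    """Generate a full virtual study; optionally write its files.

    Donors split evenly between the BV and GSV groups.  Each direction
    receives 3–4 specimens (uniform draw); each specimen independently
    fails with ``dropout_prob``, but the failure mask is redrawn until at
    least two specimens per direction survive.
    """
    rng = np.random.default_rng(config.seed)
    study = StudyData(config=config, truth={}, vein_type={})
    n_bv = (config.n_donors + 1) // 2
    for i in range(config.n_donors):
        group = "BV" if i < n_bv else "GSV"
        donor_id = f"{group}_D{i + 1:02d}"
        truth = draw_donor_params(group, rng, stress_max=config.stress_max)
        study.truth[donor_id] = truth
        study.vein_type[donor_id] = group
        lo, hi = config.specimens_per_direction
        for direction in StripDirection:
            n_spec = int(rng.integers(lo, hi + 1))
            while True:
                keep = rng.random(n_spec) >= config.dropout_prob
                if keep.sum() >= 2:
                    break
            for j in range(n_spec):
                rec = generate_specimen(
                    truth,
                    direction,
                    rng,
                    specimen_id=f"{donor_id}_{direction.short}_{j + 1}",
                    donor_id=donor_id,
                    vein_type=group,
                    noise_stress_rel=config.noise_stress_rel,
                    specimen_scale_sd=config.specimen_scale_sd,
                    n_points=config.n_points,
                    stress_max=config.stress_max,
                    stretch_margin=config.stretch_margin,
                )
                if keep[j]:
                    study.records.append(rec)
    if out_dir is not None:
        study.write(out_dir)
    return study
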