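"""Constrained global identification of the 4-fiber-family parameters.

The model object holds one donor's pair of representative curves
(circumferential and longitudinal).  The objective is the unweighted sum
of squared stress residuals over both directions,

    Q = sum_i [ (P_circ_exp - P_circ_mod)_i^2 + (P_long_exp - P_long_mod)_i^2 ],

where model stresses are evaluated at the experimental stretches with the
transverse stretch solved to zero transverse stress at every point — the
uniaxial constraints are satisfied exactly by construction, so the search
is bound-constrained only.  Optional per-direction weights multiply each
bracketed sum.

``fit()`` runs a global evolutionary stage (differential evolution over
the box bounds, with the severely scale-disparate k2 parameters searched
in log10) followed by bound-constrained local least-squares refinement
from the evolutionary optimum plus multistart points; the best restart
wins.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution, least_squares

from . import __version__
from .curves import RepresentativeCurve
from .params import FourFiberParams
from .uniaxial import SolverError, StripDirection, transverse_stretches

__all__ = [
    "FitConfig",
    "FourFiberModel",
    "FourFiberResults",
    "ObjectiveInfeasible",
    "FitError",
    "objective",
    "fit",
    "r_squared",
    "coefficient_of_determination",
]

_PENALTY = 1e12


def coefficient_of_determination(observed, predicted) -> float:
    """R^2 = 1 - SS_res / SS_tot, SS_tot about the observed mean.

    NaN (undefined) when the observed values have zero variance.
    """
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.size < 2:
        raise ValueError("R^2 needs at least two points")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        warnings.warn("zero variance in observed values: R^2 undefined", stacklevel=2)
        return float("nan")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot


class ObjectiveInfeasible(RuntimeError):
    """The uniaxial sub-solver failed at some experimental point."""


class FitError(RuntimeError):
    """Every restart of the optimization was infeasible."""


@dataclass(frozen=True)
class FitConfig:
    """Optimizer settings and box bounds.

    Bounds default to generous boxes around the magnitudes reported for
    venous tissue: mu in (1e-3, 5e3] kPa, k1 in [0, 5e4] kPa, k2 in
    (1e-6, 5e4], beta in [0, 90] degrees.  ``n_multistarts`` local
    refinements of at most ``max_evals`` objective evaluations each follow
    the evolutionary stage.  ``stress_tol`` is the relative residual
    tolerance handed to the uniaxial sub-solver.
    """

    mu_bounds: tuple[float, float] = (1e-3, 5e3)
    k1_bounds: tuple[float, float] = (0.0, 5e4)
    k2_bounds: tuple[float, float] = (1e-6, 5e4)
    beta_bounds: tuple[float, float] = (0.0, 90.0)
    n_multistarts: int = 32
    max_evals: int = 2000
    seed: int = 20230515
    use_global: bool = True
    de_popsize: int = 8
    de_maxiter: int = 40
    weights: tuple[float, float] = (1.0, 1.0)
    stress_tol: float = 1e-9
    #: stop launching restarts once Q falls below this fraction of the
    #: data's total squared stress (an essentially exact fit)
    q_stop_rel: float = 1e-10

    def __post_init__(self) -> None:
        if self.mu_bounds[0] <= 0 or self.k2_bounds[0] <= 0:
            raise ValueError("mu and k2 lower bounds must be positive")
        if self.k1_bounds[0] < 0:
            raise ValueError("k1 lower bound must be non-negative")
        if not (0 <= self.beta_bounds[0] < self.beta_bounds[1] <= 90):
            raise ValueError("beta bounds must satisfy 0 <= lo < hi <= 90")
        if self.n_multistarts < 1 or self.max_evals < 1:
            raise ValueError("n_multistarts and max_evals must be positive")

    # optimizer works on x = [log10 mu, y(k1_c), log10 k2_c, y(k1_a),
    # log10 k2_a, y(k1_d), log10 k2_d, beta], with the shifted-log map
    # y = log10(k1 + _K1_SHIFT): k1 spans four decades in published tables,
    # and the shift keeps the isotropic limit k1 = 0 exactly reachable at
    # the lower bound.

    _K1_SHIFT = 1e-2

    @classmethod
    def _k1_to_y(cls, k1: float) -> float:
        return math.log10(k1 + cls._K1_SHIFT)

    @classmethod
    def _y_to_k1(cls, y: float) -> float:
        return max(10.0**y - cls._K1_SHIFT, 0.0)

    def transformed_bounds(self) -> list[tuple[float, float]]:
        lmu = tuple(math.log10(b) for b in self.mu_bounds)
        lk2 = tuple(math.log10(b) for b in self.k2_bounds)
        lk1 = tuple(self._k1_to_y(b) for b in self.k1_bounds)
        return [lmu, lk1, lk2, lk1, lk2, lk1, lk2, self.beta_bounds]

    @classmethod
    def params_from_x(cls, x: np.ndarray) -> FourFiberParams:
        return FourFiberParams(
            mu=10.0 ** x[0],
            k1_circ=cls._y_to_k1(float(x[1])),
            k2_circ=10.0 ** x[2],
            k1_axial=cls._y_to_k1(float(x[3])),
            k2_axial=10.0 ** x[4],
            k1_diag=cls._y_to_k1(float(x[5])),
            k2_diag=10.0 ** x[6],
            beta_deg=float(np.clip(x[7], 0.0, 90.0)),
        )

    @classmethod
    def x_from_params(cls, p: FourFiberParams) -> np.ndarray:
        return np.array(
            [
                math.log10(p.mu),
                cls._k1_to_y(p.k1_circ),
                math.log10(p.k2_circ),
                cls._k1_to_y(p.k1_axial),
                math.log10(p.k2_axial),
                cls._k1_to_y(p.k1_diag),
                math.log10(p.k2_diag),
                p.beta_deg,
            ]
        )


def _as_direction_dict(curves) -> dict[StripDirection, RepresentativeCurve]:
    if isinstance(curves, dict):
        out = {}
        for k, v in curves.items():
            key = k if isinstance(k, StripDirection) else StripDirection.parse(k)
            out[key] = v
        return out
    raise TypeError("curves must be a mapping direction -> RepresentativeCurve")


class FourFiberModel:
    """One donor's pair of representative curves, ready to fit.

    Parameters
    ----------
    circ, long : RepresentativeCurve
        Representative circumferential and longitudinal curves.
    weights : (float, float)
        Per-direction weights multiplying the squared-residual sums
        (circumferential, longitudinal); default (1, 1).
    tension_only : bool
        Zero the fiber contribution of shortened families (off by
        default; the energy is otherwise evaluated as written).
    """

    def __init__(
        self,
        circ: RepresentativeCurve,
        long: RepresentativeCurve,
        *,
        weights: tuple[float, float] = (1.0, 1.0),
        tension_only: bool = False,
    ) -> None:
        if circ.direction is not StripDirection.CIRCUMFERENTIAL:
            raise ValueError("first curve must be circumferential")
        if long.direction is not StripDirection.LONGITUDINAL:
            raise ValueError("second curve must be longitudinal")
        if any(w < 0 for w in weights):
            raise ValueError("weights must be non-negative")
        self.curves = {
            StripDirection.CIRCUMFERENTIAL: circ,
            StripDirection.LONGITUDINAL: long,
        }
        self.weights = tuple(float(w) for w in weights)
        self.tension_only = bool(tension_only)
        self.donor_id = circ.donor_id

    # ------------------------------------------------------------ builders

    @classmethod
    def from_curves(cls, curves, **kw) -> "FourFiberModel":
        d = _as_direction_dict(curves)
        return cls(d[StripDirection.CIRCUMFERENTIAL], d[StripDirection.LONGITUDINAL], **kw)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, donor_id: str | None = None, **kw
    ) -> "FourFiberModel":
        """Build from a long-format representative-curve frame with columns
        donor_id, direction, stretch, nominal_stress_kPa."""
        required = {"donor_id", "direction", "stretch", "nominal_stress_kPa"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        donors = df["donor_id"].unique()
        if donor_id is None:
            if len(donors) != 1:
                raise ValueError(
                    f"frame holds donors {list(donors)}; pass donor_id explicitly"
                )
            donor_id = donors[0]
        sub = df[df["donor_id"] == donor_id]
        if sub.empty:
            raise ValueError(f"donor {donor_id!r} not present")
        curves = {}
        for label, g in sub.groupby("direction"):
            direction = StripDirection.parse(label)
            g = g.sort_values("nominal_stress_kPa")
            curves[direction] = RepresentativeCurve(
                donor_id=str(donor_id),
                direction=direction,
                stretch=g["stretch"].to_numpy(),
                stress=g["nominal_stress_kPa"].to_numpy(),
                n_specimens=0,
                vein_type=str(g["vein_type"].iloc[0]) if "vein_type" in g else "",
            )
        return cls.from_curves(curves, **kw)

    # ----------------------------------------------------------- objective

    def predict(self, params: FourFiberParams, direction: StripDirection, stretch=None):
        """Model nominal stresses at the given stretches (defaults to the
        experimental stretches of that direction)."""
        if stretch is None:
            stretch = self.curves[direction].stretch
        _, P = transverse_stretches(
            stretch, direction, params, tension_only=self.tension_only
        )
        return P

    def residuals(self, params: FourFiberParams) -> np.ndarray:
        """sqrt(weight) * (experimental - model) stresses, both directions
        concatenated (circumferential first)."""
        parts = []
        for direction, w in zip(
            (StripDirection.CIRCUMFERENTIAL, StripDirection.LONGITUDINAL), self.weights
        ):
            curve = self.curves[direction]
            try:
                P_mod = self.predict(params, direction)
            except SolverError as err:
                raise ObjectiveInfeasible(
                    f"uniaxial solve failed for donor {self.donor_id}, "
                    f"{direction.value} direction: {err}"
                ) from err
            parts.append(math.sqrt(w) * (curve.stress - P_mod))
        return np.concatenate(parts)

    def objective(self, params: FourFiberParams) -> float:
        """The sum-of-squares objective Q in kPa^2."""
        r = self.residuals(params)
        return float(r @ r)

    def r_squared(self, params: FourFiberParams, direction: StripDirection) -> float:
        """Coefficient of determination of the model stresses against one
        direction's experimental stresses; NaN if the experimental
        stresses have zero variance (undefined)."""
        curve = self.curves[direction]
        return coefficient_of_determination(curve.stress, self.predict(params, direction))

    # ----------------------------------------------------------------- fit

    def _heuristic_starts(self, config: FitConfig) -> list[np.ndarray]:
        """Data-informed starting points: matrix stiffness from the secant
        to the first grid point (small-strain E ~ 3 mu), moderate fibers,
        one start per candidate diagonal angle."""
        secants = []
        for c in self.curves.values():
            dlam = c.stretch[0] - 1.0
            if dlam > 0 and c.stress[0] > 0:
                secants.append(c.stress[0] / dlam)
        E0 = float(np.median(secants)) if secants else 100.0
        mu0 = float(np.clip(E0 / 3.0, config.mu_bounds[0] * 1.01, config.mu_bounds[1] * 0.99))
        starts = []
        for beta in (45.0, 30.0, 60.0, 75.0):
            p = FourFiberParams(
                mu=mu0, k1_circ=10.0, k2_circ=10.0, k1_axial=10.0, k2_axial=10.0,
                k1_diag=10.0, k2_diag=10.0, beta_deg=beta,
            )
            starts.append(FitConfig.x_from_params(p))
        return starts

    def fit(self, config: FitConfig | None = None, **overrides) -> "FourFiberResults":
        """Global evolutionary search plus multistart local refinement.

        Returns the best restart as a :class:`FourFiberResults`.  The
        whole trajectory is a deterministic function of ``config.seed``.
        """
        if config is None:
            config = FitConfig()
        if overrides:
            config = replace(config, **overrides)
        rng = np.random.default_rng(config.seed)
        bounds = config.transformed_bounds()
        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])
        n_evals = 0

        penalty_r = math.sqrt(_PENALTY / self._n_residuals())

        def penalized_residuals(x: np.ndarray) -> np.ndarray:
            nonlocal n_evals
            n_evals += 1
            try:
                r = self.residuals(FitConfig.params_from_x(x))
            except ObjectiveInfeasible:
                return np.full(self._n_residuals(), penalty_r)
            if not np.all(np.isfinite(r)) or np.max(np.abs(r)) > 1e30:
                return np.full(self._n_residuals(), penalty_r)
            return r

        def penalized_Q(x: np.ndarray) -> float:
            r = penalized_residuals(x)
            return float(r @ r)

        starts: list[np.ndarray] = []
        if config.use_global:
            de = differential_evolution(
                penalized_Q,
                bounds,
                seed=int(rng.integers(2**31 - 1)),
                popsize=config.de_popsize,
                maxiter=config.de_maxiter,
                tol=0.0,
                mutation=(0.5, 1.0),
                recombination=0.7,
                init="latinhypercube",
                polish=False,
            )
            starts.append(np.asarray(de.x))
        starts.extend(self._heuristic_starts(config))
        while len(starts) < config.n_multistarts:
            starts.append(lo + (hi - lo) * rng.random(len(bounds)))
        starts = starts[: max(config.n_multistarts, 1)]

        # an essentially exact fit: no point refining further restarts
        q_floor = config.q_stop_rel * sum(
            w * float(c.stress @ c.stress)
            for w, c in zip(self.weights, self.curves.values())
        )
        best_x, best_Q = None, math.inf
        diagnostics = []
        for i, x0 in enumerate(starts):
            x0 = np.clip(x0, lo, hi)
            try:
                sol = least_squares(
                    penalized_residuals,
                    x0,
                    bounds=(lo, hi),
                    method="trf",
                    x_scale="jac",
                    ftol=1e-10,
                    xtol=1e-12,
                    gtol=1e-10,
                    max_nfev=config.max_evals,
                )
                Q_i = 2.0 * sol.cost
                diagnostics.append(
                    dict(restart=i, Q=float(Q_i), nfev=int(sol.nfev), status=int(sol.status))
                )
                if Q_i < best_Q and Q_i < _PENALTY / 2:
                    best_Q, best_x = Q_i, sol.x
                if best_Q <= q_floor:
                    break
            except Exception as err:  # keep other restarts alive
                diagnostics.append(dict(restart=i, error=f"{type(err).__name__}: {err}"))
        if best_x is None:
            raise FitError(
                "all restarts infeasible; per-restart diagnostics: "
                + json.dumps(diagnostics)
            )

        params = FitConfig.params_from_x(best_x)
        Q = self.objective(params)
        return FourFiberResults(
            model=self,
            params=params,
            Q=Q,
            r2_circ=self.r_squared(params, StripDirection.CIRCUMFERENTIAL),
            r2_long=self.r_squared(params, StripDirection.LONGITUDINAL),
            converged=True,
            n_evals=n_evals,
            seed=config.seed,
            config=config,
            diagnostics=diagnostics,
        )

    def _n_residuals(self) -> int:
        return sum(len(c) for c in self.curves.values())


@dataclass
class FourFiberResults:
    """Outcome of one fit: parameter estimates, goodness of fit and
    optimizer diagnostics."""

    model: FourFiberModel
    params: FourFiberParams
    Q: float
    r2_circ: float
    r2_long: float
    converged: bool
    n_evals: int
    seed: int
    config: FitConfig
    diagnostics: list = field(default_factory=list)

    def predict(self, direction: StripDirection, stretch=None):
        return self.model.predict(self.params, direction, stretch)

    def summary(self) -> str:
        """Human-readable parameter table for one donor."""
        p = self.params
        rows = [
            ("mu (kPa)", p.mu),
            ("k1_circ (kPa)", p.k1_circ),
            ("k2_circ (-)", p.k2_circ),
            ("k1_axial (kPa)", p.k1_axial),
            ("k2_axial (-)", p.k2_axial),
            ("k1_diag (kPa)", p.k1_diag),
            ("k2_diag (-)", p.k2_diag),
            ("beta (deg)", p.beta_deg),
        ]
        lines = [
            f"4-fiber-family fit — donor {self.model.donor_id}",
            "=" * 46,
        ]
        lines += [f"{name:<16s}{value:>14.6g}" for name, value in rows]
        lines += [
            "-" * 46,
            f"{'Q (kPa^2)':<16s}{self.Q:>14.6g}",
            f"{'R^2 circ':<16s}{self.r2_circ:>14.6f}",
            f"{'R^2 long':<16s}{self.r2_long:>14.6f}",
            f"{'evaluations':<16s}{self.n_evals:>14d}",
            f"{'seed':<16s}{self.seed:>14d}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return dict(
            donor_id=self.model.donor_id,
            params=self.params.to_dict(),
            Q_kPa2=self.Q,
            R2_circ=self.r2_circ,
            R2_long=self.r2_long,
            converged=self.converged,
            n_evals=self.n_evals,
            seed=self.seed,
            n_multistarts=self.config.n_multistarts,
            max_evals=self.config.max_evals,
            version=__version__,
        )

    def to_json(self, path) -> None:
        from pathlib import Path

        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    def plot(self, ax=None):
        """Experimental points and fitted curves, one axes per call."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        styles = {
            StripDirection.CIRCUMFERENTIAL: dict(color="C0", label="circumferential"),
            StripDirection.LONGITUDINAL: dict(color="C1", label="longitudinal"),
        }
        for direction, style in styles.items():
            c = self.model.curves[direction]
            lam = np.linspace(1.0, c.stretch.max(), 100)
            ax.plot(lam, self.predict(direction, lam), "-", **style)
            ax.plot(c.stretch, c.stress, "o", ms=4, color=style["color"])
        ax.set_xlabel("stretch (-)")
        ax.set_ylabel("nominal stress (kPa)")
        ax.legend()
        return ax


# ------------------------------------------------------- functional surface


def objective(params: FourFiberParams, curves, *, weights=(1.0, 1.0)) -> float:
    """Q for a parameter set against a {direction: curve} mapping."""
    return FourFiberModel.from_curves(curves, weights=weights).objective(params)


def fit(curves, config: FitConfig | None = None, **overrides) -> FourFiberResults:
    """Fit the eight parameters to a {direction: curve} mapping."""
    return FourFiberModel.from_curves(curves).fit(config, **overrides)


def r_squared(params: FourFiberParams, curve: RepresentativeCurve, direction=None) -> float:
    """R^2 of the model against one representative curve."""
    direction = direction or curve.direction
    if not isinstance(direction, StripDirection):
        direction = StripDirection.parse(direction)
    _, P_mod = transverse_stretches(curve.stretch, direction, params)
    return coefficient_of_determination(curve.stress, P_mod)
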