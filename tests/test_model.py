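"""Objective bookkeeping, R^2, and the global fit contract."""

from dataclasses import replace

import numpy as np
import pytest

from venafit import (
    FitConfig,
    FourFiberModel,
    FourFiberParams,
    RepresentativeCurve,
    StripDirection,
    coefficient_of_determination,
    r_squared,
    stretch_at_stress,
    transverse_stretches,
)

from conftest import neo_hookean, random_params

CIRC = StripDirection.CIRCUMFERENTIAL
LONG = StripDirection.LONGITUDINAL

#: small but well-conditioned optimizer budget for unit tests
FAST = dict(n_multistarts=3, de_popsize=4, de_maxiter=12, max_evals=400)


def curves_from_params(params, donor="v1", m=20, stress_max=200.0):
    """Exact representative curves generated by the forward model."""
    out = {}
    grid = np.linspace(stress_max / m, stress_max, m)
    for d in StripDirection:
        lam = np.array([stretch_at_stress(params, d, P) for P in grid])
        out[d] = RepresentativeCurve(
            donor_id=donor, direction=d, stretch=lam, stress=grid, n_specimens=2
        )
    return out


@pytest.fixture(scope="module")
def truth():
    return FourFiberParams(
        mu=30.0, k1_circ=800.0, k2_circ=2.0, k1_axial=400.0, k2_axial=8.0,
        k1_diag=50.0, k2_diag=30.0, beta_deg=50.0,
    )


@pytest.fixture(scope="module")
def truth_curves(truth):
    return curves_from_params(truth)


class TestObjective:
    def test_self_consistency_is_zero(self, truth, truth_curves):
        model = FourFiberModel.from_curves(truth_curves)
        assert model.objective(truth) == pytest.approx(0.0, abs=1e-12)

    def test_zero_model_worked_sum(self, truth_curves):
        # negligible model stress against the 10..200 kPa grid, m=20, both
        # directions: Q = 2 * sum((10 k)^2) = 574,000 kPa^2
        tiny = neo_hookean(1e-6)
        model = FourFiberModel.from_curves(truth_curves)
        assert model.objective(tiny) == pytest.approx(574_000.0, rel=1e-6)

    def test_constant_offset_identity(self, truth, truth_curves):
        delta = 7.5
        shifted = {
            d: RepresentativeCurve(
                donor_id=c.donor_id, direction=d, stretch=c.stretch,
                stress=c.stress + delta, n_specimens=c.n_specimens,
            )
            for d, c in truth_curves.items()
        }
        model = FourFiberModel.from_curves(shifted)
        m = len(truth_curves[CIRC])
        assert model.objective(truth) == pytest.approx(2 * m * delta**2, rel=1e-9)

    def test_scaling_equivariance(self, truth, truth_curves):
        # stresses and stress-like parameters scale together: Q -> c^2 Q
        c = 3.0
        scaled_params = replace(
            truth, mu=truth.mu * c, k1_circ=truth.k1_circ * c,
            k1_axial=truth.k1_axial * c, k1_diag=truth.k1_diag * c,
        )
        off = neo_hookean(5.0)  # evaluate away from the optimum
        off_scaled = neo_hookean(5.0 * c)
        scaled_curves = {
            d: RepresentativeCurve(
                donor_id=cu.donor_id, direction=d, stretch=cu.stretch,
                stress=cu.stress * c, n_specimens=cu.n_specimens,
            )
            for d, cu in truth_curves.items()
        }
        q1 = FourFiberModel.from_curves(truth_curves).objective(off)
        q2 = FourFiberModel.from_curves(scaled_curves).objective(off_scaled)
        assert q2 == pytest.approx(c**2 * q1, rel=1e-9)

    def test_per_direction_weights(self, truth, truth_curves):
        base = FourFiberModel.from_curves(truth_curves)
        weighted = FourFiberModel.from_curves(truth_curves, weights=(2.0, 0.5))
        tiny = neo_hookean(1e-6)
        q_c = 287_000.0  # one direction's zero-model sum
        assert base.objective(tiny) == pytest.approx(2 * q_c, rel=1e-6)
        assert weighted.objective(tiny) == pytest.approx(2.5 * q_c, rel=1e-6)


class TestRSquared:
    def test_perfect_fit(self, truth, truth_curves):
        assert r_squared(truth, truth_curves[CIRC]) == pytest.approx(1.0, abs=1e-12)

    def test_mean_model_scores_zero(self):
        y = np.array([10.0, 20.0, 30.0])
        assert coefficient_of_determination(y, np.full(3, y.mean())) == pytest.approx(0.0)

    def test_two_point_worked_example(self):
        assert coefficient_of_determination([100.0, 200.0], [110.0, 190.0]) == pytest.approx(0.96)

    def test_zero_variance_undefined(self):
        with pytest.warns(UserWarning, match="undefined"):
            out = coefficient_of_determination([5.0, 5.0], [4.0, 6.0])
        assert np.isnan(out)

    def test_q_equals_sum_of_residual_sums(self, truth_curves):
        # with unit weights Q = SS_res,circ + SS_res,long
        probe = neo_hookean(50.0)
        model = FourFiberModel.from_curves(truth_curves)
        ss = 0.0
        for d in StripDirection:
            c = truth_curves[d]
            _, P_mod = transverse_stretches(c.stretch, d, probe)
            ss += float(np.sum((c.stress - P_mod) ** 2))
        assert model.objective(probe) == pytest.approx(ss, rel=1e-12)


class TestFit:
    def test_noiseless_curve_recovery(self, truth_curves):
        res = FourFiberModel.from_curves(truth_curves).fit(FitConfig(seed=11, **FAST))
        assert res.r2_circ >= 0.999
        assert res.r2_long >= 0.999
        assert res.converged

    def test_determinism_same_seed_same_result(self, truth_curves):
        cfg = FitConfig(seed=42, **FAST)
        model = FourFiberModel.from_curves(truth_curves)
        r1, r2 = model.fit(cfg), model.fit(cfg)
        assert r1.params == r2.params
        assert r1.Q == r2.Q
        assert (r1.r2_circ, r1.r2_long) == (r2.r2_circ, r2.r2_long)

    def test_neo_hookean_nested_recovery(self):
        # data without fiber stiffening: fitted fibers must be negligible
        curves = curves_from_params(neo_hookean(300.0), stress_max=200.0)
        res = FourFiberModel.from_curves(curves).fit(FitConfig(seed=5, **FAST))
        peak = 200.0
        fiber_share = []
        for d in StripDirection:
            c = curves[d]
            _, P_full = transverse_stretches(c.stretch, d, res.params)
            matrix_only = replace(res.params, k1_circ=0.0, k1_axial=0.0, k1_diag=0.0)
            _, P_matrix = transverse_stretches(c.stretch, d, matrix_only)
            fiber_share.append(np.max(np.abs(P_full - P_matrix)) / peak)
        small_k1 = max(res.params.k1_circ, res.params.k1_axial, res.params.k1_diag) <= 1e-2
        assert small_k1 or max(fiber_share) < 1e-3

    def test_best_restart_wins(self, truth_curves):
        res = FourFiberModel.from_curves(truth_curves).fit(FitConfig(seed=3, **FAST))
        finished = [d["Q"] for d in res.diagnostics if "Q" in d]
        assert res.Q <= min(finished) * (1 + 1e-9)

    def test_q_matches_recomputed_objective(self, truth_curves):
        model = FourFiberModel.from_curves(truth_curves)
        res = model.fit(FitConfig(seed=9, **FAST))
        assert res.Q == pytest.approx(model.objective(res.params), rel=1e-10)

    def test_summary_and_report_roundtrip(self, truth_curves, tmp_path):
        res = FourFiberModel.from_curves(truth_curves).fit(
            FitConfig(seed=2, n_multistarts=1, use_global=False, max_evals=100)
        )
        text = res.summary()
        assert "mu (kPa)" in text and "R^2 circ" in text
        res.to_json(tmp_path / "fit.json")
        import json

        d = json.loads((tmp_path / "fit.json").read_text())
        assert d["params"]["beta_deg"] == pytest.approx(res.params.beta_deg)
        assert d["seed"] == 2


class TestFromDataframe:
    def test_roundtrip_through_long_frame(self, truth_curves):
        from venafit.curves import representative_curves_frame

        df = representative_curves_frame(list(truth_curves.values()))
        model = FourFiberModel.from_dataframe(df)
        assert model.donor_id == "v1"
        np.testing.assert_allclose(
            model.curves[CIRC].stress, truth_curves[CIRC].stress
        )

    def test_multiple_donors_require_explicit_choice(self, truth_curves):
        from venafit.curves import representative_curves_frame

        df = representative_curves_frame(list(truth_curves.values()))
        import pandas as pd

        both = pd.concat([df, df.assign(donor_id="v2")], ignore_index=True)
        with pytest.raises(ValueError, match="donor_id"):
            FourFiberModel.from_dataframe(both)
        model = FourFiberModel.from_dataframe(both, donor_id="v2")
        assert model.donor_id == "v2"
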