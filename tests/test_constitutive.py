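"""Strain energy, invariants and analytic stress of the 4-fiber model."""

import math

import numpy as np
import pytest

from venafit import (
    EnergyOverflowError,
    FourFiberParams,
    ParameterError,
    PrincipalStretches,
    energy_gradient,
    evaluate_state,
    invariants,
    pk1_stress,
    strain_energy,
)

from conftest import neo_hookean, random_params


class TestParams:
    def test_rejects_inadmissible_values(self):
        good = dict(mu=1.0, k1_circ=0.0, k2_circ=1.0, k1_axial=0.0, k2_axial=1.0,
                    k1_diag=0.0, k2_diag=1.0, beta_deg=45.0)
        with pytest.raises(ParameterError):
            FourFiberParams(**{**good, "mu": 0.0})
        with pytest.raises(ParameterError):
            FourFiberParams(**{**good, "k1_circ": -1.0})
        with pytest.raises(ParameterError):
            FourFiberParams(**{**good, "k2_diag": 0.0})
        with pytest.raises(ParameterError):
            FourFiberParams(**{**good, "beta_deg": 95.0})

    def test_json_roundtrip(self, tmp_path, rng):
        p = random_params(rng)
        path = tmp_path / "params.json"
        p.to_json(path)
        assert FourFiberParams.from_json(path) == p

    def test_family_order_and_symmetry(self, anisotropic_params):
        angles = anisotropic_params.family_angles_rad()
        assert angles[0] == 0.0 and angles[1] == math.pi / 2
        assert angles[2] == -angles[3] == math.radians(45.0)
        assert anisotropic_params.family_k1()[2] == anisotropic_params.family_k1()[3]


class TestInvariants:
    def test_identity_state(self, anisotropic_params):
        I1, I4 = invariants(PrincipalStretches(1, 1, 1), anisotropic_params)
        assert I1 == pytest.approx(3.0, abs=1e-15)
        assert I4 == pytest.approx(np.ones(4), abs=1e-15)

    def test_circumferential_family_squared_stretch(self):
        # beta=0 family: I4 is the squared circumferential stretch
        p = neo_hookean(100.0)
        st = PrincipalStretches(1 / 1.2, 1.2, 1.0)
        _, I4 = invariants(st, p)
        assert I4[0] == pytest.approx(1.44, rel=1e-14)
        assert I4[1] == pytest.approx(1.0, rel=1e-14)

    def test_diagonal_families_at_45_degrees(self):
        p = FourFiberParams(mu=1, k1_circ=0, k2_circ=1, k1_axial=0, k2_axial=1,
                            k1_diag=1, k2_diag=1, beta_deg=45.0)
        st = PrincipalStretches.incompressible(1.1, 1.3)
        _, I4 = invariants(st, p)
        expected = (1.1**2 + 1.3**2) / 2.0  # cos^2 45 = sin^2 45 = 1/2
        assert I4[2] == pytest.approx(expected, rel=1e-14)
        assert I4[3] == pytest.approx(expected, rel=1e-14)
        assert expected == pytest.approx(1.45)

    def test_rejects_nonpositive_stretch(self):
        with pytest.raises(ValueError):
            PrincipalStretches(0.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            PrincipalStretches(1.0, -0.5, 1.0)


class TestStrainEnergy:
    def test_zero_at_identity(self, anisotropic_params):
        assert strain_energy(PrincipalStretches(1, 1, 1), anisotropic_params) == 0.0

    def test_matrix_term_closed_form(self):
        # W = mu/2 (I1 - 3) when fibers carry nothing
        st = PrincipalStretches.incompressible(1.2, 1.0)
        W = strain_energy(st, neo_hookean(100.0))
        assert W == pytest.approx(50.0 * (1.44 + 1.0 + 1.0 / 1.44 - 3.0), rel=1e-12)
        assert W == pytest.approx(6.7222, rel=1e-4)

    def test_single_fiber_term_closed_form(self):
        # one circumferential family: k1/(4 k2) (exp(k2 (I4-1)^2) - 1)
        p = FourFiberParams(mu=1e-12, k1_circ=10.0, k2_circ=1.0, k1_axial=0, k2_axial=1,
                            k1_diag=0, k2_diag=1, beta_deg=45.0)
        st = PrincipalStretches.incompressible(1.1, 1.0)
        W = strain_energy(st, p)
        assert W == pytest.approx(2.5 * math.expm1(0.21**2), rel=1e-10)
        assert W == pytest.approx(0.11272, rel=1e-4)

    def test_overflow_reported_not_silent(self):
        p = FourFiberParams(mu=1.0, k1_circ=1.0, k2_circ=1e4, k1_axial=0, k2_axial=1,
                            k1_diag=0, k2_diag=1, beta_deg=45.0)
        with pytest.raises(EnergyOverflowError):
            strain_energy(PrincipalStretches.incompressible(1.4, 1.0), p)

    def test_small_k2_series_limit(self):
        # k2 -> 0: term tends to (k1/4)(I4-1)^2
        st = PrincipalStretches.incompressible(1.2, 1.0)
        p_tiny = FourFiberParams(mu=1e-12, k1_circ=10.0, k2_circ=1e-12, k1_axial=0,
                                 k2_axial=1, k1_diag=0, k2_diag=1, beta_deg=0.0)
        assert strain_energy(st, p_tiny) == pytest.approx(2.5 * 0.44**2, rel=1e-9)

    def test_monotone_in_k1_under_fiber_tension(self, rng):
        st = PrincipalStretches.incompressible(1.2, 1.1)  # all I4 > 1
        base = random_params(rng)
        W0 = strain_energy(st, base)
        from dataclasses import replace
        for name in ("k1_circ", "k1_axial", "k1_diag"):
            W1 = strain_energy(st, replace(base, **{name: getattr(base, name) * 2}))
            assert W1 > W0

    def test_mirror_symmetry(self, rng):
        # swap T<->Z, circ<->axial families, beta -> 90 - beta
        for _ in range(20):
            p = random_params(rng)
            mirrored = FourFiberParams(
                mu=p.mu, k1_circ=p.k1_axial, k2_circ=p.k2_axial,
                k1_axial=p.k1_circ, k2_axial=p.k2_circ,
                k1_diag=p.k1_diag, k2_diag=p.k2_diag, beta_deg=90.0 - p.beta_deg,
            )
            lr, lt, lz = rng.uniform(0.9, 1.2, 3)
            W = strain_energy(PrincipalStretches(lr, lt, lz), p)
            Wm = strain_energy(PrincipalStretches(lr, lz, lt), mirrored)
            assert Wm == pytest.approx(W, rel=1e-12)

    def test_tension_only_switch_drops_shortened_families(self):
        p = FourFiberParams(mu=1e-12, k1_circ=10.0, k2_circ=1.0, k1_axial=0, k2_axial=1,
                            k1_diag=0, k2_diag=1, beta_deg=0.0)
        st = PrincipalStretches.incompressible(0.9, 1.0)  # circ family shortened
        assert strain_energy(st, p, tension_only=True) == pytest.approx(0.0, abs=1e-12)
        assert strain_energy(st, p) > 1e-3


class TestStress:
    def test_stress_free_reference(self, anisotropic_params):
        P = pk1_stress(PrincipalStretches(1, 1, 1), anisotropic_params, p=anisotropic_params.mu)
        assert P == pytest.approx((0.0, 0.0, 0.0), abs=1e-12)

    def test_neo_hookean_uniaxial_closed_form(self):
        # incompressible uniaxial: P = mu (lam - lam^-2) with p = mu/lam
        mu, lam = 100.0, 1.2
        st = PrincipalStretches(1 / math.sqrt(lam), lam, 1 / math.sqrt(lam))
        P_RR, P_TT, P_ZZ = pk1_stress(st, neo_hookean(mu), p=mu / lam)
        assert P_TT == pytest.approx(mu * (lam - lam**-2), rel=1e-12)
        assert P_TT == pytest.approx(50.556, rel=1e-4)
        assert P_RR == pytest.approx(0.0, abs=1e-10)
        assert P_ZZ == pytest.approx(0.0, abs=1e-10)

    def test_gradient_matches_finite_differences(self, rng):
        # analytic dW/dlam vs central differences over the working regime
        checked = 0
        while checked < 100:
            p = random_params(rng)
            lam = rng.uniform(0.8, 1.4, 3)
            st = PrincipalStretches(*lam)
            try:
                if strain_energy(st, p) > 1e3:
                    continue
            except EnergyOverflowError:
                continue
            checked += 1
            grad = energy_gradient(st, p)
            for i in range(3):
                h = 1e-6 * lam[i]
                hi_, lo_ = lam.copy(), lam.copy()
                hi_[i] += h
                lo_[i] -= h
                fd = (
                    strain_energy(PrincipalStretches(*hi_), p)
                    - strain_energy(PrincipalStretches(*lo_), p)
                ) / (2 * h)
                assert grad[i] == pytest.approx(fd, rel=1e-6)

    def test_fibers_do_not_load_thickness_direction(self, rng):
        # radial gradient is the matrix term alone for any fiber content
        for _ in range(10):
            p = random_params(rng, k2_range=(0.5, 5.0))
            st = PrincipalStretches(*rng.uniform(0.9, 1.2, 3))
            dR, _, _ = energy_gradient(st, p)
            assert dR == pytest.approx(p.mu * st.lam_R, rel=1e-14)

    def test_evaluate_state_bundles_consistently(self, anisotropic_params):
        st = PrincipalStretches.incompressible(1.15, 1.05)
        state = evaluate_state(st, anisotropic_params, p=12.0)
        assert state.W == pytest.approx(strain_energy(st, anisotropic_params))
        assert (state.P_RR, state.P_TT, state.P_ZZ) == pytest.approx(
            pk1_stress(st, anisotropic_params, 12.0)
        )
        I1, I4 = invariants(st, anisotropic_params)
        assert state.I1 == pytest.approx(I1)
        assert state.I4 == pytest.approx(tuple(I4))
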