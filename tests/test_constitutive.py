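"""Constitutive model: energies, stresses, damage law."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from meniscus_cdm import constitutive as const
from meniscus_cdm.constitutive import (Criterion, DamageParams, DamageState,
                                       DeformationState, MaterialParams,
                                       apply_damage, cauchy_stress_undamaged,
                                       compute_C6, damage_cdf,
                                       damage_criterion, strain_energy,
                                       update_damage_state)

FIBER_Y = (0.0, 1.0, 0.0)


def random_states(n, seed=0, scale=0.1):
    """Random invertible deformation gradients with positive J."""
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n:
        F = np.eye(3) + scale * rng.standard_normal((3, 3))
        if np.linalg.det(F) > 0.3:
            out.append(F)
    return out


def numeric_cauchy(F, params):
    """Independent oracle: sigma = (dPsi/dF) F^T / J by central differences."""
    h = 1e-6
    P = np.zeros((3, 3))
    a0 = np.array(params.fiber_dir)
    for i in range(3):
        for j in range(3):
            Fp, Fm = F.copy(), F.copy()
            Fp[i, j] += h
            Fm[i, j] -= h
            ep = strain_energy(DeformationState.from_F(Fp, a0), params)
            em = strain_energy(DeformationState.from_F(Fm, a0), params)
            P[i, j] = (ep - em) / (2 * h)
    return P @ F.T / np.linalg.det(F)


@pytest.fixture(scope="module")
def params():
    return const.AVERAGE_ELASTIC.with_fiber(FIBER_Y)


class TestStrainEnergy:
    def test_reference_configuration_has_zero_energy(self, params):
        st_ = DeformationState.from_F(np.eye(3), FIBER_Y)
        assert strain_energy(st_, params) == pytest.approx(0.0, abs=1e-12)

    def test_fiber_term_vanishes_in_compression(self, params):
        # uniaxial isochoric compression along the fiber: lambda_tilde < 1
        lam = 0.9
        F = np.diag([lam ** -0.5, lam, lam ** -0.5])
        st_ = DeformationState.from_F(F, FIBER_Y)
        no_fibers = MaterialParams(C1=params.C1, C2=params.C2, C3=0.0,
                                   C4=1.0, C5=0.0, lambda_m=1.01, K=params.K,
                                   fiber_dir=FIBER_Y)
        assert strain_energy(st_, params) == pytest.approx(
            strain_energy(st_, no_fibers), rel=1e-12)

    def test_ground_substance_against_symbolic_oracle(self):
        # Veronda-Westmann term C1 (e^{C2 (I1-3)} - 1) - C1 C2/2 (I2 - 3)
        # checked against arbitrary-precision symbolic evaluation at the
        # invariants of an attainable isochoric stretch state
        import sympy

        a, b = 1.2, 0.95
        F = np.diag([a, b, 1.0 / (a * b)])
        st_ = DeformationState.from_F(F, (0, 0, 1))
        C1, C2 = sympy.Rational(7, 10), sympy.Rational(13, 10)
        I1, I2 = sympy.nsimplify(st_.I1_tilde), sympy.nsimplify(st_.I2_tilde)
        expected = float(C1 * (sympy.exp(C2 * (I1 - 3)) - 1)
                         - C1 * C2 / 2 * (I2 - 3))
        p = MaterialParams(C1=0.7, C2=1.3, C3=0.0, C4=1.0, C5=0.0,
                           lambda_m=1.01, K=1000.0, fiber_dir=(0, 0, 1))
        # fiber along z is in compression here, so only F1 contributes
        assert strain_energy(st_, p) == pytest.approx(expected, rel=1e-10)

    def test_negative_jacobian_rejected(self, params):
        with pytest.raises(ValueError):
            DeformationState.from_F(np.diag([1.0, -1.0, 1.0]), FIBER_Y)


class TestCauchyStress:
    def test_reference_is_stress_free(self, params):
        st_ = DeformationState.from_F(np.eye(3), FIBER_Y)
        assert np.allclose(cauchy_stress_undamaged(st_, params), 0.0,
                           atol=1e-12)

    def test_volumetric_limit_closed_form(self):
        p = MaterialParams(C1=0.0, C2=1.0, C3=0.0, C4=1.0, C5=0.0,
                           lambda_m=1.01, K=500.0, fiber_dir=FIBER_Y)
        F = np.diag([1.1, 1.05, 0.97])
        st_ = DeformationState.from_F(F, FIBER_Y)
        J = st_.J
        expected = p.K * np.log(J) / J * np.eye(3)
        assert np.allclose(cauchy_stress_undamaged(st_, p), expected,
                           atol=1e-12)

    def test_matches_numeric_energy_gradient_on_random_states(self, params):
        worst = 0.0
        for F in random_states(100, seed=42):
            st_ = DeformationState.from_F(F, FIBER_Y)
            sig = cauchy_stress_undamaged(st_, params)
            ref = numeric_cauchy(F, params)
            denom = max(np.abs(ref).max(), 1e-8)
            worst = max(worst, np.abs(sig - ref).max() / denom)
        assert worst < 1e-3

    def test_objectivity_under_rotation(self, params):
        from scipy.stats import special_ortho_group
        rng = np.random.default_rng(3)
        for k in range(20):
            F = np.eye(3) + 0.08 * rng.standard_normal((3, 3))
            if np.linalg.det(F) < 0.5:
                continue
            Q = special_ortho_group.rvs(3, random_state=100 + k)
            s1 = cauchy_stress_undamaged(
                DeformationState.from_F(Q @ F, FIBER_Y), params)
            s0 = cauchy_stress_undamaged(
                DeformationState.from_F(F, FIBER_Y), params)
            assert np.abs(s1 - Q @ s0 @ Q.T).max() < 1e-10


class TestFiberLaw:
    def test_C6_printed_fitted_averages(self):
        # continuity constant for C3=0.43, C4=40.83, C5=119.63, lm=1.048
        C6 = compute_C6(0.43, 40.83, 119.63, 1.048)
        assert C6 == pytest.approx(-122.75, abs=0.05)
        # both branches agree at the transition by construction
        toe = 0.43 * (np.exp(40.83 * 0.048) - 1.0)
        lin = 119.63 * 1.048 + C6
        assert toe == pytest.approx(lin, rel=1e-12)

    def test_C6_degenerate_limit(self):
        assert compute_C6(0.7, 5.0, 0.0, 1.0 + 1e-9) == pytest.approx(
            0.0, abs=1e-6)

    def test_branch_continuity_at_transition(self, params):
        lm = params.lambda_m
        eps = 1e-9
        lo = const.fiber_tension_batch(np.array([lm - eps]), params)[0]
        hi = const.fiber_tension_batch(np.array([lm + eps]), params)[0]
        assert abs(hi - lo) < 1e-10 * params.C5 + 1e-6 * params.C5

    def test_tension_only(self, params):
        lam = np.linspace(0.5, 1.0, 20)
        assert np.all(const.fiber_tension_batch(lam, params) == 0.0)

    def test_energy_is_C1_at_transition(self, params):
        # F2 continuous with continuous derivative at lambda_m
        lm = params.lambda_m
        for eps in (1e-7, 1e-6):
            lo, hi = const.fiber_energy_batch(
                np.array([lm - eps, lm + eps]), params)
            assert hi - lo == pytest.approx(
                2 * eps * const.fiber_tension_batch(
                    np.array([lm]), params)[0] / lm, rel=1e-2)


class TestDamageCriterion:
    def test_von_mises_hand_arithmetic(self, params):
        sig = np.diag([2.0, -1.0, -1.0])
        st_ = DeformationState.from_F(np.eye(3), FIBER_Y)
        assert damage_criterion(st_, sig, "von_mises") == pytest.approx(3.0)

    def test_hydrostatic_stress_gives_zero(self, params):
        st_ = DeformationState.from_F(np.eye(3), FIBER_Y)
        assert damage_criterion(st_, 5.0 * np.eye(3),
                                "von_mises") == pytest.approx(0.0, abs=1e-12)

    def test_max_normal_strain_picks_largest_principal(self):
        # E = diag(0.10, -0.02, -0.03) realized through F = sqrt(2E + I)
        E = np.diag([0.10, -0.02, -0.03])
        F = np.diag(np.sqrt(2 * np.diag(E) + 1.0))
        st_ = DeformationState.from_F(F, FIBER_Y)
        assert damage_criterion(st_, np.zeros((3, 3)),
                                Criterion.MAX_NORMAL_STRAIN) == pytest.approx(0.10)

    def test_uniaxial_von_mises_equals_first_principal_stress(self):
        """In uniaxial stress the von Mises criterion reduces to a maximum
        normal stress criterion."""
        from meniscus_cdm.material_point import simulate_uniaxial, _uniaxial_F
        p = const.AVERAGE_ELASTIC
        sol = simulate_uniaxial(p, None, "longitudinal",
                                np.linspace(1.0, 1.12, 13))
        for i in range(1, len(sol.stretch)):
            F = _uniaxial_F(sol.stretch[i], sol.lateral[i])
            st_ = DeformationState.from_F(F, FIBER_Y)
            sig = cauchy_stress_undamaged(st_, p.with_fiber(FIBER_Y))
            assert abs(sig[0, 0]) < 1e-6 and abs(sig[2, 2]) < 1e-6
            vm = damage_criterion(st_, sig, "von_mises")
            s1 = np.linalg.eigvalsh(sig)[-1]
            assert vm == pytest.approx(s1, rel=1e-4)


class TestDamageEvolution:
    DP = DamageParams(Criterion.VON_MISES, mu_min=1.0, mu_max=3.0, D_max=0.58)

    def test_cdf_endpoints_and_midpoint(self):
        assert damage_cdf(self.DP.mu_min, self.DP) == 0.0
        assert damage_cdf(self.DP.mu_max, self.DP) == pytest.approx(
            self.DP.D_max)
        assert damage_cdf(2.0, self.DP) == pytest.approx(0.5 * self.DP.D_max)

    @given(st.floats(min_value=0.0, max_value=10.0))
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_cdf_monotone_continuous_bounded(self, xi):
        D = damage_cdf(xi, self.DP)
        assert 0.0 <= D <= self.DP.D_max
        assert damage_cdf(xi + 1e-4, self.DP) >= D - 1e-12

    def test_cdf_zero_slope_at_thresholds(self):
        h = 1e-5
        for mu in (self.DP.mu_min, self.DP.mu_max):
            slope = (damage_cdf(mu + h, self.DP) -
                     damage_cdf(mu - h, self.DP)) / (2 * h)
            assert abs(slope) < 1e-8

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            DamageParams(Criterion.VON_MISES, 2.0, 2.0, 0.5)

    def test_apply_damage_scales_componentwise(self):
        sig = np.diag([4.0, 0.0, 0.0])
        assert np.allclose(apply_damage(sig, 0.0), sig)
        assert np.allclose(apply_damage(sig, 0.5), np.diag([2.0, 0.0, 0.0]))
        assert np.allclose(apply_damage(sig, 0.58), 0.42 * sig)
        with pytest.raises(ValueError):
            apply_damage(sig, 1.0)

    def test_update_is_irreversible_history_maximum(self):
        # load-unload-reload: D frozen during unloading (oracle: running max)
        path = np.r_[np.linspace(0, 2.5, 30), np.linspace(2.5, 0.5, 10),
                     np.linspace(0.5, 3.5, 20)]
        state = DamageState()
        expect_running = np.maximum.accumulate(path)
        for xi, xr in zip(path, expect_running):
            state = update_damage_state(state, xi, self.DP)
            assert state.xi_max == pytest.approx(xr)
            assert state.D == pytest.approx(damage_cdf(xr, self.DP))


class TestParameterValidation:
    def test_fiber_direction_normalized(self):
        p = MaterialParams(C1=1.0, C2=1.0, C3=0.1, C4=10.0, C5=5.0,
                           lambda_m=1.05, fiber_dir=(0.0, 2.0, 0.0))
        assert np.linalg.norm(p.fiber_dir) == pytest.approx(1.0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            MaterialParams(C1=-1.0, C2=1.0, C3=0.1, C4=10.0, C5=5.0,
                           lambda_m=1.05)
        with pytest.raises(ValueError):
            MaterialParams(C1=1.0, C2=1.0, C3=0.1, C4=10.0, C5=5.0,
                           lambda_m=0.99)
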