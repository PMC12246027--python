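"""Material-point verification of the constitutive model."""

import numpy as np
import pytest

from chondrosim.constitutive import (
    FibrilHistory,
    InvalidDeformationError,
    KinematicState,
    MaterialParams,
    anion_concentration,
    chemical_expansion,
    donnan_pressure,
    fcd_current,
    fibril_network_stress,
    fibril_stress_update,
    neo_hookean_stress,
    permeability,
    secondary_fibril_directions,
    total_stress,
)


def _nh_energy(F, params):
    """Stored energy whose Cauchy-stress derivative is the Neo-Hookean law:
    W = K/2 (ln J)^2 + G/2 (I1 - 3 J^(2/3))."""
    K = params.E_nf / (3 * (1 - 2 * params.nu_nf))
    G = params.E_nf / (2 * (1 + params.nu_nf))
    J = np.linalg.det(F)
    return K / 2 * np.log(J) ** 2 + G / 2 * (np.trace(F.T @ F) - 3 * J ** (2 / 3))


def _nh_stress_fd(F, params, h=1e-7):
    """Independent oracle: sigma = (1/J) dW/dF F^T by central differences."""
    P = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            Fp, Fm = F.copy(), F.copy()
            Fp[i, j] += h
            Fm[i, j] -= h
            P[i, j] = (_nh_energy(Fp, params) - _nh_energy(Fm, params)) / (2 * h)
    return P @ F.T / np.linalg.det(F)


class TestNeoHookean:
    def test_identity_gives_zero_stress(self):
        sig = neo_hookean_stress(np.eye(3), MaterialParams())
        assert np.allclose(sig, 0.0)

    def test_pure_rotation_gives_zero_stress(self, rng):
        A = rng.standard_normal((3, 3))
        R, _ = np.linalg.qr(A)
        sig = neo_hookean_stress(R, MaterialParams())
        assert np.allclose(sig, 0.0, atol=1e-9)

    def test_matches_numerical_energy_derivative(self):
        params = MaterialParams(E_nf=1e6, nu_nf=0.1)
        F = np.diag([1.1, 1.0, 1.0])
        sig = neo_hookean_stress(F, params)
        sig_fd = _nh_stress_fd(F, params)
        assert np.allclose(sig, sig_fd, rtol=1e-6, atol=1e-6 * np.abs(sig).max())
        assert np.allclose(sig, sig.T)

    def test_matches_energy_derivative_on_general_deformation(self, rng):
        params = MaterialParams()
        F = np.eye(3) + 0.1 * rng.standard_normal((3, 3))
        assert np.linalg.det(F) > 0
        sig = neo_hookean_stress(F, params)
        sig_fd = _nh_stress_fd(F, params)
        assert np.allclose(sig, sig_fd, rtol=1e-5, atol=1e-5 * np.abs(sig).max())

    def test_objectivity_under_rotation(self, rng):
        params = MaterialParams()
        for _ in range(5):
            F = np.eye(3) + 0.15 * rng.standard_normal((3, 3))
            if np.linalg.det(F) <= 0.2:
                continue
            R, _ = np.linalg.qr(rng.standard_normal((3, 3)))
            if np.linalg.det(R) < 0:
                R[:, 0] *= -1
            sig = neo_hookean_stress(F, params)
            sig_rot = neo_hookean_stress(R @ F, params)
            assert np.allclose(sig_rot, R @ sig @ R.T, rtol=1e-10, atol=1e-4)

    def test_negative_jacobian_rejected(self):
        with pytest.raises(InvalidDeformationError):
            neo_hookean_stress(np.diag([-1.0, 1.0, 1.0]), MaterialParams())


class TestFibrilViscoelasticity:
    def test_compression_carries_no_stress(self):
        h = fibril_stress_update(-0.05, -0.1, FibrilHistory(), MaterialParams(), 1e-3)
        assert h.sigma_f == 0.0

    def test_elastic_limit_without_damping(self):
        params = MaterialParams(eta=0.0, E0=10e6)
        h = fibril_stress_update(0.02, 0.0, FibrilHistory(), params, 1e-3)
        assert h.sigma_f == pytest.approx(0.2e6)

    def test_slow_ramp_reaches_algebraic_equilibrium(self):
        """At vanishing strain rate the viscoelastic law collapses onto its
        rates-to-zero algebraic solution sigma = E0*eps (the Maxwell branch
        overstress eta*rate becomes negligible)."""
        params = MaterialParams()
        rate = 1e-6
        eps_target = 0.05
        n = 200
        dt = eps_target / rate / n
        h = FibrilHistory()
        for k in range(1, n + 1):
            h = fibril_stress_update(k * eps_target / n, rate, h, params, dt)
        sigma_eq = params.E0 * eps_target  # algebraic equilibrium of the law
        assert h.sigma_f == pytest.approx(sigma_eq, rel=0.01)

    def test_relaxation_after_hold_decays_overstress(self):
        params = MaterialParams()
        h = FibrilHistory()
        # fast ramp builds overstress
        for k in range(1, 11):
            h = fibril_stress_update(k * 0.005, 50.0, h, params, 1e-4)
        over_initial = h.sigma_f - params.E0 * h.eps_f
        assert over_initial > 0
        # hold strain: overstress must relax monotonically toward zero
        for _ in range(50):
            prev = h.sigma_f
            h = fibril_stress_update(0.05, 0.0, h, params, 10.0)
            assert h.sigma_f <= prev + 1e-9
        assert h.sigma_f - params.E0 * 0.05 < over_initial


class TestFibrilNetwork:
    def test_single_primary_fibril_outer_product(self):
        params = MaterialParams(C=3.0)
        ez = np.array([0.0, 0.0, 1.0])
        sig = fibril_network_stress([1e6], [ez], rho_z=0.5, params=params, n_primary=1)
        expected = np.zeros((3, 3))
        expected[2, 2] = 1.5e6
        assert np.allclose(sig, expected)

    def test_all_compressed_fibrils_give_zero(self):
        params = MaterialParams()
        dirs = secondary_fibril_directions()
        stresses = np.zeros(len(dirs))  # tension-only: compressed -> 0 stress
        sig = fibril_network_stress(stresses, dirs, 0.3, params, n_primary=0)
        assert np.allclose(sig, 0.0)

    def test_secondary_set_equibiaxial_is_in_plane_isotropic(self):
        """Under equibiaxial in-plane stretch the direction-set sum must be
        symmetric and isotropic in the stretched plane (direct-summation
        oracle over the 13 directions)."""
        params = MaterialParams(eta=0.0)
        dirs = secondary_fibril_directions()
        eps = np.diag([0.05, 0.05, 0.0])
        eps_f = np.einsum("ki,ij,kj->k", dirs, eps, dirs)
        stresses = np.where(eps_f > 0, params.E0 * eps_f, 0.0)
        sig = fibril_network_stress(stresses, dirs, 0.3, params, n_primary=0)
        assert np.allclose(sig, sig.T)
        assert sig[0, 0] == pytest.approx(sig[1, 1], rel=1e-10)
        assert abs(sig[0, 1]) < 1e-8 * sig[0, 0]


class TestPermeabilityAndFCD:
    @pytest.mark.parametrize("k0,M,J,expected", [
        (3.0e-16, 5.0, 1.0, 3.0e-16),
        (1e-15, 5.0, 0.8, 3.2768e-16),
        (1e-15, 0.0, 0.37, 1e-15),
    ])
    def test_permeability_values(self, k0, M, J, expected):
        params = MaterialParams(k0=k0, M=M)
        assert permeability(J, params) == pytest.approx(expected, rel=1e-12)

    def test_permeability_rejects_nonpositive_J(self):
        with pytest.raises(InvalidDeformationError):
            permeability(0.0, MaterialParams())

    def test_fcd_reference_and_compression(self):
        assert fcd_current(1.0, 200.0, 0.8) == pytest.approx(200.0)
        assert fcd_current(0.9, 200.0, 0.8) == pytest.approx(200.0 * 0.8 / 0.7)
        Js = np.linspace(0.5, 1.5, 40)
        vals = fcd_current(Js, 200.0, 0.8)
        assert np.all(np.diff(vals) < 0)  # compression concentrates charge

    def test_fixed_charge_conservation_identity(self, rng):
        """c_FCD * (current fluid volume factor) is invariant: the law encodes
        conservation of fixed charges exactly."""
        for _ in range(20):
            J = rng.uniform(0.4, 1.8)
            c0 = rng.uniform(0.0, 300.0)
            n0 = rng.uniform(0.55, 0.9)
            c = fcd_current(J, c0, n0)
            assert c * (n0 - 1 + J) == pytest.approx(c0 * n0, rel=1e-14, abs=1e-12)

    def test_pore_collapse_rejected(self):
        with pytest.raises(InvalidDeformationError):
            fcd_current(0.1, 200.0, 0.8)


class TestOsmoticTerms:
    def _equal_coeff_params(self, **kw):
        return MaterialParams(gamma_ext=1.0, gamma_int=1.0,
                              phi_ext=1.0, phi_int=1.0, **kw)

    def test_zero_fcd_equal_coefficients_gives_zero_pressure(self):
        params = self._equal_coeff_params()
        assert donnan_pressure(0.0, params) == pytest.approx(0.0, abs=1e-9)

    def test_closed_form_value(self):
        params = self._equal_coeff_params(T=310.0, c_ext=150.0)
        expected = 8.314 * 310.0 * (np.sqrt(200.0 ** 2 + 4 * 150.0 ** 2) - 300.0)
        assert donnan_pressure(200.0, params) == pytest.approx(expected, rel=1e-12)

    def test_continuity_and_monotonicity_near_zero(self):
        params = self._equal_coeff_params()
        assert abs(donnan_pressure(1e-9, params)) < 1e-5
        cs = np.linspace(0.0, 400.0, 50)
        vals = donnan_pressure(cs, params)
        assert np.all(vals >= -1e-9)
        assert np.all(np.diff(vals) > 0)

    def test_chemical_expansion_limits(self):
        params = MaterialParams()
        assert chemical_expansion(0.0, 100.0, params) == 0.0
        p0 = MaterialParams(kappa=0.0, a0=400.0)
        assert chemical_expansion(150.0, 100.0, p0) == pytest.approx(400.0 * 150.0)
        t1 = chemical_expansion(150.0, 50.0, params)
        t2 = chemical_expansion(150.0, 200.0, params)
        assert t2 < t1  # ionic screening weakens repulsion

    def test_anion_concentration_donnan_equilibrium(self):
        params = self._equal_coeff_params()
        c_m = anion_concentration(200.0, params)
        # electroneutral ideal Donnan: c-(c- + cFCD) = c_ext^2
        assert c_m * (c_m + 200.0) == pytest.approx(params.c_ext ** 2, rel=1e-12)


class TestTotalStress:
    def test_reference_configuration_stress_free(self):
        params = MaterialParams(gamma_ext=1.0, gamma_int=1.0,
                                phi_ext=1.0, phi_int=1.0)
        state = KinematicState(F=np.eye(3), c_FCD0=0.0, n_fl0=0.8)
        sig = total_stress(state, params, p_eff=0.0)
        assert np.allclose(sig, 0.0, atol=1e-6)

    def test_pure_osmotic_term_is_isotropic(self):
        params = MaterialParams(a0=0.0, gamma_ext=1.0, gamma_int=1.0,
                                phi_ext=1.0, phi_int=1.0)
        state = KinematicState(F=np.eye(3), c_FCD0=200.0, n_fl0=0.8)
        sig = total_stress(state, params)
        dpi = donnan_pressure(200.0, params)
        assert np.allclose(sig, -dpi * np.eye(3), rtol=1e-12)
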