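"""Polarizabilities, spectra, Cauchy moments."""

import numpy as np
import pytest

from conftest import optimize_molecular, optimize_synthetic
from tdpbhf import oracle as orc
from tdpbhf.constants import HARTREE_TO_EV
from tdpbhf.ground import CouplingSpec
from tdpbhf.properties import (PolarizabilityRecord, SpectrumSticks,
                               dipole_gradients, dispersion_scan,
                               finite_field_polarizability,
                               fit_cauchy_moments, frequency_grid,
                               gaussian_broaden, polarizability,
                               polarizability_sos, transition_moments,
                               transition_properties)
from tdpbhf.response import build_response_matrices, solve_excitations
from tdpbhf.scf import ActiveSpace, select_active_space
from tdpbhf.tdhf import tdhf_polarizability


def _response_setup(system, lam):
    st = optimize_molecular(system, lam)
    mats = build_response_matrices(st)
    exc = solve_excitations(mats, method="direct")
    grads = dipole_gradients(mats, st.absorbed()[0].dipole_mo)
    return st, mats, exc, grads


class TestPolarizability:
    def test_isotropic_is_third_of_trace(self):
        rec = PolarizabilityRecord(0.0, np.diag([1.0, 2.0, 3.0]))
        assert rec.isotropic == pytest.approx(2.0)

    @pytest.mark.parametrize("lam", [0.0, 0.05])
    def test_static_value_matches_finite_field(self, h2_system, lam):
        _, _, ref, mo = h2_system
        st, mats, exc, grads = _response_setup(h2_system, lam)
        a_resp = polarizability(mats, grads, 0.0, method="direct").alpha
        act = select_active_space(ref, 0.1, lam)
        a_ff = finite_field_polarizability(
            mo, CouplingSpec.uniform(act), act, ref.n_occ,
            st.angles.gamma)
        assert np.abs(a_resp - a_ff).max() < 1e-5

    def test_tdhf_limit_matches_independent_cphf(self, h2o_system):
        _, _, ref, mo = h2o_system
        _, mats, exc, grads = _response_setup(h2o_system, 0.0)
        for omega in (0.0, 0.1):
            a = polarizability(mats, grads, omega, known_omegas=exc.omega,
                               method="direct").alpha
            a_ref = tdhf_polarizability(mo, ref, omega)
            assert np.abs(a - a_ref).max() < 1e-10

    @pytest.mark.parametrize("lam", [0.0, 0.05])
    def test_sum_over_states_identity(self, synthetic_mo, lam):
        """Complete-space SOS rebuild equals the linear-response value."""
        fx, mo = synthetic_mo
        st = optimize_synthetic(fx, mo, lam)
        mats = build_response_matrices(st)
        exc = solve_excitations(mats, method="direct")
        grads = dipole_gradients(mats, st.absorbed()[0].dipole_mo)
        for omega in (0.0, 0.1):
            a_lin = polarizability(mats, grads, omega,
                                   known_omegas=exc.omega,
                                   method="direct").alpha
            a_sos = polarizability_sos(exc, grads, omega).alpha
            assert np.abs(a_lin - a_sos).max() < 1e-8

    def test_even_in_frequency(self, h2_system):
        _, mats, exc, grads = _response_setup(h2_system, 0.0)
        ap = polarizability(mats, grads, 0.2, method="direct").alpha
        am = polarizability(mats, grads, -0.2, method="direct").alpha
        assert np.abs(ap - am).max() < 1e-10


class TestTransitionProperties:
    def test_zero_moments_zero_strength(self):
        sticks = SpectrumSticks(np.array([5.0]), np.array([0.0]),
                                np.zeros((1, 3)))
        assert sticks.strengths[0] == 0.0
        assert not sticks.visible[0]

    def test_moments_match_exact_diagonalization_noninteracting(self):
        """With a one-electron H the response poles and residues are exact:
        moments from Eq-42-style contraction equal <0|μ|n> from full
        diagonalization."""
        from tdpbhf.scf import MOIntegrals
        from tdpbhf.ground import optimize_pbhf
        n, n_occ = 3, 1
        rng = np.random.default_rng(2)
        h = np.diag([-1.0, 0.3, 0.9])
        dip = rng.normal(size=(3, n, n))
        dip = 0.5 * (dip + dip.transpose(0, 2, 1))
        mo = MOIntegrals(h, np.zeros((n, n, n, n)), dip, 0.0)
        act = ActiveSpace((0, 1, 2), {p: 0.0 for p in range(n)}, n)
        st = optimize_pbhf(mo, CouplingSpec.uniform(act), act, n_occ)
        mats = build_response_matrices(st)
        exc = solve_excitations(mats)
        T = transition_moments(exc, dipole_gradients(mats, dip))
        rep = orc.FockSpaceRep(n)
        H = rep.hamiltonian(mo, None)
        w, V = np.linalg.eigh(H)
        psi0 = V[:, 0]
        mu_ops = [sum(-dip[c][p, q] * rep.E(p, q)
                      for p in range(n) for q in range(n)) for c in range(3)]
        for k in range(exc.n_states):
            idx = np.where(np.abs((w - w[0]) - exc.omega[k]) < 1e-8)[0]
            for c in range(3):
                t_exact = np.sqrt(sum((psi0 @ mu_ops[c] @ V[:, j]) ** 2
                                      for j in idx))
                assert abs(T[k, c]) == pytest.approx(t_exact, abs=1e-9)

    def test_oscillator_strengths_rotation_invariant(self, h2o_system):
        _, mats, exc, grads = _response_setup(h2o_system, 0.0)
        f0 = transition_properties(exc, grads).strengths
        # rigid rotation of the molecule = orthogonal mix of the dipole
        # component operators
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th), 0.0],
                      [np.sin(th), np.cos(th), 0.0],
                      [0.0, 0.0, 1.0]])
        dip = _response_setup(h2o_system, 0.0)[0].absorbed()[0].dipole_mo
        dip_rot = np.einsum("cd,dpq->cpq", R, dip)
        grads_rot = dipole_gradients(mats, dip_rot)
        f1 = transition_properties(exc, grads_rot).strengths
        assert np.abs(f0 - f1).max() < 1e-10

    def test_energies_reported_in_ev(self, h2_system):
        _, mats, exc, grads = _response_setup(h2_system, 0.0)
        sticks = transition_properties(exc, grads)
        assert sticks.energies_ev[0] == pytest.approx(
            exc.omega[0] * HARTREE_TO_EV)


class TestBroadening:
    def test_single_stick_peak_and_area(self):
        sticks = SpectrumSticks(np.array([5.0]), np.array([1.0]),
                                np.ones((1, 3)))
        grid, curve = gaussian_broaden(sticks, 0.1)
        assert grid[np.argmax(curve)] == pytest.approx(5.0, abs=0.005)
        area = np.trapezoid(curve, grid)
        assert area == pytest.approx(1.0, abs=1e-6)

    def test_linearity_in_sticks(self):
        one = SpectrumSticks(np.array([5.0]), np.array([0.3]),
                             np.ones((1, 3)))
        two = SpectrumSticks(np.array([5.0, 5.0]), np.array([0.3, 0.3]),
                             np.ones((2, 3)))
        g1, c1 = gaussian_broaden(one, 0.1)
        g2, c2 = gaussian_broaden(two, 0.1)
        assert np.allclose(c2, 2.0 * c1, atol=1e-12)

    def test_visibility_filter_keeps_data(self):
        sticks = SpectrumSticks(np.array([4.0, 6.0]),
                                np.array([0.005, 0.5]), np.ones((2, 3)))
        assert list(sticks.visible) == [False, True]
        assert sticks.strengths[0] == 0.005   # data retained

    def test_empty_sticks_empty_curve(self):
        sticks = SpectrumSticks(np.zeros(0), np.zeros(0), np.zeros((0, 3)))
        _, curve = gaussian_broaden(sticks, 0.1)
        assert np.allclose(curve, 0.0)

    def test_invalid_sigma(self):
        sticks = SpectrumSticks(np.array([5.0]), np.array([1.0]),
                                np.ones((1, 3)))
        with pytest.raises(ValueError):
            gaussian_broaden(sticks, 0.0)


class TestDispersion:
    def test_grid_rule(self):
        assert np.allclose(frequency_grid(0.0351),
                           [0.0, 0.01, 0.02, 0.03])
        assert np.allclose(frequency_grid(0.02), [0.0, 0.01, 0.02])

    def test_isotropic_monotone_below_first_pole(self, h2_system):
        _, mats, exc, grads = _response_setup(h2_system, 0.0)
        recs = dispersion_scan(mats, grads, exc, method="direct")
        iso = [r.isotropic for r in recs]
        assert all(b > a for a, b in zip(iso, iso[1:]))

    def test_scan_matches_independent_cphf_dispersion(self, h2o_system):
        _, _, ref, mo = h2o_system
        _, mats, exc, grads = _response_setup(h2o_system, 0.0)
        recs = dispersion_scan(mats, grads, exc, method="direct")
        for r in recs:
            a_ref = tdhf_polarizability(mo, ref, r.omega)
            assert np.abs(r.alpha - a_ref).max() < 1e-5


class TestCauchyFit:
    def test_exact_polynomial_recovery(self):
        recs = [PolarizabilityRecord(w, (40.0 + 250.0 * w * w) * np.eye(3))
                for w in (0.0, 0.01, 0.02, 0.03, 0.04)]
        fit = fit_cauchy_moments(recs, omega_res=0.08)
        assert fit.s_minus_2 == pytest.approx(40.0, abs=1e-10)
        assert fit.s_minus_4 == pytest.approx(250.0, abs=1e-7)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_fit_window_lower_half(self, h2_system):
        _, mats, exc, grads = _response_setup(h2_system, 0.0)
        recs = dispersion_scan(mats, grads, exc, method="direct")
        fit = fit_cauchy_moments(recs, omega_res=float(exc.omega[0]))
        assert fit.window[1] == pytest.approx(exc.omega[0] / 2.0)
        assert fit.r_squared > 0.99
        # S(-2) approximates the directly computed static value within 1%
        static = polarizability(mats, grads, 0.0,
                                method="direct").isotropic
        assert abs(fit.s_minus_2 - static) / abs(static) < 0.01

    def test_too_few_points_rejected(self):
        recs = [PolarizabilityRecord(w, np.eye(3)) for w in (0.0, 0.01)]
        with pytest.raises(ValueError, match=">= 3"):
            fit_cauchy_moments(recs, omega_res=1.0)
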