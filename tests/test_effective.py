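"""Fourier Hamiltonian assembly, Floquet orders, propagator and matrix log."""

import numpy as np
import pytest

import masfloquet as mf
from masfloquet import operators as ops
from masfloquet.effective import (exact_effective_stack, floquet_stack,
                                  propagator_stack, shift_hamiltonian)
from masfloquet.rotations import lab_coupling_trace

from conftest import random_orientation, random_system

WR = 100e3


def _fh(system, ori):
    return mf.fourier_hamiltonian(system, ori)


def _herm_defect(m):
    return np.max(np.abs(m - m.conj().swapaxes(-1, -2)))


class TestFourierHamiltonian:
    def test_zero_shift_h0_vanishes(self, three_spin, rng):
        fh = _fh(three_spin, random_orientation(rng))
        assert np.all(fh.component(0) == 0)

    def test_h0_is_diagonal_shift_operator(self, three_spin_shifted):
        h0 = shift_hamiltonian(three_spin_shifted)
        assert np.max(np.abs(h0 - np.diag(np.diag(h0)))) == 0
        w = three_spin_shifted.zeeman_frequencies_rad()
        expect = sum(wi * ops.single_spin(3, i + 1, "z")
                     for i, wi in enumerate(w))
        np.testing.assert_allclose(h0, expect, atol=1e-9)

    def test_conjugate_component_symmetry(self, three_spin_shifted, rng):
        fh = _fh(three_spin_shifted, random_orientation(rng))
        for n in range(-2, 3):
            np.testing.assert_allclose(fh.component(n).conj().T,
                                       fh.component(-n), atol=1e-9)

    def test_reconstruction_matches_direct_time_evaluation(self, three_spin_shifted, rng):
        # H(t=0) from the five Fourier components vs assembling the static
        # Hamiltonian from the brute-force lab-frame couplings at t = 0
        ori = random_orientation(rng)
        fh = _fh(three_spin_shifted, ori)
        h_t0 = fh.at_time(0.0, WR)
        direct = shift_hamiltonian(three_spin_shifted).astype(complex)
        for pr in three_spin_shifted.pairs:
            w0 = lab_coupling_trace(pr, ori, np.array([0.0]))[0]
            direct = direct + w0 * ops.dipolar_pair_operator(3, pr.p, pr.q)
        np.testing.assert_allclose(h_t0, direct, atol=1e-6)

    def test_single_pair_components_share_one_operator(self, rng):
        sys2 = mf.build_spin_system([[0, 0, 0], [0, 0, 1.75]])
        fh = _fh(sys2, random_orientation(rng))
        a = ops.dipolar_pair_operator(2, 1, 2)
        for n in (-2, -1, 1, 2):
            hn = fh.component(n)
            coef = hn[0, 0] / a[0, 0]
            np.testing.assert_allclose(hn, coef * a, atol=1e-9)


class TestFloquetEffective:
    def test_order1_equals_h0(self, three_spin_shifted, rng):
        fh = _fh(three_spin_shifted, random_orientation(rng))
        h1 = mf.floquet_effective(fh, WR, 1)
        np.testing.assert_allclose(h1.matrix, fh.component(0), atol=1e-12)

    def test_two_spin_higher_orders_vanish(self, rng):
        # a single dipolar pair: all H^(n) commute, orders 2 and 3 are zero
        sys2 = mf.build_spin_system([[0, 0, 0], [0, 0, 1.75]])
        fh = _fh(sys2, random_orientation(rng))
        h1 = mf.floquet_effective(fh, WR, 1).matrix
        for order in (2, 3):
            h = mf.floquet_effective(fh, WR, order).matrix
            assert np.max(np.abs(h - h1)) < 1e-12 * max(np.abs(h1).max(), 1.0)

    @pytest.mark.parametrize("n_spins", [3, 4])
    def test_hermitian_on_random_systems(self, rng, n_spins):
        for _ in range(3):
            system = random_system(rng, n_spins)
            fh = _fh(system, random_orientation(rng))
            for order in (1, 2, 3):
                h = mf.floquet_effective(fh, WR, order).matrix
                assert _herm_defect(h) < 1e-12 * max(np.linalg.norm(h), 1.0)

    def test_order_contributions_scale_with_inverse_wr_powers(self, three_spin_shifted, rng):
        fh = _fh(three_spin_shifted, random_orientation(rng))
        c = 3.0
        h = {o: mf.floquet_effective(fh, WR, o).matrix for o in (1, 2, 3)}
        hc = {o: mf.floquet_effective(fh, c * WR, o).matrix for o in (1, 2, 3)}
        np.testing.assert_allclose(hc[1], h[1], atol=1e-12)
        np.testing.assert_allclose(hc[2] - hc[1], (h[2] - h[1]) / c, atol=1e-9)
        np.testing.assert_allclose(hc[3] - hc[2], (h[3] - h[2]) / c**2,
                                   atol=1e-9)

    def test_order2_term_is_zero_quantum(self, rng):
        # [H2bar, Fz] = 0 exactly: the order-2 term cannot split lines
        for n_spins in (3, 4):
            system = random_system(rng, n_spins)
            fh = _fh(system, random_orientation(rng))
            h2 = (mf.floquet_effective(fh, WR, 2).matrix
                  - mf.floquet_effective(fh, WR, 1).matrix)
            fz = ops.collective(n_spins, "z")
            comm = h2 @ fz - fz @ h2
            assert np.max(np.abs(comm)) < 1e-10 * np.linalg.norm(h2)

    def test_dipolar_only_traceless(self, three_spin, rng):
        fh = _fh(three_spin, random_orientation(rng))
        for order in (2, 3):
            h = mf.floquet_effective(fh, WR, order).matrix
            assert abs(np.trace(h)) < 1e-10 * max(np.linalg.norm(h), 1.0)

    def test_invalid_order_rejected(self, three_spin, rng):
        fh = _fh(three_spin, random_orientation(rng))
        with pytest.raises(ValueError):
            mf.floquet_effective(fh, WR, 4)


class TestPropagator:
    def test_unitarity(self, three_spin_shifted, rng):
        fh = _fh(three_spin_shifted, random_orientation(rng))
        u = mf.propagator(fh, WR, 500)
        np.testing.assert_allclose(u @ u.conj().T, np.eye(8), atol=1e-10)

    def test_time_independent_limit_is_closed_form(self, rng):
        # shifts only (couplings zeroed): U = exp(-i H0 tau) for any slicing
        from scipy.linalg import expm
        system = random_system(rng, 3)
        fh = _fh(system, random_orientation(rng))
        hn = np.zeros_like(fh.components[np.newaxis])
        hn[0, 2] = shift_hamiltonian(system)
        for n_slices in (4, 37, 200):
            u = propagator_stack(hn, WR, n_slices)[0]
            np.testing.assert_allclose(
                u, expm(-1j * hn[0, 2] / WR), atol=1e-10)

    def test_midpoint_self_convergence_quadratic(self, three_spin, rng):
        # defect against a much finer slicing falls as n_slices^-2
        fh = _fh(three_spin, random_orientation(rng))
        hn = fh.components[np.newaxis]
        wr = 25e3
        ref = propagator_stack(hn, wr, 6400)[0]
        defects = [np.linalg.norm(propagator_stack(hn, wr, n)[0] - ref)
                   for n in (100, 400)]
        ratio = defects[0] / defects[1]
        assert ratio == pytest.approx(16.0, rel=0.15)

    def test_too_few_slices_rejected(self, three_spin, rng):
        fh = _fh(three_spin, random_orientation(rng))
        with pytest.raises(ValueError):
            mf.propagator(fh, WR, 3)


class TestExactEffective:
    def test_identity_maps_to_zero(self):
        h = mf.exact_effective(np.eye(8, dtype=complex), WR)
        np.testing.assert_allclose(h.matrix, 0.0, atol=1e-12)

    def test_round_trip_and_eigenvalue_range(self, three_spin_shifted, rng):
        from scipy.linalg import expm
        fh = _fh(three_spin_shifted, random_orientation(rng))
        wr = 40e3
        u = mf.propagator(fh, wr, 1000)
        ham = mf.exact_effective(u, wr)
        assert _herm_defect(ham.matrix) < 1e-12 * np.linalg.norm(ham.matrix)
        np.testing.assert_allclose(expm(-1j * ham.matrix / wr), u, atol=1e-9)
        eigs_hz = ham.eigenvalues_hz()
        assert np.all(eigs_hz > -wr / 2 - 1e-6)
        assert np.all(eigs_hz <= wr / 2 + 1e-6)

    def test_weak_shift_splitting_recovered(self):
        # well-separated pair with shifts: effective one-quantum frequencies
        # equal the shift offsets when wr >> all couplings
        system = mf.build_spin_system([[0, 0, 0], [0, 0, 40.0]],
                                      shifts_ppm=[0.05, 0.2], larmor_hz=1e9)
        fh = _fh(system, mf.RotorOrientation(25.0, 70.0, 0.0))
        wr = 500e3
        ham = mf.exact_effective(mf.propagator(fh, wr, 800), wr)
        spec = mf.stick_spectrum(ham)
        keep = np.abs(spec.intensities) > 1e-6
        freqs = np.unique(np.round(spec.frequencies_hz[keep], 2))
        assert set(freqs) == {50.0, 200.0}

    def test_order3_residual_falls_with_inverse_cube(self, three_spin):
        # Frobenius distance exact-vs-order3 drops 8x when wr doubles;
        # rotor axis in the molecular plane so both constructions share the
        # micromotion frame at t = 0
        ori = mf.RotorOrientation(alpha_deg=0.0, beta_deg=67.0, gamma_deg=33.0)
        fh = _fh(three_spin, ori)
        res = {}
        for wr in (250e3, 500e3):
            u = mf.propagator(fh, wr, 2000)
            hx = mf.exact_effective(u, wr).matrix
            h3 = mf.floquet_effective(fh, wr, 3).matrix
            res[wr] = np.linalg.norm(hx - h3)
        assert res[250e3] / res[500e3] == pytest.approx(8.0, rel=0.2)
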