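"""Stick spectra, binning, regions and moment analysis."""

import numpy as np
import pytest

import masfloquet as mf
from masfloquet.constants import GAUSSIAN_FWHM_FACTOR
from masfloquet.spectra import (EmptyRegionError, SpectrumError,
                                ZeroIntensityError)

from conftest import random_orientation, random_system


def _sticks(freqs, intens, wr=100e3, construction="exact"):
    return mf.StickSpectrum(frequencies_hz=np.asarray(freqs, dtype=float),
                            intensities=np.asarray(intens, dtype=float),
                            spinning_frequency_hz=wr,
                            construction=construction)


def _effective(matrix, wr=100e3):
    return mf.EffectiveHamiltonian(matrix=np.asarray(matrix, dtype=complex),
                                   construction="exact",
                                   spinning_frequency_hz=wr)


class TestStickSpectrum:
    def test_single_spin_one_transition(self):
        # H = 2 pi * 100 Hz * Iz on one spin: all intensity at +100 Hz
        from masfloquet import operators as ops
        h = 2 * np.pi * 100.0 * ops.single_spin(1, 1, "z")
        spec = mf.stick_spectrum(_effective(h))
        keep = np.abs(spec.intensities) > 1e-12
        assert np.allclose(spec.frequencies_hz[keep], 100.0)
        assert spec.total_intensity == pytest.approx(0.5)

    def test_zero_hamiltonian_conserves_total(self):
        spec0 = mf.stick_spectrum(_effective(np.zeros((8, 8))))
        assert np.allclose(spec0.frequencies_hz, 0.0)
        assert spec0.total_intensity == pytest.approx(6.0)  # Tr(Fx F-) for N=3

    def test_total_intensity_identical_across_constructions(self, three_spin_shifted, rng):
        fh = mf.fourier_hamiltonian(three_spin_shifted, random_orientation(rng))
        wr = 80e3
        hams = [mf.floquet_effective(fh, wr, o) for o in (1, 2, 3)]
        hams.append(mf.exact_effective(mf.propagator(fh, wr, 800), wr))
        totals = [mf.stick_spectrum(h).total_intensity for h in hams]
        np.testing.assert_allclose(totals, totals[0], rtol=1e-9)

    def test_isolated_pair_fully_refocused(self, rng):
        # exact effective Hamiltonian of a dipolar pair over the rotor
        # period is zero: single line at 0 carrying everything
        sys2 = mf.build_spin_system([[0, 0, 0], [0, 0, 1.75]])
        fh = mf.fourier_hamiltonian(sys2, random_orientation(rng))
        ham = mf.exact_effective(mf.propagator(fh, 100e3, 1000), 100e3)
        spec = mf.stick_spectrum(ham)
        assert np.max(np.abs(spec.frequencies_hz)) < 1e-6
        assert spec.total_intensity == pytest.approx(2.0, rel=1e-9)

    def test_non_hermitian_rejected(self):
        bad = np.array([[0.0, 1.0], [0.0, 0.0]])
        with pytest.raises(SpectrumError):
            mf.stick_spectrum(_effective(bad))


class TestMoments:
    def test_single_stick(self):
        rep = mf.moments(_sticks([123.0], [2.0]))
        assert rep.m1_hz == 123.0
        assert rep.m2_central_hz2 == pytest.approx(0.0, abs=1e-9)
        assert rep.gaussian_fwhm_hz == pytest.approx(0.0, abs=1e-4)

    def test_symmetric_doublet(self):
        a = 40.0
        rep = mf.moments(_sticks([-a, a], [1.0, 1.0]))
        assert rep.m1_hz == pytest.approx(0.0)
        assert rep.m2_raw_hz2 == pytest.approx(a**2)
        assert rep.gaussian_fwhm_hz == pytest.approx(GAUSSIAN_FWHM_FACTOR * a)

    def test_gaussian_stick_cloud_recovers_fwhm(self):
        rng = np.random.default_rng(7)
        sigma = 50.0
        freqs = rng.normal(0.0, sigma, 100_000)
        rep = mf.moments(_sticks(freqs, np.ones_like(freqs)))
        assert rep.gaussian_fwhm_hz == pytest.approx(117.7, rel=0.01)

    def test_central_m2_subtracts_line_shift(self):
        shifted = mf.moments(_sticks([90.0, 110.0], [1.0, 1.0]))
        centered = mf.moments(_sticks([-10.0, 10.0], [1.0, 1.0]))
        assert shifted.m2_central_hz2 == pytest.approx(centered.m2_central_hz2)
        assert shifted.m2_raw_hz2 > shifted.m2_central_hz2

    def test_empty_and_zero_intensity_distinguished(self):
        region = mf.SpectralRegion(((1000.0, 2000.0),))
        with pytest.raises(EmptyRegionError):
            mf.moments(_sticks([0.0], [1.0]), region)
        with pytest.raises(ZeroIntensityError):
            mf.moments(_sticks([1500.0], [0.0]), region)


class TestBinnedSpectrum:
    def test_resolution(self):
        binned = mf.bin_spectrum(_sticks([0.0], [1.0]), 2000.0, 20000)
        assert binned.resolution_hz == pytest.approx(0.1)

    def test_integral_conserved_with_broadening(self):
        spec = _sticks([-200.0, 50.0, 30.0], [1.0, 2.5, 0.5])
        binned = mf.bin_spectrum(spec, 2000.0, 5000, broadening_hz=5.0)
        assert binned.integral == pytest.approx(spec.total_intensity, rel=1e-6)

    def test_binned_moments_converge_to_stick_moments(self):
        rng = np.random.default_rng(3)
        freqs = rng.uniform(-300, 300, 500)
        intens = rng.uniform(0.5, 1.0, 500)
        spec = _sticks(freqs, intens)
        exact = mf.moments(spec)
        errs = []
        for npts in (2_000, 20_000):
            b = mf.bin_spectrum(spec, 1000.0, npts)
            m1 = np.sum(b.frequencies_hz * b.amplitudes) / b.integral
            errs.append(abs(m1 - exact.m1_hz))
        assert errs[1] < errs[0]
        assert errs[1] < 0.05

    def test_negative_broadening_rejected(self):
        with pytest.raises(SpectrumError):
            mf.bin_spectrum(_sticks([0.0], [1.0]), 100.0, 10, broadening_hz=-1.0)


class TestRegions:
    def test_center_band_interval(self):
        region = mf.center_band(100e3, reference_hz=0.0)
        assert region.intervals == ((-50e3, 50e3),)

    def test_center_band_excludes_outlier(self):
        spec = _sticks([0.75 * 100e3], [1.0], wr=100e3)
        region = mf.center_band(spec)
        assert not region.mask(spec.frequencies_hz).any()

    def test_exact_transitions_within_twice_half_band(self, three_spin, rng):
        fh = mf.fourier_hamiltonian(three_spin, random_orientation(rng))
        wr = 30e3
        ham = mf.exact_effective(mf.propagator(fh, wr, 1000), wr)
        spec = mf.stick_spectrum(ham)
        assert np.max(np.abs(spec.frequencies_hz)) <= wr + 1e-6

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(SpectrumError):
            mf.SpectralRegion(((0.0, 10.0), (5.0, 20.0)))

    def test_midpoint_partition(self):
        spec = _sticks([0.0], [1.0], wr=100e3)
        regions = mf.assign_line_regions(spec, [0.0, 700.0])
        assert regions[0].intervals == ((-50e3, 350.0),)
        assert regions[1].intervals == ((350.0, 50e3),)

    def test_single_shift_gets_full_band(self):
        spec = _sticks([0.0], [1.0], wr=100e3)
        (region,) = mf.assign_line_regions(spec, [10.0])
        assert region.intervals == mf.center_band(spec).intervals

    def test_unsorted_shifts_preserve_order(self):
        spec = _sticks([0.0], [1.0], wr=100e3)
        regions = mf.assign_line_regions(spec, [700.0, 0.0])
        assert regions[0].intervals == ((350.0, 50e3),)

    def test_combination_lines_weak_in_gap_clustering(self):
        # shifted three-spin system at 100 kHz: single-quantum regions carry
        # far more intensity than anything outside them
        system = mf.three_spin_one_shift()
        spec = mf.powder_spectrum(system, 100e3, "order2",
                                  mf.zcw_orientations(200))
        shifts = system.zeeman_frequencies_hz()
        regions = mf.assign_line_regions(spec, [0.0, 700.0], method="gap",
                                         gap_hz=150.0)
        in_lines = sum(mf.moments(spec, r).total_intensity
                       for r in {r.intervals: r for r in regions}.values())
        total_band = mf.moments(spec, mf.center_band(spec)).total_intensity
        assert in_lines > 0.9 * total_band
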