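"""Stick spectra, binned spectra and moment analysis.

The effective Hamiltonian is diagonalized; the transition frequencies are
eigenvalue differences and the transition intensities come from the initial
density operator (F_x by default) and the detection operator (F^- by
default) transformed into the eigenbasis:

    I_ij = Re[ (sigma_0)_ij (d_ji)^* ],   omega_ij = E_i - E_j.

The intensity-weighted raw moments of a spectral region are

    M_n = sum omega_ij^n I_ij / sum I_ij,

and the line width is reported as the FWHM of the Gaussian with the same
central second moment, FWHM = 2 sqrt(2 ln 2) sqrt(M2 - M1^2).  Frequencies
are signed (the first moment measures the center of gravity), so line shifts
do not inflate the reported width; the raw second moment is reported as well.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import operators as ops
from .constants import GAUSSIAN_FWHM_FACTOR
from .effective import EffectiveHamiltonian

#: Transitions with |intensity| below this fraction of the total are dropped.
INTENSITY_TOL = 1e-12

#: Transitions closer than this (Hz) are merged (degenerate eigenvalues).
MERGE_TOL_HZ = 1e-9


class SpectrumError(ValueError):
    pass


class EmptyRegionError(SpectrumError):
    """Region contains no transitions at all."""


class ZeroIntensityError(SpectrumError):
    """Region contains transitions but their total intensity is zero."""


@dataclass(frozen=True)
class SpectralRegion:
    """One or more disjoint closed frequency intervals, Hz.

    Intervals are treated as half-open (lo, hi] when selecting transitions so
    that adjacent regions sharing a boundary never double-count a stick.
    """

    intervals: tuple[tuple[float, float], ...]

    def __post_init__(self):
        ivs = tuple((float(lo), float(hi)) for lo, hi in self.intervals)
        for lo, hi in ivs:
            if not (np.isfinite(lo) and np.isfinite(hi)) or hi <= lo:
                raise SpectrumError(f"bad interval ({lo}, {hi})")
        for (lo1, hi1) in ivs:
            for (lo2, hi2) in ivs:
                if (lo1, hi1) < (lo2, hi2) and hi1 > lo2 and hi2 > lo1:
                    raise SpectrumError("region intervals overlap")
        object.__setattr__(self, "intervals", ivs)

    def mask(self, frequencies_hz: np.ndarray) -> np.ndarray:
        f = np.asarray(frequencies_hz)
        out = np.zeros(f.shape, dtype=bool)
        for lo, hi in self.intervals:
            out |= (f > lo) & (f <= hi)
        return out

    def intersect(self, other: "SpectralRegion") -> "SpectralRegion":
        ivs = []
        for lo1, hi1 in self.intervals:
            for lo2, hi2 in other.intervals:
                lo, hi = max(lo1, lo2), min(hi1, hi2)
                if hi > lo:
                    ivs.append((lo, hi))
        if not ivs:
            raise SpectrumError("empty intersection of regions")
        return SpectralRegion(tuple(ivs))


@dataclass(frozen=True)
class StickSpectrum:
    """Transition list: signed frequencies (Hz) and non-negative weights.

    ``state_pairs`` (i, j eigenstate indices) is kept for single-orientation
    spectra and is None for pooled powder spectra.  ``total_intensity`` is
    conserved across effective-Hamiltonian constructions.
    """

    frequencies_hz: np.ndarray
    intensities: np.ndarray
    spinning_frequency_hz: float
    construction: str
    state_pairs: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def total_intensity(self) -> float:
        return float(np.sum(self.intensities))

    def __len__(self) -> int:
        return self.frequencies_hz.size


@dataclass(frozen=True)
class MomentReport:
    """Raw/central moments and Gaussian-equivalent FWHM of a region, Hz."""

    m1_hz: float
    m2_raw_hz2: float
    m2_central_hz2: float
    gaussian_fwhm_hz: float
    total_intensity: float
    region: SpectralRegion | None = None


def _merge_degenerate(freq: np.ndarray, inten: np.ndarray,
                      tol_hz: float = MERGE_TOL_HZ):
    if freq.size == 0:
        return freq, inten
    order = np.argsort(freq)
    f, w = freq[order], inten[order]
    groups = np.concatenate([[0], np.cumsum(np.diff(f) > tol_hz)])
    nf = np.bincount(groups, weights=f * w)
    nw = np.bincount(groups, weights=w)
    safe = np.where(nw == 0, 1.0, nw)
    return nf / safe, nw


def sticks_from_matrix(hbar: np.ndarray, sigma0: np.ndarray,
                       detect: np.ndarray):
    """Transition frequencies (Hz) and intensities of one hermitian matrix.

    Returns (freq, inten, pairs) with insignificant transitions removed.
    """
    energies, vec = np.linalg.eigh(hbar)
    sig = vec.conj().T @ sigma0 @ vec
    det = vec.conj().T @ detect @ vec
    # amp_ij = sigma_ij * d_ji: the coefficient of exp(-i w_ij t) in
    # Tr[sigma(t) d]; summing over ij gives Tr[sigma0 d], so the total
    # intensity is basis independent (conserved across constructions)
    amp = sig * det.T
    total = abs(np.sum(amp.real))
    imag_leak = abs(np.sum(amp.imag))
    if total > 0 and imag_leak > 1e-8 * total:
        warnings.warn(
            f"imaginary intensity residual {imag_leak / total:.2e} of total; "
            "check operator phases", RuntimeWarning, stacklevel=2)
    omega = (energies[:, None] - energies[None, :]) / (2.0 * np.pi)
    inten = amp.real
    keep = np.abs(inten) > INTENSITY_TOL * max(total, 1e-300)
    idx = np.argwhere(keep)
    return omega[keep], inten[keep], idx


def stick_spectrum(ham: EffectiveHamiltonian,
                   initial: np.ndarray | None = None,
                   detect: np.ndarray | None = None) -> StickSpectrum:
    """Stick spectrum of one effective Hamiltonian.

    ``initial`` defaults to F_x, ``detect`` to F^- = F_x - i F_y.
    """
    h = ham.matrix
    scale = max(np.linalg.norm(h), 1.0)
    if np.max(np.abs(h - h.conj().T)) > 1e-10 * scale:
        raise SpectrumError("effective Hamiltonian is not hermitian")
    n = int(np.log2(h.shape[0]))
    if initial is None:
        initial = ops.collective(n, "x")
    if detect is None:
        detect = ops.lowering(n)
    freq, inten, pairs = sticks_from_matrix(h, initial, detect)
    return StickSpectrum(frequencies_hz=freq, intensities=inten,
                         spinning_frequency_hz=ham.spinning_frequency_hz,
                         construction=ham.construction, state_pairs=pairs)


def sticks_stack(hbar: np.ndarray, weights: np.ndarray,
                 sigma0: np.ndarray, detect: np.ndarray):
    """Pooled transitions of a stack of hermitian matrices.

    ``hbar``: (norient, d, d); ``weights``: (norient,) powder weights folded
    into the intensities.  Returns (freq, inten) arrays, degenerates merged
    per orientation but not across orientations.
    """
    energies, vec = np.linalg.eigh(hbar)
    vh = vec.conj().swapaxes(-1, -2)
    sig = vh @ sigma0 @ vec
    det = vh @ detect @ vec
    amp = (sig * det.swapaxes(-1, -2)).real
    omega = (energies[..., :, None] - energies[..., None, :]) / (2.0 * np.pi)
    amp = amp * weights[:, None, None]
    total = abs(float(np.sum(amp)))
    keep = np.abs(amp) > INTENSITY_TOL * max(total, 1e-300)
    return omega[keep], amp[keep]


def moments(spectrum: StickSpectrum,
            region: SpectralRegion | None = None) -> MomentReport:
    """Intensity-weighted first/second moments of a spectral region.

    Raises :class:`EmptyRegionError` if no transition lies in the region and
    :class:`ZeroIntensityError` if transitions exist but carry no intensity.
    """
    freq = spectrum.frequencies_hz
    inten = spectrum.intensities
    if region is not None:
        m = region.mask(freq)
        freq, inten = freq[m], inten[m]
    if freq.size == 0:
        raise EmptyRegionError("no transitions in region")
    total = float(np.sum(inten))
    if total == 0.0:
        raise ZeroIntensityError("transitions in region have zero intensity")
    m1 = float(np.sum(freq * inten) / total)
    m2_raw = float(np.sum(freq**2 * inten) / total)
    m2_central = max(m2_raw - m1**2, 0.0)
    return MomentReport(m1_hz=m1, m2_raw_hz2=m2_raw,
                        m2_central_hz2=m2_central,
                        gaussian_fwhm_hz=GAUSSIAN_FWHM_FACTOR * np.sqrt(m2_central),
                        total_intensity=total, region=region)


@dataclass(frozen=True)
class BinnedSpectrum:
    frequencies_hz: np.ndarray
    amplitudes: np.ndarray

    @property
    def resolution_hz(self) -> float:
        return float(self.frequencies_hz[1] - self.frequencies_hz[0])

    @property
    def integral(self) -> float:
        return float(np.sum(self.amplitudes))


def bin_spectrum(spectrum: StickSpectrum, window_hz: float,
                 npoints: int, broadening_hz: float = 0.0,
                 center_hz: float = 0.0) -> BinnedSpectrum:
    """Intensity-conserving histogram of the sticks, optionally convolved
    with a Lorentzian of FWHM ``broadening_hz`` (the frequency-domain
    equivalent of exponential line broadening).

    Digital resolution is window/npoints; amplitudes hold the intensity per
    bin, so ``sum(amplitudes)`` equals the stick intensity inside the window.
    """
    if npoints < 2:
        raise SpectrumError("npoints must be >= 2")
    if broadening_hz < 0:
        raise SpectrumError("broadening must be >= 0")
    lo = center_hz - window_hz / 2.0
    hi = center_hz + window_hz / 2.0
    edges = np.linspace(lo, hi, npoints + 1)
    hist, _ = np.histogram(spectrum.frequencies_hz, bins=edges,
                           weights=spectrum.intensities)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if broadening_hz > 0.0:
        res = window_hz / npoints
        half = int(np.ceil(30.0 * broadening_hz / res))
        x = np.arange(-half, half + 1) * res
        g = broadening_hz / 2.0
        kern = g / (x**2 + g**2)
        kern /= kern.sum()
        hist = np.convolve(hist, kern, mode="same")
    return BinnedSpectrum(frequencies_hz=centers, amplitudes=hist)


def center_band(spectrum_or_wr, reference_hz: float = 0.0) -> SpectralRegion:
    """Center-band region (reference - nu_r/2, reference + nu_r/2].

    Accepts a :class:`StickSpectrum` (spinning frequency from metadata) or a
    spinning frequency in Hz.
    """
    wr = getattr(spectrum_or_wr, "spinning_frequency_hz", spectrum_or_wr)
    return SpectralRegion(((reference_hz - wr / 2.0, reference_hz + wr / 2.0),))


def assign_line_regions(spectrum: StickSpectrum, shifts_hz,
                        method: str = "midpoint",
                        gap_hz: float | None = None,
                        min_intensity: float = 1e-6) -> list[SpectralRegion]:
    """One region per resonance line, inside the center band.

    ``method="midpoint"`` partitions the center band at midpoints between
    consecutive isotropic shifts (regions tile the band; combination lines
    are absorbed by the nearest single-quantum region).  ``method="gap"``
    clusters the transition frequencies at gaps larger than ``gap_hz``
    (default nu_r/100) and returns, per shift, the cluster containing it;
    combination-line clusters are excluded from all line regions.

    Returns the regions in the order the shifts were given.
    """
    shifts = np.asarray(shifts_hz, dtype=float)
    if shifts.size < 1:
        raise SpectrumError("need at least one shift")
    band = center_band(spectrum)
    (blo, bhi), = band.intervals
    order = np.argsort(shifts)
    sorted_shifts = shifts[order]
    if method == "midpoint":
        mids = 0.5 * (sorted_shifts[:-1] + sorted_shifts[1:])
        bounds = np.concatenate([[blo], mids, [bhi]])
        regions_sorted = [SpectralRegion(((bounds[i], bounds[i + 1]),))
                          for i in range(sorted_shifts.size)]
    elif method == "gap":
        if gap_hz is None:
            gap_hz = spectrum.spinning_frequency_hz / 100.0
        mask = (np.abs(spectrum.intensities)
                > min_intensity * abs(spectrum.total_intensity))
        f = np.sort(spectrum.frequencies_hz[mask & band.mask(
            spectrum.frequencies_hz)])
        if f.size == 0:
            raise EmptyRegionError("no transitions in center band")
        splits = np.nonzero(np.diff(f) > gap_hz)[0]
        starts = np.concatenate([[0], splits + 1])
        ends = np.concatenate([splits, [f.size - 1]])
        clusters = [(f[a] - gap_hz / 2, f[b] + gap_hz / 2)
                    for a, b in zip(starts, ends)]
        regions_sorted = []
        for s in sorted_shifts:
            hit = [c for c in clusters if c[0] < s <= c[1]]
            if not hit:
                hit = [min(clusters, key=lambda c: min(abs(s - c[0]),
                                                       abs(s - c[1])))]
            regions_sorted.append(SpectralRegion((hit[0],)))
    else:
        raise SpectrumError(f"unknown method {method!r}")
    out: list[SpectralRegion] = [None] * shifts.size  # type: ignore
    for pos, reg in zip(order, regions_sorted):
        out[pos] = reg
    return out
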