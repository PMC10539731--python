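"""Deterministic powder sampling and powder averaging.

Orientations follow a ZCW-style equal-area low-discrepancy construction:
the polar cosine runs uniformly over [-1, 1] while the azimuth advances by
the golden angle, giving deterministic, RNG-free coverage of the sphere for
any requested count.  The crystallite gamma angle defaults to 0: eigenvalue
derived quantities depend on gamma only through the time origin of the
effective Hamiltonian, and a gamma grid can be requested for
intensity-sensitive studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import operators as ops
from .effective import effective_hamiltonian_stack
from .rotations import RotorOrientation, fourier_coefficient_stack
from .spectra import StickSpectrum, sticks_stack
from .spin_system import SpinSystem

#: Golden-section fraction used for the azimuthal progression.
_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0

#: Orientation chunk size for the exact construction (keeps the sliced
#: propagator working set at a few hundred MB).
_EXACT_CHUNK = 256


@dataclass(frozen=True)
class OrientationSet:
    """Deterministic set of crystallite orientations with uniform weights."""

    alpha_deg: np.ndarray
    beta_deg: np.ndarray
    gamma_deg: np.ndarray
    weights: np.ndarray
    scheme: str

    @property
    def count(self) -> int:
        return self.alpha_deg.size

    def __iter__(self):
        for a, b, g, w in zip(self.alpha_deg, self.beta_deg, self.gamma_deg,
                              self.weights):
            yield RotorOrientation(alpha_deg=float(a), beta_deg=float(b),
                                   gamma_deg=float(g), weight=float(w))

    def as_radians(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Angles in radians, as arrays."""
        return (np.deg2rad(self.alpha_deg), np.deg2rad(self.beta_deg),
                np.deg2rad(self.gamma_deg))


def zcw_orientations(count: int, sample_gamma: bool = False,
                     gamma_steps: int = 8) -> OrientationSet:
    """Equal-area ZCW-style orientation set.

    Parameters
    ----------
    count
        Number of (alpha, beta) crystallite orientations (>= 10).
    sample_gamma
        If set, each (alpha, beta) point is replicated over a uniform
        ``gamma_steps``-point gamma grid (weights renormalized).
    """
    if count < 10:
        raise ValueError("need at least 10 orientations")
    j = np.arange(count)
    alpha = 360.0 * np.mod(j * _GOLDEN, 1.0)
    cosb = -1.0 + (2.0 * j + 1.0) / count
    beta = np.degrees(np.arccos(cosb))
    if sample_gamma:
        if gamma_steps < 1:
            raise ValueError("gamma_steps must be >= 1")
        gam = 360.0 * np.arange(gamma_steps) / gamma_steps
        alpha = np.repeat(alpha, gamma_steps)
        beta = np.repeat(beta, gamma_steps)
        gamma = np.tile(gam, count)
    else:
        gamma = np.zeros_like(alpha)
    n = alpha.size
    return OrientationSet(alpha_deg=alpha, beta_deg=beta, gamma_deg=gamma,
                          weights=np.full(n, 1.0 / n),
                          scheme=f"zcw-golden-{count}"
                                 + ("-gamma" if sample_gamma else ""))


def powder_spectrum(system: SpinSystem, wr_hz: float, construction: str,
                    orientations: OrientationSet, n_slices: int = 1000,
                    initial: np.ndarray | None = None,
                    detect: np.ndarray | None = None) -> StickSpectrum:
    """Powder-averaged stick spectrum: transitions from every orientation
    pooled with their powder weights folded into the intensities.

    Pooling (rather than averaging per-orientation moments) is what makes
    the subsequent moment analysis match a moment analysis of the binned
    powder spectrum.
    """
    n = system.n_spins
    if initial is None:
        initial = ops.collective(n, "x")
    if detect is None:
        detect = ops.lowering(n)
    aniso = np.array([p.anisotropy for p in system.pairs])
    uvecs = np.stack([p.unit_vector for p in system.pairs])
    al, be, ga = orientations.as_radians()
    chunk = _EXACT_CHUNK if construction == "exact" else 8192
    freqs, intens = [], []
    for start in range(0, orientations.count, chunk):
        sl = slice(start, start + chunk)
        coeffs = fourier_coefficient_stack(aniso, uvecs, al[sl], be[sl],
                                           ga[sl])
        hbar = effective_hamiltonian_stack(system, coeffs, wr_hz,
                                           construction, n_slices)
        f, w = sticks_stack(hbar, orientations.weights[sl], initial, detect)
        freqs.append(f)
        intens.append(w)
    return StickSpectrum(frequencies_hz=np.concatenate(freqs),
                         intensities=np.concatenate(intens),
                         spinning_frequency_hz=wr_hz,
                         construction=construction,
                         metadata={"scheme": orientations.scheme,
                                   "n_orientations": orientations.count,
                                   "n_slices": n_slices})


def powder_average(per_orientation, orientations: OrientationSet):
    """Weighted accumulation of a per-orientation computation.

    ``per_orientation(orientation)`` may return a scalar/ndarray (weighted
    mean is returned) or a :class:`StickSpectrum` (transitions are pooled
    with weights folded into intensities, so moments of the result are the
    intensity-weighted powder moments).  Metadata (spinning frequency,
    construction) must agree across orientations.
    """
    pooled_f, pooled_i = [], []
    acc = None
    meta = None
    for ori in orientations:
        res = per_orientation(ori)
        if isinstance(res, StickSpectrum):
            key = (res.spinning_frequency_hz, res.construction)
            if meta is None:
                meta = key
            elif meta != key:
                raise ValueError(
                    f"inconsistent spectrum metadata across orientations: "
                    f"{meta} vs {key}")
            pooled_f.append(res.frequencies_hz)
            pooled_i.append(res.intensities * ori.weight)
        else:
            val = np.asarray(res, dtype=float) * ori.weight
            acc = val if acc is None else acc + val
    if meta is not None:
        return StickSpectrum(frequencies_hz=np.concatenate(pooled_f),
                             intensities=np.concatenate(pooled_i),
                             spinning_frequency_hz=meta[0],
                             construction=meta[1],
                             metadata={"scheme": orientations.scheme})
    return acc
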