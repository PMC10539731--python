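"""Spin systems: coordinates, shifts, pairwise dipolar couplings, orientations.

A spin system is specified by proton coordinates (angstrom), isotropic
chemical shifts (ppm) and a Larmor frequency (Hz).  From the coordinates we
derive, for every pair p < q, the internuclear distance, the dipolar-coupling
anisotropy

    delta_pq = -2 (mu0/4pi) gamma_p gamma_q hbar / r_pq^3      [rad s^-1]

and the orientation of the internuclear vector expressed in the crystallite
frame.  The crystallite frame is the principal-axis system of the reference
pair (1,2): its z axis points along r_1 -> r_2 and, when a third spin exists
that is not collinear with the first two, that spin lies in the x-z plane.
Planar systems therefore have all azimuths phi = 0.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field

import numpy as np

from .constants import GAMMA_H, HBAR, MU0_OVER_4PI

#: Minimum allowed internuclear distance (angstrom); closer spins would give
#: unphysically divergent couplings and usually indicate an input mistake.
MIN_DISTANCE_A = 0.5


class SpinSystemError(ValueError):
    """Raised for invalid spin-system input."""


def dipolar_anisotropy(distance_angstrom: float,
                       gamma1: float = GAMMA_H,
                       gamma2: float = GAMMA_H) -> float:
    """Dipolar-coupling anisotropy delta = -2 (mu0/4pi) g1 g2 hbar / r^3.

    Parameters
    ----------
    distance_angstrom
        Internuclear distance in angstrom (> 0).
    gamma1, gamma2
        Gyromagnetic ratios in rad s^-1 T^-1 (default: proton).

    Returns
    -------
    float
        Anisotropy in rad s^-1.  Negative for two like-sign gyromagnetic
        ratios; divide by 2 pi for the value in Hz.
    """
    if distance_angstrom <= 0:
        raise SpinSystemError(f"distance must be > 0, got {distance_angstrom}")
    r = distance_angstrom * 1e-10
    return -2.0 * MU0_OVER_4PI * gamma1 * gamma2 * HBAR / r**3


@dataclass(frozen=True)
class Spin:
    """One spin-1/2 nucleus.

    ``position`` is stored in the canonical crystallite frame (see module
    docstring), angstrom.  ``index`` is 1-based.
    """

    index: int
    position: np.ndarray
    shift_ppm: float = 0.0
    gamma: float = GAMMA_H

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise SpinSystemError(f"spin {self.index}: bad position {self.position}")
        object.__setattr__(self, "position", pos)


@dataclass(frozen=True)
class DipolarPair:
    """Dipolar coupling between spins p < q.

    ``theta_deg``/``phi_deg`` are the polar/azimuthal angles of the
    internuclear unit vector r_p -> r_q in the crystallite frame; the
    reference pair (1,2) has theta = phi = 0 by construction.
    ``anisotropy`` is in rad s^-1 (negative for two protons).
    """

    p: int
    q: int
    distance: float
    anisotropy: float
    theta_deg: float
    phi_deg: float

    @property
    def unit_vector(self) -> np.ndarray:
        th = math.radians(self.theta_deg)
        ph = math.radians(self.phi_deg)
        return np.array([math.sin(th) * math.cos(ph),
                         math.sin(th) * math.sin(ph),
                         math.cos(th)])


@dataclass(frozen=True)
class SpinSystem:
    """An ordered collection of spins with all pairwise dipolar couplings."""

    spins: tuple[Spin, ...]
    larmor_hz: float
    pairs: tuple[DipolarPair, ...] = field(default=())

    @property
    def n_spins(self) -> int:
        return len(self.spins)

    @property
    def dim(self) -> int:
        return 2 ** self.n_spins

    def pair(self, p: int, q: int) -> DipolarPair:
        lo, hi = min(p, q), max(p, q)
        for pr in self.pairs:
            if (pr.p, pr.q) == (lo, hi):
                return pr
        raise SpinSystemError(f"no pair ({p},{q}) in system")

    def zeeman_frequencies_hz(self) -> np.ndarray:
        """Isotropic-shift offsets omega_p/(2 pi) = shift_ppm * larmor * 1e-6, Hz."""
        return np.array([s.shift_ppm * self.larmor_hz * 1e-6 for s in self.spins])

    def zeeman_frequencies_rad(self) -> np.ndarray:
        return 2.0 * np.pi * self.zeeman_frequencies_hz()

    def coordinates(self) -> np.ndarray:
        return np.stack([s.position for s in self.spins])

    def subsystem(self, indices: tuple[int, ...]) -> "SpinSystem":
        """Sub-system of the given (1-based) spins, couplings re-derived
        from the same coordinates.  Used for the three-spin decomposition
        of multi-spin second moments."""
        if len(set(indices)) < 2:
            raise SpinSystemError("subsystem needs >= 2 distinct spins")
        coords = [self.spins[i - 1].position for i in indices]
        shifts = [self.spins[i - 1].shift_ppm for i in indices]
        gammas = [self.spins[i - 1].gamma for i in indices]
        return build_spin_system(coords, shifts, self.larmor_hz, gammas=gammas)


def _canonical_frame(coords: np.ndarray) -> np.ndarray:
    """Rotate/translate coordinates into the PAS of pair (1,2).

    z along r1->r2; the first spin not collinear with (1,2) fixes the x-z
    plane.  Degenerate (all-collinear) systems get an arbitrary transverse
    frame, which is irrelevant because all theta are then 0 or 180 degrees.
    """
    coords = coords - coords[0]
    z = coords[1] - coords[0]
    nz = np.linalg.norm(z)
    if nz < MIN_DISTANCE_A:
        raise SpinSystemError("spins 1 and 2 coincide (or are closer than 0.5 A)")
    z = z / nz
    x = None
    for c in coords[2:]:
        v = c - np.dot(c, z) * z
        if np.linalg.norm(v) > 1e-9:
            x = v / np.linalg.norm(v)
            break
    if x is None:
        # collinear system: any transverse direction will do
        trial = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(trial, z)) > 0.9:
            trial = np.array([0.0, 1.0, 0.0])
        v = trial - np.dot(trial, z) * z
        x = v / np.linalg.norm(v)
    y = np.cross(z, x)
    rot = np.stack([x, y, z])  # rows: new basis vectors
    return coords @ rot.T


def build_spin_system(coordinates,
                      shifts_ppm=None,
                      larmor_hz: float = 1.0e9,
                      gammas=None) -> SpinSystem:
    """Build a :class:`SpinSystem` from raw coordinates and shifts.

    Coordinates are in angstrom and may be given in any lab frame; they are
    moved into the canonical crystallite frame (z along r1->r2).  Shifts in
    ppm; ``larmor_hz`` converts them to Hz.
    """
    coords = np.asarray(coordinates, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 2:
        raise SpinSystemError("need >= 2 spins, each a 3-vector in angstrom")
    n = coords.shape[0]
    if shifts_ppm is None:
        shifts_ppm = [0.0] * n
    if len(shifts_ppm) != n:
        raise SpinSystemError("one shift per spin required")
    if gammas is None:
        gammas = [GAMMA_H] * n
    coords = _canonical_frame(coords)

    spins = tuple(
        Spin(index=i + 1, position=coords[i], shift_ppm=float(shifts_ppm[i]),
             gamma=float(gammas[i]))
        for i in range(n)
    )
    pairs = []
    for p in range(n):
        for q in range(p + 1, n):
            d = coords[q] - coords[p]
            r = float(np.linalg.norm(d))
            if r < MIN_DISTANCE_A:
                raise SpinSystemError(
                    f"spins {p + 1} and {q + 1} closer than {MIN_DISTANCE_A} A")
            u = d / r
            theta = math.degrees(math.acos(np.clip(u[2], -1.0, 1.0)))
            if abs(u[0]) < 1e-12 and abs(u[1]) < 1e-12:
                phi = 0.0
            else:
                phi = math.degrees(math.atan2(u[1], u[0])) % 360.0
                if abs(phi) < 1e-9 or abs(phi - 360.0) < 1e-9:
                    phi = 0.0
            pairs.append(DipolarPair(
                p=p + 1, q=q + 1, distance=r,
                anisotropy=dipolar_anisotropy(r, spins[p].gamma, spins[q].gamma),
                theta_deg=theta, phi_deg=phi))
    return SpinSystem(spins=spins, larmor_hz=float(larmor_hz), pairs=tuple(pairs))


def pair_orientation(system: SpinSystem, p: int, q: int) -> tuple[float, float]:
    """(theta, phi) in degrees of the r_p -> r_q direction, crystallite frame."""
    if p == q:
        raise SpinSystemError("p and q must differ")
    pr = system.pair(p, q)
    if (p, q) == (pr.p, pr.q):
        return pr.theta_deg, pr.phi_deg
    # reversed direction: antipodal point on the sphere
    theta = 180.0 - pr.theta_deg
    phi = (pr.phi_deg + 180.0) % 360.0
    return theta, phi


# ---------------------------------------------------------------------------
# TOML I/O


def from_toml(path) -> SpinSystem:
    """Read a spin system from a TOML file.

    Expected layout::

        larmor_hz = 1.0e9
        [[spin]]
        position = [0.0, 0.0, 0.0]
        shift_ppm = 0.0
    """
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    try:
        larmor = float(data.get("larmor_hz", 1.0e9))
        spins = data["spin"]
        coords = [s["position"] for s in spins]
        shifts = [float(s.get("shift_ppm", 0.0)) for s in spins]
    except (KeyError, TypeError) as exc:
        raise SpinSystemError(f"malformed spin-system file {path}: {exc}") from exc
    return build_spin_system(coords, shifts, larmor)


def to_toml_str(system: SpinSystem, comment: str = "") -> str:
    lines = []
    if comment:
        for ln in comment.splitlines():
            lines.append(f"# {ln}")
    lines.append(f"larmor_hz = {system.larmor_hz!r}")
    for s in system.spins:
        lines.append("")
        lines.append("[[spin]]")
        pos = ", ".join(repr(float(x)) for x in s.position)
        lines.append(f"position = [{pos}]")
        lines.append(f"shift_ppm = {s.shift_ppm!r}")
    return "\n".join(lines) + "\n"
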