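"""Rank-2 reduced Wigner elements and rotor-periodic dipolar Fourier coefficients.

Under magic-angle spinning the secular dipolar coupling of a pair becomes
rotor-periodic,

    omega_pq(t) = sum_{m=-2}^{2} omega_pq^(m) exp(i m w_r t),

where the five complex coefficients depend on the orientation of the
internuclear vector in the rotor frame.  The normalization is fixed by the
static limit: for a pair along the field, omega = delta/2 multiplying the
operator 2 I_pz I_qz - I_px I_qx - I_py I_qy.

Euler convention: ZYZ, active rotations; a crystallite orientation
(alpha, beta, gamma) maps crystallite-frame vectors into the rotor frame via
R_z(gamma) R_y(beta) R_z(alpha).  With this ordering (alpha, beta) are the
azimuth and polar angle of the rotor axis seen from the crystallite -- the
two angles a powder scheme must cover -- while gamma is the rotor phase at
t = 0: eigenvalue-derived quantities depend on it only through the time
origin of the effective Hamiltonian, so it defaults to 0.  The overall phase
convention is fixed by the brute-force rotation oracle used in the tests;
powder-averaged observables do not depend on it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import MAGIC_ANGLE

_SQ38 = np.sqrt(3.0 / 8.0)
_SQ32 = np.sqrt(3.0 / 2.0)


def reduced_wigner(m: int, mp: int, beta_deg: float) -> float:
    """Rank-2 reduced Wigner element d^2_{m,mp}(beta), beta in degrees.

    Convention: d^2_{m,mp}(beta) = <2 m| exp(-i beta J_y) |2 mp>.
    """
    if abs(m) > 2 or abs(mp) > 2:
        raise ValueError(f"|m|, |m'| must be <= 2, got ({m}, {mp})")
    b = np.deg2rad(beta_deg)
    c, s = np.cos(b), np.sin(b)
    key = (m, mp)
    table = {
        (2, 2): (1 + c) ** 2 / 4,
        (2, 1): -s * (1 + c) / 2,
        (2, 0): _SQ38 * s**2,
        (2, -1): -s * (1 - c) / 2,
        (2, -2): (1 - c) ** 2 / 4,
        (1, 1): (1 + c) * (2 * c - 1) / 2,
        (1, 0): -_SQ32 * s * c,
        (1, -1): (1 - c) * (2 * c + 1) / 2,
        (0, 0): (3 * c**2 - 1) / 2,
    }
    if key in table:
        return float(table[key])
    # symmetry completion: d_{m,m'} = (-1)^{m-m'} d_{m',m} = d_{-m',-m}
    if (mp, m) in table:
        return float((-1) ** (m - mp) * table[(mp, m)])
    if (-mp, -m) in table:
        return float(table[(-mp, -m)])
    return float((-1) ** (m - mp) * table[(-m, -mp)])


def reduced_wigner_matrix(beta_deg: float) -> np.ndarray:
    """Full 5x5 table d^2_{m,mp}(beta), rows/cols ordered m = -2..2."""
    return np.array([[reduced_wigner(m, mp, beta_deg)
                      for mp in range(-2, 3)] for m in range(-2, 3)])


def rotation_matrix_zyz(alpha: float, beta: float, gamma: float) -> np.ndarray:
    """Active ZYZ rotation matrix R_z(alpha) R_y(beta) R_z(gamma), radians."""
    ca, sa = np.cos(alpha), np.sin(alpha)
    cb, sb = np.cos(beta), np.sin(beta)
    cg, sg = np.cos(gamma), np.sin(gamma)
    rz_a = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1.0]])
    ry_b = np.array([[cb, 0, sb], [0, 1.0, 0], [-sb, 0, cb]])
    rz_g = np.array([[cg, -sg, 0], [sg, cg, 0], [0, 0, 1.0]])
    return rz_a @ ry_b @ rz_g


@dataclass(frozen=True)
class RotorOrientation:
    """Euler angles (degrees) taking the crystallite frame into the rotor
    frame via R_z(gamma) R_y(beta) R_z(alpha), with a quadrature weight
    (weights of an orientation set sum to 1).  (alpha, beta) locate the
    rotor axis on the crystallite sphere; gamma is the rotor phase."""

    alpha_deg: float
    beta_deg: float
    gamma_deg: float = 0.0
    weight: float = 1.0

    def __post_init__(self):
        if not self.weight > 0:
            raise ValueError("orientation weight must be > 0")


def _rotor_frame_angles(unit_vectors: np.ndarray,
                        alpha: np.ndarray,
                        beta: np.ndarray,
                        gamma: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Polar angle and azimuth of pair vectors in the rotor frame.

    unit_vectors: (npair, 3); alpha/beta/gamma: (norient,) radians.
    Returns (norient, npair) arrays.
    """
    ca, sa = np.cos(alpha), np.sin(alpha)
    cb, sb = np.cos(beta), np.sin(beta)
    cg, sg = np.cos(gamma), np.sin(gamma)
    # rows of R_z(g) R_y(b) R_z(a) written out to avoid a (norient,3,3) einsum
    r = np.empty((alpha.size, 3, 3))
    r[:, 0, 0] = cg * cb * ca - sg * sa
    r[:, 0, 1] = -cg * cb * sa - sg * ca
    r[:, 0, 2] = cg * sb
    r[:, 1, 0] = sg * cb * ca + cg * sa
    r[:, 1, 1] = -sg * cb * sa + cg * ca
    r[:, 1, 2] = sg * sb
    r[:, 2, 0] = -sb * ca
    r[:, 2, 1] = sb * sa
    r[:, 2, 2] = cb
    v = np.einsum("oij,pj->opi", r, unit_vectors)
    beta_r = np.arccos(np.clip(v[..., 2], -1.0, 1.0))
    gamma_r = np.arctan2(v[..., 1], v[..., 0])
    return beta_r, gamma_r


def fourier_coefficient_stack(anisotropies: np.ndarray,
                              unit_vectors: np.ndarray,
                              alpha_rad: np.ndarray,
                              beta_rad: np.ndarray,
                              gamma_rad: np.ndarray) -> np.ndarray:
    """Dipolar Fourier coefficients for many orientations at once.

    Parameters
    ----------
    anisotropies
        (npair,) couplings delta_pq in rad s^-1.
    unit_vectors
        (npair, 3) internuclear directions in the crystallite frame.
    alpha_rad, beta_rad, gamma_rad
        (norient,) crystallite -> rotor Euler angles, radians.

    Returns
    -------
    ndarray, complex, shape (norient, npair, 5)
        omega^(m) for m = -2..2 (index m+2), rad s^-1.  omega^(0) = 0 at
        the magic angle; omega^(-m) = conj(omega^(m)).
    """
    beta_r, gamma_r = _rotor_frame_angles(unit_vectors, alpha_rad, beta_rad,
                                          gamma_rad)
    s, c = np.sin(beta_r), np.cos(beta_r)
    half_delta = 0.5 * anisotropies[np.newaxis, :]
    w1 = -half_delta * (np.sqrt(2.0) / 2.0) * s * c * np.exp(1j * gamma_r)
    w2 = half_delta * 0.25 * s**2 * np.exp(2j * gamma_r)
    out = np.zeros(beta_r.shape + (5,), dtype=complex)
    out[..., 3] = w1
    out[..., 4] = w2
    out[..., 1] = np.conj(w1)
    out[..., 0] = np.conj(w2)
    return out


def dipolar_fourier_coefficients(pair, orientation: RotorOrientation) -> np.ndarray:
    """Five Fourier coefficients omega^(m), m = -2..2, for one pair and one
    crystallite orientation.  See :func:`fourier_coefficient_stack`."""
    out = fourier_coefficient_stack(
        np.array([pair.anisotropy]),
        pair.unit_vector[np.newaxis, :],
        np.array([np.deg2rad(orientation.alpha_deg)]),
        np.array([np.deg2rad(orientation.beta_deg)]),
        np.array([np.deg2rad(orientation.gamma_deg)]),
    )
    return out[0, 0]


def lab_coupling_trace(pair, orientation: RotorOrientation,
                       rotor_period_fractions: np.ndarray) -> np.ndarray:
    """Brute-force omega_pq(t) over one rotor period by Cartesian rotation.

    Rotates the internuclear vector into the rotor frame, spins it about the
    rotor axis and tilts by the magic angle into the lab frame; returns
    delta/2 * (3 cos^2 Theta(t) - 1)/2 at the given fractions of the rotor
    period.  This is the independent oracle for the Fourier coefficients.
    """
    rot = rotation_matrix_zyz(np.deg2rad(orientation.gamma_deg),
                              np.deg2rad(orientation.beta_deg),
                              np.deg2rad(orientation.alpha_deg))
    v_rot = rot @ pair.unit_vector
    phases = 2.0 * np.pi * np.asarray(rotor_period_fractions)
    out = np.empty(phases.shape)
    tilt = rotation_matrix_zyz(0.0, MAGIC_ANGLE, 0.0)
    for i, ph in enumerate(phases):
        spin = rotation_matrix_zyz(ph, 0.0, 0.0)
        v_lab = tilt @ (spin @ v_rot)
        cos_t = v_lab[2]
        out[i] = 0.5 * pair.anisotropy * 0.5 * (3.0 * cos_t**2 - 1.0)
    return out
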