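"""Effective Hamiltonians under MAS: Floquet orders 1-3 and numerically exact.

The rotor-periodic Hamiltonian H(t) = sum_n H^(n) exp(i n w_r t) (n = -2..2)
is built from the spin system's shift and dipolar terms.  Two routes to a
time-independent description are provided:

* perturbative: single-mode Floquet (van Vleck) effective Hamiltonians,
  truncated at order 1, 2 or 3, built from commutators of the H^(n);
* exact: the time-ordered propagator over one rotor period, computed by
  midpoint time slicing, followed by the principal matrix logarithm
  H = (i/tau_r) ln U(tau_r), evaluated through the Schur form of the
  unitary so that hermiticity and the principal branch are guaranteed.

All Hamiltonian matrices are in rad s^-1; spinning frequencies are given in
Hz and converted internally (w_r = 2 pi nu_r).

Functions with a ``_stack`` suffix operate on arrays with a leading
orientation axis; the dataclass-based API wraps them for single orientations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import operators as ops
from .rotations import RotorOrientation, fourier_coefficient_stack
from .spin_system import SpinSystem

_CONSTRUCTIONS = ("order1", "order2", "order3", "exact")


@dataclass(frozen=True)
class FourierHamiltonian:
    """Operator-valued Fourier components H^(n), n = -2..2.

    ``components`` has shape (5, d, d) with index n+2; rad s^-1.
    H^(-n) = H^(n) dagger; H^(0) holds only the shift terms because the
    m = 0 spatial component vanishes at the magic angle.
    """

    components: np.ndarray
    system: SpinSystem
    orientation: RotorOrientation

    def component(self, n: int) -> np.ndarray:
        if abs(n) > 2:
            raise ValueError("n must be in -2..2")
        return self.components[n + 2]

    def at_time(self, t: float, wr_hz: float) -> np.ndarray:
        """Reconstruct H(t) for spinning frequency wr_hz."""
        w = 2.0 * np.pi * wr_hz
        phases = np.exp(1j * np.arange(-2, 3) * w * t)
        return np.einsum("n,nij->ij", phases, self.components)


@dataclass(frozen=True)
class EffectiveHamiltonian:
    """A hermitian effective Hamiltonian tagged with its construction."""

    matrix: np.ndarray
    construction: str
    spinning_frequency_hz: float
    orientation: RotorOrientation | None = None

    def __post_init__(self):
        if self.construction not in _CONSTRUCTIONS:
            raise ValueError(f"unknown construction {self.construction!r}")

    def eigenvalues_hz(self) -> np.ndarray:
        return np.linalg.eigvalsh(self.matrix) / (2.0 * np.pi)


# ---------------------------------------------------------------------------
# Fourier components of the Hamiltonian


def pair_operator_stack(system: SpinSystem) -> np.ndarray:
    """(npair, d, d) array of 2 I_pz I_qz - I_px I_qx - I_py I_qy."""
    n = system.n_spins
    return np.stack([ops.dipolar_pair_operator(n, pr.p, pr.q)
                     for pr in system.pairs])


def shift_hamiltonian(system: SpinSystem) -> np.ndarray:
    """H^(0) = sum_p omega_p I_pz (rad s^-1), diagonal in the Zeeman basis."""
    n = system.n_spins
    freqs = system.zeeman_frequencies_rad()
    h0 = np.zeros((system.dim, system.dim), dtype=complex)
    for p, w in enumerate(freqs, start=1):
        if w != 0.0:
            h0 += w * ops.single_spin(n, p, "z")
    return h0


def hamiltonian_fourier_stack(system: SpinSystem,
                              coefficients: np.ndarray) -> np.ndarray:
    """Assemble H^(n) for a stack of orientations.

    ``coefficients``: (norient, npair, 5) from
    :func:`masfloquet.rotations.fourier_coefficient_stack`.
    Returns (norient, 5, d, d), rad s^-1.
    """
    a_ops = pair_operator_stack(system)
    hn = np.einsum("opn,pij->onij", coefficients, a_ops)
    hn[:, 2] += shift_hamiltonian(system)
    return hn


def fourier_hamiltonian(system: SpinSystem,
                        orientation: RotorOrientation) -> FourierHamiltonian:
    """Fourier components of the rotor-periodic Hamiltonian for one
    crystallite orientation."""
    coeffs = fourier_coefficient_stack(
        np.array([pr.anisotropy for pr in system.pairs]),
        np.stack([pr.unit_vector for pr in system.pairs]),
        np.array([np.deg2rad(orientation.alpha_deg)]),
        np.array([np.deg2rad(orientation.beta_deg)]),
        np.array([np.deg2rad(orientation.gamma_deg)]),
    )
    hn = hamiltonian_fourier_stack(system, coeffs)[0]
    return FourierHamiltonian(components=hn, system=system,
                              orientation=orientation)


# ---------------------------------------------------------------------------
# Floquet effective Hamiltonians


def _comm(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return a @ b - b @ a


def floquet_stack(hn: np.ndarray, wr_hz: float, max_order: int) -> np.ndarray:
    """Van Vleck effective Hamiltonian truncated at ``max_order``.

    ``hn``: (..., 5, d, d) Fourier components (index n+2).  Returns
    (..., d, d).  The order-k contribution scales as w_r^-(k-1).
    """
    if max_order not in (1, 2, 3):
        raise ValueError(f"max_order must be 1, 2 or 3, got {max_order}")
    if wr_hz <= 0:
        raise ValueError("spinning frequency must be > 0")
    w = 2.0 * np.pi * wr_hz
    h = {n: hn[..., n + 2, :, :] for n in range(-2, 3)}
    hbar = h[0].copy()
    if max_order >= 2:
        # (1/2) sum_{n!=0} [H(n), H(-n)]/(n w): +/- n pairs combine
        h2 = sum(_comm(h[n], h[-n]) / n for n in (1, 2)) / w
        hbar = hbar + h2
    if max_order >= 3:
        nz = (-2, -1, 1, 2)
        t1 = sum(_comm(h[n], _comm(h[0], h[-n])) / n**2 for n in nz)
        t2 = 0.0
        # k = -n is excluded: those terms reproduce the H(0) cross commutator
        # already counted (with weight 1/2) in t1, and including them spoils
        # the w_r^-3 convergence toward the exact effective Hamiltonian
        for n in nz:
            for k in nz:
                m = -k - n
                if abs(m) > 2 or m == 0:
                    continue
                t2 = t2 + _comm(h[n], _comm(h[k], h[m])) / (n * k)
        hbar = hbar + (0.5 * t1 + t2 / 3.0) / w**2
    return hbar


def floquet_effective(fh: FourierHamiltonian, wr_hz: float,
                      max_order: int) -> EffectiveHamiltonian:
    """Floquet effective Hamiltonian of order 1, 2 or 3 for one orientation."""
    hbar = floquet_stack(fh.components[np.newaxis], wr_hz, max_order)[0]
    return EffectiveHamiltonian(matrix=hbar, construction=f"order{max_order}",
                                spinning_frequency_hz=wr_hz,
                                orientation=fh.orientation)


# ---------------------------------------------------------------------------
# Exact effective Hamiltonian via the rotor-period propagator


def propagator_stack(hn: np.ndarray, wr_hz: float,
                     n_slices: int = 1000) -> np.ndarray:
    """Time-ordered propagator over one rotor period, midpoint slicing.

    ``hn``: (norient, 5, d, d).  Returns (norient, d, d) unitaries.
    The midpoint rule gives a global defect decreasing as n_slices^-2.
    """
    if n_slices < 4:
        raise ValueError("n_slices must be >= 4")
    w = 2.0 * np.pi * wr_hz
    tau = 1.0 / wr_hz
    dt = tau / n_slices
    t_mid = (np.arange(n_slices) + 0.5) * dt
    phases = np.exp(1j * np.outer(t_mid, np.arange(-2, 3)) * w)  # (S, 5)
    # slice Hamiltonians (norient, S, d, d); hermitian by construction
    ht = np.einsum("sn,onij->osij", phases, hn)
    lam, vec = np.linalg.eigh(ht)
    u = np.einsum("osik,osk,osjk->osij", vec, np.exp(-1j * lam * dt),
                  np.conj(vec))
    # time-ordered product U = U_{S-1} ... U_0 via pairwise tree reduction;
    # slice index increases with time throughout the reduction
    while u.shape[1] > 1:
        if u.shape[1] % 2:
            tail = u[:, -1:]
            u = u[:, :-1]
        else:
            tail = None
        u = np.matmul(u[:, 1::2], u[:, 0::2])
        if tail is not None:
            u = np.concatenate([u, tail], axis=1)
    return u[:, 0]


def propagator(fh: FourierHamiltonian, wr_hz: float,
               n_slices: int = 1000) -> np.ndarray:
    """Rotor-period propagator for one orientation (see propagator_stack)."""
    return propagator_stack(fh.components[np.newaxis], wr_hz, n_slices)[0]


def exact_effective_stack(u: np.ndarray, wr_hz: float,
                          branch_tol: float = 1e-6) -> np.ndarray:
    """Principal-branch effective Hamiltonians from rotor-period unitaries.

    H = (i/tau_r) ln U via the complex Schur form (diagonal for a normal
    matrix), eigenphases taken in (-pi, pi] so eigenvalues lie in
    (-w_r/2, +w_r/2] (Hz scale: (-nu_r/2, +nu_r/2]).  Warns when an
    eigenphase sits within ``branch_tol`` * 2 pi of the branch cut.
    """
    from scipy.linalg import schur

    u = np.asarray(u)
    single = u.ndim == 2
    if single:
        u = u[np.newaxis]
    tau = 1.0 / wr_hz
    out = np.empty_like(u)
    for i, ui in enumerate(u):
        t, z = schur(ui, output="complex")
        phases = np.angle(np.diag(t))  # in (-pi, pi]
        if np.any(np.pi - np.abs(phases) < branch_tol * 2.0 * np.pi):
            warnings.warn(
                "eigenphase close to the +/-pi branch cut; effective "
                "eigenvalues are only defined modulo the spinning frequency",
                RuntimeWarning, stacklevel=2)
        energies = -phases / tau  # rad s^-1, in (-w_r/2, +w_r/2]
        h = (z * energies) @ z.conj().T
        out[i] = 0.5 * (h + h.conj().T)
    return out[0] if single else out


def exact_effective(u: np.ndarray, wr_hz: float,
                    orientation: RotorOrientation | None = None,
                    branch_tol: float = 1e-6) -> EffectiveHamiltonian:
    """Exact effective Hamiltonian from a rotor-period propagator."""
    h = exact_effective_stack(u, wr_hz, branch_tol=branch_tol)
    return EffectiveHamiltonian(matrix=h, construction="exact",
                                spinning_frequency_hz=wr_hz,
                                orientation=orientation)


def effective_hamiltonian_stack(system: SpinSystem,
                                coefficients: np.ndarray,
                                wr_hz: float,
                                construction: str,
                                n_slices: int = 1000) -> np.ndarray:
    """One-call route from Fourier coefficients to effective Hamiltonians."""
    hn = hamiltonian_fourier_stack(system, coefficients)
    if construction == "exact":
        u = propagator_stack(hn, wr_hz, n_slices)
        return exact_effective_stack(u, wr_hz)
    order = {"order1": 1, "order2": 2, "order3": 3}.get(construction)
    if order is None:
        raise ValueError(f"unknown construction {construction!r}")
    return floquet_stack(hn, wr_hz, order)
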