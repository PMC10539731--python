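"""Spin-1/2 product operators on the Zeeman product basis.

Basis ordering: spin 1 is the most significant qubit, the all-up state
|up...up> comes first.  All matrices are dense complex ndarrays of dimension
2^N; the systems of interest here are small (N <= 5).
"""

from functools import lru_cache

import numpy as np

_IX = np.array([[0.0, 0.5], [0.5, 0.0]], dtype=complex)
_IY = np.array([[0.0, -0.5j], [0.5j, 0.0]], dtype=complex)
_IZ = np.array([[0.5, 0.0], [0.0, -0.5]], dtype=complex)
_ID = np.eye(2, dtype=complex)

_SINGLE = {"x": _IX, "y": _IY, "z": _IZ}


def _kron_chain(mats):
    out = mats[0]
    for m in mats[1:]:
        out = np.kron(out, m)
    return out


@lru_cache(maxsize=None)
def single_spin(n_spins: int, index: int, axis: str) -> np.ndarray:
    """Operator I_{index,axis} embedded in the N-spin product space.

    ``index`` is 1-based, matching the spin-system numbering.
    """
    if axis not in _SINGLE:
        raise ValueError(f"axis must be one of x, y, z, got {axis!r}")
    if not 1 <= index <= n_spins:
        raise ValueError(f"spin index {index} outside 1..{n_spins}")
    mats = [_ID] * n_spins
    mats[index - 1] = _SINGLE[axis]
    out = _kron_chain(mats)
    out.setflags(write=False)
    return out


@lru_cache(maxsize=None)
def collective(n_spins: int, axis: str) -> np.ndarray:
    """Total spin operator F_axis = sum_p I_{p,axis}."""
    out = sum(single_spin(n_spins, p, axis) for p in range(1, n_spins + 1))
    out.setflags(write=False)
    return out


@lru_cache(maxsize=None)
def lowering(n_spins: int) -> np.ndarray:
    """F^- = F_x - i F_y, the standard detection operator."""
    out = collective(n_spins, "x") - 1j * collective(n_spins, "y")
    out.setflags(write=False)
    return out


@lru_cache(maxsize=None)
def raising(n_spins: int) -> np.ndarray:
    out = collective(n_spins, "x") + 1j * collective(n_spins, "y")
    out.setflags(write=False)
    return out


@lru_cache(maxsize=None)
def dipolar_pair_operator(n_spins: int, p: int, q: int) -> np.ndarray:
    """Secular homonuclear dipolar operator 2 I_pz I_qz - I_px I_qx - I_py I_qy."""
    if p == q:
        raise ValueError("dipolar operator needs two distinct spins")
    out = (
        2.0 * single_spin(n_spins, p, "z") @ single_spin(n_spins, q, "z")
        - single_spin(n_spins, p, "x") @ single_spin(n_spins, q, "x")
        - single_spin(n_spins, p, "y") @ single_spin(n_spins, q, "y")
    )
    out.setflags(write=False)
    return out


def commutator(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return a @ b - b @ a


def zeeman_magnetization(n_spins: int) -> np.ndarray:
    """Diagonal of F_z: total magnetic quantum number M per basis state."""
    return np.real(np.diag(collective(n_spins, "z")))
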