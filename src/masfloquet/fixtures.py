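"""Built-in model spin systems.

These are the small proton clusters used throughout the package's numerical
studies: a CH2-like strongly coupled pair with one (three-spin) or two
(four-spin) more distant protons, with or without isotropic chemical-shift
differences, plus an isoceles three-spin mimic of the CH2/CaH protons of a
crystalline amino-acid phosphate.  Coordinates in angstrom; couplings are
derived from the coordinates, never entered by hand.
"""

from __future__ import annotations

from .spin_system import SpinSystem, build_spin_system

#: CH2-like pair (r12 = 1.75 A) plus a remote proton at 3.0 A.
#: Derived couplings (Hz): delta12/2pi = -44826, delta13/2pi = -8898,
#: delta23/2pi = -5734 (r23 = 3.47 A, theta13 = 90 deg, theta23 = 120 deg).
#: Note: one printed source rounds delta23/2pi to -5750 Hz; the coordinates
#: give -5734 Hz and the coordinate-derived value is used.
_THREE_SPIN_COORDS = [[0.0, 0.0, 0.0], [0.0, 0.0, 1.75], [3.0, 0.0, 0.0]]

#: Four-spin extension: fourth proton at (3.5, 0, 2.0) A in the same plane.
#: Extra couplings (Hz): delta14/2pi = -3667, delta24/2pi = -5561,
#: delta34/2pi = -27420.
_FOUR_SPIN_COORDS = _THREE_SPIN_COORDS + [[3.5, 0.0, 2.0]]


def three_spin(shifts_ppm=(0.0, 0.0, 0.0), larmor_hz: float = 1.0e9) -> SpinSystem:
    """The planar three-spin CH2 mimic (optionally with shifts)."""
    return build_spin_system(_THREE_SPIN_COORDS, list(shifts_ppm), larmor_hz)


def three_spin_one_shift(larmor_hz: float = 1.0e9) -> SpinSystem:
    """Three-spin system with shifts 0, 0, 0.7 ppm (one shifted line)."""
    return three_spin((0.0, 0.0, 0.7), larmor_hz)


def three_spin_three_shifts(larmor_hz: float = 1.0e9) -> SpinSystem:
    """Three-spin system with shifts -0.1, 0.2, 0.7 ppm (three lines)."""
    return three_spin((-0.1, 0.2, 0.7), larmor_hz)


def four_spin(shifts_ppm=(0.0, 0.0, 0.0, 0.0), larmor_hz: float = 1.0e9) -> SpinSystem:
    """The planar four-spin system (CH2 mimic plus two remote protons)."""
    return build_spin_system(_FOUR_SPIN_COORDS, list(shifts_ppm), larmor_hz)


def serine_phosphate_mimic(shifts_ppm=(4.4, 3.9, 4.8),
                           larmor_hz: float = 851.4e6) -> SpinSystem:
    """Isoceles three-spin mimic of the CH2/CaH protons of crystalline
    ortho-phospho-L-serine: r12 = 1.60 A, r13 = r23 = 2.35 A (apex angles
    at spins 1 and 2 of 70 degrees).

    The default shifts are representative CH2/CaH proton values; the default
    Larmor frequency corresponds to a 20 T magnet.  Both are adjustable --
    the line-shift study probes their spinning-frequency dependence, not
    their absolute values.
    """
    import math

    r13 = 2.35
    apex = math.radians(70.0)
    coords = [[0.0, 0.0, 0.0], [0.0, 0.0, 1.60],
              [r13 * math.sin(apex), 0.0, r13 * math.cos(apex)]]
    return build_spin_system(coords, list(shifts_ppm), larmor_hz)


FIXTURES = {
    "three-spin": three_spin,
    "three-spin-one-shift": three_spin_one_shift,
    "three-spin-three-shifts": three_spin_three_shifts,
    "four-spin": four_spin,
    "serine-phosphate-mimic": serine_phosphate_mimic,
}


def get_fixture(name: str) -> SpinSystem:
    try:
        return FIXTURES[name]()
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}") from None
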