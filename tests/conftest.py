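import numpy as np
import pytest

import masfloquet as mf


@pytest.fixture(scope="session")
def three_spin():
    """Planar CH2-mimic three-spin system, no shifts."""
    return mf.three_spin()


@pytest.fixture(scope="session")
def three_spin_shifted():
    """Three-spin system with shifts -0.1, 0.2, 0.7 ppm at 1 GHz."""
    return mf.three_spin_three_shifts()


@pytest.fixture(scope="session")
def four_spin():
    return mf.four_spin()


@pytest.fixture(scope="session")
def small_powder():
    """Small deterministic orientation set for fast powder averages."""
    return mf.zcw_orientations(300)


@pytest.fixture()
def rng():
    return np.random.default_rng(20210701)


def random_orientation(rng):
    return mf.RotorOrientation(alpha_deg=float(rng.uniform(0, 360)),
                               beta_deg=float(np.degrees(
                                   np.arccos(rng.uniform(-1, 1)))),
                               gamma_deg=float(rng.uniform(0, 360)))


def random_system(rng, n_spins=3, with_shifts=True):
    """Random compact proton cluster with pair distances >= 1.2 A."""
    while True:
        coords = rng.uniform(-2.5, 2.5, size=(n_spins, 3))
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        if np.all(d[np.triu_indices(n_spins, 1)] > 1.2):
            break
    shifts = rng.uniform(-1, 1, n_spins) if with_shifts else np.zeros(n_spins)
    return mf.build_spin_system(coords, shifts, 1e9)
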