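"""Physical constants and fixed geometry used throughout the package.

All internal angular frequencies are in rad s^-1; user-facing I/O is in Hz
and ppm.
"""

import numpy as np

#: Proton gyromagnetic ratio, rad s^-1 T^-1 (CODATA).
GAMMA_H = 2.6752218744e8

#: Reduced Planck constant, J s (CODATA).
HBAR = 1.054571817e-34

#: mu_0 / (4 pi), T^2 m^3 J^-1 (exact in SI to the relevant precision).
MU0_OVER_4PI = 1.0e-7

#: Magic angle theta_m = arccos(1/sqrt(3)), radians, full double precision.
#: Not configurable: off-magic-angle spinning is out of scope.
MAGIC_ANGLE = float(np.arccos(1.0 / np.sqrt(3.0)))

#: 2 sqrt(2 ln 2): converts a Gaussian sigma to its FWHM.
GAUSSIAN_FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))
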