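"""Build proton spin systems from coordinates and inspect their couplings.

The dipolar-coupling anisotropy delta_pq = -2 (mu0/4pi) gamma^2 hbar / r^3
follows from the internuclear distance alone; orientations are expressed in
the principal-axis frame of the reference pair (1,2).
"""

import masfloquet as mf

TWO_PI = 2.0 * 3.141592653589793

system = mf.three_spin()
print("three-spin CH2 mimic (distances in A, couplings in Hz):")
for pair in system.pairs:
    print(f"  pair ({pair.p},{pair.q}): r = {pair.distance:5.2f} A, "
          f"delta/2pi = {pair.anisotropy / TWO_PI:9.1f} Hz, "
          f"theta = {pair.theta_deg:6.2f} deg")

print("\nfour-spin system:")
for pair in mf.four_spin().pairs:
    print(f"  pair ({pair.p},{pair.q}): delta/2pi = "
          f"{pair.anisotropy / TWO_PI:9.1f} Hz")

print("\nThe 1.75 A pair models a CH2 group; its -44.8 kHz coupling "
      "dominates the residual broadening.  Couplings fall off as r^-3.")
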