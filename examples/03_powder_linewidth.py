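"""Powder-averaged residual line width versus spinning frequency.

The center-band second moment of the powder line, expressed as the FWHM of
the Gaussian with the same M2, falls linearly with 1/nu_r when the
second-order dipolar Hamiltonian dominates.
"""

import masfloquet as mf

system = mf.three_spin()
res = mf.linewidth_scan(system,
                        wr_list_hz=[50e3, 75e3, 100e3, 150e3, 200e3, 250e3],
                        constructions=("order2",), orientations=2000)
print("Gaussian-equivalent FWHM over the center band (order-2, no shifts):")
for _, row in res.table.iterrows():
    print(f"  nu_r = {row.wr_hz / 1e3:5.0f} kHz   FWHM = {row.fwhm_hz:7.1f} Hz")
fit = res.fits[("order2", "center_band")]
print(f"\nlinear fit FWHM vs 1/nu_r: slope = {fit['slope']:.3e} Hz^2, "
      f"R^2 = {fit['r2']:.6f}")
print("R^2 ~ 1: the residual width is inversely proportional to the "
      "spinning frequency, halving the width for double the rate.")
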