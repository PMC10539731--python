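"""Spinning-frequency-dependent line shifts from the second-order Hamiltonian.

The second-order dipolar term is a zero-quantum operator: it does not split
lines but drags their center of gravity (first moment) away from the
isotropic shift by an amount that shrinks with the spinning frequency --
a systematic error in apparent proton chemical shifts at finite MAS rates.
"""

import masfloquet as mf

system = mf.three_spin_three_shifts()  # shifts -0.1, 0.2, 0.7 ppm at 1 GHz
res = mf.shift_deviation_scan(system, wr_list_hz=[100e3, 200e3, 400e3],
                              constructions=("order2",), orientations=1000)
shifts = system.zeeman_frequencies_hz()
print("per-line first-moment deviation from the isotropic shift (Hz):")
for (wr, region), grp in res.table.groupby(["wr_hz", "region"]):
    row = grp.iloc[0]
    print(f"  nu_r = {wr / 1e3:4.0f} kHz  {region}: "
          f"M1 - shift = {row.m1_dev_hz:+8.2f} Hz   (FWHM {row.fwhm_hz:6.1f} Hz)")
print("\nDeviations of a few Hz at fast MAS, falling as the spinning "
      "frequency rises: chemical-shift referencing in proton solids is "
      "rate dependent.")
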