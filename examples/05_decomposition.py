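"""Second-moment additivity: four spins from three-spin fragments.

When second-order terms dominate, the center-band M2 of a four-spin system
equals 3/4 of the sum over its four three-spin sub-systems.  Line widths of
large coupling networks can therefore be predicted from three-spin pieces.
"""

import masfloquet as mf

res = mf.subsystem_decomposition(mf.four_spin(),
                                 wr_list_hz=(100e3, 150e3, 200e3),
                                 orientations=5000)
print("center-band M2 (Hz^2), powder averaged, order-2 construction:")
for _, row in res.table.iterrows():
    print(f"  nu_r = {row.wr_hz / 1e3:4.0f} kHz: full = {row.m2_full_hz2:9.1f}, "
          f"3/4 * sum(triples) = {row.m2_weighted_sum_hz2:9.1f}, "
          f"deviation = {row.deviation_pct:.2e} %")
print(f"\nmax deviation {res.fits['max_deviation_pct']:.2e} % -- far below "
      "1%: the three-spin decomposition is essentially exact here.")
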