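"""Deconvolution error surfaces for a DAB/HTX double stain.

Simulates camera signals for every input-concentration pair on the grid
c* = {0.1, 1, 2, 4, 8}^2, unmixes them in the B/G plane with normalised
stain vectors measured at c' = 1, and summarises the relative errors
(c*_out - c*_in)/c*_in.  Cells with an input of 0.1 are excluded from the
averages: there the error denominator makes the relative error explode.
"""

import numpy as np

import stainsim as ss

stains = (ss.catalogue_stain("DAB"), ss.catalogue_stain("HTX"))
wideband = ss.wideband_system()
led = ss.sequential_led_system()

surfaces = {
    "wideband": ss.error_surface(wideband, stains),
    "LED": ss.error_surface(led, stains),
}

for label, surface in surfaces.items():
    per_stain = ss.average_abs_error(surface)
    pooled = ss.average_abs_error(surface, pooled=True)
    print(f"{label}: mean |relative error| "
          + ", ".join(f"{k} = {100 * v:.1f}%" for k, v in per_stain.items())
          + f", pooled = {100 * pooled:.1f}%")
    print(f"  most negative HTX output: {surface.c_out[1].min():+.3f}")

ratio = (ss.average_abs_error(surfaces['wideband'], pooled=True)
         / ss.average_abs_error(surfaces['LED'], pooled=True))
c1, c2 = surfaces["wideband"].c_in
high = (c1 >= 4) & (c2 >= 4)
avg_high = 100 * np.nanmean(np.abs(surfaces["wideband"].delta[:, high]))
print()
print(f"wideband / LED pooled error ratio: {ratio:.1f}x")
print(f"wideband mean |error| at high inputs (both c* >= 4): {avg_high:.1f}%")
print()
print("Linear unmixing of the non-linearly formed wideband signals is off by")
print("more than half the true concentration at high stain loads, while the")
print("quasi-monochromatic LED system stays in the low percent range.")
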