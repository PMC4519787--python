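"""Concentration dependence of stain vectors and the AAV quality criterion.

Measures normalised DAB and HTX stain vectors at relative concentrations
c' = 1..5 under three optical systems and reports the average angle
variation (AAV): the mean angular deviation of the vectors from their
common mean direction.  Under ideal monochromatic conditions the vectors
share one direction (AAV = 0); the wider the spectral bands involved, the
more the measured vector depends on the concentration it was measured at.
"""

import stainsim as ss

systems = {
    "D65 + colour sensor (wideband)": ss.wideband_system(),
    "sequential RGB LED + mono sensor": ss.sequential_led_system(),
    "monochromatic (ideal)": ss.monochromatic_system(),
}
stains = [ss.catalogue_stain("DAB"), ss.catalogue_stain("HTX")]

print(f"{'system':36s} {'stain':5s} AAV [deg]")
for label, system in systems.items():
    for stain in stains:
        sweep = ss.stain_vector_sweep(system, stain, concentrations=(1, 2, 3, 4, 5))
        aav = ss.average_angle_variation(sweep)
        print(f"{label:36s} {stain.name:5s} {aav:10.4f}")

print()
print("A nonzero AAV means the 'constant' stain vector used for linear")
print("unmixing in fact rotates with stain concentration; the wideband")
print("system's AAV is roughly an order of magnitude above the LED system's.")
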