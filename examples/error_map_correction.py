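"""Correcting deconvolution results with a precomputed error map.

The deconvolution error is a deterministic aberrance, not noise, so the
input-to-output concentration map of a given optical system can be inverted
and used to correct measurements taken under the same spectral conditions.
A refined error surface (step 0.25 in c*) is computed once for the wideband
system, then measured output pairs are mapped back to input concentrations.
"""

import numpy as np

import stainsim as ss

system = ss.wideband_system()
stains = (ss.catalogue_stain("DAB"), ss.catalogue_stain("HTX"))
surface = ss.refined_surface(system, stains, step=0.25)


def measure(c_in, channels=("B", "G")):
    """Simulate what the deconvolution would report for a true input pair."""
    raw = [ss.measure_stain_vector(system, s, 1.0).project(channels)
           for s in stains]
    matrix = ss.StainMatrix.from_vectors([v.normalise() for v in raw], channels)
    idx = [system.channels.index(ch) for ch in channels]
    sample = ss.SampleComposition.of((stains[0], c_in[0] / raw[0].norm),
                                     (stains[1], c_in[1] / raw[1].norm))
    return ss.unmix_exact(matrix, ss.sample_absorbance_vector(system, sample)[idx])


rng = np.random.default_rng(11)
print(f"{'true input':>18s} {'deconvolved':>18s} {'corrected':>18s}")
for _ in range(4):
    c_in = rng.uniform(1.0, 7.0, 2)
    c_out = measure(c_in)
    corrected = ss.error_map_correct(surface, c_out)
    fmt = lambda v: f"({v[0]:5.2f}, {v[1]:5.2f})"
    print(f"{fmt(c_in):>18s} {fmt(c_out):>18s} {fmt(corrected):>18s}")

print()
print("The raw deconvolution output misses the true concentrations by tens")
print("of percent; inverting the system's own error map recovers them to a")
print("fraction of a percent, because the error is systematic, not random.")
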