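"""Ground truth to cell measurements: error propagation into segmentation.

Generates a seeded synthetic cell scene with known DAB/HTX concentration
planes, renders it to RGB camera images under the wideband and LED systems,
deconvolves the images pixel-wise by QR least squares, and compares
threshold-based cell measurements between the ground-truth input planes and
the deconvolved output planes.
"""

import numpy as np

import stainsim as ss

scene = ss.make_cell_scene(128, 128, 12, seed=7)
stains = (ss.catalogue_stain("DAB"), ss.catalogue_stain("HTX"))

for label, system in (("wideband", ss.wideband_system()),
                      ("LED", ss.sequential_led_system())):
    matrix = ss.StainMatrix.from_vectors(
        [ss.measure_stain_vector(system, s, 1.0) for s in stains])
    rgb = ss.render_rgb(system, scene, stains)
    result = ss.deconvolve_image(rgb, system, matrix, ground_truth=scene)
    print(f"{label}: max |relative error| per pixel "
          + ", ".join(f"{k} = {100 * v:.1f}%"
                      for k, v in result.max_abs_relative_error.items()))
    for s, name in enumerate(scene.stain_names):
        lo = min(0.0, result.c_out.planes[s].min())
        hi = max(scene.planes[s].max(), result.c_out.planes[s].max())
        rows = {}
        for kind, planes in (("input", scene.planes),
                             ("output", result.c_out.planes)):
            plane8 = ss.rescale_to_8bit(planes[s], lo, hi)
            mask = ss.threshold(plane8, "default")
            rows[kind] = ss.label_and_measure(mask, planes[s])
        print(f"  {name}: objects input/output = "
              f"{rows['input'].count}/{rows['output'].count}, "
              f"mean pixel concentration = "
              f"{rows['input'].pixel_mean:.3f}/{rows['output'].pixel_mean:.3f}")

print()
print("Object counts and mean concentrations measured on the deconvolved")
print("planes drift from the ground truth under wideband conditions, while")
print("the LED system reproduces the input measurements almost exactly.")
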