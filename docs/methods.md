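# Methods

## Signal-formation model

All spectral quantities live on one fixed wavelength grid, 405–700 nm in
5 nm steps (60 samples). A stain `i` is described by its optical-density
spectrum `δ_i(λ)` per unit relative concentration; a mixture at
concentrations `c_i` transmits

    τ_mix(λ) = 10^(−Σ_i δ_i(λ) c_i)

(Beer–Lambert, base 10, no scattering or fluorescence). A camera channel
`ch` with illumination `I_rel(λ)` and sensitivity `s_ch(λ)` records

    V'_ch = Σ_k I_rel(λ_k) s_ch(λ_k) τ_mix(λ_k),

the plain sum over the grid. Blank signals `V'_0,ch` are the same sums with
all concentrations zero, and channel absorbance is `A_ch = −log10(V'/V'_0)`.
Signals are kept in 64-bit floating point end to end; 8-bit quantisation
(blank mapped to 255, half-up rounding) is an optional step of the imaging
pipeline, and de-quantisation clamps zero pixels at half an LSB so the
logarithm stays finite.

Three reference system layouts are built in:

- **wideband**: one wideband illuminant (default the embedded CIE D65
  table) shared by all channels, three colour-sensor sensitivities;
- **sequential LED**: three narrowband LED illuminants paired with one
  monochrome sensitivity, modelling sequential acquisition of three
  monochrome frames;
- **monochromatic**: each channel's `I·s` product is nonzero at exactly one
  grid wavelength. In this limit `A_ch` is exactly linear in every `c_i`,
  which the test-suite uses as a machine-precision oracle for the entire
  pipeline.

A CIE 1964 XYZ rendering of the transmitted light (blank normalised to
Y = 100) is included to validate that simulated mixtures have plausible
stain colours.

## Unmixing, stain vectors, AAV

A stain vector is the absorbance vector of a pure stain at a reference
concentration; unmixing solves `M c = A` with the stain vectors as columns
of `M`, either exactly on a square channel subset (default the B/G plane
for two stains) or by QR least squares on all three channels. When
unit-length stain vectors are used, the resulting normalised concentrations
relate to relative ones by `c* = ‖q‖ c′`; the package computes `‖q‖` on the
same channel subset used for unmixing, since the projected vectors are the
ones actually normalised and inverted. Negative outputs are reported, never
clipped: they are the geometric signature of absorbance vectors falling
outside the fan spanned by the stain vectors and one of the effects the
simulation exists to expose.

The average angle variation (AAV) of a set of normalised stain vectors
measured at `c′ = 1..5` is the mean angle between each vector and their
normalised mean. The angle is computed from the chord
(`2 arcsin(‖v − v̄‖/2)`) rather than `arccos` of a dot product, which loses
half its significant digits for the near-zero angles of quasi-monochromatic
systems. The mean vector includes all five sweep vectors (the `c′ = 1`
reference is not treated specially). Matrices whose condition number
exceeds 1e8 (or with an equivalent QR diagonal ratio) are rejected as
collinear.

## Error surfaces, exclusion rule, comparison

For a stain pair, `error_surface` sweeps every input pair on a grid
(default `c* ∈ {0.1, 1, 2, 4, 8}` per stain), forward-simulates the mixture
at `c′_i = c*_i/‖q_i‖`, computes absorbances, unmixes with the normalised
`c′ = 1` vectors in the B/G plane, and records outputs and relative errors
`Δ = (c*_out − c*_in)/c*_in` (undefined, flagged NaN, at `c*_in = 0`).
Because the relative error's denominator makes cells with `c*_in = 0.1`
explode, summary averages exclude all cells where either input is below 1
(`min_c_in` threshold, configurable). The pooled average is the mean of
both stains' retained `|Δ|` values; per-stain means are reported alongside.
System comparison reports the per-stain and pooled error ratios; a
denominator below 1e-12 (a monochromatic reference, zero up to round-off)
is flagged infinite rather than raised.

## Error-map correction

The deconvolution error is a deterministic aberrance of a fixed spectral
configuration, so the simulated input→output map can be inverted to correct
measurements taken under the same conditions. The forward map is smooth in
the inputs; correction therefore spline-interpolates `c*_out(c*_in)` on the
surface's regular grid (cubic where the grid allows) and inverts it by
bounded least squares started at the grid node with the closest simulated
output. A refined grid with step 0.25 in `c*` keeps the interpolation error
far below the deconvolution error being corrected; in tests, off-node
queries are recovered to well within 2% (typically 1e-4 relative). A
measurement no input in the calibrated range can produce (residual above
1e-6 of the measurement scale) is refused rather than extrapolated. An
earlier design that linearly interpolated the *inverse* map on the
scattered output points was abandoned: where the forward map saturates, the
outputs nearly collide and that inversion is ill-conditioned.

## Surrogate spectra

The measured curves behind the original reference hardware (vendor LED and
CCD data sheets, measured chromogen spectra) are not publicly retrievable,
so the package ships fixed parametric surrogates — sums of Gaussian bands
with version-controlled parameters (`spectra._SURROGATE_BANDS`). They were
designed against independent published anchors, not fitted to any output of
this package's tests:

- **Stains** are normalised to peak OD 1.0 at unit concentration. HTX
  (hemalum) is one broad band at 565 nm (FWHM 150 nm); DAB is a band at
  430 nm (FWHM 180 nm) plus a 0.35-amplitude shoulder at 580 nm (FWHM
  140 nm). These shapes reproduce the well-known per-channel absorbance
  ratios of the Ruifrok–Johnston H and DAB stain vectors (H ≈
  (0.65, 0.70, 0.29), DAB ≈ (0.27, 0.57, 0.78) in R/G/B).
- **LEDs** are single bands at 628/527/465 nm with FWHM 20/25/20 nm,
  vendor-typical for red/green/royal-blue emitters.
- **Colour-sensor channels** are wide Bayer main bands (FWHM 85–110 nm)
  plus the secondary response lobes characteristic of dye-filter CCD
  channels without a sharp IR cut: the red channel responds ≈20% in the
  blue, the green channel ≈40% in the far red, the blue channel ≈5% in the
  red. The far-red lobe of the green channel matters most: both stains are
  nearly transparent there, so the green absorbance saturates first at high
  concentration, rotating mixture absorbances blue-ward out of the
  stain-vector fan — the mechanism behind the negative HTX outputs.
- **The monochrome sensor** is one very broad band (530 nm, FWHM 300 nm),
  strictly positive across the working range.

Every quantitative claim in the tests and the acceptance report is a claim
about these surrogates, not about the irrecoverable originals; the
qualitative structure (wideband ≫ LED ≫ monochromatic error ordering,
error growth with concentration disparity, negative outputs, cross-stain
contamination) is the part expected to transfer.

## Synthetic scenes

`make_cell_scene` draws soft-edged ellipses (random centre, semi-axes
5–12% of the image size, orientation; flat core with a linear 25% rim;
overlaps combined by per-pixel maximum) with per-cell peak concentrations
drawn uniformly from each stain's range, default (0.5, 4.0) — mid-range
histological stain loads. It is fully determined by its seed. It emulates
the spatial statistics of a stained cell field, not real morphology: no
texture inside cells, no chromatin structure, no out-of-focus light, no
noise. Passing tests therefore demonstrate error *propagation* into
segmentation, not segmentation performance on real tissue.
`make_selfsimilar_scene` builds the complementary fully controlled pattern:
an n×n grid of flat squares carrying the first stain's values with
centred, recursively nested inset squares carrying the other stain's, so
every pixel's ground-truth pair is exactly one of the requested values
(plus 0) and pure-stain patches exist by construction.

Cell quantification uses 8-bit rescaling with a unified display range per
stain (minimum 0 unless the output plane is negative), automatic
thresholds — isodata mean-split ("default"), Otsu, Yen, via scikit-image —
foreground above threshold, 8-connected component labelling (the
particle-analysis convention) with no minimum object size, and per-object
area/mean-concentration plus mask-wide pixel-mean measurements.

## Problem sizes and determinism

The default error surfaces are 5×5 concentration grids (25 forward
simulations of 60-wavelength sums each), correction maps 32×32, and the
test scenes 96×96–128×128 pixels with ≤ 12 cells — sizes at which every
pipeline in the package runs in seconds while leaving the measured effects
far from any discretisation floor. All randomness flows through explicit
`numpy` generator seeds; reruns of any config + seed are bit-identical.
The acceptance quantities are deterministic functions of the shipped
spectra and use no randomness at all.

## Known limitations

- Surrogate fidelity: parameters are plausible and anchored as described,
  but they are not the original curves; figure-level numerals tied to those
  curves (exact AAV values, per-figure error maxima) are not reproducible
  and are not claimed.
- The model excludes scattering (DAB is treated as a pure absorber),
  fluorescence, optics, sensor noise and non-linear electronics; results
  are a best-case lower bound on real-system error.
- Error-map correction assumes the measurement was taken under exactly the
  calibrated spectral conditions and within the calibrated concentration
  range; it refuses rather than extrapolates outside it.
- The generic solver handles N stains on ≥ N channels, but all shipped
  evaluations and defaults target the two-stain DAB/HTX case.
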