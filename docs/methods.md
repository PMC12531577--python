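# Methods

This note records the physical model, the numerical choices, and the design
decisions behind `multiplane25d`, together with what the synthetic data do
and do not emulate.

## Optical model

**Scalar diffraction.**  The detection PSF is computed from the pupil
function by a centered 2-D FFT; polarization (vectorial) effects at NA 1.2
are ignored.  The pupil is sampled on an `n × n` grid (default 512) over
the normalized radius ρ ∈ [−1, 1) with the aperture edge at ρ = 1
inclusive; amplitude is uniform (no apodization).  Defocus uses the
non-paraxial phase φ = (2π/λ)·n_imm·z·√(1 − (NA ρ/n_imm)²), which is the
correct operator for stage scanning in an index-matched (water) immersion.
Validation: the in-focus lateral FWHM agrees within 3% with an independent
radial-quadrature (Bessel-J₀) oracle and with 0.51 λ/NA; the on-axis axial
FWHM (0.598 µm at NA 1.2, n 1.33, λ 0.515 µm) agrees with the closed form
0.88 λ/(n − √(n² − NA²)) and with a 1-D quadrature oracle; per-slice energy
obeys Parseval to better than 0.5% and is conserved across defocus.

**Sampling.**  Zero-padding the pupil by `pad_factor` gives the FFT a
native lateral pitch λ/(2·NA·pad).  Defaults: pad 4 (≈54 nm) for rendering,
pad 8 (≈27 nm) for FWHM characterization; pitches coarser than λ/(4·NA)
are rejected.  Axial sampling is caller-chosen; 50 nm is used for PSF
characterization and 0.25 µm for scan rendering.  On-axis profiles are
computed directly as the squared zero-frequency pupil sum (no FFT), which
is exact and lets fine axial rasters stay cheap.

**Normalization.**  PSF volumes carry a tag: `peak` (default), `energy`
(peak per-slice energy → 1, making slices 2-D densities for rendering), or
`none` (raw |FFT|², used by the energy tests).

## Layer-cake EDOF element

The commercial element's true zone radii are proprietary; zones are
modeled as **equal-area annuli** (r_j = √(j/N)) so each carries the same
share of collected fluorescence — consistent with the near-uniform axial
profile the element produces.  Focal offsets are evenly spaced and
centered, z_j = (j − (N−1)/2)·span/N (±1.5, ±0.5 µm for the default
four-zone, 4 µm design); an `invert_zone_order` flag reverses the
innermost↔outermost assignment (the on-axis profile is insensitive to it).
Zones add in **intensity** (incoherent superposition); propagation within
a zone stays coherent.  With these defaults the on-axis EDOF profile has a
Gaussian-fit FWHM of 3.91 µm, stays within a factor 2 of its maximum over
the central 80% of the span, and broadens the in-focus lateral FWHM by
1.11× (half-max measure).

**Axial extension and its readout dependence.**  The ratio of EDOF to
widefield axial FWHM is 6.5 when both profiles are read on-axis
(peak-pixel).  Real bead measurements usually integrate over a finite
region, which broadens the narrow widefield profile far more than the
already-extended EDOF profile: summing intensity over an ROI disc of
radius 0.2 / 0.3 / 0.5 µm lowers the apparent extension to ≈5.8 / 4.5 /
3.4.  The characterization report can include this sweep
(`include_roi_readout=True`).  Published extension factors for such
systems should therefore be compared only under a matched readout
definition; the package reports the on-axis definition as its primary
number because it is parameter-free.

**FWHM measurement.**  `measure_fwhm` offers a least-squares Gaussian with
constant baseline — fitted within ±1.5 half-max widths of the peak so
diffraction side lobes do not bias the baseline — and linear half-max
interpolation.  Axial profiles use the Gaussian fit.  The *lateral
broadening factor* uses the half-max measure: the EDOF lateral profile is
a sharp annular core on a broad pedestal, and a Gaussian fit collapses
onto the core (ratio ≈ 1.0) while the literal width at half maximum
(1.11×) reflects what the profile actually looks like.  Finite-bead and
camera-pixel effects are applied as convolution kernels: a projected-sphere
2-D kernel plus a square pixel aperture laterally, and a sphere
cross-section-area 1-D kernel axially (valid because 100 nm ≪ lateral
FWHM, so the axial smearing decouples).

## Splitter geometry and radiometry

Plane depth intervals are half-open ([0,4), [4,8), [8,12), [12,16) µm) so
boundary depths resolve deterministically.  Quadrant origins default to
the sensor corners with an optional guard gap; the published quadrant
shape is (870, 750) px = (width, height), i.e. 93.96 × 81.0 µm at
108 nm/px.  "Vertical flip" is row-axis reversal, used consistently by the
renderer and the splitter module.  Per-path transmissions are products of
the two cascade splits — exactly 0.25 each for lossless 50:50 components —
and path-length compensation optics are collapsed into the plane-center
values.

## Forward model

Rendering is **emitter-wise PSF lookup**, not per-slice convolution:
each emitter interpolates the sampled PSF volume at its continuous defocus
(linear between z slices, spline laterally), scaled so that brightness
counts expected photons for an energy-normalized PSF.  PSF volumes are
laterally cropped (6 µm half-width for scans), so a strongly defocused
emitter contributes only its central halo portion; this truncation loses
some far-defocus energy but leaves peak-position measurements unaffected.
Scan PSFs span ±8 µm of defocus; emitters farther out of focus are skipped
on request (`out_of_range="skip"`), again a deliberate truncation of
negligible, diffuse light.

The sCMOS model is counts = gain·(Poisson(QE·photons) + N(0, read noise))
+ offset, clipped and quantized to 16 bits.  Defaults (QE 0.82, read noise
1 e⁻, offset 100, gain 0.5) are typical published sCMOS figures.  Exposure
time is absorbed into emitter brightness.  Every random stage draws from
`numpy` SeedSequence substreams spawned from a single seed, so adding a
stage never perturbs earlier stages and all outputs are bit-reproducible.

## Synthetic scenes

Bead monolayers enforce a minimum pairwise separation (1 µm default;
2 µm in characterization runs) so FWHM fits and centroids see isolated
beads; bead brightness defaults to 2000 photons against a 20 photon/px
background, placing localization and fit errors in the few-percent regime.
Hydrogel scenes draw Poisson counts at the requested density, uniform in
the slab.  Nuclei phantoms are axis-aligned ellipsoids (axial ratio 0.7)
filled with uniform emitters; centers are laterally non-overlapping so
projections cannot merge nuclei, and the default per-emitter brightness
(1500 photons at density 8 µm⁻³) reflects brightly stained tissue nuclei,
for which the 25% per-path transmission costs little contrast.  The
phantoms deliberately omit chromatin texture, scattering, autofluorescence
gradients and preparation-specific background, so passing closed-loop
tests demonstrates pipeline correctness on well-behaved data, not
performance on real tissue.

## Processing pipeline

**Registration** is pure per-plane translation (the instrument shows no
measurable rotation/scale between quadrants): beads are detected as local
maxima above mean + 5 robust σ, refined by background-subtracted center of
mass in a 7×7 window, matched to the Z12−16 reference by nearest neighbour
within 5 px, and summarized by the median displacement.  Closed-loop
recovery of injected misregistrations is accurate to <0.05 px; the
acceptance bound is 0.2 px.

**Plane spacing** fits a Gaussian with baseline to each bead's intensity
versus stage z (±3 µm window around the trace maximum, max intensity in a
3×3 box as the readout) and takes the median peak position per plane;
peak-amplitude variation is (max−min)/mean over the four plane medians.

**Stitching** follows the grid/collection approach: pairwise offsets on
nominal overlaps by exhaustive integer NCC search (±(absolute threshold+2)
px) with parabolic sub-pixel refinement — robust on the narrow strips a
tile grid produces, where circular phase correlation aliases.  A pair is
accepted if its post-shift correlation ≥ 0.3, its deviation from nominal
is ≤ 8 px absolutely and ≤ 2.5× the mean deviation of accepted pairs.
Rejected pairs fall back to their nominal offsets, but such links enter
the global least-squares solve only where needed to keep the tile graph
connected; otherwise they would drag well-linked tiles toward the nominal
layout.  Fusion uses linear (feathered) blending.  On 3×3 grids with ≤4 px
stage jitter the solver places tiles within 0.05–0.15 px RMS of truth.

**Bilateral filter** is implemented by explicit window shifts (spatial
Gaussian × range Gaussian, 3σ truncation, symmetric borders) rather than
an approximate library routine, so its large-σ_range limit equals the
truncated Gaussian blur exactly — a property the tests rely on.

**Nucleus-counting harness**: bilateral prefilter, Otsu threshold,
small-object removal, distance-transform watershed.  The 2.5D side sums
the four registered focal volumes into a 16 µm extended-focus composite
(so nuclei straddling plane boundaries keep their whole column signal)
and is compared against the MIP of a 32-slice widefield z-stack of the
same phantom.

**Depth coding** normalizes each plane to its own maximum and blends
plane colors additively (default palette blue→green→orange→red for
Z0−4→Z12−16).

## Problem sizes

Characterization runs use 60 beads over the full 94 × 81 µm quadrant with
a 0.25 µm stage scan (65 positions); unit tests use 256-sample pupils,
300-px quadrants and 15–25 beads, which preserve every physical relation
at a few percent accuracy.  The stitching property uses 3×3 grids of
200-px tiles at 10% overlap; the counting harness uses 10 nuclei in a
27.6 µm field with a 0.5 µm z-stack.

## Known limitations

- No aberrations, index mismatch, or vectorial high-NA corrections; the
  simulated widefield PSF is therefore narrower than typical measured ones,
  and quantities expressed *relative to the widefield PSF* (e.g. the axial
  extension factor) come out correspondingly larger than bead measurements
  on real instruments report.
- The layer-cake zone geometry is a model (equal-area, even offsets), not
  the proprietary element's true prescription; only span-level quantities
  (EDOF width, uniformity, lateral cost band) should be compared.
- Rendering point-samples pixel centers rather than integrating over the
  pixel aperture (the aperture enters the FWHM analysis as a kernel
  instead); sub-pixel localization biases from this are ≪ 0.05 px.
- The stitching thresholds reproduce the documented gate semantics, not
  the exact internals of any external implementation.
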