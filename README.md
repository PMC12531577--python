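# multiplane25d

Simulation and analysis toolkit for **multiplane 2.5D microscopy** — a
widefield fluorescence modality in which a *layer-cake* pupil element
extends each focal plane's depth of field to a ~4 µm slab, and a
*quad-plane image splitter* records four such slabs (Z0−4, Z4−8, Z8−12,
Z12−16, centered at z = 2, 6, 10, 14 µm) side by side on one sCMOS sensor.
One exposure then captures a coarsely depth-resolved 16 µm volume that a
conventional widefield microscope would need a 32-slice z-stack to cover.

The package is for microscopists and method developers who want to study
this detection scheme — its PSF engineering, radiometry, registration and
stitching behaviour — without hardware: it generates realistic synthetic
camera data with known ground truth and runs the full processing chain on
it (or on real quadrant TIFFs).

## Model

The detection PSF is computed with scalar Fourier optics.  The pupil is
sampled over the normalized radius ρ = sinθ/sinθ_max, defocus enters as the
non-paraxial phase

    φ(ρ; z) = (2π/λ) · n · z · √(1 − (NA·ρ/n)²),

and each slice of the intensity PSF is |F{P(ρ) e^{iφ}}|².  The layer cake
is modeled as N concentric annular zones (equal-area by default) with focal
offsets evenly spanning the EDOF range; zones are mutually incoherent, so

    PSF_EDOF(x, y, z) = Σ_j t_j · |F{A_j(ρ) e^{iφ(ρ; z − z_j)}}|².

The splitter contributes per-path transmissions (exactly 25% each for
lossless 50:50 splits), vertical flips on two of the four paths, quadrant
placement on the sensor, and optional sub-pixel misregistrations.  Scenes
(bead monolayers, 3-D hydrogel suspensions, nuclei phantoms, two-color
bead fields) are rendered emitter-by-emitter through a sampled PSF volume
and pushed through an sCMOS model (quantum efficiency, Poisson shot noise,
Gaussian read noise, offset, 16-bit quantization).

The processing module mirrors the real pipeline: quadrant cropping and
un-flipping, bead-based plane registration (Z12−16 reference), plane
spacing and FWHM characterization, AIP/MIP projections, depth color
coding, chromatic-shift measurement, bilateral prefiltering, a classical
nucleus-counting harness, and grid stitching with FIJI-style thresholds
(regression 0.3, max/avg displacement 2.5, absolute displacement 8.0).

## Worked example

```python
import numpy as np
from multiplane25d import OpticalConfig, SplitterConfig, NoiseModel, design_layercake
from multiplane25d import workflows as wf

optics = OpticalConfig(pupil_grid_n=256)   # reduced grid: same physics, faster
report = wf.psf_characterization_report(optics, design_layercake(4, 4.0))
print(f"widefield axial FWHM : {report['widefield']['axial_fwhm_um']:.3f} um")
print(f"EDOF axial FWHM      : {report['edof']['axial_fwhm_um']:.3f} um")
print(f"axial extension      : {report['axial_extension_factor']:.2f}x")
print(f"lateral broadening   : {report['lateral_broadening_factor']:.2f}x")

splitter = SplitterConfig(quadrant_shape_px=(300, 300), sensor_shape_px=(600, 600))
scan = wf.characterize_interplane(optics, splitter, NoiseModel(),
                                  n_beads=20, z_step=0.25, seed=1)
print(f"plane peaks (um)     : {[round(p, 2) for p in scan['peak_positions_um']]}")
print(f"mean spacing (um)    : {scan['mean_spacing_um']:.3f}")
print(f"peak variation       : {scan['variation_percent']:.1f}%")
```

prints

```
widefield axial FWHM : 0.598 um
EDOF axial FWHM      : 3.911 um
axial extension      : 6.54x
lateral broadening   : 1.11x
plane peaks (um)     : [2.0, 5.99, 10.01, 14.0]
mean spacing (um)    : 4.001
peak variation       : 7.3%
```

Reading the numbers: the ideal widefield axial FWHM (0.598 µm) matches the
closed form 0.88·λ/(n − √(n² − NA²)) at NA 1.2 in water; the four-zone
layer cake stretches it to 3.91 µm, i.e. the PSF stays in focus across the
4 µm slab at a modest (~1.1×) lateral resolution cost.  The simulated bead
z-scan recovers the four plane centers at 2, 6, 10, 14 µm — 4 µm spacing —
with plane-to-plane peak variation well under 15%.  Note that the *ratio*
of axial FWHMs depends strongly on how the axial profile is read out: the
on-axis (peak-pixel) profiles above give 6.5×, while integrating bead
intensity over a finite ROI broadens the widefield profile much more than
the EDOF one and lowers the apparent extension to 3–4.5× (see
`include_roi_readout=True` and `docs/methods.md`).

The same workflows are exposed as a CLI:

```sh
m25d simulate-psf    --outdir out/psf
m25d characterize    --outdir out/char --seed 1
m25d acquire-process --outdir out/grid --seed 1
```

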