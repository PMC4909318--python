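# Methods

`spheroid25d` analyses confocal z-stacks of fluorescent multi-cellular
spheroid (micro-tumour) cultures in 2.5D: all decisions are taken on the
Maximum Intensity Projection (MIP) and the height view (Z-buffer), and
3D quantities are recovered by an explicit shape model instead of full
volumetric processing.  This document describes the model, its
assumptions, the parameters that matter, and the numerical choices made
where the design was genuinely open.

## Model and assumptions

**Imaging model.** A stack holds one *stable* channel (a whole-cell
label expressed by every tumour cell, e.g. RFP) and one *marker*
channel (a nuclear stain marking a subpopulation, e.g. EdU in
proliferating cells).  Voxels are anisotropic: lateral pixels of
~0.6–1.3 µm against a z-step of ~10 µm.  Two preconditions are assumed
of the input: the stack is corrected for uneven background
illumination, and the z-step does not exceed the average cell diameter
(violations trigger a warning, not an error).

**Shape model.** Each spheroid is an ellipsoid whose third axis is
parallel to z.  This holds for cultures grown in a homogeneous matrix
(nearly spherical) and for sandwich cultures (two axes in the plane).
The lateral section is measured by a least-squares ellipse fit to the
2D segmentation mask; the vertical semi-axis `c` and centre depth `z_c`
come from the height view and the axial intensity profile.

**Attenuation model.** Absorption and scattering are taken as constant
inside spheroid tissue and zero outside, so the stable-channel signal
along a column through the spheroid centre decays as Beer–Lambert,
`I(z) ∝ exp(−µ·d(z))` with `d` the tissue path length.  The fraction
retained at depth z is `P_att(z) = 100·I(z)/I_max`.  The depth at which
`P_att` falls to the user threshold `P_min` (default 50%) bounds the
*analyzable region*.  Comparing that depth with the vertical diameter
`2c` yields three visibility classes: `full` (everything measurable),
`half` (at least the upper half measurable; counts extrapolated to the
hidden half), `not-analyzable` (less than half measurable; the spheroid
is excluded, since surface counts cannot be extrapolated to a core with
different oxygen/nutrient conditions).  The marker channel is assumed
to attenuate like the stable channel, reasonable when the two emission
wavelengths are close.

**Counting model.** Marker-positive nuclei are blobs of roughly known
radius.  They are detected as local minima of a scale-normalised
Laplacian-of-Gaussian (LoG) response, either on the full stack (3D
mode) or on the marker MIP with z read from the height view (2.5D
mode, several-fold faster).  For a `half` spheroid, spots above the
analyzable plane are counted and scaled by the ratio of the ellipsoid
volume to the analyzable cap volume,
`V_cap(h) = π·a·b·h²(3c−h)/(3c²)`, which reduces to doubling when the
plane passes through the centre (`h = c`).

## Pipeline

1. **Projection** — per-pixel max over z gives the MIP; the argmax (ties
   to the shallowest slice) gives the height view.
2. **2D segmentation** — a disk range filter (max−min over radius
   `r_range`) on the height view measures local depth inhomogeneity;
   spheroid pixels are homogeneous (low range), background is random.
   Thresholding at `max_z_range`, hole filling, removal of sub-cell
   speckle, and 8-connected labelling yield candidate masks; components
   with mean MIP intensity below `min_MIP` are dropped as spurious.
3. **Ellipse fitting and circularity filtering** — moments-initialised
   Nelder–Mead refinement of the five ellipse parameters against the
   mask indicator; masks whose circularity falls below the threshold
   are labelled non-elliptical and excluded from 3D extrapolation
   (they are overwhelmingly lateral overlaps or mis-segmentations).
4. **3D extrapolation** — `z_c` is the median height-view depth over
   the mask's outer rim (rim pixels sit near the equator); `I(z)` is
   averaged over the 3×3 neighbourhood of the ellipse centre; the top
   of the spheroid is the inflection point of the smoothed profile
   above `z_c`; `c = z_c − z_top`.  Masks with equivalent radius below
   `min_radius` use `c = (a+b)/2` instead — their axial extent is below
   what a 10 µm z-step resolves.
5. **Attenuation classification** — analyzable depth from the `P_min`
   crossing (sub-slice interpolated) and the visibility class.
6. **Spot detection, assignment, correction** — as above; spots are
   assigned to the spheroid whose 2D mask contains their lateral
   position, and a spot table plus per-spheroid raw and corrected
   counts are reported.

A `baseline_2d` mode skips the correction (all spots inside a 2D mask
count, nothing is extrapolated); it exists as the comparison point and
is biased low for large spheroids.

## Parameters

| Parameter | Default | Unit | Meaning |
|---|---|---|---|
| `cell_diameter` | 12 | µm | expected average cell diameter |
| `r_range` | 3 | µm | range-filter radius (¼ cell diameter) |
| `max_z_range` | auto | slices | threshold on the range-filtered height view; derived from the extent of the first histogram peak |
| `min_mip` | auto | intensity | threshold on a component's mean MIP intensity; the MIP background mean |
| `min_radius` | 24 | µm | below this equivalent radius, `c` is set to the in-plane mean radius |
| `attenuation_percentage` | 50 | % | minimal retained signal `P_min` |
| `max_spot_radius` | 8 | µm | maximal nucleus radius; also the merge distance |
| `spot_scale` | auto | µm | LoG σ; grid-optimised on the marker MIP |
| `min_circularity` | 0.7 | – | elliptical/non-elliptical cut (see below) |

Auto rules: `max_z_range` builds the integer histogram of the
range-filtered height view, smooths with a 3-bin moving average, finds
the first local maximum, and takes the first later bin under 10% of the
peak count; degenerate histograms fall back to half the slice count
with a warning.  `min_MIP` is the mean MIP intensity outside the
thresholded foreground.  `spot_scale` maximises the strongest
candidate-spot response of the negated scale-normalised LoG over 20
log-spaced σ in `[max_spot_radius/10, max_spot_radius]` — the peak
response is the classical scale-selection criterion (σ* = s for a
Gaussian blob of standard deviation s, r/√2 for a disk of radius r);
aggregate sums over all response pixels are dominated by edge ringing
at small scales and are not scale-selective.  The spot intensity
threshold is the median marker-MIP intensity over the union of the
segmented spheroid masks, one threshold per image.

## Numerical choices

* **Ellipse objective.** The fitted ellipse minimises the summed squared
  difference between an anti-aliased indicator (linear edge ramp about
  one pixel wide) and the mask — the same optimum as the binary
  symmetric difference, but smooth enough for derivative-free
  refinement (Nelder–Mead, ≤200 iterations, initialised from the
  equal-second-moments ellipse, which is within a pixel for convex
  masks).
* **Circularity.** Podczeck-style factor `A / (π(F_max/2)²)` with
  `F_max` the maximal Feret diameter: 1 for a circle, b/a for an
  ellipse.  The contour-based Feret estimate overshoots by about half a
  pixel per side, so one pixel is subtracted before use.  A
  perimeter-based variant (`4πA/P²`) is available.  The default cut of
  0.7 comes from measured distributions on synthetic scenes:
  well-separated spheroids segmented from the height view score
  0.76–0.89 (boundary raggedness), laterally merged pairs 0.52–0.60.
* **Inflection detection.** The top of a spheroid appears as a
  sigmoidal rise of the profile; cell-scale texture produces spurious
  curvature zero-crossings all along the interior plateau.  The
  crossing is therefore anchored at the steepest-rise sample above the
  centre (where a sigmoid's second difference genuinely changes sign)
  and interpolated between the bracketing samples.  Profiles are
  smoothed with a Gaussian of one z-step before use; the same applies
  to crossing detection for the analyzable depth, which starts strictly
  after the profile maximum so the rising flank cannot trigger it.
* **LoG response.** Computed in physical units: Gaussian smoothing with
  per-axis σ in voxels, then an exactly DC-free discrete second
  difference (`[1,−2,1]`) per axis divided by the squared axis spacing,
  summed and multiplied by σ².  Two details matter with 10 µm z-steps:
  a voxel-unit Laplacian would overweight the axial term by the squared
  spacing ratio, and the truncated derivative kernel of a sub-voxel
  axial σ is not DC-free, which leaks the image background into the
  response.
* **Spot candidate filtering.** Local minima (26-connectivity in 3D,
  8 in 2D) weaker than 5 robust standard deviations of the response
  (MAD estimate) are discarded — pixel noise produces a carpet of
  shallow minima whose extremes reach ~4.5σ in a megavoxel image while
  genuine nuclei sit an order of magnitude deeper.  Responses within
  one pixel-margin of the lateral image border are ignored
  (replicate-padding artifacts).  Greedy non-maximum suppression merges
  minima closer than `max_spot_radius` laterally and one z-step (or one
  spot radius, whichever is larger) axially; a single nucleus produces
  minima on neighbouring slices, and detections closer than the axial
  sampling distance are not resolvable.
* **Wilson interval.** Closed form with the standard-normal quantile;
  endpoints are clamped to `[0, p̂]` / `[p̂, 1]` against floating-point
  rounding at p̂ ∈ {0, 1}.
* **Boundary conventions.** Visibility equalities go to the more
  permissive class (`depth = 2c` is full, `depth = c` is half).  Ties
  in the height view break to the shallowest slice.  Objects touching
  the image border are kept but flagged.

## Synthetic scenes

The generator emulates exactly the assumptions above, so every pipeline
stage is testable without external data: ellipsoids placed with lateral
separation (or deliberate overlap), filled with dart-thrown cell
centres (default packing 0.5, spacing 0.85 cell diameters) rendered as
Gaussian blobs over a constant tissue base; an exact
`positive_fraction` subset becomes marker-channel nuclei; per-column
cumulative tissue occupancy gives Beer–Lambert attenuation (applied to
both channels); an anisotropic Gaussian stands in for the PSF; constant
background and Gaussian noise are added and the result is quantised to
16 bit.  Defaults mirror a 10×/0.4 NA spinning-disk acquisition:
1.3 µm pixels, 10 µm z-step, 12 µm cells, µ = 0.01 µm⁻¹ (half-intensity
depth ln 2/µ ≈ 69 µm, so spheroids beyond ~100 µm diameter are only
partially visible), PSF σ 0.4 µm lateral / 3 µm axial.

Not emulated: scattering anisotropy, depth-dependent PSF broadening,
spherical aberration, photobleaching, necrotic cores, stromal channels,
uneven illumination.  Passing tests therefore demonstrate correctness
of the algorithmic chain under the stated physics, not robustness to
every artifact of real acquisitions.

Closed-form attenuation checks use background-corrected scenes
(`background_level = 0`): with an additive offset B and signal
amplitude A the 50% crossing of `P_att` moves to `ln(2/(1−B/A))/µ`
for any implementation, which is a property of the quantity, not of
the code.  This mirrors the background-correction precondition of the
method.

## Problem sizes and test design

The test-suite simulations use volumes of roughly 128–320 pixels
laterally and 12–30 slices with 1–5 spheroids per scene, 20 replicate
stacks for sphere-recovery statistics, 100 nuclei for detection
metrics, and 100 replicate spot populations for the counting-bias
check; these sizes give stable statistics while keeping the suite fast.
The counting-bias check works at the estimator level — uniform spot
populations in a known ellipsoid, with everything below the analyzable
plane hidden — because the binomial tolerance it asserts is the
sampling error of the cap-volume extrapolation itself; image-level
estimation adds z-step-scale geometry error (~1%/µm of depth error in
the cap fraction) that belongs to the ellipsoid-recovery checks, where
it is asserted at its own one-z-step tolerance.

## Known limitations

* The vertical semi-axis is resolved to about one z-step; near
  `depth ≈ 2c` the full/half classification can flip accordingly.
  Corrected counts remain consistent because the counting plane and the
  cap volume use the same estimate.
* Lateral overlaps are filtered out, not split; heavily overlapping
  cultures lose a corresponding fraction of spheroids (flagged in the
  non-elliptical class).
* The attenuation estimate relies on a reasonably uniform stable-marker
  expression; strongly heterogeneous expression biases the axial
  profile.
* 2.5D spot mode only sees nuclei that win the MIP at their lateral
  position; dense multi-layer nuclei are undercounted relative to 3D
  mode.
* ROI ingestion covers polygon/freehand/traced/oval/rectangle ImageJ
  ROIs; composite/shape ROIs are not supported.
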