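# Methods

This note records the models, parameter choices, numerical conventions, and
known limitations of the `spheroquant` pipeline.

## Calibration and containers

Brightfield projections are calibrated at 1389 µm / 1992 px ≈ 0.697 µm/px;
all distances are reported in micrometres via this pixel size.  Coordinates
are (x, y) with x = column and y = row; angles are measured from the +x
axis with y pointing down and, for axial quantities (fiber orientation,
ellipse angle), folded to [0, π).

## Image operators

- **8-bit conversion** linearly rescales [min, max] to [0, 255]; a constant
  image maps to 0.
- **Gaussian blur**: the macro parameter "10-pixel gaussian blur" is read
  as σ = 10 px (the parameter of the common GUI implementation is sigma);
  the value is configurable on every profile.
- **Despeckle** is one pass of a 3×3 median; the disk-radius median filter
  uses the sliding-histogram rank filter for 8-bit input.
- **CLAHE** follows the blocksize/bins/max-slope parametrization: per-tile
  histograms are clipped at `max_slope · tile_px / bins` with uniform
  redistribution (iterated to a fixed point), and pixels are bilinearly
  interpolated between the four surrounding tile mappings.  An infinite
  slope reduces to plain adaptive equalization; a blocksize larger than the
  image falls back to global equalization with a warning.
- **Rolling-ball background** is fitted to a 3×3-mean presmoothed copy (the
  standard GUI default) so the ball does not ride into noise dips, and
  subtracted from the original, clipped at 0.  Without presmoothing,
  5%-noise scenes produced patchy ~1.5 σ residual plateaus that thresholds
  picked up as spurious cells.
- **Auto-thresholds** (Otsu, Kapur max-entropy, Li minimum-cross-entropy,
  Minimum, Triangle) are implemented as explicit optimizers of their
  defining criteria on a 256-bin histogram (pooled across slices when the
  stack-histogram flag is set).  Li iterates the class-mean fixed point;
  Minimum smooths the histogram with a window-3 mean until exactly two
  maxima remain (cap 10,000 iterations) and thresholds at the valley;
  Triangle maximizes the distance to the peak-to-tail chord.  Because the
  valley between well-separated modes is empty, different optimizers can
  return different bins of a tie plateau; equivalence is therefore defined
  on the induced pixel partition, not the bin index.  Polarity is explicit
  everywhere: brightfield objects are dark, so their masks take pixels at
  or below the threshold.
- **Shape descriptors**: circularity `4πA/P²` uses the Crofton perimeter
  estimator (the naive pixel-edge count overestimates smooth boundaries and
  would keep disks well below 1); roundness is `4A/(π·major²)`; ellipse
  axes/angle come from second moments.  Foreground components are
  8-connected, holes 4-connected.

## Segmentation accuracy of the printed operator chains

A blurred step edge crosses its mid-level exactly at the true boundary, so
boundary localization accuracy is set by where each threshold lands in the
edge ramp.  Measured on synthetic scenes (σ = 10 blur, 80 px spheroid in a
512² frame, the same linear fraction as a 400 µm spheroid in the 1389 µm
field):

- **Otsu** lands near the mid-level: boundary within ±0.6 px.
- **Minimum** lands slightly dark of mid (the populous background mode
  drags the smoothed valley): mask radius −2.0 to −2.7 px.  This matches
  `skimage.threshold_minimum` exactly and is intrinsic to the method.
- **Kapur max-entropy** lands at 80–90% of the ramp: mask radius
  +12 to +15 px.  This was verified robust to body/background texture,
  contrast, rim/halo boundary renderings, and foreground fraction; it is a
  property of the entropy criterion on dark-object images with a dominant
  background mode.

Consequences: the Minimum-method (M4) profile recovers cell counts exactly
on clean and 5%-noise scenes and median migration distances to within
+2–4 px (a systematic overestimate equal to the mask undershoot), while the
MaxEntropy (MDA-MB-231) profile yields a generous body mask that absorbs
cells migrating within ~20 px of the boundary and shifts distances by
−12 px.  Distance tolerances tighter than ~3 px are therefore not
achievable with either printed chain; comparisons between conditions are
unaffected because the offset is common to all frames of a profile.

## Synthetic scenes

The generator renders what the screening and migration stages need to see,
not SHG physics:

- **Spheroid scenes**: a dark disk (level 6000) and dark elliptical cells
  (level 9000) on a bright background (level 20000), with multiplicative
  texture — body ±40% at 15 px correlation (packed-cell contrast),
  background ±15% at 60 px (illumination mottle) — plus optional additive
  Gaussian noise; "5% noise" means σ = 700 = 5% of the background-to-body
  contrast.  Truth objects carry the seed; rendering is bit-reproducible,
  and cells are rejected at construction if they touch the spheroid disk.
- **Fiber fields**: `n` anti-aliased segments (default 300 of length 40 px,
  width 3 px) at uniform random positions with axial orientations drawn
  von Mises(2·mean, κ)/2 folded to [0, π); κ = 0 is uniform.  Crossings
  combine by maximum.
- **F/B pairs**: backward = base image (+ noise per slice), forward =
  true-ratio × clean backward (+ independent noise), clipped at 0.

What the generator does *not* emulate: out-of-focus light, optical PSFs,
depth attenuation in z-stacks, fiber curvature, and cell morphology beyond
ellipses.  Passing recovery tests therefore demonstrates the correctness of
the computation chain, not robustness to every real-microscopy artifact.

## WTMM anisotropy

Wavelets are the two first partial derivatives of an isotropic Gaussian,
L1-normalized per scale; default grid 27 log-spaced scales from 2 px to
min(H, W)/8 (the count is standard for this analysis; the range is chosen
to keep the kernel support inside the frame).  Modulus maxima are pixels
whose modulus exceeds bilinear samples 1 px away on both sides along the
gradient direction (≥ forward / > backward to break exact ties), above a
floor of 10⁻³ of the global maximum, and further than 2·scale from the
border.  Angle PDFs use 18 bins of 10° over the axial domain with
modulus weights; the anisotropy factor is the PDF range in units of the
uniform density.  A z-stack pools the maxima of all its slices into one
PDF per scale.  Scales with fewer maxima than bins, or beyond min(H, W)/4,
are flagged (NaN), not errors.

The isotropy null redraws orientations uniformly with one draw per *fiber*,
not per maximum: maxima chain along each fiber and share its orientation,
so treating them as independent draws understates the variance of an
isotropic field by the chain length (an iid-maxima null was exceeded by
every κ = 0 field tested).  Validation restricts to the resolved-fiber
scale band — scales between the fiber width and a quarter of the fiber
length — because beyond ~L/4 a single maximum aggregates several fibers
and the factor of an isotropic field inflates.

For the migrating-cell-front region, nuclei are segmented from DAPI
(smooth + Otsu on the stack histogram) and the analysis mask is the union
of 50 px circles at each nucleus centroid — three circles spaced evenly
along the fitted major axis when half of it exceeds 100 px — minus the
nuclei pixels themselves.

## Statistics

Normality is tested per group (Shapiro–Wilk) and variance homogeneity with
median-centered Levene (Brown–Forsythe), both gated at α = 0.05
(configurable).  The decision tree: all-normal + equal variance →
Student's t / ANOVA (+ Tukey HSD); all-normal + unequal → Welch t / Welch
ANOVA (+ Games–Howell); otherwise Wilcoxon rank-sum (Mann–Whitney with
continuity and tie corrections) / Kruskal–Wallis (+ Dunn).  Dunn p-values
are the uncorrected two-sided normal probabilities of the tie-corrected
rank-mean z statistics; no correction is layered across endpoints.  The
compact letter display starts from one column holding all groups, splits
any column containing both members of a significant pair, absorbs subset
columns, and letters the result; the defining invariant (share a letter ⇔
non-significant) is asserted on every emitted display.  The letter count is
not guaranteed minimal.  The plate-reader vendor's proprietary
cell-expansion algorithm is unknown; the constrained-dilation emulation
(nearest-nucleus EDT assignment capped at 50 µm) is a stand-in and labeled
as such.

## Validation problem sizes

Desk-scale sizes keep full validation under ~2 minutes: 20 scenes of
512×512 px with 10–30 cells for migration recovery; 256×256 fiber fields
over 12 scales, 6 concentrations × 10 seeds, for the anisotropy panel;
2000 replicates for the type-I error.  Screening truth-table boundary
diameters (350/450 µm) are evaluated on analytic shape descriptors of the
ideal geometry: the fitted axes of any imaged disk carry a fraction of a
micrometre of rasterization spread on either side of the truth, which a
knife-edge inclusive bound cannot tolerate; interior and exterior cases run
through the full imaging pipeline as well.

## Known limitations

- Boundary localization biases of the Minimum and MaxEntropy thresholds
  (above) put a ~2–3 px floor on absolute distance accuracy; per-scene
  medians at 10–30 cells additionally carry ~5–10 px of parity granularity
  when a count error of ±1 coincides with a gap at the median.
- The anisotropy factor definition (PDF range over uniform) is one of
  several in use for WTMM-style analyses; outputs label it, and numerical
  values are not comparable across definitions.
- The manual artifact-removal step of the original workflow is replaced by
  an auditable exclusion-mask input.
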