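# spheroquant

Quantitative image analysis for 3D tumor-spheroid invasion assays in
collagen I hydrogels, with second-harmonic-generation (SHG) readouts of
collagen remodeling.

Breast-cancer spheroids embedded in collagen are imaged in brightfield every
12 h for 72 h; migrating cells detach from the spheroid body and invade the
matrix, remodeling the surrounding collagen as they go.  `spheroquant`
implements the full computation stack for this assay as a tested, reusable
library:

- **Spheroid screening** — decide whether a candidate spheroid is uniform
  enough for embedding: circularity `4πA/P² > 0.55`, roundness
  `4A/(π·major²) > 0.80`, both fitted-ellipse axes within 350–450 µm.
- **Migration quantification** — segment the spheroid body and the
  migrating cells with cell-line-specific operator chains (median-filter /
  rolling-ball background, CLAHE, despeckle, Max Entropy / Minimum /
  Triangle auto-thresholds), then report, per spheroid per timepoint, the
  cell count, the median circularity, and the median migration distance —
  the Euclidean distance from each cell's center of mass to the nearest
  spheroid-boundary pixel.
- **SHG forward/backward ratio** — voxelwise F/B division of paired
  z-stacks, masked by the Li threshold of the pooled forward histogram;
  the median ratio reports on collagen fibril diameter and packing.
- **Fluorescence intensity** — per-slice and per-stack median antibody
  signal; 2D nuclei segmentation with constrained expansion for per-cell
  intensities.
- **WTMM anisotropy** — the 2D wavelet transform modulus maxima method:
  gradient fields from first-derivative-of-Gaussian wavelets across a grid
  of scales, modulus maxima along the gradient direction, modulus-weighted
  angle distributions, and a scale-resolved anisotropy factor
  `F = (max p − min p)·n_bins` that is 0 for isotropic (disordered) fiber
  fields and large for aligned ones.
- **Statistics** — the assay's decision tree (Shapiro–Wilk and Levene gates
  choosing Student/Welch/Wilcoxon/ANOVA/Welch-ANOVA/Kruskal–Wallis, with
  Tukey HSD / Games–Howell / Dunn post-hocs) and compact-letter-display
  reporting where groups sharing no letter differ significantly.
- **Synthetic ground truth** — generators for brightfield-like spheroid
  scenes, von Mises-oriented fiber fields, and paired F/B stacks with known
  truth, so every stage is verifiable without the original microscopy data.

## Worked example

Run the end-to-end synthetic demo (screening → migration time course → F/B
ratio → anisotropy → statistics), everything driven by one seed:

```sh
spheroquant demo --seed 3 --out demo_out
```

`demo_out/summary.csv` then holds the migration time course of a synthetic
spheroid whose 12 cells drift outward 10 px per frame:

```
spheroid_id  timepoint_h  n_cells  median_distance_um  median_circularity
   spheroid          0.0       12           28.604416            0.915418
   spheroid         12.0       12           37.518297            0.970816
   spheroid         24.0       12           53.343756            1.000000
   spheroid         36.0       12           58.470262            0.967255
   spheroid         48.0       12           62.057349            0.969708
   spheroid         60.0       12           68.929675            0.963175
   spheroid         72.0       12           76.261231            0.967702
```

All 12 cells are recovered at every timepoint and the median migration
distance increases monotonically, tracking the programmed outward drift
(10 px ≈ 7 µm per 12 h at the 0.697 µm/px brightfield calibration).
`fb_results.csv` shows the F/B ratios recovered from paired synthetic
stacks (true ratios 0.5 and 2.0):

```
true_ratio,median_ratio,mask_fraction
0.5,0.5000072449715787,0.27944183349609375
2.0,2.0000053622017027,0.28131103515625
```

and `stats.json` reports the chosen test with its letter display — e.g. a
control group at a higher migration level gets letter `b` while the two
treated groups share `a`.

Every subcommand is also available individually (`spheroquant synth`,
`screen`, `migrate`, `fbratio`, `d93`, `wtmm`, `stats`); see `--help`.

## Library quick start

```python
from spheroquant import migration, synthgen

truth = synthgen.random_scene_truth(seed=1, n_cells=15)
img, _ = synthgen.make_spheroid_scene(truth, (512, 512), pixel_size=0.697)
profile = migration.PROFILES["m4"]
mask, contour = migration.segment_spheroid(img, profile)
cells = migration.segment_cells(img, mask, profile)
dists = [
    migration.nearest_boundary_distance(c.center_of_mass, contour, 0.697)
    for c in cells
]
```

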