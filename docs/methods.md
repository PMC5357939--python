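# Methods

## Problem and model

`heprofiler` quantifies the histological difference between normal
epithelium and early neoplastic lesions in H&E-stained tissue regions of
interest (ROIs).  The core assumption is that the diagnostic signal lives
in (a) stain-channel texture at several spatial scales and (b) the
spatial arrangement of cell nuclei: normal acinar epithelium presents
nuclei as ordered "beads in a row" along the basement membrane, while
lesions fill the epithelial band with dense, scattered nuclei.  The
pipeline turns each ROI into a fixed 241-dimensional feature vector and
classifies cohorts of ROIs with a bagged decision-tree ensemble under
leave-one-out cross-validation (LOOCV).

## Stain model

Transmitted-light H&E color formation follows Beer–Lambert:
`I_c = (I0+1) · exp(−OD_c) − 1` with `I0 = 255`, so a saturated pixel has
exactly zero optical density.  `OD` is a linear mix of per-stain
densities through a 3×3 matrix of unit-norm absorption vectors — the
canonical H&E pair (H ≈ [0.65, 0.70, 0.29], E ≈ [0.07, 0.99, 0.11]) with
the residual completed as the unit cross product.  Color deconvolution
inverts this mix; negative densities (pixels outside the stain simplex)
are clipped in the physical channels but retained in a `raw` plane, so
the forward remix of `raw` reproduces the input exactly and the clipped
round trip is accurate to ≤ 2 intensity levels on stained imagery.  The
synthetic renderer uses the same basis, making unmixing exactly
invertible up to 8-bit quantization — a deliberate identity that turns
the round trip into a sharp correctness test.

## Synthetic data: what it emulates and what it does not

No suitable public dataset pairs H&E ROIs with per-nucleus ground truth
at this geometry, so the package ships a generator whose defaults define
the study conditions:

* pixel scale 0.5 µm/px (20× objective); ROI = a centered disk of radius
  0.45·image_size in a 256×256 frame;
* `epithelial`: 45 nuclei of radius 9±1 px at even arclength spacing on
  concentric rings (spacing 2.4·r along rings, 2.6·r between rings),
  positional jitter 1.5 px, lumen fraction 0.30;
* `neoplastic`: 70 nuclei of radius 8±1 px by hard-core uniform scatter
  (minimum spacing 2.2·r), lumen fraction 0.05;
* `himyc`: a larger-nuclei scattered variant (42 nuclei, radius
  10.5 px, lumen 0.02) so the three-group path is exercised;
* per-image stain gain ~ LogNormal(0, 0.2), additive Gaussian pixel
  noise (σ = 3 intensity levels); nucleus H density 0.90·gain, cytoplasm
  H 0.12 / E 0.35·gain, lumen unstained.

Counts and spacings were chosen once so that nuclei remain *resolvable*
at this scale: touching-nucleus splitting (watershed) is out of scope,
so the generator does not create heavily overlapping nuclei.  Per-image
RNG streams derive from a root seed via `SeedSequence(root, spawn_key=
(index,))`, so cohorts are bit-reproducible and parallelizable.

A `separation_specs(s)` dial interpolates the two classes toward a
common geometry (jitter grows, an increasing fraction of epithelial
nuclei scatters, lesion density and lumen relax toward the epithelial
values; counts move quadratically in `s` to stay clear of the packing
jamming density mid-dial).  At `s = 0` the two classes are draws from
the same process, so held-out AUC falls to chance — the negative control
of the end-to-end test.

The renders are *not* photorealistic: no stroma, vessels, nerves,
chromatin texture inside nuclei, focus blur or compression artifacts.
Passing tests therefore demonstrate that the pipeline recovers the
arrangement/texture contrast it is designed for, not that it is robust
to every nuisance of real slides.

## Preprocessing

*Histogram matching.* The reference is the unweighted mean of per-image
normalized 256-bin histograms (each image counts equally), computed
within ROI masks and per RGB channel independently.  Matching maps the
image CDF onto the reference CDF with ties resolved to the lowest
intensity; pixels outside the ROI pass through.  The transform is
idempotent up to ±1 intensity level.  When two cohorts are compared,
one shared reference must be used — separate references are themselves
a batch effect (see `examples/04`).

*Effective tissue mask.* Channel difference blue − green (both stains
absorb green strongly and blue weakly, so B−G tracks total stain and is
near zero on lumen/secretion/glass), contrast-limited linear mapping
saturating 1 % tails, Otsu threshold, morphological opening and closing
with a 3 px disk, filling of holes < 500 px, intersection with the ROI
mask.  A constant difference image degenerates to the full ROI mask
with a warning.

*Otsu.* Implemented directly as the lowest 256-bin threshold maximizing
between-class variance; unit tests pin it to an exhaustive search.

## Nuclei segmentation

MSER runs on the hematoxylin *density* image (nuclei bright), smoothed
with σ = 1 px and quantized to 8 bit at a fixed density scale of 2.0 OD.
The component tree comes from `skimage.morphology.max_tree`; for each
canonical component at level v the variation is
`(area(ancestor at ≤ v−Δ) − area) / area` with Δ = 5.  Candidates with
variation ≤ 0.5 and area in [30, 2000] px are accepted greedily by
increasing variation with nested duplicates suppressed, yielding
pairwise-disjoint regions.  Selection then keeps regions with area in
[50, 800] px (radii ≈ 4–16 px at 0.5 µm/px) whose pixel overlap with the
high-hematoxylin-rate mask is ≥ 50 %.  The rate mask is white tophat
(disk radius 10) → maximum filter (5 px) → Gaussian (σ = 2) → full-range
rescale → Otsu.  Centroids round to the nearest pixel in the location
map; collisions keep multiplicity.

On the default synthetic classes this recovers nucleus counts within
~6 % and centroid-matching F1 ≈ 0.97 at 10 px tolerance; the
larger-nuclei `himyc` class is harder (~16 % count error) because
near-touching large nuclei merge into single stable components.

## The 241-feature catalogue

Texture features are computed on both stain-density channels (quantized
to 8 bit) at five neighborhoods, encoded as name prefixes: per-nucleus
bounding box (no prefix, e.g. `Contrast-H`), 35×35 window per nucleus
(`Nhood`), 50×50 tiles requiring ≥ 50 % effective tissue
(`mROI-Block`) or ≥ 50 % ROI coverage (`ROI-Block`), and the whole ROI
box (`ROI`).  Per-instance values are averaged into one number per
catalogue entry.  Families:

| family | definition | count |
|---|---|---|
| GLCM | mean intensity, contrast, correlation, energy, homogeneity of the symmetric, normalized co-occurrence matrix, 16 gray levels, averaged over offsets (0,1),(1,1),(1,0),(1,−1) | 5×5×2 = 50 |
| LBP | rotation-invariant uniform codes, P=8, R=1; 10-bin histogram (`LBP1H…LBP10H` etc.) | 10×5×2 = 100 |
| SIFT | dense gradient-orientation descriptors (16×16 patches, 4×4 cells, 8 orientation bins, step 8, L2-normalized with 0.2 clipping); per-band energy mean+sd over grid points in each 35×35 window, band means over the ROI | 32 + 16 |
| MSER | region count, density per 10⁴ tissue px, mean/sd area, mean stability, mean eccentricity | 6 |
| distances | per-nucleus statistics of Euclidean distances to neighbors in a 100 px window (mean/max/sd/skewness), count and mean distance in the 35 px window, mean nucleus area | 7 |
| angles | circular statistics of neighbor orientations (below) | 10 |
| density | mean/max/sd/skew/kurtosis/percentiles of the Gaussian-filtered (σ = 8 px) location map within tissue, plus a 10-bin LBP (P=8, R=2) of the quantized density image | 20 |

Total 241; the catalogue is a frozen, ordered, machine-readable table
and the single source of truth for feature order.

LBP and SIFT are computed once per channel over the whole image and
aggregated per window, avoiding window-border artifacts; image-border
pixels whose circular neighborhood leaves the frame are excluded from
LBP histograms.

*Angular statistics are axial.*  A neighbor's direction from a nucleus
is an orientation without a sign: a row of nuclei presents neighbors
along both directions of the row axis, so first-moment circular
statistics of the raw angles cannot distinguish a perfect row (θ and
θ+π) from uniform scatter — both have resultant length ≈ 0.  Angles are
therefore doubled before the trigonometric moments (the standard axial
transform), and ABS variants fold to |θ| ∈ [0, π] first.  With R the
mean resultant length of the doubled angles: variance 1−R, circular sd
√(−2 ln R) (R floored at 1e−12), angular deviation √(2(1−R)) (the
`Std0` variant), skewness `mean(sin 2(θ−μ))` and kurtosis
`mean(cos 2(θ−μ))`.  A one-direction collinear neighborhood still has
variance 0 and four neighbors at 0, π/2, π, 3π/2 still have variance 1.

*Missing data.*  Catalogue entries with no valid neighborhood instance
(e.g. nucleus-anchored features of a nucleus-free ROI) are NaN with a
flag; the KS screen drops them pairwise, classification imputes
training-fold medians.

## Feature selection

Per-feature two-sample Kolmogorov–Smirnov test between two control
cohorts; D is evaluated at all pooled breakpoints (exact under ties),
the p-value uses the asymptotic Kolmogorov distribution with effective
size n_x·n_y/(n_x+n_y).  Features with p ≥ α = 0.05 are retained, in
catalogue order, with no multiple-testing correction (the screen is
conservative in what it keeps; a correction would retain more).  Monte
Carlo at n = 50/50 puts the realized type-I rate at ≈ 0.035 — identical
to the exact-distribution rate, the shortfall from 0.05 being the
discreteness of D, not the asymptotic approximation.

## Classification

Random forest: 50 trees, bootstrap resampling with replacement,
√p candidate features per split, unlimited depth, minimum leaf 1.
Importances are mean impurity decrease normalized to sum 1.  LOOCV
trains exactly n models; fold f's RNG seed derives from
`SeedSequence(root, spawn_key=(f,))`, so folds are reproducible and a
sample's held-out prediction is independent of its own row.  AUC uses
the Mann–Whitney rank formulation (ties ½), identical to the empirical
ROC area; multiclass evaluation takes maximum-probability labels (ties
to the lowest class index) and one-vs-rest ROC per class.  No feature
standardization (trees are scale-invariant).

## Reporting

t-SNE (z-scored features, PCA initialization, fixed seed) in 2-D or
3-D; average-linkage Euclidean hierarchical clustering of z-scored
features for heatmap row/column orderings (constant features dropped);
polar histograms over (−π, π].  All plot helpers return their numbers,
so figures are regenerable and testable without image comparison.

## Problem sizes used by the test suite and acceptance script

End-to-end checks run on synthetic cohorts of 100 ROIs per class (held-
out AUC and permutation null), 12 per class × 5 seeds × 3 settings for
the separation dial, 10 renders for segmentation recovery, and 1000
simulated null features for KS calibration; LOOCV bookkeeping is checked
at n = 426 (two-group) and n = 582 (three-group) on synthetic feature
matrices.  The acceptance script uses 30 ROIs per class for its
end-to-end AUC.  These sizes make the whole suite run in minutes on one
CPU while keeping every statistical check comfortably powered.

## Known limitations

* The catalogue reproduces the documented naming scheme, family
  structure and total arity, but per-family counts within the total are
  this package's own composition choice.
* MSER stability uses the one-sided ancestor approximation of variation
  common in practical implementations, not the original two-sided
  definition.
* Segmentation has no splitting of touching nuclei; dense lesion tissue
  with overlapping nuclei will be under-counted.
* The KS screen's asymptotic p-values are slightly conservative below
  n ≈ 30 per group.
* Synthetic realism limits are listed above; conclusions about real
  tissue require real annotated cohorts.
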