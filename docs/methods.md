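# Methods

`nucoloc` quantifies how nuclear proteins and chromatin states are arranged
in Schwann-cell (SC) nuclei imaged by multi-channel confocal microscopy,
and compares wild-type (Wt) against Trembler-J-like (TrJ) genotypes.  The
pipeline runs six stages: scene input (real TIFF stacks or the synthetic
generator), 3-D nucleus segmentation on the DAPI channel, chromatin
classification, peripheral-versus-central profiling, five-way
colocalization, and nonparametric group comparison.

## Segmentation

Nuclei are segmented on a blurred duplicate of the DAPI channel: Gaussian
blur with sigma 5 px applied in-plane (stacks are blurred slice by slice,
the common behaviour for 2-D Gaussian filtering of a z-stack), followed by
an intensity window of [30, 255] on the blurred image and 26-connected 3-D
component labelling.  Components below `min_voxels` (default 50) are
discarded as speckle.  All intensity measurements are taken on the raw
channels under the resulting masks; the blurred duplicate exists only for
mask-making.  Whether the blurred image should be rescaled before
thresholding is an open point in interactive tools; we threshold the
blurred image directly, in the same 8-bit units.

Touching nuclei are not split — no watershed step is applied.  The
synthetic scenes place nuclei apart by construction; on crowded real
fields under-segmentation of touching nuclei is a known limitation.

Volumes are `voxel_count x dz*dy*dx` (µm³).  Mean intensities are summed
fluorescence per nuclear voxel, in arbitrary 8-bit units.

### Voxel size

Published acquisition parameters for this kind of data are internally
tense: a stack-level voxel of 0.379/0.379/1.00 µm (x/y/z) versus a
0.21 µm z-step and 0.1 µm pixels for the per-nucleus chromatin work.
Voxel size is therefore an explicit configuration item everywhere.  The
I/O layer defaults to (dz, dy, dx) = (1.00, 0.379, 0.379) µm for externally
supplied stacks; the synthetic generator emulates the per-nucleus regime at
(0.21, 0.1, 0.1) µm.  The finer grid matters quantitatively: with ~3 µm
nuclear semi-minor axes, a 5 px blur at 0.379 µm/px is wider than the
nuclear rim and the fixed low threshold then dilates and merges masks,
whereas at 0.1 µm/px the same printed blur/threshold pair recovers
ellipsoid volumes to within a few percent.

## Chromatin classification

Inside a nuclear ROI, DAPI voxels in [150, 255] are heterochromatin
(DAPI-dark, HC), voxels in [50, 150) are euchromatin (DAPI-light, EC), and
voxels below 50 belong to neither class.  Both boundaries are inclusive
exactly as printed (>= 150 dark, >= 50 light).  Total chromatin (TC) is
EC ∪ HC by default; a flag (`tc_includes_sub_light`) re-admits sub-50
nuclear voxels for users who prefer the broader reading.

Signal masks for H3K4me3, PMP22 and Lamin B1 are fixed-threshold
binarizations at 50 (inclusive), symmetric with the EC lower bound; Otsu
thresholding is available per channel.  Interactive per-nucleus visual
thresholding is deliberately not reproduced — fixed thresholds keep runs
reproducible.

## Peripheral vs central profiles

Two straight vectors are traced per z-plane through the in-plane mask
centroid: longitudinal along the principal axis (second moments of the
mask) and transverse perpendicular to it, sampled at 1-pixel steps
(nearest voxel) and clipped to the mask.  Transverse vectors split into
three equal-length sectors (distal thirds peripheral); longitudinal
vectors into four quarters (distal quarters peripheral).  Remainders under
integer division are assigned so sector sizes never differ by more than
one sample: transverse remainders go to the central sector first (then the
left peripheral), longitudinal remainders outward first (left peripheral,
right peripheral, then left central).  Raw samples, not per-plane means,
are pooled across planes and, by default, across both vector kinds; pooled
and per-kind summaries are both available.  Hand-traced vectors in the
original workflow are replaced by this deterministic surrogate.

## Colocalization

Five pairings per nucleus: (i) EC signal (H3K4me3) vs TC (DAPI restricted
to EC ∪ HC), (ii) EC mask (H3K4me3) vs HC mask (DAPI-dark), (iii) PMP22
signal vs EC signal, (iv) PMP22 mask vs HC mask, (v) PMP22 signal vs
Lamin B1 signal.  For each, on every usable z-slice of the cleared crop:

* **Manders split coefficients.** `M1` is the fraction of the query
  channel's summed intensity co-occurring with the reference channel, `M2`
  the converse; role-swap symmetry is exact.  The denominator names the
  normalizing channel, matching the printed formulas (note the printed
  verbal labels for M1/M2 are not fully consistent with those formulas;
  the formulas win here).  On signal-level pairings the partner/self
  criterion is intensity >= the per-role signal threshold (50), i.e.
  thresholded Manders; this keeps read noise in the empty parts of a
  cleared crop from inflating co-occurrence.  On the raw primitive the
  default criterion is simply intensity > 0, and the thresholds are
  configurable.  A zero denominator yields a flagged NaN, never 0 — an
  empty channel must not fabricate anticolocalization.
* **Rank correlations.** Spearman's rho (average ranks on ties) and
  Kendall's tau-b (tie-corrected) over the ROI voxels of the slice.
  Pearson's r is not reported: these intensity distributions are far from
  normal.
* **Summary.** Per-nucleus coefficient = median across slices, consistent
  with median-based reporting throughout; NaN slices are ignored.

The **Costes randomization test** runs once per pairing on the usable
slice nearest the nucleus middle: the ROI bounding box is tiled into
3x3-px blocks (edge blocks zero-padded and scrambled with the rest), the
blocks of one channel are permuted uniformly 100 times with a run-derived
seed, and the reported value is the percentage of scrambles whose
correlation with the unscrambled partner is below the observed one.
Values above 95% indicate non-chance colocalization.  The correlation
engine is Spearman for consistency with the reported coefficients; the
classical Pearson engine is available via `use_pearson`.  Block size and
scramble count are declared defaults, not inferred values.

## Group statistics

Groups are compared with the two-sample Mann–Whitney U test, two-tailed:
exact null distribution when the smaller group has at most 8 observations
and no ties are present, otherwise the normal approximation with tie and
continuity corrections.  (Published wording conflates "Mann–Whitney U" and
"signed-rank"; for independent genotype groups the rank-sum U test is the
applicable one and is what is implemented.)  Shapiro–Wilk p-values are
recorded per group but never switch the pipeline to a parametric branch.
Distributions are summarized by medians with bootstrap percentile 95%
confidence intervals (10,000 seeded resamples; the CI construction used by
the original statistics package is unstated, so the bootstrap is a
declared substitute).  Intervals are omitted below n = 8.  No
multiple-testing correction is applied by default (a Bonferroni option
exists).  Nuclei are treated as independent observations; animal-level
nesting is not modelled — a documented simplification.

In the comparisons table, within-genotype peripheral-vs-central rows reuse
the two-group schema with group 1 = peripheral and group 2 = central.

## Synthetic scenes

The generator builds ground-truthed two-genotype scenes:

* **Geometry.** Axis-aligned ellipsoids elongated 3:1 along x (the fiber
  axis), fixed z semi-axis 2.6 µm, volumes drawn per nucleus from a normal
  distribution (Wt 280 ± 45 µm³, TrJ 170 ± 30 µm³, reflecting the smaller
  TrJ nuclei).  Placement on a jittered grid makes overlap impossible; an
  explicit field shape switches to rejection sampling and raises
  `PlacementError` when full.
* **Chromatin.** HC is grown as ~1 µm ellipsoidal blobs (5x10x10 voxels)
  with centres kept off the extreme rim (normalized radius <= 0.85),
  trimmed so the HC voxel count hits the configured fraction exactly
  (Wt 0.18, TrJ 0.25).  DAPI levels: EC core 95 (Wt) / 110 (TrJ), EC
  shell 55, HC 200, interchromatin pockets 35.  The periphery sits at the
  dim end of the DAPI-light band so that the fixed segmentation thresholds
  track the true boundary; the pockets host signal that should co-occur
  with neither chromatin class.  H3K4me3 marks EC only (core level 130
  Wt / 100 TrJ, attenuated to 0.55x in the outer shell so the central
  predominance of the euchromatic mark is expressed clearly in both
  genotypes), and is absent from HC.
* **Signals.** PMP22-positive voxels (15% of the nucleus) are drawn with
  explicit quotas: a fraction in EC (Wt 0.75, TrJ 0.60), a fraction in HC
  (Wt 0.10, TrJ 0.22), remainder in the dim pockets; 75% of them sit in
  the peripheral shell (outer third of the normalized elliptical radius,
  mirroring thirds-based sectoring).  Lamin B1 voxels (12%) are 90%
  peripheral.  Levels: PMP22 70 (Wt) / 100 (TrJ), Lamin B1 110 (Wt) /
  80 (TrJ).  Cytoplasmic PMP22 fills a perinuclear halo at level 40 —
  present so ROI clearing has something to clear, but below the signal
  mask threshold.  The realized per-nucleus overlap and peripheral
  fractions are recorded as ground truth, which is what recovery tests
  compare against (quota rounding makes the realized value the honest
  target).
* **Noise and determinism.** Per-nucleus multiplicative level jitter
  (sd 0.08; 0.03 for the DAPI counterstain, which is the most stable
  stain) plus additive Gaussian read noise (sd 6), clipped to [0, 255].
  Poisson shot noise and PSF blur are deliberately omitted for exact
  reproducibility at 8-bit scale: a given seed yields a bit-identical
  scene.  All randomness flows from one `numpy` Generator.

What passing on these scenes shows — and does not show: the scenes have
sharp compartment boundaries, no optics (PSF, z-attenuation, bleed-through),
no cytoplasmic aggresomes and no touching nuclei, so the validation
demonstrates correctness of the measurement chain and recovery of known
ground truth, not robustness to real acquisition artefacts.

## Validation problem sizes

Parameter recovery uses 2-nuclei scenes per overlap fraction
f ∈ {0, 0.25, 0.5, 0.75, 1} at zero and default noise (20 nuclei total)
with recovery demanded within ±0.05, and 5-nuclei scenes for the 10%
volume check.  Direction-of-effect runs 50 nuclei per genotype at a fixed
seed.  Type-I calibration simulates 1,000 null comparisons of n = 20 vs 20.
These sizes give stable medians while keeping a full validation run at
desk scale.

## Known limitations

* No watershed: touching nuclei merge.
* Vector profiles assume roughly convex per-plane masks (marching stops at
  the first step outside the mask).
* The Costes null scrambles blocks within the ROI bounding box; pixels
  dragged in from padded edge blocks enter the null correlations, which is
  conservative for elongated ROIs.
* Genotype effects are encoded as intensity-level and placement-quota
  differences; absolute intensities have no physical calibration and only
  orderings are meaningful.
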