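# Methods

This note documents the models and procedures implemented in `petlymph`, the
constants that govern them, the design choices made where the procedure was
genuinely open, and what the synthetic phantoms do and do not establish.

## Volume model and preprocessing

A scan is a 3-D grid of non-negative scalars with voxel spacing in mm; axes
are `(x, y, z)` with `z` running cranio-caudally (index 0 at the head).
Values are either activity concentration (Bq/ml) or SUV.  SUV conversion is
`SUV = concentration × body weight [g] / injected dose [Bq]`; the injected
dose is assumed decay-corrected to scan start — vendor-specific variants
(lean-body-mass SUV, SUVpeak) are out of scope.

Denoising uses an isotropic Gaussian, **σ = 2.0 in voxel units** by default.
The width is interpreted in voxels because that is the common default of
standard filter implementations; a `sigma_in_mm` flag converts per-axis when
a physical width is wanted.  Boundary handling is reflect-padding so the
brain and bladder peaks — the cropping landmarks — are not dimmed at the
scan ends.  Smoothing precedes SUV conversion; the two commute up to the
scalar factor, but the stated order is kept so intermediates match.

## Cropping heuristic

Scan length varies by acquisition protocol, so scans are standardized by
cropping at brain and urinary-bladder level:

1. maximum projection onto the xz-plane (max, not sum, both here and in
   step 3, because the profile is defined as a function of SUV *maxima*);
2. extremity trimming: keep the symmetric band of **60 %** of the image
   width centred on the x-column with maximal summed intensity (the body
   axis).  The exact trimming rule is an open design point; this central-band
   heuristic is simple and deterministic;
3. per-slice maximum across x → a 1-D cranio-caudal profile;
4. smooth with a 1-D Gaussian (**σ = 2 slices**), find local maxima, and
   call a peak *significant* when its prominence is at least **25 %** of the
   smoothed profile maximum.  The first and last significant peaks are the
   boundaries.  The prominence rule operationalizes "distinct physiological
   uptake"; both constants are configurable.

Boundary slices count as *outside*: a region is kept only if all its voxels
satisfy `z_top < z < z_bottom`.  This exclusive convention matches the
exclusion of boundary-overlapping lesions from analysis (the brain and
bladder blobs themselves are always removed this way).  With fewer than two
significant peaks, the cranial boundary is set if one peak exists and the
affected scan passes through unfiltered with a warning (strict mode raises
instead) — the behaviour in this degenerate case is a package choice.

Known failure mode, reproduced in the tests: when the brain is outside the
field of view the first significant peak sits at a salivary-gland-level
head-and-neck focus or a cranial tumor lesion, cropping the scan too low.
A dense neck ridge can also lose prominence to a brighter focus below, in
which case the crop lands at that focus.

True idempotence of re-cropping holds only when the re-cropped scan retains
the full landmark extent; cropping exactly at the peak slices puts the peaks
on the array edge where no interior maximum exists.  The test suite checks
idempotence with a margin beyond the landmarks.

## Segmentation

* **Threshold**: voxels with SUV < 2.5 are excluded (`≥ 2.5` is kept — the
  threshold value itself is inside).  A fixed, sensitive threshold keeps all
  potential tumor lesions; adaptive (%SUVmax, background-relative)
  thresholds are deliberately out of scope.
* **Watershed**: flooding watershed on the negated SUV inside the mask,
  26-connectivity, basins seeded at the regional maxima of the (already
  denoised) SUV image.  The implementation floods every masked voxel into a
  basin, so no watershed-line voxels remain and the mask is partitioned
  exactly; a separate line-resolution tie-break is therefore unnecessary.
* **Texture merge**: for each region, symmetric co-occurrence counts over
  all 26 direction offsets at distance 1 (pairs fully inside the region),
  on SUV quantized into **0.5-SUV bins anchored at the 2.5 threshold**;
  contrast `Σ(i−j)²p`, entropy `−Σp log₂p`, inverse difference moment
  `Σp/(1+(i−j)²)`; the *aggregated* texture is their mean.  Adjacent regions
  merge while their absolute aggregated difference is **strictly below 2**.
  The merge schedule is best-first — always the currently most similar
  adjacent pair, recomputing the merged region's texture before the next
  step — which makes the result deterministic and order-independent.
  Regions too small to carry texture (fewer than two voxels, or no interior
  pair) never merge.  Absolute-SUV binning was chosen over per-region
  min–max binning so texture is comparable across scans; the bin width is
  configurable.
* **Volume filter**: regions smaller than 2.0 ml are excluded (`≥ 2.0 ml`
  is kept; note the strict/non-strict asymmetry with the merge threshold).
  The filter runs after merging — whether it preceded merging is not
  determinable from the pipeline's description; filtering *segmented
  volumes* after merging is the natural reading and is what is implemented.

## The 31 features

Per region: 19 SUV-based, 6 shape-based, 6 spatial location features.

SUV statistics are computed over the raw value list (population variance).
Conventions fixed here: **energy is the raw `Σv²`** (uniformity `Σp²` over
the histogram is the histogram analogue), entropy/uniformity use the same
0.5-SUV bins as segmentation, **kurtosis is Pearson** (normal → 3), and
skewness/kurtosis of constant or single-voxel regions are defined as 0.

NGTDM features follow the standard neighbourhood grey-tone difference
definitions (coarseness, contrast, busyness, complexity) on the quantized
region with 26-neighbourhoods restricted to the region; coarseness is capped
at `1/ε` with **ε = 1e-6** for flat regions, and busyness/complexity/contrast
guard their degenerate denominators to 0.

The outside difference is the mean SUV inside the region minus the mean over
its 1-voxel 26-connected dilation shell, excluding voxels of other segmented
regions (shell thickness configurable).

Shape: surface area by exposed-face counting (each face weighted by its
physical area); area–surface ratio is **V/S** in mm (bounded for bounded
voxel size; the opposite orientation would diverge for small regions);
compactness is the sphere-normalized `36πV²/S³`; maximum diameter is the
largest distance between voxel centres (convex-hull accelerated).  The
surface difference estimates surface regularity as the mean ratio of
Euclidean to geodesic distance between sampled surface-voxel pairs, the
geodesic running along the 26-connected surface-voxel graph with physical
edge lengths; **up to 500 pairs** are drawn from a seeded generator (seed 0
by default) so the feature is deterministic; a single-voxel region scores 1.

Location: the centroid as fractions of the body bounding box — x and y over
the grid extent, z over the cropped `[z_top, z_bottom]` interval — and the
major axis as the unit eigenvector of the voxel-coordinate inertia tensor
for the largest eigenvalue, sign-fixed to non-negative z (then x, then y
for axial-plane axes); an isotropic tensor maps to `(0, 0, 1)`.

**Normalization** to a standardized body size: with
`L = (z_bottom − z_top)·dz` in mm, `scaled_volume = V[ml]/L³·10⁶`,
`scaled_surface_area = S[mm²]/L²·10⁴`, `max_diameter = d[mm]/L`.  SUV and
texture features live in absolute SUV with fixed bins, hence are
resolution-independent by construction and pass through; the centroid and
axis are already normalized.  This concrete scheme (features computed on the
original grid, then transformed — no resampling) is the package's own
design; every constant is configurable.

## Classification

`RandomForestClassifier` (bootstrap per tree, depth-capped, `mtry` features
per split) provides the trees; prediction is an explicit **per-tree majority
vote** with ties resolved toward the earliest class in the canonical order
T, T+NT, BRAIN, SK, HN, HT, RK, LK, LI, GI, G, BL, BF, NT+NT.

Nested cross-validation: per repetition the data are partitioned **at
patient level** into three parts (region-level partitioning is available by
flag but leaks within-patient correlation); the parts rotate through
test/validation/train so each region is a test case exactly once per
repetition; the inner step trains one forest per hyperparameter pair on the
training part and keeps the pair with the best validation accuracy; that
forest predicts the test part.  Defaults: depth grid {4, 8, 16, ∞}, mtry
grid {6, 10, 16} (≈ √31, and denser), **500 trees**, 10 repetitions,
unstratified partitions (stratification by flag).  Confusion-matrix cells
are averaged across repetitions and rounded half-up to integers; the
per-region final label is the modal prediction.  Rounding averaged cells can
move the matrix total by a few counts relative to the region count — this is
inherent to the average-then-round reporting convention.  A class missing
from a training part simply cannot be predicted in that rotation (logged,
not fatal; singleton classes occur in clinical data).

Reported percentages round half-up (82.5 % → 83 %); raw proportions are kept
internally.

## Synthetic phantoms

The generator emulates the gross structure of a whole-body FDG distribution
on a 68×52×200 grid at 3 mm isotropic spacing (a pediatric-size body of
≈ 20×16×60 cm): a body background of SUV 1.0 (additive noise sd 0.12) inside
an elliptic cylinder, and per-class ellipsoidal blobs with
location/size/uptake priors — brain (SUV ≈ 9) and bladder (≈ 10) at the
extremes, a posterior midline column of 4–5 elongated skeleton blobs
(≈ 5), paired kidneys (≈ 7), heart (≈ 6), head-and-neck foci (≈ 5.5),
scattered GI foci (≈ 5.5), rare paired brown fat, liver and genital foci,
Poisson(4.1, min 1) tumor lesions (SUV 8–13, 8–35 ml) anywhere in the nodal
stations, and rare composed volumes built from two overlapping blobs
(tumor+organ → T+NT, organ+organ → NT+NT).  Expected per-patient counts
were set once to mirror the class marginals of the clinical reference
cohort (skeleton-heavy; liver/genital/bladder rare).  15 % of cohort
patients are generated without a brain to exercise the cropping failure
mode.

Blob profiles are Gaussian, with width and amplitude solved analytically so
that **after** the pipeline's σ = 2 denoising the blob peaks at its nominal
class SUV and crosses SUV 2.5 exactly at the ground-truth ellipsoid
boundary.  This makes recoverability a design property rather than an
accident of blob size: the threshold+watershed stage recovers truth blobs
with Dice ≈ 0.95 regardless of size, and the residual inaccuracy is
discretization and texture noise.  Class texture is multiplicative
log-normal noise (sd 0.04–0.20, tumors noisiest).  Placement rejects
overlaps within a 1.25× keep-out ellipsoid (error after 100 attempts).  All
randomness derives from one seed; phantoms are bit-reproducible.

What the phantoms do *not* model: PET physics (PSF, scatter, attenuation,
reconstruction artifacts), organ shapes beyond ellipsoids/columns,
partial-volume bias, inter-scanner SUV calibration error, and realistic
intra-class texture.  Passing the end-to-end tests therefore demonstrates
the pipeline's mechanics — recovery, cropping, feature informativeness,
leakage-free model selection, determinism — not clinical-grade accuracy on
real scans.  On these phantoms the class signatures are deliberately
distinct, so nested-CV tumor sensitivity/specificity (≈ 0.97–0.99) sit well
above the clinical reference values (83 % / 91 %); the clinical operating
point is checked by exact reconstruction of the shipped reference confusion
matrix instead.

## Problem sizes for the packaged evaluations

The cohort-scale evaluation (acceptance script and acceptance tests) uses
60 phantoms (≈ 600–900 regions), 10 repetitions, 300 trees, and the
hyperparameter grid {8, ∞} × {6, 16} — a representative operating point
chosen so a full evaluation completes in minutes on one CPU.  The
determinism check uses a 4-patient cohort and 2 repetitions.  The library
defaults (500 trees, full grid) remain as documented above.

## Numerical and degenerate-input conventions

* co-occurrence/NGTDM on < 2 voxels (or no interior pair/neighbourhood):
  undefined-texture error;
* empty dilation shell for the outside difference: error;
* flat z-profile or all-zero projection: boundaries not found / warning;
* empty watershed mask: empty labeling;
* single-class training set: degenerate constant classifier with warning;
* feature vectors with missing entries: prediction refuses;
* confusion matrices validate the closed 14-class vocabulary; empty manual
  classes yield NaN accuracy; sensitivity without tumor columns raises.
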