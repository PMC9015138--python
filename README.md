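# petlymph

Automatic segmentation and tissue classification of FDG-PET uptake volumes in
whole-body scans of lymphoma patients.

## The problem

Lymphoma is a systemic disease with a multifocal involvement pattern, and
FDG-PET shows every metabolically active focus — tumor lesions, but also the
brain, the heart, the kidneys, the skeleton, salivary glands, bowel and
activated brown fat.  Measuring the metabolic tumor volume, or any texture or
heterogeneity marker, over a large trial requires separating tumor uptake
from this physiological background automatically; doing it by hand does not
scale beyond a handful of scans.  `petlymph` implements a complete pipeline
for this task, for researchers working with whole-body PET of (pediatric)
Hodgkin lymphoma:

1. **Preprocessing** — Gaussian denoising (σ = 2.0), SUV conversion
   (`SUV = activity · body weight / injected dose`), coronal
   maximum-intensity projections for visual QC.
2. **Scan cropping** — a heuristic that standardizes scan length by locating
   the two most reliable high-uptake landmarks: the volume is max-projected
   onto the xz-plane, trimmed of lateral extremities, collapsed to a
   cranio-caudal profile of SUV maxima, and the first and last significant
   peak (prominence ≥ 25 % of the profile maximum after smoothing) become
   the brain-level and bladder-level boundaries.  Regions overlapping a
   boundary or outside are excluded.
3. **Segmentation** — voxels with SUV < 2.5 are excluded; a flooding
   watershed on the negated SUV topography partitions the rest into
   catchment basins; 26-adjacent basins whose aggregated co-occurrence
   texture (mean of contrast, entropy and inverse difference moment at
   distance 1, all 26 directions) differs by less than 2 are merged;
   regions under 2.0 ml are dropped.
4. **Features** — 31 descriptors per region: 19 SUV-based (order statistics
   and moments, NGTDM coarseness/contrast/busyness/complexity, mean
   inside-outside difference), 6 shape-based (volume/surface ratio, surface
   regularity, scaled surface and volume, compactness `36πV²/S³`, maximum
   diameter) and 6 spatial (principal-axis direction and body-normalized
   centroid).  Size features are scaled by the cropped body length so that
   patient size and scanner resolution drop out without resampling.
5. **Classification** — a random forest over 14 tissue categories
   (T, T+NT, BRAIN, SK, HN, HT, RK, LK, LI, GI, G, BL, BF, NT+NT) with
   patient-level nested cross-validation: three parts rotate through
   train/validation/test, the inner step selects maximum tree depth and
   features-per-split, and results are averaged over ten repetitions.
   For the binary decision, T and T+NT both count as tumor.
6. **Evaluation** — 14×14 confusion matrix (rows automatic, columns
   manual), tumor/non-tumor sensitivity/specificity/PPV/NPV and
   `F1 = 2 / (sensitivity⁻¹ + PPV⁻¹)`, per-tissue accuracies and
   per-patient error summaries.

Because clinical trial scans cannot be redistributed, the package includes a
**synthetic phantom generator** (`petlymph.phantom`) producing ground-truthed
whole-body scans — organ-like blobs with class-specific uptake, size, texture
and location priors — so every stage is testable end to end.

## Worked example

```bash
python examples/03_segment_and_features.py
```

prints, for a seeded phantom:

```
regions per stage: {'watershed': 16, 'merged': 16, 'volume_filtered': 16, 'crop_filtered': 14, 'features': 14}
 region_id  volume_ml  suv_max  suv_mean  compactness  centroid_z truth
         1     19.467    7.054     3.826        0.321       0.546    LK
         2      9.666    9.455     4.343        0.306       0.549     T
         ...
        13     29.133   10.488     4.564        0.295       0.437     T
        14     25.650   10.815     4.147        0.244       0.668  T+NT
```

16 uptake volumes are segmented; the brain and bladder overlap the cropping
boundaries and are excluded, leaving 14 classifiable regions.  `suv_max`
separates tumor lesions (≈ 9–13) from organ uptake (≈ 4–7), and `centroid_z`
places each region within the cropped body (0 = brain level, 1 = bladder
level).  `examples/04_classify_cohort.py` runs the nested-CV classifier on a
small cohort and prints the confusion matrix and binary metrics;
`examples/05_reference_evaluation.py` reproduces the clinical reference
metrics below.

The command-line interface mirrors the stages
(`petlymph suv | crop | segment | features | train | predict | evaluate |
phantom | run-all`); see `petlymph --help`.

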