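# Methods

`roifinder` turns coarse, multi-element X-ray fluorescence (XRF) microscopy
maps into a ranked list of fine-scan targets. This note records the models
and procedures it implements, the defaults and why they are set where they
are, what the synthetic scan generator does and does not emulate, and the
numerical conventions that make runs reproducible.

## Problem setting

An XRF microscope raster-scans a focused X-ray probe over a cryo-frozen
sample and records, after spectrum fitting, one 2D grid of fluorescence
counts per chemical element (K, P, S, Ca, Zn, Fe, ...). Coarse survey scans
(0.25 µm step) are fast but must be followed by slow, high-resolution fine
scans of a few chosen cells. The package automates the choice: detect
individual bacterial cells in the coarse maps, embed them in a
principal-component space built from morphological and elemental features,
cluster them softly, and hand the control system stage coordinates of the
cells most worth scanning.

The motivating biology is treatment-response screening in *E. coli*:
healthy cells frozen live (type A) retain high intracellular potassium,
because K is pumped in across an intact inner membrane; membrane-disrupting
poisoning (type B, ethanol) lets K leak out while Ca, Zn and P rise;
azide/copper treatment (type C) shows the highest K. Potassium contrast is
therefore the load-bearing feature for the A-vs-B call.

## Segmentation

1. **Composite image** — the per-pixel sum of the K, P, S and Ca channels.
   These four elements contrast well against the background; summing them
   makes cells visible even at short dwell times.
2. **3×3 median filter**, reflect-padded at the borders, to suppress
   single-pixel shot noise before thresholding.
3. **Otsu threshold × 1.25** on the filtered composite. The Otsu value is
   computed on a 256-bin equal-width histogram over [min, max]; the
   returned threshold is the bin edge maximizing the between-class
   variance, ties broken toward the lower edge for determinism. The 1.25
   multiplier tightens the mask around the cell interior. A constant
   (degenerate) image yields an all-background mask with a warning rather
   than an error, so empty scans flow through the pipeline.
4. **Connected components** under 8-connectivity (diagonally touching
   boundary pixels stay in one cell). Components of **≤ 8 pixels are
   rejected** as image-processing artifacts; the filter is exclusive (9 px
   is the smallest accepted cell). ROI ids are assigned in raster order of
   each component's first pixel.

Conventions stated once: 0-based (row, col) indexing; half-open bounding
boxes; stage x along columns, y along rows, origin at the top-left pixel
center (a configurable flip is the integration point for a real beamline).
Whether the threshold should be computed on normalized rather than raw
counts is unstated upstream; raw filtered counts are used here.

## Features

Seven features per cell at the defaults: area `a` (pixel count),
eccentricity `e` of the ellipse with the same normalized second central
moments as the pixel set (0 = circle, → 1 = line; 0 for a single pixel),
and the **maximum** count of K, P, Ca, Zn and Fe over the cell's pixels.
The maximum can be swapped for the mean or any user reduction; max was
retained as the default because cell-averaged counts showed no clustering
benefit in the source workflow. Aggregators read the raw channel grids —
the median-filtered composite exists only for segmentation. S contributes
to segmentation but is not a feature. Counts are used as-is: PCA on
standardized features is invariant to positive per-feature rescaling, so a
count-to-concentration conversion would not move the cluster structure.

## PCA

Features are standardized column-wise (mean 0, sample standard deviation 1,
n−1 denominator; a constant column is an error naming the feature). The
decomposition is the SVD `Xs = U S Vᵀ`, equivalent to the
eigendecomposition `C = V Λ Vᵀ` of `C = XsᵀXs/(n−1)` with `Λ = S²/(n−1)`.
Scores are `Xs V`; loadings are `V S/(n−1)`; the scree is `Λ/ΣΛ`.
Eigenvector signs are fixed so each column's largest-magnitude entry is
positive (ties → first index), making fits bit-reproducible. Clustering
uses the first **2** components by default — enough to separate two
treatment groups — while the scree is always available because real
campaigns need more components to exhaust the variance.

## Clustering and confidence

Hard k-means (k = 2 default) minimizes the within-cluster sum of squares;
the implementation is scikit-learn's Lloyd algorithm with k-means++ starts,
best of 10 initializations, seeded. (Empty-cluster handling is therefore
scikit-learn's center relocation.)

Fuzzy k-means (fuzzy c-means) minimizes `Σᵢ Σⱼ wᵢⱼᵐ ‖xᵢ − cⱼ‖²` subject to
row-stochastic weights, with fuzziness **m = 2** (m → 1 recovers hard
clustering; m ≤ 1 is rejected with a pointer to `kmeans`). Updates
alternate `cⱼ = Σ wᵢⱼᵐ xᵢ / Σ wᵢⱼᵐ` and
`wᵢⱼ = 1 / Σ_c (‖xᵢ−cⱼ‖/‖xᵢ−c_c‖)^{2/(m−1)}` until `max|ΔW| < 1e-9` or 300
iterations; the objective history is recorded and is non-increasing. A
point coincident with a center receives an indicator weight row (the
formula would divide by zero). Initialization is the hard k-means solution
with the same seed: deterministic and fast to converge.

A cell's **confidence** is its largest membership weight (∈ [1/k, 1]);
cells **strictly below 0.99** are flagged as borderline — outliers,
dividing cells and scan artifacts concentrate there. The flag threshold is
strict by definition: a cell at exactly 0.99 is kept.

For the two-treatment scenario the cluster with the higher mean max-K is
labeled type A (healthy), the other type B; a tie raises and asks for
manual assignment. The heuristic is deliberately scoped to k = 2 — with
type C present the K ordering inverts (C is highest), so no automatic
3-type rule is offered.

## Recommendation

Two criteria, both deterministic:

- **nearest neighbor**: for each selected cell, the closest non-selected,
  non-excluded cell by Euclidean distance in the 2-PC plane (ties → lower
  index), de-duplicated and sorted by distance. One neighbor per selected
  cell, not one global neighbor.
- **cluster confidence**: members of a target cluster with confidence above
  a floor, sorted by descending confidence, truncated to n.

Interactive lasso selection is replaced by an index-set / polygon-in-PC-
space API (`select_in_polygon`). Output is CSV/JSON with stage coordinates
`(x, y) = origin + (col, row) × step`; EPICS integration stays outside.

## Evaluation

- **Dice score** per cluster: `DS = 2T_P/(2T_P + F_P + F_N)`, counting a
  cluster's members as positive predictions for its matched label.
  Clusters are unordered, so the cluster↔label bijection maximizing the
  mean DS is chosen by exhaustive search (exact for k ≤ 4).
- **Subsampling experiment**: for each proportion p, sample
  `ceil(p·n_type)` cells per type without replacement, rerun PCA (2 PCs) +
  k-means, average the mean dice over the repetitions. The ceil rule is
  what reproduces the published per-type sample counts from an
  81 A + 25 B population (29/9 at 35% ... 69/22 at 85%).
- **SNR** of a scan against a reference binary mask:
  `(mean inside − mean outside)/std outside`. The definition is a
  documented choice (no formula is published for the quoted values), so
  only the monotone trend with dwell time is asserted, never the printed
  1.64/0.97/0.80.

## Synthetic scans

The real beamline scans are not distributable, so the generator emulates
them with known ground truth:

- **Cells** are filled ellipses rasterized by center-of-pixel inclusion
  (area and eccentricity then have closed-form continuous counterparts for
  validation). Semi-axes default to 3.5–6.0 px major and 1.5–2.75 px minor
  at the 0.25 µm step — roughly the 2 × 0.8 µm envelope of *E. coli* — so
  every planted cell clears the 8-px filter. Placement is rejection
  sampling with a 2-px exclusion margin; failure after 500 tries per cell
  raises.
- **Rates** (expected counts/pixel at the 100 ms reference dwell):
  background 2 everywhere; type A K=60, P=40, S=30, Ca=8, Zn=6, Fe=5;
  type B K=15, P=55, S=30, Ca=30, Zn=20, Fe=5; type C K=90, P=40, S=30,
  Ca=10, Zn=8, Fe=5. These magnitudes are invented (no absolute scales are
  published) but reproduce the qualitative chemistry: K leakage in poisoned
  cells, elevated Ca/Zn/P in type B, highest K in type C. All configurable
  via YAML.
- **Noise**: every pixel count is Poisson with mean
  `rate × dwell/100 ms` — contrast grows ∝ dwell and background noise
  ∝ √dwell, so SNR falls as dwell is shortened, matching the qualitative
  published behavior. An optional `noise_seed` redraws the noise on an
  identical scene.
- **Artifacts**: random connected speckles of 1–8 px with a high added rate
  in the four composite channels, planted on free background — exactly the
  population the ≤ 8 px filter must remove.

What a green test does *not* establish: the default populations are nearly
linearly separable in (max K, max Ca), so clustering accuracy saturates
near 1.0 at every subsampling proportion. The published accuracy ramp
(≈ 0.64 → 0.86 with sample size) reflects real-data variability — touching
cells, scan corruption, biological spread — that this simulator does not
model. Likewise the simulator has no detector physics (escape peaks,
pile-up), no spectra, and no spatially structured background.

## Numerical choices and degenerate inputs

- Negative input counts (possible after upstream background subtraction)
  are clamped to 0 with a warning at load time.
- Otsu on a constant image raises `DegenerateImageError`; `binarize`
  converts that into an all-background mask plus warning.
- Fuzzy weights at zero distance use the indicator convention; equidistant
  points get exactly uniform weights.
- Standardization treats a column as constant when its sd is below
  1e-12 × max(1, |mean|).
- All randomness — simulator, k-means initialization, subsampling — flows
  through explicit integer seeds; rerunning any stage with the same inputs
  and seed reproduces byte-identical CSV artifacts.

## Known limitations

- Touching or dividing cells are not split (no watershed); they surface as
  low-confidence outliers instead.
- The treatment-label heuristic covers only the two-treatment case.
- The MAPS-style HDF5 adapter guesses an undocumented layout and is
  excluded from the test gate; validate it against real files before use.
- Dice-score matching is exhaustive over cluster↔label bijections and is
  only practical for k ≤ 4 (which covers the intended use).
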