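# roifinder

Cell detection, clustering and fine-scan recommendation for X-ray
fluorescence (XRF) microscopy coarse scans.

XRF microscopes raster a focused X-ray probe over a cryo-frozen sample and
produce one 2D fluorescence-count map per chemical element. Coarse survey
scans are fast; the high-resolution fine scans that resolve subcellular
elemental distributions are slow, so beam time hinges on choosing the right
few cells to fine-scan. `roifinder` automates that choice for single-cell
work (the motivating case is treatment screening of *E. coli*, where
intracellular potassium separates cells frozen live from membrane-disrupted,
poisoned ones):

1. **Segment** — sum the K, P, S and Ca maps into one composite, median
   filter (3×3), threshold at 1.25× the Otsu value, take 8-connected
   components, reject artifacts of ≤ 8 pixels.
2. **Featurize** — 7 features per cell: area *a*, eccentricity *e*, and the
   maximum count of K, P, Ca, Zn and Fe over the cell's pixels.
3. **Embed** — standardize, then PCA (`Xs = USVᵀ`, scores `XsV`, loadings
   `VS/(n−1)`); keep 2 components for clustering, report the full scree.
4. **Cluster** — hard k-means (k = 2) and fuzzy k-means (m = 2) minimizing
   `Σᵢⱼ wᵢⱼᵐ‖xᵢ−cⱼ‖²`; each cell's *confidence* is its largest membership
   weight, and cells below 0.99 are flagged as borderline.
5. **Recommend** — stage coordinates of either the nearest neighbors of a
   selection in the PC plane, or a cluster's most confident members.

Because real beamline scans are rarely shareable, the package ships a
synthetic scan simulator (elliptical cells, treatment-specific elemental
rate profiles, speckle artifacts, Poisson noise scaling with dwell time)
with full ground truth, so every stage is testable at desk scale. See
`docs/methods.md` for the models, defaults and caveats.

## Worked example

```python
import numpy as np
from roifinder import synthetic, pipeline
from roifinder.recommend import recommend_from_cluster

# a 128x128 coarse scan: 8 healthy (A) + 8 poisoned (B) cells, 3 artifacts
scan, truth = synthetic.generate_scan((128, 128), {"A": 8, "B": 8},
                                      artifact_count=3, seed=42)
res = pipeline.run_pipeline([scan], pipeline.PipelineConfig(seed=0))

print(len(res.rois))                            # 16  (all cells, no artifacts)
print(np.round(res.pca_model.explained_ratio, 3))
# [0.54  0.23  0.123 0.075 0.024 0.005 0.003]
print(res.type_mapping)                         # {1: 'A', 0: 'B'}

rec = recommend_from_cluster(res.fuzzy, 0, n_recommend=3, rois=res.rois)
for r in rec.recommended:
    print(r.roi_id, tuple(np.round(r.centroid_um, 2)), round(r.score, 3))
# 3  (2.33, 10.3)    0.984
# 11 (10.52, 21.87)  0.971
# 8  (23.63, 17.91)  0.97
```

All 16 planted cells are recovered and the three ≤ 8-px artifacts are
filtered out; the first two principal components carry 77% of the feature
variance; the cluster with the higher mean potassium is labeled type A
(healthy) and the per-cell predicted types match the ground truth. The
recommendation lists the three most confidently clustered members of
cluster 0 with their stage coordinates in µm (x = column direction,
y = row direction) — the hand-off a scan-control system consumes.

The same workflow is available from the shell:

```sh
roifinder simulate --shape 128 128 --cells A=8,B=8 --seed 42 --out scan.h5
roifinder run scan.h5 --seed 0 --out out/
roifinder evaluate --features out/features.csv --reps 200 --out table.csv
```

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the whole analysis from scratch: it simulates two A/B coarse scans
and executes the full pipeline, runs the 81 + 25-cell subsampling
experiment (proportions 0.35–0.85, 200 repetitions each, per-type sample
sizes by the ceil rule), and measures the SNR/recovery of one scene scanned
at 50, 25 and 12.5 ms dwell, printing a summary and writing the result file
to `--out`.
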