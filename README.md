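# thalparc

Diffusion-MRI parcellation of the thalamus into its major nuclei, and
construction of a probabilistic atlas from a cohort of parcellated
subjects — implemented as a tested, reusable pipeline exercised end-to-end
on a synthetic cohort generator.

## The problem

The thalamus looks homogeneous on T1-weighted MRI, but its nuclei differ in
local fiber architecture, which diffusion MRI can see.  The pipeline here
follows a cluster-then-fuse strategy:

1. **Mask refinement.** Starting from a whole-thalamus mask, remove voxels
   with CSF probability > 5% (ventricle border) and voxels with fractional
   anisotropy FA > 0.55 (internal capsule).  FA comes from the standard
   tensor eigenvalue form
   `FA = sqrt(3/2) * sqrt(Σ(λi − λ̄)²) / sqrt(Σλi²)`.
2. **ODF features.** Each voxel's orientation distribution function (ODF)
   is expanded in the real symmetric spherical-harmonic basis of order 6
   (28 coefficients); the clustering feature is the mean coefficient vector
   over 50 residual-bootstrap ODF samples.
3. **Spatially constrained k-means.** Each thalamus is split into k = 7
   clusters by Lloyd iterations under the combined metric
   `d(x, c) = 0.5‖x − c_x‖ + 0.5‖f − c_f‖`,
   with positions in millimetres and features pre-multiplied by 100 so both
   terms share a numeric range.  Initialization is the element-wise average
   of many (5000 by default) randomly initialized position-only k-means
   runs, aligned across runs by minimum-cost centroid matching.  Clusters
   are then named by maximal overlap against a reference labeling
   (A, VA, MD, VLV, VLD, Pu, CL-LP-PuM per hemisphere).
4. **Atlas construction.** Per-subject parcellations are warped to a
   template grid (nearest-neighbor, labels are categorical), per-label
   subject proportions form the 14-frame SPAM (spatial probabilistic atlas
   map), and the maximum-likelihood atlas takes the per-voxel argmax label
   with seeded random tie-breaks.
5. **Evaluation.** Atlas-based and cluster-based segmentations of the same
   subject are compared per nucleus with Dice overlap
   `2|A∩B|/(|A|+|B|)`, percentage volume difference
   `(V_atlas − V_clust)/V_clust × 100`, centroid distance (mm) and the
   maximum centroid-to-voxel radius (mm).

Real scan data are not required: `thalparc.synthetic` generates reproducible
subject bundles (ellipsoidal bilateral thalami, 7 compact planted nuclei per
side with distinct single-fiber ODF prototypes plus coefficient noise,
planted CSF/high-FA contamination rims, known affine transforms) with the
statistical structure the pipeline assumes, so every stage can be validated
against known ground truth.

## Worked example

The numbered drivers under `analysis/` run the whole study; each writes its
tables under `results/`:

```sh
python analysis/01_simulate_cohort.py      # 10 synthetic subjects
python analysis/02_parcellate_subjects.py  # cluster-based parcellation
python analysis/03_build_atlas.py          # SPAM + max-likelihood atlas
python analysis/04_evaluate_agreement.py   # atlas vs cluster metrics
```

Representative output (exact values depend on the seeds set in the
scripts):

```
mean ARI vs planted nuclei: 0.943 (min 0.878)
subjects with QC flags (candidates for exclusion): 0/10
SPAM: 14 frames over 10 subjects
atlas support: 398 template voxels; 28 with tied modes (random tie-break)
overall mean Dice: 0.742; mean |%dV|: 32.9%; mean centroid distance: 1.25 mm
```

Reading: the clustering recovers the planted nuclei almost perfectly
(adjusted Rand index near 1); the fused atlas, applied back to individual
subjects through their exact affines, agrees with the direct clustering at
mean Dice ≈ 0.74 with centroid displacements of ~1 mm — small against the
~4.5 mm nucleus radii, so the two routes localize the same structures.

A `thalparc` CLI exposes each stage standalone
(`simulate`, `refine-mask`, `fit-features`, `cluster`, `build-atlas`,
`segment`, `evaluate`, `summarize`); run `thalparc --help`.

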