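# Methods

This note documents the models, parameter choices and numerical decisions
behind `thalparc`, and what the synthetic validation does and does not
establish about real data.

## Mask refinement

The whole-thalamus mask is intersected with `csf_prob ≤ 0.05` and
`fa ≤ 0.55`.  Both comparisons are strict removals ("higher than"): a voxel
exactly at a threshold is kept.  No morphological cleanup (hole filling,
largest-component selection) follows thresholding.  All inputs must be
co-registered on one voxel grid; the package does not resample between FA
and anatomical grids.

FA is computed from tensor eigenvalues with the standard closed form and is
scale-invariant (`FA(cλ) = FA(λ)`); an all-zero tensor returns 0 by
convention.  `fit_tensor_loglinear` provides an ordinary least-squares
log-attenuation tensor fit (eigenvalues clamped at zero) for deriving FA
from single-shell attenuations, but the pipeline default consumes a
precomputed FA map.

## ODF features

ODFs are represented in the real, antipodally symmetric spherical-harmonic
basis with even degrees only, `(l, m)` ordered lexicographically; order 6
gives 28 coefficients.  The real basis is assembled from the complex
harmonics in the convention stated in `thalparc.sh` (the diffusion-MRI
standard); it is fixed and documented so coefficient files are portable.
`fit_sh` is a least-squares projection with an optional Laplace–Beltrami
ridge `λ(l(l+1))²`; the default `λ = 0` keeps evaluate/fit round-trips
exact to ~1e−15 with ≥ 28 well-spread directions.

The clustering feature of a voxel is the arithmetic mean of its bootstrap
ODF coefficient vectors (raw coefficients, no per-sample normalization),
then multiplied by the feature scale (default 100) inside the k-means.

## Spatially constrained k-means

Assignment metric: `w_s·‖x − c_x‖ + w_f·‖f − c_f‖` with `w_s = w_f = 0.5`,
positions in world millimetres (through the affine, so anisotropic voxels
such as 2×2×2.5 mm are handled correctly), features pre-scaled by 100.

The default metric sums *unsquared* Euclidean distances — the literal
"weighted linear combination of Euclidean distances".  Under this metric
the arithmetic-mean centroid update is a heuristic (the exact minimizer
would be a geometric median), so the objective is not provably monotone;
convergence is declared on a fixed point of the assignment, and tests audit
that fixed point against a brute-force per-voxel scan.  `squared_metric=True`
squares both terms, which is exactly k-means on concatenated scaled vectors
and has a non-increasing objective (asserted per iteration in tests).  Both
variants are first-class; the unsquared one is the default.

Initialization: `n_init_runs` independently seeded position-only k-means
runs; each run's centroids are aligned to the first run's by minimum-cost
one-to-one matching (Hungarian algorithm on the spatial distance matrix)
and the aligned centroids are averaged element-wise.  Each restart uses
k-means++ seeding — still an independent random initialization per run, but
one that avoids the split/merge local optima that plain random-point
seeding falls into on well-separated structures, which would otherwise
pollute the cross-run average.  Voxel positions are canonicalized to
lexicographic order first, so the initialization depends only on the voxel
set, not its memory order.  The default is 5000 restarts; the test suite
and the analysis scripts use 50, which on the synthetic cohorts changes the
averaged centroids by less than the voxel size.

Initial feature centroids are per-cluster mean features over the partition
induced by spatial distance to the averaged initial centroids.  An empty
cluster arising mid-iteration is repaired by re-seeding its centroid at the
voxel farthest from its currently nearest centroid; repair is bounded and
errors out rather than looping.

Cluster naming: a one-to-one maximum-overlap assignment (Hungarian on the
k×k overlap matrix) against a reference labeling.  In the synthetic
pipeline the reference is the planted ground truth, standing in for the
anatomical labeling an expert performs on real parcellations.

QC: a parcellation is flagged when any cluster falls below 1% of the mask
or fragments into more than one 26-connected component larger than 10% of
the cluster.  Flags mark candidates for exclusion; nothing is dropped
automatically.

## Atlas construction and application

Label volumes are pulled onto the template grid by mapping each target
voxel center through the inverse subject-to-template affine and rounding to
the nearest source voxel (order-0 interpolation; labels are categorical and
must never be averaged).  SPAM frame `l` holds the fraction of subjects
carrying label `l` at each voxel — every value an exact multiple of `1/N`,
per-voxel sums ≤ 1 (1 exactly where all subjects are labeled).  Frame order
is the LUT order, left-hemisphere block (codes 1–7) then right (8–14).

Maximum-likelihood labeling takes the per-voxel argmax; voxels with all
probabilities zero stay background.  Multi-mode ties draw uniformly from
the tied labels using one seeded RNG stream consumed in raster-scan order,
so a fixed seed fixes the volume and the tie statistics are testable (a
planted 50/50 tie resolves each way 500 ± 50 times in 1000 seeds).

Atlas-based segmentation of a subject warps the probability frames (not the
discrete atlas) into subject space and takes the in-mask argmax; mask
voxels outside the warped atlas support inherit the nearest labeled in-mask
voxel's label (Euclidean distance in mm), so the mask is covered completely
with no interpolation-induced label mixing.  Warping the discrete volume
instead is available behind `discrete_warp=True`.

Transforms are affine throughout.  Nonlinear template construction is out
of scope; the synthetic pipeline's template space is defined by the
generator's known ground-truth affines, which makes registration exact by
construction and lets the fusion logic be tested without confounds.

## Evaluation

Dice is computed in the intersection/union form and equals the classical
`2|A∩B|/(|A|+|B|)` identically (property-tested on random pairs).  Two
empty sets give Dice 0 with a warning.  Volumes for the percentage
difference are voxel counts (both parcellations live on one subject grid);
the exact anti-symmetry identity is `%ΔV(a,b) = −%ΔV(b,a)·V_a/V_b`.
Centroids are means of voxel-center world coordinates; the maximum radius
is the largest centroid-to-voxel distance.  Summary tables report
mean ± sd (n−1 denominator; sd 0 with n = 1), median and quartiles per
nucleus and hemisphere; nuclei absent from either parcellation are reported
with a missing flag, never silently dropped.

## Synthetic cohort: what it emulates, and what it does not

Each subject holds two disjoint ellipsoids (semi-axes 9×12×10 mm, 2×2×2.5 mm
voxels, ~900 mask voxels per subject) in a template anatomy fixed by the
cohort seed.  Nuclei are nearest-seed cells of k well-spread seed points
per hemisphere — convex, hence compact and 26-connected, mirroring the
compactness the spatial term of the clustering enforces.  Per-subject
anatomical variability comes from Gaussian jitter of the seed points
(default sd 1 mm) and a small random rigid+scaling transform (default ≤ 2 mm
translation, ≤ 2° rotation, ≤ 1% scale), applied as the inverse of the known
subject-to-template affine so that warping back to the template is exact.

Each nucleus carries a single-fiber ODF prototype: a Watson angular profile
`exp(κ(u·v)²)` with κ = 16 at a nucleus-specific orientation, projected
onto the order-6 basis and normalized to unit coefficient norm.
Orientations are drawn as a rotated spherical Fibonacci set and re-drawn
until all pairwise prototype distances reach the requested separation
(default 0.4).  Bootstrap stacks add independent Gaussian noise
(default sd 0.1) per coefficient and sample.  The defaults therefore give a
prototype-contrast-to-noise ratio of 4, and the 50-sample mean reduces
effective feature noise by a further factor of √50 ≈ 7.  No quantitative
measurement of real inter-nucleus ODF contrast informed these values; they
are this package's choice of a regime where recovery is expected but not
trivial, and the recovery results must be read as validating the machinery,
not as predicting real-data accuracy.

Tissue maps and FA are piecewise-constant with planted contamination: a
CSF-probability rim (0.30) of configurable width around each thalamus, a
high-FA (0.70) band on the lateral boundary, low FA (0.25) and low CSF
(0.02) inside.  Mask refinement at the default thresholds removes exactly
the planted rims — by construction, so refinement tests are exact.

Not emulated: raw DWI signals and their estimation chain (the generator
emits SH coefficients directly), partial-volume gradients, spatially
correlated noise, nonlinear anatomical variability, real nucleus shapes and
their ODF heterogeneity.  Consequently the synthetic Dice/ARI figures are
upper bounds relative to real cohorts of this resolution.

## Problem sizes and determinism

The analysis scripts and the acceptance script use 10-subject cohorts,
50-restart initialization and ~900-voxel masks — sizes at which the entire
chain runs in seconds while every planted property remains testable.  All
randomness flows from explicit integer seeds through
`numpy.random.SeedSequence`; identical configuration and seed reproduce
cohorts, parcellations and atlases bit-identically.  On cohorts drawn at
the default contrast-to-noise of 4, per-subject recovery ARI typically
falls in 0.88–1.0 (mean ≈ 0.94); the residual disagreement is concentrated
on nucleus boundaries, where the planted seed-Voronoi partition and the
k-means centroid partition legitimately differ by a voxel.

## Known limitations

- The unsquared combined metric lacks a monotone-objective guarantee;
  in practice it converges in a handful of iterations on all tested data,
  and the squared variant is available where the guarantee matters.
- Atlas quality at this grid scale is surface-limited: nuclei of ~25
  voxels lose ~0.2 Dice to nearest-neighbor rasterization alone when
  subjects are resampled through differing affines.
- Hemisphere splitting assumes two connected components (falls back to the
  world-x sign), which suits bilateral thalamic masks but not arbitrary
  topologies.
- `n_subjects` replaces no statistical model of anatomical variability:
  SPAM probabilities quantify label agreement under the generator's jitter
  model only.
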