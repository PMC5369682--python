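# Methods

This note documents the models, parameter choices and numerical decisions
behind `oculoseg`, and what the synthetic phantom does and does not
emulate.

## Pipeline overview

Each case is a pair of co-registered 3D channels ("T1" ≙ gadolinium
T1w VIBE, "T2" ≙ T2w) with voxel spacing in mm, plus (for training and
evaluation) an integer label map {0 background, 1 sclera+cornea, 2
vitreous humor, 3 lens, 4 tumor}. Processing stages:

1. landmark detection → rigid alignment to a canonical frame → percentile
   intensity normalization (→ optional ROI crop);
2. joint active-shape-model segmentation of sclera/cornea, VH and lens;
3. per-voxel features inside a θ-band around the fitted VH;
4. random-forest tumor likelihood;
5. graph-cut MAP inference of the binary tumor labeling.

## Canonical frame and preprocessing

The canonical frame puts the VH center at the origin, the lens–VH axis
along +y, and the optic disc in the y–x half-plane (x > 0), which fixes
roll. The disc itself has no intensity signature in the phantom, so the
detector places it on the detected globe at the anatomical ~15° off the
posterior pole; supplying landmarks from a CSV file is the supported
general path (clinical detectors are cohort-specific). Detection is
threshold + connected-component analysis: the VH is the largest T2-bright
blob, the lens is the embedded cavity with the lowest mean T1 (the tumor
cavity enhances on T1, the lens does not).

Channels are resampled with trilinear interpolation, label maps with
nearest neighbor (labels are categorical). Intensity normalization is a
two-landmark piecewise-linear map (percentiles 1/99 → 0/100), monotone by
construction and idempotent on the landmark grid. Inter-channel rigid
co-registration uses Mattes mutual information with a regular-step
gradient-descent optimizer; its contract is tested by recovery of known
synthetic motion (< 0.5 voxel), since no clinical gold standard exists.
The ROI crop keeps the sclera bounding box plus an 8 mm margin and
preserves world coordinates (the origin shifts with the crop), so crop
bookkeeping round-trips exactly; at 0.5 mm spacing and a 12 mm globe this
yields the ~80³-voxel working region the rest of the pipeline assumes.

## Shape model

All three structures are modeled jointly: concatenated mesh vertices
(3 × 642 icosphere vertices) form one shape vector. Generalized Procrustes
alignment runs against a unit-size mean and rescales the final
configuration to the cohort's average centroid size, which keeps model
coordinates in mm and makes re-alignment of an aligned set an exact
identity. PCA is taken about the sample mean of the aligned shapes, so at
most n−1 modes are nonzero and training shapes are reconstructed exactly
when all modes are kept; the retained count is the smallest M with
cumulative variance ≥ `variance_kept` (default 0.95).

Per landmark and channel, k = 7 profile samples spaced s = 0.75 mm are
taken along the outward vertex normal (replicate padding outside the
grid); the model stores their mean and per-sample variance. Fitting
alternates (a) a best-match search along each normal (±3 mm in 0.25 mm
steps, diagonal Mahalanobis distance with variance loading
1e−3·mean-variance + 1e−6) and (b) a similarity-pose + clamped-coefficient
update (|b_m| ≤ 3√λ_m), stopping when the mean landmark displacement drops
below 0.05 mm or after 50 iterations. k, s, the search range/step and the
variance fraction are engineering defaults surfaced in the configuration;
the underlying method specifies none of them.

Meshes are voxelized by dense surface sampling (step = half the smallest
spacing), hole filling, and a signed nearest-surface-normal test for
shell voxels; painting order sclera → VH → lens resolves nesting
innermost-wins, which recovers the sclera shell. A unit sphere voxelizes
to within ~1% of its analytic volume on a fine grid.

## Features

* **STD** (8 planes): T1, T2, anisotropic-diffused T1 (SimpleITK
  gradient anisotropic diffusion, 10 iterations, conductance 1.0, run in
  relative voxel units so the explicit scheme respects the 3D stability
  bound), their 6-neighbor von-Neumann means (center excluded, replicate
  padding), and per-axial-slice SLIC superpixel mean intensities of both
  channels (joint two-channel segmentation per slice; nominal region side
  10 voxels, regularization 0.1 interpreted as skimage compactness on
  unit-normalized intensities, with a permissive fragment-merge threshold
  because low regularization produces irregular superpixels).
* **EPSF** (3 planes): unsigned exact Euclidean distance transforms (mm,
  anisotropic spacing honored) to the boundary voxel sets of the lens and
  of the anatomical vitreous chamber (VH ∪ endophytic tumor — the tumor
  lies inside the chamber whose boundary the feature encodes); and the
  tumor-location prior: voxelwise mean of the aligned training tumor
  masks, Gaussian-smoothed with σ = 3 mm ("reflect" boundaries), clipped
  to [0, 1]. A boundary voxel is a region voxel with ≥ 1 non-region face
  neighbor; distances are therefore exactly zero on the boundary set.

Classification is restricted to the θ-band: the fitted VH plus voxels
within θ mm outside its boundary. Following the cross-validated settings
of the underlying study, θ = 0 for the STD-only scenario and θ = 2 mm
otherwise.

## Likelihood and MRF

The default likelihood is a 200-tree random forest (sqrt-features per
split, bootstrap, OOB score logged) trained on all positive voxels and a
pooled uniform 20% subsample of negatives. Any classifier implementing
the `VoxelClassifier` contract (fit rows / emit probabilities) can stand
in — e.g. an externally trained 3D CNN; no deep model is bundled.

The MRF energy is the negative log posterior up to the partition
constant: unary `−log max(P_y(i), ε)` with ε = 1e−6, and a
contrast-sensitive Potts pairwise term `λ·w(i,j)` on masked face-neighbor
pairs, where w is the two-channel similarity above and (σ²_T1, σ²_T2) are
the population variances of tumor-voxel intensities in the training set
(floored at 1e−6 when degenerate). Using w directly as the discontinuity
cost (rather than −log w, which diverges for equal intensities) is the
standard contrast-sensitive weight; both forms are available behind
`pairwise_form`. λ multiplies the pairwise term — the only reading under
which (α, λ) acts as a smoothness-strength pair.

Max-flow runs on `scipy.sparse.csgraph.maximum_flow` with capacities
quantized at 1e7 (int32-safe given the −log ε ≈ 13.8 unary bound); since
all pairwise costs are non-negative the energy is submodular and the
min-cut labeling is the exact global optimum up to quantization, which is
orders of magnitude below practically occurring energy gaps. The labeling
may contain several connected components by design. An exhaustive
enumeration oracle (≤ 20 voxels, lexicographic tie-break) cross-checks the
solver in the tests.

## Synthetic phantom: what it emulates, what it does not

Geometry: a spherical globe (default radius 9.5 mm, pediatric scale) with
a 2 mm sclera/cornea shell — reported clinical shell overlaps imply a
composite coat (sclera/choroid/retina) of roughly this thickness at MRI
resolution, and thinner shells make shell Dice pathologically harsh; a
lens ellipsoid embedded in the VH; an endophytic tumor as a
sphere-union blob seeded on the interior VH boundary (main sphere tangent
to the shell plus four 0.3 r bumps, clipped to the VH). Landmarks: VH
center, lens center, optic disc 15° off the posterior pole. Meshes share
one icosphere parameterization, so vertex k corresponds anatomically
across cases.

Intensities (arbitrary units 0–200, Gaussian noise sd 10 per channel):
tumor T1 (115) is deliberately close to sclera T1 (110) — both enhance
with gadolinium — while VH is T2-bright (160) and tumor T2 intermediate
(85), so the channels carry complementary information and intensity alone
does not separate tumor from the scleral coat inside the θ-band. Cohorts
jitter globe size, shell thickness, lens scale, tumor radius (1.5–6 mm,
spanning tens of voxels to >2000 voxels), tumor position on the lower
hemisphere, and a ±1.5 mm center offset. Default grid 64³ at 0.6 mm keeps
a leave-one-out experiment over 12 cases within minutes on one CPU; these
sizes are the package's study conditions, configurable for larger runs.

Not emulated: MRI physics (no k-space, no partial-volume mixing —
noise-free phantoms are exactly piecewise constant), retinal detachment,
calcification, tumor heterogeneity, inter-channel misregistration (the
channels are born aligned; the co-registration operator is exercised with
injected synthetic motion). Passing tests on phantoms therefore
demonstrate the correctness and the directional behavior of the
machinery (graph-cut refinement helps; EPSF helps; a pathological shape
model beats a healthy-trained one on pathological eyes), not clinical
accuracy levels.

## Known limitations

* The tumor-location prior is averaged over few training cases; deep in
  the globe it is near zero, and very large tumors (radius ≳ 5 mm) lose a
  little accuracy where their interior extends into low-prior territory.
  On the phantom cohort this makes the Dice-vs-size curve saturate and
  dip slightly for the largest size bin instead of increasing
  monotonically: the small-tumor penalty that dominates clinical data
  only bites below ~r = 1 mm here, which is under the cohort's smallest
  radius.
* The landmark detector is phantom-oriented (threshold + components);
  clinical use is expected to go through landmarks-by-file.
* SLIC parameters are interpreted in skimage semantics; other SLIC
  implementations scale the regularizer differently.
* The healthy-model comparison uses phantom cohorts generated from the
  same geometric distribution (tumor presence being the only difference),
  not an independent healthy-eye atlas.
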