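# oculoseg

Automatic segmentation of eye structures and ocular tumors in multi-channel
3D MRI.

Retinoblastoma is an intraocular tumor of early childhood that grows from
the retina into the vitreous humor (VH). Treatment planning and follow-up
need 3D delineations of both the healthy eye anatomy (sclera/cornea, VH,
lens) and the tumor across two MRI contrasts (a gadolinium-enhanced T1w
VIBE and a T2w sequence), a task normally done slice-by-slice by a
radiologist. `oculoseg` implements a fully automatic pipeline for this
problem, aimed at researchers in ophthalmic image analysis:

1. **Pathological active shape model (PM).** Healthy structures are
   segmented with a joint point-distribution model: corresponded landmarks
   `x = x̄ + Φ b` (Procrustes alignment + PCA, coefficients clamped at
   ±3√λₘ) with per-landmark intensity profiles sampled along surface
   normals in both channels. The model is trained on *pathological* eyes:
   tumors contribute no landmarks but their appearance enters the profile
   statistics, which makes the fit robust when a tumor sits on the VH
   boundary.
2. **Patient-specific features (EPSF).** From the fitted anatomy, each
   voxel i gets `f_i^EPSF = [f_i^l, f_i^vh, f_i^t]`: Euclidean distances
   (mm) to the lens and VH boundary voxel sets, `f^l_i = min_{b∈B_l} |i−b|`,
   plus a cross-patient tumor-location prior (cohort mean of training tumor
   masks, smoothed with a 3D Gaussian, σ = 3 mm). These complement standard
   intensity features (T1, T2, anisotropic-diffused T1, their 6-neighbor
   means, and per-slice SLIC superpixel means).
3. **Likelihood + MRF refinement.** A random forest (200 trees, all
   positive voxels, 20% of negatives) models `P(f_i | Y_i)` inside a θ-band
   around the fitted VH (θ = 2 mm). The binary labeling is refined as the
   MAP of an MRF whose pairwise prior is contrast-sensitive in both
   channels,
   `P(Y_i,Y_j) = α·exp(−ΔT1²/2σ²_T1) + (1−α)·exp(−ΔT2²/2σ²_T2)`
   (α = 0.3, smoothness weight λ = 0.7), solved exactly by min-cut/max-flow.

Because clinical retinoblastoma MRI is not publicly available, the package
ships a seeded synthetic eye-phantom generator (sclera shell, VH, lens,
endophytic tumor blob, two-channel contrast, noise, optional bias field)
that produces cohorts with ground-truth labels, landmarks and
topology-matched surface meshes, so every stage is runnable and testable
end to end.

## Worked example

Train a bundle on five phantoms and segment a held-out case:

```python
import json, oculoseg as oc

cases = oc.generate_cohort(6, seed=7)
for i, c in enumerate(cases[:5]):
    oc.save_case(c, f"cohort/case_{i:03d}")
oc.save_case(cases[5], "heldout")

oc.run_train("cohort", "bundle", oc.PipelineConfig(seed=7))
result = oc.run_segment("bundle", "heldout", "seg")
print(json.dumps(result, indent=2, sort_keys=True))
```

prints

```json
{
  "converged": true,
  "iterations": 7,
  "metrics": {
    "structure_dsc": {
      "lens": 0.7172413793103448,
      "sclera": 0.9525181514348277,
      "vh": 0.9627372212217759
    },
    "tumor_dsc_gc": 0.9192673992673993,
    "tumor_hd_mm": 2.5455845134240076,
    "tumor_msd_mm": 0.28651004008809255
  }
}
```

The shape-model fit converged in 7 iterations; the fitted sclera and VH
overlap the ground truth at Dice ≈ 0.95/0.96 (the lens, a small structure
trained from only five shapes, is lower), and the graph-cut tumor labeling
reaches Dice 0.92 with a 2.5 mm Hausdorff distance and a 0.29 mm mean
surface error against the phantom's ground truth.

The same pipeline is available from the shell:

```bash
oculoseg phantom --n 16 --seed 7 --out cohort/
oculoseg train --cohort cohort/ --out bundle/
oculoseg segment --model bundle/ --case cohort/case_000 --out seg/
oculoseg experiment --cohort cohort/ --out exp/   # LOOCV, STD vs STD+EPSF
```

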