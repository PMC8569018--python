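# embryopt

Quantitative whole-embryo phenotyping from optical projection tomography
(OPT) and confocal imaging, aimed at developmental biologists who need
unbiased, numeric readouts of embryo shape — for example to grade the
severity of patterning defects across a drug dose–response or a mutant
series in zebrafish.

The package implements the full chain:

1. **OPT reconstruction** — rotation-axis correction of the projection
   series (opposite projections at θ and θ+180° are mirrored, reduced to
   their Gaussian gradient modulus and cross-correlated; the median
   per-pair displacement, halved, is the axis offset) followed by
   slice-wise filtered back-projection (ramp filter, linear
   interpolation, 400 equally spaced angles over 360°).
2. **Segmentation** — the nuclear channel *U* is smoothed at three
   increasing scales σ₁ < σ₂ < σ₃ and combined into two normalized
   scale-sensitive difference images

   u₁ = (U_σ₁ − U_σ₂) / U_σ₂,  u₂ = (U_σ₂ − U_σ₃) / U_σ₃,

   thresholded as *w*·u₁ + (1−*w*)·u₂ > *t*; connected components inside
   a voxel-count window become embryo instances.
3. **Morphometry** — a 26-entry descriptor vector per embryo: volume,
   surface area, principal axis lengths L₁ ≥ L₂ ≥ L₃ and their ratios,
   solidity, extent, sphericity, centerline (skeleton) length and
   tortuosity, skeleton-to-surface distance statistics (mean, SD/mean,
   skewness, kurtosis), min-subtracted intensity statistics, the AP
   index (correlation of geodesic distance maps seeded at the anterior
   and posterior landmarks, which are the brightest points of the head
   and tail marker channels), the A–P chord and depth statistics.
4. **Morphospace** — descriptors are z-scored and decomposed by PCA;
   embryos are grouped into four severity clusters (hierarchical/Ward,
   k-means or k-medoids), labels ordered along PC1.
5. **Gradient profiling** — confocal nuclear stacks are segmented by
   per-section local-mean thresholding; per-nucleus intensities are
   lowess-fitted against distance from the embryonic margin and
   aggregated as mean ± SEM; domain sizes are measured as
   signal-area/embryo-area ratios on maximum-intensity projections.

A built-in phantom generator produces curved-tube embryo bodies with
known centerline, tortuosity, radius profile and marker landmarks,
severity-graded cohorts, parallel-beam sinograms with an adjustable
rotation-axis offset, and nuclear stacks with a prescribed intensity
gradient — so the whole pipeline is testable end-to-end with exact
ground truth and no data downloads.

## Worked example

```python
from embryopt.phantom import PhantomSpec, make_embryo_phantom, forward_project
from embryopt.recon import estimate_axis_shift, apply_axis_correction, reconstruct_fbp
from embryopt.segmentation import segment_embryos
from embryopt.morphometry import detect_landmarks, compute_descriptor_vector

vol, truth = make_embryo_phantom(PhantomSpec(target_tortuosity=1.3, seed=0))
sino = forward_project(vol.channel("nuclear"), n_angles=400, axis_offset_px=3)
shift = estimate_axis_shift(sino)           # -> 3.000
rec = reconstruct_fbp(apply_axis_correction(sino, shift))

inst = segment_embryos(vol.channel("nuclear"))[0]
lm = detect_landmarks(vol.channel("anterior"), vol.channel("posterior"), inst)
dv = compute_descriptor_vector(vol, inst, lm, "demo", "wt")
print(round(shift, 3), round(dv.descriptors["tortuosity"], 3),
      round(dv.descriptors["solidity"], 3))
```

prints `3.0 1.307 0.486`: the injected 3-pixel axis offset is recovered
exactly, the measured centerline tortuosity is within 1% of the
requested 1.3 (arc length / chord of the generated body), and solidity
is well below 1 because the bent tube leaves a concave gap towards its
convex hull.

The same workflow is available from the shell:

```sh
embryopt simulate --out phantom.tif --sinogram sino.tif --axis-offset 3
embryopt reconstruct sino.tif --out recon.tif
embryopt measure phantom.tif --out descriptors.csv
embryopt run-all --output-dir out --seed 1     # synthetic cohort demo
```

`run-all` generates a 4-level severity cohort (20 phantoms), segments
and measures every embryo, fits the PCA morphospace and writes
`descriptors.csv`, `morphospace_model.json`, `scores_clusters.csv` and a
run log with every effective parameter.

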