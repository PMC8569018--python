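# Methods

This note documents the models, parameter defaults and numerical choices
behind `embryopt`, and what the synthetic fixtures do and do not show
about real data.

## OPT geometry and rotation-axis correction

The forward model is parallel-beam: OPT optics are telecentric, so each
projection is treated as a set of line integrals through the sample,
acquired at equally spaced angles over a full 360° turn (400 angles by
default, matching common practice for these instruments). The sample
rotates about a vertical axis; detector rows map to the volume z axis.

If the rotation axis projects a few pixels away from the detector centre
column, back-projection smears every feature into a ring. The correction
exploits a symmetry of parallel-beam data: the projection at θ+180° is
the left–right mirror of the projection at θ, displaced by **twice** the
axis offset. The estimator therefore

1. picks `n_pairs` (default 16) opposite-side pairs spread evenly over
   the series;
2. mirrors the second member and reduces both images to their Gaussian
   gradient modulus (σ = 30 µm, converted to pixels via the detector
   pixel size — about 3 px at typical sampling), which makes the
   registration signal independent of global intensity scale;
3. cross-correlates the pair (plain, un-centred correlation: the
   gradient modulus has zero background, so the peak is not diluted by
   window-edge effects; mean-subtracted correlation measurably biases
   the argmax on smooth images);
4. takes the column displacement at the argmax, restricted to
   ±width/4 and to near-zero row lag (the offset is purely horizontal),
   with optional 3-point parabolic sub-pixel refinement (default on);
5. returns the median over pairs, divided by two.

The halving in step 5 matters: the per-pair displacement is 2× the
offset. The median makes single corrupted pairs harmless. Positive shift
means the axis sits right of the detector centre column; correction
translates every projection by −shift with edge-value fill.

Reconstruction is slice-by-slice filtered back-projection with the
standard ramp (Ram–Lak) filter and linear interpolation, keeping all
360° of angles (opposite angles average, which also averages residual
asymmetries). Negative ringing values are retained; binarization is left
to the segmentation stage. Volumes default to 6.5 µm isotropic voxels.

## Two-scale segmentation

The nuclear channel U smoothed at σ₁ < σ₂ < σ₃ yields

    u1 = (U_σ1 − U_σ2) / max(U_σ2, ε)
    u2 = (U_σ2 − U_σ3) / max(U_σ3, ε)
    body = w·u1 + (1 − w)·u2 > t

u₁ responds to structure between σ₁ and σ₂ (nuclear texture), u₂ to
structure between σ₂ and σ₃ (the embryo body against background); the
normalization makes both ratios invariant to global intensity scale.
Defaults: σ = 6.5/19.5/58.5 µm (1/3/9 voxels at the rendering
resolution), w = 0.7, t = 0.5, calibrated once on the default phantom
body (IoU 0.97 against ground truth) and held constant across samples.
Scales comparable to or larger than the body radius are a poor choice:
they smear the body into a halo several times its volume.

The ε guard defaults to 1% of the volume maximum. This is deliberately
far above floating-point noise: with any background noise present, a
near-zero smoothed denominator would otherwise amplify tiny differences
into huge spurious u-values and the threshold would pick up large
background components. Connected components use 26-connectivity;
instances must fall inside a [min_size, max_size] voxel window (default
10³–10⁷) and are returned largest-first. Marker channels are never used
for segmentation.

## Morphometry

**Landmarks.** Anterior/posterior anchors are the brightest voxels of
the head/tail marker channels within a 5-voxel dilation of the mask,
ties broken at the lowest linear (z, y, x) index.

**Centerline.** The centerline is the minimum-cost path through the
mask between the near-medial voxels closest to the two landmarks, with
each 26-neighbour step weighted by its Euclidean length divided by the
squared Euclidean distance transform (EDT). The 1/EDT² penalty makes the
optimal path run along the ridge of the distance transform — the medial
axis — and prunes side branches automatically, and it is robust on
perfectly symmetric bodies where iterative thinning degenerates. Anchor
candidates are restricted to voxels at least 50% of the maximum depth,
so a quasi-spherical mask collapses centrally instead of spanning its
diameter; the path of an elongated body consequently stops about one
radius short of its end caps. Path coordinates are smoothed with a
7-voxel moving average (endpoints pinned) before measuring length,
which removes voxel-staircase inflation; on analytic bodies the
straight tube then measures tortuosity 1.000 and a semicircular tube
1.56 (π/2 = 1.571).

**Descriptors** (26, per embryo): voxel and physical volume; surface
area by exposed-face counting divided by the standard 1.5 isotropic
correction; equivalent-ellipsoid full axis lengths L₁ ≥ L₂ ≥ L₃ from
4·√eigenvalue of the voxel-coordinate covariance (only the ratios are
used downstream, so the constant is inert) and the three ratios;
solidity = voxel count over convex-hull voxel count (hull of voxel
centres, so a convex digitized body scores exactly 1); extent
(bounding-box fill); sphericity; centerline length and tortuosity
(length / endpoint chord); mean, SD/mean, sample skewness and excess
kurtosis of the centerline-to-surface distances, excluding path voxels
closer to a path end than their own surface distance (there the nearest
surface is the end cap, not the lateral wall, and would contaminate the
local-radius distribution); the same four statistics of in-mask
intensity after subtracting the in-mask minimum; the AP index; the A–P
landmark chord; and mean/max mask depth. Sample statistics use the
bias-corrected (n−1) formulas. A constant sample reports spread 0 and
its higher moments as NaN (the designated missing value); the
morphospace fit drops such rows with a warning.

**AP index.** Two distance maps are seeded at the anterior and
posterior landmarks (snapped to the nearest mask voxel if ≤ 3 voxels
outside) and their Pearson correlation over all mask voxels is
returned. Distances are geodesic within the mask by default —
26-neighbour shortest paths with Euclidean step weights, computed with
Dijkstra on a sparse adjacency — because an embryo is a curved body and
within-body distance is the biologically meaningful one; an ambient
Euclidean variant is available. For a straight body dₐ + dₚ is constant
along the axis and the index is −1; it rises as the body folds.

## Morphospace and severity clustering

Selected descriptors are z-scored (ddof = 1, the `prcomp(scale.=TRUE)`
convention) and decomposed by SVD. Variance explained per component is
the corresponding squared singular value over their sum (equivalently,
eigenvalues of the feature correlation matrix over the feature count);
per-variable contributions to PC1/PC2 are squared loadings normalized
to 100% per component. Zero-variance features are an error (they carry
no information and break scaling). Projection of new cohorts applies
the stored means/scales/loadings, so a fit-on-reference /
project-mutants workflow is supported alongside pooled fits.

Clustering operates on the scaled descriptors by default (PC-score
space is a flag) with k fixed at 4, reflecting the
unperturbed/slightly/moderately/heavily-perturbed severity reading of
dose–response cohorts. Methods: Ward/Euclidean hierarchical (the
default; deterministic and row-order invariant), seeded k-means, and an
exact-swap PAM k-medoids (implemented in-package; cohort sizes here are
tens of embryos, where exact PAM is instant). Labels are renumbered
1..k by ascending mean PC1 score so they order along the dominant
severity axis; note PC1's sign, hence the direction of that ordering,
is arbitrary as in any PCA.

## Gradient profiling

Nuclei are segmented per optical section by an adaptive local-mean
threshold (pixel > windowed mean + offset; radius default 8 px, offset
default 1% of the stack maximum — zero offset lets each nucleus' own
Gaussian tail cross its windowed mean and produces halo artefacts,
while large absolute offsets drop legitimately dim far-margin nuclei
under a steep gradient), refined by one 3×3 erosion and dilation,
labelled in 3D across sections, and size-filtered (default ≥ 30
voxels). An optional per-section exclusion region removes
extraembryonic (YSL) nuclei. Per nucleus the centroid, voxel count,
per-channel mean intensity and the distance of the centroid from a
configured margin plane (clamped at 0) are recorded.

Per-embryo intensity-versus-distance profiles are lowess fits evaluated
on a shared distance grid; the group curve is the pointwise mean ± SEM
across embryos. The smoothing span defaults to 0.3 and should be
lowered (≈ 0.2) for dense, low-noise data: the span trades variance
against curvature bias, and on a noiseless exponential with 200 nuclei
the bias is ~6% at 0.3 versus ~4% at 0.2. Domain sizes are
signal-area/embryo-area ratios on maximum-intensity projections, both
regions Otsu-thresholded (the signal within the embryo region) — a
reproducible replacement for manual polygon tracing.

## The phantom generator

Phantom embryos are tubes built as a union of spheres along a
Catmull–Rom spline, which guarantees an analytically known centerline
for skeleton and tortuosity ground truth. By default the centerline is
a planar circular arc whose arc/chord ratio equals the requested
tortuosity (solved from τ = θ / 2·sin(θ/2)), spanning 72% of the volume
x-extent inside a (48, 72, 96)-voxel grid at 6.5 µm/voxel with a 42 µm
tube radius. Channel 0 fills the tube at intensity 100 (arbitrary
units); channels 1/2 are Gaussian marker spots (σ = 20 µm) at the
centerline endpoints, emulating head/tail expression landmarks.
Gaussian noise is additive. Forward projection rotates the padded
volume per angle (linear interpolation) and sums along the beam, which
conserves total intensity per angle to <1%; the axis offset is applied
as a detector-column shift after projection.

Severity cohorts grade four knobs monotonically with dose level:
tortuosity mean/SD, sinusoidal thickness modulation, body-length
scaling, and a mid-body radius pinch that lowers solidity. The default
4-level cohort (tortuosity means 1.03/1.18/1.38/1.62, lengths scaled
1.0→0.70, pinch 0→0.45, noise σ = 2 on intensity 100) represents a
strong, well-separated dose–response; all bodies taper head-to-tail
(radius ×1.12→×0.82), as real embryos do — a perfectly constant-radius
body is degenerate for radius-distribution statistics. Confocal
fixtures place Gaussian-blob nuclei (σ = 2 voxels) with ≥ 2-diameter
separation and set each peak intensity from a supplied decay function
of margin distance.

What the phantoms do **not** emulate: optical scattering and
attenuation, yolk autofluorescence, nuclear texture inside the body,
touching embryos, and anisotropic confocal sampling. Passing tests
therefore demonstrate correctness of the algorithms under the stated
geometry and noise model, not robustness to every imaging artefact;
the segmentation weight/threshold in particular will need per-study
calibration on real data, as is usual.

## Problem sizes and determinism

Default test and acceptance runs use 48–104-voxel phantom grids, 400
projection angles for reconstruction fidelity (64 for axis round-trip
checks, where the angle count is not the quantity under test), a
20-phantom cohort, and 50–200-nucleus stacks — sizes chosen so the full
suite runs in a couple of minutes on one CPU while every estimate stays
comfortably inside its tolerance. All generators are pure functions of
(spec, seed); re-running a pipeline with the same configuration and
seed reproduces byte-identical CSV/JSON artifacts.

## Known limitations

- Parallel-beam only; no cone-beam, iterative reconstruction or
  flat-field handling.
- The centerline stops ~1 radius short of flat end caps (see above);
  tortuosity and radius statistics are unaffected by construction.
- The 26-descriptor set reconstructs the named descriptor families
  (axis ratios, tortuosity, solidity, skeleton-distance and intensity
  statistics, AP index) plus standard shape fillers; an exact match to
  any particular instrument pipeline's descriptor list would require
  that pipeline's definitions.
- k is fixed at 4; no automatic model selection.
- Lowess span and nuclei-threshold offset are study-level knobs with
  documented defaults, not auto-tuned.
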