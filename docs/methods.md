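# Methods

This note documents the models, conventions and numerical choices behind
`sama3d`, in the spirit of a methods section: what each stage assumes, which
parameters matter, and what the validation phantoms do and do not establish.

## Image model and preprocessing (Tier 1)

The input is a single-channel z-stack of non-negative intensities with an
anisotropic voxel spacing (dz, dy, dx). Two acquisition artifacts are
modeled explicitly:

* **Local background** — slowly varying offset per slice. Estimated by a
  per-slice grayscale opening (minimum- then maximum-filter) with a square
  window of side `2·background_radius + 1` (default radius 32 voxels) and
  subtracted. The window must exceed the structures' diameter, otherwise
  they are flattened into the background estimate.
* **Depth attenuation** — luminosity decays with distance from the
  objective. Compensated by per-slice gains: the robust slice maximum
  (99.9th percentile by default; the exact maximum is configurable) is
  averaged over the three-slice window {i−1, i, i+1} (truncated at stack
  ends), and each slice is scaled to the brightest window value. Gains are
  capped at 10× so near-empty slices are not amplified into noise. On a
  uniformly lit stack all gains are exactly 1; under geometric decay the
  interior slices equalize exactly and the two end slices retain a small
  truncation bias of about ±(1−d)/2.

Between those two stages sit a 3D median filter (default radius 1, i.e. a
3³ box — the smallest neighborhood that removes single-voxel noise while
preserving cavities only ~2 voxels in radius; larger radii are available
but erase small lumena), optional minimum/maximum/variance filters
(disabled by default), and a separable Gaussian blur whose sigma (default
1) is specified in physical units and converted per axis through the
spacing. Rank filters use cubic-box neighborhoods, not balls — faster, and
the small difference is absorbed by the configurable radii. An optional
pluggable denoise hook replaces heavier external denoising tools.

For crowded images an optional *gradient separation* stage subtracts the
radius-1 morphological gradient (max − min) from the image: edges are
eroded, dim single-voxel bridges between touching structures disappear,
deep interiors are untouched. It is off by default since it slightly
shrinks all objects.

Tier 1 ends with a threshold (Otsu by default, a fixed value optionally).
The *morphometrics branch* applies per-slice hole filling to the binary
mask — structures are measured filled, so a lumen does not perturb volume
or moments — while the *lumen branch* keeps interior darkness intact.
Per-slice (2D) filling is the default; a cavity that opens at the top or
bottom slice still closes in-plane, which pure-3D filling (available via
config) would not do.

## Shape descriptors

Measured per 26-connected component (components under `min_voxels = 64`
are discarded as debris):

* **Volume** V = voxel count × voxel volume.
* **Principal semi-axes** from the eigen-decomposition of the spacing-aware
  second-moment matrix of voxel centers, with the within-voxel uniform
  variance (spacing²/12 per axis) added to the diagonal — voxels are cubes,
  not points, and omitting this term biases the shortest axis of thin
  objects several percent low. Semi-axis_k = sqrt(5 λ_k), the
  moment-matched solid ellipsoid. Ties in the eigenvalue order give axis
  ratios of exactly 1.
* **Elongation / flatness** Elon1 = long/middle, Elon2 = middle/short.
* **Surface area** from a marching-cubes isosurface of the mask, smoothed
  with a 0.8-voxel Gaussian and contoured at 0.5. Voxel-face counting would
  overestimate the area of a sphere by ~50% and break the sphericity anchor;
  with this estimator a rasterized radius-10 sphere gives S = 1.01.
* **Sphericity** S = ((36 π V²)/A³)^(1/3).
* **RVE** = V / ((4/3) π L M S): ≈ 1 for convex ellipsoidal structures
  (0.99 for rasterized test ellipsoids), decreasing toward 0 with branching.
* **Quality** Q = Elon1 − Elon2 + 5·RLV: positive for elongated,
  lumen-bearing structures; negative for flat ones.

RLV is defined lumen/structure (∈ [0, 1)); the reciprocal convention is
exported as a derived column `rlv_inverse` for compatibility.

## Lumen segmentation

A lumen is an enclosed region darker than its surrounding shell. Candidate
voxels are (hole-filled structure mask) minus (lumen-branch image above the
lumen threshold); candidates are labeled 26-connected, components smaller
than `min_lumen_voxels = 27` are dropped, and — implementing "enclosed" —
components adjacent to the *outside* of the filled mask are rejected (dim
rinds at structure boundaries are open, not holes). Each lumen is assigned
to the structure whose filled mask contains its centroid, with a
majority-overlap fallback; unassignable lumena are flagged and excluded.

The lumen threshold is inherently a per-image choice (it depends on
staining and imaging); the automated default `interior-otsu` mimics what a
user does — it runs Otsu on the eroded structure interiors only, so the
threshold separates cavity from shell rather than background from
foreground. A global-Otsu option and explicit numeric thresholds (per
image or per experiment) are available.

## Skeletons and complexity

Each filled structure mask is thinned to a unit-width skeleton
(topology-preserving 3D thinning; if thinning annihilates a blob-like
component the voxel nearest its centroid is kept, so every structure has a
skeleton). Voxels are classified by 26-neighbor count — 1 endpoint,
2 path, ≥3 junction (adjacent junction voxels merge into one node) — and
branches are the maximal paths between nodes. Branch length sums true
Euclidean steps under the voxel spacing (diagonals count √2 or √3 × 
spacing), so doubling the spacing doubles the cumulated length C exactly.
Conventions: an unbranched duct is 1 branch; an isolated voxel is one
zero-length branch; a cycle contributes one branch of its perimeter.

Two cleanups counter discretization artifacts: terminal spurs shorter than
`prune_length = 2` voxels are removed iteratively, and junction clusters
with exactly two incident branches (a surface bump diagonal to a straight
chain would otherwise split one duct into two branches) are thinned to
their shortest internal path. With both, a rasterized solid ellipsoid
reports exactly one branch.

## Statistics

The experimental unit for hypothesis tests is the **per-stack mean** (each
stack is one replicate); pooling individual structures is available but is
pseudo-replication and flagged as such. For each parameter: one-way ANOVA
across conditions and, when exactly two conditions are present, a
two-sided Wilcoxon rank-sum test — exact by enumeration of the full
rank-sum permutation distribution (dynamic programming over midranks) for
group sizes ≤ 10, a tie-corrected normal approximation beyond. The
**reported p-value is the larger** of the two: a deliberately conservative
convention. With 6 stacks per condition the exact Wilcoxon floor is
2/924 ≈ 0.00216. Two-sided throughout; no multiple-testing correction by
default (per-parameter reporting), with Benjamini–Hochberg available as an
opt-in column.

PCA uses the correlation matrix (variables standardized, ddof = 1);
zero-variance variables are dropped with a warning, rows with missing
values excluded with a logged count. Reproducibility curves are Gaussian
KDEs per replicate with a single Silverman rule-of-thumb bandwidth
computed on the pooled sample, so curve shapes are directly comparable;
superimposition is quantified by the pairwise two-sample
Kolmogorov–Smirnov distance (0 = identical).

## Validation phantoms

The phantom module renders what the statistics are validated against:
40 prolate ellipsoids per 64×256×256 stack, placed by rejection sampling
with ≥ 2 voxels clearance and fully interior to the grid, uniformly random
orientation, shell intensity 200 on background 20 (8-bit-like scale),
lumen intensity equal to the background (a dark hole, not a void). Sizes:
two minor semi-axes uniform in [5, 7] voxels and a major semi-axis uniform
in [14, 20] — duct-like shapes, deliberately: a thinning skeleton only
retains an arm whose protrusion exceeds its half-thickness, so
near-spherical phantoms would make branching undetectable *by
construction*, and real epithelial ducts are elongated. Lumena are
concentric scaled copies with a single fraction uniform in [0.5, 0.6] of
the parent semi-axes, which keeps the thinnest cavity ≥ 2.5 voxels
(survives the 1-voxel blur) and the thinnest shell wall ≥ 2 voxels (does
not leak at the lumen threshold). These defaults were fixed once from
those geometric constraints.

Conditions: C1 reference (every structure hollow); C2 doubles the major
axis's sampling maximum; C3 halves the lumen probability; C4 replaces each
ellipsoid by two sharing a center, the second's orientation rotated 90°
about a random axis perpendicular to the first's long axis (the lumen sits
in the first ellipsoid — the pair shares a center, so two would merge).
Stacks are clean by default; depth attenuation (multiplicative per-slice
decay) and additive Gaussian noise are available as opt-in artifacts so
the compensation and denoising stages can be exercised.

What a green validation establishes: the pipeline recovers the generated
structure count exactly, detects essentially all lumena in the reference
condition, and separates all four designed contrasts at the 6-vs-6
Wilcoxon floor or better. What it does not establish: performance on real
confocal data — phantoms have no point-spread-function blur, no spectral
crosstalk, no tiling seams, no touching structures (enforced clearance),
and piecewise-constant intensities. Detection is not perfect even here:
in C3 roughly 90% of true lumena are found (the adaptive interior-otsu
threshold occasionally loses the smallest cavities), so the detected lumen
fraction slightly underestimates the generated probability.

## Degenerate inputs and edge handling

Filters use reflective boundaries. Labels with fewer than 4 voxels raise a
degenerate-moments error (excluded by the default size filter). An empty
threshold result is a warning, not an error. All-zero slices get the
capped depth gain. Structures touching the stack border are kept by
default (`exclude_border` available). Identical constant groups compare
with p = 1. Every stage preserves grid shape, spacing metadata and the
declared intensity range; all randomness flows from explicit seeds, and
rerunning any stage on the same inputs is bit-identical.
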