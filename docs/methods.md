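# Methods

## Scope and model

`bspim` implements the computational core of biospeckle selective plane
illumination microscopy: converting per-position time-lapse speckle stacks
into 3D activity volumes, counting live nematodes in them, and quantifying
contrast against brightfield. Because no public image data exist for this
kind of acquisition, the package ships a first-class simulator whose output
has the statistical structure the analysis responds to, with exact ground
truth. Everything downstream (GD, filtering, counting, regression) operates
identically on simulated and real scan directories.

## Coherent speckle simulation

Fully developed polarized speckle at a sensor pixel is a circular complex
Gaussian amplitude; its intensity is exponential with speckle contrast
σ/⟨I⟩ = 1. We simulate the amplitude directly and evolve it in time as a
per-pixel stationary AR(1) process

    E(t+1) = ρ E(t) + sqrt(1 − ρ²) η(t),

with η fresh circular complex Gaussian noise. This reproduces exactly the
two properties the GD index measures — a stationary exponential intensity
marginal and a tunable temporal decorrelation (lag-k field autocorrelation
ρ^k) — at a small fraction of the cost of wave-optics propagation, which is
why AR(1) surrogates are standard in dynamic-speckle method development. A
finite speckle grain (default 2 px) is imposed by Gaussian low-pass
filtering the amplitude and renormalizing the variance; per-pixel marginals
remain circular Gaussian.

Scene content enters through two static per-position maps:

* **ρ map** — background `ρ_bg = 1` (static medium); live nematodes set
  ρ = 0.5 inside their footprint. The decorrelating region extends 60 µm
  (`activity_halo_um`) beyond the anatomical capsule: the field at a pixel
  sums scattered contributions from a neighbourhood on the scale of the
  speckle grain and of the medium disturbed by the moving body, so
  activity reaches somewhat past the outline. Dead animals keep ρ_bg — the
  modelling of heat-killed worms as temporally indistinguishable from
  background.
* **brightness map** — static scattering strength. Live bodies scatter
  2.5× background, dead ones 1.6× (visible in brightfield, silent in GD).
  Heterogeneous media ("soil") add a log-normal smooth brightness field
  (default log-sd 0.6, 300 µm correlation length) plus bright static
  grains (~40 glints per section, up to ~9× background, some saturating) —
  all temporally constant, which is precisely why the GD stage can reject
  them. Roots are cylinders driven above the sensor maximum every frame,
  reproducing the deliberate over-exposure trick that blots out root
  biospeckle; saturated pixels are temporally constant at full scale.

Frames are `I = exposure · brightness · |E|²` plus Gaussian read noise
(default σ = 1 DN — small but nonzero so 8-bit rescaling of pure-background
volumes is never degenerate), clipped and quantized to the sensor bit depth
(8 by default). The default `exposure_scale = 30` DN keeps the exponential
intensity tail mostly below full well.

Geometry: the sheet at position k spans the half-open slab
`[k·Δz − t/2, k·Δz + t/2)`; with the 1 mm detection sheet and Δz = 125 µm a
point-like animal appears in exactly 8 consecutive stacks, and the 3D
26-connectivity of the counter merges that footprint into one object.
Successive positions are 6.8 s apart (6.4 s acquisition + 0.4 s settle),
far beyond a live animal's decorrelation time, so fields at different
positions are drawn independently (the stationary limit). Animal motion
*between* positions is not modelled: centroids are fixed so ground-truth
counts are exact.

## Scene layout

`make_scene` places capsules by rejection sampling. Defaults: length
U(300, 1200) µm, width U(20, 30) µm — the mid-range of the 40–1500 µm FLN
envelope; bodies much below ~150 µm would be sub-resolution at the cuvette
sampling of ~39 µm/px, which mirrors the real acquisition's preference for
thick overlapping sheets so small animals are not missed. Orientations are
in-plane. Two animals must either be ≥ 500 µm apart in-plane or ≥ 1400 µm
apart in depth; the in-plane floor (~6 smoothing sigmas) keeps smoothed
blobs separable and the depth floor accounts for the ±500 µm z-smearing of
the 1 mm sheet plus smoothing margin. This keeps the mapping from scene to
expected count exact, which is what a count-recovery experiment needs from
its ground truth; a failed layout raises a `PlacementError` naming the
violated constraint.

## GD computation

Default is the **all-pairs** sum over every unordered frame pair, the
literal reading of the double sum as the total variation within a stack; a
`max_lag` variant covers lag-limited usage. For 8-bit stacks the all-pairs
sum is computed by a counting identity — Σ_{i<j}|x_i−x_j| = Σ_t L_t(N−L_t)
with L_t the count of samples ≤ t — in a numba kernel; other dtypes use the
equivalent sorted-order-statistic form Σ_k (2k−N+1)·x_(k). Both paths are
exact integer arithmetic accumulated in 64-bit (no overflow at N = 64,
8-bit input; the maximum possible sum is 1024·255 ≈ 2.6×10⁵) and are tested
against a brute-force double loop. GD is not normalized by pair count by
default (raw sum); an optional normalized mode supports cross-N comparison.

## Detection pipeline

Order: GD volume → global min–max 8-bit rescale (half-up rounding;
constant volumes map to 0) → per-slice 2D boxcar subtraction (radius 2 mm,
window forced odd and ≥ 3 px, reflect padding, negatives clipped) → 3D
Gaussian σ = 80 µm converted per axis to voxel units (anisotropic voxels:
5 px in-plane at 16 µm/px, 0.64 voxels along a 125 µm z-step) → threshold
≥ 40 → 3D connected components at 26-connectivity → discard components
< 50 voxels. Choices made where the procedure was open:

* 8-bit conversion is global over the volume, not per-slice, so per-slice
  contrast stretching cannot fabricate z-structure.
* The boxcar runs in 2D per slice: long-range variation is an in-plane
  illumination effect, and the filter's z-extent would anyway be marginal
  at 125 µm steps.
* "Voxel size 50" is a minimum component voxel *count*, the size filter of
  3D object counters, not a µm³ volume.
* Connectivity 26 is the common object-counter default and is required for
  the overlapping-sheet footprint of one animal to merge. It is
  configurable (6/18/26).
* Filtered volumes stay in float on the 0–255 scale rather than being
  re-quantized between stages; thresholds behave identically and no
  precision is lost.
* Centroids are unweighted means of member voxel centres, reported in µm
  with voxel index 0 at the origin.

## Transect S/N

`SN = (I_s − ⟨I⟩)/σ` with the sample (n−1) standard deviation. By default
⟨I⟩ and σ are computed over the *whole* profile, signal included — the
literal reading of the definition, and the contract of
`signal_to_noise(...)`. For brightfield-vs-GD comparisons the package uses
the background-window convention instead (`exclude_halfwidth`): samples
within the object window are excluded from ⟨I⟩ and σ, as in MRI-style S/N
measurement where noise is estimated from object-free background. The
reason is arithmetic, not taste: if a dominant object is included, then
σ² ≥ (I_s − ⟨I⟩)²/n, which caps SN at ~√n (≈16 for a 256-sample profile) no
matter how strong the contrast — S/N values in the hundreds on short
profiles are only possible with background-estimated noise, so that is the
convention any such measurement must have used. The object's `I_s` is the
brightest sample in its window, as an operator reading a line profile
reports it.

## Evaluation experiments

**Count recovery.** Insertion levels (0, 4, 8, 12, 16, 20) — six levels
spanning the 0–20 animals-per-cuvette design — with 3 replicates in the
clean medium and 5 in soil. Each cell simulates a full scan (256² px
≈ 39 µm/px over the 1 cm cuvette, 80 positions × 64 frames) and runs
detection with default parameters. The reduced image scale and six-level
sweep keep a full sweep at a few minutes on one CPU while preserving the
stated acquisition protocol (frames, positions, sheet, step) and the full
count range. `summarize_recovery` reports both per-replicate and per-mean
regressions (recovery plots show means with SD bars, so the per-mean R² is
the comparable one) plus Spearman rank correlation; the Spearman p-value is
an exact permutation value for ≤ 10 points, t-approximate otherwise. A
through-origin OLS mode is provided alongside the free-intercept default.

**S/N comparison.** Eight single-nematode, single-position scenes with the
static clutter log-sd swept over 0.3–1.2 and increasing glint counts. The
same full-width transect through the animal's centroid row is read from a
mid-stack raw frame and from the GD map; folds are SN_GD/SN_BF per scene,
with non-positive brightfield S/N pairs excluded as undefined.

## Numerical and degenerate-input choices

* All randomness flows through `numpy.random.Generator` seeded per scan
  from a `SeedSequence`; identical (scene, acquisition, seed) triples give
  bit-identical arrays, and clutter fields are seeded from the *scene* so a
  sample keeps its static structure across re-scans.
* `evolve_field` draws noise only over the bounding box of the
  decorrelating region; ρ = 1 pixels are returned untouched (the update is
  exactly identity there), making large static backgrounds cheap.
* Zero-variance transects raise `ZeroVarianceError` rather than returning
  infinities; constant detected counts yield R² = 0 and an undefined
  Spearman rho (NaN).
* GD volumes with a single position are depth-1 volumes equal to the
  stack's GD map; non-uniform z spacing is rejected.

## What the simulator does and does not show

Passing tests demonstrate that the pipeline recovers counts, rejects
static clutter and dead animals, and gains S/N exactly as designed *under
the model's assumptions*: AR(1) temporal statistics, static backgrounds,
non-moving animals, no optical PSF, no polarization effects, no multiple
scattering, no photobleaching, and sheet selection as a hard slab rather
than a Gaussian axial profile. Real microcosms add animal locomotion
between positions (double counting or misses), partially developed speckle,
depth-dependent attenuation and root growth — none of which are claimed
here. The simulator is a correctness harness and surrogate benchmark, not
a forward model of any particular instrument.
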