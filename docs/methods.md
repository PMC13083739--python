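# Methods

## Coordinate and transform conventions

All volumes live on axis-aligned regular grids in RAS millimetres; the
world position of voxel `(i, j, k)` is `origin + (i, j, k) · spacing`.
A rigid transform is three extrinsic rotations about the world axes
(applied `Rz · Ry · Rx`, angles in degrees), a translation in mm and an
explicit rotation centre: `p ↦ R (p − c) + c + t`. The centre defaults
to the phantom's brain centre (not the grid centre) because the probe
points that summarise motion are defined relative to the brain centre.
Transforms map reference-space coordinates into frame space, so the
reference frame's transform is the identity and correcting frame *f*
means resampling it *through* `T_f` (pull-back). Oblique or sheared
grids and non-rigid deformation are out of scope; NIfTI files with
non-diagonal affines are rejected on load rather than reoriented.

Resampling (`geometry.resample`) is trilinear or nearest-neighbour with
zero fill outside the field of view. Two trilinear passes (simulate a
moved frame, then correct it) cost roughly 5–10 % relative RMS on this
sharply textured phantom; tests that use round-trip oracles state that
tolerance explicitly.

## Synthetic phantom and frame simulator

The phantom is procedural geometry, not an atlas: a brain ellipsoid
whose outer 22 % (radially, perturbed by a seeded smooth random field to
imitate cortical folding) is a gray-matter shell split into frontal /
parietal / temporal / occipital sectors by dominant direction, plus a
cerebellar lobe, paired thalamic / striatal / hippocampal nuclei,
ventricle-like voids, and white matter filling the interior. Every named
ROI (WB, CER, FC, HIP, OC, PC, STR, TC, THA, GM, WM) holds at least 50
voxels at the default 40³–48³ grids. Composite ROIs are label unions
(GM = all gray structures, WB = everything labeled).

Two contrast regimes:

* `fdg_like` — cortex 1.0, nuclei 0.8–0.95, white matter 0.32
  (GM/WM mean ratio ≈ 3, typical of FDG), ventricles 0.08, plus an 8 %
  smooth multiplicative texture that gives registration something to
  grip.
* `met_like` — the same geometry with square-root-compressed contrast,
  rescaled to half the FDG global mean. The compression mimics the flat
  gray/white contrast of amino-acid tracers (GM/WM ≈ 1.8); the factor
  0.5 is a package choice, made once, in the absence of a standard
  reference value for the MET-to-FDG count-rate ratio. At matched counts per
  frame this regime has a lower gray-matter share of total activity and
  therefore lower per-voxel SNR, which is the property the tests rely
  on.

Motion trajectories are built from declarative specs: `static`, `drift`
(6-DOF parameters linear in frame mid-time, full amplitude at scan end),
`step` (identity before an event time, constant after), `jitter`
(zero-mean seeded Gaussian per-frame perturbations) and `composite`
(drift + step). The transform at the reference frame is exactly the
identity; when jitter makes the raw reference non-trivial the whole
trajectory is re-referenced by composing with its inverse.

Each simulated frame is the motion-displaced activity (sampled through
the inverse transform), blurred with an isotropic Gaussian PSF (default
5 mm FWHM, the typical clinical PET resolution), scaled so the expected
total is `counts_per_frame` (default 5 × 10⁵ — constant counts per
frame, matching count-matched short-frame reconstruction practice), then
Poisson-drawn per voxel. Frames default to constant 30 s durations;
duration weighting is exercised separately through the integration and
cDTH code paths. No attenuation, scatter, randoms, decay or projection
physics is modelled: noise is applied in image space as a deliberate
surrogate for count statistics. Tracer distribution is assumed static
within the scan.

What passing tests on this phantom do **not** show: performance on real
anatomy (no realistic cortical topology), on reconstruction artefacts
(no sinogram model), or on intra-frame motion, which an inter-frame
method cannot recover by construction.

## Motion estimation

Each frame is registered to the reference frame by maximising the
zero-mean normalized cross-correlation over the six rigid parameters
with a derivative-free Powell search (parameter tolerance 0.001
mm/degree, bounded iterations), on a coarse-to-fine pyramid (default two
levels: 2× decimated after anti-alias smoothing, then native grid) and
with a temporal warm start — each frame is initialised from its
neighbour's estimate, moving outward from the reference. Frames are
pre-smoothed at 6 mm FWHM (configurable) to stabilise low-count data.
The similarity is evaluated where the smoothed reference exceeds 5 % of
its maximum.

Internally the moving frame is sampled with cubic B-splines (prefiltered
once per frame per level): with trilinear sampling the similarity
optimum is biased by a few tenths of a millimetre at the 70 mm probe
radius; cubic sampling reduces recovery error to below 0.1 mm at zero
noise. Frames without signal are returned as identity and flagged
unreliable. The estimator never modifies its input and is fully
deterministic.

Measured on the synthetic phantom (40³ × 3.5 mm): zero-noise drift/step
trajectories up to 6 mm probe displacement are recovered with < 0.13 mm
maximum probe error; a 5 mm drift at 5 × 10⁵ counts/frame with Poisson
noise is recovered with ≈ 0.2 mm median probe error.

## Motion correction and integration

Correction resamples each frame through its transform into reference
space (trilinear); static images are duration-weighted voxelwise means.
This image-space inter-frame correction is an explicit stand-in for
incorporating the estimates into a list-mode reconstruction: it cannot
recover intra-frame motion and it pays one interpolation pass per frame.
That interpolation cost matters for interpreting region-level effects —
see the caveat below.

## Motion metrics

Displacement, categorisation and cDTH are computed exactly as defined in
the README. Numerical choices:

* The middle category is the closed interval `[1 mm, 2 mm]`: the outer
  inequalities ("< 1 mm" low, "> 2 mm" high) are strict, so medians of
  exactly 1 or 2 mm are *medium*.
* The median is over frames, unweighted by duration (estimation frames
  carry near-constant counts, not constant duration); a
  duration-weighted variant sits behind a flag.
* The anterior axis is +y of RAS; displacement is the 3-D Euclidean
  norm.
* cDTH uses non-strict `≤` at thresholds, 0.1 mm bins from zero to the
  maximum displacement rounded up; fractions are duration-weighted.
  `cdth_fraction` evaluates the exact fraction at an arbitrary
  threshold.

A single reference frame is used for both categorisation and the cDTH;
with one reference these two summaries are mutually consistent (at equal
durations the cDTH at the deciding median is always ≥ 0.5).

## XC evaluation

Gaussian sizes are FWHM (σ = FWHM/2.3548) with kernels truncated at 4 σ
and renormalised at the volume edges, so border voxels are not biased
toward zero. The brain mask thresholds the *filtered* reference at 30 %
of the *filtered* maximum. Both volumes are filtered over the full grid
first; the correlation sums are then restricted to the mask. The
zero-mean (Pearson) form is used throughout — it is the only form whose
anchors (1 for identical volumes up to affine intensity change, 0 for
uncorrelated, −1 for anticorrelated) survive background offsets. The
median XC summary excludes the reference frame, whose value is 1 by
construction.

## ROI statistics

Relative differences are `(ddMC − noMC)/ddMC × 100 %` of ROI means;
ROIs with zero ddMC mean are reported missing. Group summaries use
linear-interpolation quartiles (the convention is stated because several
exist). The Mann–Whitney U test is exact by full enumeration of group
labelings (midrank ties; two-sided p as the doubled smaller tail, capped
at 1) up to a combined n of 20, and a tie-corrected normal approximation
with continuity correction beyond; the method used is recorded in the
result. Bonferroni significance is `p < α/m` with `m` defaulting to the
11-ROI family. Registration QC passes iff the Euclidean difference of
two displacement vectors is ≤ 1 mm, boundary inclusive.

## Direction of correction effects — and a caveat

For translation-dominant motion of a few millimetres the evaluation
reproduces the expected clinical directions: correction raises the
median XC, cortical ROIs gain signal (positive relative difference) and
white matter loses it (negative), because motion mixes hot cortical
signal into neighbouring tissue and correction undoes that mixing.

For *pure rotations about the brain centre* the image-space surrogate
inverts those signs: the cortical shell maps approximately onto itself
under such rotations (little real blurring in the uncorrected image)
while the corrected image still pays one trilinear interpolation pass
per frame. A list-mode implementation would not pay that cost. The
seeded direction fixtures therefore use translation-dominant drift
(4.5 mm with a 1° rotation component), consistent with head motion whose
rotation centre lies in the neck/posterior rather than at the brain
centre. This resolution cost of image-space correction is a known
limitation of the surrogate, not of the metrics.

## Problem sizes

Tests and the acceptance script run at desk scale: 32³–48³ grids at
3–4 mm spacing, 4–10 frames of 30 s, 5 × 10⁵ counts per frame. These
sizes preserve every behaviour under test (boundaries, recovery
accuracy, directions) while keeping a full run in minutes; the default
`RunConfig` uses 12 × 30 s frames for the same reason. Nothing in the
implementation depends on these sizes.
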