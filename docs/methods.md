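# Methods

This note describes the imaging model behind `fibsemquant`, the estimators
it uses, what the synthetic-data generator does and does not emulate, and
the numerical choices made where the design was genuinely open.

## Imaging model

A slice-and-view acquisition mills the specimen in steps of thickness
`t` (default 40 nm) and records a secondary-electron image of each cut
face. Metallic nanoparticles are bright against the homogeneous dried cell
matrix (their secondary-electron yield is about twice that of organic
carbon). Two effects couple the image stack to particle number:

**Escape-depth glow.** Electrons escape from a characteristic depth `l`
below the face. A particle whose front surface lies a distance `z` below
the face already contributes intensity proportional to `exp(-z / l)`. With
`l` (~89 nm) larger than `t`, each particle is visible in several slices
before it is exposed, so its accumulated intensity — the *detected volume*
`V_s`, measured in background-normalized arbitrary intensity units
(a.i.u.) — exceeds its *actual volume* `V_s0` by a glow offset `V_s'`:

    V_s = V_s0 + V_s'

**Shading.** The escape depth inside the metal is negligible, so a particle
lying behind another along the milling axis contributes nothing until the
anterior particle is milled away. In an agglomerate, each projected column
carries the glow of its front-most particle only.

For a cluster with detected volume `V_c` and projected area `A_c` (the
footprint, in pixels, of the cluster projected along the milling axis onto
the cross-section plane), the number of projected particles is
`n_p = A_c / A_s` and the particle count is

    n_c = (V_c − V_s' · A_c / A_s) / V_s0

with `A_s` the single-particle projected area. The projected area is not
corrected for the SEM viewing angle: electron escape is governed by the
shortest path to the cut face, i.e. along its normal. The whole-cell dose
is `N = Σ round(n_c)`; its standard deviation propagates `V_s'`, `V_s0`
and `A_s` as fully correlated across clusters, because all clusters share
one calibration, while `V_c` and `A_c` are treated as exact.

## Pipeline stages and estimators

**Registration.** Consecutive slices are registered by the integer argmax
of their 2D cross-correlation, restricted to a ±12 px window (physical
inter-slice drift is a few pixels; an unrestricted argmax on a slice whose
content is nearly translation-invariant along one axis produces arbitrary
peaks). The row shift is estimated first on the image destriped along
columns — the horizontal substrate edge anchors it — and the column shift
is then read off the correlation at that row lag, computed on the image
destriped along rows. Shifts are integer pixels; registration precision is
set by image content and degrades where the cell cross-section vanishes.

**Tilt correction.** The SEM views the cut face under an angle θ to its
normal (52° in the reference geometry), foreshortening the vertical axis by
cos θ. The image is stretched by 1/cos θ with linear interpolation and the
vertical pixel size rescaled so physical heights are preserved. The `sin`
convention used by some instruments is selectable in the configuration.

**Cell segmentation.** The milling trench in the substrate tracks the
slicing plane and anchors the cell's lower boundary: per column, the
strongest bright-to-dark transition below the image midline, re-searched in
a band around the cross-column median (the substrate surface is a
near-horizontal plane; bright particles also produce strong downward edges
and would otherwise capture single columns). Above the trench, a two-class
Otsu threshold on the Wiener-filtered slice separates cell matrix from
resin. Bright particles straddling the boundary bite notches into the
threshold mask; these are repaired by adding the particle blob and growing
the boundary stepwise (at most 30 steps) until the surrounding ring returns
to within 10% of the matrix median. The mask is then extended outward by
10 px (the upper cell boundary is a smooth transition, not an edge) and the
boundary smoothed with a normalized disc kernel of radius 5 px,
re-thresholded at 0.5. A slice is flagged `below_contrast_limit` and left
unsegmented when the median separation of the two Otsu classes falls below
4 MAD-based within-class spreads. (A between-class-variance share criterion
cannot do this job: Otsu applied to pure Gaussian noise already attains a
~64% between-class share, and bright particles inflate a variance-based
spread; the separation/MAD form is robust to both.)

**Intensity normalization (a.i.u.).** Each slice is normalized as
`(I − μ_bg) / σ_bg` with `μ_bg` the median and `σ_bg` the MAD-based robust
standard deviation of the cell-matrix pixels (the pre-extension threshold
core, with bright outliers excluded in a second pass). The flat background
maps to 0 and the matrix noise to 1, which makes detection invariant to
global affine rescaling of the raw data and lets a fixed noise floor of
3 a.i.u. stand in for "3σ of background" everywhere.

**Detection and refinement.** Candidate blobs per slice are the hole-filled
Roberts edges of the Gaussian low-passed a.i.u. image, thresholded at 3
robust standard deviations of the in-cell gradient; blobs whose bright
quartile sits at noise level are discarded. Candidates are grouped into
26-connected 3D components and each component is refined inside its padded
bounding box (5 px in-plane, 3 slices axially) with a two-threshold Otsu.
The refined cluster keeps the voxels above the *lower* threshold, floored
at the 3 a.i.u. noise level: the lower threshold adapts to local
matrix-level drift (the stated purpose of per-cluster refinement), while
the absolute floor keeps the captured glow fraction comparable between
small and large boxes — the box-dependent upper threshold would clip faint
glow from singles but not from agglomerates. Components that do not overlap
their own rough cluster are dropped (they belong to a neighbor whose own
refinement claims them), and refined clusters that share most of their
projected footprint within glow reach are merged: they are fragments of one
axial stack whose posterior part only surfaced after the anterior was
milled.

**Volume measurement.** `V_c` (and `V_s` during calibration) is the raw
a.i.u. integral over the cluster's footprint columns across its slice
range, extended backwards over the glow slices down to the noise floor —
a "column tube", not a sum over thresholded voxels. Per-voxel thresholds
capture glow asymmetrically (an isolated particle loses its faint tail, a
dense agglomerate does not, because neighboring particles lift shared
pixels above any threshold), which biases the calibration and therefore
every count. The raw integral captures the same truncated glow series in
every column on both sides of the formula, and zero-mean background noise
integrates away over the tube.

**Calibration.** Isolated single particles are screened automatically:
projected area within 30% of the expected single-particle footprint
(`π(d/2)²` at the nominal diameter), a single contiguous near-peak plateau
no wider than one particle's exposure extent (`ceil(d/t) + 1` slices; an
axially stacked pair has the right footprint but twice the plateau), and a
successful rising-branch fit. A manual id list can override the screen.
Per single: the per-slice profile is the maximum of the lightly smoothed
a.i.u. patch over the footprint (a raw maximum over ~100 pixels carries a
2–3σ upward noise bias that flattens the fitted exponential); the escape
depth comes from a log-linear least-squares fit of the strictly
pre-exposure points (`I_k = I_0 exp(−z_k/l)`), including the peak point
only when fewer than three glow points clear the noise floor. The
first-exposure slice is found by a changepoint fit — exponential rise
versus flat plateau in log space — because a plain argmax lands one slice
late whenever plateau noise peaks on a later slice, halving that
particle's `V_s0`. `V_s'` is the accumulated intensity of the slices
strictly before first exposure (empirical estimator); the closed-form
variant `V_s' = V_s · exp(−t/l)` is available as `estimator="closed_form"`
for comparison — the two do not agree in general, and the empirical form
is the one that keeps `V_s0 + V_s' = V_s` consistent with the measured
decomposition. Constants aggregate as unweighted mean ± sample sd over the
reference particles. A diagnostic voxel size (voxels at ≥95% of the
profile peak) reproduces the analytic sphere volume within 10% on clean
phantoms; the raw `V_s0` in a.i.u. additionally contains rim glow from the
not-yet-exposed annulus during exposure slices, which is physical and
appears identically in cluster volumes.

## The synthetic-data generator

The phantom scene is a half-ellipsoid cell (a spread macrophage dome
resting on the wafer, so every cross-section touches the substrate and the
trench anchors the lower boundary in every slice) filled with spheres of
nominal diameter 74 nm, arranged as isolated singles or touching-sphere
agglomerates: `in_plane` (touching along x), `stacked` (touching along the
milling axis) and `random` (compact random packing — each new sphere
touches an existing one and the candidate closest to the centroid is kept,
emulating densely packed phagolysosomal agglomerates rather than loose
chains). Distinct agglomerates keep disjoint projected footprints so the
ground-truth cluster count is unambiguous.

The renderer implements the imaging model literally, per pixel of each
particle's footprint: exposed pixels (cut face inside the sphere) carry the
full particle level; buried pixels carry `peak · exp(−z/l)` with `z` the
distance from the face to the sphere's front surface at that pixel,
suppressed while any anterior particle covering the pixel has not yet been
entirely milled away; milled-away material contributes nothing.
Contributions add on top of the local base level (resin 0.2, matrix 0.5,
particle peak 1.0, substrate 0.1 — configuration defaults reflecting the
roughly twofold metal yield, not physics claims). The cell matrix carries
a granular texture: a 3D random field smoothed over the escape depth
axially and ~2 px laterally, amplitude 0.04 against additive Gaussian
noise of 0.05. The texture is what makes consecutive slices registrable —
the escape depth exceeds the slice thickness, so neighboring cut faces
image overlapping material and their texture is correlated, as in real
stacks; a perfectly flat matrix would leave in-plane drift unobservable.
Scripted per-slice drift and noise are applied last. Rendering is
deterministic under a fixed seed.

Default study conditions: 6.3 × 6.3 × 40 nm voxels, escape depth 89 nm,
particle diameter 74 nm, noise 0.1 × matrix level. The test phantoms use
tens to ~100 particles in frames of roughly 40–70 slices × 200–420 px —
about a factor 100 fewer voxels than a full acquisition of a real cell
(625 slices) — chosen so the full suite exercises every stage in well
under a minute per phantom.

What the phantoms do *not* emulate: curtaining and charging artifacts,
beam damage, non-spherical or polydisperse particles, diffusive lateral
spread of the glow spot (the rendered glow covers the particle's full
projected disc, which matches the volume bookkeeping in which the offset
scales with projected area, but overstates the glow fraction relative to
the published single-particle decomposition — our rendered offset fraction
is ~0.55–0.6 of `V_s` versus 62/160 ≈ 0.39 measured on real data), and
organelle substructure. Passing the recovery tests therefore demonstrates
the correctness and internal consistency of the algorithms under the
stated imaging model, not performance on every real-world artifact.

## Known limitations

* **Dense-agglomerate bias.** The counting formula assigns one glow column
  per unit of projected area. Under the renderer, spheres touching along
  the milling axis leave thin matrix gaps through which a posterior
  particle glows briefly once its anterior neighbor is milled — a
  higher-order occlusion effect the linear `A_c/A_s` correction ignores
  (and that the published formula equally ignores; it is applied here
  exactly as printed, with no higher-order model). On compact random
  agglomerates this overcounts by roughly +10–20% for clusters of 20–30
  particles; combined with the phase spread of the single-particle
  calibration (sd ≈ 30% per particle, so ~8% on a 16-particle reference
  set), end-to-end recovery on ~100-particle phantoms scatters from −8% to
  +22% across generator seeds with a mean near +6%. For comparison, the
  published whole-cell total carries a ±23% uncertainty.
* **Registration at the stack ends.** Where the cell cross-section
  vanishes there is no content that constrains in-plane shifts, and the
  cumulative drift trace wanders; this does not affect counting (no cell,
  no particles) but rules out sub-pixel registration claims outside the
  cell's extent.
* **Fitted escape depth under noise.** The profile maximum, even smoothed,
  retains a small upward noise bias on the faint glow tail, so the fitted
  `l` on noisy phantoms runs ~10–30% above the generator's value. The
  counting pipeline does not consume `l` (the empirical offset estimator
  is slice-based), so this only affects the reported calibration summary;
  on noiseless phantoms the fit is exact to machine precision, and the
  Monte-Carlo mean over 16 analytically simulated noisy profiles stays
  within the reference 89 ± 17 nm band.
* **Degenerate inputs.** Flat slices yield a flagged zero drift step; an
  exactly background-valued image normalizes to all zeros; a zero-spread
  background with signal elsewhere raises an error; unimodal refinement
  boxes keep the rough cluster and set a flag; clusters visible in fewer
  than three usable slices are rejected from calibration; an empty
  single-particle screen falls back to a manual id list or fails loudly.
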