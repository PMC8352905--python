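# Methods

This note records the models, conventions and numerical choices behind
`canalvol`, and what the phantom-based validation does and does not show.

## Grid and world conventions

A volume is a 3D scalar array plus a 4×4 affine mapping 0-based voxel
*centers* to world millimetres (the NIfTI convention).  Spacing is the
column norms of the affine's linear part; all registration math runs in
world mm.  Pipeline inputs must have at least 8 voxels per axis.  When two
scans differ in spacing, the lower-resolution one is resampled *up* to the
finer grid — downsampling a 1.2 mm canal sampled at 0.35 mm is far below
the Nyquist limit of a coarser grid and destroys the signal (measured:
a 0.35→0.7→0.35 mm round trip loses >20% of thin-tube fluid voxels, but
<1% of a properly band-limited field).  Masks are transported with nearest
neighbour only, intensities with trilinear interpolation.

## Segmentation

Otsu's threshold is computed over 256 equal-width bins spanning the ROI's
observed min–max (the classical 8-bit formulation).  Candidates are the
interior bin edges; the between-class variance is evaluated in the
cancellation-free form (c − w₀G)²/(w₀w₁) so near-tied candidates rank
stably, and ties break toward the lowest candidate.  Because bin edges are
recomputed from the data range, the chosen bin index is exactly invariant
under any positive affine intensity map — the property that lets each scan
be thresholded independently under inter-scan drift.  Class means and
weights are reported from the actual sample split, not from bin centers.
Fluid is assumed bright (T2); a flag inverts for dark-fluid modalities.
Connected components below 1 mm³ (26-connectivity) are discarded — thin
canals must not be split, specks of a few voxels are noise.  A constant
ROI is a hard "degenerate histogram" error: the region contains no
structure.

With pure binary voxelization segmentation of a noiseless phantom is
exact for any positive contrast.  With the default partial-volume
boundaries exactness at the half-occupancy surface is no longer
guaranteed voxel-for-voxel (the threshold lands near, not exactly at,
half contrast); noiseless Dice is >0.99 and that is the honest statement.

## Rigid registration

Similarity is normalized cross-correlation over the overlap (out-of-field
samples excluded; <5% overlap is an error), making alignment invariant to
the gain/offset drift the segmentation also tolerates.  The transform is
p′ = R(p−c) + c + t with R parameterized by intrinsic XYZ Euler angles
(degrees) about the fixed volume's grid center.  Optimization is a
3-level coarse-to-fine pyramid (×2 anti-aliased decimation per level)
with Powell's derivative-free search at each level (xtol 1e-3, 60
iterations); the best-so-far transform is kept and never scores below the
initializer.  On default phantoms this recovers poses up to 10°/5 mm to
within ~0.03° and ~0.01 mm, far inside the one-voxel acceptance band.
Registration is global; a labyrinth-local ROI refinement was considered
and left out because the global optimum on whole-head-like content was
already sub-voxel on all test cases.

`mirror_lr` reflects the volume across the mid-sagittal plane of its own
field of view by flipping the data array along the left–right grid axis
(identified from the affine's orientation codes).  For an axis-aligned
affine this is exactly the negation of world L-R coordinates about the
volume's L-R center, and keeping the affine unchanged makes the
involution bit-exact.  An L-R axis oblique to the grid (direction cosine
< 0.99) is refused and an explicit axis must be passed.

## Defect volumetry

The defect is `pre ∧ ¬post` on the pre-operative grid (the reference must
be measured on its native grid).  Because the two segmented surfaces never
coincide exactly, the raw difference carries a thin shell over the whole
labyrinth; the manual cleanup step is emulated deterministically:
intersect with a declared keep-region (box or mask around the expected
plugging site), drop components under 1 mm³, keep the largest remaining
component.  All parameters are logged in the result's provenance.  The
primary output is 100·|defect|/|reference labyrinth| with the reference
restricted to the ipsilateral labyrinth; absolute mm³ is secondary.

Contralateral mode (no pre-operative scan): mirror the scan, register the
mirrored volume back onto the original (correcting head asymmetry),
segment the operated and mirrored-healthy labyrinth in the same ROI, and
use mirrored-healthy as the reference.  If the operated side turns out to
hold *more* fluid than the mirrored reference, a negative-volume warning
is recorded — the likely cause is a swapped side assignment.

## The phantom

The phantom generates what the pipeline's intended inputs look like: a
bright fluid labyrinth on dark background at 0.35 mm isotropic spacing.
Geometry: three torus shells (superior canal R 3.2 mm in a plane tilted
45° from sagittal, posterior R 3.0 mm roughly orthogonal to it, lateral
R 2.8 mm near-horizontal; tube radius 0.6 mm) joined to a vestibule
ellipsoid (2.2/1.7/1.4 mm semi-axes) and a cochlea blob, each canal
centerline passing through the vestibule center.  An ampulla marker sits
at −160° of superior-canal arc and a common-crus marker at +160°
(0° = top of the loop, the arcuate-eminence region); plug arcs that reach
the ampulla marker set an involvement flag.

Partial volume is approximated by 3× supersampled occupancy averaging;
voxel intensity is background + contrast·occupancy and the true mask is
the noiseless occupancy ≥ 0.5 support.  Plugging erases the fluid signal
of superior-canal points whose centerline angle lies in the arc (points
shared with other structures are protected, so a plug never eats the
vestibule), reusing the pre volume's noise realization; the true defect
and its exact relative volume follow.  The defaults are the validated
study conditions: contrast 90, noise sd 4.5 (5% of contrast), drift gain
1.1 / offset 10, post-scan pose 3° plus ~1 mm translation; the post scan's
noise sd is scaled by the gain so its relative noise matches.  Bilateral
phantoms mirror the geometry exactly across the mid-sagittal plane (the
left ear's primitives are x-reflections of the right's, which makes the
noiseless channel bit-exactly symmetric).  `calibrate_extent` bisects the
plug arc so the *true* defect fraction hits a requested percentage —
truth-side geometry only, independent of the measurement pipeline.

What the phantom does **not** emulate: Rician noise statistics, bias
fields, susceptibility/motion artifacts, anatomically accurate cochlear
spirals, and real inter-subject anatomy.  Passing tests therefore show
the pipeline's arithmetic and its robustness to drift/pose/noise at
realistic SNR — not segmentation performance on clinical data.

## Rendering

Emission–absorption ray casting with an orthographic camera (anatomy at
this scale needs no perspective cue, and orthographic rays admit exact
closed-form checks).  Default sampling step: half the smallest voxel
spacing.  Transfer-function alpha is per-sample at that step (no opacity
correction), so a homogeneous slab composites to exactly 1−(1−α)ⁿ.
The segmentation mask is applied both to sample opacity *and* to the
intensity volume before interpolation, so rendered pixels are
bit-independent of every voxel outside the mask.  Early ray termination
triggers at accumulated opacity 0.99.  The default transfer function
ramps alpha from the Otsu threshold of the mask-restricted histogram
upward — a documented stand-in for an expert's manual choice.  PNGs are
written with straight (non-premultiplied) alpha.

## Agreement statistics

ICC for average measures from the two-way mean squares: absolute
agreement (MSR−MSE)/(MSR+(MSC−MSE)/n) by default — raters measure the
same physical volume, so calibration offsets should count — and two-way
mixed consistency (MSR−MSE)/MSR as the alternative.  Significance is
F = MSR/MSE on (n−1, (n−1)(k−1)) df.  Qualitative bands: <0.4 poor,
0.4–0.79 general, ≥0.80 good (the conventional band edges; the upper edge
anchors at 0.80).  Zero between-target variance is an explicit error.

## Problem sizes used in validation

Unilateral phantoms are 64³ voxels at 0.35 mm (22.4 mm field of view),
bilateral 96×64×64; these hold a full labyrinth (±7 mm reach) with
margin while keeping a full pipeline run to a few tens of seconds, so the
validation sweeps (4-point recovery, 20-phantom classification, 5-pose
registration) run end to end in minutes.

## Known limitations

- The keep-region emulation of manual editing is only as good as the
  declared region; a region missing the plugging site yields an empty
  defect with a warning, not an error.
- Very small defects (<1 mm³ after cleanup) are indistinguishable from
  segmentation shell noise by construction of the size filter.
- Registration assumes same-modality scans; NCC is not appropriate for
  CT–MRI pairs.
- The ICC accepts any number ≥2 of raters but has no missing-data
  support.
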