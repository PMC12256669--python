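# Methods

This note records the models, numerical choices and limitations behind
`mlemlab`, in the spirit of a methods appendix.

## Projector pair

The forward projector follows the rotate-and-sum construction: at each
acquisition angle the image is rotated about the grid center and each pixel
column is summed into one detector bin (bins = grid size, bin pitch = pixel
pitch). Interpolation is bicubic in the cubic-convolution sense (Keys
kernel, a = −1/2) — the kernel classically meant by "bicubic" in image
processing toolboxes. Rather than resampling per angle at run time, the
operator is assembled once per geometry as a sparse matrix whose row for
detector bin *j* at angle *θ* holds the column sums of the rotation weights;
this is algebraically identical to rotate-then-sum but roughly 40× faster,
and it makes the back-projector available as the exact matrix transpose.

Working with a matched adjoint pair has two consequences the package relies
on: the dot-product (adjoint) test holds to machine precision, and the MLEM
update below is an exact EM iteration, so its log-likelihood is provably
non-decreasing. The operator is strictly linear; nonnegativity is enforced
by clipping its *outputs* at zero (cubic kernels have small negative lobes),
not inside the operator. Linearity and adjointness tests therefore disable
the output clip.

Angles span a 360° arc. The full-scale profile uses 1° sampling; volume
experiments use the scaled profile (3°, see below).

## Poisson noise

Sinogram bins are independent Poisson counts with rate
`count_scale × value`; the result is reported back on the original scale.
Sampling is inverse-CDF on a seeded uniform field: exactly one uniform per
bin regardless of rate. This makes paired experiments — the lesion-free
control versus each hot-spot variant under the same seed — run under common
random numbers: bins whose rates agree receive identical counts, so error
images between paired reconstructions are free of common-mode noise. The
replicate noise floor (below) deliberately breaks the pairing by varying
the seed.

Default count scales: 1.0 for the cardiac experiments (myocardium value 75
then yields realistic projection counts, ~600 per bin) and 100 for the
disk/checkerboard demonstrations, whose published counterparts are
essentially noise-free visualizations.

## MLEM

Update: `Xᵏ⁺¹ = Xᵏ · R⁻¹{S / R{Xᵏ}} / R⁻¹{1}`. The sensitivity image
`R⁻¹{1}` is computed once per geometry. The initial estimate is uniform
ones inside the inscribed circle and zero outside; a user-supplied initial
must be strictly positive inside that field of view (multiplicative updates
preserve zeros). Division guard: bins where both the data and the projected
estimate are below `max(1e-12, 1e-6 × max(S))` contribute a ratio of 1 (no
update); the relative part of the threshold keeps interpolation spillover
(~10⁻⁷ of the peak bin) from seeding enormous ratios once the estimate has
emptied a region — with count data the threshold is far below one count, so
no real measurement is ever masked. Elsewhere the denominator is clamped at
1e-12. The log-likelihood trace clamps projections at the same guard so the
trace stays finite; the public `poisson_loglik` keeps the exact convention
(−∞ when a zero-rate bin holds counts).

Default iteration count is 15 with snapshots at odd iterations 1–15.
Volumes are reconstructed slice-by-slice along z; the stacked implementation
is numerically identical to per-slice calls (asserted in tests). No
regularization, no ordered subsets, no resolution modelling — plain MLEM.

## Phantoms

**Disk / checkerboard.** The disk is binary (optionally Gaussian-blurred
with mass-preserving truncation). The checkerboard defaults to 32-px
squares at 256 (16-px at the scaled 128 matrix), low/high = 0/1, and the
hot spot is a disk one square wide whose value is `ratio × high`.

**Cardiac-torso emission map.** The LV is a truncated half-ellipsoidal
shell: outer semi-axes (r, L, r) with r = 29.7 mm and L = 94.3 mm, wall
thickness 10 mm (a typical myocardial value; not fixed by the study design
and exposed as a parameter), open at the base, apex at +y of the cardiac
frame, myocardium value 75. Blood pool and lung are a uniform background
(0.5) on a *spherical* support — a sphere is rotation-invariant, so volume
rotation conserves total intensity exactly. The optional lung lesion is a
30 mm sphere at `ratio × 75`, placed on the +z (lateral) side of the wall
at a 6 mm edge-to-edge gap, 30% of the LV length from the base
(mid-to-basal). Voxels are 2.34 mm isotropic.

Voxelization is analytic: each voxel coordinate is mapped by the inverse
heart orientation into the cardiac frame and evaluated against the implicit
surfaces, with a linear antialias ramp of 1.5 voxels across every surface
(sub-voxel partial-volume softening; also what keeps resampling error low
under rotations). No resampling is involved in phantom construction.

The heart orientation triple (ZY, XZ, YX) = (−90°, −20°, −50°) is applied
as extrinsic rotations about x, then y, then z. Under this convention the
LV long axis lies ~20° off the reconstruction (z) axis, and the lesion
shares transverse slices with the LV — the configuration that produces the
artifact. After the mitigation rotation (+90° about y) the LV–lesion offset
acquires a 0.77 z-component (~39 mm of axial separation), moving the spot
out of the LV's slices. `reorient_to_cardiac_axes` applies the exact
inverse orientation in a single bicubic resampling; in the reoriented frame
fixed-y slices are short-axis planes and fixed-x slices are
horizontal-long-axis planes, with the lateral wall toward +z.

## Artifact quantification

The LV is segmented on the *control* reconstruction only: slices are
upsampled 6× (bicubic), Otsu-thresholded, and the largest connected
component is kept; the same mask is applied to every S/M variant. Each
slice is normalized by its maximum inside the mask, and the signed error is
`control − index` inside the mask (positive = suppressed, negative =
intensified). Sectors are quadrants about the LV center, with the lateral
sector centered on the lesion direction. The analysis slices are the five
transverse slices centered on the lesion's z — the slices where spot and
LV coexist.

The **noise floor** is the maximum lateral-sector mean |error| over five
control-vs-control replicate reconstructions that differ only in their
noise seed. Errors below (or within 2× of) this floor are treated as
indistinguishable from noise.

A caveat discovered with this pipeline: because every slice is normalized
to its own LV maximum, the artifactual *intensification* of the wall zone
nearest the spot (≈10% at S/M = 4) rescales the entire index slice, which
injects a uniform positive pseudo-error (~0.05) into sectors that are
physically untouched; with the scale effect removed, the septal error sits
inside the noise floor. The package keeps the normalization as part of the
emulated processing chain and reports the sector statistics as measured.

The **checkerboard** distortion is summarized by RMS error (relative to the
paired control reconstruction) inside two perpendicular bands of the spot's
width crossing at the spot versus elsewhere, spot excluded with a
one-radius margin. Empirically the bands run along the ±45° diagonals of
the board (band/rest RMS ratio ≈ 2.2 at 5:1, versus ≈ 0.6 for axis-aligned
bands), so the diagonal orientation is the default.

The **halo check** samples a line from the septal wall through the LV
center, the lateral wall and the spot; the minimum of the wall-to-spot gap
segment is compared with the control background mean − 3σ. A positive
margin means no photopenic halo.

The **Gibbs overshoot** utility evaluates the N-harmonic Fourier partial
sum of a unit-jump square wave on a fine grid near the discontinuity with a
local refinement around the argmax; 1000 harmonics give 8.949% of the jump
(the Wilbraham–Gibbs limit), one harmonic 13.66%.

## Problem sizes

Full-scale settings are a 256 matrix with 1° sampling. The package's
standard experiment profile — used by the test suite and
`scripts/acceptance.py` — is the scaled one: 128 matrix, 3° sampling for
the cardiac runs (1° for the 2-D disk/checkerboard), 5 analysis slices,
15 iterations, 5 noise replicates; the mitigation experiment reconstructs
a ±56 mm slab (49 slices) in the rotated frame. These sizes reproduce all
qualitative findings while keeping a full run to a few CPU-minutes.

## Known limitations

* No attenuation, scatter, detector response or motion is modelled; the
  phantom reduces all organs except the LV and the lesion to a uniform
  background. Conclusions transfer to real data only insofar as the
  artifact is a property of the reconstruction itself.
* The projector is 2-D slice-by-slice; no 3-D system model.
* The emulated cardiac geometry is a simplified shell, not a NURBS-based
  anatomical phantom; absolute error magnitudes should be read as
  qualitative, the orderings (ratio monotonicity, sector contrasts) as the
  robust findings.
* Otsu segmentation assumes the control slice is effectively bimodal; very
  noisy or low-count settings may need a different threshold.
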