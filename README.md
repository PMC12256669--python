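# mlemlab

A simulation laboratory for studying the **local distortion that a nearby
hot spot induces during MLEM reconstruction** of emission-tomography
(SPECT/PET-style) images — in particular the artifactual perfusion defect a
hot lung lesion creates in the adjacent lateral wall of the left ventricle
(LV) in myocardial perfusion imaging.

It is aimed at medical-physics and image-reconstruction researchers who
want a fully synthetic, reproducible testbed: every input is generated by
code (no external data), every experiment is seeded, and the whole pipeline
— phantom → sinogram → Poisson noise → MLEM → artifact quantification — is
exposed as a small library plus a `simlab` command-line tool.

## The model

Projections are acquired by a Radon transform over a 360° arc: the image is
rotated (bicubic interpolation) and each pixel column is summed into a
detector bin. Internally this rotate-and-sum operator is assembled once per
geometry as a sparse system matrix `R`; the unfiltered back-projection
`R⁻¹` is its exact transpose, so the pair is a matched adjoint pair.

Reconstruction is classical maximum-likelihood expectation-maximization
(MLEM). With measured sinogram `S` and estimate `Xᵏ`, the multiplicative
update is

    Xᵏ⁺¹ = Xᵏ · R⁻¹{ S / R{Xᵏ} } / R⁻¹{1}

where `R⁻¹{1}` is the sensitivity image. Each update is an exact EM step
for the Poisson likelihood `Σ_b [S_b log λ_b − λ_b]`, `λ = R{X}`, so the
log-likelihood trace is non-decreasing — a property the test suite checks
on every instance.

The `MLEM` class follows a model/results layout: construct it from data
(one sinogram, or a stack of per-slice sinograms, plus the geometry), call
`.fit(n_iter=...)`, and inspect the returned `MLEMResults` (final estimate,
iteration snapshots, log-likelihood trace, `summary()` table).

Phantoms include a blurrable disk, a checkerboard with an optional
high-contrast spot, and a simplified cardiac-torso emission map: a
truncated half-ellipsoidal LV shell (length 94.3 mm, radius 29.7 mm,
myocardium value 75, 2.34 mm isotropic voxels, heart orientation
ZY = −90°, XZ = −20°, YX = −50°) with an optional 30 mm spherical lung
lesion beside the lateral wall at spot-to-myocardium (S/M) ratios
0.5 / 1 / 2 / 4. The analysis chain mirrors clinical processing: Otsu
segmentation of the LV on the control reconstruction, normalization to the
LV maximum, signed error images, per-sector (lateral / anterior / septal /
inferior) wall statistics, and circumferential/line profiles.

## Worked example

```python
import mlemlab as ml

geom = ml.ProjectionGeometry.with_step(128, 3.0)     # 360° arc, 3° steps
disk = ml.make_disk(128, 40, 75.0, 0)                # sharp-edged disk
sino = ml.add_poisson_noise(ml.forward_project(disk, geom), seed=7)

res = ml.MLEM(sino, geom).fit(n_iter=15)
print(res.summary())
print(f"NRMSE vs truth: {res.nrmse(disk):.3f}")
```

prints

```
MLEM reconstruction results
===========================
grid size            : 128 x 128
angles               : 120 over 360 deg
slices               : 1
iterations           : 15
snapshots at         : [1, 3, 5, 7, 9, 11, 13, 15]
log-lik (first iter) : 5.34621e+07
log-lik (last iter)  : 7.75543e+07
monotone trace       : True
min / max estimate   : 0 / 80.0278
```

The log-likelihood rises monotonically across the 15 iterations, and the
reconstruction reaches a normalized RMS error of 0.087 against the true
disk. The max estimate (80.0) overshoots the true plateau (75) — the edge
ringing that motivates the disk experiment.

The CLI exposes the same machinery:

```bash
$ simlab gibbs --n-terms 1000
overshoot(1000 harmonics) = 8.9490 % of the jump

$ simlab adjoint-test --size 32 --trials 10
max relative <Rx,y> vs <x,R'y> mismatch over 10 draws: 1.370e-16

$ simlab run config.yaml --seed 1 --out results/   # full experiment bundles
```

where `config.yaml` names one of the four experiments (`gibbs_disk`,
`checkerboard`, `cardiac`, `cardiac_rotated`); see
`mlemlab.experiments.ExperimentConfig`.

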