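# Methods

This note documents the models, numerical choices and limitations behind
`dosewarp`: a pipeline for estimating interfraction anatomical deformation
between a planning CT and daily CBCT-like images of the male pelvis, and for
accumulating fraction doses on the planning anatomy.

## Coordinate and field conventions

Volumes are axis-aligned grids with 0-based voxel indices in `(x, y, z)`
order; world coordinates in mm are `origin + index * spacing`.  A
`DeformationField` stores per-voxel displacements **in mm on the fixed
frame's grid** in the *pull-back* convention: the warped volume at fixed
position `x` samples the moving volume at `x + u(x)`.  Every producer of
fields (the networks, the FFD, the phantom's exact field) and every consumer
(warping, Jacobian analysis, dose accumulation) shares this single
convention; the phantom's ground-truth field is stored the same way so it
can be fed directly into any downstream stage.  Rigid transforms follow the
resampling convention as well (fixed points are mapped into the moving
frame).

Scalar volumes are warped by trilinear interpolation with edge-clamped
out-of-bounds handling.  Label volumes are warped channel-wise on one-hot
indicators and recombined by argmax; ties resolve to the lowest label code.
One-hot warping avoids the ordinal artifacts of interpolating integer codes.

## The synthetic pelvic phantom

Every quantitative claim in the test suite is made against a phantom whose
anatomy and deformation are analytic, so ground truth is exact rather than
itself the output of a registration.

**Anatomy.** Body (ellipsoid, 88×80×70 mm half-axes), two lateral bone
arcs (cylindrical shells, ~700 HU), prostate (ellipsoid, 22×18×18 mm
half-axes ≈ 30 cm³), bladder (sphere, 26 mm radius ≈ 74 cm³ when full),
rectum (capsule along z, 14 mm radius).  The rectum is a capsule rather
than a flat-capped cylinder because planar end caps lying on lattice planes
alias an entire voxel slice at once under resampling, which dominates the
Dice error of thin structures.  Label codes are 0 background, 1 body,
2 rectum, 3 bladder, 4 prostate; bone is an intensity feature of the body,
not a label.

**Deformation.** The planning→daily map `F(x) = x + u(x)` is a sum of
three analytically differentiable components:

* radial bladder-filling expansion — pure scaling by `bladder_scale` inside
  the bladder (so the daily/planning volume ratio is exactly the cube of
  the factor) with a Gaussian decay (τ = 15 mm) outside;
* a localized prostate offset — a constant vector weighted by a wide
  Gaussian (σ = 45 mm), approximating a rigid prostate shift with smooth
  falloff;
* a low-frequency *divergence-free* sinusoidal body warp: each displacement
  component depends only on the two other coordinates, so the divergence
  vanishes identically and the warp is volume-preserving to first order.

The generator evaluates det J numerically on the grid and rejects any
parameter set that folds.  The daily volumes are rendered by evaluating the
analytic planning anatomy at `F⁻¹(y)` (fixed-point inversion of the
analytic field, convergent because ‖∇u‖ < 1), so no interpolation chain
blurs the ground truth and the stored field is exact by construction.

**Study conditions.** Per-subject deformation parameters are drawn once
from ranges typical of interfraction pelvic change: bladder filling
1.0–1.3×, prostate displacement 1–5 mm in a random direction, global warp
amplitude 2–5 mm.  CBCT-like degradation applies contrast compression
(×0.8), a +30 HU bias, and 25 HU Gaussian noise; planning CTs carry 5 HU
noise.  Labels are deformed but never degraded.

**Grids.** The default phantom grid is 96×96×48 at 2 mm.  At this
resolution the exact-field label round trip (rasterize daily labels, warp
back, compare with planning labels) reaches Dice ≥ 0.973 for every organ;
at 3 mm the double-rasterization aliasing floor for the rectum is ~0.94
regardless of deformation amplitude, which is why the coarser grid is not
the default.  The registration and training studies use a compact
64×64×32 grid at 2.5 mm (`STUDY_GEOMETRY`) with proportionally tightened
geometry, trading rasterization fidelity for minutes-scale runtimes.

**Planning dose.** Prescription (80 Gy default) held exactly inside the
prostate expanded by a 7 mm margin, with a Gaussian falloff (σ = 8 mm) of
the distance beyond the margin.  This emulates a planning-style boosted
prostate dose sufficient for exercising DVH machinery; it is not a
treatment-planning-system dose.

**What the phantom does not emulate:** CBCT scatter/beam-hardening physics,
couch and metal artifacts, sliding interfaces, content change (the rectal
gas option changes intensity, not topology), inter-subject anatomical
variability beyond the deformation parameters.  Passing tests therefore
demonstrate algorithmic correctness and recoverability of smooth
deformations — not clinical performance on patient data.

## Displacement-field networks

Three weakly supervised U-Net variants regress a dense displacement field
from stacked fixed/moving inputs:

| variant  | inputs (channels)            | loss                                  |
|----------|------------------------------|---------------------------------------|
| `sc`     | scans (2)                    | 1·NMI + 4·smooth                      |
| `msk`    | label images (2)             | 2·L1 + 4·smooth                       |
| `sc_msk` | scans + label images (4)     | 1·NMI + 2·L1 + 4·smooth               |

Label inputs are the single-channel integer-coded images scaled by 1/4; the
L1 loss, however, is computed on one-hot encodings of the four foreground
structures (summed over channels, averaged over voxels) so that confusing
bladder with rectum costs the same as confusing rectum with body.  The
`sc_msk` loss includes the smoothness term with weight 4 (a regularized
field is strictly preferable and the weight list supplies the value even
though one printed loss formula omits the term).

*NMI* is a differentiable Parzen estimate with triangular kernels and 32
bins on [0, 1]-normalized intensities (clip window −1024…1575 HU),
returned negated so lower = more similar; constant-to-the-binning images
fall back to −1 with zero gradient.  *Smoothness* is a diffusion
regularizer: the mean squared forward-difference gradient over components,
axes and positions (a linear field `u_c = c·x_a` gives exactly c²/9).

**Architecture and autodiff.** The U-Net (one conv+LeakyReLU block per
level, 2× average pooling, mirrored decoder with skip concatenation,
separable-linear upsampling, a small-initialized flow head so training
starts at the identity) and its optimizer are implemented directly in
numpy with hand-written backward passes (im2col convolutions against BLAS);
gradients are verified against finite differences in the test suite.  By
default the field is predicted at half resolution from average-pooled
inputs and linearly upsampled — losses are always evaluated at full
resolution — which cuts convolution cost 8× with little accuracy loss at
the organ scales involved; `down_factor=1` disables it.  There is no
diffeomorphic integration layer: smoothness is encouraged by the loss and
folding is *measured*, not prevented.

**Training.** Adam, batch of one volume pair, learning rate 0.0005
multiplied by 0.7 every 10 epochs, 150 epochs by default, checkpoint chosen
by the best validation measure — mean organ Dice for the label-aware
variants, total loss for `sc`.  Subject-level splits are 70/15/15 across
three folds, stratified (e.g. by images-per-subject and scanner class),
with all images of a subject confined to one partition.  The desk-scale
studies (`dosewarp.studies`) use reduced widths (8/16/16 encoder, 16/12
decoder), learning rate 1e-3 and 20 epochs on 28 phantom subjects
(20 train / 4 validation / 4 test); under these conditions the held-out
mean organ Dice reproduces the qualitative ordering
`msk ≈ sc_msk > sc > rigid-only`.

## B-spline FFD baseline

The classical comparator parameterizes displacement by a cubic B-spline
control lattice with 8 mm final spacing and optimizes the same soft-binned
NMI with an adaptive-step (Adam) stochastic gradient descent on random
voxel subsamples (2000 per iteration, 200 iterations per level), over a
4-level image pyramid with resolution divided by 4, 4, 2, 1 and Gaussian
smoothing of σ = factor/2 voxels per level.  A small diffusion penalty
(weight 0.1) on the control lattice keeps texture-free interior regions
from drifting — without it NMI can continue improving while geometric error
grows, since homogeneous regions leave displacement unconstrained.  The
dense field is evaluated by separable tensor-product cubic interpolation
(`bspline_to_dense`), cross-checked in tests against SimpleITK's
`BSplineTransform` as an independent oracle.  As a safeguard the optimizer
never returns a field that degrades full-grid NMI relative to the identity.
On the study grid a 4 mm sinusoidal warp is recovered with ~1 voxel mean
endpoint error inside the body in ~10 s.

## Geometric evaluation

Dice, average surface distance (ASD), Hausdorff distance (HD) and its 95th
percentile are computed between planning and warped daily masks.  Discrete
conventions: the surface of a mask is its face-connectivity border voxels
(the array edge counts as outside); distances are Euclidean mm between
voxel centers; ASD is one-directional (first mask → second) as is common
for planning-vs-deformed comparisons, with a symmetric option; HD95 takes
the linear-interpolation 95th percentile per direction, then the maximum.
All of these agree exactly with a brute-force double-loop oracle on small
masks in the test suite.  Two empty masks have Dice 1 by convention;
surface distances are undefined (an error) for empty masks.

Folding is quantified as the percentage of voxels within a structure where
the Jacobian determinant of `x ↦ x + u(x)` is ≤ 0, with derivatives by
central differences in mm (one-sided at the boundary).

## Dose accumulation and DVH reporting

Assuming dose deformation-invariance, each fraction's dose is the planning
dose rigidly resampled into the fraction frame; the accumulated dose pulls
every fraction dose back through that fraction's deformation field and sums
on the planning grid (linear in each fraction, order-invariant).  Dose
warping is plain trilinear interpolation without Jacobian weighting —
adequate for slowly varying dose, but a known approximation where tissue
compresses or expands (energy/mass remapping is out of scope).

DVH curves are cumulative with 0.1 Gy bins; Dmean is computed directly from
masked voxels (binning-independent); D98% inverts the cumulative curve with
linear interpolation; VxGy is the exact fraction of voxels at or above the
threshold.  The reported index set follows GETUG recommendations: D98% and
V76Gy for the prostate, V70Gy for the bladder, V72Gy for the rectum, and
Dmean for all structures; differences are signed (accumulated − planning).
Wall structures (5 mm rectum / 7 mm bladder negative expansions) are
available via morphological erosion but whole-organ masks are the default,
matching the evaluation-time index list.

## Rigid initialization

Bone-based 6-DOF alignment: both volumes are thresholded at 200 HU
(configurable), smoothed into soft indicators (σ = 4 mm), and registered
with a multi-resolution mean-squares Euler transform (SimpleITK's
registration framework).  On phantom data a known translation is recovered
within 0.5 mm.  The threshold default reflects the usual
trabecular/cortical bone range.

## Numerical and degenerate-input choices

* Zero deformation fields reproduce inputs exactly for labels (argmax of
  exact indicators) and to float round-off for scalars.
* Field inversion (phantom generation) is fixed-point iteration, valid for
  ‖∇u‖ < 1; the generator's fold check guarantees this regime.
* The soft-binned self-NMI is slightly above −2 (kernel spreading); the
  independence value is ≈ −1.
* `fraction_dose` clamps tiny negative interpolation overshoots to zero.
* All stochastic components (phantom sampling, weight init, shuffling, FFD
  voxel subsampling) derive from explicit integer seeds; identical seeds
  give bit-identical results on a fixed platform.

## Known limitations

* The networks are CPU-scale: reduced widths and half-resolution fields are
  the default study configuration; the architecture is configurable but not
  benchmarked at clinical grid sizes.
* The FFD's diffusion penalty weight (0.1) was chosen on the phantom
  recovery task; very different intensity distributions may want retuning.
* No DICOM ingestion (NIfTI only), no couch/metal handling, no CBCT dose
  recalculation, no biological dose conversion, no hypothesis testing in
  `compare_methods`.
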