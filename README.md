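# dosewarp

Contour-guided deformable image registration and dose accumulation for
CBCT-guided radiotherapy of the pelvis — with a synthetic phantom that makes
every stage testable against exact ground truth.

## The problem

During fractionated prostate radiotherapy the anatomy changes day to day:
the bladder fills, the rectum distends, the prostate shifts. Estimating the
dense deformation between the planning CT and each daily cone-beam CT (CBCT)
lets the delivered dose be *accumulated* on the planning anatomy — warp each
fraction's dose back and sum — so the clinical team can compare it with the
plan. The package is aimed at medical-physics researchers who want a small,
fully inspectable implementation of this pipeline: registration networks,
a classical free-form-deformation baseline, the standard geometric metrics,
Jacobian folding analysis, and DVH-index reporting, all exercised on a
phantom with analytically known deformations instead of patient data.

## What's inside

* **Registration networks** (`dosewarp.registration`): three weakly
  supervised U-Net variants regressing a dense displacement field u on the
  fixed grid (pull-back convention: `warped(x) = moving(x + u(x))`):
  - `sc` — scans only, loss `1·NMI(S_f, S_m∘φ) + 4·L_smooth(φ)`
  - `msk` — label images only, loss `2·L1(M_f, M_m∘φ) + 4·L_smooth(φ)`
  - `sc_msk` — both (4 input channels), loss
    `1·NMI + 2·L1 + 4·L_smooth`

  with NMI a differentiable soft-binned normalized mutual information, L1 a
  one-hot label distance and L_smooth a diffusion regularizer on ∇u. Adam,
  learning rate 0.0005 × 0.7 every 10 epochs, best-validation checkpointing,
  subject-stratified 70/15/15 splits. The network stack (3-D convolutions
  with explicit backprop) is pure numpy — no GPU or DL framework required.
* **FFD baseline** (`dosewarp.ffd`): cubic B-spline lattice (8 mm), NMI,
  adaptive-step stochastic gradient descent on voxel subsamples, 4-level
  multi-resolution pyramid (4/4/2/1).
* **Metrics** (`dosewarp.metrics`): DSC `2|A∩B|/(|A|+|B|)`, average surface
  distance, Hausdorff distance and its 95th percentile, and the percentage
  of voxels per structure with Jacobian determinant ≤ 0 (folding).
* **Dose** (`dosewarp.dose`): fraction-dose construction under dose
  deformation-invariance, DVF-based warping and accumulation, cumulative
  DVHs and the GETUG index set (prostate D98%/V76Gy, bladder V70Gy, rectum
  V72Gy, Dmean everywhere).
* **Phantom** (`dosewarp.phantom`): paired planning/daily pelvic anatomies
  (body, bone arcs, prostate, bladder, rectum) deformed by an analytic
  diffeomorphism (bladder filling, prostate shift, divergence-free body
  warp), CBCT-like degradation, a planning-style dose, and the *exact*
  deformation field.
* **Pipeline + CLI** (`dosewarp.pipeline`, `dosewarp` command): phantom →
  preprocess → register → evaluate → accumulate → report, with JSON
  manifests and CSV outputs.

## Worked example

Register a daily phantom anatomy to its planning anatomy with the FFD
baseline and evaluate against the planning contours:

```python
from dosewarp import make_phantom, warp
from dosewarp.phantom import study_spec
from dosewarp.preprocess import clip_normalize
from dosewarp.ffd import ffd_register, FFDConfig
from dosewarp.metrics import evaluate_structures
from dosewarp.dose import dvh_indices

pair = make_phantom(study_spec(0))          # 64x64x32 @ 2.5 mm subject
fixed = clip_normalize(pair.planning_image) # HU -> [0, 1]
moving = clip_normalize(pair.daily_image)

field = ffd_register(fixed, moving, FFDConfig(seed=0))
warped = warp(pair.daily_labels, field)

for m in evaluate_structures(pair.planning_labels, warped, field):
    print(f"{m.structure:9s} DSC {m.dsc:.3f}  ASD {m.asd_mm:.2f} mm  "
          f"HD95 {m.hd95_mm:.2f} mm  fold {m.fold_pct:.2f}%")

print(dvh_indices(pair.planning_dose, pair.planning_labels))
```

Output:

```
rectum    DSC 0.931  ASD 0.94 mm  HD95 2.50 mm  fold 0.00%
bladder   DSC 0.788  ASD 3.46 mm  HD95 6.12 mm  fold 0.00%
prostate  DSC 0.855  ASD 1.96 mm  HD95 5.00 mm  fold 0.00%
{'prostate': {'Dmean': 80.0, 'D98': 80.0, 'V76': 100.0},
 'bladder': {'Dmean': 12.9, 'V70': 4.8}, 'rectum': {'Dmean': 7.1, 'V72': 0.0}}
```

Reading it: the intensity-driven FFD recovers the rectum and prostate well
(DSC 0.93/0.86, sub-voxel to ~2 mm mean surface error) but underestimates
the large bladder-filling change (DSC 0.79) — exactly the failure mode that
motivates feeding contours to the registration. No voxel folds (det J > 0
everywhere). The planning dose holds the 80 Gy prescription in the prostate
(D98% = 80 Gy, V76Gy = 100 %) with low bladder/rectum doses.

Training the contour-guided networks on a phantom cohort and comparing all
methods end-to-end is wrapped in `dosewarp.studies`:

```python
from dosewarp.studies import dl_study
res = dl_study(seed=0, epochs=20)   # ~10 CPU-minutes
```

which reports held-out mean organ DSC per variant against the rigid-only
baseline (label-guided variants ≈ 0.94 vs ≈ 0.84 intensity-only vs ≈ 0.83
rigid on the default cohort).

## Conventions worth knowing

* Axis order `(x, y, z)`, world mm = `origin + index * spacing`; NIfTI-1
  throughout; displacement fields are 4-D NIfTI in mm, pull-back convention.
* Label codes: 0 background, 1 body, 2 rectum, 3 bladder, 4 prostate.
* `docs/methods.md` documents the models, defaults and limitations in
  detail.
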