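"""Desk-scale benchmark studies on the synthetic phantom cohort.

These are the package's reference experiments — small enough for CPU minutes,
large enough to exercise every stage end-to-end:

* :func:`dl_study` — train the three network variants on a cohort of phantom
  subjects (subject-level 70/15/15 split) and report held-out mean organ Dice
  against the rigid-only baseline, plus per-organ folding percentages.
* :func:`ffd_study` — recover a pure sinusoidal body warp with the classical
  FFD and report the mean endpoint error against the analytic field.
* :func:`dose_study` — accumulate several fractions through the exact fields
  and compare accumulated vs planned GETUG DVH indices.

All randomness is derived from the single ``seed`` argument.  The cohort uses
the compact 64×64×32 @ 2.5 mm study grid; training runs use reduced channel
widths (see DEFAULT_NET) so a full three-variant study stays within CPU-scale
minutes.
"""

from __future__ import annotations

import numpy as np

from .dose import accumulate, dose_report, dvh_indices, fraction_dose
from .fields import warp
from .ffd import FFDConfig, ffd_register
from .grids import ImageVolume, ORGAN_LABELS, RigidTransform
from .losses import nmi_loss
from .metrics import dsc, fold_pct
from .phantom import make_phantom, study_spec
from .preprocess import clip_normalize
from .registration import RegNetConfig, RegPair, make_splits, train

__all__ = ["dl_study", "ffd_study", "dose_study", "DEFAULT_NET"]

#: Reduced-width network used by the desk-scale studies.
DEFAULT_NET = dict(
    enc_channels=(8, 16, 16),
    dec_channels=(16, 12),
    final_channels=(),
    down_factor=2,
    lr_init=1e-3,
)


def _mean_organ_dsc(warped_labels, fixed_labels) -> float:
    return float(np.mean([
        dsc(warped_labels.data == c, fixed_labels.data == c)
        for c in ORGAN_LABELS.values()
    ]))


def build_cohort(n: int, seed: int) -> dict:
    """n phantom subjects on the study grid, keyed s00..; deterministic."""
    base = np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)
    return {
        f"s{i:02d}": make_phantom(study_spec(int(s))) for i, s in enumerate(base)
    }


def dl_study(seed: int = 0, epochs: int = 20, n_subjects: int = 28,
             variants=("msk", "sc", "sc_msk"), verbose: bool = False) -> dict:
    """Train each variant on a shared cohort split; report held-out metrics.

    Returns per-variant held-out mean organ DSC, the rigid-only baseline DSC,
    per-organ folding percentages of the predicted fields, and the training
    history tail.
    """
    cohort = build_cohort(n_subjects, seed)
    plan = make_splits(sorted(cohort), seed=seed + 7)
    fold = plan.folds[0]
    pairs = {s: RegPair.from_phantom(cohort[s], s) for s in cohort}

    rigid = float(np.mean([
        _mean_organ_dsc(pairs[s].moving_labels, pairs[s].fixed_labels)
        for s in fold["test"]
    ]))

    out = {"rigid_mean_dsc": rigid, "split": fold, "variants": {}}
    for variant in variants:
        cfg = RegNetConfig(variant=variant, epochs=epochs, seed=seed, **DEFAULT_NET)
        net, hist = train(
            cfg,
            [pairs[s] for s in fold["train"]],
            [pairs[s] for s in fold["val"]],
            verbose=verbose,
        )
        test_scores, folds_by_organ = [], {o: [] for o in ORGAN_LABELS}
        for s in fold["test"]:
            p = pairs[s]
            fld = net.predict(p)
            warped = warp(p.moving_labels, fld)
            test_scores.append(_mean_organ_dsc(warped, p.fixed_labels))
            for organ, code in ORGAN_LABELS.items():
                folds_by_organ[organ].append(
                    fold_pct(fld, p.fixed_labels.data == code)
                )
        out["variants"][variant] = {
            "test_mean_dsc": float(np.mean(test_scores)),
            "per_subject_dsc": test_scores,
            "fold_pct": {o: float(np.mean(v)) for o, v in folds_by_organ.items()},
            "best_epoch": net.best_epoch,
            "final_train_loss": hist[-1]["train_loss"],
            "first_train_loss": hist[0]["train_loss"],
        }
    return out


def ffd_study(seed: int = 0, warp_amp_mm: float = 4.0) -> dict:
    """FFD recovery of a pure sinusoidal warp against the analytic field."""
    pair = make_phantom(
        study_spec(seed, bladder_scale=1.0, prostate_shift_mm=0.0,
                   warp_amp_mm=warp_amp_mm)
    )
    fixed = clip_normalize(pair.planning_image)
    moving = clip_normalize(pair.daily_image)
    fld = ffd_register(fixed, moving, FFDConfig(seed=seed))
    body = pair.planning_labels.data >= 1
    epe = np.linalg.norm(
        fld.displacement - pair.true_field.displacement, axis=-1
    )
    nmi_before = nmi_loss(fixed, moving)
    nmi_after = nmi_loss(fixed, warp(moving, fld))
    return {
        "mean_epe_mm": float(epe[body].mean()),
        "mean_epe_voxels": float((epe[body] / pair.planning_labels.spacing[0]).mean()),
        "nmi_before": nmi_before,
        "nmi_after": nmi_after,
        "nmi_improved": bool(nmi_after < nmi_before),
        "fold_pct_body": fold_pct(fld, body),
    }


def dose_study(seed: int = 0, n_fractions: int = 5) -> dict:
    """Accumulate fraction doses through exact fields; compare DVH indices.

    Fractions share the planning anatomy (deterministic geometry) and differ
    in their daily deformations; under dose deformation-invariance each
    fraction dose is the planning dose itself, pulled back through the
    fraction's true field.
    """
    base = np.random.default_rng(seed).integers(0, 2**31 - 1, size=n_fractions)
    fracs = [make_phantom(study_spec(int(s))) for s in base]
    ref = fracs[0]
    plan_dose = ref.planning_dose
    frac_doses = [
        fraction_dose(plan_dose, RigidTransform(), frame_id=f"fraction_{k}")
        for k in range(n_fractions)
    ]
    acc = accumulate(frac_doses, [f.true_field for f in fracs])
    planned_total = ImageVolume(
        plan_dose.data * n_fractions, plan_dose.spacing, plan_dose.origin,
        plan_dose.frame_id,
    )
    plan_ix = dvh_indices(planned_total, ref.planning_labels)
    acc_ix = dvh_indices(acc.dose, ref.planning_labels)
    diff = dose_report(plan_ix, acc_ix)
    rel = abs(diff["prostate"]["Dmean"]) / plan_ix["prostate"]["Dmean"]
    return {
        "planning": plan_ix,
        "accumulated": acc_ix,
        "difference": diff,
        "prostate_dmean_rel_dev": float(rel),
        "n_fractions": n_fractions,
    }
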