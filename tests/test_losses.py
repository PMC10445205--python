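"""Registration losses: closed forms, oracle checks, gradient correctness."""

import numpy as np
import pytest

from dosewarp.fields import DeformationField
from dosewarp.grids import ImageVolume, LabelVolume
from dosewarp.losses import (
    l1_grad,
    mask_l1_loss,
    nmi_loss,
    nmi_loss_grad,
    one_hot,
    smoothness_grad,
    smoothness_loss,
    total_loss,
)


def histogram_mi_oracle(a, b, bins):
    """Plain hard-binned MI/NMI estimate, independent of the soft-binned path."""
    h, _, _ = np.histogram2d(a.ravel(), b.ravel(), bins=bins, range=[[0, 1], [0, 1]])
    p = h / h.sum()
    pa, pb = p.sum(1), p.sum(0)
    def ent(q):
        q = q[q > 0]
        return -(q * np.log(q)).sum()
    return (ent(pa) + ent(pb)) / ent(p)


class TestNMI:
    def test_self_similarity_beats_shuffled(self, rng):
        x = rng.uniform(0, 1, size=(12, 12, 12))
        sh = rng.permutation(x.ravel()).reshape(x.shape)
        assert nmi_loss(x, x) < nmi_loss(x, sh)

    def test_symmetric(self, rng):
        a = rng.uniform(0, 1, size=(10, 10, 10))
        b = np.clip(a + rng.normal(0, 0.2, a.shape), 0, 1)
        assert nmi_loss(a, b) == pytest.approx(nmi_loss(b, a), abs=1e-6)

    def test_invariant_under_intensity_flip(self, rng):
        # MI is invariant under bijective remapping; binning is mirror-symmetric
        x = rng.uniform(0, 1, size=(12, 12, 12))
        assert nmi_loss(x, 1.0 - x) == pytest.approx(nmi_loss(x, x), abs=0.02)

    def test_independent_noise_near_oracle_independence_value(self, rng):
        a = rng.uniform(0, 1, size=(16, 16, 16))
        b = rng.uniform(0, 1, size=(16, 16, 16))
        oracle = histogram_mi_oracle(a, b, 32)
        assert -nmi_loss(a, b) == pytest.approx(oracle, abs=0.05)
        assert -nmi_loss(a, b) == pytest.approx(1.0, abs=0.1)

    def test_tracks_hard_histogram_oracle(self, rng):
        a = rng.uniform(0, 1, size=(14, 14, 14))
        b = np.clip(0.7 * a + 0.3 * rng.uniform(0, 1, a.shape), 0, 1)
        assert -nmi_loss(a, b, bins=32) == pytest.approx(
            histogram_mi_oracle(a, b, 32), abs=0.08
        )

    def test_constant_image_fallback_no_nan(self):
        y = np.linspace(0, 1, 216).reshape(6, 6, 6)
        # exactly-on-bin constant: zero marginal entropy -> defined fallback
        x = np.zeros((6, 6, 6))
        val, grad = nmi_loss_grad(x, y)
        assert val == -1.0 and np.all(grad == 0)
        # constant between bin centers still has tiny entropy; must stay finite
        assert np.isfinite(nmi_loss(np.full((6, 6, 6), 0.5), y))

    def test_bins_validated(self, rng):
        x = rng.uniform(size=(4, 4, 4))
        with pytest.raises(ValueError):
            nmi_loss(x, x, bins=4)

    def test_gradient_matches_finite_differences(self, rng):
        a = rng.uniform(0, 1, size=(8, 8, 8))
        b = np.clip(a + rng.normal(0, 0.1, a.shape), 0.01, 0.99)
        _, g = nmi_loss_grad(a, b, bins=16)
        eps = 1e-6
        for idx in [(1, 2, 3), (4, 4, 4), (7, 0, 5)]:
            bp, bm = b.copy(), b.copy()
            bp[idx] += eps
            bm[idx] -= eps
            fd = (nmi_loss_grad(a, bp, 16)[0] - nmi_loss_grad(a, bm, 16)[0]) / (2 * eps)
            assert g[idx] == pytest.approx(fd, rel=1e-4, abs=1e-9)


class TestMaskL1:
    def test_identical_is_zero(self, rng):
        lab = rng.integers(0, 5, size=(8, 8, 8))
        assert mask_l1_loss(lab, lab) == 0.0

    def test_disjoint_masks_closed_form(self):
        # two disjoint single-organ masks, each a fraction f of the volume -> 2f
        n = 10
        a = np.zeros((n, n, n), dtype=int)
        b = np.zeros_like(a)
        a[:2] = 4  # f = 0.2
        b[2:4] = 4
        f = 0.2
        assert mask_l1_loss(a, b) == pytest.approx(2 * f)

    def test_decreases_monotonically_with_realignment(self):
        base = np.zeros((20, 8, 8), dtype=int)
        base[4:9] = 3
        losses = []
        for shift in range(5, -1, -1):
            moved = np.roll(base, shift, axis=0)
            losses.append(mask_l1_loss(base, moved))
        assert all(l1 > l2 for l1, l2 in zip(losses, losses[1:]))
        assert losses[-1] == 0.0

    def test_invalid_codes_rejected(self):
        with pytest.raises(ValueError):
            mask_l1_loss(np.full((4, 4, 4), 9), np.zeros((4, 4, 4), dtype=int))

    def test_gradient_is_signed_mismatch(self):
        f = one_hot(np.zeros((4, 4, 4), dtype=int))
        w = one_hot(np.full((4, 4, 4), 4, dtype=int))
        loss, g = l1_grad(f, w)
        assert loss == pytest.approx(1.0)  # prostate channel all-mismatch
        assert g.shape == f.shape
        np.testing.assert_allclose(g[3], 1.0 / 64)  # prostate channel, warped too high


class TestSmoothness:
    def test_zero_and_constant_fields(self):
        assert smoothness_loss(np.zeros((3, 5, 5, 5))) == 0.0
        assert smoothness_loss(np.full((3, 5, 5, 5), 7.3)) == 0.0

    @pytest.mark.parametrize("c", [0.5, 2.0])
    def test_linear_field_closed_form(self, c):
        # u_x = c * x index: every forward difference along x is c for one of
        # the nine (component, axis) pairs -> loss = c^2 / 9
        shape = (6, 7, 8)
        u = np.zeros((3,) + shape)
        u[0] = c * np.arange(shape[0])[:, None, None]
        assert smoothness_loss(u) == pytest.approx(c**2 / 9.0, abs=1e-6)

    def test_accepts_deformation_field_in_mm(self):
        u = np.zeros((5, 5, 5, 3))
        u[..., 1] = 2.0 * np.arange(5)[None, :, None]
        fld = DeformationField(u, spacing=(2.0, 2.0, 2.0))
        assert smoothness_loss(fld) == pytest.approx(4.0 / 9.0)

    def test_gradient_matches_finite_differences(self, rng):
        u = rng.normal(size=(3, 5, 5, 5))
        _, g = smoothness_grad(u)
        eps = 1e-6
        for idx in [(0, 1, 2, 3), (2, 4, 0, 1)]:
            up, um = u.copy(), u.copy()
            up[idx] += eps
            um[idx] -= eps
            fd = (smoothness_grad(up)[0] - smoothness_grad(um)[0]) / (2 * eps)
            assert g[idx] == pytest.approx(fd, rel=1e-5, abs=1e-10)


class TestTotalLoss:
    def _volumes(self, rng):
        img = ImageVolume(rng.uniform(0, 1, (8, 8, 8)), spacing=1.0)
        lab = LabelVolume(rng.integers(0, 5, (8, 8, 8)), spacing=1.0)
        fld = DeformationField(np.zeros((8, 8, 8, 3)), (1, 1, 1))
        return img, lab, fld

    def test_perfect_alignment_floors(self, rng):
        img, lab, fld = self._volumes(rng)
        total, comps = total_loss("sc_msk", fld, fixed=img, warped_moving=img,
                                  fixed_labels=lab, warped_labels=lab)
        assert comps["l1"] == 0.0
        assert comps["smooth"] == 0.0
        # self-similarity floor: equals the direct self-NMI, well below the
        # independence value (soft binning keeps it above the hard-bin -2)
        assert comps["nmi"] == nmi_loss(img, img)
        assert comps["nmi"] < -1.4

    def test_default_weights_follow_variant_table(self, rng):
        img, lab, fld = self._volumes(rng)
        _, comps = total_loss("msk", fld, fixed_labels=lab, warped_labels=lab)
        assert set(comps) == {"l1", "smooth"}
        total, comps = total_loss(
            "sc_msk", fld, fixed=img, warped_moving=img,
            fixed_labels=lab, warped_labels=lab,
        )
        assert total == pytest.approx(
            1.0 * comps["nmi"] + 2.0 * comps["l1"] + 4.0 * comps["smooth"]
        )

    def test_doubling_label_weight_doubles_contribution(self, rng):
        img, lab, fld = self._volumes(rng)
        other = LabelVolume(rng.integers(0, 5, (8, 8, 8)), spacing=1.0)
        t1, c1 = total_loss("msk", fld, fixed_labels=lab, warped_labels=other)
        t2, c2 = total_loss("msk", fld, fixed_labels=lab, warped_labels=other,
                            weights={"l1": 4.0})
        assert c1["l1"] == c2["l1"]
        assert t2 - t1 == pytest.approx(2.0 * c1["l1"])

    def test_missing_labels_rejected(self, rng):
        img, lab, fld = self._volumes(rng)
        with pytest.raises(ValueError):
            total_loss("msk", fld)
        with pytest.raises(ValueError):
            total_loss("sc_msk", fld, fixed=img, warped_moving=img)
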