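"""Geometric metrics against brute-force oracles and closed forms."""

import numpy as np
import pytest

from dosewarp.fields import DeformationField
from dosewarp.grids import GridError
from dosewarp.metrics import (
    asd,
    dsc,
    fold_pct,
    hd,
    hd95,
    jacobian_det,
    surface_distances,
    surface_voxels,
)

# ---------------------------------------------------------------------------
# brute-force oracle: O(|SA|*|SB|) double loop with the same surface rule
# ---------------------------------------------------------------------------

def brute_surface(mask):
    out = np.zeros_like(mask, dtype=bool)
    nx, ny, nz = mask.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if not mask[i, j, k]:
                    continue
                for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                          (0, 0, 1), (0, 0, -1)):
                    a, b, c = i + d[0], j + d[1], k + d[2]
                    if not (0 <= a < nx and 0 <= b < ny and 0 <= c < nz):
                        out[i, j, k] = True
                        break
                    if not mask[a, b, c]:
                        out[i, j, k] = True
                        break
    return out


def brute_directed(a, b, spacing):
    pa = np.argwhere(brute_surface(a)) * spacing
    pb = np.argwhere(brute_surface(b)) * spacing
    return np.array([np.sqrt(((p - pb) ** 2).sum(axis=1)).min() for p in pa])


def random_mask(rng, shape):
    """A random blobby nonempty mask."""
    while True:
        n = rng.integers(1, 4)
        m = np.zeros(shape, dtype=bool)
        for _ in range(n):
            c = rng.uniform(0, np.array(shape) - 1, size=3)
            r = rng.uniform(1.0, max(shape) / 2)
            idx = np.stack(np.meshgrid(*[np.arange(s) for s in shape],
                                       indexing="ij"), axis=-1)
            m |= ((idx - c) ** 2).sum(-1) <= r**2
        if m.any():
            return m


class TestDice:
    def test_equal_nonempty_is_one(self):
        m = np.zeros((5, 5, 5), dtype=bool)
        m[1:3] = True
        assert dsc(m, m) == 1.0

    def test_disjoint_is_zero_and_both_empty_is_one(self):
        a = np.zeros((5, 5, 5), dtype=bool)
        b = np.zeros_like(a)
        a[0], b[4] = True, True
        assert dsc(a, b) == 0.0
        assert dsc(np.zeros_like(a), np.zeros_like(a)) == 1.0

    def test_counting_example(self, rng):
        # |A|=100, |B|=60, |A∩B|=40 -> 2*40/160 = 0.5
        a = np.zeros(1000, dtype=bool)
        b = np.zeros(1000, dtype=bool)
        a[:100] = True
        b[60:120] = True
        assert dsc(a.reshape(10, 10, 10), b.reshape(10, 10, 10)) == 0.5

    def test_symmetry(self, rng):
        a = random_mask(rng, (10, 10, 10))
        b = random_mask(rng, (10, 10, 10))
        assert dsc(a, b) == dsc(b, a)

    def test_shape_mismatch(self):
        with pytest.raises(GridError):
            dsc(np.ones((3, 3, 3), bool), np.ones((4, 4, 4), bool))


class TestSurfaceDistances:
    def test_two_point_distance(self):
        a = np.zeros((9, 9, 9), bool)
        b = np.zeros_like(a)
        a[2, 4, 4] = True
        b[7, 4, 4] = True
        d_ab, d_ba = surface_distances(a, b, spacing=(2.0, 1.0, 1.0))
        assert d_ab == pytest.approx([10.0])  # 5 voxels * 2 mm
        assert hd(a, b, spacing=(2.0, 1.0, 1.0)) == pytest.approx(10.0)

    def test_identical_masks_zero(self, rng):
        m = random_mask(rng, (8, 8, 8))
        d_ab, d_ba = surface_distances(m, m)
        assert d_ab.max() == 0.0 and d_ba.max() == 0.0
        assert asd(m, m) == hd(m, m) == hd95(m, m) == 0.0

    def test_empty_mask_rejected(self):
        m = np.ones((4, 4, 4), bool)
        with pytest.raises(ValueError):
            surface_distances(m, np.zeros_like(m))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        spacing = rng.uniform(0.5, 3.0, size=3)
        a = random_mask(rng, (12, 11, 10))
        b = random_mask(rng, (12, 11, 10))
        assert np.array_equal(surface_voxels(a), brute_surface(a))
        d_ab, d_ba = surface_distances(a, b, spacing)
        np.testing.assert_array_equal(np.sort(d_ab), np.sort(brute_directed(a, b, spacing)))
        np.testing.assert_array_equal(np.sort(d_ba), np.sort(brute_directed(b, a, spacing)))

    def test_directed_distance_is_asymmetric(self):
        # small box inside the face of a big box: h(A,B) != h(B,A)
        a = np.zeros((12, 12, 12), bool)
        b = np.zeros_like(a)
        a[1:11, 1:11, 1:11] = True
        b[5:7, 5:7, 5:7] = True
        d_ab, d_ba = surface_distances(a, b)
        assert d_ab.max() != d_ba.max()
        assert asd(a, b) != asd(b, a)
        assert asd(a, b, symmetric=True) == asd(b, a, symmetric=True)

    def test_hd95_not_above_hd(self, rng):
        for _ in range(20):
            a = random_mask(rng, (9, 9, 9))
            b = random_mask(rng, (9, 9, 9))
            assert hd95(a, b) <= hd(a, b) + 1e-12


class TestJacobian:
    def _field(self, u, spacing=(1.0, 1.0, 1.0)):
        return DeformationField(u, spacing)

    def test_zero_field_unit_determinant(self):
        det = jacobian_det(self._field(np.zeros((6, 6, 6, 3)))).data
        np.testing.assert_allclose(det, 1.0)

    def test_uniform_scale(self):
        s = 1.1
        shape = (8, 8, 8)
        idx = np.stack(np.meshgrid(*[np.arange(n, dtype=float) for n in shape],
                                   indexing="ij"), axis=-1)
        u = (s - 1.0) * idx  # spacing 1 mm
        det = jacobian_det(self._field(u)).data
        np.testing.assert_allclose(det[1:-1, 1:-1, 1:-1], s**3, atol=1e-6)

    def test_pure_shear_preserves_volume(self):
        shape = (8, 8, 8)
        idx = np.stack(np.meshgrid(*[np.arange(n, dtype=float) for n in shape],
                                   indexing="ij"), axis=-1)
        u = np.zeros(shape + (3,))
        u[..., 0] = 0.3 * idx[..., 1]  # x displaced by y: shear
        det = jacobian_det(self._field(u)).data
        np.testing.assert_allclose(det[1:-1, 1:-1, 1:-1], 1.0, atol=1e-9)

    def test_composition_det_is_product_to_first_order(self, rng):
        shape = (10, 10, 10)
        idx = np.stack(np.meshgrid(*[np.arange(n, dtype=float) for n in shape],
                                   indexing="ij"), axis=-1)
        def smooth(seed, amp=0.02):
            r = np.random.default_rng(seed)
            ph = r.uniform(0, 2 * np.pi, 3)
            u = np.stack([
                amp * np.sin(2 * np.pi * idx[..., (a + 1) % 3] / 10 + ph[a])
                for a in range(3)
            ], axis=-1)
            return u
        u1, u2 = smooth(0), smooth(1)
        # compose: x -> x + u2 + u1(x + u2) ~ u1 + u2 at small amplitude
        comp = u1 + u2
        d1 = jacobian_det(self._field(u1)).data
        d2 = jacobian_det(self._field(u2)).data
        dc = jacobian_det(self._field(comp)).data
        np.testing.assert_allclose(dc, d1 * d2, atol=1e-3)


class TestFolding:
    def test_identity_zero_percent(self):
        fld = DeformationField(np.zeros((6, 6, 6, 3)), (1, 1, 1))
        assert fold_pct(fld, np.ones((6, 6, 6), bool)) == 0.0

    def test_sawtooth_folds_exact_count(self):
        # u_x = -2 on the single plane x=6, zero elsewhere; central differences
        # give du/dx = -1 exactly at x=5 (det J = 0 there, positive elsewhere),
        # so exactly one 6x6 plane of the 12x6x6 mask folds: m/n = 36/432.
        n = 12
        u = np.zeros((n, 6, 6, 3))
        u[6, :, :, 0] = -2.0
        fld = DeformationField(u, (1, 1, 1))
        mask = np.ones((n, 6, 6), bool)
        assert fold_pct(fld, mask) == pytest.approx(100.0 * 36 / 432)

    def test_empty_mask_rejected(self):
        fld = DeformationField(np.zeros((4, 4, 4, 3)), (1, 1, 1))
        with pytest.raises(ValueError):
            fold_pct(fld, np.zeros((4, 4, 4), bool))

    def test_phantom_true_field_never_folds(self, study_pair):
        for code in (2, 3, 4):
            mask = study_pair.planning_labels.data == code
            assert fold_pct(study_pair.true_field, mask) == 0.0
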