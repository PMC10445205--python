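"""Fraction dose mapping, accumulation and DVH indices."""

import numpy as np
import pytest

from dosewarp.dose import (
    GETUG_INDEX_SET,
    accumulate,
    dose_report,
    dvh,
    dvh_indices,
    fraction_dose,
    wall_mask,
)
from dosewarp.fields import DeformationField
from dosewarp.grids import ImageVolume, LabelVolume, RigidTransform


def _dose(data, spacing=(1.0, 1.0, 1.0)):
    return ImageVolume(np.asarray(data, dtype=float), spacing=spacing,
                       frame_id="planning")


class TestFractionDose:
    def test_identity_rigid_preserves_dose(self, rng):
        d = _dose(rng.uniform(0, 80, (8, 8, 8)))
        out = fraction_dose(d, RigidTransform())
        np.testing.assert_array_equal(out.data, d.data)

    def test_two_voxel_translation_shifts_exactly(self, rng):
        d = _dose(rng.uniform(0, 80, (10, 10, 10)), spacing=(2.0, 2.0, 2.0))
        t = RigidTransform(translation=(4.0, 0.0, 0.0))  # +2 voxels in x
        out = fraction_dose(d, t)
        np.testing.assert_allclose(out.data[:8], d.data[2:], atol=1e-4)

    def test_rigid_round_trip_recovers_interior(self):
        # a linear dose ramp is reproduced exactly by trilinear interpolation,
        # isolating the transform round-trip error itself
        idx = np.stack(np.meshgrid(*[np.arange(12.0)] * 3, indexing="ij"), axis=-1)
        d = _dose(1.5 * idx[..., 0] + 0.8 * idx[..., 1] + 0.4 * idx[..., 2] + 10.0)
        t = RigidTransform(rotation=(0.05, -0.03, 0.08),
                           translation=(1.0, -2.0, 0.5), center=(6, 6, 6))
        fwd = fraction_dose(d, t)
        back = fraction_dose(fwd, t.inverse(), frame_id="planning")
        interior = (slice(3, -3),) * 3
        np.testing.assert_allclose(back.data[interior], d.data[interior], atol=1e-3)


class TestAccumulate:
    def _identity_fields(self, shape, n):
        return [DeformationField.zero(shape, (1, 1, 1)) for _ in range(n)]

    def test_identity_fields_sum_exactly(self, rng):
        d = _dose(rng.uniform(0, 2, (6, 6, 6)))
        acc = accumulate([d] * 5, self._identity_fields(d.shape, 5))
        np.testing.assert_allclose(acc.dose.data, 5 * d.data, atol=1e-12)

    def test_linear_in_each_fraction(self, rng):
        d = _dose(rng.uniform(0, 2, (6, 6, 6)))
        flds = self._identity_fields(d.shape, 3)
        base = accumulate([d] * 3, flds).dose.data
        doubled = accumulate([d, _dose(2 * d.data), d], flds).dose.data
        np.testing.assert_allclose(doubled - base, d.data, atol=1e-12)

    def test_order_invariant(self, rng):
        doses = [_dose(rng.uniform(0, 2, (6, 6, 6))) for _ in range(3)]
        u = rng.normal(0, 0.5, size=(6, 6, 6, 3))
        flds = [DeformationField(u * k, (1, 1, 1)) for k in (0.5, 1.0, 1.5)]
        a = accumulate(doses, flds).dose.data
        b = accumulate(doses[::-1], flds[::-1]).dose.data
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_length_mismatch_rejected(self, rng):
        d = _dose(rng.uniform(size=(4, 4, 4)))
        with pytest.raises(ValueError):
            accumulate([d, d], self._identity_fields(d.shape, 3))
        with pytest.raises(ValueError):
            accumulate([d], self._identity_fields(d.shape, 1), n_expected=5)


class TestDVH:
    def _mask(self, shape=(10, 10, 10)):
        m = np.zeros(shape, bool)
        m[2:8] = True
        return m

    def test_uniform_dose_indices(self):
        m = self._mask()
        d = _dose(np.where(m, 80.0, 0.0))
        c = dvh(d, m)
        assert c.dmean == pytest.approx(80.0)
        assert c.d98 == pytest.approx(80.0, abs=0.1)
        assert c.v_at(76.0) == 100.0
        assert c.v_at(81.0) == 0.0

    def test_linear_ramp_closed_form(self):
        n = 101
        vals = np.linspace(0, 100, n)
        d = _dose(np.tile(vals[:, None, None], (1, 3, 3)))
        m = np.ones(d.shape, bool)
        c = dvh(d, m, bin_width=0.1)
        assert c.v_at(50.0) == pytest.approx(50.0, abs=1.0)
        assert c.d_at(98.0) == pytest.approx(2.0, abs=0.2)

    def test_dmean_binning_independent(self, rng):
        d = _dose(rng.uniform(0, 80, (8, 8, 8)))
        m = self._mask((8, 8, 8))
        assert dvh(d, m, bin_width=5.0).dmean == pytest.approx(
            d.data[m].mean(), abs=1e-9
        )

    def test_curve_monotone_and_anchored(self, rng):
        d = _dose(rng.uniform(0, 80, (8, 8, 8)))
        c = dvh(d, self._mask((8, 8, 8)))
        assert np.all(np.diff(c.volume_pct) <= 1e-12)
        assert c.volume_pct[0] == 100.0
        assert d.data.min() <= c.dmean <= d.data.max()

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            dvh(_dose(np.zeros((4, 4, 4))), np.zeros((4, 4, 4), bool))


class TestDoseReport:
    def _labels(self):
        lab = np.zeros((12, 12, 12), dtype=int)
        lab[:, :4] = 2   # rectum
        lab[:, 4:8] = 3  # bladder
        lab[:, 8:] = 4   # prostate
        return LabelVolume(lab, spacing=1.0)

    def test_equal_doses_zero_differences(self, rng):
        lab = self._labels()
        d = _dose(rng.uniform(60, 80, lab.shape))
        ix = dvh_indices(d, lab)
        diff = dose_report(ix, ix)
        for organ, vals in diff.items():
            for v in vals.values():
                assert v == 0.0

    def test_uniform_shift_moves_dmean_only_by_shift(self, rng):
        lab = self._labels()
        d = _dose(rng.uniform(60, 80, lab.shape))
        d2 = _dose(d.data + 1.0)
        diff = dose_report(dvh_indices(d, lab), dvh_indices(d2, lab))
        for organ in diff:
            assert diff[organ]["Dmean"] == pytest.approx(1.0, abs=1e-9)

    def test_getug_index_set(self):
        assert set(GETUG_INDEX_SET["prostate"]) == {"Dmean", "D98", "V76"}
        assert set(GETUG_INDEX_SET["bladder"]) == {"Dmean", "V70"}
        assert set(GETUG_INDEX_SET["rectum"]) == {"Dmean", "V72"}

    def test_structure_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dose_report({"prostate": {"Dmean": 1}}, {"bladder": {"Dmean": 1}})


class TestWallMask:
    def test_wall_is_boundary_shell(self):
        lab = np.zeros((20, 20, 20), dtype=int)
        idx = np.stack(np.meshgrid(*[np.arange(20)] * 3, indexing="ij"), axis=-1)
        ball = ((idx - 10) ** 2).sum(-1) <= 64
        lab[ball] = 3
        lv = LabelVolume(lab, spacing=1.0)
        wall = wall_mask(lv, "bladder", thickness_mm=3.0)
        assert wall.sum() > 0
        assert wall.sum() < ball.sum()
        assert not wall[10, 10, 10]  # core excluded
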