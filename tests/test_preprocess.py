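import numpy as np
import pytest

import nibabel as nib

import topovox as tv
from topovox.preprocess import DegenerateROIError


def _grid(data, mask=None, spacing=None):
    return tv.VoxelGrid(data=np.asarray(data, float), mask=mask, spacing=spacing)


class TestIO:
    def test_nifti_round_trip_preserves_data_and_spacing(self, tmp_path):
        rng = np.random.default_rng(0)
        for spacing in [(1, 1, 1), (2, 2, 2), (0.5, 1.0, 2.0)]:
            g = _grid(rng.normal(size=(4, 4, 4)), spacing=spacing)
            p = tmp_path / "v.nii.gz"
            tv.save_volume(g, p)
            back = tv.load_volume(p)
            assert back.shape == (4, 4, 4)
            assert back.spacing == pytest.approx(spacing)
            np.testing.assert_allclose(back.data, g.data, rtol=1e-6)

    def test_mask_round_trip(self, tmp_path):
        g = _grid(np.zeros((3, 3, 3)), mask=np.eye(3)[..., None].repeat(3, 2) > 0)
        tv.save_volume(g, tmp_path / "v.nii", mask_path=tmp_path / "m.nii")
        back = tv.load_volume(tmp_path / "v.nii", mask_path=tmp_path / "m.nii")
        np.testing.assert_array_equal(back.mask, g.mask)

    def test_non_3d_image_rejected(self, tmp_path):
        img = nib.Nifti1Image(np.zeros((4, 4), dtype=np.float32), np.eye(4))
        nib.save(img, tmp_path / "flat.nii")
        with pytest.raises(ValueError, match="3D"):
            tv.load_volume(tmp_path / "flat.nii")


class TestResample:
    def test_already_isotropic_is_bit_identical(self):
        rng = np.random.default_rng(1)
        g = _grid(rng.normal(size=(5, 6, 7)), spacing=(1, 1, 1))
        out = tv.resample_isotropic(g, 1.0)
        np.testing.assert_array_equal(out.data, g.data)

    def test_shape_follows_rounding_rule(self):
        g = _grid(np.zeros((8, 8, 8)), spacing=(2, 2, 2))
        out = tv.resample_isotropic(g, 1.0)
        assert out.shape == (16, 16, 16)
        assert out.spacing == (1.0, 1.0, 1.0)
        g2 = _grid(np.zeros((10, 8, 6)), spacing=(1.0, 1.5, 2.5))
        assert tv.resample_isotropic(g2, 1.0).shape == (10, 12, 15)

    def test_mask_stays_binary_under_resampling(self):
        rng = np.random.default_rng(2)
        m = rng.uniform(size=(6, 6, 6)) > 0.5
        g = _grid(rng.normal(size=(6, 6, 6)), mask=m, spacing=(2, 2, 2))
        out = tv.resample_isotropic(g, 1.0)
        assert set(np.unique(out.mask.astype(int))) <= {0, 1}
        out2 = tv.resample_isotropic(_grid(m.astype(float), spacing=(2, 2, 2)),
                                     1.0, is_mask=True)
        assert set(np.unique(out2.data)) <= {0.0, 1.0}

    def test_resample_idempotent_on_constant_blocks(self):
        # piecewise-constant volume: second resample to same spacing is identity
        g = _grid(np.kron(np.arange(8).reshape(2, 2, 2), np.ones((3, 3, 3))),
                  spacing=(2, 2, 2))
        once = tv.resample_isotropic(g, 1.0)
        twice = tv.resample_isotropic(once, 1.0)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-6)

    def test_nonpositive_target_rejected(self):
        with pytest.raises(ValueError):
            tv.resample_isotropic(_grid(np.zeros((3, 3, 3))), 0.0)


class TestNormalizeROI:
    def test_affine_map_endpoints(self):
        data = np.zeros((3, 1, 1))
        data[:, 0, 0] = [10, 20, 30]
        g = _grid(data, mask=np.ones_like(data, dtype=bool))
        out = tv.normalize_roi(g)
        np.testing.assert_allclose(out.data[:, 0, 0], [0, 127.5, 255])

    def test_constant_roi_maps_to_zero(self):
        g = _grid(np.full((3, 3, 3), 42.0), mask=np.ones((3, 3, 3), bool))
        assert (tv.normalize_roi(g).data == 0).all()

    def test_out_of_mask_untouched_and_endpoints_hit(self):
        rng = np.random.default_rng(3)
        data = rng.normal(size=(5, 5, 5)) * 100
        mask = rng.uniform(size=data.shape) > 0.5
        out = tv.normalize_roi(_grid(data, mask=mask))
        np.testing.assert_array_equal(out.data[~mask], data[~mask])
        assert out.data[mask].min() == 0.0
        assert out.data[mask].max() == 255.0

    def test_invariant_to_affine_intensity_rescaling(self):
        rng = np.random.default_rng(4)
        data = rng.normal(size=(4, 4, 4))
        mask = np.ones(data.shape, bool)
        a = tv.normalize_roi(_grid(data, mask=mask)).data
        b = tv.normalize_roi(_grid(3.7 * data + 11.0, mask=mask)).data
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_empty_mask_rejected(self):
        g = _grid(np.zeros((3, 3, 3)), mask=np.zeros((3, 3, 3), bool))
        with pytest.raises(DegenerateROIError):
            tv.normalize_roi(g)


class TestCrop:
    def test_single_voxel_pad0(self):
        m = np.zeros((5, 5, 5), bool)
        m[2, 3, 1] = True
        out = tv.crop_to_roi(_grid(np.arange(125).reshape(5, 5, 5), mask=m))
        assert out.shape == (1, 1, 1)
        assert out.data[0, 0, 0] == np.arange(125).reshape(5, 5, 5)[2, 3, 1]

    def test_full_mask_identity(self):
        g = _grid(np.arange(27).reshape(3, 3, 3), mask=np.ones((3, 3, 3), bool))
        out = tv.crop_to_roi(g)
        np.testing.assert_array_equal(out.data, g.data)

    def test_bounding_box_arithmetic_with_pad(self):
        m = np.zeros((10, 10, 10), bool)
        m[2:6, 2:6, 2:6] = True   # occupies [2,5]^3
        out = tv.crop_to_roi(_grid(np.zeros((10, 10, 10)), mask=m), pad=1)
        assert out.shape == (6, 6, 6)

    def test_pad_clipped_to_volume(self):
        m = np.zeros((4, 4, 4), bool)
        m[0, 0, 0] = True
        out = tv.crop_to_roi(_grid(np.zeros((4, 4, 4)), mask=m), pad=10)
        assert out.shape == (4, 4, 4)


class TestDice:
    def test_pinned_values(self):
        a = np.zeros((10, 10), bool); a[:5] = True
        assert tv.dice_coefficient(a, a) == 1.0
        b = np.zeros((10, 10), bool); b[5:] = True
        assert tv.dice_coefficient(a, b) == 0.0
        # |A|=|B|=100, |A∩B|=80
        a = np.zeros(300, bool); b = np.zeros(300, bool)
        a[:100] = True; b[20:120] = True
        assert tv.dice_coefficient(a, b) == pytest.approx(0.8)

    def test_symmetric_and_identity_iff_equal(self):
        rng = np.random.default_rng(5)
        a = rng.uniform(size=(6, 6)) > 0.4
        b = rng.uniform(size=(6, 6)) > 0.4
        assert tv.dice_coefficient(a, b) == tv.dice_coefficient(b, a)
        if not np.array_equal(a, b):
            assert tv.dice_coefficient(a, b) < 1.0

    def test_both_empty_is_one_and_mismatch_rejected(self):
        assert tv.dice_coefficient(np.zeros(4, bool), np.zeros(4, bool)) == 1.0
        with pytest.raises(ValueError):
            tv.dice_coefficient(np.zeros(4, bool), np.zeros(5, bool))
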