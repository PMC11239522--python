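"""Ventricle masking: downsampling, voxel classifier, mask up/down, apply."""

import numpy as np
import pytest
from scipy import ndimage

from somamap.types import ImageStack, MaskStack
from somamap.ventricle import (VoxelClassifier, apply_mask, downsample_iso,
                               predict_mask, train_voxel_classifier,
                               upsample_mask)


def _toy_pair(size=24, sp=25.0, hi=200, lo=100, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    vol = np.full((size,) * 3, float(lo))
    lab = np.zeros((size,) * 3, np.uint8)
    lab[size // 3:2 * size // 3, size // 3:2 * size // 3, size // 3:2 * size // 3] = 1
    vol[lab == 1] = hi
    if noise:
        vol += rng.normal(0, noise, vol.shape)
    return (ImageStack(np.clip(vol, 0, 65535).astype(np.uint16), (sp,) * 3),
            MaskStack(lab, (sp,) * 3))


class TestDownsample:
    def test_identity_when_already_at_target(self):
        s = ImageStack(np.random.default_rng(0).integers(
            0, 1000, (20, 20, 20)).astype(np.uint16), (25, 25, 25))
        out = downsample_iso(s, 25.0)
        assert out.shape == s.shape
        assert np.array_equal(out.voxels, s.voxels)

    def test_constant_stays_constant(self):
        s = ImageStack(np.full((40, 40, 40), 321, np.uint16), (6, 1.625, 1.625))
        out = downsample_iso(s, 25.0)
        assert np.all(out.voxels == 321)
        assert out.spacing_um == (25.0, 25.0, 25.0)

    def test_output_dims_ceil_rule(self):
        # 160 voxels at 6 um -> ceil(960/25)=39; at 1.625 um -> ceil(260/25)=11
        s = ImageStack(np.zeros((160, 160, 160), np.uint16), (6, 1.625, 1.625))
        assert downsample_iso(s, 25.0).shape == (39, 11, 11)

    def test_upsampling_rejected(self):
        s = ImageStack(np.zeros((8, 8, 8), np.uint16), (25, 25, 25))
        with pytest.raises(ValueError):
            downsample_iso(s, 10.0)


class TestClassifier:
    def test_perfect_separation_recovers_labels(self):
        stack, lab = _toy_pair()
        clf = train_voxel_classifier([stack], [lab], seed=0)
        pred = predict_mask(clf, stack)
        assert (pred.mask == lab.mask).mean() == 1.0
        assert set(np.unique(pred.mask)) <= {0, 1}

    def test_single_class_labels_rejected(self):
        stack, lab = _toy_pair()
        all_bg = MaskStack(np.zeros_like(lab.mask), lab.spacing_um)
        with pytest.raises(ValueError, match="single class"):
            train_voxel_classifier([stack], [all_bg])

    def test_all_zero_stack_predicts_no_ventricle(self):
        stack, lab = _toy_pair(noise=5.0)
        clf = train_voxel_classifier([stack], [lab], seed=0)
        zero = ImageStack(np.zeros_like(stack.voxels), stack.spacing_um)
        assert predict_mask(clf, zero).mask.sum() == 0

    def test_generalizes_across_scenes(self):
        # train on one noisy bright-cube volume, test F1 on another
        tr = _toy_pair(noise=10.0, seed=1)
        te = _toy_pair(noise=10.0, seed=2)
        clf = train_voxel_classifier([tr[0]], [tr[1]], seed=0)
        pred = predict_mask(clf, te[0]).mask.astype(bool)
        ref = te[1].mask.astype(bool)
        tp = (pred & ref).sum()
        f1 = 2 * tp / (pred.sum() + ref.sum())
        assert f1 >= 0.9

    def test_spacing_mismatch_rejected(self):
        stack, lab = _toy_pair()
        clf = train_voxel_classifier([stack], [lab], seed=0)
        other = ImageStack(stack.voxels, (10.0, 10.0, 10.0))
        with pytest.raises(ValueError, match="spacing"):
            predict_mask(clf, other)

    def test_save_load_roundtrip(self, tmp_path):
        stack, lab = _toy_pair()
        clf = train_voxel_classifier([stack], [lab], seed=0)
        clf.save(tmp_path / "clf.joblib")
        back = VoxelClassifier.load(tmp_path / "clf.joblib")
        assert back.feature_spec == clf.feature_spec
        assert np.array_equal(predict_mask(back, stack).mask,
                              predict_mask(clf, stack).mask)


class TestUpsample:
    def test_constants_pass_through(self):
        ones = MaskStack(np.ones((10, 10, 10), np.uint8), (25,) * 3)
        up = upsample_mask(ones, (40, 40, 40))
        assert up.mask.all() and up.shape == (40, 40, 40)
        zeros = MaskStack(np.zeros((10, 10, 10), np.uint8), (25,) * 3)
        assert not upsample_mask(zeros, (40, 40, 40)).mask.any()

    def test_volume_fraction_preserved(self):
        m = np.zeros((10, 10, 10), np.uint8)
        m[2:7, 2:7, 2:7] = 1  # 12.5% cube... fraction tracked below
        frac = m.mean()
        up = upsample_mask(MaskStack(m, (25,) * 3), (40, 40, 40))
        assert abs(up.mask.mean() - frac) < 0.1 * max(frac, 1e-9) + 0.02

    def test_target_smaller_rejected(self):
        m = MaskStack(np.ones((10, 10, 10), np.uint8), (25,) * 3)
        with pytest.raises(ValueError):
            upsample_mask(m, (5, 40, 40))

    def test_round_trip_preserves_smooth_foreground_volume(self):
        # random smooth blobs: downsample then upsample keeps volume ~15%
        rng = np.random.default_rng(0)
        for seed in range(3):
            field = ndimage.gaussian_filter(
                np.random.default_rng(seed).normal(size=(48, 48, 48)), 6)
            m = (field > np.percentile(field, 70)).astype(np.uint8)
            ms = MaskStack(m, (25,) * 3)
            small = ndimage.zoom(m.astype(float), 0.25, order=1) >= 0.5
            up = upsample_mask(MaskStack(small.astype(np.uint8), (100,) * 3),
                               (48, 48, 48))
            rel = abs(int(up.mask.sum()) - int(m.sum())) / m.sum()
            assert rel < 0.15, (seed, rel)


class TestApplyMask:
    def test_empty_mask_is_identity(self):
        s = ImageStack(np.random.default_rng(0).integers(
            0, 500, (8, 8, 8)).astype(np.uint16), (25,) * 3)
        zeros = MaskStack(np.zeros(s.shape, np.uint8), s.spacing_um)
        assert np.array_equal(apply_mask(s, zeros).voxels, s.voxels)

    def test_full_mask_zeroes_everything(self):
        s = ImageStack(np.full((8, 8, 8), 99, np.uint16), (25,) * 3)
        ones = MaskStack(np.ones(s.shape, np.uint8), s.spacing_um)
        assert not apply_mask(s, ones).voxels.any()

    def test_masking_is_idempotent(self):
        rng = np.random.default_rng(3)
        s = ImageStack(rng.integers(0, 500, (8, 8, 8)).astype(np.uint16),
                       (25,) * 3)
        m = MaskStack((rng.random((8, 8, 8)) < 0.3).astype(np.uint8),
                      s.spacing_um)
        once = apply_mask(s, m)
        twice = apply_mask(once, m)
        assert np.array_equal(once.voxels, twice.voxels)

    def test_padding_centers_content(self):
        s = ImageStack(np.full((4, 4, 4), 7, np.uint16), (25,) * 3)
        m = MaskStack(np.zeros((4, 4, 4), np.uint8), s.spacing_um)
        out = apply_mask(s, m, pad_to=(8, 8, 8))
        assert out.shape == (8, 8, 8)
        assert np.all(out.voxels[2:6, 2:6, 2:6] == 7)
        assert out.voxels.sum() == 7 * 64
        assert out.voxels.dtype == np.uint16

    def test_shape_mismatch_rejected(self):
        s = ImageStack(np.zeros((4, 4, 4), np.uint16), (25,) * 3)
        m = MaskStack(np.zeros((5, 4, 4), np.uint8), s.spacing_um)
        with pytest.raises(ValueError):
            apply_mask(s, m)
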