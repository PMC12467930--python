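"""Preprocessing pipeline: normalization, resampling, pad/crop, one-hot,
patch sampling, augmentation, NIfTI round-trips."""

import logging

import numpy as np
import pytest

from gliomark.data import LabelVolume, ModalityStack
from gliomark.phantom import PhantomSpec, generate_phantom
from gliomark.preprocess import (
    AugmentConfig,
    augment,
    one_hot,
    pad_or_crop,
    read_case,
    resample_isotropic,
    sample_tumor_patch,
    uncrop,
    write_case,
    zscore_normalize,
)


class TestZscore:
    def test_hand_computed_three_values(self):
        vol = np.zeros((3, 1, 1))
        vol[:, 0, 0] = [2.0, 4.0, 6.0]
        out = zscore_normalize(vol)
        expect = np.array([-1.224744871, 0.0, 1.224744871])  # population sd
        np.testing.assert_allclose(out[:, 0, 0], expect, atol=1e-8)

    def test_foreground_mean_zero_sd_one(self, rng):
        vol = rng.normal(5, 3, size=(12, 12, 12))
        vol[:3] = 0.0  # background
        out = zscore_normalize(vol)
        fg = out[vol != 0]
        assert abs(fg.mean()) < 1e-10 and abs(fg.std() - 1) < 1e-10
        assert (out[vol == 0] == 0).all()

    def test_idempotent_within_tolerance(self, rng):
        vol = rng.normal(size=(10, 10, 10)) + 10
        once = zscore_normalize(vol)
        twice = zscore_normalize(once, foreground_mask=vol != 0)
        np.testing.assert_allclose(twice, once, atol=1e-5)

    def test_constant_foreground_raises(self):
        with pytest.raises(ValueError, match="degenerate|constant"):
            zscore_normalize(np.full((4, 4, 4), 3.0))


class TestResample:
    def test_identity_at_target_spacing(self, rng):
        vol = rng.normal(size=(10, 10, 10))
        out, sp = resample_isotropic(vol, (1.0, 1.0, 1.0))
        assert sp == (1.0, 1.0, 1.0)
        np.testing.assert_allclose(out, vol, atol=1e-6)

    def test_constant_volume_stays_constant(self):
        vol = np.full((8, 10, 6), 2.5)
        out, _ = resample_isotropic(vol, (2.0, 1.5, 3.0))
        np.testing.assert_allclose(out, 2.5, atol=1e-10)

    def test_linear_ramp_matches_analytic_interior(self):
        # 2 mm -> 1 mm on a ramp along axis 0
        n = 12
        vol = np.broadcast_to(np.arange(n, dtype=float)[:, None, None], (n, n, n)).copy()
        out, _ = resample_isotropic(vol, (2.0, 2.0, 2.0), 1.0)
        assert out.shape == (2 * n, 2 * n, 2 * n)
        # voxel centers: output index i sits at physical (i+0.5)*1mm; input
        # index j at (j+0.5)*2mm -> expected value (i+0.5)/2 - 0.5
        i = np.arange(2 * n)
        expect = (i + 0.5) / 2.0 - 0.5
        interior = slice(2, 2 * n - 2)
        np.testing.assert_allclose(out[interior, n, n], expect[interior], atol=1e-5)

    def test_labels_keep_alphabet(self):
        lab = np.random.default_rng(0).integers(0, 5, size=(9, 9, 9))
        out, _ = resample_isotropic(lab, (2.0, 2.0, 2.0), 1.0, mode="nearest")
        assert set(np.unique(out)) <= set(range(5))

    def test_nonpositive_spacing_rejected(self):
        with pytest.raises(ValueError):
            resample_isotropic(np.ones((4, 4, 4)), (0.0, 1.0, 1.0))


class TestPadCrop:
    def test_identity_when_already_target(self, rng):
        vol = rng.normal(size=(16, 16, 16))
        out, meta = pad_or_crop(vol, (16, 16, 16))
        np.testing.assert_array_equal(out, vol)

    def test_crop_offsets_follow_centering_rule(self):
        vol = np.zeros((250, 250, 250))
        out, meta = pad_or_crop(vol, (240, 240, 155))
        assert out.shape == (240, 240, 155)
        assert [m["crop_low"] for m in meta] == [5, 5, 47]  # (250-155)//2 = 47

    def test_zero_padding_conserves_sum_and_uncrops(self, rng):
        vol = rng.normal(size=(10, 10, 10))
        out, meta = pad_or_crop(vol, (16, 20, 17))
        assert out.shape == (16, 20, 17)
        assert out.sum() == pytest.approx(vol.sum())
        np.testing.assert_array_equal(uncrop(out, meta), vol)

    def test_uncrop_restores_cropped_extent(self, rng):
        vol = rng.normal(size=(12, 12, 12))
        out, meta = pad_or_crop(vol, (8, 8, 8))
        back = uncrop(out, meta)
        assert back.shape == vol.shape
        np.testing.assert_array_equal(back[2:10, 2:10, 2:10], vol[2:10, 2:10, 2:10])


class TestOneHot:
    def test_channel_sums_partition_unity(self, small_phantom):
        oh = one_hot(small_phantom.labels)
        np.testing.assert_array_equal(oh.sum(axis=0), 1.0)

    def test_channel_counts_match_truth_stats(self, small_phantom):
        from gliomark.phantom import phantom_truth_stats

        oh = one_hot(small_phantom.labels)
        counts = phantom_truth_stats(small_phantom)["class_counts"]
        np.testing.assert_array_equal(oh.sum(axis=(1, 2, 3)).astype(int), counts)

    def test_out_of_alphabet_label_rejected(self):
        with pytest.raises(ValueError):
            one_hot(np.array([[[7]]]))


class TestPatchSampling:
    def _stack(self, shape=(40, 40, 40)):
        return ModalityStack(np.random.default_rng(0).normal(size=(4,) + shape))

    def test_single_tumor_voxel_forces_center(self):
        lab = np.zeros((40, 40, 40), dtype=int)
        lab[20, 21, 22] = 2
        p = sample_tumor_patch(self._stack(), LabelVolume(lab), size=16,
                               rng=np.random.default_rng(1))
        assert p.corner == (20 - 8, 21 - 8, 22 - 8)
        assert p.labels[8, 8, 8] == 2

    def test_no_tumor_falls_back_with_warning(self, caplog):
        lab = LabelVolume(np.zeros((40, 40, 40), dtype=int))
        with caplog.at_level(logging.WARNING, logger="gliomark.preprocess"):
            p = sample_tumor_patch(self._stack(), lab, size=16, rng=np.random.default_rng(2))
        assert "no tumor" in caplog.text
        assert p.images.shape == (4, 16, 16, 16)

    def test_two_voxel_tumor_draws_uniformly(self):
        lab = np.zeros((40, 40, 40), dtype=int)
        lab[10, 10, 10] = 1
        lab[30, 30, 30] = 1
        stack = self._stack()
        rng = np.random.default_rng(3)
        hits = sum(
            sample_tumor_patch(stack, LabelVolume(lab), size=8, rng=rng).corner[0] < 20
            for _ in range(1000)
        )
        assert abs(hits - 500) <= 50  # 3 sigma ~ 47

    def test_small_volume_padded_to_patch(self):
        stack = ModalityStack(np.ones((4, 10, 10, 10)))
        p = sample_tumor_patch(stack, None, size=16, rng=np.random.default_rng(4))
        assert p.images.shape == (4, 16, 16, 16)
        assert p.images.sum() == pytest.approx(4 * 1000)

    def test_deterministic_given_seed(self, small_phantom):
        a = sample_tumor_patch(small_phantom.images, small_phantom.labels, 24, rng=5)
        b = sample_tumor_patch(small_phantom.images, small_phantom.labels, 24, rng=5)
        np.testing.assert_array_equal(a.images, b.images)
        assert a.corner == b.corner


class TestAugment:
    def _patch(self):
        from gliomark.data import Patch

        rng = np.random.default_rng(6)
        return Patch(rng.normal(size=(4, 12, 12, 12)),
                     rng.integers(0, 5, size=(12, 12, 12)))

    def _off(self, **kw):
        return AugmentConfig(elastic_prob=0.0, elastic_sd=0.0, flip_prob=0.0,
                             intensity_scale=0.0, intensity_shift=0.0,
                             modality_dropout_prob=0.0, seed=0, **kw)

    def test_all_off_is_bit_identical(self):
        p = self._patch()
        out = augment(p, self._off())
        np.testing.assert_array_equal(out.images, p.images)
        np.testing.assert_array_equal(out.labels, p.labels)

    def test_certain_flip_is_involution(self):
        p = self._patch()
        cfg = self._off()
        cfg.flip_prob = 1.0
        cfg.flip_axes = (0,)
        twice = augment(augment(p, cfg, rng=np.random.default_rng(1)), cfg,
                        rng=np.random.default_rng(2))
        np.testing.assert_array_equal(twice.images, p.images)
        np.testing.assert_array_equal(twice.labels, p.labels)

    def test_flips_preserve_tumor_voxel_count(self):
        p = self._patch()
        cfg = self._off()
        cfg.flip_prob = 1.0
        out = augment(p, cfg, rng=np.random.default_rng(3))
        assert (out.labels > 0).sum() == (p.labels > 0).sum()

    def test_modality_dropout_zeroes_whole_channel_only(self):
        p = self._patch()
        cfg = self._off()
        cfg.modality_dropout_prob = 1.0
        out = augment(p, cfg, rng=np.random.default_rng(4))
        zeroed = [(out.images[i] == 0).all() for i in range(4)]
        assert sum(zeroed) == 3  # never all four dropped
        np.testing.assert_array_equal(out.labels, p.labels)

    def test_elastic_keeps_label_alphabet(self):
        p = self._patch()
        cfg = self._off()
        cfg.elastic_prob, cfg.elastic_sd = 1.0, 3.0
        out = augment(p, cfg, rng=np.random.default_rng(5))
        assert set(np.unique(out.labels)) <= set(range(5))

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            AugmentConfig(flip_prob=1.5)


class TestNiftiIO:
    def test_write_read_roundtrip(self, tmp_path, small_phantom):
        paths = write_case(tmp_path, "c1", small_phantom.images, small_phantom.labels)
        stack, labels = read_case({m: paths[m] for m in ("t1", "t1ce", "t2", "flair")},
                                  paths["seg"])
        np.testing.assert_array_equal(stack.images, small_phantom.images.images)
        np.testing.assert_array_equal(labels.labels, small_phantom.labels.labels)

    def test_shape_mismatch_names_offending_file(self, tmp_path, small_phantom):
        import nibabel as nib

        paths = write_case(tmp_path, "c1", small_phantom.images)
        bad = tmp_path / "bad_flair.nii.gz"
        nib.save(nib.Nifti1Image(np.zeros((4, 4, 4)), np.eye(4)), bad)
        paths["flair"] = str(bad)
        with pytest.raises(ValueError, match="bad_flair"):
            read_case({m: paths[m] for m in ("t1", "t1ce", "t2", "flair")})

    def test_invalid_label_value_rejected(self, tmp_path, small_phantom):
        import nibabel as nib

        paths = write_case(tmp_path, "c1", small_phantom.images)
        lab = np.zeros(small_phantom.labels.shape)
        lab[0, 0, 0] = 7
        seg = tmp_path / "seg7.nii.gz"
        nib.save(nib.Nifti1Image(lab, np.eye(4)), seg)
        with pytest.raises(ValueError, match="7"):
            read_case({m: paths[m] for m in ("t1", "t1ce", "t2", "flair")}, seg)
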