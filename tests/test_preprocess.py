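"""Preprocessing chain: I/O round trips, clipping, resampling, ROI cropping,
label merging, standardization and augmentation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import protoseg as ps
from protoseg.preprocess import apply_affine


class TestLoadVolume:
    def test_written_case_round_trips_voxel_identical(self, small_config, tmp_path):
        man = ps.generate_dataset(1, small_config, seed=3, out_dir=tmp_path)
        entry = man["cases"][0]
        vol, lab = ps.load_volume(tmp_path / entry["image"], tmp_path / entry["label"])
        ref_vol, ref_lab = ps.generate_case(small_config, entry["seed"])
        np.testing.assert_array_equal(vol.data, ref_vol.data)
        np.testing.assert_array_equal(lab.data, ref_lab.data)

    def test_disallowed_label_value_named_in_error(self, tmp_path):
        import nibabel as nib

        nib.save(nib.Nifti1Image(np.zeros((4, 8, 8), np.float32), np.eye(4)), tmp_path / "i.nii")
        bad = np.zeros((4, 8, 8), np.int16)
        bad[1, 2, 3] = 3
        nib.save(nib.Nifti1Image(bad, np.eye(4)), tmp_path / "l.nii")
        with pytest.raises(ValueError, match="3"):
            ps.load_volume(tmp_path / "i.nii", tmp_path / "l.nii")

    def test_missing_file_and_shape_mismatch_are_distinct_errors(self, tmp_path):
        import nibabel as nib

        nib.save(nib.Nifti1Image(np.zeros((4, 8, 8), np.float32), np.eye(4)), tmp_path / "i.nii")
        with pytest.raises(FileNotFoundError):
            ps.load_volume(tmp_path / "i.nii", tmp_path / "nope.nii")
        nib.save(nib.Nifti1Image(np.zeros((4, 8, 9), np.int16), np.eye(4)), tmp_path / "l.nii")
        with pytest.raises(ValueError, match="mismatch"):
            ps.load_volume(tmp_path / "i.nii", tmp_path / "l.nii")


class TestClipHighIntensities:
    def test_exactly_top_fraction_of_distinct_values_clipped(self):
        rng = np.random.default_rng(0)
        vals = rng.permutation(1000).astype(float).reshape(10, 10, 10)
        vol = ps.Volume(vals)
        out = ps.clip_high_intensities(vol, 0.005)
        srt = np.sort(vals.ravel())
        q = srt[994]  # the 6th-largest of 1000 distinct values
        # exactly the top 5 values replaced by q
        assert out.data.max() == q
        assert np.count_nonzero(vals > out.data) == 5
        np.testing.assert_array_equal(out.data[vals <= q], vals[vals <= q])

    def test_fraction_zero_and_constant_volume_are_identity(self):
        vol = ps.Volume(np.full((3, 8, 8), 7.0))
        np.testing.assert_array_equal(ps.clip_high_intensities(vol, 0.0).data, vol.data)
        np.testing.assert_array_equal(ps.clip_high_intensities(vol, 0.1).data, vol.data)

    def test_idempotent(self, case):
        vol, _ = case
        once = ps.clip_high_intensities(vol, 0.005)
        twice = ps.clip_high_intensities(once, 0.005)
        np.testing.assert_array_equal(once.data, twice.data)

    def test_invalid_fraction_rejected(self, case):
        with pytest.raises(ValueError):
            ps.clip_high_intensities(case[0], 0.6)


class TestResampleToSlices:
    def test_150_slices_resample_to_21_preserving_plane(self):
        cfg = ps.SynthConfig(n_slices=150, grid=(64, 64))
        vol, lab = ps.generate_case(cfg, seed=0)
        v, l = ps.resample_to_slices(vol, lab, 21)
        assert v.data.shape == (21, 64, 64)
        assert l.data.shape == (21, 64, 64)

    def test_identity_when_count_matches(self, case):
        vol, lab = case
        v, l = ps.resample_to_slices(vol, lab, vol.data.shape[0])
        np.testing.assert_array_equal(v.data, vol.data)
        np.testing.assert_array_equal(l.data, lab.data)

    def test_label_value_set_closed_under_resampling(self):
        lab = ps.LabelVolume(np.random.default_rng(0).choice([0, 4], size=(30, 8, 8)))
        vol = ps.Volume(np.zeros((30, 8, 8)))
        _, l = ps.resample_to_slices(vol, lab, 7)
        assert set(np.unique(l.data)) <= {0, 4}


class TestCropRoi:
    def test_bounding_box_arithmetic(self):
        lab = np.zeros((5, 64, 64), np.int16)
        lab[2, 10:21, 30:41] = 1
        vol = ps.Volume(np.zeros((5, 64, 64)))
        v, l = ps.crop_roi(vol, ps.LabelVolume(lab), margin=5)
        assert v.data.shape == (5, 21, 21)  # (20-10+1) + 2*5
        assert np.count_nonzero(l.data) == np.count_nonzero(lab)

    def test_margin_clamped_to_grid(self):
        lab = np.zeros((3, 40, 40), np.int16)
        lab[1, 5, 5] = 2
        v, _ = ps.crop_roi(ps.Volume(np.zeros((3, 40, 40))), ps.LabelVolume(lab), margin=100)
        assert v.data.shape == (3, 40, 40)

    def test_all_zero_label_rejected(self):
        with pytest.raises(ValueError):
            ps.crop_roi(
                ps.Volume(np.zeros((3, 40, 40))),
                ps.LabelVolume(np.zeros((3, 40, 40), np.int16)),
            )


def test_binarize_merges_all_tumor_levels():
    lab = ps.LabelVolume(np.array([[[0, 1], [2, 4]]]))
    np.testing.assert_array_equal(ps.binarize_labels(lab), [[[0, 1], [1, 1]]])
    assert ps.binarize_labels(ps.LabelVolume(np.zeros((1, 2, 2), int))).sum() == 0
    assert ps.binarize_labels(ps.LabelVolume(np.full((1, 2, 2), 4))).min() == 1


class TestStandardizeStack:
    def test_shape_contract_and_channel_replication(self, case):
        vol, lab = case
        stack = ps.standardize_stack(vol, ps.binarize_labels(lab))
        n = vol.data.shape[0]
        assert stack.images.shape == (n, 3, 256, 256)
        assert stack.masks.shape == (n, 256, 256)
        np.testing.assert_array_equal(stack.images[:, 0], stack.images[:, 1])
        np.testing.assert_array_equal(stack.images[:, 0], stack.images[:, 2])

    def test_images_in_unit_interval_and_masks_binary(self, stack):
        assert stack.images.min() >= 0.0 and stack.images.max() <= 1.0
        assert set(np.unique(stack.masks)) <= {0, 1}

    def test_constant_volume_normalizes_to_zeros(self):
        vol = ps.Volume(np.full((2, 32, 32), 5.0))
        stack = ps.standardize_stack(vol, np.zeros((2, 32, 32), np.uint8))
        assert np.all(stack.images == 0.0)

    def test_slices_share_volume_wide_calibration(self):
        data = np.zeros((2, 32, 32))
        data[0, 10:20, 10:20] = 100.0  # bright structure on slice 0 only
        data[1, :, :] = 50.0  # mid-intensity tissue slice
        stack = ps.standardize_stack(ps.Volume(data), np.zeros((2, 32, 32), np.uint8))
        # the tissue-only slice is not stretched to full brightness
        assert stack.images[1].max() == pytest.approx(0.5)
        assert stack.images[0].max() == pytest.approx(1.0)


class TestAugment:
    def test_zero_amplitude_bounds_leave_data_unchanged(self, rng):
        imgs = np.random.default_rng(1).uniform(size=(4, 3, 64, 64))
        masks = (np.random.default_rng(2).uniform(size=(4, 64, 64)) > 0.8).astype(np.uint8)
        cfg = ps.AugmentConfig(0.0, 0.0, 0.0, probability=1.0)
        out_i, out_m = ps.augment(imgs, masks, rng, cfg)
        np.testing.assert_allclose(out_i, imgs, atol=1e-12)
        np.testing.assert_array_equal(out_m, masks)

    def test_fixed_rng_state_reproduces(self):
        imgs = np.random.default_rng(1).uniform(size=(4, 3, 64, 64))
        masks = (np.random.default_rng(2).uniform(size=(4, 64, 64)) > 0.8).astype(np.uint8)
        a = ps.augment(imgs, masks, np.random.default_rng(9))
        b = ps.augment(imgs, masks, np.random.default_rng(9))
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_quarter_turn_preserves_foreground_pixel_count(self):
        mask = np.zeros((64, 64), np.uint8)
        mask[10:30, 20:45] = 1
        img = mask.astype(float)
        _, m90 = apply_affine(img, mask, rotation_deg=90.0)
        assert m90.sum() == mask.sum()
        np.testing.assert_array_equal(np.rot90(m90), mask)

    def test_size_unchanged_in_place_replacement(self, rng):
        imgs = np.zeros((5, 3, 32, 32))
        masks = np.zeros((5, 32, 32), np.uint8)
        masks[:, 10, 10] = 1
        out_i, out_m = ps.augment(imgs, masks, rng)
        assert out_i.shape == imgs.shape and out_m.shape == masks.shape


@given(st.integers(min_value=0, max_value=10_000))
def test_full_chain_preserves_binarity_and_unit_range(seed):
    cfg = ps.SynthConfig(n_slices=12, grid=(48, 48))
    vol, lab = ps.generate_case(cfg, seed=seed)
    stack = ps.preprocess_case(vol, lab, n_slices=5)
    assert stack.images.min() >= 0.0 and stack.images.max() <= 1.0
    assert set(np.unique(stack.masks)) <= {0, 1}
    assert stack.images.shape == (5, 3, 256, 256)
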