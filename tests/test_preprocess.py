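import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cascadeseg import (LabelVolume, ModalityStack, augment, classes_to_labels,
                        compose_regions, load_case, onehot, random_crop,
                        remap_labels, write_case, zscore_normalize)
from cascadeseg.preprocess import TrainingSample


def _stack(data):
    return ModalityStack(data=data, affine=np.eye(4), case_id="t")


class TestLoadCase:
    def test_missing_modality_names_it(self, small_phantom, tmp_path):
        write_case(small_phantom, tmp_path)
        (tmp_path / "clean_t1ce.nii.gz").unlink()
        with pytest.raises(FileNotFoundError, match="t1ce"):
            load_case(tmp_path, "clean")

    def test_absent_label_reported_as_none(self, small_phantom, tmp_path):
        write_case(small_phantom, tmp_path)
        (tmp_path / "clean_seg.nii.gz").unlink()
        stack, label = load_case(tmp_path, "clean")
        assert stack.data.shape[0] == 4
        assert label is None

    def test_invalid_label_values_rejected(self):
        with pytest.raises(ValueError, match="invalid"):
            LabelVolume(data=np.full((4, 4, 4), 3), affine=np.eye(4))


class TestZScore:
    def test_hand_computed_channel(self):
        # nonzero voxels [1,2,3]: mean 2, population sd sqrt(2/3)
        data = np.zeros((4, 1, 1, 3), dtype=np.float32)
        data[:, 0, 0, :] = [1.0, 2.0, 3.0]
        out = zscore_normalize(_stack(data))
        expected = np.array([-1.224745, 0.0, 1.224745], dtype=np.float32)
        np.testing.assert_allclose(out.data[0, 0, 0], expected, atol=1e-5)

    def test_nonzero_region_standardized(self, noisy_phantom):
        out = zscore_normalize(noisy_phantom.stack)
        for ci in range(4):
            mask = noisy_phantom.stack.data[ci] != 0
            vals = out.data[ci][mask]
            assert abs(vals.mean()) < 1e-5
            assert abs(vals.std() - 1.0) < 1e-5
            # untouched background
            assert np.all(out.data[ci][~mask] == 0)

    def test_constant_channel_zeroed_with_warning(self, caplog):
        data = np.zeros((4, 2, 2, 2), dtype=np.float32)
        data[:, 0] = 7.0
        with caplog.at_level("WARNING", logger="cascadeseg"):
            out = zscore_normalize(_stack(data))
        assert np.all(out.data == 0)
        assert "constant" in caplog.text

    def test_idempotent_on_standardized_input(self, noisy_phantom):
        once = zscore_normalize(noisy_phantom.stack)
        twice = zscore_normalize(once)
        np.testing.assert_allclose(once.data, twice.data, atol=1e-5)


class TestLabelEncodings:
    def test_remap_bijection(self):
        rng = np.random.default_rng(0)
        raw = rng.choice([0, 1, 2, 4], size=(6, 6, 6))
        classes = remap_labels(raw)
        assert set(np.unique(classes)) <= {0, 1, 2, 3}
        assert np.array_equal(classes_to_labels(classes), raw)

    def test_all_fours_map_to_threes(self):
        assert np.all(remap_labels(np.full((3, 3, 3), 4)) == 3)

    def test_out_of_vocabulary_rejected(self):
        with pytest.raises(ValueError):
            remap_labels(np.array([[[3]]]))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_onehot_argmax_roundtrip(self, seed):
        v = np.random.default_rng(seed).integers(0, 4, size=(5, 5, 5))
        hot = onehot(v)
        assert np.all(hot.sum(axis=0) == 1.0)
        assert np.array_equal(hot.argmax(axis=0), v)

    def test_onehot_rejects_large_class(self):
        with pytest.raises(ValueError):
            onehot(np.array([[[4]]]), n_classes=4)


class TestRandomCrop:
    def test_output_shape_contract(self, noisy_phantom):
        rng = np.random.default_rng(0)
        label = noisy_phantom.label
        sample = random_crop(zscore_normalize(noisy_phantom.stack), label, 16, rng)
        assert sample.inputs.shape == (4, 16, 16, 16)
        assert sample.target_classes.shape == (16, 16, 16)
        assert sample.target_onehot.shape == (4, 16, 16, 16)
        assert np.all(sample.target_onehot.sum(axis=0) == 1.0)

    def test_small_volume_padded_then_cropped(self, noisy_phantom):
        rng = np.random.default_rng(1)
        sample = random_crop(noisy_phantom.stack, noisy_phantom.label, 48, rng)
        assert sample.inputs.shape == (4, 48, 48, 48)

    def test_crop_deterministic_given_rng_state(self, noisy_phantom):
        a = random_crop(noisy_phantom.stack, noisy_phantom.label, 16,
                        np.random.default_rng(42))
        b = random_crop(noisy_phantom.stack, noisy_phantom.label, 16,
                        np.random.default_rng(42))
        assert np.array_equal(a.inputs, b.inputs)
        assert np.array_equal(a.target_classes, b.target_classes)

    def test_tumor_bias_centers_on_tumor(self, noisy_phantom):
        # with bias 1 every crop must contain tumor voxels
        for seed in range(5):
            sample = random_crop(noisy_phantom.stack, noisy_phantom.label, 16,
                                 np.random.default_rng(seed), tumor_bias=1.0)
            assert (sample.target_classes > 0).any()


class TestAugment:
    def _sample(self, rng):
        classes = rng.integers(0, 4, size=(8, 8, 8))
        return TrainingSample(inputs=rng.normal(size=(4, 8, 8, 8)).astype(np.float32),
                              target_classes=classes, target_onehot=onehot(classes))

    def test_flip_twice_is_identity(self, rng):
        sample = self._sample(rng)
        kw = dict(p_flip=1.0, p_rot=0.0, scale_range=(1.0, 1.0), shift_range=(0.0, 0.0))
        once = augment(sample, np.random.default_rng(0), **kw)
        back = augment(once, np.random.default_rng(0), **kw)
        np.testing.assert_array_equal(back.inputs, sample.inputs)
        np.testing.assert_array_equal(back.target_classes, sample.target_classes)

    def test_rotation_preserves_tumor_volume(self, rng):
        sample = self._sample(rng)
        out = augment(sample, np.random.default_rng(3), p_flip=0.0, p_rot=1.0,
                      scale_range=(1.0, 1.0), shift_range=(0.0, 0.0))
        for c in range(4):
            assert (out.target_classes == c).sum() == (sample.target_classes == c).sum()

    def test_intensity_affine_arithmetic(self):
        classes = np.zeros((4, 4, 4), dtype=np.int16)
        sample = TrainingSample(inputs=np.ones((4, 4, 4, 4), dtype=np.float32),
                                target_classes=classes, target_onehot=onehot(classes))
        out = augment(sample, np.random.default_rng(0), p_flip=0.0, p_rot=0.0,
                      scale_range=(1.1, 1.1), shift_range=(0.05, 0.05))
        np.testing.assert_allclose(out.inputs, 1.15, atol=1e-6)

    def test_geometric_transform_commutes_with_region_composition(self):
        # compose_regions(augment(label)) == augment(compose_regions(label))
        rng_lab = np.random.default_rng(8)
        for seed in range(10):
            classes = remap_labels(rng_lab.choice([0, 1, 2, 4], size=(8, 8, 8)))
            sample = TrainingSample(
                inputs=np.zeros((4, 8, 8, 8), dtype=np.float32),
                target_classes=classes, target_onehot=onehot(classes))
            kw = dict(scale_range=(1.0, 1.0), shift_range=(0.0, 0.0))
            out = augment(sample, np.random.default_rng(seed), **kw)
            before = compose_regions(classes_to_labels(classes))
            after = compose_regions(classes_to_labels(out.target_classes))
            # apply the same draw sequence to the wt mask via a stand-in sample
            mask_sample = TrainingSample(
                inputs=np.zeros((4, 8, 8, 8), dtype=np.float32),
                target_classes=before.wt.astype(np.int16),
                target_onehot=onehot(before.wt.astype(np.int16), 4))
            mask_out = augment(mask_sample, np.random.default_rng(seed), **kw)
            np.testing.assert_array_equal(after.wt, mask_out.target_classes.astype(bool))

    def test_label_value_set_preserved(self, rng):
        sample = self._sample(rng)
        out = augment(sample, np.random.default_rng(9))
        assert set(np.unique(out.target_classes)) == set(np.unique(sample.target_classes))
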