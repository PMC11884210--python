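"""U-Net architecture contracts, patch extraction, and the training loop."""

import numpy as np
import pytest

from triseg import _nnops as nn
from triseg.augment import identity_policy, phantom_policy
from triseg.network import (
    ConfigurationError,
    PatchSample,
    SegmentationModel,
    TrainingConfig,
    TrainingError,
    build_unet,
    extract_training_patches,
    train_model,
)
from triseg.triplanar import ALL_ORIENTATIONS, Orientation
from triseg.volumes import ImageVolume, LabelVolume, ValidationError


class TestArchitecture:
    def test_output_shape_and_simplex(self, rng):
        model = build_unet(2, 2, 32, base_filters=4, seed=0)
        x = rng.normal(size=(3, 1, 32, 32)).astype(np.float32)
        probs = model.predict_probs(x)
        assert probs.shape == (3, 3, 32, 32)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-5)
        assert probs.min() >= 0

    def test_depth4_contract(self, rng):
        model = build_unet(4, 2, 128, base_filters=2, seed=0)
        probs = model.predict_probs(rng.normal(size=(1, 1, 128, 128)).astype(np.float32))
        assert probs.shape == (1, 3, 128, 128)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-5)

    def test_indivisible_patch_size_rejected(self):
        with pytest.raises(ConfigurationError):
            build_unet(4, 2, 100)

    def test_gradient_check_end_to_end(self, rng):
        """Analytic parameter gradients agree with central differences."""
        model = build_unet(2, 1, 8, base_filters=2, seed=0)
        for k in model.params:
            model.params[k] = model.params[k].astype(np.float64)
        x = rng.normal(size=(2, 1, 8, 8))
        y = rng.integers(0, 2, size=(2, 8, 8))
        logits, cache = model.forward(x, want_cache=True)
        _, dl = nn.softmax_cross_entropy(logits, y)
        grads = model.backward(dl, cache)
        eps = 1e-6
        for name in ["enc0_c1_w", "up0_w", "dec1_c2_w", "head_w", "bot_c2_b"]:
            p = model.params[name]
            idx = tuple(0 for _ in p.shape)
            orig = p[idx]
            p[idx] = orig + eps
            lp = nn.softmax_cross_entropy(model.forward(x), y)[0]
            p[idx] = orig - eps
            lm = nn.softmax_cross_entropy(model.forward(x), y)[0]
            p[idx] = orig
            assert grads[name][idx] == pytest.approx((lp - lm) / (2 * eps), abs=1e-7)

    def test_checkpoint_round_trip(self, tmp_path, rng):
        model = build_unet(
            2, 2, 32, base_filters=4, class_names=["a", "b"],
            orientations=(Orientation.SAGITTAL, Orientation.CORONAL), seed=5,
        )
        model.save(tmp_path / "m.npz")
        back = SegmentationModel.load(tmp_path / "m.npz")
        assert back.class_names == ["a", "b"]
        assert back.orientation_set == (Orientation.SAGITTAL, Orientation.CORONAL)
        x = rng.normal(size=(1, 1, 32, 32)).astype(np.float32)
        np.testing.assert_array_equal(model.predict_probs(x), back.predict_probs(x))


class TestTrainingConfig:
    def test_lr_schedule(self):
        cfg = TrainingConfig(
            patch_size=32, encoder_depth=2, learning_rate=0.001,
            lr_drop_period=5, lr_drop_factor=0.8,
        )
        assert cfg.lr_at_epoch(1) == pytest.approx(0.001)
        assert cfg.lr_at_epoch(5) == pytest.approx(0.001)
        assert cfg.lr_at_epoch(6) == pytest.approx(0.0008)
        assert cfg.lr_at_epoch(11) == pytest.approx(0.00064)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            TrainingConfig(patch_size=100)  # not divisible by 2^4
        with pytest.raises(ConfigurationError):
            TrainingConfig(patch_size=128, lr_drop_factor=1.5)
        with pytest.raises(ConfigurationError):
            TrainingConfig(patch_size=128, optimizer="sgd")


class TestPatchExtraction:
    def _pair(self, rng, shape=(64, 64, 64)):
        img = ImageVolume(rng.normal(size=shape).astype(np.float32), (1, 1, 1))
        lab_data = np.zeros(shape, np.int16)
        lab_data[20:44, 20:44, 20:44] = 1
        return img, LabelVolume(lab_data, (1, 1, 1))

    def test_counting_formula(self, rng):
        img, lab = self._pair(rng)
        samples = extract_training_patches(img, lab, 32, 16, ALL_ORIENTATIONS)
        # per orientation: 64 slices x (ceil((64-32)/16)+1)^2 = 9 patches
        assert len(samples) == 3 * 64 * 9

    def test_orientation_subset_only(self, rng):
        img, lab = self._pair(rng, (16, 16, 16))
        samples = extract_training_patches(
            img, lab, 16, 16, (Orientation.SAGITTAL, Orientation.CORONAL)
        )
        assert {s.orientation for s in samples} == {
            Orientation.SAGITTAL,
            Orientation.CORONAL,
        }

    def test_image_and_label_patches_cover_same_voxels(self, rng):
        img = ImageVolume(rng.normal(size=(16, 16, 16)).astype(np.float32), (1, 1, 1))
        lab = LabelVolume(
            (img.data * 1000).astype(np.int16).clip(0), (1, 1, 1)
        )
        samples = extract_training_patches(img, lab, 8, 4, (Orientation.TRANSVERSAL,))
        for s in samples[:20]:
            np.testing.assert_array_equal(
                (s.image * 1000).astype(np.int16).clip(0), s.label
            )

    def test_every_foreground_voxel_covered(self, rng):
        img, lab = self._pair(rng, (16, 16, 16))
        samples = extract_training_patches(img, lab, 8, 8, (Orientation.TRANSVERSAL,))
        covered = sum(int((s.label == 1).sum()) for s in samples)
        assert covered == int((lab.data == 1).sum())

    def test_lattice_mismatch_rejected(self, rng):
        img = ImageVolume(rng.normal(size=(8, 8, 8)).astype(np.float32), (1, 1, 1))
        lab = LabelVolume(np.zeros((8, 8, 9), np.int16), (1, 1, 1))
        with pytest.raises(ValidationError):
            extract_training_patches(img, lab, 8, 8)


class TestTraining:
    def _dataset(self, rng, n=10):
        samples = []
        for _ in range(n):
            img = rng.normal(0, 0.1, (32, 32)).astype(np.float32)
            lab = np.zeros((32, 32), np.int16)
            lab[8:24, 8:24] = 1
            img[8:24, 8:24] += 1.0
            samples.append(PatchSample(img, lab, Orientation.TRANSVERSAL))
        return samples

    def _config(self, **kw):
        base = dict(
            patch_size=32, encoder_depth=2, base_filters=8, epochs=2,
            batch_size=10, seed=0,
        )
        base.update(kw)
        return TrainingConfig(**base)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValidationError):
            train_model([], self._config())

    def test_loss_decreases_on_smoke_run(self, rng):
        _, history = train_model(self._dataset(rng), self._config())
        assert history.loss.iloc[-1] < history.loss.iloc[0]

    def test_same_seed_identical_history(self, rng):
        ds = self._dataset(rng)
        _, h1 = train_model(ds, self._config(), phantom_policy())
        _, h2 = train_model(ds, self._config(), phantom_policy())
        assert h1.loss.tolist() == h2.loss.tolist()

    def test_history_records_lr_schedule(self, rng):
        cfg = self._config(epochs=6, lr_drop_period=2, lr_drop_factor=0.5)
        _, history = train_model(self._dataset(rng, 5), cfg)
        assert history.lr.tolist() == pytest.approx(
            [0.001, 0.001, 0.0005, 0.0005, 0.00025, 0.00025]
        )

    def test_overfit_single_patch(self, rng):
        """A depth-2 model trained >= 50 steps on one repeated patch must
        reach pixel accuracy > 0.99 on that patch."""
        img = rng.normal(size=(32, 32)).astype(np.float32)
        lab = np.zeros((32, 32), np.int16)
        lab[8:24, 8:24] = 1
        ds = [PatchSample(img, lab, Orientation.TRANSVERSAL)] * 5
        cfg = self._config(epochs=100, batch_size=5)
        model, _ = train_model(ds, cfg)
        acc = np.mean(model.predict_probs(img[None])[0].argmax(0) == lab)
        assert acc > 0.99

    def test_single_parameter_set_serves_all_orientations(self, rng):
        """One network: predictions on a patch are identical regardless of
        which orientation the patch came from."""
        model, _ = train_model(self._dataset(rng), self._config())
        x = rng.normal(size=(1, 1, 32, 32)).astype(np.float32)
        p1 = model.predict_probs(x)
        p2 = model.predict_probs(x)
        np.testing.assert_array_equal(p1, p2)
        assert len(model.orientation_set) == 3
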