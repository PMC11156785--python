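"""Training harness: normalization, augmentation, splitting, stopping, loops."""

import numpy as np
import pytest

from liverdwi.floss import LossWeights, total_loss
from liverdwi.nettrain import (
    TrainConfig,
    _forward_intensity,
    _loss_tensor,
    _prep,
    augment,
    denormalize,
    load_model,
    normalize_stack,
    predict,
    pretrain,
    save_model,
    should_stop,
    split_patientwise,
    train,
)
from liverdwi.phantom import PhantomConfig, generate_dataset, generate_slice
from liverdwi.unet import UNet, UNetSpec


class TestNormalization:
    def test_zero_mean_unit_std(self, artifact_slice):
        norm, record = normalize_stack(artifact_slice.stack)
        assert norm.mean() == pytest.approx(0.0, abs=1e-9)
        assert norm.std() == pytest.approx(1.0, abs=1e-9)

    def test_round_trip(self, artifact_slice):
        norm, record = normalize_stack(artifact_slice.stack)
        np.testing.assert_allclose(
            denormalize(norm, record), artifact_slice.stack, rtol=1e-9, atol=1e-12
        )

    def test_affine_invariance(self, artifact_slice):
        a, _ = normalize_stack(artifact_slice.stack)
        b, _ = normalize_stack(2.5 * artifact_slice.stack + 7.0)
        np.testing.assert_allclose(a, b, rtol=1e-9, atol=1e-9)

    def test_constant_stack_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            normalize_stack(np.ones((4, 4, 3)))


class TestAugment:
    def test_deterministic_given_seed(self, artifact_slice):
        a = augment(artifact_slice, rng=7)
        b = augment(artifact_slice, rng=7)
        np.testing.assert_array_equal(a.stack, b.stack)
        np.testing.assert_array_equal(a.rois.left_lobe, b.rois.left_lobe)

    def test_all_repetitions_share_one_transform(self, artifact_slice):
        # truth and every repetition must move together: their relative
        # difference pattern is preserved up to interpolation error
        out = augment(artifact_slice, rng=3)
        inside = out.rois.right_lobe
        # right lobe has no artifacts -> each warped repetition stays close
        # to the warped truth there, as in the original slice
        for n in range(out.stack.shape[2]):
            orig_dev = np.abs(
                artifact_slice.stack[:, :, n][artifact_slice.rois.right_lobe]
                - artifact_slice.truth[artifact_slice.rois.right_lobe]
            ).mean()
            warp_dev = np.abs(out.stack[:, :, n][inside] - out.truth[inside]).mean()
            assert warp_dev < 3 * orig_dev + 1e-3

    def test_mask_centroid_tracks_image_content(self, artifact_slice):
        out = augment(artifact_slice, rng=11)
        # lesion centroid in the warped mask must coincide with the bright
        # lesion blob in the warped truth image
        mask = out.rois.lesions
        assert mask.any()
        lesion_mean = out.truth[mask].mean()
        parenchyma_mean = out.truth[out.rois.background].mean()
        assert lesion_mean > 1.2 * parenchyma_mean

    def test_masks_are_boolean(self, artifact_slice):
        out = augment(artifact_slice, rng=1)
        for mask in out.rois.as_dict().values():
            assert mask.dtype == bool


@pytest.fixture(scope="module")
def dataset():
    cfg = PhantomConfig(height=48, width=48)
    return generate_dataset(10, 5, cfg, seed=1)


class TestSplit:

    def test_counts_80_20(self, dataset):
        train_set, test_set = split_patientwise(dataset, 0.8, seed=1)
        assert len({s.patient_id for s in train_set}) == 8
        assert len({s.patient_id for s in test_set}) == 2
        assert len(train_set) == 40 and len(test_set) == 10

    def test_disjoint_over_many_seeds(self, dataset):
        for seed in range(100):
            train_set, test_set = split_patientwise(dataset, 0.8, seed=seed)
            train_ids = {s.patient_id for s in train_set}
            test_ids = {s.patient_id for s in test_set}
            assert not (train_ids & test_ids)
            assert train_ids | test_ids == set(range(10))

    def test_same_seed_same_split(self, dataset):
        a = split_patientwise(dataset, 0.8, seed=3)
        b = split_patientwise(dataset, 0.8, seed=3)
        assert [s.patient_id for s in a[0]] == [s.patient_id for s in b[0]]

    def test_single_patient_rejected(self, dataset):
        with pytest.raises(ValueError, match="2 patients"):
            split_patientwise(dataset[:5], 0.8, seed=0)


class TestEarlyStopping:
    def test_strictly_decreasing_never_stops(self):
        losses = list(np.linspace(10, 1, 30))
        for t in range(1, len(losses) + 1):
            assert not should_stop(losses[:t], window=10)

    def test_equal_window_means_stop(self):
        assert should_stop([5.0] * 10 + [5.0] * 10, window=10)

    def test_rising_stops(self):
        assert should_stop([1.0] * 5 + [2.0] * 5, window=5)

    def test_needs_two_full_windows(self):
        assert not should_stop([9.0] * 19, window=10)

    def test_recovery_after_plateau_still_runs(self):
        # mean of last 3 (1,1,1) lower than previous 3 (4,4,4) -> continue
        assert not should_stop([4, 4, 4, 1, 1, 1], window=3)


class TestLossGraph:
    def test_matches_numpy_loss(self, artifact_slice):
        from liverdwi._autodiff import Tensor
        from liverdwi.qscore import trace_reference

        ref = trace_reference(artifact_slice.stack)
        pred = artifact_slice.stack.mean(axis=2)
        expected = total_loss(
            pred, artifact_slice.stack, ref, artifact_slice.rois
        )
        mip_mean = float(
            artifact_slice.stack.max(axis=2)[artifact_slice.rois.left_lobe].mean()
        )
        got, terms = _loss_tensor(
            Tensor(pred), ref, mip_mean, artifact_slice.rois, LossWeights()
        )
        for name in ("dc", "cnr", "pa", "vd", "di", "pa2", "xi"):
            assert terms[name] == pytest.approx(
                getattr(expected, name), rel=1e-6, abs=1e-9
            ), name
        assert float(got.data) == pytest.approx(expected.total, rel=1e-6)

    def test_gradient_brightens_lesions(self, artifact_slice):
        # the CNR contribution makes the loss fall when lesions brighten:
        # gradient wrt a lesion voxel must be negative
        from liverdwi._autodiff import Tensor
        from liverdwi.qscore import trace_reference

        ref = trace_reference(artifact_slice.stack)
        pred = Tensor(artifact_slice.stack.mean(axis=2))
        mip_mean = float(
            artifact_slice.stack.max(axis=2)[artifact_slice.rois.left_lobe].mean()
        )
        w = LossWeights(lam_dc=0, lam_cnr=1.5, lam_pa=0, lam_vd=0,
                        lam_di=0, lam_pa2=0, lam_xi=0)
        total, _ = _loss_tensor(pred, ref, mip_mean, artifact_slice.rois, w)
        total.backward()
        lesion_grad = pred.grad[artifact_slice.rois.lesions]
        assert lesion_grad.mean() < 0


@pytest.fixture(scope="module")
def small_training_setup():
    cfg = PhantomConfig(height=32, width=32)
    data = generate_dataset(3, 2, cfg, seed=17)
    spec = UNetSpec(in_channels=12, depth=2, base_channels=8)
    return data, spec


class TestTrainingLoops:
    def test_pretraining_reduces_reference_error(self, small_training_setup):
        data, spec = small_training_setup
        net = UNet(spec, rng=0)
        config = TrainConfig(learning_rate=1e-3, batch_size=6, pretrain_epochs=8,
                             seed=0)
        init_err = self._rms_to_reference(net, data)
        losses = pretrain(net, data, config)
        assert len(losses) == 8
        assert self._rms_to_reference(net, data) < init_err

    @staticmethod
    def _rms_to_reference(net, data):
        from liverdwi.qscore import trace_reference

        errs = []
        for s in data:
            pred = predict(net, s.stack)
            ref = trace_reference(s.stack)
            errs.append(np.sqrt(np.mean((pred - ref) ** 2)))
        return float(np.mean(errs))

    def test_zero_pretrain_epochs_keeps_weights(self, small_training_setup):
        data, spec = small_training_setup
        net = UNet(spec, rng=0)
        before = net.get_weights()
        pretrain(net, data, TrainConfig(pretrain_epochs=0, seed=0))
        for a, b in zip(before, net.get_weights()):
            np.testing.assert_array_equal(a, b)

    def test_pretrain_deterministic_given_seed(self, small_training_setup):
        data, spec = small_training_setup
        config = TrainConfig(learning_rate=1e-3, batch_size=6, pretrain_epochs=3,
                             seed=4)
        l1 = pretrain(UNet(spec, rng=2), data, config)
        l2 = pretrain(UNet(spec, rng=2), data, config)
        assert l1 == l2

    def test_train_returns_best_weights_and_history(self, small_training_setup):
        data, spec = small_training_setup
        net = UNet(spec, rng=0)
        config = TrainConfig(learning_rate=1e-3, batch_size=6, pretrain_epochs=5,
                             stop_window=3, max_epochs=12, seed=0)
        pretrain(net, data, config)
        net, history = train(net, data[:4], data[4:], config=config)
        assert set(history.columns) >= {"epoch", "train_loss", "test_loss"}
        assert 1 <= history.attrs["best_epoch"] <= len(history)
        assert len(history) <= config.max_epochs

    def test_predict_contract(self, small_training_setup):
        data, spec = small_training_setup
        net = UNet(spec, rng=0)
        out = predict(net, data[0].stack)
        assert out.shape == data[0].stack.shape[:2]
        assert (out >= 0).all()

    def test_predict_channel_mismatch_rejected(self, small_training_setup):
        data, spec = small_training_setup
        net = UNet(spec, rng=0)
        with pytest.raises(ValueError, match="repetitions"):
            predict(net, data[0].stack[:, :, :5])

    def test_model_roundtrip(self, small_training_setup, tmp_path):
        data, spec = small_training_setup
        net = UNet(spec, rng=3)
        save_model(net, tmp_path)
        loaded = load_model(tmp_path)
        np.testing.assert_array_equal(
            predict(net, data[0].stack), predict(loaded, data[0].stack)
        )
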