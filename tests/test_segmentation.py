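import numpy as np
import pytest
from scipy import ndimage

from splitgfr.core import AcquisitionMeta, DynamicRenogram, PatientInfo, RoiSet
from splitgfr.gates import sum_window
from splitgfr.nn import UNet
from splitgfr.phantom import sample_scene, simulate_renogram
from splitgfr.segmentation import (
    AugmentRanges,
    SegModel,
    TrainConfig,
    aggregate_folds,
    augment,
    build_input_stack,
    labels_to_roiset,
    make_fold_plan,
    predict_roiset,
    roiset_to_labels,
    soft_dice_loss,
    train,
)

SMALL = TrainConfig(
    input_size=64, base_filters=4, levels=3, epochs=2, batch_size=4, learning_rate=1e-3, folds=2
)


def _phantom_data(n, seed0=500, config=SMALL):
    data, scenes = [], []
    for s in range(n):
        scene = sample_scene(s + seed0)
        scan = simulate_renogram(scene.patient, scene.truth, scene.meta, noise=True, rng_seed=s)
        data.append((build_input_stack(scan, config), roiset_to_labels(scene.truth.rois, config.input_size)))
        scenes.append(scene)
    return data, scenes


class TestBuildInputStack:
    def test_shape_256(self, noiseless_scan):
        stack = build_input_stack(noiseless_scan, TrainConfig(input_size=256))
        assert stack.shape == (4, 256, 256)
        assert stack.dtype == np.float32

    def test_constant_scan_normalises_to_one(self):
        meta = AcquisitionMeta()
        patient = PatientInfo(age=40, sex="male", weight_kg=70, height_cm=170)
        scan = DynamicRenogram(np.full((80, 64, 64), 7.0), meta, patient)
        stack = build_input_stack(scan, TrainConfig(input_size=64))
        assert np.allclose(stack, 1.0)

    def test_all_zero_stack_warns(self):
        meta = AcquisitionMeta()
        patient = PatientInfo(age=40, sex="male", weight_kg=70, height_cm=170)
        scan = DynamicRenogram(np.zeros((80, 64, 64)), meta, patient)
        with pytest.warns(UserWarning, match="zero"):
            stack = build_input_stack(scan, TrainConfig(input_size=64))
        assert not stack.any()

    def test_resampling_consistency(self, noiseless_scan):
        """Channel sum, block-averaged back to 64, tracks sum_window/max."""
        stack = build_input_stack(noiseless_scan, TrainConfig(input_size=256))
        chan_sum = stack.sum(axis=0)
        down = chan_sum.reshape(64, 4, 64, 4).mean(axis=(1, 3))
        expected = sum_window(noiseless_scan, (9, 12))
        expected = expected / noiseless_scan.counts[8:12].max()
        assert np.corrcoef(down.ravel(), expected.ravel())[0, 1] > 0.99

    def test_summed_channel_mode(self, noiseless_scan):
        cfg = TrainConfig(input_size=64, channel_mode="summed")
        stack = build_input_stack(noiseless_scan, cfg)
        assert np.array_equal(stack[0], stack[1])
        assert np.array_equal(stack[0], stack[3])

    def test_too_few_frames(self):
        meta = AcquisitionMeta(n_frames=8)
        patient = PatientInfo(age=40, sex="male", weight_kg=70, height_cm=170)
        scan = DynamicRenogram(np.ones((8, 64, 64)), meta, patient)
        with pytest.raises(ValueError, match="frames"):
            build_input_stack(scan, TrainConfig(input_size=64))


class TestSoftDiceLoss:
    def test_identity_binary(self):
        t = (np.random.default_rng(0).random((2, 8, 8)) > 0.5).astype(float)
        assert soft_dice_loss(t, t, epsilon=1e-9) == pytest.approx(0.0, abs=1e-6)

    def test_complement(self):
        t = (np.random.default_rng(1).random((2, 8, 8)) > 0.5).astype(float)
        assert soft_dice_loss(1 - t, t, epsilon=1e-9) == pytest.approx(1.0, abs=1e-6)

    def test_half_overlap(self):
        a = np.zeros((1, 8, 8))
        b = np.zeros((1, 8, 8))
        a[0, 0, 0:4] = 1
        b[0, 0, 2:6] = 1
        assert soft_dice_loss(a, b, epsilon=1e-12) == pytest.approx(0.5, abs=1e-9)

    def test_bounds_for_probabilities(self):
        rng = np.random.default_rng(2)
        p = rng.random((3, 16, 16))
        t = (rng.random((3, 16, 16)) > 0.5).astype(float)
        loss = soft_dice_loss(p, t)
        assert 0.0 <= loss <= 1.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            soft_dice_loss(np.zeros((1, 4, 4)), np.zeros((1, 5, 5)))

    def test_rejects_non_probabilities(self):
        with pytest.raises(ValueError):
            soft_dice_loss(np.full((1, 4, 4), 2.0), np.zeros((1, 4, 4)))


class TestAugment:
    def _pair(self):
        rng = np.random.default_rng(3)
        stack = rng.random((4, 64, 64)).astype(np.float32)
        masks = np.zeros((4, 64, 64), np.float32)
        masks[0, 20:30, 20:28] = 1
        masks[1, 20:30, 40:48] = 1
        return stack, masks

    def test_zero_ranges_identity(self):
        stack, masks = self._pair()
        zero = AugmentRanges(translate_px=0, rotate_deg=0, scale=0, shear_deg=0)
        out_s, out_m = augment(stack, masks, zero, seed=1)
        assert np.allclose(out_s, stack, atol=1e-5)
        assert np.array_equal(out_m, masks)

    def test_pure_translation_shifts_centroid(self):
        """The mask centroid moves by exactly the drawn translation vector."""
        stack, masks = self._pair()
        ranges = AugmentRanges(translate_px=3, rotate_deg=0, scale=0, shear_deg=0)
        # replay the generator to learn the translation augment(seed=12) draws
        t = np.random.default_rng(12).uniform(-3, 3, size=2)
        _, out_m = augment(stack, masks, ranges, seed=12)
        before = np.array(ndimage.center_of_mass(masks[0]))
        after = np.array(ndimage.center_of_mass(out_m[0]))
        assert np.allclose(after - before, t, atol=0.5)
        assert out_m[0].sum() == pytest.approx(masks[0].sum(), rel=0.1)

    def test_determinism(self):
        stack, masks = self._pair()
        r = AugmentRanges()
        a = augment(stack, masks, r, seed=9)
        b = augment(stack, masks, r, seed=9)
        assert np.array_equal(a[0], b[0])
        assert np.array_equal(a[1], b[1])

    def test_offgrid_rejection(self):
        stack = np.zeros((1, 64, 64), np.float32)
        masks = np.zeros((1, 64, 64), np.float32)
        masks[0, 0:2, 0:2] = 1  # corner mask, huge translation pushes it out
        huge = AugmentRanges(translate_px=200, rotate_deg=0, scale=0, shear_deg=0)
        with pytest.raises(RuntimeError):
            augment(stack, masks, huge, seed=0, max_retries=3)


class TestFoldPlan:
    def test_equal_folds_24(self):
        plan = make_fold_plan(24, 4, seed=0)
        for _, test_idx in plan.rotations:
            assert len(test_idx) == 6

    def test_partition(self):
        plan = make_fold_plan(26, 4, seed=1)
        all_test = np.concatenate([t for _, t in plan.rotations])
        assert sorted(all_test) == list(range(26))
        sizes = [len(t) for _, t in plan.rotations]
        assert max(sizes) - min(sizes) <= 1

    def test_three_to_one_ratio(self):
        plan = make_fold_plan(24, 4, seed=2)
        for train_idx, test_idx in plan.rotations:
            assert len(train_idx) == 3 * len(test_idx)

    def test_no_leakage(self):
        plan = make_fold_plan(37, 4, seed=3)
        for train_idx, test_idx in plan.rotations:
            assert np.intersect1d(train_idx, test_idx).size == 0

    def test_too_few_scans(self):
        with pytest.raises(ValueError):
            make_fold_plan(3, 4)


class TestTraining:
    def test_smoke_run_loss_decreases_and_model_count(self):
        data, _ = _phantom_data(8)
        plan = make_fold_plan(8, 2, seed=0)
        cfg = TrainConfig(
            input_size=64, base_filters=4, levels=3, epochs=3, batch_size=4,
            learning_rate=2e-3, folds=2,
        )
        models = train(data, plan, cfg)
        assert len(models) == plan.folds
        for m in models:
            assert m.loss_history[-1] < m.loss_history[0]
            assert len(m.loss_history) == cfg.epochs

    def test_memorisation_two_samples(self):
        data, scenes = _phantom_data(2, seed0=600)
        cfg = TrainConfig(
            input_size=64, base_filters=8, levels=3, epochs=150, batch_size=2,
            learning_rate=1e-2, folds=2,
        )
        from splitgfr.segmentation import _train_one

        stacks = np.stack([d[0] for d in data])
        labels = np.stack([d[1] for d in data])
        model = _train_one(stacks, labels, cfg, seed=0)
        from splitgfr.evalstats import dice

        rois, _ = predict_roiset(model, stacks[0])
        truth = scenes[0].truth.rois
        assert dice(rois.kidney_left, truth.kidney_left) > 0.9
        assert dice(rois.kidney_right, truth.kidney_right) > 0.9

    def test_empty_dataset(self):
        with pytest.raises(ValueError):
            train([], make_fold_plan(4, 2), SMALL)


@pytest.fixture(scope="module")
def trained_model():
    """A modestly trained model on 32 phantoms, shared across smoke checks."""
    from splitgfr.segmentation import _train_one

    data, scenes = _phantom_data(32, seed0=700)
    cfg = TrainConfig(
        input_size=64, base_filters=8, levels=3, epochs=30, batch_size=8,
        learning_rate=1e-2, folds=2,
    )
    stacks = np.stack([d[0] for d in data])
    labels = np.stack([d[1] for d in data])
    model = _train_one(stacks, labels, cfg, seed=3)
    return model, data, scenes


class TestEquivariance:
    def test_translation_equivariance(self, trained_model):
        model, data, scenes = trained_model
        stack = data[0][0]
        shift = 6
        shifted = np.roll(stack, shift, axis=1)  # rows move down by 6 px
        pred_plain, _ = predict_roiset(model, stack)
        pred_shifted, _ = predict_roiset(model, shifted)
        a = np.roll(pred_plain.kidney_left | pred_plain.kidney_right, shift, axis=0)
        b = pred_shifted.kidney_left | pred_shifted.kidney_right
        inter = (a & b).sum()
        union = (a | b).sum()
        assert union > 0
        assert inter / union > 0.7

    def test_trained_model_segments_training_scene(self, trained_model):
        from splitgfr.evalstats import dice

        model, data, scenes = trained_model
        rois, _ = predict_roiset(model, data[1][0])
        truth = scenes[1].truth.rois
        assert dice(rois.kidney_left, truth.kidney_left) > 0.8
        assert dice(rois.kidney_right, truth.kidney_right) > 0.8


class TestPredict:
    def test_threshold_semantics(self):
        net = UNet(in_ch=4, out_ch=4, base=4, levels=2, seed=0)
        model = SegModel(net=net, descriptor=net.descriptor(), loss_history=[])
        stack = np.random.default_rng(0).random((4, 16, 16)).astype(np.float32)
        # zero the head: logits 0 -> p = 0.5 exactly -> out of mask
        net.head.w[...] = 0
        net.head.b[...] = 0
        rois, flags = predict_roiset(model, stack, raw_size=16)
        assert all(flags.values())
        assert not rois.kidney_left.any()
        # positive bias: p > 0.5 -> in mask
        net.head.b[...] = 0.1
        rois, flags = predict_roiset(model, stack, raw_size=16)
        assert rois.kidney_left.all()
        assert not any(flags.values())

    def test_deterministic(self):
        net = UNet(in_ch=4, out_ch=4, base=4, levels=2, seed=1)
        model = SegModel(net=net, descriptor=net.descriptor(), loss_history=[])
        stack = np.random.default_rng(1).random((4, 64, 64)).astype(np.float32)
        a, _ = predict_roiset(model, stack)
        b, _ = predict_roiset(model, stack)
        for k in a.masks():
            assert np.array_equal(a.masks()[k], b.masks()[k])

    def test_provenance(self):
        net = UNet(in_ch=4, out_ch=4, base=4, levels=2, seed=2)
        model = SegModel(net=net, descriptor=net.descriptor(), loss_history=[])
        stack = np.zeros((4, 64, 64), np.float32)
        rois, _ = predict_roiset(model, stack)
        assert rois.provenance == "deep-learning"


class TestModelPersistence:
    def test_descriptor_round_trip(self, tmp_path):
        net = UNet(in_ch=4, out_ch=4, base=4, levels=3, seed=5)
        model = SegModel(net=net, descriptor=net.descriptor(), loss_history=[0.5])
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = SegModel.load(path)
        assert loaded.descriptor == model.descriptor
        stack = np.random.default_rng(2).random((4, 64, 64)).astype(np.float32)
        a = net.forward(stack[None], train=False)
        b = loaded.net.forward(stack[None], train=False)
        assert np.array_equal(a, b)


class TestAggregateFolds:
    def test_pooled_count(self):
        per_rot = [{0: "a", 1: "b"}, {2: "c", 3: "d"}]
        pooled = aggregate_folds(per_rot, range(4))
        assert len(pooled) == 4

    def test_duplicate_raises(self):
        with pytest.raises(ValueError, match="more than one"):
            aggregate_folds([{0: "a"}, {0: "b"}], range(1))

    def test_gap_raises(self):
        with pytest.raises(ValueError, match="no prediction"):
            aggregate_folds([{0: "a"}], range(2))

    def test_pooled_dice_weighted_mean_identity(self):
        rng = np.random.default_rng(4)
        fold_dices = [rng.random(size) for size in (6, 6, 5, 5)]
        per_rot = []
        i = 0
        for fd in fold_dices:
            per_rot.append({i + j: d for j, d in enumerate(fd)})
            i += len(fd)
        pooled = aggregate_folds(per_rot, range(i))
        pooled_mean = np.mean(list(pooled.values()))
        weighted = sum(fd.sum() for fd in fold_dices) / i
        assert pooled_mean == pytest.approx(weighted, abs=1e-12)


class TestLabelsRoundTrip:
    def test_roiset_labels_identity_at_64(self):
        rois = sample_scene(9).truth.rois
        labels = roiset_to_labels(rois, 64)
        back, flags = labels_to_roiset(labels, 64)
        for k, m in rois.masks().items():
            assert np.array_equal(back.masks()[k], m)
        assert not any(flags.values())

    def test_upscale_downscale_identity_256(self):
        rois = sample_scene(10).truth.rois
        labels = roiset_to_labels(rois, 256)
        back, _ = labels_to_roiset(labels, 64)
        for k, m in rois.masks().items():
            assert np.array_equal(back.masks()[k], m)
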