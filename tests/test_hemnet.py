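import numpy as np
import pytest
from skimage import color

from hemdetect.hemnet import (
    ArchitectureError,
    REFERENCE_LAYOUT,
    build_hemnet,
    compose_channels,
    evaluate,
    label_candidates,
    predict,
    train,
)
from hemdetect.core_io import Box, Candidate, SeedPoint


class TestComposeChannels:
    def test_white_patch_all_ones(self):
        patch = np.full((64, 64, 3), 255, dtype=np.uint8)
        out = compose_channels(patch)
        assert out.shape == (256, 256, 3)
        np.testing.assert_allclose(out, 1.0, atol=1e-3)

    def test_black_patch_all_zeros(self):
        out = compose_channels(np.zeros((64, 64, 3), dtype=np.uint8))
        np.testing.assert_allclose(out, 0.0, atol=1e-6)

    def test_pure_red_channel_values(self):
        patch = np.zeros((32, 32, 3), dtype=np.uint8)
        patch[:, :, 0] = 255
        out = compose_channels(patch)
        assert out[:, :, 0].max() == pytest.approx(0.0, abs=1e-6)   # green
        assert out[:, :, 1].min() == pytest.approx(1.0, abs=1e-6)   # HSV value
        lab_l = color.rgb2lab(np.array([[[1.0, 0.0, 0.0]]]))[0, 0, 0] / 100
        assert out[16, 16, 2] == pytest.approx(lab_l, abs=1e-3)     # ~0.532

    def test_non_rgb_rejected(self):
        with pytest.raises(ValueError):
            compose_channels(np.zeros((32, 32)))


class TestArchitecture:
    def test_layer_shapes_match_reference(self):
        model = build_hemnet(seed=0)
        summary = model.layer_summary()
        for (name, ltype, shape), (rname, rtype, rshape) in zip(
            summary, REFERENCE_LAYOUT
        ):
            assert name == rname
            assert ltype == rtype
            if rshape is not None:
                assert shape == rshape, f"{name}: {shape} != {rshape}"

    def test_nineteen_individual_layers(self):
        assert build_hemnet().n_layers == 19

    def test_conv_output_shapes(self):
        rows = {name: shape for name, _, shape in build_hemnet().layer_summary()}
        assert rows["conv_1"] == (86, 86, 16)
        assert rows["conv_2"] == (43, 43, 16)
        assert rows["conv_4"] == (22, 22, 16)
        assert rows["fc"] == (1, 1, 2)

    def test_realized_tensor_shapes_match_summary(self, rng):
        model = build_hemnet(seed=0)
        x = rng.random((2, 256, 256, 3)).astype(np.float32)
        a1 = model.conv1.forward(x, False)
        assert a1.shape == (2, 86, 86, 16)
        a = model.pool1.forward(
            model.bn1.forward(model.relu1.forward(a1, False), False), False
        )
        assert a.shape == (2, 86, 86, 16)
        c2 = model.conv2.forward(a, False)
        assert c2.shape == (2, 43, 43, 16)
        skip = model.pool_skip.forward(a, False)
        assert skip.shape == (2, 43, 43, 16)
        logits = model.forward(x)
        assert logits.shape == (2, 2)


class TestPredict:
    def test_probabilities_sum_to_one(self, rng):
        model = build_hemnet(seed=0)
        x = rng.random((3, 256, 256, 3)).astype(np.float32)
        from hemdetect.hemnet import nn as hnn

        probs = hnn.softmax(model.forward(x))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_batch_equals_per_item(self, rng):
        model = build_hemnet(seed=0)
        x = (rng.random((3, 256, 256, 3)) * 255).astype(np.uint8)
        batch = predict(model, x)
        singles = [predict(model, x[i]) for i in range(3)]
        np.testing.assert_allclose(batch, singles, atol=1e-5)

    def test_zeroed_final_layer_gives_half(self, rng):
        model = build_hemnet(seed=0)
        model.fc.params["W"][...] = 0
        model.fc.params["b"][...] = 0
        x = (rng.random((256, 256, 3)) * 255).astype(np.uint8)
        assert predict(model, x) == pytest.approx(0.5, abs=1e-6)

    def test_wrong_shape_rejected(self, rng):
        model = build_hemnet(seed=0)
        with pytest.raises(ValueError):
            model.forward(rng.random((1, 128, 128, 3)).astype(np.float32))


def _separable_patches(n_per_class: int, rng) -> tuple[np.ndarray, np.ndarray]:
    """Dark-blob patches vs bright patches — linearly separable by design."""
    x = np.zeros((2 * n_per_class, 256, 256, 3), dtype=np.uint8)
    y = np.zeros(2 * n_per_class, dtype=np.int64)
    yy, xx = np.mgrid[0:256, 0:256]
    for i in range(2 * n_per_class):
        base = rng.integers(140, 200)
        patch = np.full((256, 256, 3), base, dtype=np.int64)
        patch += rng.normal(0, 8, (256, 256, 3)).astype(np.int64)
        if i < n_per_class:
            r = rng.integers(30, 60)
            cr, cc = rng.integers(90, 166, 2)
            blob = (yy - cr) ** 2 + (xx - cc) ** 2 <= r**2
            patch[blob] //= 4
            y[i] = 1
        x[i] = np.clip(patch, 0, 255)
    return x, y


class TestTraining:
    def test_separable_set_learned(self, rng):
        x, y = _separable_patches(96, rng)
        model = build_hemnet(seed=0)
        history = train(
            model, x, y, lr=0.01, epochs=5, batch_size=16,
            val_fraction=0.2, seed=0,
        )
        assert history.val_acc[-1] >= 0.95

    def test_zero_learning_rate_flat(self, rng):
        x, y = _separable_patches(8, rng)
        model = build_hemnet(seed=0)
        w_before = model.conv1.params["W"].copy()
        history = train(
            model, x, y, lr=0.0, epochs=3, batch_size=8,
            val_fraction=0.0, seed=0,
        )
        np.testing.assert_array_equal(model.conv1.params["W"], w_before)
        assert history.train_loss[0] == pytest.approx(
            history.train_loss[-1], abs=1e-6
        )

    def test_same_seed_identical_history(self, rng):
        x, y = _separable_patches(8, rng)
        h1 = train(build_hemnet(seed=3), x, y, lr=0.01, epochs=2,
                   batch_size=8, seed=5)
        h2 = train(build_hemnet(seed=3), x, y, lr=0.01, epochs=2,
                   batch_size=8, seed=5)
        assert h1.train_loss == h2.train_loss
        assert h1.val_acc == h2.val_acc

    def test_single_class_rejected(self, rng):
        x = (rng.random((8, 256, 256, 3)) * 255).astype(np.uint8)
        with pytest.raises(ValueError):
            train(build_hemnet(), x, np.ones(8, dtype=np.int64))

    def test_save_load_round_trip(self, tmp_path, rng):
        model = build_hemnet(seed=0)
        x = (rng.random((2, 256, 256, 3)) * 255).astype(np.uint8)
        p1 = predict(model, x)
        path = tmp_path / "weights.npz"
        model.save(path)
        from hemdetect.hemnet import HemNet

        restored = HemNet.load(path)
        np.testing.assert_allclose(predict(restored, x), p1, atol=1e-6)


class TestEvaluate:
    def test_constructed_confusion_counts(self):
        # TP=75, FN=5, TN=110, FP=10
        scores = np.concatenate(
            [np.full(75, 0.9), np.full(5, 0.1), np.full(110, 0.1), np.full(10, 0.9)]
        )
        labels = np.concatenate(
            [np.ones(80, dtype=int), np.zeros(120, dtype=int)]
        )
        m = evaluate(scores, labels)
        assert (m.tp, m.fn, m.tn, m.fp) == (75, 5, 110, 10)
        assert m.se == pytest.approx(0.9375, abs=1e-4)
        assert m.sp == pytest.approx(0.9167, abs=1e-4)
        assert m.p == pytest.approx(0.8824, abs=1e-4)
        assert m.ac == pytest.approx(0.925, abs=1e-4)

    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, 0, 0])
        m = evaluate(scores, labels)
        assert (m.se, m.sp, m.p, m.ac) == (1.0, 1.0, 1.0, 1.0)
        assert m.auc_roc == pytest.approx(1.0)

    def test_shuffled_scores_null_auc(self):
        rng = np.random.default_rng(7)
        scores = rng.random(4000)
        labels = rng.integers(0, 2, 4000)
        m = evaluate(scores, labels)
        assert m.auc_roc == pytest.approx(0.5, abs=0.05)

    def test_roc_endpoints_and_pr_tail(self):
        rng = np.random.default_rng(3)
        labels = rng.integers(0, 2, 500)
        scores = np.clip(labels * 0.4 + rng.random(500) * 0.6, 0, 1)
        m = evaluate(scores, labels)
        fpr, tpr = m.roc_curve[:, 1], m.roc_curve[:, 2]
        assert fpr.min() == 0.0 and tpr[np.argmin(fpr + tpr)] == 0.0
        assert fpr.max() == 1.0 and tpr.max() == 1.0
        # PR curve: precision at full recall equals prevalence
        full_recall = m.pr_curve[m.pr_curve[:, 1] == 1.0]
        prevalence = labels.mean()
        assert full_recall[:, 2].min() == pytest.approx(prevalence, abs=1e-9)

    def test_single_class_labels_named_error(self):
        with pytest.raises(ValueError, match="SP"):
            evaluate(np.array([0.2, 0.7]), np.array([1, 1]))
        with pytest.raises(ValueError, match="SE"):
            evaluate(np.array([0.2, 0.7]), np.array([0, 0]))


class TestLabelCandidates:
    def _cand(self, mask):
        return Candidate(
            box=Box(0, 0, mask.shape[1] - 1, mask.shape[0] - 1),
            seed=SeedPoint(1, 1), object_mask=mask,
        )

    def test_object_inside_gt_is_positive(self):
        gt = np.zeros((20, 20), dtype=bool)
        gt[5:15, 5:15] = True
        obj = np.zeros_like(gt)
        obj[6:10, 6:10] = True
        cand = label_candidates([self._cand(obj)], gt)[0]
        assert cand.label == "HE"

    def test_disjoint_object_is_negative(self):
        gt = np.zeros((20, 20), dtype=bool)
        gt[0:5, 0:5] = True
        obj = np.zeros_like(gt)
        obj[10:15, 10:15] = True
        assert label_candidates([self._cand(obj)], gt)[0].label == "non-HE"

    def test_half_overlap_boundary_inclusive(self):
        gt = np.zeros((20, 20), dtype=bool)
        gt[:, 0:10] = True
        obj = np.zeros_like(gt)
        obj[5:9, 6:14] = True          # exactly half inside
        cand = label_candidates([self._cand(obj)], gt, min_overlap=0.5)[0]
        assert cand.label == "HE"
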