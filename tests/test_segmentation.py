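import numpy as np
import pytest

from thermotee import nn
from thermotee import segmentation as seg
from thermotee.io import LabelMask, ThermalFrame
from thermotee.segmentation import (
    SegConfig,
    UNet,
    augment,
    evaluate,
    predict,
    probs_to_mask,
    train,
)


class TestAugment:
    def _pair(self, seed=0):
        rng = np.random.default_rng(seed)
        temps = rng.uniform(20, 38, size=(24, 32))
        labels = (rng.random((24, 32)) < 0.3).astype(np.uint8)
        return ThermalFrame(temps=temps), LabelMask(labels=labels)

    def test_all_disabled_is_identity(self):
        f, m = self._pair()
        f2, m2 = augment(f, m, seed=3, flips=False, rotate=False, rescale=False,
                         brightness=False, noise=False)
        np.testing.assert_array_equal(f2.temps, f.temps)
        np.testing.assert_array_equal(m2.labels, m.labels)

    def test_deterministic_given_seed(self):
        f, m = self._pair()
        a1 = augment(f, m, seed=7)
        a2 = augment(f, m, seed=7)
        np.testing.assert_array_equal(a1[0].temps, a2[0].temps)
        np.testing.assert_array_equal(a1[1].labels, a2[1].labels)

    @pytest.mark.parametrize("aug_seed", range(8))
    def test_mask_labels_never_invented(self, aug_seed):
        # nearest-neighbour resampling can only reuse existing labels (or 0)
        f, m = self._pair(seed=1)
        m.labels[m.labels == 1] = 3  # label set {0, 3}
        _, m2 = augment(f, LabelMask(m.labels), seed=aug_seed)
        assert set(np.unique(m2.labels)) <= {0, 3}

    def test_geometry_applied_identically_to_frame_and_mask(self):
        # warm pixels and patient labels coincide before, so they must after
        temps = np.full((32, 32), 20.0)
        labels = np.zeros((32, 32), np.uint8)
        temps[8:24, 10:20] = 36.0
        labels[8:24, 10:20] = 1
        f2, m2 = augment(ThermalFrame(temps), LabelMask(labels), seed=5,
                         brightness=False, noise=False)
        warm = f2.temps > 30.0
        agree = (warm == (m2.labels == 1)).mean()
        assert agree > 0.97  # only interpolated boundary pixels may disagree


class TestEvaluate:
    def test_perfect_prediction(self):
        m = LabelMask((np.arange(64).reshape(8, 8) % 4).astype(np.uint8))
        got = evaluate(m, m)
        assert got.mean_iou == 1.0 and got.mean_dice == 1.0 and got.pixel_accuracy == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((8, 8), np.uint8)
        a[:4] = 1
        b = np.zeros((8, 8), np.uint8)
        b[4:] = 1
        got = evaluate(LabelMask(a), LabelMask(b))
        assert got.per_class_iou[1] == 0.0

    def test_dice_identity_on_random_masks(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            a = LabelMask(rng.integers(0, 4, size=(32, 32)).astype(np.uint8))
            b = LabelMask(rng.integers(0, 4, size=(32, 32)).astype(np.uint8))
            m = evaluate(a, b)
            for c, iou in m.per_class_iou.items():
                am, bm = a.labels == c, b.labels == c
                dice_direct = 2 * (am & bm).sum() / (am.sum() + bm.sum())
                assert dice_direct == pytest.approx(2 * iou / (1 + iou), rel=1e-9)

    def test_iou_symmetric(self):
        rng = np.random.default_rng(9)
        a = LabelMask(rng.integers(0, 4, size=(16, 16)).astype(np.uint8))
        b = LabelMask(rng.integers(0, 4, size=(16, 16)).astype(np.uint8))
        assert evaluate(a, b).per_class_iou == evaluate(b, a).per_class_iou

    def test_empty_class_skipped_from_mean(self):
        a = np.zeros((8, 8), np.uint8)
        a[0, 0] = 1
        got = evaluate(LabelMask(a), LabelMask(a))
        assert set(got.per_class_iou) == {0, 1}  # classes 2, 3 absent from both


class TestPredictRule:
    def _probs(self, bg, pat, tube, screen, shape=(4, 4)):
        p = np.empty((4, *shape))
        for i, v in enumerate((bg, pat, tube, screen)):
            p[i] = v
        return p

    def test_forced_assignment(self):
        m = probs_to_mask(self._probs(0.1, 0.7, 0.1, 0.1), threshold=0.5)
        assert (m.labels == 1).all()

    def test_high_threshold_gives_background(self):
        m = probs_to_mask(self._probs(0.1, 0.7, 0.1, 0.1), threshold=0.9)
        assert (m.labels == 0).all()

    def test_threshold_monotone_never_adds_foreground(self):
        rng = np.random.default_rng(10)
        raw = rng.random((4, 16, 16))
        probs = raw / raw.sum(axis=0)
        prev_fg = None
        for thr in (0.3, 0.5, 0.7, 0.9):
            fg = probs_to_mask(probs, thr).labels > 0
            if prev_fg is not None:
                assert not (fg & ~prev_fg).any()
            prev_fg = fg


class TestGradients:
    def test_backward_matches_numeric_gradient(self):
        rng = np.random.default_rng(0)
        net = UNet(depth=2, base=3, classes=4, rng=rng, dtype=np.float64)
        x = rng.normal(size=(2, 1, 8, 8))
        y = rng.integers(0, 4, size=(2, 8, 8))
        w = np.array([1.0, 2.0, 0.5, 1.5])
        loss, dl = nn.weighted_softmax_ce(net.forward(x), y, w)
        for lay in net.conv_layers():
            lay.grads["w"][...] = 0
            lay.grads["b"][...] = 0
        net.backward(dl)
        lay = net.conv_layers()[3]
        eps = 1e-6
        for idx in [(0, 0, 0, 0), (1, 2, 1, 1), (2, 1, 2, 2)]:
            orig = lay.w[idx]
            lay.w[idx] = orig + eps
            lp = nn.weighted_softmax_ce(net.forward(x), y, w)[0]
            lay.w[idx] = orig - eps
            lm = nn.weighted_softmax_ce(net.forward(x), y, w)[0]
            lay.w[idx] = orig
            num = (lp - lm) / (2 * eps)
            assert num == pytest.approx(lay.grads["w"][idx], rel=1e-5, abs=1e-10)


class TestTraining:
    def test_memorizes_duplicated_pair(self, tiny_training_pairs):
        pairs = [tiny_training_pairs[0]] * 10
        cfg = SegConfig(max_epochs=25, patience=25, seed=0, lr=3e-3, augment=False,
                        base_channels=8, batch_size=4)
        model = train(pairs, cfg)
        pred = predict(model, pairs[0][0])
        m = evaluate(pred, pairs[0][1])
        assert m.per_class_iou[1] > 0.9

    def test_deterministic_history(self, tiny_training_pairs):
        cfg = SegConfig(max_epochs=2, patience=2, seed=4, base_channels=8)
        h1 = train(tiny_training_pairs, cfg).history
        h2 = train(tiny_training_pairs, cfg).history
        assert h1 == h2

    def test_best_epoch_val_loss_not_worse_than_first(self, tiny_training_pairs):
        cfg = SegConfig(max_epochs=6, patience=6, seed=0, lr=3e-3, base_channels=8)
        model = train(tiny_training_pairs, cfg)
        best = max(model.history, key=lambda h: h["val_mean_iou"])
        assert best["val_loss"] <= model.history[0]["val_loss"]

    def test_missing_class_warns_and_zero_weight(self, tiny_training_pairs):
        pairs = []
        for f, m in tiny_training_pairs[:8]:
            labels = m.labels.copy()
            labels[labels == 3] = 0  # erase the screen class everywhere
            pairs.append((f, LabelMask(labels)))
        cfg = SegConfig(max_epochs=1, patience=1, seed=0, base_channels=8)
        with pytest.warns(UserWarning, match="absent"):
            model = train(pairs, cfg)
        assert model.class_weights[3] == 0.0

    def test_too_few_pairs_rejected(self, tiny_training_pairs):
        with pytest.raises(ValueError):
            train(tiny_training_pairs[:4], SegConfig())

    def test_save_load_roundtrip(self, tiny_training_pairs, tmp_path):
        cfg = SegConfig(max_epochs=1, patience=1, seed=0, base_channels=8)
        model = train(tiny_training_pairs, cfg)
        back = seg.SegModel.load(model.save(tmp_path / "m.npz"))
        f = tiny_training_pairs[0][0]
        np.testing.assert_array_equal(
            predict(model, f).labels, predict(back, f).labels
        )
        assert back.threshold == model.threshold


class TestThresholdSelection:
    def test_grid_argmax_with_tie_toward_smaller(self, tiny_training_pairs):
        cfg = SegConfig(max_epochs=1, patience=1, seed=0, base_channels=8)
        model = train(tiny_training_pairs[:8], cfg)
        val = tiny_training_pairs[8:12]
        thr = seg.select_threshold(model, val)
        # brute-force re-scan is the definition
        step = cfg.threshold_grid
        grid = np.arange(step, 1.0, step)
        ious = []
        for t in grid:
            ious.append(np.mean([
                evaluate(predict(model, f, float(t)), m).mean_iou for f, m in val
            ]))
        best = max(ious)
        assert ious[list(grid).index(thr)] == pytest.approx(best, abs=1e-12)
        assert thr == pytest.approx(grid[int(np.argmax(ious))])

    def test_threshold_grid_too_coarse_rejected(self):
        with pytest.raises(ValueError):
            SegConfig(threshold_grid=0.2)
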