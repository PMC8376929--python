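"""Cascade detector: geometry oracles, loss arithmetic, network contracts."""

import numpy as np
import pytest

from kneepipe.detector import (CascadeConfig, Detection, PyramidError,
                               Stage1Net, Stage2Net, build_pyramid,
                               detection_accuracy, iou, multitask_loss, nms,
                               tiny_cascade_config)


def pixel_set_iou(a, b):
    """Rasterized IoU oracle: count integer pixels inside each half-open box."""
    def cells(box):
        x1, y1, x2, y2 = (int(v) for v in box)
        return {(x, y) for x in range(x1, x2) for y in range(y1, y2)}
    ca, cb = cells(a), cells(b)
    union = len(ca | cb)
    return len(ca & cb) / union if union else 0.0


def nms_oracle(dets, thr):
    """O(n^2) reference: explicit suppression table, tie-break by index."""
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].score, i))
    keep = []
    for i in order:
        if all(iou(dets[i].box, dets[j].box) <= thr for j in keep):
            keep.append(i)
    return [dets[i] for i in keep]


class TestIoU:
    def test_identical_and_disjoint(self):
        a = np.array([0, 0, 4, 4])
        assert iou(a, a) == 1.0
        assert iou(a, np.array([10, 10, 12, 12])) == 0.0

    def test_worked_example(self):
        assert np.isclose(iou([0, 0, 2, 2], [1, 0, 3, 2]), 1 / 3)

    def test_matches_pixel_set_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a = np.sort(rng.integers(0, 20, size=4).reshape(2, 2), axis=0).T.ravel()
            b = np.sort(rng.integers(0, 20, size=4).reshape(2, 2), axis=0).T.ravel()
            a = [a[0], a[2], a[1] + 1, a[3] + 1]
            b = [b[0], b[2], b[1] + 1, b[3] + 1]
            assert np.isclose(iou(a, b), pixel_set_iou(a, b))


class TestNMS:
    def test_single_and_dominated(self):
        d = Detection(np.array([0, 0, 10, 10]), 0.9)
        assert nms([d], 0.5) == [d]
        d2 = Detection(np.array([0, 0, 10, 10]), 0.8)
        kept = nms([d, d2], 0.5)
        assert len(kept) == 1 and kept[0].score == 0.9

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            n = rng.integers(1, 26)
            dets = []
            for _ in range(n):
                x1, y1 = rng.uniform(0, 50, size=2)
                w, h = rng.uniform(2, 30, size=2)
                dets.append(Detection(np.array([x1, y1, x1 + w, y1 + h]),
                                      float(rng.uniform(0, 1))))
            thr = float(rng.uniform(0.2, 0.8))
            got = nms(dets, thr)
            want = nms_oracle(dets, thr)
            assert [id(d) for d in got] == [id(d) for d in want]

    def test_empty_input(self):
        assert nms([], 0.5) == []


class TestLoss:
    def test_hand_built_two_sample_batch(self):
        # sample 0: positive with logit 0 (p=0.5), box residual 0.1 each coord,
        # kp residual 0.2 each of 12 coords; sample 1: negative, logit 0.
        pred = {"logit": np.array([0.0, 0.0]),
                "box": np.array([[0.1] * 4, [0.5] * 4]),
                "kp": np.array([[0.2] * 12, [0.9] * 12])}
        target = {"label": np.array([1, 0]),
                  "box": np.zeros((2, 4)), "kp": np.zeros((2, 12))}
        a_det, a_box, a_kp = 0.8, 0.6, 1.5
        # independent scalar computation: CE = mean(-log 0.5) over both
        # samples; box/kp means run over positive-sample coordinates only
        want = (a_det * (-np.log(0.5))
                + a_box * (4 * 0.1 ** 2) / 4
                + a_kp * (12 * 0.2 ** 2) / 12)
        got = multitask_loss(pred, target, a_det, a_box, a_kp)
        assert np.isclose(got, want)

    def test_perfect_predictions_leave_only_ce(self):
        pred = {"logit": np.array([20.0]), "box": np.zeros((1, 4)),
                "kp": np.zeros((1, 12))}
        target = {"label": np.array([1]), "box": np.zeros((1, 4)),
                  "kp": np.zeros((1, 12))}
        loss = multitask_loss(pred, target, 1.0, 0.5, 1.5)
        assert np.isclose(loss, -np.log(1 / (1 + np.exp(-20.0))), atol=1e-8)

    def test_zero_kp_weight_kills_kp_gradient(self):
        rng = np.random.default_rng(2)
        pred = {"logit": rng.normal(size=3), "box": rng.normal(size=(3, 4)),
                "kp": rng.normal(size=(3, 12))}
        target = {"label": np.array([1, 1, 0]), "box": np.zeros((3, 4)),
                  "kp": np.zeros((3, 12))}
        _, grads = multitask_loss(pred, target, 1.0, 0.5, 0.0, return_grads=True)
        assert np.array_equal(grads["kp"], np.zeros((3, 12)))

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            multitask_loss({}, {"label": np.array([1])}, -1.0, 0.5, 0.0)

    def test_negatives_contribute_only_detection_term(self):
        pred = {"logit": np.array([0.0]), "box": np.full((1, 4), 9.0),
                "kp": np.full((1, 12), 9.0)}
        target = {"label": np.array([0]), "box": np.zeros((1, 4)),
                  "kp": np.zeros((1, 12))}
        loss = multitask_loss(pred, target, 1.0, 0.5, 1.5)
        assert np.isclose(loss, -np.log(0.5))


class TestPyramid:
    def test_first_scale_from_defaults(self):
        img = np.zeros((480, 480), dtype=np.uint8)
        scales = [s for s, _ in build_pyramid(img, CascadeConfig())]
        assert np.isclose(scales[0], 48 / 80)
        assert all(a > b for a, b in zip(scales, scales[1:]))

    def test_single_level_boundary(self):
        cfg = CascadeConfig()
        side = int(np.ceil(48 / 0.6))   # smallest image giving exactly 1 level
        img = np.zeros((side, side), dtype=np.uint8)
        levels = build_pyramid(img, cfg)
        assert len(levels) == 1

    def test_halving_factor(self):
        cfg = CascadeConfig(pyramid_scale_factor=0.5)
        img = np.zeros((640, 640), dtype=np.uint8)
        scales = [s for s, _ in build_pyramid(img, cfg)]
        assert np.allclose(np.array(scales[1:]) / np.array(scales[:-1]), 0.5)

    def test_too_small_image_raises(self):
        with pytest.raises(PyramidError):
            build_pyramid(np.zeros((40, 40), dtype=np.uint8), CascadeConfig())


class TestNetworks:
    def test_stage1_output_grid_sizes(self):
        cfg = CascadeConfig()
        net = Stage1Net(cfg, np.random.default_rng(0))
        assert net.forward(np.zeros((1, 1, 48, 48))).shape == (1, 5, 1, 1)
        out = net.forward(np.zeros((1, 1, 96, 96)))
        assert out.shape[1] == 5 and out.shape[2] > 1 and out.shape[3] > 1

    def test_stage1_is_fully_convolutional(self):
        # no dense layers: the same parameters serve any input size
        cfg = tiny_cascade_config()
        net = Stage1Net(cfg, np.random.default_rng(1))
        n_params = sum(p.data.size for p in net.parameters())
        net.forward(np.zeros((1, 1, 64, 64)))
        assert sum(p.data.size for p in net.parameters()) == n_params

    def test_sliding_window_equals_per_crop_evaluation(self):
        cfg = tiny_cascade_config()
        net = Stage1Net(cfg, np.random.default_rng(2))
        rng = np.random.default_rng(3)
        img = rng.normal(size=(1, 1, 56, 56))
        full = net.forward(img)
        k = cfg.stage1_input_size
        for i in range(full.shape[2]):
            for j in range(full.shape[3]):
                crop = img[:, :, i * 8:i * 8 + k, j * 8:j * 8 + k]
                single = net.forward(crop)
                assert np.allclose(full[:, :, i, j], single[:, :, 0, 0],
                                   atol=1e-5)

    def test_stage2_output_dimensionality_and_determinism(self):
        cfg = tiny_cascade_config()
        net = Stage2Net(cfg, np.random.default_rng(4))
        net.eval()
        x = np.random.default_rng(5).normal(size=(2, 1, 48, 48))
        out = net.forward(x)
        # 1 score + 4 box offsets + 12 key-point coordinates = 17 outputs
        assert out["logit"].shape == (2,)
        assert out["box"].shape == (2, 4)
        assert out["kp"].shape == (2, 12)
        out2 = net.forward(x.copy())
        for k in out:
            assert np.array_equal(out[k], out2[k])

    def test_stage2_rejects_wrong_input_size(self):
        cfg = tiny_cascade_config()
        net = Stage2Net(cfg, np.random.default_rng(6))
        with pytest.raises(ValueError):
            net.forward(np.zeros((1, 1, 32, 32)))


class TestAccuracy:
    def test_counting(self):
        t = [np.array([0, 0, 10, 10])] * 4
        d = [Detection(np.array([0, 0, 10, 10]), 0.9),
             Detection(np.array([1, 1, 11, 11]), 0.9),
             Detection(np.array([50, 50, 60, 60]), 0.9),
             None]
        assert detection_accuracy(d, t, iou_min=0.5) == 0.5
        assert detection_accuracy([d[0]] * 4, t) == 1.0
        assert detection_accuracy([None] * 4, t) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            detection_accuracy([None], [])
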