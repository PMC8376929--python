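"""Grading network building blocks against scalar oracles."""

import numpy as np
import pytest

from kneepipe import nn
from kneepipe.grader import (GradePrediction, ResNextBlock, SEBlock,
                             SiameseGrader, TASKS, ensemble_predict,
                             gated_fuse, load_checkpoint, save_checkpoint,
                             tiny_grader_config)
from kneepipe.nn.losses import softmax


def se_oracle(p, w1, b1, w2, b2):
    """Element-wise reference for the squeeze/excite/scale equations."""
    n, c, h, w_ = p.shape
    out = np.zeros_like(p)
    for s in range(n):
        z = np.array([p[s, ch].sum() / (h * w_) for ch in range(c)])
        hidden = np.maximum(w1 @ z + b1, 0.0)
        gate = 1.0 / (1.0 + np.exp(-(w2 @ hidden + b2)))
        for ch in range(c):
            out[s, ch] = gate[ch] * p[s, ch]
    return out


class TestSEBlock:
    def test_constant_channel_squeeze_returns_constant(self):
        se = SEBlock(4, 2, rng=np.random.default_rng(0))
        p = np.zeros((1, 4, 3, 3))
        p[0, 2] = 7.5
        z = p.mean(axis=(2, 3))
        assert z[0, 2] == 7.5

    def test_zero_weights_halve_the_input(self):
        se = SEBlock(4, 2, rng=np.random.default_rng(1))
        se.fc1.weight.data[...] = 0.0
        se.fc2.weight.data[...] = 0.0
        p = np.random.default_rng(2).normal(size=(2, 4, 3, 3))
        assert np.allclose(se.forward(p), 0.5 * p)

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(3)
        se = SEBlock(4, 2, rng=rng)
        p = rng.normal(size=(3, 4, 3, 3))
        want = se_oracle(p, se.fc1.weight.data, se.fc1.bias.data,
                         se.fc2.weight.data, se.fc2.bias.data)
        assert np.allclose(se.forward(p), want, atol=1e-9)

    def test_gate_preserves_sign_pattern(self):
        rng = np.random.default_rng(4)
        se = SEBlock(8, 4, rng=rng)
        p = rng.normal(size=(2, 8, 5, 5))
        out = se.forward(p)
        assert np.all(np.sign(out) == np.sign(p))

    def test_indivisible_reduction_rejected(self):
        with pytest.raises(ValueError):
            SEBlock(6, 4)


def branch_sum_oracle(block: ResNextBlock, x: np.ndarray) -> np.ndarray:
    """Explicit per-branch evaluation of the aggregated transform: slice the
    grouped weights into ``cardinality`` independent bottlenecks and sum."""
    card, width = block.cardinality, block.width
    w_r, b_r = block.reduce.weight.data, block.reduce.bias.data
    w_g, b_g = block.grouped.weight.data, block.grouped.bias.data
    w_e, b_e = block.expand.weight.data, block.expand.bias.data
    total = None
    for i in range(card):
        sl = slice(i * width, (i + 1) * width)
        # 1x1 reduce restricted to branch i's channels
        conv_r = nn.Conv2d(x.shape[1], width, 1)
        conv_r.weight.data[...] = w_r[sl]
        conv_r.bias.data[...] = b_r[sl]
        t = np.maximum(conv_r.forward(x), 0.0)
        # branch i's 3x3 transform (its slice of the grouped convolution)
        conv_g = nn.Conv2d(width, width, 3, padding=1)
        conv_g.weight.data[...] = w_g[sl]
        conv_g.bias.data[...] = b_g[sl]
        t = np.maximum(conv_g.forward(t), 0.0)
        # branch i's contribution to the 1x1 expansion
        conv_e = nn.Conv2d(width, w_e.shape[0], 1)
        conv_e.weight.data[...] = w_e[:, sl]
        conv_e.bias.data[...] = 0.0
        t = conv_e.forward(t)
        total = t if total is None else total + t
    return total + b_e[None, :, None, None]


class TestResNextBlock:
    def test_grouped_form_equals_explicit_branch_sum(self):
        rng = np.random.default_rng(5)
        block = ResNextBlock(8, 8, cardinality=4, width=3, se_reduction=None,
                             rng=rng)
        x = rng.normal(size=(2, 8, 5, 5))
        want = x + branch_sum_oracle(block, x)
        assert np.allclose(block.forward(x), want, atol=1e-5)

    def test_zero_transform_weights_give_exact_identity(self):
        rng = np.random.default_rng(6)
        block = ResNextBlock(8, 8, cardinality=4, width=2, se_reduction=4,
                             rng=rng)
        block.expand.weight.data[...] = 0.0
        block.expand.bias.data[...] = 0.0
        x = rng.normal(size=(2, 8, 4, 4))
        assert np.array_equal(block.forward(x), x)

    def test_output_shape_matches_input_for_standard_block(self):
        block = ResNextBlock(16, 16, cardinality=4, width=4, se_reduction=8,
                             rng=np.random.default_rng(7))
        x = np.random.default_rng(8).normal(size=(1, 16, 6, 6))
        assert block.forward(x).shape == x.shape

    def test_projection_shortcut_on_channel_change(self):
        block = ResNextBlock(8, 16, cardinality=2, width=4, se_reduction=8,
                             rng=np.random.default_rng(9))
        x = np.random.default_rng(10).normal(size=(1, 8, 6, 6))
        assert block.forward(x).shape == (1, 16, 6, 6)


def fuse_oracle(f_l, f_r, w_g):
    d = len(f_l)
    f = np.zeros(d)
    g = np.zeros(d)
    for i in range(d):
        u = sum(w_g[i, j] * f_l[j] for j in range(d))
        u += sum(w_g[i, d + j] * f_r[j] for j in range(d))
        g[i] = 1.0 / (1.0 + np.exp(-u))
        f[i] = g[i] * f_l[i] + (1.0 - g[i]) * f_r[i]
    return f, g


class TestGatedFusion:
    def test_equal_features_pass_through(self):
        rng = np.random.default_rng(11)
        v = rng.normal(size=6)
        w = rng.normal(size=(6, 12))
        f, _ = gated_fuse(v, v, w)
        assert np.allclose(f, v)

    def test_zero_weights_give_exact_midpoint(self):
        rng = np.random.default_rng(12)
        f_l, f_r = rng.normal(size=6), rng.normal(size=6)
        f, g = gated_fuse(f_l, f_r, np.zeros((6, 12)))
        assert np.allclose(g, 0.5)
        assert np.allclose(f, (f_l + f_r) / 2)

    def test_matches_scalar_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            f_l, f_r = rng.normal(size=6), rng.normal(size=6)
            w = rng.normal(size=(6, 12))
            f, g = gated_fuse(f_l, f_r, w)
            wf, wg = fuse_oracle(f_l, f_r, w)
            assert np.allclose(f, wf, atol=1e-12)
            assert np.allclose(g, wg, atol=1e-12)

    def test_fusion_is_elementwise_between_inputs(self):
        rng = np.random.default_rng(14)
        f_l, f_r = rng.normal(size=8), rng.normal(size=8)
        f, _ = gated_fuse(f_l, f_r, rng.normal(size=(8, 16)))
        lo, hi = np.minimum(f_l, f_r), np.maximum(f_l, f_r)
        assert np.all(f >= lo - 1e-12) and np.all(f <= hi + 1e-12)

    def test_negated_block_swap_flips_gate_and_preserves_fusion(self):
        # exchanging the operands is undone by swapping W_g's two column
        # blocks and negating: the gate becomes 1-g and f is unchanged
        rng = np.random.default_rng(15)
        f_l, f_r = rng.normal(size=5), rng.normal(size=5)
        w = rng.normal(size=(5, 10))
        f, g = gated_fuse(f_l, f_r, w)
        w_swap = -np.concatenate([w[:, 5:], w[:, :5]], axis=1)
        f2, g2 = gated_fuse(f_r, f_l, w_swap)
        assert np.allclose(g2, 1.0 - g)
        assert np.allclose(f2, f)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            gated_fuse(np.zeros(4), np.zeros(5), np.zeros((4, 8)))


@pytest.fixture(scope="module")
def model():
    return SiameseGrader(tiny_grader_config(patch_size=32), seed=0)


class TestHeadsAndModel:

    def test_probabilities_normalized_and_uniform_for_equal_logits(self, model):
        probs = {t: softmax(np.zeros(k)) for t, k in TASKS}
        pred = GradePrediction(probs=probs)
        for t, k in TASKS:
            assert np.allclose(pred.probs[t], 1.0 / k)

    def test_shared_backbone_gives_identical_features(self, model):
        model.eval()
        x = np.random.default_rng(16).normal(size=(2, 1, 32, 32))
        f = model.backbone.forward(np.concatenate([x, x], axis=0))
        assert np.array_equal(f[:2], f[2:])

    def test_equal_patches_fuse_to_branch_feature(self, model):
        model.eval()
        x = np.random.default_rng(17).normal(size=(1, 1, 32, 32))
        logits = model.forward(x, x)
        f = model.backbone.forward(x)
        n, f_l, f_r, g = model._cache
        assert np.allclose(g * f_l + (1 - g) * f_r, f)

    def test_eval_mode_is_deterministic_and_finite_on_zero_input(self, model):
        model.eval()
        z = np.zeros((1, 1, 32, 32))
        a = model.forward(z, z)
        b = model.forward(z.copy(), z.copy())
        for t, _ in TASKS:
            assert np.array_equal(a[t], b[t])
            assert np.isfinite(a[t]).all()

    def test_train_mode_dropout_changes_outputs(self, model):
        model.train()
        x = np.random.default_rng(18).normal(size=(1, 1, 32, 32))
        a = model.forward(x, x)
        b = model.forward(x, x)
        assert any(not np.array_equal(a[t], b[t]) for t, _ in TASKS)
        model.eval()

    def test_checkpoint_roundtrip(self, model, tmp_path):
        model.eval()
        path = tmp_path / "grader.npz"
        save_checkpoint(model, path)
        clone = load_checkpoint(path)
        x = np.random.default_rng(19).normal(size=(1, 1, 32, 32))
        a, b = model.forward(x, x), clone.forward(x, x)
        for t, _ in TASKS:
            assert np.array_equal(a[t], b[t])


class TestEnsemble:
    def _pred(self, hot_task="kl", idx=0):
        probs = {}
        for t, k in TASKS:
            v = np.zeros(k)
            v[idx if t == hot_task else 0] = 1.0
            probs[t] = v
        return GradePrediction(probs=probs)

    def test_identical_models_unchanged(self):
        p = self._pred()
        e = ensemble_predict(p, p)
        for t, _ in TASKS:
            assert np.allclose(e.probs[t], p.probs[t])

    def test_one_hot_average(self):
        a = self._pred("kl", 0)
        b = self._pred("kl", 1)
        e = ensemble_predict(a, b)
        assert np.allclose(e.probs["kl"][:2], [0.5, 0.5])

    def test_averaged_vectors_still_sum_to_one(self):
        rng = np.random.default_rng(20)
        def rand_pred():
            probs = {}
            for t, k in TASKS:
                v = rng.random(k)
                probs[t] = v / v.sum()
            return GradePrediction(probs=probs)
        e = ensemble_predict(rand_pred(), rand_pred())
        for t, _ in TASKS:
            assert np.isclose(e.probs[t].sum(), 1.0)


def test_full_profile_backbone_constructs_and_runs():
    """The 50-layer stage plan (3,4,6,3 / widths 256..2048) builds and maps a
    small input to a 2048-d feature."""
    from kneepipe.grader import GraderConfig, build_backbone

    net, d = build_backbone(GraderConfig(profile="full"),
                            np.random.default_rng(21))
    assert d == 2048
    out = net.forward(np.zeros((1, 1, 64, 64)))
    assert out.shape == (1, 2048)
    assert np.isfinite(out).all()
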