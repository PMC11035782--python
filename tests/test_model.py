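"""Convolution semantics, residual blocks, and the multi-branching network."""

import numpy as np
import pytest

from afwave.errors import ConfigError, InputError
from afwave.model import (
    MBResNet,
    ResidualBlock,
    conv2d,
    feature_layer,
    residual_block,
)


class TestConv2d:
    def test_identity_kernel(self, rng):
        X = rng.normal(size=(6, 7))
        np.testing.assert_allclose(conv2d(X, np.ones((1, 1))), X)

    def test_ones_input_ones_kernel(self):
        out = conv2d(np.ones((3, 3)), np.ones((2, 2)))
        np.testing.assert_allclose(out, np.full((2, 2), 4.0))

    def test_zero_kernel_zero_output(self, rng):
        out = conv2d(rng.normal(size=(5, 5)), np.zeros((3, 3)))
        np.testing.assert_allclose(out, 0.0)

    def test_matches_nested_loop_oracle(self, rng):
        """Cross-correlation equals the double sum at every valid position."""
        for _ in range(10):
            X = rng.normal(size=(8, 8))
            theta = rng.normal(size=(3, 3))
            out = conv2d(X, theta)
            for i in range(6):
                for j in range(6):
                    ref = sum(
                        X[i + m, j + n] * theta[m, n]
                        for m in range(3)
                        for n in range(3)
                    )
                    assert out[i, j] == pytest.approx(ref, abs=1e-6)

    def test_oversized_kernel_rejected(self):
        with pytest.raises(ConfigError):
            conv2d(np.zeros((2, 2)), np.zeros((3, 3)))


class TestFeatureLayer:
    def test_identity_passthrough(self, rng):
        X = rng.normal(size=(1, 5, 5))
        w = np.ones((1, 1, 1, 1))
        out = feature_layer(X, w, np.zeros(1))
        np.testing.assert_allclose(out, X)

    def test_relu_on_all_negative_preactivation(self, rng):
        X = np.abs(rng.normal(size=(1, 4, 4)))
        w = -np.ones((1, 1, 1, 1))
        out = feature_layer(X, w, np.zeros(1), activation=lambda z: np.maximum(z, 0))
        np.testing.assert_allclose(out, 0.0)

    def test_channel_sum_doubles_for_duplicate_inputs(self, rng):
        X1 = rng.normal(size=(1, 5, 5))
        X2 = np.concatenate([X1, X1], axis=0)
        w1 = rng.normal(size=(1, 1, 3, 3))
        w2 = np.concatenate([w1, w1], axis=1)
        single = feature_layer(X1, w1, np.zeros(1))
        double = feature_layer(X2, w2, np.zeros(1))
        np.testing.assert_allclose(double, 2 * single, atol=1e-12)

    def test_channel_mismatch_rejected(self, rng):
        with pytest.raises(ConfigError):
            feature_layer(rng.normal(size=(2, 4, 4)), np.zeros((1, 3, 2, 2)), np.zeros(1))


class TestResidualBlock:
    def test_zero_weights_identity_shortcut_passes_input_through(self, rng):
        """With F forced to zero, Y = F(X) + X = X (input chosen non-negative
        so the trailing ReLU is transparent)."""
        blk = ResidualBlock(2, 2, stride=1, rng=np.random.default_rng(0))
        for conv in (blk.conv1, blk.conv2):
            conv.weight.value[...] = 0.0
        X = np.abs(rng.normal(size=(1, 2, 6, 6))).astype(np.float32)
        out = residual_block(X, blk)
        np.testing.assert_allclose(out, X, atol=1e-6)

    def test_zero_input_gives_f_of_zero(self):
        blk = ResidualBlock(2, 2, stride=1, rng=np.random.default_rng(1))
        X = np.zeros((1, 2, 6, 6), dtype=np.float32)
        out = residual_block(X, blk)
        f0 = blk.relu_out.forward(
            blk.bn2.forward(
                blk.conv2.forward(
                    blk.relu1.forward(
                        blk.bn1.forward(blk.conv1.forward(X, False), False), False
                    ),
                    False,
                ),
                False,
            )
            + X,
            False,
        )
        np.testing.assert_allclose(out, f0, atol=1e-6)

    def test_projection_shortcut_created_on_width_change(self):
        assert ResidualBlock(4, 8, stride=2).spec.shortcut == "projection"
        assert ResidualBlock(4, 4, stride=1).spec.shortcut == "identity"

    def test_backward_matches_finite_differences(self):
        """The analytic input gradient (which includes the identity shortcut
        path) agrees with central finite differences on a tiny block."""
        rng = np.random.default_rng(3)
        blk = ResidualBlock(2, 2, stride=1, rng=rng)
        X = rng.normal(size=(2, 2, 5, 5)).astype(np.float32)
        R = rng.normal(size=(2, 2, 5, 5)).astype(np.float32)

        out = blk.forward(X, train=True)
        analytic = blk.backward(R)

        eps = 1e-3
        idxs = [(0, 0, 1, 2), (1, 1, 3, 3), (0, 1, 0, 4), (1, 0, 2, 2)]
        for idx in idxs:
            xp = X.copy()
            xp[idx] += eps
            xm = X.copy()
            xm[idx] -= eps
            fd = (
                float((blk.forward(xp, True) * R).sum())
                - float((blk.forward(xm, True) * R).sum())
            ) / (2 * eps)
            assert analytic[idx] == pytest.approx(fd, rel=0.05, abs=1e-2)


class TestMBResNet:
    def test_backbone_layout_matches_standard_recipe(self):
        """7x7/64 stride-2 stem, max pool, four stages of two blocks at
        64/128/256/512, global pooling, then the branch heads."""
        net = MBResNet(n_branches=7, n_stages=4)
        spec = net.spec()
        assert spec.stem.kernel == (7, 7) and spec.stem.n_output == 64
        assert spec.stem.stride == 2
        assert spec.stage_widths == (64, 128, 256, 512)
        assert len(spec.blocks) == 8
        widths = [b.conv1.n_output for b in spec.blocks]
        assert widths == [64, 64, 128, 128, 256, 256, 512, 512]
        strides = [b.conv1.stride for b in spec.blocks]
        assert strides == [1, 1, 2, 1, 2, 1, 2, 1]
        shortcuts = [b.shortcut for b in spec.blocks]
        assert shortcuts == ["identity"] * 2 + ["projection", "identity"] * 3
        assert spec.n_branches == 7 and spec.feature_dim == 512

    def test_single_branch_returns_one_probability(self, rng):
        net = MBResNet(n_branches=1, n_stages=1, seed=0)
        p = net.forward(rng.random((2, 1, 16, 16)).astype(np.float32), train=False)
        assert p.shape == (2, 1)
        assert np.all((0 <= p) & (p <= 1))

    def test_zero_head_weights_give_half_probability(self, rng):
        net = MBResNet(n_branches=3, n_stages=1, seed=0)
        for h in net.heads:
            h.weight.value[...] = 0.0
            h.bias.value[...] = 0.0
        p = net.forward(rng.random((2, 1, 16, 16)).astype(np.float32), train=False)
        np.testing.assert_allclose(p, 0.5)

    def test_duplicate_heads_produce_identical_branches(self, rng):
        net = MBResNet(n_branches=3, n_stages=1, seed=0)
        for h in net.heads[1:]:
            h.weight.value[...] = net.heads[0].weight.value
            h.bias.value[...] = net.heads[0].bias.value
        p = net.forward(rng.random((4, 1, 16, 16)).astype(np.float32), train=False)
        np.testing.assert_allclose(p[:, 1:], p[:, :1] * np.ones((1, 2)), atol=1e-7)

    def test_forward_deterministic(self, rng):
        net = MBResNet(n_branches=2, n_stages=1, seed=0)
        x = rng.random((3, 1, 16, 16)).astype(np.float32)
        np.testing.assert_array_equal(
            net.forward(x, train=False), net.forward(x, train=False)
        )

    def test_backbone_shared_heads_private(self, rng):
        net = MBResNet(n_branches=3, n_stages=1, seed=0)
        x = rng.random((2, 1, 16, 16)).astype(np.float32)
        base = net.forward(x, train=False)
        # Mutating one head moves only that branch...
        net.heads[1].bias.value += 1.0
        p = net.forward(x, train=False)
        assert np.all(p[:, 1] != base[:, 1])
        np.testing.assert_array_equal(p[:, [0, 2]], base[:, [0, 2]])
        # ...while mutating the shared backbone moves every branch.
        net.heads[1].bias.value -= 1.0
        net.backbone.layers[0].weight.value += 0.5
        p2 = net.forward(x, train=False)
        assert np.all(p2 != base)

    def test_wrong_input_size_rejected(self):
        net = MBResNet(n_branches=1, n_stages=1)
        with pytest.raises(InputError):
            net.forward(np.zeros((1, 3, 16, 16), dtype=np.float32))
        with pytest.raises(InputError):
            net.forward(np.zeros((1, 1, 4, 4), dtype=np.float32))

    def test_state_roundtrip(self, tmp_path, rng):
        net = MBResNet(n_branches=2, n_stages=1, seed=0)
        x = rng.random((2, 1, 16, 16)).astype(np.float32)
        ref = net.forward(x, train=False)
        net.save(tmp_path / "ckpt.npz")
        other = MBResNet(n_branches=2, n_stages=1, seed=99)
        other.load(tmp_path / "ckpt.npz")
        np.testing.assert_allclose(other.forward(x, train=False), ref, atol=1e-7)

    def test_describe_prints_conv_notation(self):
        rows = MBResNet(n_branches=7, n_stages=4).describe()
        assert rows[0].startswith("2DConv(1, 64, 7x7)")
        assert any("2DConv(64, 128, 3x3)" in r for r in rows)
        assert rows[-1].endswith("sigmoid]")
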