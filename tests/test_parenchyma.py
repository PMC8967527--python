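"""Attention U-Net components: gate algebra, DAC receptive fields,
shape contracts and training behaviour."""

import numpy as np
import pytest

from nodulekit import parenchyma
from nodulekit.nn.autograd import Tensor
from nodulekit.nn.train import predict_batched
from nodulekit.parenchyma import (AttentionGate, DACBlock, DAC_BRANCHES,
                                  build_parenchyma_net, receptive_field,
                                  train_segmenter)


class TestReceptiveField:
    @pytest.mark.parametrize("branch,expected", [
        ([(3, 1)], 3),
        ([(3, 3), (1, 1)], 7),
        ([(3, 1), (3, 3), (1, 1)], 9),
        ([(3, 1), (3, 3), (3, 5), (1, 1)], 19),
        ([(1, 1)], 1),
        ([], 1),
    ])
    def test_formula(self, branch, expected):
        assert receptive_field(branch) == expected

    def test_configured_branches_match_design(self):
        assert tuple(receptive_field(b) for b in DAC_BRANCHES) == (3, 7, 9, 19)

    def test_invalid_branches_rejected(self):
        with pytest.raises(ValueError):
            receptive_field([(4, 1)])
        with pytest.raises(ValueError):
            receptive_field([(3, 0)])


class TestAttentionGate:
    def _scalar_gate(self):
        rng = np.random.default_rng(0)
        gate = AttentionGate(1, 1, rng)
        gate.wx.weight.data[:] = 1.0
        gate.wg.weight.data[:] = 1.0
        gate.wg.bias.data[:] = 0.0
        gate.phi.weight.data[:] = 1.0
        gate.phi.bias.data[:] = 0.0
        return gate

    def test_hand_worked_scalar_case(self):
        """W_x=W_g=φ=1, b=0, x=g=1 → α = sigmoid(relu(2)) ≈ 0.8808."""
        gate = self._scalar_gate()
        x = Tensor(np.ones((1, 1, 1, 1), np.float32))
        g = Tensor(np.ones((1, 1, 1, 1), np.float32))
        out = gate(x, g)
        expected = 1.0 / (1.0 + np.exp(-2.0))
        assert abs(out.data.item() - expected) < 1e-5

    def test_saturated_bias_limits(self):
        gate = self._scalar_gate()
        x = Tensor(np.full((1, 1, 2, 2), 3.0, np.float32))
        g = Tensor(np.ones((1, 1, 2, 2), np.float32))
        gate.phi.bias.data[:] = 50.0  # α → 1: output ≈ x
        np.testing.assert_allclose(gate(x, g).data, x.data, atol=1e-4)
        gate.phi.bias.data[:] = -50.0  # α → 0: output ≈ 0
        np.testing.assert_allclose(gate(x, g).data, 0.0, atol=1e-4)

    def test_alpha_strictly_in_unit_interval(self, rng):
        np_rng = np.random.default_rng(5)
        gate = AttentionGate(4, 2, np_rng)
        x = Tensor(rng.standard_normal((2, 4, 8, 8)).astype(np.float32))
        g = Tensor(rng.standard_normal((2, 4, 8, 8)).astype(np.float32))
        alpha = gate.attention(x, g).data
        assert (alpha > 0).all() and (alpha < 1).all()
        # gated output never exceeds the input in magnitude
        out = gate(x, g).data
        assert (np.abs(out) <= np.abs(x.data) + 1e-6).all()

    def test_channel_mismatch_raises(self, rng):
        gate = AttentionGate(4, 2, np.random.default_rng(0))
        bad = Tensor(np.zeros((1, 3, 4, 4), np.float32))
        g = Tensor(np.zeros((1, 3, 4, 4), np.float32))
        with pytest.raises(ValueError):
            gate(bad, g)


class TestDACBlock:
    def test_zero_weights_residual_passthrough(self):
        block = DACBlock(3, np.random.default_rng(0))
        for p in block.parameters():
            p.data[:] = 0.0
        x = np.abs(np.random.default_rng(1).standard_normal(
            (1, 3, 10, 10))).astype(np.float32)
        out = block(Tensor(x))
        np.testing.assert_allclose(out.data, x, atol=1e-6)

    def test_receptive_fields_printed_constants(self):
        block = DACBlock(2, np.random.default_rng(0))
        assert block.rf == (3, 7, 9, 19)

    @pytest.mark.parametrize("size", [20, 64])
    def test_spatial_size_unchanged(self, size):
        block = DACBlock(2, np.random.default_rng(0))
        x = Tensor(np.zeros((1, 2, size, size), np.float32))
        assert block(x).shape == (1, 2, size, size)


@pytest.fixture(scope="module")
def net():
    return build_parenchyma_net(levels=3, base_channels=4, seed=0)


class TestNetwork:
    @pytest.mark.parametrize("size", [64, 200])
    def test_same_size_probability_output(self, net, size):
        x = Tensor(np.random.default_rng(2).random(
            (1, 1, size, size)).astype(np.float32))
        out = net(x)
        assert out.shape == (1, 1, size, size)
        assert (out.data >= 0).all() and (out.data <= 1).all()

    def test_eval_determinism(self, net, rng):
        x = rng.random((2, 32, 32)).astype(np.float32)
        a = predict_batched(net, x)
        b = predict_batched(net, x)
        assert np.array_equal(a, b)

    def test_strict_policy_names_required_padding(self):
        net = build_parenchyma_net(levels=3, base_channels=4, seed=0,
                                   pad_policy="strict")
        with pytest.raises(ValueError, match="pad"):
            net(Tensor(np.zeros((1, 1, 65, 65), np.float32)))


class TestTraining:
    def test_zero_learning_rate_is_null_step(self, rng):
        net = build_parenchyma_net(levels=2, base_channels=4, seed=1)
        before = [p.data.copy() for p in net.parameters()]
        imgs = rng.random((4, 16, 16)).astype(np.float32)
        msks = (rng.random((4, 16, 16)) > 0.5).astype(np.float32)
        hist = train_segmenter(net, imgs, msks, epochs=3, lr=0.0, seed=0)
        assert len(set(np.round(hist, 10))) == 1  # loss constant
        for p, b in zip(net.parameters(), before):
            assert np.array_equal(p.data, b)

    def test_memorizes_single_pair(self, rng):
        net = build_parenchyma_net(levels=2, base_channels=4, seed=2)
        img = rng.random((1, 32, 32)).astype(np.float32)
        yy, xx = np.mgrid[:32, :32]
        msk = (((yy - 16) ** 2 + (xx - 16) ** 2) < 81).astype(np.float32)[None]
        hist = train_segmenter(net, img, msk, epochs=120, lr=3e-3, seed=0)
        assert hist[-1] < 0.05

    def test_empty_or_degenerate_data_rejected(self):
        net = build_parenchyma_net(levels=2, base_channels=2, seed=0)
        with pytest.raises(ValueError):
            train_segmenter(net, np.empty((0, 8, 8)), np.empty((0, 8, 8)))
        z = np.zeros((2, 8, 8), np.float32)
        with pytest.raises(ValueError):
            train_segmenter(net, z, z)  # all-background masks


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, tmp_path, rng):
        net = build_parenchyma_net(levels=2, base_channels=4, seed=3)
        x = rng.random((1, 24, 24)).astype(np.float32)
        p = tmp_path / "ckpt.npz"
        parenchyma.save_checkpoint(net, p)
        back = parenchyma.load_checkpoint(p)
        assert np.array_equal(predict_batched(net, x),
                              predict_batched(back, x))

    def test_missing_checkpoint_named(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="nowhere.npz"):
            parenchyma.load_checkpoint(tmp_path / "nowhere.npz")
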