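"""Architecture contracts of the multiscale residual regression network."""

import numpy as np
import pytest

from lungjac.network import (
    NetworkConfig, build_network, expected_parameter_count, load_checkpoint,
    predict_jacobian, save_checkpoint, select_channels,
)
from lungjac.preprocess import prepare_case
from lungjac.training import StudyArm


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            NetworkConfig(levels=0)
        with pytest.raises(ValueError):
            NetworkConfig(in_channels=3)
        with pytest.raises(ValueError):
            NetworkConfig(kernel_size=4)

    def test_channel_schedule(self):
        cfg = NetworkConfig(levels=4, base_filters=8)
        assert [cfg.channels_at(l) for l in range(4)] == [8, 16, 32, 64]
        assert cfg.divisor == 8


class TestShapes:
    def test_full_size_output_and_fusion_width(self):
        cfg = NetworkConfig(levels=4, base_filters=8, in_channels=2)
        model = build_network(cfg)
        x = np.random.default_rng(0).standard_normal((2, 16, 16, 16)).astype(np.float32)
        y = model.forward(x)
        assert y.shape == (1, 16, 16, 16)
        # multiscale fusion is C_0 * L channels wide
        assert model.integrate1.conv.cin == 8 * 4

    def test_reduced_depth_single_channel(self):
        cfg = NetworkConfig(levels=2, base_filters=8, in_channels=1)
        model = build_network(cfg)
        x = np.zeros((1, 16, 16, 16), dtype=np.float32)
        assert model.forward(x).shape == (1, 16, 16, 16)

    def test_level_feature_shapes(self):
        """Feature maps at level l have shape input/2^l with C_0*2^l channels."""
        cfg = NetworkConfig(levels=3, base_filters=4, in_channels=1)
        model = build_network(cfg)
        x = np.random.default_rng(1).standard_normal((1, 16, 16, 16)).astype(np.float32)
        a = model.stem.forward(x)
        for l in range(cfg.levels):
            a = model.id_blocks[l].forward(a)
            assert a.shape == (4 * 2**l, 16 // 2**l, 16 // 2**l, 16 // 2**l)
            if l < cfg.levels - 1:
                a = model.down_blocks[l].forward(a)

    def test_indivisible_extent_rejected(self):
        model = build_network(NetworkConfig(levels=4, base_filters=4, in_channels=1))
        with pytest.raises(ValueError, match="divisible"):
            model.forward(np.zeros((1, 20, 16, 16), dtype=np.float32))

    def test_channel_mismatch_rejected(self):
        model = build_network(NetworkConfig(levels=2, in_channels=2))
        with pytest.raises(ValueError, match="arm/input mismatch"):
            model.forward(np.zeros((1, 8, 8, 8), dtype=np.float32))


class TestParameterCount:
    @pytest.mark.parametrize("cfg", [
        NetworkConfig(levels=4, base_filters=8, in_channels=2),
        NetworkConfig(levels=3, base_filters=8, in_channels=1),
        NetworkConfig(levels=2, base_filters=4, in_channels=2, kernel_size=5),
    ])
    def test_matches_layer_ledger(self, cfg):
        assert build_network(cfg).parameter_count() == expected_parameter_count(cfg)


class TestResidualPaths:
    def test_identity_block_with_zero_weights_is_identity(self):
        cfg = NetworkConfig(levels=2, base_filters=4, in_channels=1)
        model = build_network(cfg)
        block = model.id_blocks[0]
        for layer in (block.conv1, block.conv2):
            layer.W.value[...] = 0.0
            layer.b.value[...] = 0.0
        # keep norm affine neutral so the residual path is exact
        x = np.abs(np.random.default_rng(0).standard_normal((4, 8, 8, 8))).astype(np.float32)
        out = block.forward(x)
        np.testing.assert_allclose(out, x, atol=1e-6)

    def test_zero_final_layer_predicts_no_volume_change(self):
        cfg = NetworkConfig(levels=2, base_filters=4, in_channels=1)
        model = build_network(cfg)
        model.integrate2.W.value[...] = 0.0
        model.integrate2.b.value[...] = 0.0
        x = np.random.default_rng(0).standard_normal((1, 8, 8, 8)).astype(np.float32)
        y = model.forward(x)
        np.testing.assert_allclose(y, 0.0, atol=1e-7)
        np.testing.assert_allclose(np.exp2(y), 1.0, atol=1e-6)


class TestForward:
    def test_deterministic_inference(self):
        model = build_network(NetworkConfig(levels=2, base_filters=4, in_channels=2))
        x = np.random.default_rng(0).standard_normal((2, 8, 8, 8)).astype(np.float32)
        np.testing.assert_array_equal(model.forward(x), model.forward(x))

    def test_nonfinite_input_rejected(self):
        model = build_network(NetworkConfig(levels=2, base_filters=4, in_channels=1))
        x = np.full((1, 8, 8, 8), np.nan, dtype=np.float32)
        with pytest.raises(ValueError, match="finite"):
            model.forward(x)

    def test_gradient_reaches_level_zero(self):
        """One optimization step changes level-0 parameters (no vanishing path)."""
        from lungjac import nn
        model = build_network(NetworkConfig(levels=3, base_filters=4, in_channels=1))
        x = np.random.default_rng(0).standard_normal((1, 8, 8, 8)).astype(np.float32)
        before = model.id_blocks[0].conv1.W.value.copy()
        opt = nn.AMSGrad(model.parameters(), lr=1e-3)
        opt.zero_grad()
        y = model.forward(x)
        model.backward(np.ones_like(y))
        assert np.abs(model.id_blocks[0].conv1.W.grad).max() > 0
        opt.step()
        assert not np.allclose(model.id_blocks[0].conv1.W.value, before)


class TestPrediction:
    def test_predict_jacobian_positive_and_unpadded(self, noiseless_case):
        prep = prepare_case(noiseless_case, multiple=2)
        model = build_network(NetworkConfig(levels=2, base_filters=4, in_channels=2))
        jmap = predict_jacobian(model, prep, StudyArm("paired", "FRC"))
        assert np.all(np.asarray(jmap.J.data) > 0)
        from lungjac.preprocess import unpad
        assert jmap.J.shape == unpad(prep.y_frc, prep.pads).shape

    def test_single_arm_selects_matching_channel(self, noiseless_case):
        prep = prepare_case(noiseless_case, multiple=2)
        xf = select_channels(prep.x, StudyArm("single", "FRC"))
        xt = select_channels(prep.x, StudyArm("single", "TLC"))
        np.testing.assert_array_equal(xf[0], prep.x[0])
        np.testing.assert_array_equal(xt[0], prep.x[1])
        assert select_channels(prep.x, StudyArm("paired", "FRC")).shape[0] == 2

    def test_arm_input_mismatch_raises(self, noiseless_case):
        prep = prepare_case(noiseless_case, multiple=2)
        model = build_network(NetworkConfig(levels=2, base_filters=4, in_channels=2))
        # a paired model fed a single-channel arm selection must fail
        with pytest.raises(ValueError, match="arm/input mismatch"):
            model.forward(select_channels(prep.x, StudyArm("single", "FRC")))


class TestCheckpoint:
    def test_round_trip(self, tmp_path):
        cfg = NetworkConfig(levels=2, base_filters=4, in_channels=2, seed=9)
        model = build_network(cfg)
        path = save_checkpoint(model, tmp_path / "ck.npz", extra={"arm": "paired_frc"})
        back, extra = load_checkpoint(path)
        assert extra == {"arm": "paired_frc"}
        assert back.cfg == cfg
        x = np.random.default_rng(0).standard_normal((2, 8, 8, 8)).astype(np.float32)
        np.testing.assert_array_equal(back.forward(x), model.forward(x))
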