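"""Executable network: gate/mask semantics, segmentation contracts,
feature extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ultraseg as us
import ultraseg.nn as nn


class TestAttentionGateForward:
    def test_zero_weights_average_the_inputs(self, rng):
        x = rng.random((4, 4, 2))
        xup = rng.random((4, 4, 2))
        out = us.attention_gate_forward(x, xup, np.zeros((3, 2)))
        assert np.allclose(out, (x + xup) / 2, atol=1e-6)

    def test_equal_inputs_pass_through_for_any_weights(self, rng):
        x = rng.random((5, 5, 3))
        w = rng.normal(size=(4, 3))
        out = us.attention_gate_forward(x, x.copy(), w)
        assert np.allclose(out, x, atol=1e-6)

    def test_output_bounded_elementwise_by_inputs(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(4, 4, 2))
        xup = rng.normal(size=(4, 4, 2))
        w = rng.normal(size=(8, 2))
        out = us.attention_gate_forward(x, xup, w)
        lo = np.minimum(x, xup)
        hi = np.maximum(x, xup)
        assert (out >= lo - 1e-6).all() and (out <= hi + 1e-6).all()

    @settings(deadline=None, max_examples=50)
    @given(seed=st.integers(0, 10_000))
    def test_convex_combination_property(self, seed):
        """The gate output is always an elementwise convex combination."""
        rng = np.random.default_rng(seed)
        c = int(rng.integers(1, 5))
        x = rng.normal(scale=3.0, size=(3, 4, c))
        xup = rng.normal(scale=3.0, size=(3, 4, c))
        w = rng.normal(size=(int(rng.integers(1, 6)), c))
        out = us.attention_gate_forward(x, xup, w)
        assert (out >= np.minimum(x, xup) - 1e-5).all()
        assert (out <= np.maximum(x, xup) + 1e-5).all()

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            us.attention_gate_forward(rng.random((4, 4, 2)),
                                      rng.random((4, 5, 2)),
                                      np.zeros((3, 2)))


class TestMaskFeatures:
    def test_all_ones_mask_is_identity(self, rng):
        f = rng.random((6, 6, 3))
        assert np.array_equal(us.mask_features(f, np.ones((6, 6), int)), f)

    def test_all_zeros_mask_zeroes_everything(self, rng):
        f = rng.random((6, 6, 3))
        assert not us.mask_features(f, np.zeros((6, 6), int)).any()

    def test_checkerboard_support_sum(self):
        f = np.full((4, 4, 2), 3.0)
        mask = np.indices((4, 4)).sum(axis=0) % 2
        out = us.mask_features(f, mask)
        assert out.sum() == 3.0 * mask.sum() * 2

    def test_off_support_is_exactly_zero(self, rng):
        f = rng.random((8, 8))
        mask = (rng.random((8, 8)) > 0.5).astype(int)
        out = us.mask_features(f, mask)
        assert not out[mask == 0].any()
        assert np.array_equal(out[mask == 1], f[mask == 1])

    def test_idempotent(self, rng):
        f = rng.random((5, 5, 2))
        mask = (rng.random((5, 5)) > 0.3).astype(int)
        once = us.mask_features(f, mask)
        assert np.array_equal(us.mask_features(once, mask), once)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            us.mask_features(rng.random((4, 4)), np.zeros((5, 4), int))

    def test_non_binary_mask_rejected(self, rng):
        with pytest.raises(ValueError, match="binary"):
            us.mask_features(rng.random((4, 4)), np.full((4, 4), 0.5))


class TestMultiResForward:
    def test_zero_path_with_identity_residual_passes_input(self, rng):
        blk = nn.MultiResBlock(6, 6, shortcut="identity", rng=rng)
        for p in blk.params():
            p.data[...] = 0.0
        x = rng.random((5, 5, 6))  # non-negative input
        assert np.allclose(us.multires_forward(x, blk), x, atol=1e-6)

    def test_same_padding_preserves_spatial_dims(self, rng):
        blk = nn.MultiResBlock(2, 9, rng=rng)
        out = us.multires_forward(rng.random((7, 11, 2)), blk)
        assert out.shape == (7, 11, 9)

    def test_channel_mismatch_rejected(self, rng):
        blk = nn.MultiResBlock(3, 6, rng=rng)
        with pytest.raises(ValueError, match="channels"):
            us.multires_forward(rng.random((4, 4, 2)), blk)


class TestSegment:
    def test_zero_output_layer_gives_constant_half(self, tiny_config, rng):
        net = us.build_network(tiny_config)
        net.out_conv.w.data[...] = 0.0
        net.out_conv.b.data[...] = 0.0
        probs = us.segment(rng.random((32, 32)), net)
        assert np.allclose(probs, 0.5)

    def test_probabilities_strictly_inside_unit_interval(self, tiny_net,
                                                         rng):
        probs = us.segment(rng.random((32, 32)), tiny_net)
        assert probs.shape == (32, 32)
        assert (probs > 0).all() and (probs < 1).all()

    def test_deterministic_across_reexecution(self, tiny_config):
        img = us.make_sample(us.PhantomParams.for_class(
            "benign", height=32, width=32, seed=0)).image
        p1 = us.segment(img, us.build_network(tiny_config))
        p2 = us.segment(img, us.build_network(tiny_config))
        assert np.array_equal(p1, p2)

    def test_input_size_mismatch_rejected(self, tiny_net, rng):
        with pytest.raises(ValueError, match="does not match"):
            us.segment(rng.random((64, 64)), tiny_net)

    @pytest.mark.parametrize("size", [(16, 16), (32, 48), (48, 16)])
    def test_output_dims_equal_input_dims(self, size, rng):
        cfg = us.ModelConfig(input_height=size[0], input_width=size[1],
                             filter_schedule=(3, 4, 6, 8, 12), seed=1)
        probs = us.segment(rng.random(size), us.build_network(cfg))
        assert probs.shape == size


class TestExtractFeatures:
    def test_stage_channels_follow_filter_schedule(self, rng):
        cfg = us.ModelConfig(input_height=32, input_width=32, seed=0)
        net = us.build_network(cfg)
        img = rng.random((32, 32))
        fm = us.extract_features(img, net, "encoder-3")
        assert fm.shape == (8, 8, 128)
        fm = us.extract_features(img, net, "decoder-2")
        assert fm.shape == (32, 32, 32)

    def test_zeroed_network_yields_zero_first_stage(self, tiny_config, rng):
        net = us.build_network(tiny_config)
        for p in net.params():
            p.data[...] = 0.0
        fm = us.extract_features(np.zeros((32, 32)), net, "encoder-1")
        assert not fm.any()

    def test_unknown_stage_error_lists_valid_names(self, tiny_net, rng):
        with pytest.raises(ValueError, match="encoder-9.*valid stages"):
            us.extract_features(rng.random((32, 32)), tiny_net, "encoder-9")


class TestNetworkStructure:
    def test_transpose_upsampling_not_executable(self):
        cfg = us.ModelConfig(upsample_mode="transpose")
        with pytest.raises(NotImplementedError):
            us.build_network(cfg)

    def test_state_round_trip(self, tiny_config, rng):
        net = us.build_network(tiny_config)
        state = net.get_state()
        img = rng.random((32, 32))
        before = us.segment(img, net)
        for p in net.params():
            p.data += 1.0
        net.set_state(state)
        assert np.array_equal(us.segment(img, net), before)

    def test_save_load_file(self, tiny_config, tmp_path, rng):
        net = us.build_network(tiny_config)
        img = rng.random((32, 32))
        before = us.segment(img, net)
        net.save(tmp_path / "w.npz")
        other = us.build_network(
            us.ModelConfig(input_height=32, input_width=32,
                           filter_schedule=(4, 8, 16, 24, 32), seed=99))
        other.load(tmp_path / "w.npz")
        assert np.array_equal(us.segment(img, other), before)
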