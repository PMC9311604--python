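"""CBAM channel/spatial attention versus independent scalar-loop oracles."""

import numpy as np
import pytest

from _oracles import cbam_oracle, channel_attention_oracle, spatial_attention_oracle
from mbeegcbam.attention import (CBAM, AttentionConfig, ChannelAttention,
                                 SpatialAttention, cbam, channel_attention,
                                 spatial_attention)


def make_channel(n_channels, ratio, seed=0, dtype=np.float64):
    return ChannelAttention(n_channels, ratio, np.random.default_rng(seed), dtype)


def make_spatial(kernel, seed=0, dtype=np.float64):
    return SpatialAttention(kernel, np.random.default_rng(seed), dtype)


class TestChannelAttention:
    def test_hand_example_identity_mlp(self):
        # channel 0: all ones (mean 1, max 1); channel 1: all zeros
        fmap = np.stack([np.ones((1, 4)), np.zeros((1, 4))])
        mod = make_channel(2, ratio=1)
        mod.w1.value = np.eye(2)
        mod.w2.value = np.eye(2)
        w = channel_attention(fmap, mod)
        expected = np.array([1 / (1 + np.exp(-2.0)), 0.5])  # sigmoid(2), sigmoid(0)
        np.testing.assert_allclose(w, expected, atol=1e-12)
        np.testing.assert_allclose(w[0], 0.8808, atol=1e-4)

    def test_constant_map_equal_weights_for_symmetric_mlp(self):
        fmap = np.full((3, 2, 5), 0.7)
        mod = make_channel(3, ratio=1)
        mod.w1.value = np.eye(3)
        mod.w2.value = np.eye(3)
        w = channel_attention(fmap, mod)
        assert np.ptp(w) < 1e-12

    def test_matches_scalar_loop_oracle(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            shape = (int(rng.integers(1, 5)), int(rng.integers(1, 3)),
                     int(rng.integers(1, 7)))
            fmap = rng.normal(size=shape)
            mod = make_channel(shape[0], ratio=int(rng.choice([1, 2, 8])),
                               seed=seed + 100)
            w = channel_attention(fmap, mod)
            expected = channel_attention_oracle(fmap, mod.w1.value, mod.w2.value)
            np.testing.assert_allclose(w, expected, atol=1e-6)

    def test_weights_strictly_in_unit_interval(self, rng):
        fmap = rng.normal(size=(8, 1, 17))
        w = channel_attention(fmap, make_channel(8, 8, seed=3))
        assert np.all(w > 0) and np.all(w < 1)

    def test_invariant_to_spatial_permutation(self, rng):
        fmap = rng.normal(size=(4, 1, 10))
        mod = make_channel(4, 2, seed=5)
        w1 = channel_attention(fmap, mod)
        w2 = channel_attention(fmap[:, :, rng.permutation(10)], mod)
        np.testing.assert_allclose(w1, w2, atol=1e-12)

    def test_hidden_width_floor_allows_large_ratio(self):
        mod = make_channel(4, ratio=8)  # hidden = max(1, 4 // 8) = 1
        assert mod.w1.value.shape == (1, 4)

    def test_channel_count_mismatch_errors(self, rng):
        with pytest.raises(ValueError, match="channels"):
            channel_attention(rng.normal(size=(5, 1, 4)), make_channel(4, 2))


class TestSpatialAttention:
    def test_sliding_window_hand_example(self):
        # single channel so mean == max == (1, 2, 3); 2x2 ones kernel, no bias
        fmap = np.array([[[1.0, 2.0, 3.0]]])
        mod = make_spatial(2)
        mod.weight.value = np.ones((2, 2, 2))
        mod.bias.value = np.zeros(1)
        m = spatial_attention(fmap, mod)
        # trailing-side padding: z = [2*(1+2), 2*(2+3), 2*3]
        expected = 1 / (1 + np.exp(-np.array([6.0, 10.0, 6.0])))
        np.testing.assert_allclose(m[0, 0], expected, atol=1e-12)

    def test_constant_input_uniform_away_from_borders(self):
        fmap = np.full((3, 1, 9), 2.0)
        mod = make_spatial(3, seed=1)
        m = spatial_attention(fmap, mod)[0, 0]
        interior = m[1:-1]
        assert np.ptp(interior) < 1e-12

    def test_matches_scalar_loop_oracle(self):
        for seed in range(10):
            rng = np.random.default_rng(seed + 50)
            shape = (int(rng.integers(1, 5)), int(rng.integers(1, 3)),
                     int(rng.integers(1, 7)))
            fmap = rng.normal(size=shape)
            mod = make_spatial(int(rng.choice([2, 3, 4])), seed=seed)
            m = spatial_attention(fmap, mod)
            expected = spatial_attention_oracle(fmap, mod.weight.value,
                                                float(mod.bias.value[0]))
            np.testing.assert_allclose(m, expected, atol=1e-6)

    def test_map_unchanged_by_channel_permutation(self, rng):
        fmap = rng.normal(size=(6, 1, 8))
        mod = make_spatial(2, seed=9)
        m1 = spatial_attention(fmap, mod)
        m2 = spatial_attention(fmap[rng.permutation(6)], mod)
        np.testing.assert_allclose(m1, m2, atol=1e-12)


class TestCBAM:
    def make(self, n_channels, ratio, kernel, seed=0):
        return CBAM(n_channels, AttentionConfig(ratio=ratio, kernel=kernel),
                    np.random.default_rng(seed), np.float64)

    def test_composition_matches_oracles(self):
        for seed in range(10):
            rng = np.random.default_rng(seed + 200)
            fmap = rng.normal(size=(4, 1, 6))
            mod = self.make(4, ratio=2, kernel=2, seed=seed)
            out = cbam(fmap, mod)
            expected = cbam_oracle(fmap, mod.channel.w1.value,
                                   mod.channel.w2.value,
                                   mod.spatial.weight.value,
                                   float(mod.spatial.bias.value[0]))
            assert np.abs(out - expected).max() < 1e-6

    def test_identity_limit_with_large_logits(self, rng):
        fmap = np.abs(rng.normal(size=(4, 1, 6))) + 0.1
        mod = self.make(4, ratio=2, kernel=2)
        big = 1e4
        mod.channel.w1.value = big * np.ones_like(mod.channel.w1.value)
        mod.channel.w2.value = np.ones_like(mod.channel.w2.value)
        mod.spatial.weight.value = np.zeros_like(mod.spatial.weight.value)
        mod.spatial.bias.value = np.array([big])
        np.testing.assert_allclose(cbam(fmap, mod), fmap, rtol=1e-6)

    def test_shape_preserved(self, rng):
        fmap = rng.normal(size=(32, 1, 17))
        out = cbam(fmap, self.make(32, ratio=8, kernel=2))
        assert out.shape == (32, 1, 17)

    def test_output_magnitude_never_exceeds_input(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            fmap = rng.normal(size=(4, 2, 6))
            out = cbam(fmap, self.make(4, ratio=2, kernel=3, seed=seed))
            assert np.all(np.abs(out) <= np.abs(fmap) + 1e-15)
            nonzero = np.abs(fmap) > 1e-12
            assert np.all(np.abs(out[nonzero]) < np.abs(fmap[nonzero]))

    def test_non_finite_map_rejected(self):
        bad = np.full((2, 1, 3), np.nan)
        with pytest.raises(ValueError, match="finite"):
            cbam(bad, self.make(2, ratio=1, kernel=2))


def test_attention_config_validation():
    with pytest.raises(ValueError):
        AttentionConfig(ratio=0, kernel=2)
    with pytest.raises(ValueError):
        AttentionConfig(ratio=2, kernel=2, hidden_activation="tanh")
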