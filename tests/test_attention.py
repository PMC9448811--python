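"""Attention mechanism: equation-level oracle equivalence, gate and map
invariants, shape contracts, and degenerate hand-computable cases."""

import numpy as np
import pytest

from hccanet import (
    AttentionWeights,
    MCCBAMConfig,
    mccbam,
    sk_channel_attention,
    sk_channel_gate,
    spatial_attention_map,
)
from hccanet.attention import SKBranchWeights

from oracles import (
    mccbam_oracle,
    sk_attention_oracle,
    sk_gate_oracle,
    spatial_map_oracle,
)


def _random_fm(seed, shape=(4, 4, 2)):
    return np.random.default_rng(seed).normal(size=shape)


def _zero_fc_weights(channels, cfg):
    w = AttentionWeights.initialize(channels, cfg, seed=0)
    for bw in w.branches.values():
        bw.fc1_w[:] = 0
        bw.fc1_b[:] = 0
        bw.fc2_w[:] = 0
        bw.fc2_b[:] = 0
    return w


class TestChannelGate:
    def test_gate_complement_holds_exactly_across_seeds(self, small_cfg):
        for seed in range(25):
            fm = _random_fm(seed)
            w = AttentionWeights.initialize(2, small_cfg, seed=seed + 100)
            for r in small_cfg.reduction_ratios:
                g = sk_channel_gate(fm, r, w)
                assert np.all(g.ma + g.mb == 1.0)
                assert np.all((g.ma > 0) & (g.ma < 1))
                assert g.ma.shape == (2,)

    def test_zero_fc_weights_give_half_gates(self, small_cfg):
        w = _zero_fc_weights(8, small_cfg)
        g = sk_channel_gate(_random_fm(0, (5, 5, 8)), 4, w)
        assert np.allclose(g.ma, 0.5)
        assert np.allclose(g.mb, 0.5)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_gate_matches_straight_line_oracle(self, small_cfg, seed):
        fm = np.random.default_rng(seed).normal(size=(4, 4, 8))
        w = AttentionWeights.initialize(8, small_cfg, seed=seed)
        for r in small_cfg.reduction_ratios:
            got = sk_channel_gate(fm, r, w).ma
            want, _, _ = sk_gate_oracle(fm, w.branch(r))
            assert np.max(np.abs(got - want)) <= 1e-5

    def test_permutation_equivariance(self, small_cfg):
        c = 6
        fm = _random_fm(3, (4, 4, c))
        w = AttentionWeights.initialize(c, small_cfg, seed=3)
        perm = np.random.default_rng(0).permutation(c)
        wp = AttentionWeights.initialize(c, small_cfg, seed=3)
        for r in small_cfg.reduction_ratios:
            b, bp = w.branch(r), wp.branch(r)
            bp.w3[:] = b.w3[:, :, perm][:, :, :, perm]
            bp.w5[:] = b.w5[:, :, perm][:, :, :, perm]
            bp.fc1_w[:] = b.fc1_w[perm]
            bp.fc2_w[:] = b.fc2_w[:, perm]
            bp.fc2_b[:] = b.fc2_b[perm]
        for r in small_cfg.reduction_ratios:
            ma = sk_channel_gate(fm, r, w).ma
            ma_p = sk_channel_gate(fm[:, :, perm], r, wp).ma
            assert np.allclose(ma_p, ma[perm], atol=1e-12)

    def test_rejects_nonfinite_input(self, small_weights):
        fm = np.full((3, 3, 2), np.nan)
        with pytest.raises(ValueError, match="non-finite"):
            sk_channel_gate(fm, 4, small_weights)


class TestChannelAttention:
    def test_preserves_input_shape(self, small_cfg):
        fm = _random_fm(1, (6, 5, 8))
        w = AttentionWeights.initialize(8, small_cfg, seed=2)
        assert sk_channel_attention(fm, 8, w).shape == fm.shape

    def test_equal_gates_average_branches(self, small_cfg):
        fm = _random_fm(2, (4, 4, 4))
        w = _zero_fc_weights(4, small_cfg)
        got = sk_channel_attention(fm, 4, w)
        _, u3, u5 = sk_gate_oracle(fm, w.branch(4))
        assert np.allclose(got, 0.5 * (u3 + u5), atol=1e-5)

    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_matches_straight_line_oracle(self, small_cfg, seed):
        fm = _random_fm(seed)
        w = AttentionWeights.initialize(2, small_cfg, seed=seed)
        got = sk_channel_attention(fm, 4, w)
        assert np.max(np.abs(got - sk_attention_oracle(fm, w.branch(4)))) <= 1e-5


class TestSpatialAttention:
    def test_zero_kernel_gives_half_everywhere(self, small_cfg):
        w = AttentionWeights.initialize(16, small_cfg, seed=0)
        w.spatial_w[:] = 0
        w.spatial_b[:] = 0
        m = spatial_attention_map(_random_fm(0, (8, 8, 16)), 7, w)
        assert np.allclose(m, 0.5)

    def test_output_shape_and_open_interval(self, small_cfg):
        w = AttentionWeights.initialize(16, small_cfg, seed=1)
        m = spatial_attention_map(_random_fm(1, (8, 8, 16)), 7, w)
        assert m.shape == (8, 8, 1)
        assert np.all((m > 0) & (m < 1))

    @pytest.mark.parametrize("seed", [20, 21, 22])
    def test_matches_straight_line_oracle(self, small_cfg, seed):
        fm = np.random.default_rng(seed).normal(size=(5, 5, 3))
        w = AttentionWeights.initialize(3, small_cfg, seed=seed)
        got = spatial_attention_map(fm, 7, w)
        want = spatial_map_oracle(fm, w.spatial_w, w.spatial_b)
        assert np.max(np.abs(got - want)) <= 1e-5

    def test_rejects_even_kernel(self, small_fm, small_weights):
        with pytest.raises(ValueError, match="odd"):
            spatial_attention_map(small_fm, 4, small_weights)


class TestMCCBAM:
    def test_triples_channel_count(self, small_cfg):
        fm = _random_fm(0, (4, 4, 8))
        w = AttentionWeights.initialize(8, small_cfg, seed=0)
        out = mccbam(fm, small_cfg, w)
        assert out.shape == (4, 4, 24)

    def test_degenerate_single_pixel_hand_case(self):
        # center-tap identity branch kernels, zero FC and spatial weights:
        # each refined branch yields v, product = v^2, spatial map = 0.5
        cfg = MCCBAMConfig(reduction_ratios=(4, 8, 16), branch_kernels=(3, 5),
                           spatial_kernel=7)
        v = 1.7
        fm = np.full((1, 1, 1), v)
        w = _zero_fc_weights(1, cfg)
        for bw in w.branches.values():
            bw.w3[:] = 0
            bw.w5[:] = 0
            bw.w3[1, 1, 0, 0] = 1.0
            bw.w5[2, 2, 0, 0] = 1.0
        w.spatial_w[:] = 0
        w.spatial_b[:] = 0
        out = mccbam(fm, cfg, w)
        assert np.allclose(out.ravel(), [0.5 * v**2] * 3)

    @pytest.mark.parametrize("seed", [30, 31, 32])
    def test_matches_composed_oracle(self, small_cfg, seed):
        fm = _random_fm(seed)
        w = AttentionWeights.initialize(2, small_cfg, seed=seed)
        got = mccbam(fm, small_cfg, w)
        want = mccbam_oracle(fm, small_cfg.reduction_ratios, w.branches,
                             w.spatial_w, w.spatial_b)
        assert np.max(np.abs(got - want)) <= 1e-5


class TestConfigValidation:
    def test_rejects_even_kernels_and_bad_ratios(self):
        with pytest.raises(ValueError):
            MCCBAMConfig(branch_kernels=(2, 5))
        with pytest.raises(ValueError):
            MCCBAMConfig(spatial_kernel=6)
        with pytest.raises(ValueError):
            MCCBAMConfig(reduction_ratios=(4, 0, 16))

    def test_weights_deterministic_under_seed(self, small_cfg):
        w1 = AttentionWeights.initialize(8, small_cfg, seed=5)
        w2 = AttentionWeights.initialize(8, small_cfg, seed=5)
        assert np.array_equal(w1.spatial_w, w2.spatial_w)
        for r in small_cfg.reduction_ratios:
            assert np.array_equal(w1.branch(r).w3, w2.branch(r).w3)

    def test_missing_branch_is_reported(self, small_fm, small_weights):
        with pytest.raises(KeyError, match="reduction ratio"):
            sk_channel_gate(small_fm, 5, small_weights)
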