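"""Dual-attention math against loop-based oracles and its invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from datransunet import reference as ref
from datransunet.attention import (ChannelAttention, DABlockConfig,
                                   DualAttentionBlock, PositionAttention,
                                   channel_affinity, spatial_affinity)
from datransunet.nn.tensor import Tensor


def _pam_weights(pam):
    return {"wq": pam.query.weight.data.astype(np.float64),
            "bq": pam.query.bias.data.astype(np.float64),
            "wk": pam.key.weight.data.astype(np.float64),
            "bk": pam.key.bias.data.astype(np.float64),
            "wv": pam.value.weight.data.astype(np.float64),
            "bv": pam.value.bias.data.astype(np.float64)}


# -- affinity maps -----------------------------------------------------

def test_single_position_affinity_is_one():
    rng = np.random.default_rng(0)
    s = spatial_affinity(rng.normal(size=(5, 1, 1)), rng.normal(size=(5, 1, 1)))
    np.testing.assert_array_equal(s, [[1.0]])


def test_equal_logits_give_uniform_affinity():
    s = spatial_affinity(np.zeros((3, 2, 2)), np.zeros((3, 2, 2)))
    np.testing.assert_allclose(s, np.full((4, 4), 0.25))


def test_single_channel_affinity_is_one():
    x = channel_affinity(np.random.default_rng(1).normal(size=(1, 3, 3)))
    np.testing.assert_array_equal(x, [[1.0]])


def test_identical_channels_share_attention_equally():
    a = np.random.default_rng(2).normal(size=(1, 2, 2))
    x = channel_affinity(np.concatenate([a, a], axis=0))
    np.testing.assert_allclose(x, np.full((2, 2), 0.5), atol=1e-6)


@pytest.mark.parametrize("seed", range(20))
def test_affinities_match_double_loop_oracles(seed):
    rng = np.random.default_rng(seed)
    b = rng.normal(size=(2, 2, 2))
    c = rng.normal(size=(2, 2, 2))
    np.testing.assert_allclose(spatial_affinity(b, c),
                               ref.spatial_affinity_reference(b, c), atol=1e-6)
    a = rng.normal(size=(3, 2, 2))
    np.testing.assert_allclose(channel_affinity(a),
                               ref.channel_affinity_reference(a), atol=1e-6)


def test_affinity_input_validation():
    with pytest.raises(ValueError):
        spatial_affinity(np.zeros((2, 2, 2)), np.zeros((2, 3, 2)))
    bad = np.zeros((2, 2, 2))
    bad[0, 0, 0] = np.nan
    with pytest.raises(ValueError):
        spatial_affinity(bad, np.zeros((2, 2, 2)))
    with pytest.raises(ValueError):
        channel_affinity(np.full((2, 2, 2), np.inf))


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(1, 4), st.integers(1, 3), st.integers(1, 3),
       st.floats(-5, 5), st.integers(0, 10_000))
def test_affinity_rows_are_stochastic(c, h, w, scale, seed):
    rng = np.random.default_rng(seed)
    a = scale * rng.normal(size=(c, h, w))
    s = spatial_affinity(a, rng.normal(size=(c, h, w)))
    x = channel_affinity(a)
    assert (s >= 0).all() and (x >= 0).all()
    np.testing.assert_allclose(s.sum(axis=-1), 1.0, atol=1e-5)
    np.testing.assert_allclose(x.sum(axis=-1), 1.0, atol=1e-5)


# -- PAM / CAM forward -------------------------------------------------

@pytest.mark.parametrize("seed", range(20))
def test_pam_matches_loop_reference(seed):
    rng = np.random.default_rng(100 + seed)
    c = int(rng.integers(1, 5))
    h, w = int(rng.integers(1, 5)), int(rng.integers(1, 5))
    pam = PositionAttention(c, np.random.default_rng(seed))
    pam.alpha.data[:] = 0.5
    a = rng.normal(size=(c, h, w)).astype(np.float32)
    np.testing.assert_allclose(pam(a), ref.pam_reference(a, _pam_weights(pam), 0.5),
                               atol=1e-5)


@pytest.mark.parametrize("seed", range(20))
def test_cam_matches_loop_reference(seed):
    rng = np.random.default_rng(200 + seed)
    c = int(rng.integers(1, 5))
    h, w = int(rng.integers(1, 5)), int(rng.integers(1, 5))
    cam = ChannelAttention()
    cam.beta.data[:] = 1.0
    a = rng.normal(size=(c, h, w)).astype(np.float32)
    np.testing.assert_allclose(cam(a), ref.cam_reference(a, 1.0), atol=1e-5)


def test_zero_gates_are_identity():
    rng = np.random.default_rng(3)
    a = rng.normal(size=(3, 4, 4)).astype(np.float32)
    pam = PositionAttention(3, np.random.default_rng(0))
    cam = ChannelAttention()
    np.testing.assert_allclose(pam(a), a, atol=1e-7)
    np.testing.assert_allclose(cam(a), a, atol=1e-7)


def test_pam_single_position_collapses_to_gated_value():
    rng = np.random.default_rng(4)
    pam = PositionAttention(3, np.random.default_rng(1))
    pam.alpha.data[:] = 0.7
    a = rng.normal(size=(3, 1, 1)).astype(np.float32)
    d = pam.value(Tensor(a[None])).numpy()[0]
    np.testing.assert_allclose(pam(a), 0.7 * d + a, atol=1e-6)


def test_cam_single_channel_scales_by_one_plus_beta():
    cam = ChannelAttention()
    cam.beta.data[:] = 0.3
    a = np.random.default_rng(5).normal(size=(1, 3, 3)).astype(np.float32)
    np.testing.assert_allclose(cam(a), 1.3 * a, atol=1e-6)


def test_pam_is_equivariant_to_spatial_permutations():
    rng = np.random.default_rng(6)
    pam = PositionAttention(3, np.random.default_rng(2))
    pam.alpha.data[:] = 0.4
    a = rng.normal(size=(3, 3, 4)).astype(np.float32)
    perm = rng.permutation(12)
    permuted = a.reshape(3, 12)[:, perm].reshape(3, 3, 4)
    out_then_perm = pam(a).reshape(3, 12)[:, perm]
    perm_then_out = pam(permuted).reshape(3, 12)
    np.testing.assert_allclose(perm_then_out, out_then_perm, atol=1e-5)


def test_cam_is_equivariant_to_channel_permutations():
    rng = np.random.default_rng(7)
    cam = ChannelAttention()
    cam.beta.data[:] = 0.8
    a = rng.normal(size=(5, 3, 3)).astype(np.float32)
    perm = rng.permutation(5)
    np.testing.assert_allclose(cam(a[perm]), cam(a)[perm], atol=1e-5)


def test_batched_execution_matches_per_item_loop():
    rng = np.random.default_rng(8)
    batch = rng.normal(size=(3, 4, 5, 5)).astype(np.float32)
    pam = PositionAttention(4, np.random.default_rng(3))
    pam.alpha.data[:] = 0.2
    cam = ChannelAttention()
    cam.beta.data[:] = 0.6
    blk = DualAttentionBlock(DABlockConfig(4, 2), np.random.default_rng(4)).eval()
    for module in (pam, cam, blk):
        together = module(batch)
        one_by_one = np.stack([module(batch[i]) for i in range(3)])
        np.testing.assert_allclose(together, one_by_one, atol=1e-5)


# -- dual-attention block ----------------------------------------------

@pytest.mark.parametrize("in_ch,reduction,mid", [(64, 16, 4), (8, 16, 1), (32, 4, 8),
                                                 (3, 1, 3)])
def test_block_intermediate_width_floor_rule(in_ch, reduction, mid):
    assert DABlockConfig(in_ch, reduction).mid_channels == mid


@pytest.mark.parametrize("shape,reduction", [((32, 8, 8), 16), ((8, 6, 6), 16),
                                             ((16, 4, 4), 4), ((2, 5, 7), 1)])
def test_block_preserves_shape(shape, reduction):
    blk = DualAttentionBlock(DABlockConfig(shape[0], reduction),
                             np.random.default_rng(9))
    out = blk(np.random.default_rng(10).normal(size=shape).astype(np.float32))
    assert out.shape == shape


def test_block_matches_explicit_branch_composition():
    rng = np.random.default_rng(11)
    blk = DualAttentionBlock(DABlockConfig(32, 16), np.random.default_rng(12)).eval()
    x = rng.normal(size=(1, 32, 8, 8)).astype(np.float32)
    xt = Tensor(x)
    pam_branch = blk.post_pam(blk.pam(blk.pre_pam(xt)))
    cam_branch = blk.post_cam(blk.cam(blk.pre_cam(xt)))
    expected = blk.out_conv(pam_branch + cam_branch).numpy()
    np.testing.assert_allclose(blk(x), expected, atol=1e-5)


def test_block_rejects_wrong_channel_count():
    blk = DualAttentionBlock(DABlockConfig(8, 16), np.random.default_rng(13))
    with pytest.raises(ValueError):
        blk(np.zeros((4, 4, 4), dtype=np.float32))
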