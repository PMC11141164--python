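"""Model assembly: shapes, token counts, determinism, parameter accounting."""

import numpy as np
import pytest

from datransunet import (DATransUNet, NetworkConfig, build_model,
                         count_parameters, load_checkpoint, load_pretrained,
                         r50_config, save_checkpoint, tiny_config)
from datransunet.losses import ce_dice_loss
from datransunet.network import ConfigError
from datransunet.nn.tensor import Tensor, no_grad


def _rand_image(cfg, seed=0, batch=1):
    rng = np.random.default_rng(seed)
    return rng.normal(size=(batch, cfg.in_channels, cfg.img_size, cfg.img_size)
                      ).astype(np.float32)


def test_tiny_forward_shape_contract():
    cfg = tiny_config(n_classes=2)
    model = build_model(cfg, seed=0).eval()
    with no_grad():
        out = model(_rand_image(cfg))
    assert out.shape == (1, 2, 64, 64)


def test_img_size_must_divide_by_16():
    with pytest.raises(ConfigError):
        tiny_config(img_size=60)


def test_token_counts_follow_the_patch_grid(r50_baseline):
    with no_grad():
        enc = r50_baseline.encode(_rand_image(r50_baseline.cfg))
    assert enc.tokens.shape == (1, 196, 768)
    # skips deep -> shallow: sizes double, channels drop 512/256/64
    assert [tuple(s.shape[1:]) for s in enc.skips] == [
        (512, 28, 28), (256, 56, 56), (64, 112, 112)]
    assert r50_config(img_size=256).n_patches == 256
    assert tiny_config().n_patches == 16


def test_encode_rejects_wrong_input_size():
    model = build_model(tiny_config(), seed=0)
    with pytest.raises(ValueError):
        model.encode(np.zeros((1, 1, 48, 48), dtype=np.float32))


def test_same_seed_gives_identical_models_and_outputs():
    cfg = tiny_config(n_classes=2)
    a = build_model(cfg, seed=5).eval()
    b = build_model(cfg, seed=5).eval()
    x = _rand_image(cfg, seed=1)
    with no_grad():
        ya, yb = a(x).numpy(), b(x).numpy()
    np.testing.assert_array_equal(ya, yb)
    with no_grad():
        np.testing.assert_array_equal(ya, a(x).numpy())


def test_da_off_model_has_no_attention_parameters():
    cfg = tiny_config(da_encoder=False, da_skips=(False, False, False))
    model = build_model(cfg, seed=0)
    names = [n for n, _ in model.named_parameters()]
    assert not any("da" in n or "pam" in n or "cam" in n for n in names)
    # the baseline count ignores the reduction knob entirely
    counts = {count_parameters(build_model(
        tiny_config(da_encoder=False, da_skips=(False, False, False), reduction=r),
        seed=0)) for r in (1, 4, 16)}
    assert len(counts) == 1


def test_parameter_count_decreases_with_reduction():
    counts = [count_parameters(build_model(tiny_config(reduction=r), seed=0))
              for r in (1, 2, 4, 8, 16)]
    assert all(a > b for a, b in zip(counts, counts[1:]))


def test_tiny_count_matches_independent_per_layer_arithmetic():
    """Hand count of the tiny architecture, written out layer by layer."""
    def conv(k, cin, cout, bias=False):
        return k * k * cin * cout + (cout if bias else 0)

    def block(cin, cout):   # conv-BN-relu twice
        return conv(3, cin, cout) + 2 * cout + conv(3, cout, cout) + 2 * cout

    def dablock(c, mid):
        pre = 2 * (conv(3, c, mid) + 2 * mid)
        pam = 3 * (conv(1, mid, mid, bias=True)) + 1
        cam = 1
        post = 2 * (conv(3, mid, mid) + 2 * mid)
        out = conv(1, mid, c, bias=True)
        return pre + pam + cam + post + out

    backbone = block(1, 8) + block(8, 16) + block(16, 32) + block(32, 64)
    attention = dablock(64, 4) + dablock(32, 2) + dablock(16, 1) + dablock(8, 1)
    embed = conv(1, 64, 32, bias=True) + 16 * 32
    per_layer = 4 * conv(1, 32, 32, bias=True) + 2 * 2 * 32 \
        + conv(1, 32, 64, bias=True) + conv(1, 64, 32, bias=True)
    transformer = 2 * per_layer + 2 * 32
    decoder = (conv(3, 32, 32) + 2 * 32                      # conv_more
               + conv(3, 64, 16) + 2 * 16 + conv(3, 16, 16) + 2 * 16
               + conv(3, 32, 8) + 2 * 8 + conv(3, 8, 8) + 2 * 8
               + conv(3, 16, 8) + 2 * 8 + conv(3, 8, 8) + 2 * 8
               + conv(3, 8, 8) + 2 * 8 + conv(3, 8, 8) + 2 * 8)
    head = conv(3, 8, 2, bias=True)
    expected = backbone + attention + embed + transformer + decoder + head
    assert count_parameters(build_model(tiny_config(n_classes=2), seed=0)) == expected


def test_every_parameter_receives_gradient():
    """After one update the zero-initialized gates are live, so a second
    backward pass must reach every parameter, attention projections
    included (at exact initialization alpha = 0 blocks the value path
    by construction)."""
    from datransunet import nn

    cfg = tiny_config(n_classes=2, img_size=32)
    model = build_model(cfg, seed=2)
    opt = nn.SGD(model.parameters(), lr=1e-2, momentum=0.0)
    rng = np.random.default_rng(0)
    x = rng.normal(size=(2, 1, 32, 32)).astype(np.float32)
    labels = rng.integers(0, 2, (2, 32, 32))
    for step in range(2):
        loss = ce_dice_loss(model(Tensor(x)), labels, 2)
        opt.zero_grad()
        loss.backward()
        if step == 0:
            assert np.abs(model.encoder_da.pam.alpha.grad).max() > 0
            assert np.abs(model.encoder_da.cam.beta.grad).max() > 0
            opt.step()
    missing = [n for n, p in model.named_parameters()
               if p.grad is None or not np.isfinite(p.grad).all()
               or np.abs(p.grad).max() == 0.0]
    assert missing == []


def test_filter_skips_identity_and_shape_preservation():
    cfg = tiny_config(da_skips=(False, False, False))
    model = build_model(cfg, seed=0).eval()
    with no_grad():
        enc = model.encode(_rand_image(cfg))
        filtered = model.filter_skips(enc.skips)
    for s, f in zip(enc.skips, filtered):
        np.testing.assert_array_equal(s.numpy(), f.numpy())

    cfg_on = tiny_config(da_skips=(True, False, False))   # single-layer variant
    model_on = build_model(cfg_on, seed=0).eval()
    with no_grad():
        enc = model_on.encode(_rand_image(cfg_on))
        filtered = model_on.filter_skips(enc.skips)
    assert [f.shape for f in filtered] == [s.shape for s in enc.skips]
    assert not np.allclose(filtered[0].numpy(), enc.skips[0].numpy())
    np.testing.assert_array_equal(filtered[1].numpy(), enc.skips[1].numpy())


def test_decode_at_zero_input_returns_the_head_bias_map():
    cfg = tiny_config(n_classes=3)
    model = build_model(cfg, seed=4).eval()
    tokens = Tensor(np.zeros((1, cfg.n_patches, cfg.hidden_size), dtype=np.float32))
    skips = [Tensor(np.zeros((1, c, cfg.img_size // s, cfg.img_size // s),
                             dtype=np.float32))
             for c, s in zip(cfg.skip_channels, (8, 4, 2))]
    with no_grad():
        out = model.decode(tokens, skips).numpy()
    expected = np.broadcast_to(model.seg_head.bias.data[None, :, None, None], out.shape)
    np.testing.assert_allclose(out, expected, atol=1e-6)


def test_checkpoint_round_trip_is_bitwise(tmp_path):
    cfg = tiny_config(n_classes=2)
    model = build_model(cfg, seed=6).eval()
    x = _rand_image(cfg, seed=2)
    with no_grad():
        before = model(x).numpy()
    save_checkpoint(model, tmp_path / "ckpt.npz")
    loaded = load_checkpoint(tmp_path / "ckpt.npz").eval()
    with no_grad():
        after = loaded(x).numpy()
    np.testing.assert_array_equal(before, after)


def test_pretrained_hook_warm_starts_matching_tensors(tmp_path):
    base = build_model(tiny_config(da_encoder=False, da_skips=(False,) * 3), seed=1)
    save_checkpoint(base, tmp_path / "base.npz")
    target = build_model(tiny_config(), seed=2)
    n = load_pretrained(target, tmp_path / "base.npz")
    assert n > 0
    np.testing.assert_array_equal(target.patch_embed.weight.data,
                                  base.patch_embed.weight.data)
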