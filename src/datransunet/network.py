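"""The dual-attention TransUNet and its DA-free baseline.

Architecture: a hybrid CNN encoder produces multi-scale features; the
deepest (1/16-scale) map is optionally refined by a dual-attention block,
tokenized by a 1x1 patch projection and processed by a ViT-style
transformer; a cascaded upsampling decoder restores resolution, fusing
the three encoder skips, each optionally filtered by its own
dual-attention block.  With every DA flag off the model is exactly the
TransUNet baseline, which is what the parameter accounting compares
against.

Two backbones are provided.  ``r50`` is the ResNet-50-style hybrid of the
TransUNet reference design (weight-standardized convs + GroupNorm,
pre-activation bottlenecks in three stages of 3/4/9 units, skips at
64/256/512 channels, 1024-channel 1/16-scale output): this is the only
encoder consistent with the published parameter counts.  ``tiny`` takes
the architectural narrative literally -- three plain convolution blocks,
each halving size and doubling width -- and exists for desk-scale
training and tests.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import nn
from .attention import DABlockConfig, DualAttentionBlock
from .nn import functional as F
from .nn.tensor import Tensor


class ConfigError(ValueError):
    pass


@dataclass
class NetworkConfig:
    """Architectural hyperparameters of the segmentation network."""

    img_size: int = 224
    in_channels: int = 3
    n_classes: int = 2
    backbone: str = "r50"
    hidden_size: int = 768
    n_layers: int = 12
    n_heads: int = 12
    mlp_dim: int = 3072
    skip_channels: tuple[int, int, int] = (512, 256, 64)   # deep -> shallow
    decoder_channels: tuple[int, int, int, int] = (256, 128, 64, 16)
    head_channels: int = 512
    da_encoder: bool = True
    da_skips: tuple[bool, bool, bool] = (True, True, True)
    reduction: int = 16
    transformer_dropout: float = 0.1

    def __post_init__(self):
        if self.img_size % 16:
            raise ConfigError("img_size must be divisible by 16")
        if self.backbone not in ("r50", "tiny"):
            raise ConfigError(f"unknown backbone {self.backbone!r}")
        if self.hidden_size % self.n_heads:
            raise ConfigError("hidden_size must divide evenly among heads")
        self.skip_channels = tuple(self.skip_channels)
        self.decoder_channels = tuple(self.decoder_channels)
        self.da_skips = tuple(bool(f) for f in self.da_skips)
        if len(self.da_skips) != 3 or len(self.skip_channels) != 3:
            raise ConfigError("exactly three skip connections are modeled")

    @property
    def grid(self) -> int:
        return self.img_size // 16

    @property
    def n_patches(self) -> int:
        return self.grid * self.grid

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})


def r50_config(**overrides) -> NetworkConfig:
    """Full-scale hybrid configuration (ViT-B/16 on an R50 stem)."""
    base = dict(img_size=224, in_channels=3, n_classes=2, backbone="r50",
                hidden_size=768, n_layers=12, n_heads=12, mlp_dim=3072,
                skip_channels=(512, 256, 64), decoder_channels=(256, 128, 64, 16),
                head_channels=512)
    base.update(overrides)
    return NetworkConfig(**base)


def tiny_config(**overrides) -> NetworkConfig:
    """Desk-scale configuration for CPU training and tests."""
    base = dict(img_size=64, in_channels=1, n_classes=2, backbone="tiny",
                hidden_size=32, n_layers=2, n_heads=2, mlp_dim=64,
                skip_channels=(32, 16, 8), decoder_channels=(16, 8, 8, 8),
                head_channels=32, transformer_dropout=0.0)
    base.update(overrides)
    return NetworkConfig(**base)


@dataclass
class EncoderOutput:
    """Transformer tokens plus the three skip maps, ordered deep -> shallow."""

    tokens: Tensor          # (B, grid^2, hidden)
    skips: list             # [1/8-scale, 1/4-scale, 1/2-scale] feature maps


# -- hybrid ResNetV2 backbone -----------------------------------------

class PreActBottleneck(nn.Module):
    def __init__(self, cin: int, cout: int, cmid: int, rng, stride: int = 1):
        super().__init__()
        self.gn1 = nn.GroupNorm(32, cmid)
        self.conv1 = nn.Conv2d(cin, cmid, 1, rng, bias=False, weight_standardized=True)
        self.gn2 = nn.GroupNorm(32, cmid)
        self.conv2 = nn.Conv2d(cmid, cmid, 3, rng, stride=stride, padding=1,
                               bias=False, weight_standardized=True)
        self.gn3 = nn.GroupNorm(32, cout)
        self.conv3 = nn.Conv2d(cmid, cout, 1, rng, bias=False, weight_standardized=True)
        self.has_proj = stride != 1 or cin != cout
        if self.has_proj:
            self.proj = nn.Conv2d(cin, cout, 1, rng, stride=stride, bias=False,
                                  weight_standardized=True)
            self.gn_proj = nn.GroupNorm(cout, cout)

    def forward(self, x):
        residual = self.gn_proj(self.proj(x)) if self.has_proj else x
        y = F.relu(self.gn1(self.conv1(x)))
        y = F.relu(self.gn2(self.conv2(y)))
        y = self.gn3(self.conv3(y))
        return F.relu(residual + y)


class ResNetV2(nn.Module):
    """Stem + three bottleneck stages (3/4/9 units) of the hybrid encoder."""

    def __init__(self, in_channels: int, rng):
        super().__init__()
        self.root_conv = nn.Conv2d(in_channels, 64, 7, rng, stride=2, padding=3,
                                   bias=False, weight_standardized=True)
        self.root_gn = nn.GroupNorm(32, 64)
        self.pool = nn.MaxPool2d(3, stride=2, padding=1)
        self.block1 = self._stage(64, 256, 64, 3, rng, first_stride=1)
        self.block2 = self._stage(256, 512, 128, 4, rng, first_stride=2)
        self.block3 = self._stage(512, 1024, 256, 9, rng, first_stride=2)
        self.out_channels = 1024

    @staticmethod
    def _stage(cin, cout, cmid, n_units, rng, first_stride):
        units = [PreActBottleneck(cin, cout, cmid, rng, stride=first_stride)]
        units += [PreActBottleneck(cout, cout, cmid, rng) for _ in range(n_units - 1)]
        return nn.Sequential(*units)

    def forward(self, x):
        x = F.relu(self.root_gn(self.root_conv(x)))
        feat_half = x                       # 64 ch @ 1/2
        x = self.pool(x)
        feat_quarter = self.block1(x)       # 256 ch @ 1/4
        feat_eighth = self.block2(feat_quarter)   # 512 ch @ 1/8
        deep = self.block3(feat_eighth)     # 1024 ch @ 1/16
        return deep, [feat_eighth, feat_quarter, feat_half]


class TinyBackbone(nn.Module):
    """Three plain conv blocks, each halving size and doubling width."""

    def __init__(self, in_channels: int, widths: Sequence[int], rng):
        # widths shallow -> deep, e.g. (8, 16, 32); deepest output is 2*widths[-1]
        super().__init__()
        w0, w1, w2 = widths
        self.block1 = self._block(in_channels, w0, rng)
        self.block2 = self._block(w0, w1, rng)
        self.block3 = self._block(w1, w2, rng)
        self.down = self._block(w2, 2 * w2, rng)
        self.out_channels = 2 * w2

    @staticmethod
    def _block(cin, cout, rng):
        return nn.Sequential(
            nn.Conv2d(cin, cout, 3, rng, stride=2, padding=1, bias=False),
            nn.BatchNorm2d(cout),
            nn.ReLU(),
            nn.Conv2d(cout, cout, 3, rng, padding=1, bias=False),
            nn.BatchNorm2d(cout),
            nn.ReLU(),
        )

    def forward(self, x):
        feat_half = self.block1(x)
        feat_quarter = self.block2(feat_half)
        feat_eighth = self.block3(feat_quarter)
        deep = self.down(feat_eighth)       # 1/16 scale
        return deep, [feat_eighth, feat_quarter, feat_half]


# -- transformer -------------------------------------------------------

class MultiHeadSelfAttention(nn.Module):
    def __init__(self, hidden: int, n_heads: int, rng):
        super().__init__()
        self.n_heads = n_heads
        self.head_dim = hidden // n_heads
        self.query = nn.Linear(hidden, hidden, rng)
        self.key = nn.Linear(hidden, hidden, rng)
        self.value = nn.Linear(hidden, hidden, rng)
        self.out = nn.Linear(hidden, hidden, rng)

    def forward(self, x):
        n, t, h = x.shape
        def split(v):
            return F.transpose(F.reshape(v, (n, t, self.n_heads, self.head_dim)),
                               (0, 2, 1, 3))
        q, k, v = split(self.query(x)), split(self.key(x)), split(self.value(x))
        scores = F.matmul(q, F.transpose(k, (0, 1, 3, 2))) * (1.0 / np.sqrt(self.head_dim))
        attn = F.softmax(scores, axis=-1)
        ctx = F.matmul(attn, v)
        ctx = F.reshape(F.transpose(ctx, (0, 2, 1, 3)), (n, t, h))
        return self.out(ctx)


class TransformerBlock(nn.Module):
    def __init__(self, cfg: NetworkConfig, rng, drop_rng):
        super().__init__()
        self.norm1 = nn.LayerNorm(cfg.hidden_size)
        self.attn = MultiHeadSelfAttention(cfg.hidden_size, cfg.n_heads, rng)
        self.norm2 = nn.LayerNorm(cfg.hidden_size)
        self.fc1 = nn.Linear(cfg.hidden_size, cfg.mlp_dim, rng)
        self.fc2 = nn.Linear(cfg.mlp_dim, cfg.hidden_size, rng)
        self.drop = nn.Dropout(cfg.transformer_dropout, drop_rng)

    def forward(self, x):
        x = x + self.drop(self.attn(self.norm1(x)))
        y = self.drop(self.fc2(self.drop(F.gelu(self.fc1(self.norm2(x))))))
        return x + y


# -- decoder -----------------------------------------------------------

def _conv_bn_relu(cin, cout, rng):
    return nn.Sequential(nn.Conv2d(cin, cout, 3, rng, padding=1, bias=False),
                         nn.BatchNorm2d(cout), nn.ReLU())


class DecoderBlock(nn.Module):
    def __init__(self, cin: int, cskip: int, cout: int, rng):
        super().__init__()
        self.cskip = cskip
        self.conv1 = _conv_bn_relu(cin + cskip, cout, rng)
        self.conv2 = _conv_bn_relu(cout, cout, rng)

    def forward(self, x, skip=None):
        x = F.upsample_bilinear2x(x)
        if self.cskip:
            if skip is None:
                raise ConfigError("decoder stage expects a skip feature")
            if skip.shape[1] != self.cskip:
                raise ConfigError(
                    f"skip has {skip.shape[1]} channels, decoder expects {self.cskip}")
            x = F.concat([x, skip], axis=1)
        return self.conv2(self.conv1(x))


# -- full model --------------------------------------------------------

class DATransUNet(nn.Module):
    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        drop_rng = np.random.default_rng(rng.integers(2**31))
        if cfg.backbone == "r50":
            self.backbone = ResNetV2(cfg.in_channels, rng)
        else:
            widths = tuple(reversed(cfg.skip_channels))
            self.backbone = TinyBackbone(cfg.in_channels, widths, rng)
        deep_ch = self.backbone.out_channels

        if cfg.da_encoder:
            self.encoder_da = DualAttentionBlock(
                DABlockConfig(deep_ch, cfg.reduction), rng)
        else:
            self.encoder_da = nn.Identity()
        for i, flag in enumerate(cfg.da_skips):
            da = (DualAttentionBlock(DABlockConfig(cfg.skip_channels[i], cfg.reduction), rng)
                  if flag else nn.Identity())
            setattr(self, f"skip_da{i}", da)

        self.patch_embed = nn.Conv2d(deep_ch, cfg.hidden_size, 1, rng)
        self.pos_embed = nn.Parameter(
            rng.normal(0.0, 0.02, (1, cfg.n_patches, cfg.hidden_size)))
        self.embed_drop = nn.Dropout(cfg.transformer_dropout, drop_rng)
        self.blocks = nn.Sequential(*[TransformerBlock(cfg, rng, drop_rng)
                                      for _ in range(cfg.n_layers)])
        self.encoder_norm = nn.LayerNorm(cfg.hidden_size)

        self.conv_more = _conv_bn_relu(cfg.hidden_size, cfg.head_channels, rng)
        ins = (cfg.head_channels,) + cfg.decoder_channels[:-1]
        skips = cfg.skip_channels + (0,)
        self.dec1 = DecoderBlock(ins[0], skips[0], cfg.decoder_channels[0], rng)
        self.dec2 = DecoderBlock(ins[1], skips[1], cfg.decoder_channels[1], rng)
        self.dec3 = DecoderBlock(ins[2], skips[2], cfg.decoder_channels[2], rng)
        self.dec4 = DecoderBlock(ins[3], skips[3], cfg.decoder_channels[3], rng)
        self.seg_head = nn.Conv2d(cfg.decoder_channels[3], cfg.n_classes, 3, rng,
                                  padding=1)

    # -- staged API ----------------------------------------------------
    def encode(self, image) -> EncoderOutput:
        x = image if isinstance(image, Tensor) else Tensor(np.asarray(image, dtype=np.float32))
        if x.ndim == 3:
            x = F.reshape(x, (1,) + x.shape)
        if x.shape[2] != self.cfg.img_size or x.shape[3] != self.cfg.img_size:
            raise ValueError(
                f"expected {self.cfg.img_size}x{self.cfg.img_size} input, got "
                f"{x.shape[2]}x{x.shape[3]}")
        deep, skips = self.backbone(x)
        deep = self.encoder_da(deep)
        emb = self.patch_embed(deep)                       # (B, hidden, g, g)
        n, h = emb.shape[0], emb.shape[1]
        tokens = F.transpose(F.reshape(emb, (n, h, -1)), (0, 2, 1))
        tokens = self.embed_drop(tokens + self.pos_embed)
        return EncoderOutput(tokens=tokens, skips=skips)

    def filter_skips(self, skips):
        return [getattr(self, f"skip_da{i}")(s) for i, s in enumerate(skips)]

    def transform(self, tokens):
        return self.encoder_norm(self.blocks(tokens))

    def decode(self, tokens, skips):
        n, t, h = tokens.shape
        g = self.cfg.grid
        x = F.reshape(F.transpose(tokens, (0, 2, 1)), (n, h, g, g))
        x = self.conv_more(x)
        x = self.dec1(x, skips[0])
        x = self.dec2(x, skips[1])
        x = self.dec3(x, skips[2])
        x = self.dec4(x)
        return self.seg_head(x)

    def forward(self, image):
        enc = self.encode(image)
        tokens = self.transform(enc.tokens)
        skips = self.filter_skips(enc.skips)
        return self.decode(tokens, skips)


def build_model(cfg: NetworkConfig, seed: int = 0) -> DATransUNet:
    return DATransUNet(cfg, seed=seed)


def count_parameters(model: nn.Module) -> int:
    return nn.count_parameters(model)


# -- checkpointing -----------------------------------------------------

def save_checkpoint(model: DATransUNet, path) -> None:
    arrays = {f"param::{n}": p.data for n, p in model.named_parameters()}
    arrays.update({f"buffer::{n}": b for n, b in model.named_buffers()})
    arrays["config_json"] = np.array(json.dumps(model.cfg.to_dict()))
    np.savez(path, **arrays)


def load_checkpoint(path) -> DATransUNet:
    with np.load(path, allow_pickle=False) as data:
        cfg = NetworkConfig.from_dict(json.loads(str(data["config_json"])))
        model = build_model(cfg, seed=0)
        state = {}
        for key in data.files:
            if key.startswith("param::"):
                state[key[len("param::"):]] = data[key]
            elif key.startswith("buffer::"):
                state["buffer::" + key[len("buffer::"):]] = data[key]
        model.load_state_dict(state)
    return model


def load_pretrained(model: DATransUNet, path) -> int:
    """Load externally trained weights by parameter name.

    The file must be an ``.npz`` whose keys follow this package's naming
    (as written by :func:`save_checkpoint`).  Entries whose name or shape
    do not match are skipped, so a DA-free checkpoint can warm-start a
    DA-enabled model.  Returns the number of parameters loaded.
    """
    loaded = 0
    params = dict(model.named_parameters())
    with np.load(path, allow_pickle=False) as data:
        for key in data.files:
            if not key.startswith("param::"):
                continue
            name = key[len("param::"):]
            if name in params and params[name].data.shape == data[key].shape:
                params[name].data = data[key].astype(np.float32)
                loaded += 1
    return loaded
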