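"""Encoder–decoder segmentation networks: UNet, SegNet and DeepLab-v3 style.

All three families map an RGB patch to per-pixel class scores at full input
resolution; the *instance* variant of each carries a second, independently
parameterized copy of the decoder branch emitting an n-dimensional embedding
per pixel (the embedding is later clustered into instances).  Width is
controlled by ``base_channels`` so tiny CPU-trainable variants exist alongside
full-size ones.

The DeepLab-style family downsamples with strided convolutions and then grows
its receptive field with atrous (dilated) convolutions and a small
multi-dilation pyramid, following the atrous encoder–decoder idea; the
``mobilenetv2_style`` backbone replaces the plain residual body with
inverted-residual blocks (1×1 expand → 3×3 depthwise → 1×1 project).  No
pretrained weights are used anywhere.

When a model carries an embedding head, the embedding decoder's input is
augmented with two fixed-scale coordinate channels — an explicit positional
signal the pull/push loss shapes into per-instance clusters — and, by
default, gradients from the embedding branch are stopped at the shared
encoder, so the two tasks do not compete for encoder capacity in the tiny
CPU-scale variants.  The semantic path never sees coordinates and stays
translation-covariant.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np

from . import nn
from .nn import Tensor

__all__ = ["ModelConfig", "NetworkOutput", "build_model",
           "add_embedding_decoder", "save_checkpoint", "load_checkpoint"]

FAMILIES = ("unet", "segnet", "deeplabv3")


@dataclass
class ModelConfig:
    family: str = "deeplabv3"
    base_channels: int = 16
    depth: int = 3
    num_classes: int = 2
    embedding_dim: Optional[int] = None
    backbone: str = "simple"  # deeplabv3 only: "simple" | "mobilenetv2_style"
    coord_features: Optional[bool] = None  # default: on iff embedding head
    detach_embedding: bool = True  # stop embedding grads at the encoder

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        if self.base_channels < 4:
            raise ValueError("base_channels must be >= 4")
        if self.embedding_dim is not None and self.embedding_dim < 2:
            raise ValueError("embedding_dim must be >= 2")
        if self.coord_features is None:
            self.coord_features = self.embedding_dim is not None

    @property
    def in_channels(self) -> int:
        return 3


@dataclass
class NetworkOutput:
    """Per-pixel class scores and (for instance variants) embeddings."""

    class_scores: Tensor  # (N, num_classes, H, W)
    embeddings: Optional[Tensor] = None  # (N, embedding_dim, H, W)


def _conv_bn_relu(cin, cout, rng, k=3, stride=1, dilation=1, groups=1):
    return nn.Sequential(
        nn.Conv2d(cin, cout, k, rng, stride=stride, dilation=dilation,
                  groups=groups, bias=False),
        nn.BatchNorm2d(cout),
        nn.ReLU(),
    )


def _double_conv(cin, cout, rng):
    return nn.Sequential(_conv_bn_relu(cin, cout, rng),
                         _conv_bn_relu(cout, cout, rng))


class _Residual(nn.Module):
    def __init__(self, ch, rng, dilation=1):
        super().__init__()
        self.body = nn.Sequential(
            _conv_bn_relu(ch, ch, rng, dilation=dilation),
            nn.Conv2d(ch, ch, 3, rng, dilation=dilation, bias=False),
            nn.BatchNorm2d(ch),
        )

    def forward(self, x):
        return (self.body(x) + x).relu()


class _InvertedResidual(nn.Module):
    """MobileNet-v2-style block: expand 1×1 → depthwise 3×3 → project 1×1."""

    def __init__(self, ch, rng, expansion=4, dilation=1):
        super().__init__()
        mid = ch * expansion
        self.body = nn.Sequential(
            _conv_bn_relu(ch, mid, rng, k=1),
            _conv_bn_relu(mid, mid, rng, k=3, dilation=dilation, groups=mid),
            nn.Conv2d(mid, ch, 1, rng, bias=False),
            nn.BatchNorm2d(ch),
        )

    def forward(self, x):
        return self.body(x) + x


class _SegModel(nn.Module):
    """Shared dual-head plumbing for all three families."""

    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        self.embed_decoder: Optional[nn.Module] = None
        self.embed_head: Optional[nn.Module] = None
        self.coord_rng = np.random.default_rng(0)

    # subclasses provide: encode(x)->feats, make_decoder(rng)->(module, out_ch)

    # Coordinate channels use a fixed scale (1 unit = COORD_SCALE_PX input
    # pixels) so the pixel-to-coordinate ratio is identical for any patch or
    # tile size; during training a random constant offset per sample makes
    # the embedding robust to where the crop sat in its tile.
    COORD_SCALE_PX = 64.0

    def _coord_maps(self, n, h, w, feat_h, feat_w) -> Tensor:
        stride = h / feat_h
        rr = ((np.arange(feat_h, dtype=np.float32) + 0.5) * stride
              - h / 2) / self.COORD_SCALE_PX
        cc = ((np.arange(feat_w, dtype=np.float32) + 0.5) * (w / feat_w)
              - w / 2) / self.COORD_SCALE_PX
        grid = np.stack(np.meshgrid(rr, cc, indexing="ij"))
        coords = np.broadcast_to(grid[None], (n, 2, feat_h, feat_w)).copy()
        if self.training:
            coords += self.coord_rng.uniform(-0.5, 0.5, size=(n, 2, 1, 1)
                                             ).astype(np.float32)
        return Tensor(coords)

    def _embed_features(self, feats, in_shape):
        """Detached (by default) encoder features + coordinate channels."""
        is_list = isinstance(feats, list)
        if self.config.detach_embedding:
            feats = [f.detach() for f in feats] if is_list else feats.detach()
        if self.config.coord_features:
            deep = feats[-1] if is_list else feats
            n, _, fh, fw = deep.shape
            coords = self._coord_maps(in_shape[0], in_shape[2], in_shape[3],
                                      fh, fw)
            deep = nn.concat([deep, coords], axis=1)
            feats = feats[:-1] + [deep] if is_list else deep
        return feats

    def forward(self, x: Tensor) -> NetworkOutput:
        feats = self.encode(x)
        scores = self.head(self.decoder(feats))
        emb = None
        if self.embed_decoder is not None:
            emb = self.embed_head(
                self.embed_decoder(self._embed_features(feats, x.shape)))
        return NetworkOutput(class_scores=scores, embeddings=emb)


class _ListDecoder(nn.Module):
    """UNet decoder: upsample, concat skip, double conv — per level."""

    def __init__(self, channels: list[int], rng, extra_in: int = 0):
        super().__init__()
        # channels: encoder channels low->high, last entry = bottleneck
        self.blocks = []
        prev = channels[-1] + extra_in
        for i, skip_ch in enumerate(reversed(channels[:-1])):
            block = _double_conv(prev + skip_ch, skip_ch, rng)
            self.blocks.append(block)
            self._children[f"block{i}"] = block
            prev = skip_ch
        self.up = nn.Upsample(2)
        self.out_channels = prev

    def forward(self, feats):
        skips, x = feats[:-1], feats[-1]
        for block, skip in zip(self.blocks, reversed(skips)):
            x = self.up(x)
            x = block(nn.concat([x, skip], axis=1))
        return x


class UNet(_SegModel):
    def __init__(self, config: ModelConfig, rng):
        super().__init__(config)
        c, d = config.base_channels, config.depth
        self.enc_channels = [c * 2**i for i in range(d)] + [c * 2**d]
        self.enc_blocks = []
        cin = config.in_channels
        for i, ch in enumerate(self.enc_channels[:-1]):
            b = _double_conv(cin, ch, rng)
            self.enc_blocks.append(b)
            self._children[f"enc{i}"] = b
            cin = ch
        self.bottleneck = _double_conv(cin, self.enc_channels[-1], rng)
        self.pool = nn.MaxPool2d()
        self.decoder = self.make_decoder(rng)
        self.head = nn.Conv2d(self.decoder.out_channels, config.num_classes, 1, rng)

    def make_decoder(self, rng, extra_in: int = 0):
        return _ListDecoder(self.enc_channels, rng, extra_in)

    def encode(self, x):
        skips = []
        for b in self.enc_blocks:
            x = b(x)
            skips.append(x)
            x = self.pool(x)
        return skips + [self.bottleneck(x)]


class _SegNetDecoder(nn.Module):
    def __init__(self, channels: list[int], rng, extra_in: int = 0):
        super().__init__()
        self.stages = []
        chs = list(reversed(channels))
        chs[0] += extra_in
        for i, (cin, cout) in enumerate(zip(chs[:-1], chs[1:])):
            stage = nn.Sequential(nn.Upsample(2), _double_conv(cin, cout, rng))
            self.stages.append(stage)
            self._children[f"stage{i}"] = stage
        self.out_channels = chs[-1]

    def forward(self, x):
        for s in self.stages:
            x = s(x)
        return x


class SegNet(_SegModel):
    def __init__(self, config: ModelConfig, rng):
        super().__init__(config)
        c, d = config.base_channels, config.depth
        self.channels = [c * 2**i for i in range(d + 1)]
        stages = []
        cin = config.in_channels
        for ch in self.channels[:-1]:
            stages += [_double_conv(cin, ch, rng), nn.MaxPool2d()]
            cin = ch
        stages.append(_double_conv(cin, self.channels[-1], rng))
        self.encoder = nn.Sequential(*stages)
        self.decoder = self.make_decoder(rng)
        self.head = nn.Conv2d(self.decoder.out_channels, config.num_classes, 1, rng)

    def make_decoder(self, rng, extra_in: int = 0):
        return _SegNetDecoder(self.channels, rng, extra_in)

    def encode(self, x):
        return self.encoder(x)


class _DeepLabDecoder(nn.Module):
    """Two upsample+conv stages back to full resolution (output stride 4)."""

    def __init__(self, cin, cmid, rng, extra_in: int = 0):
        super().__init__()
        self.body = nn.Sequential(
            nn.Upsample(2), _conv_bn_relu(cin + extra_in, cmid, rng),
            nn.Upsample(2), _conv_bn_relu(cmid, cmid, rng),
        )
        self.out_channels = cmid

    def forward(self, x):
        return self.body(x)


class _ASPP(nn.Module):
    """Lite atrous spatial pyramid: parallel 1×1 and dilated 3×3 branches."""

    def __init__(self, cin, cbranch, rng, dilations=(2, 4)):
        super().__init__()
        self.branches = [_conv_bn_relu(cin, cbranch, rng, k=1)]
        for d in dilations:
            self.branches.append(_conv_bn_relu(cin, cbranch, rng, dilation=d))
        for i, b in enumerate(self.branches):
            self._children[f"branch{i}"] = b
        self.project = _conv_bn_relu(cbranch * len(self.branches), cin, rng, k=1)

    def forward(self, x):
        return self.project(nn.concat([b(x) for b in self.branches], axis=1))


class DeepLabV3(_SegModel):
    def __init__(self, config: ModelConfig, rng):
        super().__init__(config)
        c = config.base_channels
        body_ch = 2 * c
        stem = [
            _conv_bn_relu(config.in_channels, c, rng, stride=2),
            _conv_bn_relu(c, body_ch, rng, stride=2),
        ]
        block = (_InvertedResidual if config.backbone == "mobilenetv2_style"
                 else _Residual)
        body = [block(body_ch, rng, dilation=1),
                block(body_ch, rng, dilation=2)]
        self.encoder = nn.Sequential(*stem, *body, _ASPP(body_ch, c, rng))
        self.encoder_out = body_ch
        self.decoder = self.make_decoder(rng)
        self.head = nn.Conv2d(self.decoder.out_channels, config.num_classes, 1, rng)

    def make_decoder(self, rng, extra_in: int = 0):
        return _DeepLabDecoder(self.encoder_out, self.config.base_channels,
                               rng, extra_in)

    def encode(self, x):
        return self.encoder(x)


_CLASSES = {"unet": UNet, "segnet": SegNet, "deeplabv3": DeepLabV3}


def add_embedding_decoder(model: _SegModel, embedding_dim: int,
                          rng: np.random.Generator,
                          coord_features: Optional[bool] = None) -> _SegModel:
    """Attach a structurally identical, freshly initialized second decoder.

    The new branch reads the same encoder features (plus coordinate channels
    unless ``coord_features=False``) and emits ``embedding_dim`` channels per
    pixel; the semantic head is untouched.
    """
    if embedding_dim < 2:
        raise ValueError("embedding_dim must be >= 2")
    if coord_features is not None:
        model.config.coord_features = coord_features
    elif model.config.embedding_dim is None:
        # decoder added post hoc: apply the "on iff embedding head" default
        model.config.coord_features = True
    extra = 2 if model.config.coord_features else 0
    dec = model.make_decoder(rng, extra_in=extra)
    model.embed_decoder = dec
    model._children["embed_decoder"] = dec
    head = nn.Conv2d(dec.out_channels, embedding_dim, 1, rng)
    model.embed_head = head
    model._children["embed_head"] = head
    model.config.embedding_dim = embedding_dim
    return model


def build_model(config: ModelConfig, seed: int = 0) -> _SegModel:
    """Construct a network per ``config`` with deterministic initialization."""
    rng = np.random.default_rng(seed)
    model = _CLASSES[config.family](config, rng)
    model.coord_rng = np.random.default_rng(seed + 10_000)
    if config.embedding_dim is not None:
        add_embedding_decoder(model, config.embedding_dim, rng)
    return model


def semantic_parameters(model: _SegModel) -> list:
    """Parameters the discriminative loss must NOT touch (semantic head)."""
    return model.head.parameters()


def save_checkpoint(model: _SegModel, path) -> None:
    """Weights as ``.npz`` with an embedded JSON ModelConfig manifest."""
    state = model.named_state()
    cfg = json.dumps(asdict(model.config))
    np.savez(path, __config__=np.frombuffer(cfg.encode(), dtype=np.uint8),
             **state)


def load_checkpoint(path) -> _SegModel:
    with np.load(path) as data:
        cfg = json.loads(bytes(data["__config__"].tobytes()).decode())
        state = {k: data[k] for k in data.files if k != "__config__"}
    config = ModelConfig(**cfg)
    model = build_model(config, seed=0)
    model.load_state(state)
    return model
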