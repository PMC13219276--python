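"""The hybrid convolution/attention classifier.

Architecture, from pixels to logits: a convolutional backbone, a 1x1 "head"
convolution lifting the feature map into the attention channel width, a
MobileViT-style block (local 3x3 convolution, patch unfolding, multi-head
self-attention across patches, refolding, 1x1 projection, residual add),
sequential CBAM channel+spatial gating, an ESA spatial gate built from
dilated convolutions, then global average pooling, dropout and an affine
classifier.

The bundled ``tiny`` backbone (three stride-2 conv/norm/SiLU stages) keeps
everything trainable on a CPU in minutes; the well-known ImageNet backbones
occupy the same slot and can be plugged in through ``register_backbone``
when an implementation is available at runtime.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (
    BatchNorm2d, Conv2d, Dropout, GlobalAvgPool2d, Linear, Module,
    MultiHeadSelfAttention, Sequential, SiLU, Tensor, concat, pad_replicate,
)

__all__ = [
    "HybridConfig", "LayerParamAccount", "MobileViTBlock", "CBAM", "ESA",
    "TinyBackbone", "HybridClassifier", "build_hybrid", "count_parameters",
    "pinned_reference_accounts", "register_backbone",
]


@dataclass(frozen=True)
class HybridConfig:
    backbone: str = "tiny"
    attention_channels: int = 64        # 1280 for the ImageNet backbones
    patch_size: int = 2
    n_heads: int = 4
    dropout: float = 0.2
    n_classes: int = 7
    input_size: int = 224
    cbam_reduction: int = 16
    seed: int = 0

    def validate(self) -> None:
        if self.attention_channels % self.n_heads:
            raise ValueError("attention_channels must be divisible by n_heads")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if self.patch_size < 1:
            raise ValueError("patch_size must be >= 1")


@dataclass
class LayerParamAccount:
    """Trainable-scalar counts per named layer."""

    per_layer: dict[str, int]
    total: int = field(init=False)

    def __post_init__(self):
        self.total = sum(self.per_layer.values())


def count_parameters(model: Module) -> LayerParamAccount:
    """Count trainable scalars, grouped by the model's top-level children."""
    groups: dict[str, int] = {}
    for name, p in model.named_parameters():
        key = name.split(".")[0]
        groups[key] = groups.get(key, 0) + int(p.data.size)
    return LayerParamAccount(groups)


class MobileViTBlock(Module):
    """Local 3x3 conv -> unfold into ``patch_size`` pixel groups -> multi-head
    self-attention across patch positions -> refold -> 1x1 conv -> residual."""

    def __init__(self, channels: int, patch_size: int = 2, n_heads: int = 4,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.patch_size = patch_size
        self.conv_local = Conv2d(channels, channels, 3, padding=1, rng=rng)
        self.attention = MultiHeadSelfAttention(channels, n_heads, rng=rng)
        self.conv_proj = Conv2d(channels, channels, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        p = self.patch_size
        if H % p or W % p:
            raise ValueError(f"spatial dims ({H}x{W}) not divisible by patch size {p}")
        y = self.conv_local(x)
        hp, wp = H // p, W // p
        # (B, C, H, W) -> (B*p*p, hp*wp, C): attention runs across patch
        # positions, separately for each intra-patch pixel offset
        y = (y.reshape(B, C, hp, p, wp, p)
              .transpose(0, 3, 5, 2, 4, 1)
              .reshape(B * p * p, hp * wp, C))
        y = self.attention(y)
        y = (y.reshape(B, p, p, hp, wp, C)
              .transpose(0, 5, 3, 1, 4, 2)
              .reshape(B, C, H, W))
        return self.conv_proj(y) + x


class CBAM(Module):
    """Convolutional Block Attention: a shared two-layer bottleneck gates the
    channels from pooled descriptors, then a 7x7 conv over channel-wise
    average/max maps gates positions.  Both gates are sigmoid-bounded."""

    def __init__(self, channels: int, reduction: int = 16, spatial_kernel: int = 7,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if channels < reduction:
            raise ValueError("channel count must be >= reduction ratio")
        rng = rng or np.random.default_rng(0)
        mid = channels // reduction
        self.fc1 = Linear(channels, mid, bias=False, rng=rng)
        self.fc2 = Linear(mid, channels, bias=False, rng=rng)
        # edge-replicate padding keeps the gate free of border artifacts
        self._spatial_pad = spatial_kernel // 2
        self.conv_spatial = Conv2d(2, 1, spatial_kernel, rng=rng)

    def _channel_gate(self, x: Tensor) -> Tensor:
        avg = x.mean(axis=(2, 3))
        mx = x.max(axis=(2, 3))
        z = self.fc2(self.fc1(avg).relu()) + self.fc2(self.fc1(mx).relu())
        return z.sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        x = x * self._channel_gate(x).reshape(B, C, 1, 1)
        avg = x.mean(axis=1, keepdims=True)
        mx = x.max(axis=1, keepdims=True)
        pooled = pad_replicate(concat([avg, mx], axis=1), self._spatial_pad)
        gate = self.conv_spatial(pooled).sigmoid()
        return x * gate


class ESA(Module):
    """Enhanced spatial attention: channel-wise average and max maps pass
    through parallel dilated 3x3 convolutions (rates 1, 2, 3) for multi-scale
    context, fused by a 1x1 conv into a sigmoid gate."""

    def __init__(self, channels: int, mid: int = 4, dilations=(1, 2, 3),
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.dilations = tuple(dilations)
        self.branches = [Conv2d(2, mid, 3, dilation=d, rng=rng)
                         for d in dilations]
        self.fuse = Conv2d(mid * len(dilations), 1, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        avg = x.mean(axis=1, keepdims=True)
        mx = x.max(axis=1, keepdims=True)
        pooled = concat([avg, mx], axis=1)
        feats = [br(pad_replicate(pooled, d)).relu()
                 for br, d in zip(self.branches, self.dilations)]
        gate = self.fuse(concat(feats, axis=1)).sigmoid()
        return x * gate


class TinyBackbone(Module):
    """Three stride-2 conv/norm/SiLU stages (overall stride 8), ending at
    ``out_channels`` feature maps — a desk-scale stand-in occupying the same
    interface as the ImageNet backbones."""

    out_channels = 32

    def __init__(self, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stem = Sequential(
            Conv2d(3, 16, 3, stride=2, padding=1, bias=False, rng=rng),
            BatchNorm2d(16), SiLU(),
            Conv2d(16, 32, 3, stride=2, padding=1, bias=False, rng=rng),
            BatchNorm2d(32), SiLU(),
            Conv2d(32, self.out_channels, 3, stride=2, padding=1, bias=False, rng=rng),
            BatchNorm2d(self.out_channels), SiLU(),
        )

    def forward(self, x):
        return self.stem(x)


_BACKBONES = {"tiny": lambda rng: TinyBackbone(rng=rng)}


def register_backbone(name: str, factory) -> None:
    """Register a backbone factory ``factory(rng) -> Module`` (the module must
    expose ``out_channels``)."""
    _BACKBONES[name] = factory


class HybridClassifier(Module):
    def __init__(self, config: HybridConfig):
        super().__init__()
        config.validate()
        rng = np.random.default_rng(config.seed)
        if config.backbone not in _BACKBONES:
            raise ValueError(
                f"no backbone provider registered for {config.backbone!r}; "
                "use 'tiny' or register_backbone()")
        self.config = config
        self.backbone = _BACKBONES[config.backbone](rng)
        C = config.attention_channels
        self.head = Sequential(
            Conv2d(self.backbone.out_channels, C, 1, bias=False, rng=rng),
            BatchNorm2d(C), SiLU(),
        )
        self.mobilevit = MobileViTBlock(C, config.patch_size, config.n_heads, rng=rng)
        self.cbam = CBAM(C, reduction=min(config.cbam_reduction, C), rng=rng)
        self.esa = ESA(C, rng=rng)
        self.pool = GlobalAvgPool2d()
        self.dropout = Dropout(config.dropout)
        self.classifier = Linear(C, config.n_classes, rng=rng)

    def forward(self, x) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        f = self.backbone(x)
        f = self.head(f)
        f = self.mobilevit(f)
        f = self.cbam(f)
        f = self.esa(f)
        z = self.dropout(self.pool(f))
        return self.classifier(z)


def build_hybrid(config: HybridConfig) -> HybridClassifier:
    return HybridClassifier(config)


def pinned_reference_accounts(n_classes: int = 7) -> dict[str, int]:
    """Parameter counts of the three architecture rows that are fixed by
    construction regardless of backbone internals: the stem convolution
    (3->32, 3x3, no bias, plus per-channel scale/shift normalization), the
    feature-head convolution (320->1280, 1x1, no bias, plus normalization),
    and the affine classifier (1280 -> n_classes with bias)."""
    stem = Sequential(Conv2d(3, 32, 3, stride=2, padding=1, bias=False),
                      BatchNorm2d(32))
    head = Sequential(Conv2d(320, 1280, 1, bias=False), BatchNorm2d(1280))
    classifier = Linear(1280, n_classes)
    return {
        "stem": count_parameters(stem).total,
        "head_conv": count_parameters(head).total,
        "classifier": count_parameters(classifier).total,
    }
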