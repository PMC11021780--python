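"""Two-stage cascaded 3-D encoder–decoder segmentation network.

Stage 1 is a plain 3-D U-Net (4 down-/up-sampling levels) that produces a
coarse 4-class segmentation of the 4-modality input.  Its per-voxel class
probabilities are concatenated with the input (8 channels) and refined by
stage 2, an architecturally identical U-Net in which every 3³ convolution is
a dynamic convolution and whose deepest (fourth) skip connection passes
through the EM attention block before concatenation.  Both logits tensors are
returned so the composite loss can supervise the stages jointly; the cascade
is differentiable end-to-end because stage-1 probabilities (not hard labels)
are fused.

Geometry, with base width 16 and a 128³ input: encoder features of 16/32/64/
128 channels at sides 128/64/32/16, a 256-channel bottleneck at 8³; the
fourth lateral tensor entering the attention block is 128 × 16³.  The spatial
side must be divisible by 16 (four halvings).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .autodiff import (Module, Parameter, Tensor, concat, conv3d, he_init,
                       maxpool3d_2, relu, reshape, softmax, sqrt, tmean,
                       upsample3d_2)
from .dynconv import DyConvConfig, DynamicConv3d
from .ema import EmaConfig, EMAttention3d

N_CLASSES = 4
LEVELS = 4


@dataclasses.dataclass
class StageConfig:
    in_channels: int
    out_channels: int = N_CLASSES
    base_width: int = 16
    conv_kind: str = "standard"          # "standard" | "dynamic"
    ema_on_fourth_lateral: bool = False
    norm_groups: int = 8
    dyconv: DyConvConfig | None = None   # template; channels filled per layer
    ema: EmaConfig | None = None

    def __post_init__(self) -> None:
        if self.conv_kind not in ("standard", "dynamic"):
            raise ValueError(f"unknown conv_kind '{self.conv_kind}'")


class Conv3dLayer(Module):
    """Standard stride-1 'same' convolution layer."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        self.weight = Parameter(he_init(rng, (cout, cin, k, k, k), fan_in=cin * k ** 3))
        self.bias = Parameter(np.zeros(cout, dtype=np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias)


class GroupNorm(Module):
    """Group normalization over (channels-in-group × space) of one sample."""

    def __init__(self, channels: int, groups: int, eps: float = 1e-5):
        if channels % groups:
            groups = 1
        self.groups = groups
        self.channels = channels
        self.eps = eps
        self.gamma = Parameter(np.ones(channels, dtype=np.float32))
        self.beta = Parameter(np.zeros(channels, dtype=np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        c, d, h, w = x.data.shape
        g = self.groups
        xg = reshape(x, (g, (c // g) * d * h * w))
        mu = tmean(xg, axis=1, keepdims=True)
        centered = xg - mu
        var = tmean(centered * centered, axis=1, keepdims=True)
        normed = centered / sqrt(var + self.eps)
        normed = reshape(normed, (c, d, h, w))
        gamma = reshape(self.gamma, (c, 1, 1, 1))
        beta = reshape(self.beta, (c, 1, 1, 1))
        return normed * gamma + beta


def _make_conv(cin: int, cout: int, kind: str, rng: np.random.Generator,
               dyconv_template: DyConvConfig | None) -> Module:
    if kind == "dynamic":
        tpl = dyconv_template or DyConvConfig(in_channels=cin, out_channels=cout)
        cfg = dataclasses.replace(tpl, in_channels=cin, out_channels=cout)
        return DynamicConv3d(cfg, rng)
    return Conv3dLayer(cin, cout, 3, rng)


class ConvBlock(Module):
    """(conv3³ → GN → ReLU) × 2."""

    def __init__(self, cin: int, cout: int, kind: str, groups: int,
                 rng: np.random.Generator, dyconv_template=None):
        self.conv1 = _make_conv(cin, cout, kind, rng, dyconv_template)
        self.norm1 = GroupNorm(cout, groups)
        self.conv2 = _make_conv(cout, cout, kind, rng, dyconv_template)
        self.norm2 = GroupNorm(cout, groups)

    def __call__(self, x: Tensor) -> Tensor:
        x = relu(self.norm1(self.conv1(x)))
        x = relu(self.norm2(self.conv2(x)))
        return x


class Stage(Module):
    """One encoder–decoder stage with 4 levels and lateral skip connections."""

    def __init__(self, config: StageConfig, rng: np.random.Generator):
        self.config = config
        w = config.base_width
        kind = config.conv_kind
        groups = config.norm_groups
        tpl = config.dyconv
        widths = [w * 2 ** level for level in range(LEVELS)]          # 16..128
        self.encoder = []
        cin = config.in_channels
        for cw in widths:
            self.encoder.append(ConvBlock(cin, cw, kind, groups, rng, tpl))
            cin = cw
        self.bottleneck = ConvBlock(widths[-1], widths[-1] * 2, kind, groups, rng, tpl)
        # decoder: upsample, project channels down (pointwise), concat skip, block
        self.up_proj = []
        self.decoder = []
        cin = widths[-1] * 2
        for cw in reversed(widths):
            self.up_proj.append(Conv3dLayer(cin, cw, 1, rng))
            self.decoder.append(ConvBlock(2 * cw, cw, kind, groups, rng, tpl))
            cin = cw
        self.head = Conv3dLayer(widths[0], config.out_channels, 1, rng)
        self.ema = None
        if config.ema_on_fourth_lateral:
            ema_cfg = config.ema or EmaConfig(channels=widths[-1])
            if ema_cfg.channels != widths[-1]:
                ema_cfg = dataclasses.replace(ema_cfg, channels=widths[-1])
            self.ema = EMAttention3d(ema_cfg, rng)

    def forward(self, x: Tensor, training: bool = False) -> Tensor:
        self._validate(x)
        skips = []
        for block in self.encoder:
            x = block(x)
            skips.append(x)              # lateral feature, pre-pooling
            x = maxpool3d_2(x)
        x = self.bottleneck(x)
        if self.ema is not None:
            skips[-1] = self.ema.forward(skips[-1], training=training)
        for proj, block, skip in zip(self.up_proj, self.decoder, reversed(skips)):
            x = proj(upsample3d_2(x))
            x = block(concat([skip, x], axis=0))
        return self.head(x)

    __call__ = forward

    def _validate(self, x: Tensor) -> None:
        c = x.data.shape[0]
        if c != self.config.in_channels:
            raise ValueError(f"stage expects {self.config.in_channels} channels, got {c}")
        for s in x.data.shape[1:]:
            if s % 2 ** LEVELS:
                raise ValueError(
                    f"spatial size {x.data.shape[1:]} not divisible by {2 ** LEVELS}")

    # -- structural audit ----------------------------------------------------

    def conv3_layers(self) -> list[Module]:
        """All 3³ convolution layers (standard or dynamic) in the stage."""
        out = []
        for m in self.modules():
            if isinstance(m, Conv3dLayer) and m.weight.data.shape[-1] == 3:
                out.append(m)
            elif isinstance(m, DynamicConv3d):
                out.append(m)
        return out

    def fourth_lateral_geometry(self, side: int) -> tuple[int, int]:
        """(channels, side) of the deepest skip tensor for a ``side``³ input."""
        return self.config.base_width * 2 ** (LEVELS - 1), side // 2 ** (LEVELS - 1)


def build_stage(config: StageConfig, rng: np.random.Generator) -> Stage:
    return Stage(config, rng)


@dataclasses.dataclass
class CascadeOutput:
    stage1_logits: Tensor     # (4, S, S, S)
    stage2_logits: Tensor


class CascadeNet(Module):
    """The full coarse-to-fine cascade."""

    def __init__(self, base_width: int = 16, norm_groups: int = 8,
                 dyconv: DyConvConfig | None = None, ema: EmaConfig | None = None,
                 rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.stage1_config = StageConfig(
            in_channels=4, base_width=base_width, conv_kind="standard",
            norm_groups=norm_groups)
        self.stage2_config = StageConfig(
            in_channels=8, base_width=base_width, conv_kind="dynamic",
            ema_on_fourth_lateral=True, norm_groups=norm_groups,
            dyconv=dyconv, ema=ema)
        self.stage1 = Stage(self.stage1_config, rng)
        self.stage2 = Stage(self.stage2_config, rng)

    def forward(self, stack: Tensor | np.ndarray, training: bool = False) -> CascadeOutput:
        x = stack if isinstance(stack, Tensor) else Tensor(stack)
        s1 = self.stage1.forward(x, training=training)
        fused = fuse_inputs(x, s1)
        s2 = self.stage2.forward(fused, training=training)
        return CascadeOutput(stage1_logits=s1, stage2_logits=s2)

    __call__ = forward

    def set_temperature(self, tau: float) -> None:
        for m in self.modules():
            if isinstance(m, DynamicConv3d):
                m.temperature = tau

    def parameter_count(self) -> dict[str, int]:
        return {"stage1": sum(p.data.size for p in self.stage1.parameters()),
                "stage2": sum(p.data.size for p in self.stage2.parameters())}


def fuse_inputs(stack: Tensor, stage1_logits: Tensor) -> Tensor:
    """Concatenate stage-1 class probabilities with the modality stack.

    Softmax (not argmax) keeps the cascade differentiable, so the joint loss
    trains stage 1 through stage 2 as well.
    """
    if stack.data.shape[1:] != stage1_logits.data.shape[1:]:
        raise ValueError(f"spatial shapes differ: {stack.data.shape[1:]} vs "
                         f"{stage1_logits.data.shape[1:]}")
    probs = softmax(stage1_logits, axis=0)
    return concat([probs, stack], axis=0)


def icunet_forward(net: CascadeNet, stack, training: bool = False) -> CascadeOutput:
    """Functional alias for the full cascade forward pass."""
    return net.forward(stack, training=training)
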