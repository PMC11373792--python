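"""Residual classifiers and their attention/deformable modifications.

Seven families are buildable:

* ``resnet18`` / ``resnet34`` — basic blocks, stage depths (2,2,2,2) /
  (3,4,6,3)
* ``resnet50`` / ``resnet101`` — bottleneck blocks (expansion 4),
  depths (3,4,6,3) / (3,4,23,3)
* ``cbam_resnet34`` — ResNet34 with CBAM blocks after the stem max
  pool and after the Conv2 stage
* ``se_resnet34`` — ResNet34 with SE blocks at the same two points
* ``se_resnet34_dcn`` — additionally replaces the first 3x3
  convolution of the first Conv2 block with a deformable convolution

plus ``se_resnet_small``, a reduced SE-residual variant (3x3 stem, two
SE-attended stages) for desk-scale experiments on small inputs.

"Conv2" follows the standard stage naming: the first residual stage
after the stem (conv2_x). Attention placement is stage-level — one
block after the stem pool, one after the whole Conv2 stage — and is
configurable through ``ModelConfig.attention_points``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .attention import CBAMBlock, SEBlock
from .core import Module, Parameter, Sequential
from .deform import DeformableConv2d
from .functional import softmax
from .layers import BatchNorm2d, Conv2d, GlobalAvgPool, Identity, Linear, MaxPool2d, ReLU

__all__ = ["ModelConfig", "ResNet", "build_resnet", "build_modified_model", "build_model",
           "module_census", "FAMILIES"]

FAMILIES = (
    "resnet18",
    "resnet34",
    "resnet50",
    "resnet101",
    "cbam_resnet34",
    "se_resnet34",
    "se_resnet34_dcn",
    "se_resnet_small",
)

_PLAIN_DEPTHS = {
    "resnet18": ("basic", (2, 2, 2, 2)),
    "resnet34": ("basic", (3, 4, 6, 3)),
    "resnet50": ("bottleneck", (3, 4, 6, 3)),
    "resnet101": ("bottleneck", (3, 4, 23, 3)),
}


@dataclass(frozen=True)
class ModelConfig:
    """Architecture description; serializable alongside checkpoints."""

    family: str = "resnet34"
    num_classes: int = 7
    se_reduction: int = 16
    cbam_kernel: int = 7
    attention_points: tuple[str, ...] = ("stem", "conv2")  # legal: stem, conv2
    input_size: int = 224
    base_channels: int = 64
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        for p in self.attention_points:
            if p not in ("stem", "conv2"):
                raise ValueError(f"illegal attention point {p!r}")
        if self.cbam_kernel % 2 == 0:
            raise ValueError("cbam_kernel must be odd")

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "num_classes": self.num_classes,
            "se_reduction": self.se_reduction,
            "cbam_kernel": self.cbam_kernel,
            "attention_points": list(self.attention_points),
            "input_size": self.input_size,
            "base_channels": self.base_channels,
            "rng_seed": self.rng_seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["attention_points"] = tuple(d.get("attention_points", ("stem", "conv2")))
        return cls(**d)


class BasicBlock(Module):
    expansion = 1

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        stride: int,
        rng: np.random.Generator,
        deformable_first: bool = False,
    ) -> None:
        conv_cls = DeformableConv2d if deformable_first else Conv2d
        self.conv1 = conv_cls(in_ch, out_ch, 3, stride=stride, padding=1, bias=False, rng=rng)
        self.bn1 = BatchNorm2d(out_ch)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(out_ch, out_ch, 3, padding=1, bias=False, rng=rng)
        self.bn2 = BatchNorm2d(out_ch)
        self.relu_out = ReLU()
        if stride != 1 or in_ch != out_ch:
            self.down_conv = Conv2d(in_ch, out_ch, 1, stride=stride, bias=False, rng=rng)
            self.down_bn = BatchNorm2d(out_ch)
        else:
            self.down_conv = None
            self.down_bn = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = self.bn2(self.conv2(self.relu1(self.bn1(self.conv1(x)))))
        shortcut = self.down_bn(self.down_conv(x)) if self.down_conv else x
        return self.relu_out(out + shortcut)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.relu_out.backward(dout)
        dmain = self.conv1.backward(self.bn1.backward(self.relu1.backward(
            self.conv2.backward(self.bn2.backward(d)))))
        dshort = self.down_conv.backward(self.down_bn.backward(d)) if self.down_conv else d
        return dmain + dshort


class Bottleneck(Module):
    expansion = 4

    def __init__(self, in_ch: int, mid_ch: int, stride: int, rng: np.random.Generator) -> None:
        out_ch = mid_ch * self.expansion
        self.conv1 = Conv2d(in_ch, mid_ch, 1, bias=False, rng=rng)
        self.bn1 = BatchNorm2d(mid_ch)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(mid_ch, mid_ch, 3, stride=stride, padding=1, bias=False, rng=rng)
        self.bn2 = BatchNorm2d(mid_ch)
        self.relu2 = ReLU()
        self.conv3 = Conv2d(mid_ch, out_ch, 1, bias=False, rng=rng)
        self.bn3 = BatchNorm2d(out_ch)
        self.relu_out = ReLU()
        if stride != 1 or in_ch != out_ch:
            self.down_conv = Conv2d(in_ch, out_ch, 1, stride=stride, bias=False, rng=rng)
            self.down_bn = BatchNorm2d(out_ch)
        else:
            self.down_conv = None
            self.down_bn = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = self.relu1(self.bn1(self.conv1(x)))
        out = self.relu2(self.bn2(self.conv2(out)))
        out = self.bn3(self.conv3(out))
        shortcut = self.down_bn(self.down_conv(x)) if self.down_conv else x
        return self.relu_out(out + shortcut)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.relu_out.backward(dout)
        dmain = self.bn3.backward(d)
        dmain = self.conv3.backward(dmain)
        dmain = self.relu2.backward(dmain)
        dmain = self.conv2.backward(self.bn2.backward(dmain))
        dmain = self.relu1.backward(dmain)
        dmain = self.conv1.backward(self.bn1.backward(dmain))
        dshort = self.down_conv.backward(self.down_bn.backward(d)) if self.down_conv else d
        return dmain + dshort


class ResNet(Module):
    """Stem + four residual stages + global average pool + linear head.

    ``forward`` emits logits; use :meth:`predict_proba` for the softmax
    distribution at inference.
    """

    def __init__(self, config: ModelConfig) -> None:
        self.config = config
        rng = np.random.default_rng(config.rng_seed)
        base = config.base_channels
        family = config.family

        if family == "se_resnet_small":
            self._build_small(config, rng)
            return

        if family in _PLAIN_DEPTHS:
            block_kind, depths = _PLAIN_DEPTHS[family]
        else:
            block_kind, depths = "basic", _PLAIN_DEPTHS["resnet34"][1]

        self.stem_conv = Conv2d(3, base, 7, stride=2, padding=3, bias=False, rng=rng)
        self.stem_bn = BatchNorm2d(base)
        self.stem_relu = ReLU()
        self.stem_pool = MaxPool2d(3, 2, 1)

        attn = self._attention_factory(family, config, rng)
        self.attn_stem = attn(base) if (attn and "stem" in config.attention_points) else Identity()

        stages: list[Sequential] = []
        in_ch = base
        widths = (base, base * 2, base * 4, base * 8)
        for si, (width, depth) in enumerate(zip(widths, depths)):
            blocks: list[Module] = []
            for bi in range(depth):
                stride = 2 if (si > 0 and bi == 0) else 1
                deform = family == "se_resnet34_dcn" and si == 0 and bi == 0
                if block_kind == "basic":
                    blk = BasicBlock(in_ch, width, stride, rng, deformable_first=deform)
                    in_ch = width
                else:
                    blk = Bottleneck(in_ch, width, stride, rng)
                    in_ch = width * Bottleneck.expansion
                blocks.append(blk)
            stages.append(Sequential(*blocks))
        self.stages = stages

        self.attn_conv2 = attn(widths[0] * (4 if block_kind == "bottleneck" else 1)) \
            if (attn and "conv2" in config.attention_points) else Identity()

        self.gap = GlobalAvgPool()
        self.fc = Linear(in_ch, config.num_classes, rng=rng)
        self._small = False

    def _build_small(self, config: ModelConfig, rng: np.random.Generator) -> None:
        base = min(config.base_channels, 16)
        self.stem_conv = Conv2d(3, base, 3, stride=1, padding=1, bias=False, rng=rng)
        self.stem_bn = BatchNorm2d(base)
        self.stem_relu = ReLU()
        self.stem_pool = Identity()
        self.attn_stem = SEBlock(base, config.se_reduction, rng) \
            if "stem" in config.attention_points else Identity()
        self.stages = [
            Sequential(BasicBlock(base, base, 1, rng)),
            Sequential(BasicBlock(base, base * 2, 2, rng)),
        ]
        self.attn_conv2 = SEBlock(base, config.se_reduction, rng) \
            if "conv2" in config.attention_points else Identity()
        self.gap = GlobalAvgPool()
        self.fc = Linear(base * 2, config.num_classes, rng=rng)
        self._small = True

    @staticmethod
    def _attention_factory(family: str, config: ModelConfig, rng: np.random.Generator):
        if family in ("se_resnet34", "se_resnet34_dcn"):
            return lambda ch: SEBlock(ch, config.se_reduction, rng)
        if family == "cbam_resnet34":
            return lambda ch: CBAMBlock(ch, config.se_reduction, config.cbam_kernel, rng)
        return None

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = self.stem_pool(self.stem_relu(self.stem_bn(self.stem_conv(x))))
        out = self.attn_stem(out)
        for si, stage in enumerate(self.stages):
            out = stage(out)
            if si == 0:
                out = self.attn_conv2(out)
        feats = self.gap(out)
        return self.fc(feats)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        d = self.gap.backward(self.fc.backward(dlogits))
        for si in range(len(self.stages) - 1, -1, -1):
            if si == 0:  # attn_conv2 sits after stage 0, unwind it first
                d = self.attn_conv2.backward(d)
            d = self.stages[si].backward(d)
        d = self.attn_stem.backward(d)
        d = self.stem_pool.backward(d)
        d = self.stem_bn.backward(self.stem_relu.backward(d))
        return self.stem_conv.backward(d)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x))


def build_resnet(config: ModelConfig) -> ResNet:
    """Plain residual classifier; rejects the modified families."""
    if config.family not in _PLAIN_DEPTHS:
        raise ValueError(f"build_resnet handles plain depths only, not {config.family!r}")
    return ResNet(config)


def build_modified_model(config: ModelConfig) -> ResNet:
    """SE/CBAM/DCN-modified ResNet34 variants (and the small SE variant)."""
    if config.family in _PLAIN_DEPTHS:
        raise ValueError(f"{config.family!r} is a plain family; use build_resnet")
    return ResNet(config)


def build_model(config: ModelConfig) -> ResNet:
    return build_resnet(config) if config.family in _PLAIN_DEPTHS else build_modified_model(config)


def module_census(model: ResNet) -> dict[str, int]:
    """Counts of notable module types: SE, CBAM, deformable conv, linear,
    convolutional stages (stem + residual stages)."""
    counts = {"se": 0, "cbam": 0, "deformable_conv": 0, "linear": 0, "stages": 1 + len(model.stages)}
    for mod in model._all_modules():
        if isinstance(mod, SEBlock):
            counts["se"] += 1
        elif isinstance(mod, CBAMBlock):
            counts["cbam"] += 1
        elif isinstance(mod, DeformableConv2d):
            counts["deformable_conv"] += 1
        elif isinstance(mod, Linear):
            counts["linear"] += 1
    return counts
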