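"""Residual backbones producing the six-level feature pyramid C0-C5.

Level contract: C0 is the stem output (stride 2), C1-C4 the four residual
stages (strides 4, 8, 16, 32), and C5 a stride-64 map obtained by
parameter-free stride-2 subsampling of C4.  Spatial sizes obey
``ceil(input / stride)`` at every level for arbitrary input sizes.

The ``tiny`` variant is a reduced-width, group-normalized network meant for
CPU-scale training exercises; the ResNet/ResNeXt builders follow the
standard published stage layouts (and therefore the standard parameter
counts).
"""

from __future__ import annotations

from dataclasses import dataclass

from . import nn
from .tensor import Tensor

__all__ = ["PyramidLevels", "build_backbone", "Backbone", "LEVEL_NAMES"]

LEVEL_NAMES = ("C0", "C1", "C2", "C3", "C4", "C5")
LEVEL_STRIDES = {"C0": 2, "C1": 4, "C2": 8, "C3": 16, "C4": 32, "C5": 64}

MIN_INPUT = 64


@dataclass
class PyramidLevels:
    """Ordered multi-scale feature maps with per-level stride metadata."""

    maps: dict[str, Tensor]
    strides: dict[str, int]

    def __getitem__(self, name: str) -> Tensor:
        return self.maps[name]

    def shape_of(self, name: str) -> tuple:
        return self.maps[name].shape

    @property
    def names(self) -> list[str]:
        return list(self.maps)


class Bottleneck(nn.Module):
    expansion = 4

    def __init__(self, in_ch: int, width: int, stride: int = 1,
                 groups: int = 1, norm=nn.BatchNorm2d):
        super().__init__()
        out_ch = width * self.expansion
        self.conv1 = nn.Conv2d(in_ch, width, 1, bias=False)
        self.bn1 = norm(width)
        self.conv2 = _conv3(width, width, stride, groups)
        self.bn2 = norm(width)
        self.conv3 = nn.Conv2d(width, out_ch, 1, bias=False)
        self.bn3 = norm(out_ch)
        self.downsample = None
        if stride != 1 or in_ch != out_ch:
            self.downsample = nn.Sequential(
                nn.Conv2d(in_ch, out_ch, 1, stride=stride, bias=False),
                norm(out_ch),
            )

    def forward(self, x: Tensor) -> Tensor:
        identity = self.downsample(x) if self.downsample is not None else x
        y = self.bn1(self.conv1(x)).relu()
        y = self.bn2(self.conv2(y)).relu()
        y = self.bn3(self.conv3(y))
        return (y + identity).relu()


class _GroupedConv3(nn.Module):
    """3x3 grouped convolution assembled from per-group convolutions."""

    def __init__(self, in_ch: int, out_ch: int, stride: int, groups: int):
        super().__init__()
        if in_ch % groups or out_ch % groups:
            raise ValueError("channels must divide groups")
        self.groups = groups
        self.convs = nn.ModuleList([
            nn.Conv2d(in_ch // groups, out_ch // groups, 3, stride=stride,
                      padding=1, bias=False)
            for _ in range(groups)
        ])

    def forward(self, x: Tensor) -> Tensor:
        from .tensor import concat

        cg = x.shape[1] // self.groups
        outs = [conv(x[:, i * cg:(i + 1) * cg]) for i, conv in enumerate(self.convs)]
        return concat(outs, axis=1)


def _conv3(in_ch, out_ch, stride, groups):
    if groups == 1:
        return nn.Conv2d(in_ch, out_ch, 3, stride=stride, padding=1, bias=False)
    return _GroupedConv3(in_ch, out_ch, stride, groups)


class Backbone(nn.Module):
    """ResNet-style extractor exposing C0-C5."""

    def __init__(self, blocks: tuple[int, ...], base_width: int = 64,
                 groups: int = 1, width_per_group: int = 64):
        super().__init__()
        self.conv1 = nn.Conv2d(3, base_width, 7, stride=2, padding=3, bias=False)
        self.bn1 = nn.BatchNorm2d(base_width)
        widths = [64, 128, 256, 512]
        in_ch = base_width
        self.stages = nn.ModuleList()
        for i, (n, w) in enumerate(zip(blocks, widths)):
            stage = nn.ModuleList()
            stride = 1 if i == 0 else 2
            width = w * groups * width_per_group // 64
            for j in range(n):
                stage.append(Bottleneck(in_ch, width, stride if j == 0 else 1,
                                        groups=groups))
                in_ch = width * Bottleneck.expansion
            self.stages.append(stage)
        self.channels = {
            "C0": base_width,
            **{f"C{i + 1}": widths[i] * Bottleneck.expansion for i in range(4)},
        }
        self.channels["C5"] = self.channels["C4"]

    def forward(self, x: Tensor) -> PyramidLevels:
        return self.extract_pyramid(x)

    def extract_pyramid(self, x: Tensor) -> PyramidLevels:
        if x.shape[2] < MIN_INPUT or x.shape[3] < MIN_INPUT:
            raise ValueError(f"input must be at least {MIN_INPUT}x{MIN_INPUT} pixels")
        c0 = self.bn1(self.conv1(x)).relu()
        y = c0.maxpool2d(3, 2, 1)
        maps = {"C0": c0}
        for i, stage in enumerate(self.stages):
            for block in stage:
                y = block(y)
            maps[f"C{i + 1}"] = y
        maps["C5"] = maps["C4"].subsample2()
        return PyramidLevels(maps=maps, strides=dict(LEVEL_STRIDES))


class _TinyStage(nn.Module):
    def __init__(self, in_ch: int, out_ch: int, stride: int):
        super().__init__()
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, stride=stride, padding=1, bias=False)
        self.gn1 = nn.GroupNorm(min(8, out_ch), out_ch)
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, padding=1, bias=False)
        self.gn2 = nn.GroupNorm(min(8, out_ch), out_ch)
        self.proj = nn.Conv2d(in_ch, out_ch, 1, stride=stride, bias=False)

    def forward(self, x: Tensor) -> Tensor:
        identity = self.proj(x)
        y = self.gn1(self.conv1(x)).relu()
        y = self.gn2(self.conv2(y))
        return (y + identity).relu()


class TinyBackbone(nn.Module):
    """Reduced-width group-normalized backbone for CPU-scale experiments.

    Group normalization (rather than batch statistics) keeps single-image
    mini-batches stable when training from scratch.
    """

    def __init__(self, widths: tuple[int, ...] = (16, 24, 32, 48, 64)):
        super().__init__()
        self.conv1 = nn.Conv2d(3, widths[0], 3, stride=2, padding=1, bias=False)
        self.gn1 = nn.GroupNorm(min(8, widths[0]), widths[0])
        self.stages = nn.ModuleList([
            _TinyStage(widths[i], widths[i + 1], 2) for i in range(4)
        ])
        self.channels = {f"C{i}": widths[i] for i in range(5)}
        self.channels["C5"] = widths[4]

    def forward(self, x: Tensor) -> PyramidLevels:
        return self.extract_pyramid(x)

    def extract_pyramid(self, x: Tensor) -> PyramidLevels:
        if x.shape[2] < MIN_INPUT or x.shape[3] < MIN_INPUT:
            raise ValueError(f"input must be at least {MIN_INPUT}x{MIN_INPUT} pixels")
        y = self.gn1(self.conv1(x)).relu()
        maps = {"C0": y}
        for i, stage in enumerate(self.stages):
            y = stage(y)
            maps[f"C{i + 1}"] = y
        maps["C5"] = maps["C4"].subsample2()
        return PyramidLevels(maps=maps, strides=dict(LEVEL_STRIDES))


_BUILDERS = {
    "resnet50": lambda: Backbone((3, 4, 6, 3)),
    "resnet101": lambda: Backbone((3, 4, 23, 3)),
    "resnext50": lambda: Backbone((3, 4, 6, 3), groups=32, width_per_group=4),
    "resnext101": lambda: Backbone((3, 4, 23, 3), groups=32, width_per_group=4),
    "tiny": lambda: TinyBackbone(),
}


def build_backbone(name: str):
    """Construct a named backbone; unknown names raise a configuration error."""
    try:
        builder = _BUILDERS[name]
    except KeyError:
        raise ValueError(
            f"unknown backbone {name!r}; choose from {sorted(_BUILDERS)}"
        ) from None
    return builder()
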