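"""Full detector assembly: backbone + neck + anchor-free head.

Builders cover the three reference configurations whose parameter counts
are tracked (the plain-FPN FCOS baseline and the two TD-Det variants) and
a reduced-width `tiny` build for CPU-scale training exercises.  The neck is
swappable: any module mapping the backbone pyramid to head-ready maps fits,
which is the plug-and-play contract the shape tests pin down.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .backbone import PyramidLevels, build_backbone
from .head import (DetectionSet, FCOSHead, HeadConfig, assign_targets,
                   decode_and_nms, scale_ranges_for, total_loss)
from .tensor import Tensor
from .tfpn import FPN, TFPN, NeckConfig

__all__ = ["Detector", "build_fcos_baseline", "build_tddet",
           "build_tiny_detector", "preprocess_image"]

_MEAN = 0.45
_STD = 0.225


def preprocess_image(image: np.ndarray) -> Tensor:
    """HxWx3 uint8 -> normalized (1,3,H,W) tensor."""
    x = image.astype(np.float32) / 255.0
    x = (x - _MEAN) / _STD
    return Tensor(x.transpose(2, 0, 1)[None])


class Detector(nn.Module):
    def __init__(self, backbone, neck, head: FCOSHead,
                 neck_input_levels: tuple[str, ...], neck_kind: str):
        super().__init__()
        self.backbone = backbone
        self.neck = neck
        self.head = head
        self.neck_input_levels = neck_input_levels
        self.neck_kind = neck_kind   # "tfpn" | "fpn"

    # -- forward ---------------------------------------------------------
    def head_maps(self, pyramid: PyramidLevels) -> list[Tensor]:
        if self.neck_kind == "tfpn":
            out = self.neck(pyramid)
            return [out[lv] for lv in self.neck.config.levels]
        return self.neck([pyramid[lv] for lv in self.neck_input_levels])

    def forward(self, images: Tensor) -> list[dict]:
        return self.head(self.head_maps(self.backbone(images)))

    # -- training --------------------------------------------------------
    def loss_for(self, image: np.ndarray, boxes: np.ndarray,
                 labels: np.ndarray, sampler_rng=None):
        outputs = self(preprocess_image(image))
        shapes = [tuple(o["cls"].shape[2:]) for o in outputs]
        cfg = self.head.config
        assignment = assign_targets(shapes, cfg.strides, boxes, labels,
                                    scale_ranges_for(cfg.strides))
        bundle = total_loss(outputs, assignment, cfg.num_classes,
                            use_sampler=cfg.use_sampler,
                            sampler_size=cfg.sampler_size,
                            sampler_rng=sampler_rng)
        return bundle, assignment

    # -- inference -------------------------------------------------------
    def predict(self, image: np.ndarray) -> DetectionSet:
        was_training = self.training
        self.eval()
        try:
            outputs = self(preprocess_image(image))
        finally:
            self.train(was_training)
        shapes = [tuple(o["cls"].shape[2:]) for o in outputs]
        cfg = self.head.config
        h, w = image.shape[:2]
        return decode_and_nms(outputs, shapes, cfg.strides, (w, h),
                              score_thr=cfg.score_thr, nms_iou=cfg.nms_iou,
                              max_dets=cfg.max_dets)


# ---------------------------------------------------------------------------
# builders

_VARIANT_STRIDES = {"RV": (4, 8, 16, 32, 64), "PV": (2, 4, 8, 16, 32)}


def build_fcos_baseline(num_classes: int = 2,
                        backbone_name: str = "resnet50",
                        seed: int | None = None) -> Detector:
    """Plain-FPN FCOS: 5 head levels at strides 8-128, neck width 256."""
    if seed is not None:
        nn.seed_init(seed)
    backbone = build_backbone(backbone_name)
    levels = ("C2", "C3", "C4")
    neck = FPN([backbone.channels[lv] for lv in levels], out_ch=256, num_outs=5)
    head = FCOSHead(HeadConfig(num_classes=num_classes,
                               strides=(8, 16, 32, 64, 128)))
    return Detector(backbone, neck, head, levels, "fpn")


def build_tddet(variant: str, num_classes: int = 2,
                backbone_name: str = "resnet50",
                neck_config: NeckConfig | None = None,
                use_standard_fpn: bool = False,
                seed: int | None = None) -> Detector:
    """TD-Det: T-FPN over C1-C5 (RV) or C0-C4 (PV) plus the FCOS head.

    ``use_standard_fpn`` swaps the T-FPN for a standard top-down pyramid on
    the same level set — the neck-ablation configuration.
    """
    if seed is not None:
        nn.seed_init(seed)
    cfg = neck_config or NeckConfig(variant=variant)
    if cfg.variant != variant:
        raise ValueError("neck_config variant mismatch")
    backbone = build_backbone(backbone_name)
    in_channels = {lv: backbone.channels[lv] for lv in cfg.levels}
    head = FCOSHead(HeadConfig(num_classes=num_classes,
                               strides=_VARIANT_STRIDES[variant]))
    if use_standard_fpn:
        neck = FPN([in_channels[lv] for lv in cfg.levels], out_ch=cfg.d1,
                   num_outs=len(cfg.levels))
        return Detector(backbone, neck, head, cfg.levels, "fpn")
    neck = TFPN(in_channels, cfg)
    return Detector(backbone, neck, head, cfg.levels, "tfpn")


def build_tiny_detector(variant: str = "PV", num_classes: int = 2,
                        d1: int = 32, stacked_convs: int = 2,
                        use_standard_fpn: bool = False,
                        seed: int | None = None) -> Detector:
    """Reduced-width detector (tiny backbone, narrow neck/head) for CPU runs."""
    if seed is not None:
        nn.seed_init(seed)
    backbone = build_backbone("tiny")
    cfg = NeckConfig(variant=variant, d1=d1, heads=4, mlp_ratio=1, reduction=4)
    in_channels = {lv: backbone.channels[lv] for lv in cfg.levels}
    head = FCOSHead(HeadConfig(num_classes=num_classes, in_channels=d1,
                               feat_channels=d1, stacked_convs=stacked_convs,
                               gn_groups=8, strides=_VARIANT_STRIDES[variant]))
    if use_standard_fpn:
        neck = FPN([in_channels[lv] for lv in cfg.levels], out_ch=d1,
                   num_outs=len(cfg.levels))
        return Detector(backbone, neck, head, cfg.levels, "fpn")
    neck = TFPN(in_channels, cfg)
    return Detector(backbone, neck, head, cfg.levels, "tfpn")
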