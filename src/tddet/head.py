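"""Anchor-free detection head (FCOS style) with the composite loss.

Every feature-map location predicts class scores, four distances
(l, t, r, b) to the sides of its box, and a centerness score.  A location
is a positive sample when it falls inside a ground-truth box and its
largest distance fits the scale range of its pyramid level; a location
inside several boxes regresses the smallest-area one.  The training loss is

    L_total = L_cls + L_reg + L_center

with L_cls a sigmoid focal loss over all locations normalized by the
number of positives, L_reg = −ln IoU between decoded and target boxes on
positives, and L_center a binary cross-entropy against the continuous
centerness target sqrt((min(l,r)/max(l,r)) · (min(t,b)/max(t,b))).

At test time the classification score is multiplied by the predicted
centerness before ranking, followed by class-wise non-maximum suppression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .tensor import Tensor, concat

__all__ = [
    "FCOSHead", "HeadConfig", "TargetAssignment", "LossBundle", "DetectionSet",
    "assign_targets", "centerness_target", "focal_loss", "iou_loss",
    "centerness_loss", "total_loss", "decode_and_nms", "iou_of",
    "pairwise_iou", "nms", "level_points", "scale_ranges_for",
]

INF = 1e8


# ---------------------------------------------------------------------------
# geometry


def iou_of(box_a, box_b) -> float:
    """Continuous-coordinate IoU of two (xmin, ymin, xmax, ymax) boxes."""
    ax0, ay0, ax1, ay1 = box_a
    bx0, by0, bx1, by1 = box_b
    area_a = max(ax1 - ax0, 0.0) * max(ay1 - ay0, 0.0)
    area_b = max(bx1 - bx0, 0.0) * max(by1 - by0, 0.0)
    if area_a <= 0.0 or area_b <= 0.0:
        return 0.0
    iw = min(ax1, bx1) - max(ax0, bx0)
    ih = min(ay1, by1) - max(ay0, by0)
    if iw <= 0.0 or ih <= 0.0:
        return 0.0
    inter = iw * ih
    return inter / (area_a + area_b - inter)


def pairwise_iou(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """IoU matrix between (N,4) and (M,4) box arrays."""
    if len(a) == 0 or len(b) == 0:
        return np.zeros((len(a), len(b)))
    area_a = np.clip(a[:, 2] - a[:, 0], 0, None) * np.clip(a[:, 3] - a[:, 1], 0, None)
    area_b = np.clip(b[:, 2] - b[:, 0], 0, None) * np.clip(b[:, 3] - b[:, 1], 0, None)
    iw = np.clip(np.minimum(a[:, None, 2], b[None, :, 2])
                 - np.maximum(a[:, None, 0], b[None, :, 0]), 0, None)
    ih = np.clip(np.minimum(a[:, None, 3], b[None, :, 3])
                 - np.maximum(a[:, None, 1], b[None, :, 1]), 0, None)
    inter = iw * ih
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / np.maximum(union, 1e-12), 0.0)


def nms(boxes: np.ndarray, scores: np.ndarray, iou_thr: float) -> np.ndarray:
    """Greedy non-maximum suppression; returns kept indices, score order."""
    order = np.argsort(-scores, kind="stable")
    keep = []
    suppressed = np.zeros(len(boxes), dtype=bool)
    for i in order:
        if suppressed[i]:
            continue
        keep.append(i)
        ious = pairwise_iou(boxes[i:i + 1], boxes)[0]
        suppressed |= ious > iou_thr
        suppressed[i] = True
    return np.array(keep, dtype=int)


# ---------------------------------------------------------------------------
# head module


@dataclass(frozen=True)
class HeadConfig:
    num_classes: int = 2
    in_channels: int = 256
    feat_channels: int = 256
    stacked_convs: int = 4
    gn_groups: int = 32
    strides: tuple[int, ...] = (8, 16, 32, 64, 128)
    score_thr: float = 0.025
    nms_iou: float = 0.5
    max_dets: int = 100
    use_sampler: bool = False          # optional 256 @ 1:1 sampling rule
    sampler_size: int = 256


def scale_ranges_for(strides: tuple[int, ...]) -> list[tuple[float, float]]:
    """Per-level regression ranges tied to the stride set (8x spacing)."""
    bounds = [8.0 * s for s in strides[:-1]]
    ranges = []
    lo = 0.0
    for b in bounds:
        ranges.append((lo, b))
        lo = b
    ranges.append((lo, INF))
    return ranges


class FCOSHead(nn.Module):
    """Shared classification/regression towers with per-level scales."""

    def __init__(self, config: HeadConfig):
        super().__init__()
        self.config = config
        c_in, c = config.in_channels, config.feat_channels
        self.cls_tower = nn.ModuleList()
        self.reg_tower = nn.ModuleList()
        for i in range(config.stacked_convs):
            ic = c_in if i == 0 else c
            self.cls_tower.append(_ConvGN(ic, c, config.gn_groups))
            self.reg_tower.append(_ConvGN(ic, c, config.gn_groups))
        self.cls_pred = nn.Conv2d(c, config.num_classes, 3, padding=1)
        self.reg_pred = nn.Conv2d(c, 4, 3, padding=1)
        # centerness predicted from the regression tower
        self.ctr_pred = nn.Conv2d(c, 1, 3, padding=1)
        self.scales = nn.ModuleList([nn.Scale(1.0) for _ in config.strides])

    def forward(self, maps: list[Tensor]) -> list[dict]:
        if len(maps) != len(self.config.strides):
            raise ValueError("one feature map per configured stride expected")
        outs = []
        for level, x in enumerate(maps):
            c = x
            for m in self.cls_tower:
                c = m(c)
            r = x
            for m in self.reg_tower:
                r = m(r)
            reg = self.scales[level](self.reg_pred(r))
            outs.append({
                "cls": self.cls_pred(c),
                "reg": reg,                      # log-distances; exp at use
                "ctr": self.ctr_pred(r),
            })
        return outs

    def prediction_layers(self):
        """Final prediction convolutions (for Gaussian initialization)."""
        return [self.cls_pred, self.reg_pred, self.ctr_pred]


class _ConvGN(nn.Module):
    def __init__(self, in_ch, out_ch, groups):
        super().__init__()
        self.conv = nn.Conv2d(in_ch, out_ch, 3, padding=1, bias=False)
        self.gn = nn.GroupNorm(min(groups, out_ch), out_ch)

    def forward(self, x):
        return self.gn(self.conv(x)).relu()


# ---------------------------------------------------------------------------
# target assignment


@dataclass
class TargetAssignment:
    points: np.ndarray        # (L, 2) location centers in input pixels
    level_ids: np.ndarray     # (L,)
    labels: np.ndarray        # (L,) class id, -1 for background
    bbox_targets: np.ndarray  # (L, 4) distances l, t, r, b
    centerness: np.ndarray    # (L,) defined on positives
    npos: int

    @property
    def positive_mask(self) -> np.ndarray:
        return self.labels >= 0


def level_points(shapes: list[tuple[int, int]],
                 strides: tuple[int, ...]) -> tuple[np.ndarray, np.ndarray]:
    """Location centers ((x+0.5)·stride) for every level, flattened."""
    pts, lids = [], []
    for lid, ((h, w), s) in enumerate(zip(shapes, strides)):
        ys, xs = np.mgrid[0:h, 0:w]
        p = np.stack([(xs.ravel() + 0.5) * s, (ys.ravel() + 0.5) * s], axis=1)
        pts.append(p)
        lids.append(np.full(h * w, lid))
    return np.concatenate(pts), np.concatenate(lids)


def centerness_target(l, t, r, b):
    """sqrt((min(l,r)/max(l,r)) · (min(t,b)/max(t,b))); 0 on degenerate input."""
    l, t, r, b = (np.asarray(v, dtype=np.float64) for v in (l, t, r, b))
    mx_lr = np.maximum(l, r)
    mx_tb = np.maximum(t, b)
    with np.errstate(invalid="ignore", divide="ignore"):
        val = np.sqrt((np.minimum(l, r) / np.maximum(mx_lr, 1e-12))
                      * (np.minimum(t, b) / np.maximum(mx_tb, 1e-12)))
    val = np.where((mx_lr <= 0) | (mx_tb <= 0), 0.0, val)
    return float(val) if val.ndim == 0 else val


def assign_targets(shapes: list[tuple[int, int]], strides: tuple[int, ...],
                   boxes: np.ndarray, labels: np.ndarray,
                   ranges: list[tuple[float, float]] | None = None
                   ) -> TargetAssignment:
    """FCOS assignment over flattened pyramid locations.

    ``boxes`` is (G,4) in input pixels; ``labels`` (G,) class ids.
    """
    if ranges is None:
        ranges = scale_ranges_for(strides)
    points, level_ids = level_points(shapes, strides)
    n = len(points)
    out_labels = np.full(n, -1, dtype=int)
    out_bbox = np.zeros((n, 4))
    out_ctr = np.zeros(n)
    if len(boxes) == 0:
        return TargetAssignment(points, level_ids, out_labels, out_bbox,
                                out_ctr, 0)
    lo = np.array([ranges[i][0] for i in level_ids])
    hi = np.array([ranges[i][1] for i in level_ids])
    l = points[:, 0:1] - boxes[None, :, 0]
    t = points[:, 1:2] - boxes[None, :, 1]
    r = boxes[None, :, 2] - points[:, 0:1]
    b = boxes[None, :, 3] - points[:, 1:2]
    dists = np.stack([l, t, r, b], axis=-1)        # (P, G, 4)
    inside = dists.min(axis=-1) > 0
    maxd = dists.max(axis=-1)
    in_range = (maxd > lo[:, None]) & (maxd <= hi[:, None])
    candidate = inside & in_range
    areas = np.where(candidate,
                     (boxes[:, 2] - boxes[:, 0]) * (boxes[:, 3] - boxes[:, 1]),
                     np.inf)
    best = areas.argmin(axis=1)
    has = candidate.any(axis=1)
    idx = np.flatnonzero(has)
    gi = best[idx]
    out_labels[idx] = labels[gi]
    out_bbox[idx] = dists[idx, gi]
    out_ctr[idx] = centerness_target(out_bbox[idx, 0], out_bbox[idx, 1],
                                     out_bbox[idx, 2], out_bbox[idx, 3])
    return TargetAssignment(points, level_ids, out_labels, out_bbox, out_ctr,
                            int(has.sum()))


# ---------------------------------------------------------------------------
# losses


@dataclass
class LossBundle:
    cls: Tensor
    reg: Tensor
    center: Tensor

    @property
    def total(self) -> Tensor:
        return self.cls + self.reg + self.center

    def as_floats(self) -> dict[str, float]:
        return {"Lcls": self.cls.item(), "Lreg": self.reg.item(),
                "Lcenter": self.center.item(),
                "Ltotal": self.cls.item() + self.reg.item() + self.center.item()}


_EPS = 1e-7


def focal_loss(cls_logits: Tensor, labels: np.ndarray, npos: int,
               alpha: float = 0.25, gamma: float = 2.0) -> Tensor:
    """Sigmoid focal loss summed over locations/classes, divided by Npos.

    ``cls_logits`` is (L, C); ``labels`` holds -1 for background.  With no
    positives the sum is normalized by 1, so empty images stay finite.
    """
    n, c = cls_logits.shape
    onehot = np.zeros((n, c), dtype=np.float32)
    pos = labels >= 0
    onehot[np.flatnonzero(pos), labels[pos]] = 1.0
    y = Tensor(onehot)
    p = cls_logits.sigmoid()
    p = p.clip_min(_EPS)
    q = (1.0 - p).clip_min(_EPS)
    pos_term = y * q.pow(gamma) * p.log() * (-alpha)
    neg_term = (1.0 - y) * p.pow(gamma) * q.log() * (alpha - 1.0)
    return (pos_term + neg_term).sum() * (1.0 / max(npos, 1))


def _dist_iou(pred: Tensor, target: np.ndarray) -> Tensor:
    """IoU between boxes decoded from distances at a shared location."""
    tgt = Tensor(target.astype(np.float32))
    pl, pt, pr, pb = (pred[:, i] for i in range(4))
    tl, tt, tr, tb = (tgt[:, i] for i in range(4))
    area_p = (pl + pr) * (pt + pb)
    area_t = (tl + tr) * (tt + tb)
    iw = pl.minimum(tl) + pr.minimum(tr)
    ih = pt.minimum(tt) + pb.minimum(tb)
    inter = iw * ih
    union = area_p + area_t - inter
    return inter / union.clip_min(1e-12)


def iou_loss(pred_dists: Tensor, target_dists: np.ndarray) -> Tensor:
    """−ln IoU averaged over positive locations (clamped below at 1e−6)."""
    n = pred_dists.shape[0]
    if n == 0:
        return Tensor(0.0)
    iou = _dist_iou(pred_dists, target_dists).clip_min(1e-6)
    return -(iou.log().sum()) * (1.0 / n)


def centerness_loss(pred_logits: Tensor, targets: np.ndarray) -> Tensor:
    """Binary cross-entropy against continuous centerness targets."""
    n = pred_logits.shape[0]
    if n == 0:
        return Tensor(0.0)
    y = Tensor(targets.astype(np.float32))
    p = pred_logits.sigmoid().clip_min(_EPS)
    q = (1.0 - pred_logits.sigmoid()).clip_min(_EPS)
    return -((y * p.log() + (1.0 - y) * q.log()).sum()) * (1.0 / n)


def _flatten_outputs(outputs: list[dict], num_classes: int):
    cls = concat([o["cls"].transpose(0, 2, 3, 1).reshape(-1, num_classes)
                  for o in outputs], axis=0)
    reg = concat([o["reg"].transpose(0, 2, 3, 1).reshape(-1, 4)
                  for o in outputs], axis=0)
    ctr = concat([o["ctr"].transpose(0, 2, 3, 1).reshape(-1)
                  for o in outputs], axis=0)
    return cls, reg, ctr


def total_loss(outputs: list[dict], assignment: TargetAssignment,
               num_classes: int, use_sampler: bool = False,
               sampler_size: int = 256, sampler_rng=None) -> LossBundle:
    """Composite loss over one image's head outputs.

    With ``use_sampler`` the classification term is computed on a fixed-size
    sample of locations at a 1:1 positive:negative ratio instead of over all
    locations (the optional sampling rule; focal-over-all is the default).
    """
    cls, reg, ctr = _flatten_outputs(outputs, num_classes)
    labels = assignment.labels
    npos = assignment.npos
    if use_sampler:
        rng = sampler_rng or np.random.default_rng(0)
        pos_idx = np.flatnonzero(labels >= 0)
        neg_idx = np.flatnonzero(labels < 0)
        k = sampler_size // 2
        pos_take = rng.permutation(pos_idx)[:k]
        neg_take = rng.permutation(neg_idx)[:max(sampler_size - len(pos_take),
                                                 len(pos_take))][:sampler_size - len(pos_take)]
        take = np.concatenate([pos_take, neg_take])
        l_cls = focal_loss(cls[take], labels[take], max(len(pos_take), 1))
    else:
        l_cls = focal_loss(cls, labels, npos)
    pos = np.flatnonzero(labels >= 0)
    if len(pos):
        pred_dists = reg[pos].exp()
        l_reg = iou_loss(pred_dists, assignment.bbox_targets[pos])
        l_ctr = centerness_loss(ctr[pos], assignment.centerness[pos])
    else:
        l_reg = Tensor(0.0)
        l_ctr = Tensor(0.0)
    return LossBundle(cls=l_cls, reg=l_reg, center=l_ctr)


# ---------------------------------------------------------------------------
# decoding


@dataclass
class DetectionSet:
    boxes: np.ndarray      # (D, 4), continuous coordinates, image-clipped
    scores: np.ndarray     # (D,) descending
    class_ids: np.ndarray  # (D,)

    def __len__(self):
        return len(self.scores)

    @classmethod
    def empty(cls):
        return cls(np.zeros((0, 4)), np.zeros(0), np.zeros(0, dtype=int))


def decode_and_nms(outputs: list[dict], shapes: list[tuple[int, int]],
                   strides: tuple[int, ...], image_size: tuple[int, int],
                   score_thr: float = 0.025, nms_iou: float = 0.5,
                   max_dets: int = 100, pre_nms_top: int = 1000
                   ) -> DetectionSet:
    """Decode distances into boxes and run class-wise NMS.

    Ranking score = classification probability × centerness probability;
    boxes are clipped to ``image_size`` = (width, height).
    """
    w_img, h_img = image_size
    all_boxes, all_scores, all_cls = [], [], []
    for out, (h, w), s in zip(outputs, shapes, strides):
        cls = np.asarray(out["cls"].data if isinstance(out["cls"], Tensor)
                         else out["cls"])
        regd = np.asarray(out["reg"].data if isinstance(out["reg"], Tensor)
                          else out["reg"])
        ctrd = np.asarray(out["ctr"].data if isinstance(out["ctr"], Tensor)
                          else out["ctr"])
        nc = cls.shape[1]
        scores = _sigmoid(cls[0].transpose(1, 2, 0).reshape(-1, nc))
        ctr_p = _sigmoid(ctrd[0].reshape(-1))
        dists = np.exp(regd[0].transpose(1, 2, 0).reshape(-1, 4))
        ys, xs = np.mgrid[0:h, 0:w]
        px = (xs.ravel() + 0.5) * s
        py = (ys.ravel() + 0.5) * s
        ranked = scores * ctr_p[:, None]
        flat = ranked.ravel()
        if len(flat) > pre_nms_top:
            top = np.argpartition(-flat, pre_nms_top)[:pre_nms_top]
        else:
            top = np.arange(len(flat))
        loc, cid = np.divmod(top, nc)
        keep = flat[top] > score_thr
        loc, cid, sc = loc[keep], cid[keep], flat[top][keep]
        boxes = np.stack([px[loc] - dists[loc, 0], py[loc] - dists[loc, 1],
                          px[loc] + dists[loc, 2], py[loc] + dists[loc, 3]],
                         axis=1)
        boxes[:, 0::2] = np.clip(boxes[:, 0::2], 0, w_img)
        boxes[:, 1::2] = np.clip(boxes[:, 1::2], 0, h_img)
        all_boxes.append(boxes)
        all_scores.append(sc)
        all_cls.append(cid)
    boxes = np.concatenate(all_boxes) if all_boxes else np.zeros((0, 4))
    scores = np.concatenate(all_scores) if all_scores else np.zeros(0)
    cids = np.concatenate(all_cls) if all_cls else np.zeros(0, dtype=int)
    keep_idx = []
    for c in np.unique(cids):
        mask = np.flatnonzero(cids == c)
        kept = nms(boxes[mask], scores[mask], nms_iou)
        keep_idx.append(mask[kept])
    if keep_idx:
        keep_idx = np.concatenate(keep_idx)
    else:
        keep_idx = np.zeros(0, dtype=int)
    order = keep_idx[np.argsort(-scores[keep_idx], kind="stable")][:max_dets]
    return DetectionSet(boxes=boxes[order], scores=scores[order],
                        class_ids=cids[order])


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
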