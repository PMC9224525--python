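"""Detection metrics: IoU matching, PR curves, the AP family, mRecall and
the efficiency indices.

AP follows the COCO-style protocol: greedy per-image matching in score
order, the precision envelope sampled at 101 recall points, averaging over
IoU thresholds 0.50:0.05:0.95 for mAP, with small/medium area splits at
32² and 96² pixels.  mRecall is the mean over classes of the maximum recall
reached at IoU 0.5 with at most ``max_dets`` retained detections per image.

The efficiency indices divide AP50 *as a fraction* by the per-iteration
training time or per-image testing time, reported in %/s to two decimals —
e.g. AP50 = 71.6% at 0.045 s/img gives P_testing = 0.716/0.045 = 15.91.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .head import DetectionSet, pairwise_iou

__all__ = ["MatchResult", "MetricsReport", "EfficiencyIndex",
           "match_detections", "pr_curve", "average_precision", "summarize",
           "efficiency_index", "IOU_THRESHOLDS"]

IOU_THRESHOLDS = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))
AREA_SMALL = (0.0, 32.0**2)
AREA_MEDIUM = (32.0**2, 96.0**2)


@dataclass
class MatchResult:
    tp: np.ndarray            # per detection, score order
    matched_gt: np.ndarray    # per ground truth
    ignored_det: np.ndarray   # detections excluded from TP/FP accounting

    @property
    def n_tp(self) -> int:
        return int(self.tp.sum())

    @property
    def n_fp(self) -> int:
        return int(((~self.tp) & (~self.ignored_det)).sum())

    @property
    def n_fn(self) -> int:
        return int((~self.matched_gt).sum())


def match_detections(detections: DetectionSet, truth_boxes: np.ndarray,
                     truth_labels: np.ndarray, iou_thr: float,
                     class_id: int | None = None,
                     gt_ignore: np.ndarray | None = None) -> MatchResult:
    """Greedy matching in descending score order.

    A detection is a true positive when its best-IoU unmatched same-class
    ground truth reaches ``iou_thr``.  Ground truths flagged in
    ``gt_ignore`` may absorb detections without contributing TP or FP
    (the area-range convention).
    """
    boxes, scores, cids = detections.boxes, detections.scores, detections.class_ids
    if class_id is not None:
        sel = cids == class_id
        boxes, scores = boxes[sel], scores[sel]
        gsel = truth_labels == class_id
        truth_boxes = truth_boxes[gsel]
        gt_ignore = gt_ignore[gsel] if gt_ignore is not None else None
    if gt_ignore is None:
        gt_ignore = np.zeros(len(truth_boxes), dtype=bool)
    order = np.argsort(-scores, kind="stable")
    tp = np.zeros(len(boxes), dtype=bool)
    ignored = np.zeros(len(boxes), dtype=bool)
    matched = np.zeros(len(truth_boxes), dtype=bool)
    ious = pairwise_iou(boxes, truth_boxes)
    for i in order:
        best_j, best_iou, best_ignored = -1, iou_thr, False
        for j in range(len(truth_boxes)):
            if matched[j]:
                continue
            # prefer real ground truths over ignored ones at equal validity
            if ious[i, j] >= best_iou:
                if best_j >= 0 and not best_ignored and gt_ignore[j]:
                    continue
                best_j, best_iou, best_ignored = j, ious[i, j], bool(gt_ignore[j])
        if best_j >= 0:
            matched[best_j] = True
            if best_ignored:
                ignored[i] = True
            else:
                tp[i] = True
    return MatchResult(tp=tp[order], matched_gt=matched[~gt_ignore],
                       ignored_det=ignored[order])


def pr_curve(scores: np.ndarray, tp: np.ndarray, n_gt: int):
    """Cumulative precision/recall along the score-sorted detection list.

    With no detections the curve is the single conventional point
    (precision 1, recall 0).  Zero ground truths make recall undefined.
    """
    if n_gt <= 0:
        raise ValueError("recall undefined without ground truths")
    order = np.argsort(-scores, kind="stable")
    tp = np.asarray(tp, dtype=float)[order]
    if len(tp) == 0:
        return np.array([1.0]), np.array([0.0])
    ctp = np.cumsum(tp)
    cfp = np.cumsum(1.0 - tp)
    precision = ctp / (ctp + cfp)
    recall = ctp / n_gt
    return precision, recall


def average_precision(precision: np.ndarray, recall: np.ndarray) -> float:
    """101-point interpolated AP (precision envelope at recall 0.00:0.01:1)."""
    if len(precision) == 0:
        return 0.0
    # envelope: best precision at recall >= r
    order = np.argsort(recall, kind="stable")
    rec = np.asarray(recall)[order]
    prec = np.asarray(precision)[order]
    env = np.maximum.accumulate(prec[::-1])[::-1]
    samples = np.linspace(0.0, 1.0, 101)
    idx = np.searchsorted(rec, samples, side="left")
    vals = np.where(idx < len(rec), env[np.minimum(idx, len(rec) - 1)], 0.0)
    return float(vals.mean())


def _area(boxes: np.ndarray) -> np.ndarray:
    return np.clip(boxes[:, 2] - boxes[:, 0], 0, None) * \
        np.clip(boxes[:, 3] - boxes[:, 1], 0, None)


def _class_eval(detections: list[DetectionSet], truths: list[tuple],
                class_id: int, iou_thr: float, max_dets: int,
                area_range: tuple[float, float] | None = None):
    """Score-sorted TP flags and ground-truth count for one class."""
    all_scores, all_tp = [], []
    n_gt = 0
    for det, (gboxes, glabels) in zip(detections, truths):
        det = DetectionSet(det.boxes[:max_dets], det.scores[:max_dets],
                           det.class_ids[:max_dets])
        gsel = np.asarray(glabels) == class_id
        gb = np.asarray(gboxes, dtype=float).reshape(-1, 4)[gsel]
        ignore = np.zeros(len(gb), dtype=bool)
        if area_range is not None and len(gb):
            a = _area(gb)
            ignore = ~((a > area_range[0]) & (a <= area_range[1]))
        res = match_detections(det, gb, np.full(len(gb), class_id),
                               iou_thr, class_id=class_id, gt_ignore=ignore)
        n_gt += int((~ignore).sum())
        sel = det.class_ids == class_id
        scores = det.scores[sel]
        order = np.argsort(-scores, kind="stable")
        keep = ~res.ignored_det
        if area_range is not None:
            dareas = _area(det.boxes[sel][order])
            out_of_range = ~((dareas > area_range[0]) & (dareas <= area_range[1]))
            # unmatched detections outside the range do not count as FP
            keep &= res.tp | ~out_of_range
        all_scores.append(scores[order][keep])
        all_tp.append(res.tp[keep])
    scores = np.concatenate(all_scores) if all_scores else np.zeros(0)
    tp = np.concatenate(all_tp) if all_tp else np.zeros(0, dtype=bool)
    return scores, tp, n_gt


@dataclass
class MetricsReport:
    ap_per_class: dict          # {class_id: {iou_thr: AP}}
    mAP: float
    AP50: float
    AP75: float
    APs: float
    APm: float
    mRecall: float
    pr_curves: dict = field(default_factory=dict)   # {class_id: (P, R)} at 0.5

    def as_percent(self) -> dict[str, float]:
        return {k: round(100.0 * getattr(self, k), 1)
                for k in ("mAP", "AP50", "AP75", "APs", "APm", "mRecall")}


def summarize(detections: list[DetectionSet], truths: list[tuple],
              num_classes: int, max_dets: int = 100) -> MetricsReport:
    """Dataset-level metrics; classes without ground truth are excluded."""
    if len(detections) != len(truths):
        raise ValueError("detections/truths length mismatch")
    classes_present = [c for c in range(num_classes)
                       if any((np.asarray(t[1]) == c).any() for t in truths if len(t[1]))]
    ap_per_class: dict = {}
    pr_curves = {}
    recalls50 = {}
    aps_small, aps_medium = [], []
    for c in classes_present:
        ap_per_class[c] = {}
        for thr in IOU_THRESHOLDS:
            scores, tp, n_gt = _class_eval(detections, truths, c, thr, max_dets)
            p, r = pr_curve(scores, tp, n_gt)
            ap_per_class[c][thr] = average_precision(p, r)
            if abs(thr - 0.5) < 1e-9:
                pr_curves[c] = (p, r)
                recalls50[c] = float(r.max()) if len(r) else 0.0
        s_aps, m_aps = [], []
        for thr in IOU_THRESHOLDS:
            for rng, bucket in ((AREA_SMALL, s_aps), (AREA_MEDIUM, m_aps)):
                scores, tp, n_gt = _class_eval(detections, truths, c, thr,
                                               max_dets, area_range=rng)
                if n_gt > 0:
                    bucket.append(average_precision(*pr_curve(scores, tp, n_gt)))
        if s_aps:
            aps_small.append(float(np.mean(s_aps)))
        if m_aps:
            aps_medium.append(float(np.mean(m_aps)))
    if not classes_present:
        raise ValueError("no ground truth in any class")
    per_class_means = {c: float(np.mean(list(v.values())))
                       for c, v in ap_per_class.items()}
    ap50 = float(np.mean([ap_per_class[c][0.5] for c in classes_present]))
    ap75 = float(np.mean([ap_per_class[c][0.75] for c in classes_present]))
    return MetricsReport(
        ap_per_class=ap_per_class,
        mAP=float(np.mean(list(per_class_means.values()))),
        AP50=ap50,
        AP75=ap75,
        APs=float(np.mean(aps_small)) if aps_small else 0.0,
        APm=float(np.mean(aps_medium)) if aps_medium else 0.0,
        mRecall=float(np.mean(list(recalls50.values()))),
        pr_curves=pr_curves,
    )


@dataclass
class EfficiencyIndex:
    p_training: float | None = None
    p_testing: float | None = None


def efficiency_index(ap50_percent: float,
                     training_time_s_per_iter: float | None = None,
                     testing_time_s_per_img: float | None = None
                     ) -> EfficiencyIndex:
    """AP50 (fraction) over seconds, to two decimals; zero AP gives zero."""
    frac = ap50_percent / 100.0
    out = EfficiencyIndex()
    for name, t in (("p_training", training_time_s_per_iter),
                    ("p_testing", testing_time_s_per_img)):
        if t is None:
            continue
        if t <= 0:
            raise ValueError("time must be positive")
        setattr(out, name, round(frac / t, 2))
    return out
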