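"""Head behavior: assignment rules, loss closed forms, decoding and NMS."""

import math

import numpy as np
import pytest

from tddet.head import (DetectionSet, assign_targets, centerness_loss,
                        centerness_target, decode_and_nms, focal_loss,
                        iou_loss, iou_of, nms, pairwise_iou, scale_ranges_for,
                        total_loss)
from tddet.tensor import Tensor


class TestAssignment:
    STRIDES = (8, 16, 32, 64, 128)

    def shapes(self, h=64, w=64):
        return [(-(-h // s), -(-w // s)) for s in self.STRIDES]

    def test_center_of_lone_box_is_positive_and_symmetric(self):
        # box centered on a stride-8 location, max distance 20 -> level 0
        boxes = np.array([[100.0 - 20, 100.0 - 20, 100 + 20, 100 + 20]])
        asg = assign_targets([(32, 32)], (8,), boxes, np.array([1]),
                             ranges=[(0, 64.0)])
        # location (12.5*8=100, 100) is the exact center
        i = np.flatnonzero((asg.points == [100, 100]).all(axis=1))[0]
        assert asg.labels[i] == 1
        l, t, r, b = asg.bbox_targets[i]
        assert l == r and t == b
        assert asg.centerness[i] == pytest.approx(1.0)

    def test_outside_all_boxes_is_background(self):
        boxes = np.array([[0.0, 0.0, 16.0, 16.0]])
        asg = assign_targets(self.shapes(256, 256), self.STRIDES, boxes,
                             np.array([0]))
        far = (asg.points > 40).all(axis=1)
        assert (asg.labels[far] == -1).all()

    def test_nested_boxes_assign_smaller_area(self):
        big = [0.0, 0.0, 60.0, 60.0]
        small = [16.0, 16.0, 44.0, 44.0]
        boxes = np.array([big, small])
        labels = np.array([0, 1])
        asg = assign_targets([(16, 16)], (8,), boxes, labels,
                             ranges=[(0, 1e8)])
        i = np.flatnonzero((asg.points == [28, 28]).all(axis=1))[0]
        assert asg.labels[i] == 1   # the smaller box wins

    def test_scale_range_moves_large_objects_up_levels(self):
        # max distances inside a 200x200 box span (100, 200], so positives
        # sit on the (64,128] and (128,256] levels only
        boxes = np.array([[0.0, 0.0, 200.0, 200.0]])
        asg = assign_targets(self.shapes(256, 256), self.STRIDES, boxes,
                             np.array([0]))
        lv = set(asg.level_ids[asg.labels >= 0])
        assert lv == {1, 2}
        # the exact center (max distance 100) lands on level 1
        i = np.flatnonzero((np.abs(asg.points - 100) <= 8).all(axis=1)
                           & (asg.level_ids == 1))
        assert (asg.labels[i] >= 0).any()

    def test_empty_annotations_all_background(self):
        asg = assign_targets([(8, 8)], (8,), np.zeros((0, 4)),
                             np.zeros(0, dtype=int))
        assert asg.npos == 0 and (asg.labels == -1).all()

    def test_npos_counts_positives(self):
        boxes = np.array([[0.0, 0.0, 40.0, 40.0]])
        asg = assign_targets([(8, 8)], (8,), boxes, np.array([0]),
                             ranges=[(0, 64.0)])
        assert asg.npos == int((asg.labels >= 0).sum()) > 0


class TestCenterness:
    def test_anchor_values(self):
        assert centerness_target(2, 3, 2, 3) == pytest.approx(1.0)
        assert centerness_target(1, 1, 3, 3) == pytest.approx(1 / 3)
        assert centerness_target(0, 2, 4, 2) == pytest.approx(0.0)

    def test_degenerate_all_zero(self):
        assert centerness_target(0, 0, 0, 0) == 0.0

    def test_bounded_and_maximal_only_at_symmetry(self, rng):
        vals = rng.uniform(0, 10, size=(200, 4))
        c = centerness_target(vals[:, 0], vals[:, 1], vals[:, 2], vals[:, 3])
        assert ((c >= 0) & (c <= 1)).all()
        sym = np.isclose(vals[:, 0], vals[:, 2]) & \
            np.isclose(vals[:, 1], vals[:, 3])
        assert np.allclose(c[np.isclose(c, 1.0)], 1.0)
        assert (c[~sym] < 1.0).all()


class TestLosses:
    def test_focal_closed_form_at_half(self):
        """One positive location with p_t = 0.5."""
        logit = np.zeros((1, 1), np.float32)        # sigmoid -> 0.5
        loss = focal_loss(Tensor(logit), np.array([0]), npos=1)
        assert loss.item() == pytest.approx(0.25 * 0.25 * math.log(2), rel=1e-4)

    def test_focal_vanishes_for_confident_correct(self):
        logits = np.full((3, 2), -20.0, np.float32)
        logits[0, 1] = 20.0
        loss = focal_loss(Tensor(logits), np.array([1, -1, -1]), npos=1)
        assert loss.item() < 1e-6

    def test_focal_reduces_to_cross_entropy(self):
        logit = np.array([[0.4]], np.float32)
        loss = focal_loss(Tensor(logit), np.array([0]), npos=1,
                          alpha=1.0, gamma=0.0)
        p = 1 / (1 + math.exp(-0.4))
        assert loss.item() == pytest.approx(-math.log(p), rel=1e-5)

    def test_focal_no_positives_stays_finite(self):
        logits = np.zeros((4, 2), np.float32)
        loss = focal_loss(Tensor(logits), np.full(4, -1), npos=0)
        assert np.isfinite(loss.item()) and loss.item() > 0

    def test_iou_loss_zero_at_perfect(self):
        d = np.array([[3.0, 4.0, 5.0, 6.0]], np.float32)
        assert iou_loss(Tensor(d), d).item() == pytest.approx(0.0, abs=1e-6)

    def test_iou_loss_third_overlap(self):
        # two distance boxes around one location with IoU exactly 1/3
        pred = np.array([[10.0, 10.0, 0.0001, 10.0]], np.float32)
        # same height; horizontal shift gives intersection 5, union 15
        pred = np.array([[10.0, 5.0, 0.0, 5.0]], np.float32)
        tgt = np.array([[5.0, 5.0, 5.0, 5.0]], np.float32)
        loss = iou_loss(Tensor(pred), tgt)
        assert loss.item() == pytest.approx(-math.log(1 / 3), rel=1e-4)

    def test_iou_loss_monotone_along_interpolation(self):
        start = np.array([[2.0, 2.0, 8.0, 8.0]], np.float32)
        target = np.array([[5.0, 5.0, 5.0, 5.0]], np.float32)
        prev = np.inf
        for a in np.linspace(0, 0.95, 12):
            cur = iou_loss(Tensor(start + a * (target - start)), target).item()
            assert cur < prev + 1e-9
            prev = cur

    def test_centerness_bce_values(self):
        logits = Tensor(np.array([0.0], np.float32))
        loss = centerness_loss(logits, np.array([1.0]))
        assert loss.item() == pytest.approx(math.log(2), rel=1e-5)
        exact = centerness_loss(Tensor(np.array([40.0], np.float32)),
                                np.array([1.0]))
        assert exact.item() == pytest.approx(0.0, abs=1e-5)

    def test_centerness_entropy_lower_bound(self, rng):
        targets = rng.uniform(0, 1, size=8)
        ent = -(targets * np.log(targets + 1e-12)
                + (1 - targets) * np.log(1 - targets + 1e-12)).mean()
        for _ in range(10):
            logits = Tensor(rng.normal(size=8).astype(np.float32))
            assert centerness_loss(logits, targets).item() >= ent - 1e-5


class TestIoU:
    def test_identical_boxes(self):
        assert iou_of((0, 0, 10, 10), (0, 0, 10, 10)) == 1.0

    def test_disjoint_boxes(self):
        assert iou_of((0, 0, 10, 10), (20, 0, 30, 10)) == 0.0

    def test_third_overlap(self):
        assert iou_of((0, 0, 10, 10), (5, 0, 15, 10)) == pytest.approx(1 / 3)

    def test_degenerate_box(self):
        assert iou_of((0, 0, 0, 10), (0, 0, 10, 10)) == 0.0

    def test_symmetry_and_rasterization_oracle(self, rng):
        for _ in range(30):
            a = np.sort(rng.integers(0, 40, size=4).astype(float))
            b = np.sort(rng.integers(0, 40, size=4).astype(float))
            boxa = (a[0], a[1], a[2] + 1, a[3] + 1)
            boxb = (b[0], b[1], b[2] + 1, b[3] + 1)
            assert iou_of(boxa, boxb) == pytest.approx(iou_of(boxb, boxa))
            # pixel-set oracle on integer boxes
            grid = np.zeros((50, 50, 2), bool)
            for k, bx in enumerate((boxa, boxb)):
                grid[int(bx[1]):int(bx[3]), int(bx[0]):int(bx[2]), k] = True
            inter = (grid[..., 0] & grid[..., 1]).sum()
            union = (grid[..., 0] | grid[..., 1]).sum()
            oracle = inter / union if union else 0.0
            assert abs(iou_of(boxa, boxb) - oracle) < 1e-3


def brute_force_nms(boxes, scores, thr):
    """O(n^2) reference: keep a box iff no higher-scored kept box overlaps."""
    order = np.argsort(-scores, kind="stable")
    kept = []
    for i in order:
        if all(iou_of(boxes[i], boxes[j]) <= thr for j in kept):
            kept.append(i)
    return np.array(kept, dtype=int)


class TestDecodeNMS:
    def test_nms_matches_brute_force_on_random_instances(self, rng):
        for trial in range(200):
            n = int(rng.integers(1, 21))
            xy = rng.uniform(0, 80, size=(n, 2))
            wh = rng.uniform(2, 30, size=(n, 2))
            boxes = np.concatenate([xy, xy + wh], axis=1)
            scores = rng.uniform(0, 1, size=n)
            got = nms(boxes, scores, 0.5)
            want = brute_force_nms(boxes, scores, 0.5)
            np.testing.assert_array_equal(np.sort(got), np.sort(want))

    def test_two_identical_boxes_keep_one(self):
        boxes = np.array([[0, 0, 10, 10], [0, 0, 10, 10]], float)
        keep = nms(boxes, np.array([0.9, 0.8]), 0.5)
        assert list(keep) == [0]

    def test_single_strong_location_decodes_its_box(self):
        h = w = 4
        cls = np.full((1, 1, h, w), -20.0, np.float32)
        ctr = np.full((1, 1, h, w), -20.0, np.float32)
        reg = np.zeros((1, 4, h, w), np.float32)
        cls[0, 0, 1, 2] = 12.0
        ctr[0, 0, 1, 2] = 12.0
        reg[0, :, 1, 2] = np.log([4.0, 4.0, 6.0, 6.0])
        out = [{"cls": cls, "reg": reg, "ctr": ctr}]
        det = decode_and_nms(out, [(h, w)], (8,), (64, 64), score_thr=0.05)
        assert len(det) == 1
        # location center is ((2+0.5)*8, (1+0.5)*8) = (20, 12)
        np.testing.assert_allclose(det.boxes[0], [16, 8, 26, 18], atol=1e-5)

    def test_detection_set_sorted_descending(self, rng):
        h = w = 8
        cls = rng.normal(size=(1, 2, h, w)).astype(np.float32)
        reg = rng.normal(scale=0.2, size=(1, 4, h, w)).astype(np.float32)
        ctr = rng.normal(size=(1, 1, h, w)).astype(np.float32)
        det = decode_and_nms([{"cls": cls, "reg": reg, "ctr": ctr}],
                             [(h, w)], (8,), (64, 64), score_thr=0.0)
        assert (np.diff(det.scores) <= 1e-9).all()
        assert det.boxes[:, 0::2].max() <= 64 and det.boxes[:, 1::2].max() <= 64


class TestTotalLoss:
    def _toy_outputs(self, rng, h=8, w=8, c=2):
        return [{"cls": Tensor(rng.normal(size=(1, c, h, w)).astype(np.float32)),
                 "reg": Tensor(rng.normal(scale=0.3, size=(1, 4, h, w)).astype(np.float32)),
                 "ctr": Tensor(rng.normal(size=(1, 1, h, w)).astype(np.float32))}]

    def test_additivity_is_exact(self, rng):
        outs = self._toy_outputs(rng)
        boxes = np.array([[8.0, 8.0, 40.0, 40.0]])
        asg = assign_targets([(8, 8)], (8,), boxes, np.array([1]),
                             ranges=[(0, 64.0)])
        bundle = total_loss(outs, asg, num_classes=2)
        f = bundle.as_floats()
        assert f["Ltotal"] == pytest.approx(
            f["Lcls"] + f["Lreg"] + f["Lcenter"], rel=1e-7)

    def test_zero_object_image_finite(self, rng):
        outs = self._toy_outputs(rng)
        asg = assign_targets([(8, 8)], (8,), np.zeros((0, 4)),
                             np.zeros(0, dtype=int))
        bundle = total_loss(outs, asg, num_classes=2)
        f = bundle.as_floats()
        assert np.isfinite(f["Ltotal"]) and f["Lreg"] == 0 and f["Lcenter"] == 0

    def test_sampler_variant_runs_and_is_finite(self, rng):
        outs = self._toy_outputs(rng)
        boxes = np.array([[8.0, 8.0, 40.0, 40.0]])
        asg = assign_targets([(8, 8)], (8,), boxes, np.array([0]),
                             ranges=[(0, 64.0)])
        bundle = total_loss(outs, asg, num_classes=2, use_sampler=True,
                            sampler_rng=np.random.default_rng(0))
        assert np.isfinite(bundle.as_floats()["Ltotal"])


def test_single_sgd_step_decreases_loss(tiny_detector_factory):
    """Gradient sanity on a one-object synthetic image."""
    from tddet import nn
    from tddet.train import init_weights

    model = tiny_detector_factory("PV")
    init_weights(model, seed=3)
    rng = np.random.default_rng(3)
    img = (rng.uniform(0, 60, size=(96, 96, 3))).astype(np.uint8)
    img[30:50, 40:64] = [200, 60, 40]
    boxes = np.array([[40.0, 30.0, 64.0, 50.0]])
    labels = np.array([0])
    opt = nn.SGD(model.parameters(), lr=0.005, momentum=0.9)
    before, _ = model.loss_for(img, boxes, labels)
    l0 = before.as_floats()["Ltotal"]
    opt.zero_grad()
    before.total.backward()
    opt.step()
    after, _ = model.loss_for(img, boxes, labels)
    assert after.as_floats()["Ltotal"] < l0
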